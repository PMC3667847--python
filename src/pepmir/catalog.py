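"""Published pepper mature miRNA sequences used as realistic fixtures.

A selection from the pepper small-RNA catalog: conserved family members
(miRBase-style names) and novel, pepper-specific matures. The simulator
plants these in synthetic genomes, and the conserved set doubles as a
known-miRNA reference for conservation classification in examples and tests.
"""

CONSERVED_MATURES: dict[str, str] = {
    "can-miR156a-c": "UUGACAGAAGAUAGAGAGCAC",
    "can-miR159a-c": "UUUGGAUUGAAGGGAGCUCUA",
    "can-miR160": "UGCCUGGCUCCCUGUAUGCCA",
    "can-miR162a-e": "UCGAUAAACCUCUGCAUCCAG",
    "can-miR164a-b": "UGGAGAAGCAGGGCACGUGCA",
    "can-miR166a-h": "UCGGACCAGGCUUCAUUCCCC",
    "can-miR167a-c": "UGAAGCUGCCAGCAUGAUCUA",
    "can-miR168a-b": "UCGCUUGGUGCAGGUCGGGAC",
    "can-miR169a-g": "UAGCCAAGGAUGACUUGCCU",
    "can-miR171a-e": "UGAUUGAGCCGUGCCAAUAUC",
    "can-miR172a-d": "AGAAUCUUGAUGAUGCUGCAU",
    "can-miR319a": "CUUGGACUGAAGGGAGCUCCC",
    "can-miR390a-b": "AAGCUCAGGAGGGAUAGCGCC",
    "can-miR394a": "UUGGCAUUCUGUCCACCUCC",
    "can-miR395a-j": "CUGAAGUGUUUGGGGGAACUC",
    "can-miR396a": "UUCCACAGCUUUCUUGAACUG",
    "can-miR397a": "UCAUCUACGCUGCACUCAAUC",
    "can-miR398c": "UAUGUUCUCAGGUCACCCCUA",
    "can-miR403": "UUAGAUUCACGCACAAACUCG",
    "can-miR408a": "UGCACUGCCUCUUCCCUGGCU",
    "can-miR4414b": "AGCUGCUGAAUCAUUGGUUCG",
}

NOVEL_MATURES: dict[str, str] = {
    "can-miR-n001": "UUUCUGUUUUGAUAGUAGGCCU",
    "can-miR-n002a-c": "UUGCAAACACACCUGAAUCGU",
    "can-miR-n003a": "UGUAGUUGUAGCCAUUCUAUU",
    "can-miR-n004": "UAAGAUCGAGCACAAGUUGUU",
    "can-miR-n005": "UUCGAUACGCACCUGAAUCGCC",
    "can-miR-n006": "CAACAAUCAUCCUUUGGGCUUU",
    "can-miR-n007": "UUGAACCUUCAGGUGAGUUGC",
    "can-miR-n010": "UUAUGAGAUAAGUUCAACACG",
    "can-miR-n013": "UUUUAGCAAGAGUUGUUUUCC",
    "can-miR-n014": "CUGAAGUUCGUUACUGUUGUC",
    "can-miR-n017": "CUAAGCAACGCUAUGUCGAGU",
    "can-miR-n023": "AUGACUUACUUUGACUUGGCACA",
    "can-miR-n024": "UCAACUGCAAACCUGUAAGCCU",
    "can-miR-n026": "UGUCACAAUGAACUCCAUCCCA",
    "can-miR-n027": "AUGAAAGUUGUCGAUGCCAAC",
    "can-miR-n029": "UUAGAGUGAGCUCAACAGAGU",
    "can-miR-n031": "UUCCCAGUCCAGGCAUUCCAAC",
    "can-miR-n032": "UGUUCCUGUAGAUAAGCCACU",
    "can-miR-n033": "UAGAGAAAGCAUGGCUUCAGGU",
    "can-miR-n034": "ACGGAUGAACUCGCAGAAGGACGA",
}
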