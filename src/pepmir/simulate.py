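"""Synthetic study generator: planted hairpin genomes, multi-library small-RNA
reads, and target sites of prescribed penalty score.

The generator emulates a plant small-RNA sequencing study: several tissue
libraries of 18-26 nt inserts dominated by the 24 nt and 21 nt size classes
with a 5' U/A bias, miRNA hairpin loci with mature >> star read asymmetry,
random degradation background, ncRNA contamination, and a 3' sequencing
adapter on every read.  Everything is deterministic under a fixed seed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np

from .genome_mapper import build_index, map_tag
from .sequence_io import SequenceRecord, revcomp_rna
from .structure import extract_duplex, fold

logger = logging.getLogger(__name__)

# Illumina small-RNA 3' adapter
DEFAULT_ADAPTER = "TGGAATTCTCGGGTGCCAAGG"

# background length distribution of genome-derived fragments, peaked at 24 nt
# with a secondary 21 nt class, mirroring the canonical siRNA/miRNA profile
LENGTH_WEIGHTS = {
    18: 0.015,
    19: 0.02,
    20: 0.03,
    21: 0.145,
    22: 0.14,
    23: 0.135,
    24: 0.47,
    25: 0.03,
    26: 0.015,
}

VIOLATIONS = (
    "mismatch_count",
    "bulge_size",
    "bulge_count",
    "strand_bias",
)


@dataclass
class PlantedMiRNA:
    """A designed hairpin locus with its ground truth."""

    name: str
    mature: str
    star: str
    precursor: str
    mature_offset: int  # of the mature within the precursor
    violation: str | None = None  # designed rejection reason, None = clean
    antisense_fraction: float = 0.0
    star_ratio: float = 0.08
    # filled by plant_genome:
    contig: str | None = None
    start: int | None = None  # precursor start, 0-based
    strand: str = "+"

    @property
    def mature_locus(self) -> tuple[str, int, int, str] | None:
        """(contig, start, end, strand) of the mature read on the genome."""
        if self.contig is None or self.start is None:
            return None
        L = len(self.mature)
        if self.strand == "+":
            s = self.start + self.mature_offset
        else:
            s = self.start + len(self.precursor) - self.mature_offset - L
        return (self.contig, s, s + L, self.strand)


@dataclass
class SimConfig:
    """Study-level simulation parameters.

    Fractions partition each library's reads: ``degradation_fraction`` +
    ``ncrna_fraction`` + ``low_quality_fraction`` <= 1; the remainder goes to
    planted miRNA loci (mature + star). ``fidelity`` is the probability that
    a mature read starts exactly at the annotated 5' end (the rest are +-1 nt
    isomiR offsets).
    """

    n_libraries: int = 10
    reads_per_library: int = 200_000
    degradation_fraction: float = 0.68
    ncrna_fraction: float = 0.07
    low_quality_fraction: float = 0.01
    fidelity: float = 0.95
    star_ratio: float = 0.08  # star reads per mature read
    five_prime_ua_bias: float = 0.75
    adapter: str = DEFAULT_ADAPTER
    read_length: int = 34
    seed: int = 0

    def __post_init__(self) -> None:
        total = (
            self.degradation_fraction
            + self.ncrna_fraction
            + self.low_quality_fraction
        )
        if total > 1:
            raise ValueError("fractions sum above 1")

    @property
    def library_names(self) -> list[str]:
        return [f"lib{j + 1:02d}" for j in range(self.n_libraries)]


# ---------------------------------------------------------------------------
# hairpin design
# ---------------------------------------------------------------------------

_NO_PAIR = {  # bases that neither Watson-Crick nor wobble pair with the key
    "A": "ACG",
    "C": "AUC",
    "G": "AG",
    "U": "CU",
}


def _random_rna(rng: np.random.Generator, n: int, gc: float = 0.40) -> str:
    p = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    return "".join(rng.choice(list("ACGU"), size=n, p=p))


def _edit_positions(n_edits: int, length: int) -> list[int]:
    """Deterministic, well-separated interior mature positions (0-based)."""
    if n_edits == 0:
        return []
    lo, hi = 3, length - 5
    if n_edits == 1:
        return [(lo + hi) // 2]
    step = (hi - lo) / (n_edits - 1)
    return sorted({round(lo + k * step) for k in range(n_edits)})


def design_hairpin(
    mature: str,
    n_mismatch: int = 0,
    bulges: Sequence[tuple[str, int]] = (),
    loop_len: int = 8,
    flank_len: int = 20,
    seed: int = 0,
    name: str = "hairpin",
    max_attempts: int = 60,
) -> PlantedMiRNA:
    """Construct a precursor whose duplex has the requested defects.

    The star arm starts as the reverse complement of the mature and receives
    the requested edits: ``n_mismatch`` isolated non-pairing substitutions
    and ``bulges`` as (side, size) insertions ('star') or deletions
    ('mature'). The result is re-folded with the built-in folder and the
    designed diagnostics are asserted; random flanks/loops are retried a
    bounded number of times.
    """
    if loop_len < 4:
        raise ValueError("loop_len must be >= 4")
    mature = mature.upper().replace("T", "U")
    L = len(mature)
    rng = np.random.default_rng(seed)
    # mismatches are realized as one contiguous symmetric internal loop
    # (n:n): the star-side run uses a single base that pairs none of the
    # opposing mature bases, so the designed loop cannot re-pair no matter
    # how the rest of the window folds
    runs: list[tuple[int, str]] = []
    if n_mismatch:
        for s0 in range(3, L - 4 - n_mismatch):
            run = mature[s0 : s0 + n_mismatch]
            # the unpaired mature run must not be able to pair internally
            # (minimum hairpin loop 3 permits pairs 4+ apart within the run)
            if any(
                run[j] not in _NO_PAIR[run[i]]
                for i in range(len(run))
                for j in range(i + 4, len(run))
            ):
                continue
            allowed = [x for x in "ACGU" if all(x in _NO_PAIR[c] for c in run)]
            if allowed:
                runs.extend((s0, x) for x in allowed)
        if not runs:
            raise RuntimeError(
                f"no non-pairing internal loop possible for {mature}"
            )
    for attempt in range(max_attempts):
        # the star pairs the mature minus its 2-nt 3' overhang; keeping the
        # duplex imperfectly mirror-symmetric (together with the overhang
        # break in the flanks below) stops the mature/star reads from also
        # matching the opposite strand of their own hairpin
        star = list(revcomp_rna(mature[: L - 2]))
        if n_mismatch:
            s0, base = runs[rng.integers(len(runs))]
            for p in range(s0, s0 + n_mismatch):
                star[L - 3 - p] = base
        # apply bulges at separated interior star coordinates, right to left so
        # earlier insertions/deletions do not shift later ones
        star_seq = "".join(star)
        Ls = len(star_seq)
        if len(bulges) == 1:
            qs = [Ls // 2 + 2]
        else:
            qs = [Ls * (k + 1) // (len(bulges) + 1) for k in range(len(bulges))]
        for (side, size), q in sorted(zip(bulges, qs), key=lambda x: -x[1]):
            if side == "star":
                star_seq = star_seq[:q] + "C" * size + star_seq[q:]
            elif side == "mature":
                star_seq = star_seq[:q] + star_seq[q + size :]
            else:
                raise ValueError(f"bulge side must be mature|star, got {side!r}")
        loop = _random_rna(rng, loop_len)
        # complementary flanks extend the stem below the duplex, anchoring the
        # designed topology as the clearly optimal fold even inside larger
        # genomic windows; the two flank bases forming the star 3' overhang
        # are made non-pairing so the overhang stays single-stranded
        f5 = _random_rna(rng, flank_len, gc=0.6)
        rc5 = revcomp_rna(f5)
        o1 = _NO_PAIR[f5[-1]][rng.integers(len(_NO_PAIR[f5[-1]]))]
        o2 = _NO_PAIR[f5[-2]][rng.integers(len(_NO_PAIR[f5[-2]]))]
        f3 = o1 + o2 + rc5[2:]
        precursor = f5 + mature + loop + star_seq + f3
        offset = flank_len
        st = fold(precursor)
        duplex = extract_duplex(st, (offset, offset + L))
        if duplex is None:
            continue
        want_bulges = sorted((s, z) for s, z in bulges)
        got_bulges = sorted(duplex.bulges)
        if duplex.n_mismatch != n_mismatch or got_bulges != want_bulges:
            continue
        star_lo, star_hi = duplex.star_span
        star_read = precursor[star_lo:star_hi]
        # neither the mature nor the star may match the precursor antisense
        rc_prec = revcomp_rna(precursor)
        if mature in rc_prec or star_read in rc_prec:
            continue
        return PlantedMiRNA(
            name=name,
            mature=mature,
            star=precursor[star_lo:star_hi],
            precursor=precursor,
            mature_offset=offset,
        )
    raise RuntimeError(
        f"could not realize designed hairpin for {name} after {max_attempts} tries"
    )


def design_violating(
    reason: str, rng: np.random.Generator, max_mature_draws: int = 60
) -> PlantedMiRNA:
    """A plant engineered to fail one annotation rule.

    Defective stems are hard to realize for arbitrary sequences (a weakened
    duplex lets the folder find alternative pairings), so the mature itself
    is drawn at random (5' U, like most canonical small RNAs) and re-drawn
    until the designed defect survives folding.
    """
    if reason not in VIOLATIONS:
        raise ValueError(f"unknown violation {reason!r}; one of {VIOLATIONS}")
    for _ in range(max_mature_draws):
        mature = "U" + _random_rna(rng, 20)
        seed = int(rng.integers(2**31))
        try:
            if reason == "mismatch_count":
                plant = design_hairpin(mature, n_mismatch=5, seed=seed)
            elif reason == "bulge_size":
                plant = design_hairpin(mature, bulges=[("star", 3)], seed=seed)
            elif reason == "bulge_count":
                plant = design_hairpin(
                    mature, bulges=[("star", 2), ("mature", 1)], seed=seed
                )
            else:  # strand_bias: a clean hairpin with planted antisense reads
                plant = design_hairpin(mature, seed=seed)
                plant.antisense_fraction = 0.35
        except RuntimeError:
            continue
        plant.violation = reason
        return plant
    raise RuntimeError(f"could not realize a {reason} plant")


# ---------------------------------------------------------------------------
# genome construction
# ---------------------------------------------------------------------------


def make_ncrna_decoys(rng: np.random.Generator, n: int = 4, length: int = 600):
    """Random reference sequences standing in for an rRNA/tRNA exclusion set
    (synthetic; no homology to any real ncRNA is implied)."""
    return [
        SequenceRecord(f"ncrna_decoy_{i + 1}", _random_rna(rng, length))
        for i in range(n)
    ]


def plant_genome(
    n_contigs: int,
    contig_len: int,
    plants: Sequence[PlantedMiRNA],
    seed: int = 0,
    gc: float = 0.40,
    max_attempts: int = 10,
):
    """Random background contigs with precursors inserted at recorded loci.

    Each planted mature is verified to map back to exactly its recorded
    locus (chance duplicates trigger a re-draw of the background). Returns
    (genome records, list of placed PlantedMiRNA with coordinates set).
    """
    rng = np.random.default_rng(seed)
    for attempt in range(max_attempts):
        contigs = {
            f"contig{i + 1}": list(
                _random_rna(rng, contig_len).replace("U", "T")
            )
            for i in range(n_contigs)
        }
        placed: list[PlantedMiRNA] = []
        occupied: dict[str, list[tuple[int, int]]] = {c: [] for c in contigs}
        ok = True
        for plant in plants:
            n = len(plant.precursor)
            for _ in range(200):
                contig = f"contig{rng.integers(n_contigs) + 1}"
                start = int(rng.integers(0, contig_len - n))
                if all(
                    e <= start or s >= start + n
                    for s, e in occupied[contig]
                ):
                    break
            else:
                ok = False
                break
            strand = "+" if rng.random() < 0.5 else "-"
            ins = plant.precursor if strand == "+" else revcomp_rna(plant.precursor)
            contigs[contig][start : start + n] = list(ins.replace("U", "T"))
            occupied[contig].append((start, start + n))
            placed.append(
                replace(plant, contig=contig, start=start, strand=strand)
            )
        if not ok:
            continue
        genome = [
            SequenceRecord(cname, "".join(seq)) for cname, seq in contigs.items()
        ]
        # screen: every planted mature must map back to its truth locus, with
        # any extra hits confined to its own precursor (a perfect duplex makes
        # the mature match the star arm antisense -- that is real hairpin
        # geometry, not a collision)
        index = build_index(genome, seed_len=18)
        clean = True
        for plant in placed:
            hits = map_tag(index, plant.mature, max_loci=25)
            locus = plant.mature_locus
            assert locus is not None
            if hits is None or locus not in [
                (h.contig, h.start, h.end, h.strand) for h in hits
            ]:
                clean = False
                break
            p_lo, p_hi = plant.start, plant.start + len(plant.precursor)
            for h in hits:
                if (h.contig, h.start, h.end, h.strand) == locus:
                    continue
                if not (h.contig == plant.contig and p_lo <= h.start and h.end <= p_hi):
                    clean = False
                    break
            if not clean:
                break
        if clean:
            return genome, placed
    raise RuntimeError("could not build a collision-free planted genome")


# ---------------------------------------------------------------------------
# read simulation
# ---------------------------------------------------------------------------


def _finish_read(insert_dna: str, config: SimConfig, rid: str, qual: int = 40):
    read = (insert_dna + config.adapter)[: config.read_length]
    if len(read) < config.read_length:
        read = read + "A" * (config.read_length - len(read))
    return SequenceRecord(rid, read, chr(qual + 33) * len(read))


def simulate_libraries(
    genome: Sequence[SequenceRecord],
    plants: Sequence[PlantedMiRNA],
    ncrna_refs: Sequence[SequenceRecord],
    config: SimConfig,
) -> dict[str, list[SequenceRecord]]:
    """Multinomial read sampling for every library; returns reads per library.

    Sources per library: planted matures (with +-1 nt offsets at rate
    1-fidelity), stars at ``star_ratio``, antisense mature reads for
    strand-bias designs, degradation fragments from random genome positions
    (length profile peaked at 24 nt, 5' U/A biased), ncRNA fragments, and a
    small low-quality read class removed by the quality filter.
    """
    rng = np.random.default_rng(config.seed)
    contig_seqs = {rec.id: rec.seq.upper().replace("T", "U") for rec in genome}
    contig_names = list(contig_seqs)
    lengths = np.array(sorted(LENGTH_WEIGHTS), dtype=int)
    lweights = np.array([LENGTH_WEIGHTS[l] for l in lengths])
    lweights = lweights / lweights.sum()

    mirna_total = 1.0 - (
        config.degradation_fraction
        + config.ncrna_fraction
        + config.low_quality_fraction
    )
    # per-plant per-library abundance weights, drawn once
    plant_w = rng.uniform(0.7, 1.3, size=(len(plants), config.n_libraries))

    out: dict[str, list[SequenceRecord]] = {}
    for j, lib in enumerate(config.library_names):
        reads: list[SequenceRecord] = []
        n_reads = config.reads_per_library
        n_deg = rng.binomial(n_reads, config.degradation_fraction)
        n_nc = rng.binomial(n_reads, config.ncrna_fraction)
        n_bad = rng.binomial(n_reads, config.low_quality_fraction)
        n_mirna = n_reads - n_deg - n_nc - n_bad
        w = plant_w[:, j]
        alloc = rng.multinomial(n_mirna, w / w.sum()) if len(plants) else []
        k = 0
        for plant, n_p in zip(plants, alloc):
            ratio = plant.star_ratio
            n_star = rng.binomial(n_p, ratio / (1.0 + ratio))
            n_mat = n_p - n_star
            n_anti = (
                rng.binomial(n_mat, plant.antisense_fraction)
                if plant.antisense_fraction
                else 0
            )
            n_mat -= n_anti
            n_shift = rng.binomial(n_mat, 1.0 - config.fidelity)
            n_exact = n_mat - n_shift
            L = len(plant.mature)
            off = plant.mature_offset
            for _ in range(n_exact):
                reads.append(
                    _finish_read(
                        plant.mature.replace("U", "T"), config, f"{lib}_{k}"
                    )
                )
                k += 1
            for _ in range(n_shift):
                d = -1 if rng.random() < 0.5 else 1
                ins = plant.precursor[off + d : off + d + L]
                reads.append(
                    _finish_read(ins.replace("U", "T"), config, f"{lib}_{k}")
                )
                k += 1
            for _ in range(n_anti):
                reads.append(
                    _finish_read(
                        revcomp_rna(plant.mature).replace("U", "T"),
                        config,
                        f"{lib}_{k}",
                    )
                )
                k += 1
            for _ in range(n_star):
                reads.append(
                    _finish_read(plant.star.replace("U", "T"), config, f"{lib}_{k}")
                )
                k += 1
        # degradation fragments
        deg_lens = rng.choice(lengths, size=n_deg, p=lweights)
        for ln in deg_lens:
            for _ in range(10):
                cname = contig_names[rng.integers(len(contig_names))]
                cseq = contig_seqs[cname]
                pos = int(rng.integers(0, len(cseq) - ln))
                frag = cseq[pos : pos + ln]
                if rng.random() < 0.5:
                    frag = revcomp_rna(frag)
                if (
                    rng.random() > config.five_prime_ua_bias
                    or frag[0] in "UA"
                ):
                    break
            reads.append(
                _finish_read(frag.replace("U", "T"), config, f"{lib}_{k}")
            )
            k += 1
        # ncRNA contamination
        for _ in range(n_nc):
            ref = ncrna_refs[rng.integers(len(ncrna_refs))]
            ln = int(rng.choice(lengths, p=lweights))
            pos = int(rng.integers(0, len(ref.seq) - ln))
            frag = ref.seq[pos : pos + ln]
            reads.append(
                _finish_read(frag.replace("U", "T"), config, f"{lib}_{k}")
            )
            k += 1
        # unusable low-quality reads
        for _ in range(n_bad):
            ln = int(rng.choice(lengths, p=lweights))
            reads.append(
                _finish_read(_random_rna(rng, ln).replace("U", "T"),
                             config, f"{lib}_{k}", qual=2)
            )
            k += 1
        out[lib] = reads
    return out


def simulate_study(
    n_clean: int = 30,
    n_violating: int = 10,
    config: SimConfig | None = None,
    n_contigs: int = 4,
    contig_len: int = 50_000,
    mature_pool: dict[str, str] | None = None,
    known_pool: dict[str, str] | None = None,
):
    """One-call study generator used by tests and the CLI.

    Returns (genome, plants, ncrna_refs, reads_per_library, known_refs).
    Clean plants are drawn from the published catalog (conserved first, then
    novel); violating plants cycle through the five designed rejection
    reasons. ``known_refs`` is the conserved catalog as a miRBase-style
    reference for conservation classification.
    """
    from . import catalog

    config = config or SimConfig()
    rng = np.random.default_rng(config.seed)
    if mature_pool is None:
        mature_pool = {**catalog.CONSERVED_MATURES, **catalog.NOVEL_MATURES}
    if known_pool is None:
        known_pool = catalog.CONSERVED_MATURES
    names = list(mature_pool)
    if n_clean + n_violating > len(names):
        raise ValueError("mature pool too small for requested plant count")
    plants: list[PlantedMiRNA] = []
    for i in range(n_clean):
        nm = names[i]
        plants.append(
            design_hairpin(
                mature_pool[nm],
                seed=int(rng.integers(2**31)),
                name=f"clean_{nm}",
            )
        )
    for i in range(n_violating):
        reason = VIOLATIONS[i % len(VIOLATIONS)]
        plant = design_violating(reason, rng)
        plant.name = f"violating_{reason}_{i + 1}"
        plant.violation = reason
        plants.append(plant)
    genome, placed = plant_genome(
        n_contigs, contig_len, plants, seed=int(rng.integers(2**31))
    )
    ncrna_refs = make_ncrna_decoys(rng)
    reads = simulate_libraries(genome, placed, ncrna_refs, config)
    known_refs = [SequenceRecord(k, v) for k, v in known_pool.items()]
    return genome, placed, ncrna_refs, reads, known_refs


# ---------------------------------------------------------------------------
# target-site construction of prescribed score
# ---------------------------------------------------------------------------

_WOBBLE_SITE = {"G": "U", "U": "G"}  # base to place opposite for a G:U pair


def make_target_site(
    mirna: str,
    edits: Sequence[tuple[int, str]],
    seed: int = 0,
) -> tuple[str, float]:
    """Build a site from revcomp(mirna) with edits; return (site, expected S).

    Edits are (miRNA position 1-based, kind) with kind in {mismatch, wobble,
    bulge_t, bulge_m}; at most one bulge in total, positions distinct and
    away from the termini. The expected score is computed analytically from
    the penalty table and the position 2-13 doubling window.
    """
    m = mirna.upper().replace("T", "U")
    L = len(m)
    rng = np.random.default_rng(seed)
    n_bulges = sum(1 for _, kind in edits if kind in ("bulge_t", "bulge_m"))
    if n_bulges > 1:
        raise ValueError("at most one single-nucleotide bulge/gap allowed")
    positions = [p for p, _ in edits]
    if len(set(positions)) != len(positions):
        raise ValueError("edit positions must be distinct")
    if any(not 2 <= p <= L - 1 for p in positions):
        raise ValueError("edit positions must be interior (2..L-1)")
    site = list(revcomp_rna(m))  # site[L-p] is opposite miRNA position p
    expected = 0.0
    insert_at: int | None = None
    insert_base = "C"
    delete_at: int | None = None
    for p, kind in sorted(edits, key=lambda e: -e[0]):
        double = 2.0 if DOUBLE_LO <= p <= DOUBLE_HI else 1.0
        if kind == "mismatch":
            choices = _NO_PAIR[m[p - 1]]
            site[L - p] = choices[rng.integers(len(choices))]
            expected += 1.0 * double
        elif kind == "wobble":
            base = _WOBBLE_SITE.get(m[p - 1])
            if base is None:
                raise ValueError(
                    f"no wobble possible opposite {m[p - 1]} at position {p}"
                )
            site[L - p] = base
            expected += 0.5 * double
        elif kind == "bulge_t":
            # the inserted base must pair neither flanking miRNA base, and
            # the flanks must differ, or the gap could slide to a cheaper
            # (lower-penalty) position and the analytic score would not be
            # the optimum
            m0, m1 = m[p - 1], m[p]
            allowed = [x for x in "ACGU" if x in _NO_PAIR[m0] and x in _NO_PAIR[m1]]
            if m0 == m1 or not allowed:
                raise ValueError(f"bulge_t not realizable at position {p}")
            insert_at = L - p  # between bases opposite positions p and p+1
            insert_base = allowed[int(rng.integers(len(allowed)))]
            expected += 1.0 * double
        elif kind == "bulge_m":
            if m[p - 2] == m[p - 1] or m[p - 1] == m[p]:
                raise ValueError(f"bulge_m not realizable at position {p}")
            delete_at = L - p
            expected += 1.0 * double
        else:
            raise ValueError(f"unknown edit kind {kind!r}")
    if insert_at is not None:
        site.insert(insert_at, insert_base)
    if delete_at is not None:
        del site[delete_at]
    built = "".join(site)
    # construction check: with a gap in play, a designed substitution can
    # sometimes re-pair under a slid alignment; verify the analytic score is
    # actually the optimum by enumerating every one-gap placement
    if _enumerate_min_penalty(m, built) + 1e-9 < expected:
        raise ValueError(
            "edit spec not realizable: an alternative alignment is cheaper"
        )
    return built, expected


_PAIRS_WC = {("A", "U"), ("U", "A"), ("G", "C"), ("C", "G")}
_PAIRS_GU = {("G", "U"), ("U", "G")}


def _enumerate_min_penalty(mirna: str, site: str) -> float:
    """Penalty optimum by direct enumeration of gap placements (generator-side
    validation; independent of the scoring module's dynamic program)."""

    def col(mb: str, tb: str, pos: int) -> float:
        p = 0.0 if (mb, tb) in _PAIRS_WC else 0.5 if (mb, tb) in _PAIRS_GU else 1.0
        return p * (2.0 if DOUBLE_LO <= pos <= DOUBLE_HI else 1.0)

    def gap(pos: int) -> float:
        return 2.0 if DOUBLE_LO <= pos <= DOUBLE_HI else 1.0

    t = site[::-1]
    L, S = len(mirna), len(t)
    if S == L:
        return sum(col(mirna[i], t[i], i + 1) for i in range(L))
    best = float("inf")
    if S == L + 1:
        for g in range(S):
            pen = gap(max(g, 1))
            pen += sum(col(mirna[i], t[i], i + 1) for i in range(g))
            pen += sum(col(mirna[i], t[i + 1], i + 1) for i in range(g, L))
            best = min(best, pen)
    else:
        for g in range(L):
            pen = gap(g + 1)
            pen += sum(col(mirna[i], t[i], i + 1) for i in range(g))
            pen += sum(col(mirna[i], t[i - 1], i + 1) for i in range(g + 1, L))
            best = min(best, pen)
    return best


from .targets import DOUBLE_HI, DOUBLE_LO  # noqa: E402  (shared constants)
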