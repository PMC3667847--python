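"""Folding and duplex geometry: oracle equivalence, consistency, duplex reports."""

import numpy as np
import pytest

from pepmir.sequence_io import revcomp_rna
from pepmir.structure import (
    SecondaryStructure,
    dotbracket_to_pairs,
    extract_duplex,
    fold,
    pairs_to_dotbracket,
    read_vienna,
    validate_structure,
    write_vienna,
)

from .conftest import brute_force_fold_score, random_rna


class TestFold:
    def test_gc_hairpin_example(self):
        st_ = fold("GGGAAAACCC")
        assert st_.dotbracket == "(((....)))"
        assert st_.score == 9

    def test_unpairable_sequence(self):
        st_ = fold("AAAAAAAAAA")
        assert st_.dotbracket == ".........."
        assert st_.score == 0

    def test_deterministic(self):
        seq = "GCGCAAUUAGCUAGGCUAGCUAGGAA"
        a, b = fold(seq), fold(seq)
        assert a.dotbracket == b.dotbracket and a.pairs == b.pairs

    def test_too_short_rejected(self):
        with pytest.raises(ValueError):
            fold("ACGUACGUA")

    def test_n_never_pairs(self):
        st_ = fold("GGGNNNNCCCAAAA")
        assert all(st_.pairs[i] == -1 for i in range(3, 7))

    def test_score_matches_enumeration_oracle(self, rng):
        for _ in range(120):
            n = int(rng.integers(10, 17))
            seq = random_rna(rng, n)
            assert fold(seq).score == brute_force_fold_score(seq), seq

    def test_structure_internally_consistent_on_random_input(self, rng):
        for _ in range(40):
            seq = random_rna(rng, int(rng.integers(20, 80)))
            st_ = fold(seq)
            validate_structure(st_.dotbracket, st_.pairs)  # raises on defect


class TestDotbracket:
    def test_round_trip(self):
        db = "((..((...))..))..."
        assert pairs_to_dotbracket(dotbracket_to_pairs(db)) == db

    @pytest.mark.parametrize("bad", ["((.)", "..)..", "(.x.)"])
    def test_malformed_rejected(self, bad):
        with pytest.raises(ValueError):
            dotbracket_to_pairs(bad)


def _perfect_hairpin(mature, loop="ACAACAUC", flank=12):
    """Precursor with the mature fully paired to its reverse complement."""
    f5 = "GCGAUCGGUCAG"[:flank]
    return f5 + mature + loop + revcomp_rna(mature) + revcomp_rna(f5), len(f5)


class TestExtractDuplex:
    MATURE = "UUGCAAACACACCUGAAUCGU"

    def test_perfect_duplex_no_mismatches(self):
        prec, off = _perfect_hairpin(self.MATURE)
        st_ = fold(prec)
        d = extract_duplex(st_, (off, off + len(self.MATURE)))
        assert d is not None
        assert d.n_mismatch == 0
        assert d.bulges == []
        assert d.mismatch_ratio == 0.0
        assert d.overhang_3p == 2 and d.overhang_5p == 2
        lo, hi = d.star_span
        assert hi - lo == len(self.MATURE)

    def test_designed_mismatches_counted(self):
        from pepmir.simulate import design_hairpin

        plant = design_hairpin(self.MATURE, n_mismatch=3, seed=11)
        st_ = fold(plant.precursor)
        d = extract_duplex(
            st_, (plant.mature_offset, plant.mature_offset + len(self.MATURE))
        )
        assert d.n_mismatch == 3
        assert d.mismatch_ratio == pytest.approx(3 / 21)

    def test_mature_across_loop_is_rejected(self):
        prec, off = _perfect_hairpin(self.MATURE)
        mid = len(prec) // 2
        assert extract_duplex(fold(prec), (mid - 10, mid + 11)) is None

    def test_mature_outside_window_is_error(self):
        prec, off = _perfect_hairpin(self.MATURE)
        with pytest.raises(ValueError):
            extract_duplex(fold(prec), (0, len(prec) + 5))

    def test_unstructured_mature_returns_none(self):
        st_ = fold("A" * 60)
        assert extract_duplex(st_, (10, 31)) is None

    def test_flank_extension_invariance(self):
        # extending flanks that already pair leaves the duplex unchanged
        from pepmir.simulate import design_hairpin

        p20 = design_hairpin(self.MATURE, n_mismatch=2, seed=3, flank_len=20)
        core = p20.precursor[8:-8]  # trim part of the paired flanks
        d_full = extract_duplex(fold(p20.precursor), (20, 41))
        d_core = extract_duplex(fold(core), (12, 33))
        assert d_full.n_mismatch == d_core.n_mismatch
        assert d_full.bulges == d_core.bulges

    def test_high_mismatch_ratio_reported(self):
        # hand-built structure: a duplex with a 7-base unpaired mature run
        mature = "UUGCAAACACACCUGAAUCGU"
        star = revcomp_rna(mature[13:19]) + revcomp_rna(mature[:6])
        prec = mature + "AACA" + star
        pairs = [-1] * len(prec)
        db = ["."] * len(prec)
        for i in list(range(0, 6)) + list(range(13, 19)):
            j = (
                len(prec) - 1 - i
                if i < 6
                else len(mature) + 4 + (18 - i)
            )
            pairs[i], pairs[j] = j, i
            db[i], db[j] = "(", ")"
        st_ = SecondaryStructure(prec, "".join(db), pairs, 0.0)
        d = extract_duplex(st_, (0, len(mature)))
        assert d is not None
        assert d.mismatch_ratio > 0.3


class TestVienna:
    def test_round_trip(self):
        st_ = fold("GGGCAAAAGCCCAUAUGG")
        text = write_vienna([("hp1", st_)])
        (name, parsed), = read_vienna(text)
        assert name == "hp1"
        assert parsed.seq == st_.seq
        assert parsed.dotbracket == st_.dotbracket
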