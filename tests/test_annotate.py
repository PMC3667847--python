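"""Annotation rules: windows, candidate evaluation, families, conservation."""

import pytest

from pepmir.annotate import (
    HairpinCandidate,
    apply_novel_filters,
    candidate_windows,
    classify_conservation,
    group_families,
    select_locus,
    seq_distance,
)
from pepmir.genome_mapper import GenomeHit
from pepmir.sequence_io import SequenceRecord


class TestCandidateWindows:
    HIT = GenomeHit("c1", 5000, 5021, "+")

    def test_full_grid_mid_contig(self):
        wins = candidate_windows(self.HIT, 100_000)
        assert len(wins) == 25
        sizes = {we - ws for ws, we in wins}
        assert max(sizes) == 21 + 1000
        assert min(sizes) == 21 + 200

    def test_clipping_deduplicates(self):
        hit = GenomeHit("c1", 50, 71, "+")
        wins = candidate_windows(hit, 100_000)
        # upstream extents all clip to 50, so only 5 distinct windows remain
        assert len(wins) == 5
        assert all(ws == 0 for ws, we in wins)

    def test_empty_extension_set_rejected(self):
        with pytest.raises(ValueError):
            candidate_windows(self.HIT, 100_000, extensions=())


class TestSelectLocus:
    def _cand(self, star, mism, plen, start):
        from unittest.mock import Mock

        c = Mock(spec=HairpinCandidate)
        c.star = object() if star else None
        c.duplex = Mock(n_mismatch=mism)
        c.precursor = "A" * plen
        c.window = (start, start + plen)
        return c

    def test_single_candidate_identity(self):
        c = self._cand(True, 0, 80, 0)
        assert select_locus([c]) is c

    def test_star_wins_over_fewer_mismatches(self):
        a = self._cand(True, 2, 90, 0)
        b = self._cand(False, 0, 80, 0)
        assert select_locus([a, b]) is a

    def test_tie_broken_by_shortest_then_leftmost(self):
        a = self._cand(True, 1, 90, 10)
        b = self._cand(True, 1, 80, 50)
        c = self._cand(True, 1, 80, 20)
        assert select_locus([a, b, c]) is c

    def test_empty_list_rejected(self):
        with pytest.raises(ValueError):
            select_locus([])


class TestSeqDistance:
    def test_identical(self):
        assert seq_distance("ACGUACGU", "ACGUACGU") == 0

    def test_single_substitution(self):
        assert seq_distance("ACGUACGUA", "ACGAACGUA") == 1

    def test_offset_alignment(self):
        a = "UUGCAAACACACCUGAAUCGU"
        assert seq_distance(a, a[1:] + "A") <= 2  # shifted copy stays close


class TestClassifyConservation:
    REF = [SequenceRecord("mir-x", "UUGCAAACACACCUGAAUCGU")]

    @pytest.mark.parametrize("n_mut, expected", [(0, "conserved"), (1, "conserved"), (2, "conserved"), (3, "novel")])
    def test_mismatch_boundary(self, n_mut, expected):
        seq = list(self.REF[0].seq)
        for i in range(n_mut):
            pos = 2 + 3 * i
            seq[pos] = "G" if seq[pos] != "G" else "C"
        cls, ref = classify_conservation("".join(seq), self.REF)
        assert cls == expected
        assert (ref == "mir-x") == (expected == "conserved")

    def test_length_difference_gate(self):
        cls, _ = classify_conservation("UUGCA", self.REF)
        assert cls == "novel"


def _ann(seq, counts, loci=(), star=True):
    from pepmir.annotate import MiRNAAnnotation

    return MiRNAAnnotation(
        name=seq,
        mature=seq,
        star="A" * len(seq),
        star_observed=star,
        loci=list(loci),
        counts=list(counts),
        libraries=[f"L{i}" for i in range(len(counts))],
    )


class TestGroupFamilies:
    def test_one_mismatch_same_family(self):
        a = _ann("UUGCAAACACACCUGAAUCGU", [100])
        b = _ann("UUGCAAACACACCUGAAUCGA", [50])
        group_families([a, b])
        assert a.family == b.family
        assert a.name.endswith("a") and b.name.endswith("b")

    def test_three_mismatches_different_families(self):
        a = _ann("UUGCAAACACACCUGAAUCGU", [100])
        b = _ann("UUGCAAACACACCAGUAUCGA", [50])
        group_families([a, b])
        assert a.family != b.family

    def test_transitive_closure(self):
        base = "UUGCAAACACACCUGAAUCGU"
        b = base[:5] + "GG" + base[7:]      # 2 from base
        c = b[:12] + "GG" + b[14:]          # 2 from b, 4 from base
        anns = [_ann(base, [9]), _ann(b, [5]), _ann(c, [1])]
        assert seq_distance(base, c) > 2
        group_families(anns)
        assert len({x.family for x in anns}) == 1

    def test_families_numbered_by_abundance(self):
        a = _ann("UUGCAAACACACCUGAAUCGU", [10])
        b = _ann("AGGGAGGCCAGGCAUCCAGGA", [500])
        group_families(anns := [a, b])
        assert b.family.endswith("fam1") and a.family.endswith("fam2")


class TestNovelFilters:
    def test_novel_kept_with_star_and_abundance(self):
        a = _ann("U" * 21, [1500, 10], star=True)
        assert apply_novel_filters([a]) == [a]

    def test_novel_without_star_dropped(self):
        a = _ann("U" * 21, [1500, 10], star=False)
        assert apply_novel_filters([a]) == []

    def test_peak_999_dropped_at_default(self):
        a = _ann("U" * 21, [999, 800], star=True)
        assert apply_novel_filters([a]) == []
        # total mode: 999 + 800 >= 1000 passes
        assert apply_novel_filters([a], per_library=False) == [a]

    def test_conserved_bypass(self):
        a = _ann("U" * 21, [5], star=False)
        a.conservation = "conserved"
        assert apply_novel_filters([a]) == [a]
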