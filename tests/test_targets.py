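"""Position-dependent target penalty scoring and transcript scanning."""

import numpy as np
import pytest

from pepmir.sequence_io import SequenceRecord, revcomp_rna
from pepmir.targets import (
    GAP_M,
    GAP_T,
    GU,
    MISMATCH,
    WC,
    predict_targets,
    render_alignment,
    scan_transcript,
    score_site,
)

from .conftest import brute_force_score, random_rna

MIR_N002 = "UUGCAAACACACCUGAAUCGU"


class TestScoreSite:
    def test_perfect_complement_scores_zero(self):
        aln = score_site(MIR_N002, revcomp_rna(MIR_N002))
        assert aln.score == 0.0
        assert all(s == WC for s in aln.states)

    def test_wobble_outside_seed_half_point(self):
        # G:U opposite miRNA position 15: site base U opposite the G
        m = "UUGCAAACACACCUGAAUCGU"
        assert m[14] == "G"
        site = list(revcomp_rna(m))
        site[len(m) - 15] = "U"
        aln = score_site(m, "".join(site))
        assert aln.score == 0.5
        assert aln.states[14] == GU

    def test_mismatch_in_doubling_window(self):
        site = list(revcomp_rna(MIR_N002))
        site[len(MIR_N002) - 5] = "A"  # opposite position 5 (A): A-A mismatch
        aln = score_site(MIR_N002, "".join(site))
        assert aln.score == 2.0
        assert aln.states[4] == MISMATCH

    def test_target_bulge_outside_window_costs_one(self):
        site = list(revcomp_rna(MIR_N002))
        site.insert(len(MIR_N002) - 16, "C")  # adjacent to miRNA position 16
        aln = score_site(MIR_N002, "".join(site))
        assert aln.score == 1.0
        assert aln.states.count(GAP_T) == 1

    def test_mirna_bulge_is_gap_m(self):
        site = list(revcomp_rna(MIR_N002))
        del site[len(MIR_N002) - 16]  # miRNA position 16 left unpaired
        aln = score_site(MIR_N002, "".join(site))
        assert aln.score == 1.0
        assert aln.states.count(GAP_M) == 1

    def test_site_length_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            score_site(MIR_N002, "ACGU" * 10)

    def test_oracle_equivalence_random_pairs(self, rng):
        for _ in range(2000):
            L = int(rng.integers(18, 25))
            m = random_rna(rng, L)
            S = L + int(rng.integers(-1, 2))
            site = random_rna(rng, S)
            assert score_site(m, site).score == pytest.approx(
                brute_force_score(m, site)
            ), (m, site)

    def test_monotone_under_extra_mismatch(self, rng):
        for _ in range(50):
            m = random_rna(rng, 21)
            site = list(revcomp_rna(m))
            base = score_site(m, "".join(site)).score
            k = int(rng.integers(0, 21))
            site[k] = "A" if site[k] != "A" else "G"
            assert score_site(m, "".join(site)).score >= base

    def test_zero_iff_exact_reverse_complement(self, rng):
        for _ in range(30):
            m = random_rna(rng, 21)
            site = random_rna(rng, 21)
            s = score_site(m, site).score
            assert (s == 0.0) == (site == revcomp_rna(m))


class TestScanTranscript:
    def test_planted_site_found(self, rng):
        m = random_rna(rng, 21)
        site = revcomp_rna(m)
        tr = SequenceRecord("t1", random_rna(rng, 400) + site + random_rna(rng, 400))
        hits = scan_transcript(m, tr, cutoff=0.0)
        assert len(hits) == 1
        assert hits[0].score == 0.0
        assert tr.seq[slice(*hits[0].site_span)] == site

    def test_random_transcript_empty_at_zero_cutoff(self, rng):
        m = random_rna(rng, 21)
        tr = SequenceRecord("t", random_rna(rng, 2000))
        assert scan_transcript(m, tr, cutoff=0.0) == []

    def test_cleavage_position_opposite_position_ten(self, rng):
        m = random_rna(rng, 21)
        start = 100
        tr = SequenceRecord(
            "t", random_rna(rng, start) + revcomp_rna(m) + random_rna(rng, 50)
        )
        (hit,) = scan_transcript(m, tr, cutoff=0.0)
        # site spans [100, 121); miRNA position 10 is opposite 121-10 = 111
        assert hit.cleavage_pos == start + len(m) - 10

    def test_above_cutoff_excluded(self):
        from pepmir.simulate import make_target_site

        site, expected = make_target_site(
            MIR_N002, [(5, "mismatch"), (9, "mismatch"), (15, "wobble")]
        )
        assert expected == 4.5
        tr = SequenceRecord("t", "ACGU" * 30 + site + "ACGU" * 30)
        assert scan_transcript(MIR_N002, tr, cutoff=4.0) == []


class TestPredictTargets:
    def test_empty_transcripts(self):
        table = predict_targets([("m", MIR_N002)], [])
        assert len(table) == 0

    def test_two_disjoint_sites_two_rows(self, rng):
        m = random_rna(rng, 21)
        rc = revcomp_rna(m)
        tr = SequenceRecord(
            "t", random_rna(rng, 60) + rc + random_rna(rng, 60) + rc + random_rna(rng, 60)
        )
        table = predict_targets([("m", m)], [tr], cutoff=0.0)
        assert len(table) == 2

    def test_sorted_by_mirna_then_score(self, rng):
        m1, m2 = random_rna(rng, 21), random_rna(rng, 21)
        trs = [
            SequenceRecord("a", random_rna(rng, 40) + revcomp_rna(m1) + random_rna(rng, 40)),
            SequenceRecord("b", random_rna(rng, 40) + revcomp_rna(m2) + random_rna(rng, 40)),
        ]
        table = predict_targets([("m2", m2), ("m1", m1)], trs, cutoff=1.0)
        assert list(table["miRNA"]) == sorted(table["miRNA"])
        for _, grp in table.groupby("miRNA"):
            assert list(grp["S"]) == sorted(grp["S"])


def test_alignment_rendering_shows_site_five_prime_left():
    aln = score_site(MIR_N002, revcomp_rna(MIR_N002))
    text = render_alignment(aln)
    lines = text.splitlines()
    assert lines[0].startswith("miRNA  3'")
    assert lines[2].startswith("target 5'")
    assert revcomp_rna(MIR_N002) in lines[2]
    assert set(lines[1].strip()) == {"|"}
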