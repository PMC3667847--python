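"""Generator contracts: designed hairpins, planted genomes, read simulation,
and target-site construction round trips."""

import numpy as np
import pytest

from pepmir.genome_mapper import build_index, map_tag
from pepmir.sequence_io import revcomp_rna
from pepmir.simulate import (
    SimConfig,
    design_hairpin,
    design_violating,
    make_target_site,
    plant_genome,
    simulate_libraries,
    simulate_study,
)
from pepmir.structure import extract_duplex, fold
from pepmir.targets import score_site

from .conftest import random_rna

MATURE = "UUGCAAACACACCUGAAUCGU"


class TestDesignHairpin:
    def test_clean_design_has_perfect_duplex(self):
        p = design_hairpin(MATURE, seed=1)
        d = extract_duplex(fold(p.precursor), (p.mature_offset, p.mature_offset + 21))
        assert d.n_mismatch == 0 and d.bulges == []

    def test_mismatch_design_counts(self):
        p = design_hairpin(MATURE, n_mismatch=3, seed=2)
        d = extract_duplex(fold(p.precursor), (p.mature_offset, p.mature_offset + 21))
        assert d.n_mismatch == 3

    def test_bulge_design(self):
        p = design_hairpin(MATURE, bulges=[("star", 3)], seed=3)
        d = extract_duplex(fold(p.precursor), (p.mature_offset, p.mature_offset + 21))
        assert d.bulges == [("star", 3)]

    def test_short_loop_rejected(self):
        with pytest.raises(ValueError):
            design_hairpin(MATURE, loop_len=3)

    def test_star_does_not_match_precursor_antisense(self):
        p = design_hairpin(MATURE, seed=4)
        rc = revcomp_rna(p.precursor)
        assert p.mature not in rc and p.star not in rc

    @pytest.mark.parametrize("reason", ["mismatch_count", "bulge_size", "bulge_count", "strand_bias"])
    def test_violating_designs_realizable(self, reason):
        rng = np.random.default_rng(99)
        plant = design_violating(reason, rng)
        assert plant.violation == reason


class TestPlantGenome:
    def test_planted_matures_map_to_truth(self):
        plants = [
            design_hairpin(MATURE, seed=1, name="p1"),
            design_hairpin("UGGAGAAGCAGGGCACGUGCA", seed=2, name="p2"),
        ]
        genome, placed = plant_genome(2, 8000, plants, seed=5)
        index = build_index(genome, 18)
        for p in placed:
            hits = map_tag(index, p.mature)
            locus = p.mature_locus
            assert locus in [(h.contig, h.start, h.end, h.strand) for h in hits]

    def test_no_plants_no_spurious_loci(self):
        genome, placed = plant_genome(1, 5000, [], seed=1)
        index = build_index(genome, 18)
        assert map_tag(index, MATURE) == []

    def test_same_seed_identical_genome(self):
        plants = [design_hairpin(MATURE, seed=1, name="p")]
        g1, _ = plant_genome(1, 6000, plants, seed=9)
        g2, _ = plant_genome(1, 6000, plants, seed=9)
        assert [r.seq for r in g1] == [r.seq for r in g2]


@pytest.fixture(scope="module")
def mini():
    cfg = SimConfig(n_libraries=2, reads_per_library=8000, seed=11)
    return simulate_study(
        n_clean=3, n_violating=0, config=cfg, n_contigs=1, contig_len=12_000
    ), cfg


class TestSimulateLibraries:
    def test_deterministic_under_seed(self, mini):
        (genome, plants, ncrna, reads, _), cfg = mini
        reads2 = simulate_libraries(genome, plants, ncrna, cfg)
        for lib in reads:
            assert [r.seq for r in reads[lib]] == [r.seq for r in reads2[lib]]

    def test_perfect_fidelity_reads_are_mature_or_star(self):
        cfg = SimConfig(
            n_libraries=1,
            reads_per_library=2000,
            seed=3,
            fidelity=1.0,
            degradation_fraction=0.0,
            ncrna_fraction=0.0,
            low_quality_fraction=0.0,
        )
        genome, plants, ncrna, reads, _ = simulate_study(
            n_clean=2, n_violating=0, config=cfg, n_contigs=1, contig_len=8000
        )
        allowed = {p.mature for p in plants} | {p.star for p in plants}
        from pepmir.sequence_io import trim_adapter

        for rec in reads["lib01"]:
            insert = trim_adapter(rec, cfg.adapter)
            assert insert is not None
            assert insert.seq.replace("T", "U") in allowed

    def test_mature_counts_within_binomial_tolerance(self, mini):
        (genome, plants, ncrna, reads, _), cfg = mini
        mirna_frac = 1.0 - (
            cfg.degradation_fraction + cfg.ncrna_fraction + cfg.low_quality_fraction
        )
        per_plant = mirna_frac * cfg.reads_per_library / len(plants)
        for p in plants:
            n = sum(
                1
                for rec in reads["lib01"]
                if rec.seq.startswith(p.mature.replace("U", "T"))
            )
            # plant weights vary in [0.7, 1.3]; allow that plus 4 sigma
            sd = np.sqrt(per_plant)
            assert 0.6 * per_plant - 4 * sd <= n <= 1.45 * per_plant + 4 * sd


class TestMakeTargetSite:
    def test_no_edits_zero_score(self):
        site, s = make_target_site(MATURE, [])
        assert s == 0.0 and site == revcomp_rna(MATURE)

    @pytest.mark.parametrize(
        "edits, expected",
        [
            ([(5, "mismatch")], 2.0),
            ([(15, "wobble")], 0.5),
            ([(17, "bulge_t")], 1.0),
            ([(8, "bulge_m")], 2.0),
            ([(3, "wobble"), (15, "mismatch")], 2.0),
        ],
    )
    def test_analytic_scores(self, edits, expected):
        site, s = make_target_site(MATURE, edits)
        assert s == expected
        assert score_site(MATURE, site).score == expected

    def test_two_bulges_rejected(self):
        with pytest.raises(ValueError):
            make_target_site(MATURE, [(5, "bulge_t"), (9, "bulge_m")])

    def test_round_trip_random_edit_specs(self, rng):
        kinds = ["mismatch", "wobble", "bulge_t", "bulge_m"]
        done = 0
        while done < 300:
            m = random_rna(rng, int(rng.integers(20, 23)))
            L = len(m)
            n_edits = int(rng.integers(0, 4))
            positions = rng.choice(np.arange(2, L - 1), size=n_edits, replace=False)
            positions = sorted(int(p) for p in positions)
            if any(b - a < 2 for a, b in zip(positions, positions[1:])):
                continue
            edits, bulge_used = [], False
            for p in positions:
                k = kinds[int(rng.integers(len(kinds)))]
                if k == "wobble" and m[p - 1] not in "GU":
                    k = "mismatch"
                if k.startswith("bulge"):
                    if bulge_used:
                        k = "mismatch"
                    else:
                        bulge_used = True
                edits.append((p, k))
            try:
                site, expected = make_target_site(
                    m, edits, seed=int(rng.integers(2**31))
                )
            except ValueError:
                continue  # slide-ambiguous bulge placement: redraw
            assert score_site(m, site).score == pytest.approx(expected), (m, edits)
            done += 1
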