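"""Shared fixtures and independent oracles for the test suite.

The oracles deliberately avoid the implementation's dynamic programs: the
folding oracle enumerates every legal pairing recursively, and the target
scoring oracle enumerates every possible gap placement directly.
"""

from __future__ import annotations

import numpy as np
import pytest

# pair weights mirrored from the folder's contract (GC=3, AU=2, GU=1)
PAIR_WEIGHT = {
    ("G", "C"): 3, ("C", "G"): 3,
    ("A", "U"): 2, ("U", "A"): 2,
    ("G", "U"): 1, ("U", "G"): 1,
}
MIN_LOOP = 3

WC = {("A", "U"), ("U", "A"), ("G", "C"), ("C", "G")}
GUP = {("G", "U"), ("U", "G")}


def brute_force_fold_score(seq: str) -> int:
    """Maximum total pair weight over all non-crossing pairings, by full
    recursive enumeration (exponential; for short sequences only)."""

    def best(i: int, j: int) -> int:
        if j - i <= MIN_LOOP:
            return 0
        # position i unpaired, or paired with any legal k
        score = best(i + 1, j)
        for k in range(i + MIN_LOOP + 1, j + 1):
            w = PAIR_WEIGHT.get((seq[i], seq[k]), 0)
            if w:
                score = max(score, w + best(i + 1, k - 1) + best(k + 1, j))
        return score

    return best(0, len(seq) - 1)


def _column_pen(m: str, t: str, pos: int) -> float:
    if (m, t) in WC:
        p = 0.0
    elif (m, t) in GUP:
        p = 0.5
    else:
        p = 1.0
    return p * (2.0 if 2 <= pos <= 13 else 1.0)


def _gap_pen(pos: int) -> float:
    return 1.0 * (2.0 if 2 <= pos <= 13 else 1.0)


def brute_force_score(mirna: str, site: str) -> float:
    """Minimum penalty over all <=1-gap antiparallel alignments, enumerated
    explicitly by gap position."""
    m = mirna.upper().replace("T", "U")
    t = site.upper().replace("T", "U")[::-1]
    L, S = len(m), len(t)
    if S == L:
        return sum(_column_pen(m[i], t[i], i + 1) for i in range(L))
    best = float("inf")
    if S == L + 1:  # one unpaired target base at t index g
        for g in range(S):
            pen = _gap_pen(max(g, 1))
            pen += sum(_column_pen(m[i], t[i], i + 1) for i in range(g))
            pen += sum(
                _column_pen(m[i], t[i + 1], i + 1) for i in range(g, L)
            )
            best = min(best, pen)
    elif S == L - 1:  # one unpaired miRNA base at index g
        for g in range(L):
            pen = _gap_pen(g + 1)
            pen += sum(_column_pen(m[i], t[i], i + 1) for i in range(g))
            pen += sum(
                _column_pen(m[i], t[i - 1], i + 1) for i in range(g + 1, L)
            )
            best = min(best, pen)
    else:
        raise ValueError("site length outside the one-gap window")
    return best


def random_rna(rng: np.random.Generator, n: int) -> str:
    return "".join(rng.choice(list("ACGU"), size=n))


@pytest.fixture(scope="session")
def rng() -> np.random.Generator:
    return np.random.default_rng(20260922)


@pytest.fixture(scope="session")
def small_study():
    """A small simulated study shared by annotation/pipeline tests."""
    from pepmir.simulate import SimConfig, simulate_study

    config = SimConfig(n_libraries=2, reads_per_library=20_000, seed=7)
    genome, plants, ncrna, reads, known = simulate_study(
        n_clean=6, n_violating=4, config=config, n_contigs=2, contig_len=20_000
    )
    return {
        "config": config,
        "genome": genome,
        "plants": plants,
        "ncrna": ncrna,
        "reads": reads,
        "known": known,
    }


@pytest.fixture(scope="session")
def small_study_result(small_study, tmp_path_factory):
    """Pipeline result on the small study (written to a temp dir)."""
    from pepmir.pipeline import RunConfig, run_pipeline
    from pepmir.sequence_io import write_fasta, write_fastq

    d = tmp_path_factory.mktemp("study")
    write_fasta(small_study["genome"], d / "genome.fasta")
    write_fasta(small_study["ncrna"], d / "ncrna.fasta")
    write_fasta(small_study["known"], d / "known.fasta")
    libs = {}
    for lib, recs in small_study["reads"].items():
        write_fastq(recs, d / f"{lib}.fastq")
        libs[lib] = str(d / f"{lib}.fastq")
    cfg = RunConfig(
        libraries=libs,
        genome=str(d / "genome.fasta"),
        known_mirnas=str(d / "known.fasta"),
        ncrna=str(d / "ncrna.fasta"),
        output_dir=str(d / "out"),
    )
    return run_pipeline(cfg), small_study, cfg
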