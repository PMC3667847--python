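"""miRNA target prediction by position-dependent penalty scoring.

A candidate site (read 5'->3' on the transcript) is aligned antiparallel
against the miRNA (5'->3').  Each column costs: Watson-Crick pair 0, G:U
wobble 0.5, mismatch 1, unpaired base (bulge/gap) 1; the cost is doubled when
the column falls at miRNA positions 2-13 counted from the miRNA 5' end.  At
most one single-nucleotide bulge or gap is allowed in the whole alignment, so
candidate sites are one nucleotide shorter, equal, or one longer than the
miRNA.  Sites scoring <= 4 are putative cleavage targets.

Gap position bookkeeping: an unpaired target base (GAP_T) is charged at the
5'-adjacent miRNA position; an unpaired miRNA base (GAP_M) is charged at the
skipped miRNA position itself.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import pandas as pd

from .sequence_io import SequenceRecord

WC = "WC"
GU = "GU"
MISMATCH = "MISMATCH"
GAP_T = "GAP_T"  # unpaired target base (bulge on the target strand)
GAP_M = "GAP_M"  # unpaired miRNA base (gap in the target)

_WC_PAIRS = {("A", "U"), ("U", "A"), ("G", "C"), ("C", "G")}
_GU_PAIRS = {("G", "U"), ("U", "G")}

DOUBLE_LO, DOUBLE_HI = 2, 13  # 1-based miRNA positions with doubled penalties
DEFAULT_CUTOFF = 4.0

_INF = float("inf")


@dataclass
class TargetAlignment:
    """One miRNA-vs-site alignment.

    ``states`` lists the per-column pair states in miRNA 5'->3' order.
    ``site_span`` is the 0-based half-open transcript interval of the site.
    ``cleavage_pos`` is the transcript coordinate of the base opposite miRNA
    position 10; the scissile bond lies between it and the base opposite
    position 11 (one coordinate upstream on the transcript).
    """

    mirna: str
    transcript_id: str
    site: str
    site_span: tuple[int, int]
    states: list[str]
    score: float
    cleavage_pos: int | None


def _column_state(m: str, t: str) -> str:
    if (m, t) in _WC_PAIRS:
        return WC
    if (m, t) in _GU_PAIRS:
        return GU
    return MISMATCH


def _pen(state: str, pos: int) -> float:
    base = 0.0 if state == WC else 0.5 if state == GU else 1.0
    if DOUBLE_LO <= pos <= DOUBLE_HI:
        base *= 2.0
    return base


def score_site(
    mirna: str, site: str, transcript_id: str = "", site_start: int = 0
) -> TargetAlignment:
    """Minimum-penalty antiparallel alignment of ``mirna`` against ``site``.

    ``site`` is the transcript subsequence 5'->3'; it must be one shorter,
    equal, or one longer than the miRNA (at most one single-nucleotide
    bulge/gap is permitted). Ties are broken deterministically with the gap
    placed leftmost relative to the miRNA 5' end.
    """
    m = mirna.upper().replace("T", "U")
    t = site.upper().replace("T", "U")[::-1]  # antiparallel: walk site 3'->5'
    L, S = len(m), len(t)
    if S not in (L - 1, L, L + 1):
        raise ValueError(
            f"site length {S} outside {{L-1, L, L+1}} for miRNA length {L}"
        )
    # suffix-cost DP over (miRNA consumed, site consumed, gap used); with a
    # single gap allowed, j is confined to {i-1, i, i+1}
    B: dict[tuple[int, int, int], float] = {}
    for i in range(L, -1, -1):
        # j descending: the gap-free cell (i, j, 0) consumes B[(i, j+1, 1)]
        for j in (i + 1, i, i - 1):
            if j < 0 or j > S:
                continue
            for g in (0, 1):
                if i == L and j == S:
                    B[(i, j, g)] = 0.0
                    continue
                best = _INF
                if i < L and j < S:
                    st = _column_state(m[i], t[j])
                    best = _pen(st, i + 1) + B.get((i + 1, j + 1, g), _INF)
                if g == 0 and i < L:
                    v = _pen(GAP_M, i + 1) + B.get((i + 1, j, 1), _INF)
                    best = min(best, v)
                if g == 0 and j < S:
                    v = _pen(GAP_T, max(i, 1)) + B.get((i, j + 1, 1), _INF)
                    best = min(best, v)
                B[(i, j, g)] = best
    total = B[(0, 0, 0)]
    # traceback; trying gap transitions first places the gap leftmost among
    # equal-cost alignments
    states: list[str] = []
    i = j = g = 0
    while i < L or j < S:
        cur = B[(i, j, g)]
        if (
            g == 0
            and j < S
            and _pen(GAP_T, max(i, 1)) + B.get((i, j + 1, 1), _INF) == cur
        ):
            states.append(GAP_T)
            j, g = j + 1, 1
            continue
        if (
            g == 0
            and i < L
            and _pen(GAP_M, i + 1) + B.get((i + 1, j, 1), _INF) == cur
        ):
            states.append(GAP_M)
            i, g = i + 1, 1
            continue
        states.append(_column_state(m[i], t[j]))
        i, j = i + 1, j + 1
    # transcript coordinate opposite miRNA position 10 (1-based)
    cleavage: int | None = None
    mpos = jt = 0
    for st in states:
        if st == GAP_T:
            jt += 1
            continue
        mpos += 1
        if st != GAP_M:
            if mpos == 10:
                cleavage = site_start + (S - 1 - jt)
                break
            jt += 1
    return TargetAlignment(
        mirna=m,
        transcript_id=transcript_id,
        site=site.upper().replace("T", "U"),
        site_span=(site_start, site_start + len(site)),
        states=states,
        score=total,
        cleavage_pos=cleavage,
    )


def scan_transcript(
    mirna: str,
    transcript: SequenceRecord,
    cutoff: float = DEFAULT_CUTOFF,
) -> list[TargetAlignment]:
    """All non-overlapping best sites with score <= cutoff on a transcript.

    Every window of length L-1, L and L+1 is scored; qualifying alignments
    are kept greedily by (score, position), discarding overlaps.
    """
    m = mirna.upper().replace("T", "U")
    L = len(m)
    seq = transcript.seq.upper().replace("T", "U")
    T = len(seq)
    if T < L - 1:
        raise ValueError("transcript shorter than the minimum site length")
    found: list[TargetAlignment] = []
    for wlen in (L - 1, L, L + 1):
        if wlen > T:
            continue
        for start in range(0, T - wlen + 1):
            aln = score_site(m, seq[start : start + wlen], transcript.id, start)
            if aln.score <= cutoff:
                found.append(aln)
    found.sort(key=lambda a: (a.score, a.site_span))
    kept: list[TargetAlignment] = []
    for aln in found:
        s, e = aln.site_span
        if all(e <= k.site_span[0] or s >= k.site_span[1] for k in kept):
            kept.append(aln)
    kept.sort(key=lambda a: (a.score, a.site_span))
    return kept


def render_alignment(aln: TargetAlignment) -> str:
    """Three-line rendering: miRNA 3'->5', pairing symbols, site 5'->3'."""
    sym = {WC: "|", GU: "o", MISMATCH: " ", GAP_T: " ", GAP_M: " "}
    m_line, s_line, t_line = [], [], []
    mi, ti = 0, 0
    t = aln.site[::-1]
    for st in aln.states:
        if st == GAP_M:
            m_line.append(aln.mirna[mi])
            t_line.append("-")
            mi += 1
        elif st == GAP_T:
            m_line.append("-")
            t_line.append(t[ti])
            ti += 1
        else:
            m_line.append(aln.mirna[mi])
            t_line.append(t[ti])
            mi += 1
            ti += 1
        s_line.append(sym[st])
    # flip columns so the site reads 5'->3' left to right
    return "\n".join(
        (
            "miRNA  3' " + "".join(reversed(m_line)) + " 5'",
            "          " + "".join(reversed(s_line)),
            "target 5' " + "".join(reversed(t_line)) + " 3'",
        )
    )


def predict_targets(
    mirnas: Iterable[tuple[str, str]],
    transcripts: Sequence[SequenceRecord],
    cutoff: float = DEFAULT_CUTOFF,
) -> pd.DataFrame:
    """Scan every transcript with every miRNA; tabulate qualifying sites.

    ``mirnas`` yields (name, mature sequence). The result has one row per
    site, sorted by (miRNA, S, target, start).
    """
    rows = []
    for name, seq in mirnas:
        for tr in transcripts:
            if len(tr.seq) < len(seq) - 1:
                continue
            for aln in scan_transcript(seq, tr, cutoff):
                rows.append(
                    {
                        "miRNA": name,
                        "S": aln.score,
                        "target": tr.id,
                        "start": aln.site_span[0],
                        "end": aln.site_span[1],
                        "cleavage_pos": aln.cleavage_pos,
                        "alignment": render_alignment(aln).replace("\n", ";"),
                    }
                )
    df = pd.DataFrame(
        rows,
        columns=["miRNA", "S", "target", "start", "end", "cleavage_pos", "alignment"],
    )
    return df.sort_values(["miRNA", "S", "target", "start"]).reset_index(drop=True)
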