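"""Quality, length and ncRNA-exclusion filters applied ahead of genome mapping.

The filter order is fixed (quality -> adapter -> length -> ncRNA) so that the
per-stage tallies line up with the usual small-RNA funnel report: raw reads,
adapter removed, length selected, rRNA/tRNA removed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

from .sequence_io import SequenceRecord, Tag, normalize_alphabet, revcomp_rna

logger = logging.getLogger(__name__)


@dataclass
class FilterReport:
    """Per-stage accounting of the read/tag funnel.

    ``input_tags == kept_tags + removed_by_quality + removed_by_length +
    removed_by_ncrna`` (quality removal is recorded in read units before
    collapsing, so the identity is enforced on whichever unit each stage saw;
    see the per-library tallies for read-level accounting).
    """

    input_tags: int = 0
    kept_tags: int = 0
    removed_by_quality: int = 0
    removed_by_length: int = 0
    removed_by_ncrna: int = 0
    # per-stage, per-library redundant (read-count weighted) tallies
    library_tallies: dict[str, dict[str, int]] = field(default_factory=dict)

    def check(self) -> None:
        total = (
            self.kept_tags
            + self.removed_by_quality
            + self.removed_by_length
            + self.removed_by_ncrna
        )
        if self.input_tags != total:
            raise AssertionError(
                f"funnel accounting broken: {self.input_tags} != {total}"
            )


def filter_quality(
    records: Sequence[SequenceRecord], min_mean_q: float = 20.0
) -> list[SequenceRecord]:
    """Keep reads whose mean Phred quality is >= ``min_mean_q``.

    Records without qualities pass through unchanged (with a logged warning):
    absent qualities mean the library was delivered as FASTA and the filter
    cannot apply.
    """
    missing = False
    kept = []
    offset_total = 33 * 1.0
    for rec in records:
        q = rec.qual
        if q is None:
            missing = True
            kept.append(rec)
        elif not q:
            kept.append(rec)  # empty sequence: nothing to judge
        elif sum(map(ord, q)) / len(q) - offset_total >= min_mean_q:
            kept.append(rec)
    if missing:
        logger.warning("records without qualities: quality filter skipped for them")
    return kept


def filter_length(
    tags: Sequence[Tag], min_len: int = 18, max_len: int = 26
) -> list[Tag]:
    """Keep tags with min_len <= length <= max_len (defaults 18 and 26 nt)."""
    if not 0 < min_len <= max_len:
        raise ValueError("require 0 < min_len <= max_len")
    return [t for t in tags if min_len <= len(t.seq) <= max_len]


class NcrnaIndex:
    """Exact-substring lookup over an exclusion set (both strands).

    All substrings of the references (and of their reverse complements) whose
    length falls inside the small-RNA size window are enumerated once into a
    set; membership then answers "does this tag occur inside any reference".
    """

    def __init__(
        self,
        refs: Sequence[SequenceRecord],
        min_len: int = 18,
        max_len: int = 26,
    ) -> None:
        self.min_len = min_len
        self.max_len = max_len
        self._substrings: set[str] = set()
        for ref in refs:
            seq = normalize_alphabet(ref.seq) if ref.seq else ""
            for strand_seq in (seq, revcomp_rna(seq)):
                n = len(strand_seq)
                for k in range(min_len, max_len + 1):
                    for i in range(n - k + 1):
                        self._substrings.add(strand_seq[i : i + k])

    def __contains__(self, seq: str) -> bool:
        return seq in self._substrings


def filter_ncrna(
    tags: Sequence[Tag],
    ncrna_refs: Sequence[SequenceRecord],
    index: NcrnaIndex | None = None,
) -> tuple[list[Tag], list[Tag]]:
    """Split tags into (kept, removed): removed iff the tag occurs as an exact
    substring of any reference, on either strand of the reference."""
    if index is None:
        lengths = [len(t.seq) for t in tags]
        if lengths:
            index = NcrnaIndex(ncrna_refs, min(lengths), max(lengths))
        else:
            index = NcrnaIndex(ncrna_refs)
    kept, removed = [], []
    for tag in tags:
        (removed if tag.seq in index else kept).append(tag)
    return kept, removed
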