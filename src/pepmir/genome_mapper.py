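"""Exact-match placement of tags on a contig set, both strands, multi-locus cap.

Matching is performed in DNA space (U is equated with T). The index is a
dictionary over fixed-length seeds (the first ``seed_len`` bases of every
contig position); a lookup extends the seed hit and verifies the full tag, so
its answer equals a naive scan of both strands.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

from .sequence_io import SequenceRecord, Tag, revcomp_dna

logger = logging.getLogger(__name__)


@dataclass(frozen=True, order=True)
class GenomeHit:
    """A perfect-match locus: 0-based half-open [start, end) on ``contig``."""

    contig: str
    start: int
    end: int
    strand: str  # "+" or "-"


class GenomeIndex:
    """Exact-lookup structure over fixed-length seeds of the genome."""

    def __init__(self, genome: Sequence[SequenceRecord], seed_len: int = 18):
        if not genome:
            raise ValueError("empty genome")
        names = [rec.id for rec in genome]
        if len(set(names)) != len(names):
            raise ValueError("duplicate contig names")
        self.seed_len = seed_len
        self.contigs: dict[str, str] = {
            rec.id: rec.seq.upper().replace("U", "T") for rec in genome
        }
        self._seeds: dict[str, list[tuple[str, int]]] = {}
        for name, seq in self.contigs.items():
            for i in range(len(seq) - seed_len + 1):
                seed = seq[i : i + seed_len]
                if "N" in seed:
                    continue
                self._seeds.setdefault(seed, []).append((name, i))

    def lookup(self, dna: str) -> list[tuple[str, int]]:
        """All contig positions where ``dna`` occurs exactly (forward only)."""
        if len(dna) < self.seed_len or "N" in dna:
            return []
        out = []
        for name, i in self._seeds.get(dna[: self.seed_len], ()):
            if self.contigs[name].startswith(dna, i):
                out.append((name, i))
        return out


def build_index(genome: Sequence[SequenceRecord], seed_len: int = 18) -> GenomeIndex:
    return GenomeIndex(genome, seed_len)


def map_tag(
    index: GenomeIndex, tag: Tag | str, max_loci: int = 25
) -> list[GenomeHit] | None:
    """All perfect-match loci of the tag on both strands.

    Returns None (tag discarded, logged) when the number of loci exceeds
    ``max_loci``. Hits are sorted by (contig, start, strand).
    """
    seq = tag.seq if isinstance(tag, Tag) else tag
    dna = seq.upper().replace("U", "T")
    n = len(dna)
    hits = [
        GenomeHit(name, i, i + n, "+") for name, i in index.lookup(dna)
    ] + [
        GenomeHit(name, i, i + n, "-")
        for name, i in index.lookup(revcomp_dna(dna))
    ]
    if len(hits) > max_loci:
        logger.info("tag %s discarded: %d loci > %d", dna, len(hits), max_loci)
        return None
    return sorted(hits)


def hits_to_bed(hits_by_tag: dict[str, list[GenomeHit]]) -> str:
    """Render hits as BED (0-based half-open) text."""
    lines = []
    for name, hits in hits_by_tag.items():
        for h in hits:
            lines.append(f"{h.contig}\t{h.start}\t{h.end}\t{name}\t0\t{h.strand}")
    return "\n".join(lines) + ("\n" if lines else "")
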