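"""Sequence I/O: FASTA/FASTQ reading and writing, adapter trimming, read collapsing.

Reads are handled in DNA space as they come off the sequencer; once collapsed
into unique tags they are U-normalized (RNA alphabet, uppercase) and stay that
way for the rest of the pipeline.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass
from pathlib import Path
from typing import IO, Iterable, Iterator, Mapping, Sequence

from Bio import SeqIO
from Bio.SeqIO.QualityIO import FastqGeneralIterator

RNA_ALPHABET = frozenset("ACGUN")
_DNA_COMPLEMENT = str.maketrans("ACGTUN", "TGCAAN")
_RNA_COMPLEMENT = str.maketrans("ACGUTN", "UGCAAN")


class SequenceFormatError(ValueError):
    """Raised when a sequence contains characters outside {A,C,G,T,U,N}."""


@dataclass
class SequenceRecord:
    """A named sequence with optional per-base Phred qualities.

    ``qual`` is the Sanger/Phred+33 ASCII quality string; when present it has
    one character per base.
    """

    id: str
    seq: str
    qual: str | None = None

    def __post_init__(self) -> None:
        if self.qual is not None and len(self.qual) != len(self.seq):
            raise ValueError(
                f"record {self.id!r}: quality length {len(self.qual)} "
                f"!= sequence length {len(self.seq)}"
            )

    def __len__(self) -> int:
        return len(self.seq)


@dataclass
class Tag:
    """A collapsed unique small-RNA sequence with one raw count per library.

    ``seq`` is uppercase RNA (U-normalized) and contains no N. ``counts`` is
    ordered like ``libraries``.
    """

    seq: str
    counts: list[int]
    libraries: list[str]

    def __post_init__(self) -> None:
        if len(self.counts) != len(self.libraries):
            raise ValueError("counts and libraries must have equal length")
        if "N" in self.seq:
            raise ValueError(f"tag sequence contains N: {self.seq!r}")
        if sum(self.counts) < 1:
            raise ValueError("a tag must have at least one supporting read")

    @property
    def total(self) -> int:
        return sum(self.counts)

    def __len__(self) -> int:
        return len(self.seq)


def normalize_alphabet(seq: str) -> str:
    """Uppercase and convert T->U, rejecting anything outside {A,C,G,T,U,N}."""
    if not seq:
        raise SequenceFormatError("empty sequence")
    out = seq.upper().replace("T", "U")
    for pos, ch in enumerate(out):
        if ch not in RNA_ALPHABET:
            raise SequenceFormatError(
                f"illegal character {seq[pos]!r} at position {pos}"
            )
    return out


def revcomp_dna(seq: str) -> str:
    return seq.translate(_DNA_COMPLEMENT)[::-1]


def revcomp_rna(seq: str) -> str:
    return seq.translate(_RNA_COMPLEMENT)[::-1]


def _open_text(path: str | Path, mode: str = "rt") -> IO[str]:
    """gzip-transparent text open."""
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode)  # type: ignore[return-value]
    return open(path, mode)


def read_fasta(path: str | Path) -> list[SequenceRecord]:
    with _open_text(path) as handle:
        return [
            SequenceRecord(rec.id, str(rec.seq).upper())
            for rec in SeqIO.parse(handle, "fasta")
        ]


def write_fasta(records: Iterable[SequenceRecord], path: str | Path) -> None:
    with _open_text(path, "wt") as handle:
        for rec in records:
            handle.write(f">{rec.id}\n{rec.seq}\n")


def read_fastq(path: str | Path) -> Iterator[SequenceRecord]:
    """Stream FASTQ (Sanger/Phred+33) records; gzip-transparent."""
    with _open_text(path) as handle:
        for title, seq, qual in FastqGeneralIterator(handle):
            rid = title.split(None, 1)[0]
            yield SequenceRecord(rid, seq.upper(), qual)


def write_fastq(records: Iterable[SequenceRecord], path: str | Path) -> None:
    with _open_text(path, "wt") as handle:
        for rec in records:
            qstr = rec.qual if rec.qual is not None else "I" * len(rec.seq)
            handle.write(f"@{rec.id}\n{rec.seq}\n+\n{qstr}\n")


def trim_adapter(
    record: SequenceRecord, adapter: str, min_overlap: int = 8
) -> SequenceRecord | None:
    """Return the insert 5' of the first adapter occurrence, or None.

    Matching is exact and leftmost. A full adapter match is searched first;
    if absent, a prefix of the adapter (length >= ``min_overlap``) anchored
    at the 3' end of the read also counts, covering inserts long enough that
    the adapter runs off the read. Returns None when no adapter is found or
    the insert is empty.
    """
    if not 1 <= min_overlap <= len(adapter):
        raise ValueError("require adapter length >= min_overlap >= 1")
    seq = record.seq
    if not seq:
        return None
    cut = seq.find(adapter)
    if cut == -1:
        # adapter truncated by the read end: try successively shorter prefixes
        for k in range(len(adapter) - 1, min_overlap - 1, -1):
            if seq.endswith(adapter[:k]):
                cut = len(seq) - k
                break
        else:
            return None
    if cut == 0:
        return None
    qual = record.qual[:cut] if record.qual is not None else None
    return SequenceRecord(record.id, seq[:cut], qual)


def collapse(
    records_per_library: Mapping[str, Sequence[SequenceRecord]],
) -> list[Tag]:
    """Collapse reads into unique U-normalized tags with per-library counts.

    Reads whose sequence contains N are dropped (they cannot be placed by
    perfect-match mapping downstream). Total read count is conserved over the
    remaining reads. Tags are returned sorted by descending total count then
    sequence, which makes downstream processing deterministic.
    """
    libraries = list(records_per_library)
    if len(set(libraries)) != len(libraries):
        raise ValueError("library names must be unique")
    counts: dict[str, list[int]] = {}
    for j, lib in enumerate(libraries):
        for rec in records_per_library[lib]:
            seq = rec.seq.upper().replace("T", "U")
            if "N" in seq or not seq:
                continue
            row = counts.get(seq)
            if row is None:
                row = [0] * len(libraries)
                counts[seq] = row
            row[j] += 1
    tags = [Tag(seq, row, libraries) for seq, row in counts.items()]
    tags.sort(key=lambda t: (-t.total, t.seq))
    return tags
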