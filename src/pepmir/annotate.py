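"""miRNA annotation: precursor windows, duplex criteria, strand bias, families.

For every sufficiently abundant mapped tag, candidate precursor windows are
cut around each locus (symmetric 100-500 nt extensions in 100 nt steps),
folded, and screened: miRNA* mismatch ratio <= 0.3, then -- after trimming to
the duplex +- 15 nt margins and re-folding -- the plant-miRNA duplex criteria
(<= 4 mismatched mature bases, asymmetric bulges <= 2 nt and <= 1 in number),
then >= 90% sense-strand read bias over the precursor.  Survivors are grouped
into loci and families, classified conserved/novel against a known-miRNA
reference, and novel calls are further required to show a sequenced star and
high abundance.
"""

from __future__ import annotations

import logging
from bisect import bisect_left, bisect_right
from dataclasses import dataclass, field
from typing import Sequence

from .genome_mapper import GenomeHit, GenomeIndex
from .sequence_io import SequenceRecord, Tag, normalize_alphabet, revcomp_rna
from .structure import DuplexReport, SecondaryStructure, extract_duplex, get_folder

logger = logging.getLogger(__name__)

DEFAULT_EXTENSIONS = (100, 200, 300, 400, 500)

# ordered stages of candidate evaluation; a rejection carries the name of the
# first failing rule from the window that progressed furthest
STAGES = (
    "no_hairpin",
    "mismatch_ratio",
    "no_hairpin_refold",
    "mismatch_count",
    "bulge_size",
    "bulge_count",
    "strand_bias",
)


@dataclass
class Thresholds:
    """All knobs of the annotation stage (defaults are the standard values)."""

    min_candidate_reads: int = 50
    candidate_reads_per_library: bool = False
    max_mismatch_ratio: float = 0.3
    refold_margin: int = 15
    max_mismatch: int = 4
    max_bulge_size: int = 2
    max_bulges: int = 1
    min_sense_fraction: float = 0.9
    conservation_mismatches: int = 2
    conservation_len_diff: int = 2
    family_mismatches: int = 2
    family_len_diff: int = 2
    novel_min_abundance: int = 1000
    novel_abundance_per_library: bool = True
    extensions: tuple[int, ...] = DEFAULT_EXTENSIONS
    star_end_tolerance: int = 2
    early_stop: bool = True
    folder: str = "builtin"


@dataclass
class HairpinCandidate:
    """An accepted precursor locus for one mature tag."""

    contig: str
    strand: str
    window: tuple[int, int]  # genome coords of the (trimmed) precursor
    precursor: str  # oriented 5'->3', RNA
    structure: SecondaryStructure
    mature: Tag
    mature_span: tuple[int, int]  # within precursor
    duplex: DuplexReport
    sense_fraction: float
    star: Tag | None = None

    @property
    def star_seq(self) -> str:
        lo, hi = self.duplex.star_span
        return self.precursor[lo:hi]


@dataclass
class Rejection:
    tag_seq: str
    hit: GenomeHit
    reason: str
    stage: int


@dataclass
class MiRNAAnnotation:
    name: str
    mature: str
    star: str
    star_observed: bool
    loci: list[HairpinCandidate]
    counts: list[int]
    libraries: list[str]
    variants: list[str] = field(default_factory=list)
    conservation: str = "novel"  # "conserved" | "novel"
    matched_ref: str | None = None
    family: str | None = None

    @property
    def total(self) -> int:
        return sum(self.counts)

    @property
    def length(self) -> int:
        return len(self.mature)

    @property
    def nt5(self) -> str:
        return self.mature[0]


class TagAtlas:
    """Overlap queries over all mapped tag loci on the genome.

    Backed by per-contig arrays sorted by hit start; because small-RNA tags
    are short (bounded length), an overlap query is a bounded start-range
    scan.
    """

    def __init__(self, hits_per_tag: dict[int, list[GenomeHit]], tags: Sequence[Tag]):
        self.tags = tags
        self.max_len = max((len(t.seq) for t in tags), default=30)
        per_contig: dict[str, list[tuple[int, int, str, int]]] = {}
        for tag_idx, hits in hits_per_tag.items():
            for h in hits:
                per_contig.setdefault(h.contig, []).append(
                    (h.start, h.end, h.strand, tag_idx)
                )
        self._contig: dict[str, tuple[list[int], list[tuple[int, int, str, int]]]] = {}
        for contig, rows in per_contig.items():
            rows.sort()
            self._contig[contig] = ([r[0] for r in rows], rows)

    def overlapping(self, contig: str, lo: int, hi: int):
        """All (start, end, strand, tag_idx) hits overlapping [lo, hi)."""
        if contig not in self._contig:
            return []
        starts, rows = self._contig[contig]
        i = bisect_left(starts, lo - self.max_len)
        j = bisect_right(starts, hi)
        return [r for r in rows[i:j] if r[0] < hi and r[1] > lo]

    def sense_fraction(self, contig: str, lo: int, hi: int, strand: str) -> float:
        sense = anti = 0
        for s, e, st, idx in self.overlapping(contig, lo, hi):
            c = self.tags[idx].total
            if st == strand:
                sense += c
            else:
                anti += c
        total = sense + anti
        return sense / total if total else 0.0

    def find_star(
        self, contig: str, lo: int, hi: int, strand: str, tol: int
    ) -> Tag | None:
        """A mapped tag whose locus matches [lo, hi) within +-tol at each end."""
        best: Tag | None = None
        for s, e, st, idx in self.overlapping(contig, lo - tol, hi + tol):
            if st == strand and abs(s - lo) <= tol and abs(e - hi) <= tol:
                t = self.tags[idx]
                if best is None or t.total > best.total:
                    best = t
        return best


def candidate_windows(
    hit: GenomeHit,
    contig_len: int,
    extensions: Sequence[int] = DEFAULT_EXTENSIONS,
) -> list[tuple[int, int]]:
    """All (window_start, window_end) genome intervals for a locus.

    Every (upstream, downstream) extension pair from ``extensions`` is taken
    (in genome orientation; the mature reads 5'->3' after the caller orients
    the window by strand), clipped at contig edges and deduplicated,
    preserving the small-to-large scan order.
    """
    if not extensions:
        raise ValueError("empty extension set")
    seen = set()
    out = []
    for total in sorted({u + d for u in extensions for d in extensions}):
        for up in sorted(extensions):
            down = total - up
            if down not in extensions:
                continue
            ws = max(0, hit.start - up)
            we = min(contig_len, hit.end + down)
            if (ws, we) not in seen:
                seen.add((ws, we))
                out.append((ws, we))
    return out


def _oriented_window(
    contig_seq: str, ws: int, we: int, hit: GenomeHit
) -> tuple[str, int]:
    """Window sequence with the mature reading 5'->3', and the mature offset."""
    seq = contig_seq[ws:we].replace("T", "U")
    if hit.strand == "+":
        return seq, hit.start - ws
    return revcomp_rna(seq), we - hit.end


def _to_genome_span(
    span: tuple[int, int], ws: int, we: int, strand: str
) -> tuple[int, int]:
    if strand == "+":
        return (ws + span[0], ws + span[1])
    return (we - span[1], we - span[0])


def evaluate_candidate(
    contig_seq: str,
    hit: GenomeHit,
    window: tuple[int, int],
    mature: Tag,
    atlas: TagAtlas,
    thresholds: Thresholds,
) -> HairpinCandidate | Rejection:
    """Run one precursor window through the full rule pipeline.

    Returns an accepted HairpinCandidate or a Rejection naming the first
    failing rule (rejections are values, not errors).
    """
    fold = get_folder(thresholds.folder)
    ws, we = window
    seq, off = _oriented_window(contig_seq, ws, we, hit)
    L = len(mature.seq)
    span = (off, off + L)
    st = fold(seq)
    duplex = extract_duplex(st, span)
    if duplex is None:
        return Rejection(mature.seq, hit, "no_hairpin", 0)
    if duplex.mismatch_ratio > thresholds.max_mismatch_ratio:
        return Rejection(mature.seq, hit, "mismatch_ratio", 1)
    # trim to the duplex span +- margin and re-fold
    m = thresholds.refold_margin
    lo = max(0, min(span[0], duplex.star_span[0]) - m)
    hi = min(len(seq), max(span[1], duplex.star_span[1]) + m)
    precursor = seq[lo:hi]
    pspan = (span[0] - lo, span[1] - lo)
    st2 = fold(precursor)
    duplex2 = extract_duplex(st2, pspan)
    if duplex2 is None:
        return Rejection(mature.seq, hit, "no_hairpin_refold", 2)
    if duplex2.n_mismatch > thresholds.max_mismatch:
        return Rejection(mature.seq, hit, "mismatch_count", 3)
    if any(size > thresholds.max_bulge_size for _, size in duplex2.bulges):
        return Rejection(mature.seq, hit, "bulge_size", 4)
    if len(duplex2.bulges) > thresholds.max_bulges:
        return Rejection(mature.seq, hit, "bulge_count", 5)
    # genome span of the trimmed precursor (window is oriented)
    g_lo, g_hi = _to_genome_span((lo, hi), ws, we, hit.strand)
    sense = atlas.sense_fraction(hit.contig, g_lo, g_hi, hit.strand)
    if sense < thresholds.min_sense_fraction:
        return Rejection(mature.seq, hit, "strand_bias", 6)
    star_g = _to_genome_span(duplex2.star_span, ws, we, hit.strand)
    star = atlas.find_star(
        hit.contig, star_g[0], star_g[1], hit.strand,
        thresholds.star_end_tolerance,
    )
    if star is not None and star.seq == mature.seq:
        star = None
    return HairpinCandidate(
        contig=hit.contig,
        strand=hit.strand,
        window=(g_lo, g_hi),
        precursor=precursor,
        structure=st2,
        mature=mature,
        mature_span=pspan,
        duplex=duplex2,
        sense_fraction=sense,
        star=star,
    )


def select_locus(candidates: Sequence[HairpinCandidate]) -> HairpinCandidate:
    """Deterministic best window: star seen, fewest mismatches, shortest,
    leftmost."""
    if not candidates:
        raise ValueError("empty candidate list")
    return min(
        candidates,
        key=lambda c: (
            c.star is None,
            c.duplex.n_mismatch,
            len(c.precursor),
            c.window[0],
        ),
    )


def evaluate_hit(
    contig_seq: str,
    hit: GenomeHit,
    mature: Tag,
    atlas: TagAtlas,
    thresholds: Thresholds,
) -> tuple[HairpinCandidate | None, Rejection | None]:
    """Scan the window grid for one locus; return (best accepted, rejection).

    The rejection (when nothing is accepted) is the one from the window that
    progressed furthest through the rules. With ``early_stop`` the scan ends
    as soon as a window is accepted whose candidate has an observed star and
    zero mismatches: later windows cannot beat it in select_locus' ordering.
    """
    accepted: list[HairpinCandidate] = []
    worst: Rejection | None = None
    windows = candidate_windows(hit, len(contig_seq), thresholds.extensions)
    for window in windows:
        res = evaluate_candidate(contig_seq, hit, window, mature, atlas, thresholds)
        if isinstance(res, HairpinCandidate):
            accepted.append(res)
            if (
                thresholds.early_stop
                and res.star is not None
                and res.duplex.n_mismatch == 0
            ):
                break
        elif worst is None or res.stage > worst.stage:
            worst = res
    if accepted:
        return select_locus(accepted), None
    return None, worst


def seq_distance(a: str, b: str) -> int:
    """Best ungapped overlap distance: unmatched positions of the shorter
    sequence count as mismatches."""
    la, lb = len(a), len(b)
    shorter = min(la, lb)
    best = shorter
    for off in range(-(lb - 1), la):
        matches = 0
        for i in range(max(0, off), min(la, off + lb)):
            if a[i] == b[i - off]:
                matches += 1
        if shorter - matches < best:
            best = shorter - matches
    return best


def classify_conservation(
    mature: str,
    known: Sequence[SequenceRecord],
    max_mismatches: int = 2,
    max_len_diff: int = 2,
) -> tuple[str, str | None]:
    """('conserved', best reference name) or ('novel', None)."""
    best_name, best_d = None, max_mismatches + 1
    for ref in known:
        refseq = normalize_alphabet(ref.seq)
        if abs(len(refseq) - len(mature)) > max_len_diff:
            continue
        d = seq_distance(mature, refseq)
        if d < best_d:
            best_name, best_d = ref.id, d
    if best_name is not None:
        return "conserved", best_name
    return "novel", None


class _UnionFind:
    def __init__(self, n: int):
        self.parent = list(range(n))

    def find(self, x: int) -> int:
        while self.parent[x] != x:
            self.parent[x] = self.parent[self.parent[x]]
            x = self.parent[x]
        return x

    def union(self, a: int, b: int) -> None:
        ra, rb = self.find(a), self.find(b)
        if ra != rb:
            self.parent[max(ra, rb)] = min(ra, rb)


def _loci_overlap(a: MiRNAAnnotation, b: MiRNAAnnotation) -> bool:
    for ca in a.loci:
        for cb in b.loci:
            if (
                ca.contig == cb.contig
                and ca.strand == cb.strand
                and ca.window[0] < cb.window[1]
                and cb.window[0] < ca.window[1]
            ):
                return True
    return False


def group_families(
    annotations: Sequence[MiRNAAnnotation],
    max_mismatches: int = 2,
    max_len_diff: int = 2,
    prefix: str = "mir",
) -> None:
    """Assign family names in place (transitive closure of similarity/loci).

    Two annotations are related when their matures are within
    ``max_mismatches`` ungapped-overlap distance with length difference
    <= ``max_len_diff``, or when they share an overlapping hairpin locus.
    Families are numbered by descending total abundance; members get a,b,c...
    suffixes, likewise by abundance.
    """
    n = len(annotations)
    uf = _UnionFind(n)
    for i in range(n):
        for j in range(i + 1, n):
            a, b = annotations[i], annotations[j]
            similar = (
                abs(len(a.mature) - len(b.mature)) <= max_len_diff
                and seq_distance(a.mature, b.mature) <= max_mismatches
            )
            if similar or _loci_overlap(a, b):
                uf.union(i, j)
    groups: dict[int, list[int]] = {}
    for i in range(n):
        groups.setdefault(uf.find(i), []).append(i)
    ordered = sorted(
        groups.values(),
        key=lambda idxs: (-sum(annotations[i].total for i in idxs), idxs[0]),
    )
    for fam_no, idxs in enumerate(ordered, start=1):
        members = sorted(idxs, key=lambda i: (-annotations[i].total, i))
        for pos, i in enumerate(members):
            suffix = "" if len(members) == 1 else chr(ord("a") + pos)
            annotations[i].family = f"{prefix}-fam{fam_no}"
            annotations[i].name = f"{prefix}-fam{fam_no}{suffix}"


def apply_novel_filters(
    annotations: Sequence[MiRNAAnnotation],
    min_total: int = 1000,
    per_library: bool = True,
) -> list[MiRNAAnnotation]:
    """Keep conserved calls and novel calls with an observed star and high
    abundance (peak per-library raw count, or study total, >= min_total)."""
    kept = []
    for ann in annotations:
        if ann.conservation == "conserved":
            kept.append(ann)
            continue
        abundance = max(ann.counts) if per_library else sum(ann.counts)
        if ann.star_observed and abundance >= min_total:
            kept.append(ann)
    return kept


def annotate(
    index: GenomeIndex,
    tags: Sequence[Tag],
    hits_per_tag: dict[int, list[GenomeHit]],
    known_refs: Sequence[SequenceRecord],
    thresholds: Thresholds | None = None,
) -> tuple[list[MiRNAAnnotation], list[Rejection]]:
    """Full annotation pass over mapped tags.

    ``hits_per_tag`` maps tag index -> loci (tags over the multi-locus cap
    are absent). Tags whose abundance reaches ``min_candidate_reads`` seed
    candidate searches; accepted loci are merged into per-arm annotations
    (overlapping mature spans collapse onto the most abundant tag, recorded
    as isomiR variants; opposite arms of one hairpin may both be annotated).
    """
    thresholds = thresholds or Thresholds()
    atlas = TagAtlas(hits_per_tag, tags)
    accepted: list[HairpinCandidate] = []
    rejections: list[Rejection] = []
    for tag_idx, hits in hits_per_tag.items():
        tag = tags[tag_idx]
        abundant = (
            max(tag.counts) >= thresholds.min_candidate_reads
            if thresholds.candidate_reads_per_library
            else tag.total >= thresholds.min_candidate_reads
        )
        if not abundant:
            continue
        for hit in hits:
            contig_seq = index.contigs[hit.contig]
            cand, rej = evaluate_hit(contig_seq, hit, tag, atlas, thresholds)
            if cand is not None:
                accepted.append(cand)
            elif rej is not None:
                rejections.append(rej)
    annotations = _merge_candidates(accepted, thresholds)
    for ann in annotations:
        ann.conservation, ann.matched_ref = classify_conservation(
            ann.mature,
            known_refs,
            thresholds.conservation_mismatches,
            thresholds.conservation_len_diff,
        )
    group_families(
        annotations, thresholds.family_mismatches, thresholds.family_len_diff
    )
    return annotations, rejections


def _mature_genome_span(c: HairpinCandidate) -> tuple[str, int, int, str]:
    if c.strand == "+":
        lo = c.window[0] + c.mature_span[0]
        hi = c.window[0] + c.mature_span[1]
    else:
        lo = c.window[1] - c.mature_span[1]
        hi = c.window[1] - c.mature_span[0]
    return (c.contig, lo, hi, c.strand)


def _merge_candidates(
    accepted: Sequence[HairpinCandidate], thresholds: Thresholds
) -> list[MiRNAAnnotation]:
    # group accepted loci: same contig/strand with overlapping precursors and
    # overlapping mature spans -> one arm; most abundant tag is the mature
    by_seq: dict[str, list[HairpinCandidate]] = {}
    for cand in accepted:
        by_seq.setdefault(cand.mature.seq, []).append(cand)
    arms = sorted(
        by_seq.items(), key=lambda kv: (-kv[1][0].mature.total, kv[0])
    )
    annotations: list[MiRNAAnnotation] = []
    claimed: list[tuple[str, int, int, str, MiRNAAnnotation]] = []
    for seq, cands in arms:
        tag = cands[0].mature
        spans = [_mature_genome_span(c) for c in cands]
        owner: MiRNAAnnotation | None = None
        for (contig, lo, hi, strand) in spans:
            for (c2, l2, h2, s2, ann) in claimed:
                if contig == c2 and strand == s2 and lo < h2 and l2 < hi:
                    owner = ann
                    break
            if owner:
                break
        if owner is not None:
            owner.variants.append(seq)  # isomiR of an already-claimed arm
            continue
        ann = MiRNAAnnotation(
            name=seq,  # renamed by group_families
            mature=seq,
            star=cands[0].star.seq if cands[0].star else cands[0].star_seq,
            star_observed=any(c.star is not None for c in cands),
            loci=list(cands),
            counts=list(tag.counts),
            libraries=list(tag.libraries),
        )
        annotations.append(ann)
        for sp in spans:
            claimed.append((*sp, ann))
    return annotations
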