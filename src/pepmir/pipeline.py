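"""End-to-end orchestration: reads -> filters -> mapping -> annotation ->
normalization -> target prediction, with funnel accounting and file outputs.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Sequence

import pandas as pd
import yaml

from . import quantify, targets as targets_mod
from .annotate import MiRNAAnnotation, Rejection, Thresholds, annotate
from .genome_mapper import build_index, map_tag
from .read_filter import (
    FilterReport,
    NcrnaIndex,
    filter_length,
    filter_ncrna,
    filter_quality,
)
from .sequence_io import (
    SequenceRecord,
    Tag,
    collapse,
    read_fasta,
    read_fastq,
    trim_adapter,
)

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Inputs and thresholds of one pipeline run; defaults are the standard
    values of the method."""

    libraries: dict[str, str] = field(default_factory=dict)  # name -> FASTQ
    genome: str = ""
    known_mirnas: str = ""
    ncrna: str = ""
    transcripts: str | None = None
    output_dir: str = "pepmir_out"
    adapter: str = "TGGAATTCTCGGGTGCCAAGG"
    min_overlap: int = 8
    min_mean_q: float = 20.0
    min_len: int = 18
    max_len: int = 26
    max_loci: int = 25
    seed_len: int = 18
    target_cutoff: float = 4.0
    seed: int = 0
    thresholds: Thresholds = field(default_factory=Thresholds)

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides: Any) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        data.update(overrides)
        thr = data.pop("thresholds", {})
        cfg = cls(**data)
        if thr:
            cfg.thresholds = Thresholds(**thr)
        return cfg


@dataclass
class RunSummary:
    """Per-stage tallies (funnel) plus headline counts."""

    funnel: dict[str, dict[str, int]] = field(default_factory=dict)
    tag_filter: dict[str, int] = field(default_factory=dict)
    n_tags_mapped: int = 0
    n_tags_discarded_multi: int = 0
    n_annotations: int = 0
    n_conserved: int = 0
    n_novel: int = 0
    n_families: int = 0
    n_rejections: int = 0
    n_targets: int = 0
    thresholds: dict[str, Any] = field(default_factory=dict)

    def check(self) -> None:
        for lib, row in self.funnel.items():
            if row["raw_reads"] != (
                row["quality_removed"]
                + row["adapter_unmatched"]
                + row["adapter_removed"]
            ):
                raise AssertionError(f"funnel identity broken for {lib}")

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True)


@dataclass
class RunResult:
    summary: RunSummary
    annotations: list[MiRNAAnnotation]
    rejections: list[Rejection]
    counts: pd.DataFrame
    normalized: pd.DataFrame
    targets: pd.DataFrame
    profile: pd.DataFrame
    tags: list[Tag]


def run_pipeline(config: RunConfig, write: bool = True) -> RunResult:
    """Execute every stage in order; idempotent given config and inputs."""
    for label, path in [
        ("genome", config.genome),
        ("known_mirnas", config.known_mirnas),
        ("ncrna", config.ncrna),
    ]:
        if not path or not Path(path).exists():
            raise FileNotFoundError(f"{label} input missing: {path!r}")
    for lib, path in config.libraries.items():
        if not Path(path).exists():
            raise FileNotFoundError(f"library {lib} input missing: {path!r}")

    summary = RunSummary()
    trimmed_per_library: dict[str, list[SequenceRecord]] = {}
    for lib, path in config.libraries.items():
        records = list(read_fastq(path))
        n_raw = len(records)
        records = filter_quality(records, config.min_mean_q)
        n_q = len(records)
        trimmed = []
        for rec in records:
            t = trim_adapter(rec, config.adapter, config.min_overlap)
            if t is not None:
                trimmed.append(t)
        trimmed_per_library[lib] = trimmed
        summary.funnel[lib] = {
            "raw_reads": n_raw,
            "quality_removed": n_raw - n_q,
            "adapter_unmatched": n_q - len(trimmed),
            "adapter_removed": len(trimmed),
        }

    tags = collapse(trimmed_per_library)
    for lib in config.libraries:
        j = tags[0].libraries.index(lib) if tags else 0
        summary.funnel[lib]["collapsed_reads"] = sum(t.counts[j] for t in tags)

    tags_len = filter_length(tags, config.min_len, config.max_len)
    ncrna_refs = read_fasta(config.ncrna)
    ncindex = NcrnaIndex(ncrna_refs, config.min_len, config.max_len)
    kept, removed_nc = filter_ncrna(tags_len, ncrna_refs, ncindex)
    tag_report = FilterReport(
        input_tags=len(tags),
        kept_tags=len(kept),
        removed_by_quality=0,  # quality filtering acts on reads, pre-collapse
        removed_by_length=len(tags) - len(tags_len),
        removed_by_ncrna=len(removed_nc),
    )
    for lib in config.libraries:
        j = kept[0].libraries.index(lib) if kept else 0
        summary.funnel[lib]["length_selected"] = sum(
            t.counts[j] for t in tags_len
        )
        summary.funnel[lib]["ncrna_removed_reads"] = sum(
            t.counts[j] for t in removed_nc
        )
        summary.funnel[lib]["clean_reads"] = sum(t.counts[j] for t in kept)
    tag_report.library_tallies = {
        lib: dict(row) for lib, row in summary.funnel.items()
    }
    tag_report.check()
    summary.tag_filter = {
        "input_tags": tag_report.input_tags,
        "kept_tags": tag_report.kept_tags,
        "removed_by_quality": tag_report.removed_by_quality,
        "removed_by_length": tag_report.removed_by_length,
        "removed_by_ncrna": tag_report.removed_by_ncrna,
    }

    genome = read_fasta(config.genome)
    index = build_index(genome, config.seed_len)
    hits_per_tag: dict[int, list] = {}
    n_multi = 0
    for i, tag in enumerate(kept):
        hits = map_tag(index, tag, config.max_loci)
        if hits is None:
            n_multi += 1
        elif hits:
            hits_per_tag[i] = hits
    summary.n_tags_mapped = len(hits_per_tag)
    summary.n_tags_discarded_multi = n_multi

    known_refs = read_fasta(config.known_mirnas)
    annotations, rejections = annotate(
        index, kept, hits_per_tag, known_refs, config.thresholds
    )
    annotations = _finalize(annotations, config.thresholds)
    summary.n_annotations = len(annotations)
    summary.n_conserved = sum(
        1 for a in annotations if a.conservation == "conserved"
    )
    summary.n_novel = len(annotations) - summary.n_conserved
    summary.n_families = len({a.family for a in annotations})
    summary.n_rejections = len(rejections)

    libraries = list(config.libraries)
    counts = pd.DataFrame(
        [a.counts for a in annotations],
        index=[a.name for a in annotations],
        columns=libraries if annotations else None,
    )
    if len(counts) and (counts.to_numpy() > 0).all(axis=1).any():
        s = quantify.size_factors(counts)
    elif len(counts):
        s = quantify.size_factors(counts, pseudo_reference=True)
    else:
        s = pd.Series(dtype=float)
    normalized = (
        quantify.normalized_int(counts, s) if len(counts) else counts.copy()
    )

    mapped_tags = [kept[i] for i in hits_per_tag]
    profile = quantify.length_5p_profile(mapped_tags)

    if config.transcripts:
        transcripts = read_fasta(config.transcripts)
        target_table = targets_mod.predict_targets(
            [(a.name, a.mature) for a in annotations],
            transcripts,
            config.target_cutoff,
        )
    else:
        target_table = pd.DataFrame(
            columns=["miRNA", "S", "target", "start", "end", "cleavage_pos", "alignment"]
        )
    summary.n_targets = len(target_table)
    summary.thresholds = {
        **dataclasses.asdict(config.thresholds),
        "min_len": config.min_len,
        "max_len": config.max_len,
        "max_loci": config.max_loci,
        "target_cutoff": config.target_cutoff,
    }
    summary.check()

    result = RunResult(
        summary, annotations, rejections, counts, normalized,
        target_table, profile, kept,
    )
    if write:
        _write_outputs(result, config)
    return result


def _finalize(annotations, thresholds: Thresholds):
    from .annotate import apply_novel_filters, group_families

    kept = apply_novel_filters(
        annotations,
        thresholds.novel_min_abundance,
        thresholds.novel_abundance_per_library,
    )
    group_families(kept, thresholds.family_mismatches, thresholds.family_len_diff)
    return kept


def annotations_table(annotations: Sequence[MiRNAAnnotation],
                      normalized: pd.DataFrame) -> pd.DataFrame:
    rows = []
    for a in annotations:
        row = {
            "miRNA": a.name,
            "sequence": a.mature,
            "class": a.conservation,
            "matched_ref": a.matched_ref or "",
            "star_observed": a.star_observed,
        }
        if a.name in normalized.index:
            for lib in normalized.columns:
                row[lib] = int(normalized.loc[a.name, lib])
        row["length"] = a.length
        row["nt5"] = a.nt5
        row["Hp#"] = len(a.loci)
        rows.append(row)
    return pd.DataFrame(rows)


def annotations_gff3(annotations: Sequence[MiRNAAnnotation]) -> str:
    """GFF3 (1-based closed coordinates) with precursor and mature features."""
    lines = ["##gff-version 3"]
    for a in annotations:
        for k, c in enumerate(a.loci, start=1):
            pid = f"{a.name}_hp{k}"
            lines.append(
                "\t".join(
                    [
                        c.contig, "pepmir", "miRNA_primary_transcript",
                        str(c.window[0] + 1), str(c.window[1]), ".",
                        c.strand, ".", f"ID={pid};Name={pid}",
                    ]
                )
            )
            from .annotate import _mature_genome_span

            contig, lo, hi, strand = _mature_genome_span(c)
            lines.append(
                "\t".join(
                    [
                        contig, "pepmir", "miRNA",
                        str(lo + 1), str(hi), ".", strand, ".",
                        f"ID={a.name}_mature_hp{k};Name={a.name};Derives_from={pid}",
                    ]
                )
            )
    return "\n".join(lines) + "\n"


def _write_outputs(result: RunResult, config: RunConfig) -> None:
    from .structure import write_vienna

    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    annotations_table(result.annotations, result.normalized).to_csv(
        out / "mirnas.tsv", sep="\t", index=False
    )
    (out / "mirnas.gff3").write_text(annotations_gff3(result.annotations))
    entries = [
        (f"{a.name}_hp{k}", c.structure)
        for a in result.annotations
        for k, c in enumerate(a.loci, start=1)
    ]
    (out / "hairpins.txt").write_text(write_vienna(entries))
    result.counts.to_csv(out / "counts.tsv", sep="\t")
    result.normalized.to_csv(out / "normalized_counts.tsv", sep="\t")
    result.targets.to_csv(out / "targets.tsv", sep="\t", index=False)
    if len(result.profile):
        result.profile.to_csv(out / "profile.tsv", sep="\t")
    (out / "summary.json").write_text(result.summary.to_json())
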