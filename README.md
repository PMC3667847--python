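# pepmir

A small-RNA sequencing analysis toolkit for plant miRNA discovery, built
around the hot pepper (*Capsicum annuum*) miRNA catalog. It takes raw
multi-library small-RNA reads (FASTQ) and a contig-level genome (FASTA) and
produces annotated conserved/novel miRNAs and predicted cleavage targets,
with a synthetic-data generator that stands in for real sequencing libraries
and a draft genome so every stage is testable offline.

## Who it is for

Researchers annotating miRNAs in a non-model plant from deep small-RNA
sequencing: the pipeline reproduces the standard hairpin-based discovery
procedure (adapter trimming, ncRNA exclusion, perfect-match genome mapping,
precursor folding, miRNA/miRNA\* duplex screening, strand bias, family
grouping, miRBase-style conservation classification) and the
position-dependent penalty scoring used to predict cleavage targets.

## The method

**miRNA annotation.** Reads are quality-filtered (mean Phred >= 20), 3'
adapters removed (exact, leftmost, >= 8 nt overlap), collapsed to unique
tags, restricted to 18-26 nt, screened against an rRNA/tRNA/snRNA/snoRNA
exclusion set (exact substring, both strands), and mapped to the genome by
perfect match on both strands with a 25-locus cap. Each tag with >= 50
supporting reads seeds precursor windows extended 100-500 nt (step 100) on
each side of its locus. A window is folded with a maximum pair-weight
folder (GC = 3, AU = 2, GU = 1, hairpin loop >= 3, non-crossing — a
Nussinov-style dynamic program; a thermodynamic folder can be plugged in),
the miRNA\* is located under the 2-nt 3'-overhang convention, and the
candidate must pass, in order:

1. mismatch ratio (unpaired mature bases / mature length) <= 0.3;
2. after trimming to the duplex +- 15 nt and re-folding: <= 4 mismatched
   mature bases, asymmetric bulges <= 2 nt and at most 1;
3. >= 90% of reads over the precursor on the sense strand.

Annotations are grouped into families (<= 2 mismatches or shared loci,
transitive closure), classified conserved (within 2 ungapped mismatches of a
known mature, length difference <= 2) or novel, and novel calls additionally
require a sequenced miRNA\* and a peak per-library count >= 1,000. Counts
are normalized with median-of-ratios size factors

    s_j = median_i [ k_ij / (prod_v k_iv)^(1/m) ]

over rows with all-positive counts.

**Target prediction.** A candidate site (length L-1, L or L+1 for an L-nt
miRNA) is aligned antiparallel to the miRNA; each column costs 0 (Watson-
Crick), 0.5 (G:U), or 1 (mismatch or unpaired base), doubled at miRNA
positions 2-13 from the 5' end; at most one single-nucleotide bulge or gap
is allowed; sites with total penalty S <= 4 are reported, with the predicted
cleavage position opposite miRNA positions 10-11.

## Worked example

```python
>>> from pepmir import score_site, render_alignment
>>> from pepmir.sequence_io import revcomp_rna
>>> m = "UUGCAAACACACCUGAAUCGU"          # can-miR-n002a-c
>>> aln = score_site(m, revcomp_rna(m))  # its F-box target site
>>> aln.score
0.0
>>> print(render_alignment(aln))
miRNA  3' UGCUAAGUCCACACAAACGUU 5'
          |||||||||||||||||||||
target 5' ACGAUUCAGGUGUGUUUGCAA 3'
```

A score of 0 means perfect complementarity — the strongest possible
cleavage-site prediction. Introducing a seed-region mismatch (position 5,
doubled) and a G:U wobble at position 15 raises the penalty to 2.5, still
under the reporting cutoff of 4:

```python
>>> from pepmir.simulate import make_target_site
>>> site, expected = make_target_site(m, [(5, "mismatch"), (15, "wobble")])
>>> score_site(m, site).score
2.5
```

An end-to-end run on synthetic data:

```bash
pepmir simulate --out study --seed 42 --n-libraries 3
pepmir run --config study/run.yaml
```

writes `mirnas.tsv` (catalog-style table: mature sequence, per-library
normalized counts, length, hairpin-locus count), `mirnas.gff3`,
`hairpins.txt` (dot-bracket structures), `counts.tsv`,
`normalized_counts.tsv`, `targets.tsv` and `summary.json` with the
per-library read funnel.

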