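# Methods

This note records the models, parameter choices and numerical decisions
behind pepmir, and what the synthetic-data tests do and do not demonstrate.

## Read processing

Reads are processed in the order quality -> adapter -> length -> ncRNA so
that stage tallies line up with the conventional small-RNA funnel report.
Quality filtering keeps reads with mean Phred >= 20 (`min_mean_q`); reads
without qualities pass with a logged warning. Adapter trimming is exact and
leftmost with a default minimum overlap of 8 nt; an adapter truncated by the
read end is recognized from its prefix. Exactness makes the funnel
deterministic; no mismatch tolerance is offered because downstream mapping
is perfect-match anyway. Inserts containing N are dropped at collapsing:
they cannot be placed by exact-match mapping. The ncRNA exclusion is an
exact-substring test against both strands of the supplied reference set;
this is deliberately conservative (no similarity cutoff is modeled) and the
exclusion set is an arbitrary FASTA, so genome-scale exclusion sets can be
supplied the same way.

## Mapping

Tags are placed by perfect match on both strands via a seed dictionary over
18-mers with full-length verification, equivalent to a naive scan (asserted
against one in the tests). Tags matching more than `max_loci` (default 25)
positions are discarded entirely rather than truncated to 25: truncation
would demand an arbitrary locus choice, and discarding matches common
repeat-filtering practice. Coordinates are 0-based half-open internally,
converted to 1-based closed only in GFF3 output. A minus-strand mature is
the reverse complement of the genome slice.

## Secondary structure

The built-in folder maximizes total pair weight (GC = 3, AU = 2, GU = 1;
minimum hairpin loop 3; pseudoknot-free) with an O(n^3) dynamic program,
numba-compiled so that 1 kb precursor windows fold in well under a second.
Scores are pair-weight units, not free energies: the pipeline needs hairpin
topology and duplex geometry, not thermodynamics. Users who want kcal/mol
can register an external folder (`structure.register_folder`); its scores
are then labeled by that engine.

Traceback determinism: position i prefers pairing over remaining unpaired,
and among equally scoring partners takes the **largest** closing j. A
maximum-pair-weight objective has a highly degenerate optimum; preferring
the smallest j realizes ties as spurious 4-nt local hairpins inside an
otherwise clean stem, which misreports duplex geometry. The largest-j
preference biases ties toward long-range stem pairs and leaves designed
duplex diagnostics intact.

Duplex extraction uses the Dicer convention of 2-nt 3' overhangs on both
strands: the star span runs from the partner of the mature base two in from
its 3' end to two bases past the partner of the mature 5' base, extrapolated
across unpaired termini and clipped at the precursor edge (with a warning).
The mature's two 3'-overhang bases are excluded from the pairing region, so
the mismatch ratio is (unpaired mature bases in the pairing region)/(mature
length) — the denominator is the full mature length, so a 21-mer with three
unpaired bases has ratio 3/21. Internal loops between consecutive paired
mature positions contribute min(unpaired_mature, unpaired_star) mismatched
bases; any excess on one side is an asymmetric bulge of that size.
Extraction returns nothing when the mature pairs with itself, spans both
arms, or has fewer than half its bases paired; multi-loop precursors are
thereby rejected rather than interpreted.

## Candidate evaluation

Windows extend 100-500 nt (step 100) independently upstream and downstream
(25 combinations, clipped and deduplicated). The rule order is: fold and
extract; mismatch ratio <= 0.3; trim to duplex +- 15 nt and re-fold;
mismatched bases <= 4; bulge size <= 2; bulge count <= 1; sense-strand read
fraction >= 0.9. The strand-bias denominator is the count-weighted total of
mapped tags overlapping the trimmed precursor only (not the window flanks).
A hit's rejection reason is taken from the window that progressed furthest
through the rules, which makes the report deterministic and names the rule
the locus came closest to passing. By default the window scan stops early
once a window yields an accepted candidate with an observed star and zero
mismatches, because no later window can beat it under the locus-selection
ordering (star observed, then fewest mismatches, then shortest precursor,
then leftmost); this is a pure optimization, switchable off in
`Thresholds.early_stop`.

The candidate abundance gate (>= 50 reads) is applied to the study-wide tag
total by default, switchable to per-library. The novel-miRNA abundance rule
is peak-per-library >= 1,000 by default (switchable to study total): a
tissue-specific miRNA should not be penalized for being silent elsewhere.
Star detection tolerates +-2 nt at each end of the predicted star span.
Overlapping mature spans at one locus collapse onto the most abundant tag
(other tags recorded as isomiR variants); opposite arms of one hairpin can
both be annotated when each passes independently, sharing the locus.

## Quantification

Size factors are the classic median-of-ratios estimator; rows containing
any zero are excluded from the reference. For sparse matrices a
pseudo-reference variant (geometric mean over non-zero entries) is provided
explicitly, never silently. Differential expression is out of scope. The
length/5'-nucleotide profile is count-weighted per library over
genome-matched tags.

## Target scoring

The penalty system: Watson-Crick 0, G:U 0.5, mismatch/bulge/gap 1, doubled
at miRNA positions 2-13 from the 5' end (position 1 is outside the doubled
window); at most one single-nucleotide bulge or gap in total, so candidate
sites are confined to lengths L-1, L, L+1; sites scoring <= 4 are reported.
The alignment is a dynamic program over (miRNA consumed, site consumed, gap
used); an unpaired target base is charged at the 5'-adjacent miRNA position,
an unpaired miRNA base at the skipped position itself — the simplest
assignment consistent with counting positions from the miRNA 5' end, and
config-visible in the column states. Ties are traced back with the gap
leftmost. "One bulge or gap" is read as one in total; scanning reports
non-overlapping best sites greedily by (score, position). The cleavage
position is reported as the transcript coordinate opposite miRNA position
10 (the scissile bond lies between it and the base opposite position 11).

## Synthetic data

The generator emulates a multi-tissue plant small-RNA study at desk scale:
by default 10 libraries of 200k reads (not the hundreds of millions of a
real study — recovery, not depth, is what the tests measure). Composition
per library: 68% degradation fragments drawn uniformly from the genome
(length profile peaked at 24 nt with a 21/22/23 nt shoulder, 75% 5' U/A
bias — the heterochromatic-siRNA-dominated profile typical of plant
libraries), 7% ncRNA fragments from the exclusion decoys, 1% low-quality
reads, and the remainder planted miRNA loci. Each plant receives a
per-library abundance weight drawn once from U[0.7, 1.3]; star reads accrue
at 8% of mature reads; 5% of mature reads carry +-1 nt isomiR offsets. Each
read is insert + 3' adapter truncated to 34 nt at constant quality. With
these defaults a 40-locus study at 200k reads/library leaves every planted
mature above both the 50-read candidate gate and (in expectation) the
1,000-read novel filter.

Planted hairpins are designed, not sampled: the star arm is the reverse
complement of the mature minus its 2-nt 3' overhang, edited to carry the
designed defect, flanked by mutually complementary 20-nt arms that extend
the stem and anchor the intended topology inside larger genomic windows
(with the two star-overhang bases made non-pairing so the overhang stays
single-stranded). The design is verified by re-folding; flanks and loops
are re-drawn on failure. Two consequences of the pair-weight folder shaped
this design: designed mismatches are realized as one contiguous symmetric
internal loop whose star side uses a single base that can pair none of the
opposing mature bases (isolated mismatches fragment the stem enough for the
folder to find alternative pairings), and clean plants avoid full mirror
symmetry so mature/star reads never map antisense onto their own hairpin
(which would break the 90% strand-bias rule spuriously). Criterion-violating
plants use randomly drawn matures, re-drawn until the defect survives
folding; the planted violations are excess mismatches (5), an oversized
bulge (3 nt), two bulges, and antisense read contamination (35%). A
mismatch-ratio violation (> 30% of the mature unpaired) is not plantable
under a max-weight folder — such a stem is too degenerate to fold
reproducibly — so that rule is exercised by structure-level unit tests
instead.

Constructed target sites (`make_target_site`) start from the exact reverse
complement and apply edits with analytically known costs; the construction
is validated by enumerating every one-gap alignment, and edit
specifications whose intended alignment is not the optimum (a gap that can
slide into a cheaper position through a repeat, or a substitution that can
re-pair under a slid register) are rejected so the analytic expectation is
always the true optimum.

What passing these tests shows — and does not. Recovery of planted loci
shows the rule pipeline implements the stated criteria faithfully on data
where the truth is known and hairpins fold as designed. It does not show
that the pair-weight folder matches a thermodynamic folder on real
precursors, that real degradation background is uniform (it is not), or
anything about sequencing-bias effects; the simulator models substitution
noise and ligation bias not at all.

## Problem sizes

The default test suite folds windows up to ~1 kb and runs the planted-truth
study at 3 libraries x 200k reads with 40 loci (about three minutes on one
core); unit tests use 2 libraries x 20k reads. Oracle equivalence is checked
on 10,000 random miRNA/site pairs and several hundred random sequences of
length <= 16 (the enumeration oracle is exponential).

## Known limitations

- The folder has no loop penalties; its optimum is degenerate and only
  topology, not stability, is meaningful. Free-energy statistics require a
  thermodynamic plug-in.
- Exact-substring ncRNA exclusion misses diverged copies.
- Multi-mapping tags contribute their full count at every locus in the
  strand-bias denominator.
- Family grouping uses ungapped best-overlap distance; gapped similarity is
  not considered.
- The GFF3 writer emits precursor and mature features only (no star
  features).
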