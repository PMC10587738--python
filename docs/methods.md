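# Methods

## Scope and data model

`circadyn` post-processes eccDNA catalogs — the per-circle output of a
split/discordant-read detector — and never touches reads or alignments.
All coordinates are BED-style 0-based half-open and a record's length is
always `end − start`; catalogs are TSV with an explicit header because
the detection statistics (score, coverage summaries) are first-class
inputs to filtering, not BED extras.  Contigs named `chrM`/`MT` are
treated as mitochondrial: their records are dropped at read time and the
per-sample mapped-read denominator is defined to exclude them.  Whether
"total mapped reads" counts reads or read pairs is left to the upstream
aligner; the package treats it as an opaque positive integer per sample.

## Filtering

Five criteria, each a strict inequality (boundary equality fails):
split reads > 2; score > 200; mean inside coverage > population sd
(ddof 0) of the inside coverage vector; coverage increase at both the
start and end coordinate > 0.3; uncovered fraction < 0.1.  Pass/fail is
a conjunction and order-independent; the fixed (1)–(5) order only
attributes each failing record's *first* violated criterion in the
report.  Detectors do not expose how their internal edge-increase ratio
is computed, so for simulated coverage vectors the package defines a
reproducible surrogate: with `w = min(25, length)` bases,
`inc = (mean of first w inside bases − mean of w flank bases) /
max(mean of first w inside bases, 1e-9)`, clipped to [0, 1], and
symmetrically at the end; an empty flank (contig edge) counts as zero
depth.  `w` and the sd convention are config-exposed.

## Catalog metrics

**EPM** = (number of distinct post-filter circles) / (mapped reads
excluding mitochondrial) × 10⁶.  Distinctness is by (chrom, start, end);
counting unique circles is the package's reading of the per-million
normalization and is config-switchable.

**Length peaks.**  1-bp histogram over [50, 800] bp, Gaussian-smoothed
(sd 2 bp), local maxima with prominence ≥ 5 % of the global maximum are
sub-peaks, sub-peaks within 30 bp of one another form a cluster, the
cluster center is its highest sub-peak, and the reported spacing pools
adjacent within-cluster sub-peak differences.  The parameters are
defaults, not constants; they were chosen so that a two-comb ladder with
10 bp tooth spacing and ~2 bp tooth width is resolved without splitting
noise into spurious peaks.  Peak calling below ~1000 records warns.

**GC.**  Record GC over [start, end); flanks are the equivalent-length
windows [start−L, start) and [end, end+L), averaged.  Records whose
flanks leave the contig are excluded from flank statistics and counted,
rather than clipped — clipping would bias the equivalent-length
comparison.  The distribution "peak" is the argmax of a 0.5 %-bin
histogram smoothed with a 3-bin Gaussian; the median is reported
alongside because group comparisons of GC use medians.

## Element and repeat enrichment

Assignment uses the record's start position only (containment in a
half-open interval); an any-overlap mode exists behind a flag but is not
the default.  Element classes are evaluated independently — a start can
count toward exon and CpG simultaneously — because the seven per-class
ratios are not a partition.  A separate partition mode (precedence
exon > 5′UTR > 3′UTR > intron > Gene2kbU > Gene2kbD > intergenic) serves
the exon/intron proportion analysis, where the three fractions plus
intergenic must sum to 1.  Expected fractions use the per-class union of
interval bp over total genome bp; a class with zero span yields an
undefined, flagged ratio.  Repeat ratios default to record starts
because the package consumes catalogs, not reads; a read-interval input
is accepted for read-weighted ratios.  Group comparisons are two-sided
Wilcoxon rank-sum across per-sample ratios.

## Abundance and differential statistics

"eccDNA types" are distinct coordinates; duplicates collapse before gene
counting.  Gene assignment is by junction coordinate within the gene
body — start by default; the end junction uses `end − 1`, the last
covered base of the half-open record, so that a record ending exactly at
a gene boundary is not assigned past it.  Abundance normalizes
length-corrected counts to a composition summing to 10⁶ per sample;
genes with zero counts in every sample are excluded from the universe
(their inclusion would be invisible anyway since they contribute 0 to
the normalizing sum).

The per-gene test is the unpaired two-sided Wilcoxon rank-sum even
though samples are paired pre/post, matching the study design this
implements; a paired signed-rank variant sits behind a flag.  P-values
use an exact permutation enumeration (midranks for ties; two-sided p =
Pr(|W − E W| ≥ |W_obs − E W|) over all labelings) whenever
C(n₁+n₂, n₁) ≤ 20 000, and the tie-corrected normal approximation
otherwise; scipy's exact mode declines ties, which is why the
enumeration is implemented here and scipy serves as the large-n path and
cross-check.  log2FC uses a pseudo-count of 1 abundance unit (needed
because uniquely-present genes have a zero group mean).  Significance is
raw p < 0.05 and |log2FC| ≥ 1; Benjamini–Hochberg q-values are reported
but do not gate.  Unique genes require presence in ≥ 3 samples of one
group (config), absence from the other, and two-sided Fisher p < 0.05 on
the 2×2 sample-presence table.

## Exon clusters

Catalogs are merged across groups; each gene with ≥ 1 eccDNA overlapping
one of its exons forms a cluster (any overlap, half-open); "spanning"
members fully contain at least one exon (`record.start ≤ exon.start` and
`exon.end ≤ record.end`) — containment is the testable reading of
"spanning", and the any-overlap membership is retained upstream of the
selection.  Per-exon group presence is counted at sample level, tested
with the two-sided Fisher exact test, and ranked by total sample
presence with ties broken by spanning-record count then exon id.

## Clinical indices

AUCs are trapezoidal over the 0–120 min grid divided by 60, i.e. in
value-units × hours — the convention consistent with glucose AUCs of
~33 mmol/L·h for ~15 mmol/L curves over two hours; it is
config-switchable.  The Matsuda square root is taken over the full
four-term product (the standard composite form); mean glucose/insulin
are unweighted means of the seven samples.  HOMA-β is undefined
(flagged, not infinite) at FPG ≤ 3.5.  Δ-values are (post − pre)/pre ×
100.  Remission (FPG < 7 and HbA1c < 7) and non-remission (FPG ≥ 7 or
HbA1c ≥ 7) partition the plane exactly; the boundary belongs to
non-remission.

## Association

Pearson throughout (Spearman behind a flag), two-sided p from the
t-distribution with n−2 df.  The Δ-correlation matrix uses
pairwise-complete rows; cells with < 3 complete pairs or zero variance
are flagged NA rather than zeroed.  No multiple-testing correction gates
the matrix; BH q-values accompany it.  Element-fraction–FPG correlations
pool pre and post samples into one correlation per element.  The
mean-of-per-patient-ratios convention is used for AUCins/glu.

## Synthetic-data generator

The generator is the package's study-condition stand-in for deposited
cohort data and is itself tested code.

**Genome.**  Two 1 Mb contigs of 2 kb blocks whose GC levels are drawn
from a Normal(0.40, 0.06) truncated to [0.30, 0.60].  A unimodal block
law is essential: exponential tilting of a uniform law would push the
catalog GC mode to the boundary, whereas tilting a truncated normal
moves an interior mode smoothly, making the 42.3 % target calibratable.
The 2 kb block size makes the equivalent-length flanks of 200–340 bp
records cross block boundaries often enough that flank GC regresses
toward the genome mean, reproducing the flank-below-record GC direction.

**Annotation.**  25 genes per contig on an even grid with jitter, each
14 kb: 1.2 kb UTRs, three 700 bp exons separated by introns, and exactly
2 kb up/downstream flanks.  CpG intervals (1 kb) occupy the 40
highest-GC blocks per contig; repeat elements are placed stratified per
class (SINE 10 %, LINE 15 %, LTR 7 %, satellite 2 %, six minor classes
1 % each).  Class spans were sized so that every element class covers
≥ 3 % of the genome — below that, binomial noise at the 200 000-record
null-calibration scale would exceed the ±5 % O/E band the package
promises for uniform placement.

**Lengths.**  Mixture of two Gaussian combs (centers 201 and 338 bp,
teeth at ±{0,10,20} bp with centered-binomial weights, tooth sd 2 bp)
with weights 0.55/0.35, plus a 0.10 lognormal tail (median 2 kb,
σ = 0.8, capped at 10 kb, floor 50 bp).  This puts ~90 % of mass below
500 bp and populates the 500 bp–2 kb, 2–10 kb and >10 kb bands.

**Placement.**  Importance sampling over blocks with weight
exp(β·(GC − 0.5)).  β is calibrated by bisection on [0, 20] (≤ 25
iterations, monotone response) against the smoothed-histogram GC mode of
a 40 000-record pilot, to a 0.4-point stopping tolerance; an
out-of-range target errors after the endpoint checks.  At each candidate
β the exon-forcing probability f is solved from the measured background
exon-hit rate p so that f + (1−f)·p equals the configured total
exon-start target (default 15 %): forcing alone cannot be the target
because ~5 % of background starts land in exons anyway.  Calibration is
cached per genome.

**Detection statistics.**  A configurable fraction (default 0.9) of
records draws statistics satisfying all five criteria; each remaining
record violates exactly one uniformly-chosen criterion while passing the
others.  Truth labels (0 or the violated criterion index) are retained
in the catalog, so filter sensitivity and specificity are exactly
computable.  Separate coverage-profile modes (true plateau, gap, noisy,
flat-edge, zero) generate per-base vectors for testing the statistics
computation itself.

**Cohort.**  35 patients × {pre, post}, 5000 records per sample by
default.  The post-treatment mapped-read denominator is the pre
denominator divided by 1.35 + 0.25·z with z a per-patient standard
normal, so post EPM exceeds pre EPM on average and varies per patient.
The same z shifts the post-treatment clinical draws — higher post FPG,
2hPG and HOMA-IR, lower post insulin AUC — so ΔEPM correlates
positively with the glycemic deltas and negatively with ΔISSI-2 by
construction.  Clinical curves are built from per-patient targets drawn
around the pre/post group means (FPG 11.05→5.77 mmol/L, HbA1c
10.56→9.02 %, HOMA-IR 3.41→1.53, AUCglu 33.4→22.7 mmol/L·h, AUCins
33.2→58.0 µU/mL·h) as fasting level + a meal bump + a slow ramp, with
amplitudes solved against the exact trapezoid functionals of the grid so
the realized AUCs match their targets.  The first nine patients form the
follow-up sub-cohort (three remission, six non-remission): remission
patients' M12 EPM is drawn at 0.55–0.85 × baseline and their M12
FPG/HbA1c inside the remission region; non-remission at 1.05–1.45 ×
baseline and outside it.

**What the generator does not emulate.**  Read-level data and
sequencing error; rolling-circle amplification bias; mappability
structure, acrocentric/centromeric density dips, and real repeat
sequence (repeats are placement labels, not sequence); linkage between
GC and gene placement; biological inter-patient covariance beyond the
single latent factor.  Passing tests therefore demonstrate that the
analysis operators recover planted structure at realistic scales — not
that the biological effects would be detected in real cohorts.

## Determinism and numerics

Every stochastic operation takes an explicit seed (package default
1437); fixed seeds give byte-identical outputs.  Ratios guard zero
denominators with explicit flags rather than infinities; undefined
correlations (zero variance, < 3 pairs) are NA, never 0; abundance
columns are exact compositions up to float rounding (asserted at 1e-6
relative).  Problem sizes in the test suite — 100 000 lengths for peak
recovery, 50 000 records for GC/exon recovery, 200 000 uniform starts
for the enrichment null, the default 35-patient cohort end-to-end — were
chosen as the smallest scales at which the targeted distributional
features are statistically stable.
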