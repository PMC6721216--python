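# Methods

This note documents the statistical machinery in `splicerhythm`, the
choices made where the design was genuinely open, and what the synthetic
validation scenes do and do not demonstrate.

## Data model and normalisation

Expression data live in a `TimedMatrix`: features × samples with a time
stamp (hours) per sample and a units tag (`counts`, `log2cpm`,
`log2intensity`, `score`). Three sampling designs are built in: 2-h
sampling over 48 h (24 samples, two replicates per circadian phase after
folding), 2-h sampling over 24 h inclusive of both endpoints (13
samples), and 3-h sampling for 30 h starting 12 h post synchronisation
(11 samples).

Counts are normalised with trimmed-mean-of-M-values (TMM) scale factors:
the reference sample is the one whose upper-quartile/library-size ratio
is closest to the mean of that ratio; per-sample factors are
2^(weighted trimmed mean of M-values) with 30 % of M and 5 % of A
trimmed, delta-method (inverse asymptotic variance) weights, and
features that are zero in either sample excluded; factors are
geometric-mean centred. The implementation reproduces the reference R
implementation (edgeR `calcNormFactors`) to ≤1e-6 on shared inputs (a
suite test runs the R oracle). `log2 CPM = log2((count + prior) /
(lib·factor + 2·prior) · 1e6)` with a configurable pseudo-count, default
0.5. The expression filter keeps features with mean CPM ≥ 0.5 over all
samples (inclusive) and then recomputes TMM factors on the kept set.

## Rhythm detection

**Umbrella rank test.** Sample times are folded modulo the candidate
period (24 h or 12 h) into ordered phase bins. A candidate *shape* is a
(peak bin, trough bin) pair; the circle is cut at the trough and the
resulting linear arrangement is scored Mack–Wolfe style: summed
Mann–Whitney pair counts along the rising arm plus summed reversed
counts along the falling arm (ties contribute ½ via midranks). By
default every peak×trough cut is scored (asymmetric envelopes);
`envelope="symmetric"` restricts troughs to the bin opposite the peak.

Each shape's statistic is standardised by its *exact* conditional mean
and variance given the observed value multiset — the variance is
assembled from closed-form expectations of products of pairwise
comparison indicators classified by index overlap, so ties require no
approximate correction — and converted to an upper-tail normal p-value
with a 0.5 continuity correction. The combined statistic is the minimum
per-shape p. Its reference distribution is the permutation null of that
minimum, computed once per time grid from 20 000 seeded permutations
(an internal fixed seed: the null table is part of the method and does
not vary with user seeds), with a mid-p mapping because the statistic
is discrete. For series with ≤ 8 samples the combined statistic's null
is enumerated exactly over all value permutations.

Two points motivated the permutation reference over the textbook
Bonferroni-over-shapes rule: (i) the shape statistics are strongly
dependent, so Bonferroni is drastically conservative (measured
P(p<0.05) ≈ 0.009 on a 13-point null, with a hard failure of any
uniformity check); (ii) with symmetric-only shapes the min-p statistic
takes ~50 distinct values and its atoms reach 7 %, which no monotone
mapping can smooth below a KS-detectable deviation. The asymmetric
envelope set plus mid-p permutation mapping yields measured null rates
of 3.8–5.9 % at the 5 % level and KS uniformity p-values above 0.01 on
all three built-in designs (`combination="bonferroni"` remains available
for compatibility with the conservative behaviour of classic umbrella
implementations). Known residual limitation: p-values of tied
(heavily discrete) data are referred to the tie-free null table; the
observed statistic's moments do account for ties exactly.

**Harmonic (cosinor) regression.** `y = m + a·cos(2πt/T) + b·sin(2πt/T)`
fit by least squares or, by default, by the package's vectorised Huber
IRLS (tuning constant 1.345, scale re-estimated each iteration as the
normalised median-centred MAD, ≤ 50 iterations, coefficient tolerance
1e-8). Amplitude `A = √(a²+b²)`, relative amplitude `A/|m|` (flagged
undefined when |m| < 1e-6, since log2 CPM mesors can sit near zero),
peak phase `(T/2π)·atan2(b,a) mod T`. The rank test folds times; the
regression uses unfolded times, which is the correct treatment of a
48-h series analysed at a 24-h period. statsmodels' RLM with the same
Huber constant is used as an independent cross-check in the tests, not
in the pipeline.

**Detection rule.** Features with relative amplitude < 0.1 are removed
*before* Benjamini–Hochberg correction; significance is `q < 0.05`
(48-h/2-h array design), `p < 0.005` (24-h/2-h design) or `p < 0.05`
(30-h/3-h design), per dataset profile. Relative amplitude is measured
on the log2 scale, so a multiplicative rhythm of given depth passes the
filter only for mesors up to ≈ 8 log2 units (≈ 250 CPM at depth 0.5) —
true of real pipelines of this kind as well.

## Differential rhythmicity of isoform pairs

Candidate pairs are same-gene transcripts rhythmic at the same period,
one below the strict and the other below the loose p threshold
(0.005/0.05; symmetric 0.05/0.05 in the cell-line profile), both passing
the amplitude filter. The test compares two nested cosinor models on
the concatenated series — H0: separate mesors, shared (a, b); H1: all
six parameters free — so a mesor (expression level) difference alone is
never evidence of differential rhythmicity.

With `robust=False` the classical F statistic with its exact
(2, 2n−6) reference is used. The default robust variant computes a
one-step Huber-weighted F (weights from the full-model fit, df-corrected
MAD scale, effective denominator df = Σw − 6) and refers it to a
label-permutation null: each series is mean-centred (removing the mesor
that H0 permits to differ) and the two observations at each time point
are swapped with probability ½, which is exchangeable under the shared-
rhythm null. The asymptotic F references of robust drop-in-dispersion
tests over-reject at these sample sizes (measured 0.074–0.12 at nominal
0.05 for n = 13); the permutation reference measures 0.048 on Gaussian
nulls and 5.6–6.5 % on negative-binomial log2 CPM nulls, and agrees with
an independent classical-F label-permutation oracle to a mean p
difference of ≈ 0.002. Mean-centring (not median) matters: with skewed
counting noise a median offset survives centring and widens the null.
The exchangeability argument assumes comparable noise scales in the two
series; strongly unequal-variance pairs are handled only approximately.

A pair is *phase-shifted* when its BH-adjusted q (pooled over both
periods within a tissue/condition) is below 0.05, its relative-amplitude
ratio max/min is strictly below 2, and its circular phase difference
reaches the period-dependent minimum: period/6 = 4 h at 24 h; 2 h
(tissue profile) or 3 h (cell-line profile) at 12 h. "Amplitude ratio
< 2" is implemented as max/min of the two relative amplitudes, the only
reading consistent with a symmetric pair criterion.

## Probe-level splicing scores

Probe intensities are quantile normalised (column distributions mapped
to the cross-column rank mean; ties get the mean of their would-be
quantiles), then each gene's probes×samples block is decomposed by
median polish (alternating row/column median sweeps, tolerance 0.01,
≤ 10 sweeps) into chip effects (per-sample expression), probe effects
(affinities) and residuals. Residuals are standardised by the gene's
global residual MAD (×1.4826) — per gene, not per sample, so a single
aberrant time point remains visible — and the per-sample score is the
maximum over contiguous probe runs of |Σz|/√(run length), a CUSUM-style
measure of residual persistence. A zero MAD yields zero scores with a
degeneracy flag.

The score series of each gene is then given the same treatment as an
expression series: umbrella test and robust cosinor at 24 h and 12 h,
amplitude filter at 0.1, BH within period, significance `q < 0.1`.
Because the chip effect absorbs whole-gene expression changes, genes
whose overall expression is rhythmic but whose probes move coherently
score near zero at all times. Note a structural property: an event
whose log2 depth oscillates as `depth·cos(2π(t−φ)/T)` produces a score
series proportional to |cos|, which has period T/2 — a 24-h splicing
event is therefore detected at the 12-h harmonic of its score series,
with score phase equal to the event phase modulo 12 h. Array
background correction is out of scope; the generator produces
post-background intensities. Quantile normalisation assumes a
representative number of features: scenes below ~100 genes distort the
rank-mean target and inflate the scan's false-positive rate, so
validation scenes use ≥ 150 genes (real arrays have orders of magnitude
more).

## Circular phase statistics

Circular mean via the angular resultant (undefined below resultant
length 1e-9), circular median as the data phase minimising summed
circular distances (lowest-value tie-break), dispersion as the mean
circular distance from the mean, circular SD as √(−2 ln R̄)·T/2π. The
two-cluster phase decomposition is k-means on the circle: assignment by
circular distance, centroid update by circular mean, seeded restarts
initialised from a data phase plus equal offsets around the circle
(antipodal for k = 2), best restart by within-cluster distance sum;
iterations stop rather than let the (not exactly minimised) objective
rise, making the objective non-increasing by construction. The "±"
reported with cluster centres is the circular SD of the cluster's
members.

## Promoters and motif enrichment

Promoter windows are TSS ± flank inclusive (2·flank+1 bases; the BED6
input is 0-based half-open, the TSS is the 5′ end of the interval),
reverse-complemented on the minus strand, truncated with a flag at
contig ends, and deduplicated by exact sequence keeping the first. GC
content excludes ambiguity codes from numerator and denominator. Group
comparisons use the Wilcoxon rank-sum test (exact for ≤ 12 tie-free
observations, otherwise tie-corrected normal approximation with
continuity correction, via SciPy).

Motifs are position probability matrices read from MEME minimal files
(Biopython parser; a small pseudo-count keeps all probabilities
positive). The average-odds score of a sequence is the mean over all
start positions on both strands of Π p_motif/p_background, with
ambiguous positions contributing odds 1. Enrichment of a motif in a
positive set uses per-sequence mononucleotide shuffles as 1:1 controls
(dinucleotide shuffling available), a one-tailed Fisher's exact test of
the above/below × positive/control table at every observed score
threshold, and reports the minimum Fisher p times the number of
thresholds (capped at 1) — a partition-maximisation reading whose
calibration is gated by a null-simulation test (measured P(p<0.05) = 0
over 200 null scenes at the 5 % level; the Bonferroni over thresholds
is deliberately conservative). The background model is the 0-order
base composition of the positive set, configurable. BH adjustment is
applied across a motif set.

## Synthetic data

The generator defines the study conditions. Rhythms are multiplicative
on the linear scale, `λ(t) = baseline·(1 + ρ·cos(2π(t−φ)/T))` with
ρ ∈ [0, 1), so two same-gene isoforms with equal baseline and ρ and
antiphasic peaks cancel *exactly* in the gene-level sum — rhythm
masking is an algebraic property of the generator, not a statistical
accident. Counts are negative-binomial (gamma–Poisson; Poisson at
dispersion 0) with mean `baseline(CPM) · libsize/1e6`. Defaults chosen
once and documented here, since source datasets of this kind do not
publish their noise magnitudes:

* library size 3×10⁷ per sample — typical bulk RNA-seq depth; at
  shallow depths the Poisson floor would dominate the biological
  dispersion for low-CPM transcripts;
* baselines of unspecified transcripts log-normal, median 20 CPM,
  log-sd 0.8;
* transcripts per gene geometric on [1, 18] with mean ≈ 1.7 expressed
  transcripts per gene, the typical mammalian-tissue ratio;
* dispersion regimes: 0.05 ("moderate", CV ≈ 23 % at 20 CPM — the
  package default, tissue-like), 0.02 ("low"), 0.01 ("minimal", used
  by the pair-calling validation scene so that upstream detection is
  near-certain and the scene measures the pair rules themselves);
* background filler genes (default 50) absorb the residual library
  mass 1e6 − Σ baselines, so a small scene behaves like a slice of a
  full transcriptome and stated baselines really are CPMs.

The probe-level generator writes `chip(t) + probe affinity + event +
noise` in log2 units, with per-gene chip effects optionally rhythmic so
the scan's insensitivity to expression rhythms can be verified, and
events as `depth·cos` on a contiguous probe run. The promoter generator
plants motif samples at recorded positions in i.i.d. backgrounds of
chosen GC.

What the scenes do *not* emulate: quantification uncertainty and
read-level effects (counts are drawn directly), isoform-correlated
noise within a gene, tissue-to-tissue structure (a tissue is a label),
length biases, and array background. Passing tests therefore
demonstrate the statistical machinery under its stated model, not
performance on any real dataset.

## Validation scene sizes

The default suite runs in ≈ 1 minute on one CPU: null calibrations use
1000 features/pairs, power and recovery scenes 160–500 genes, masking
100 seeded repetitions, motif calibration 200 seeded scenes. These
sizes put Monte-Carlo error comfortably inside the asserted bands while
keeping the suite quick.

## Known limitations

* A calibrated (uniform-null) rank test necessarily leaves 10 % of
  truly flat gene-level profiles below p = 0.1; workflows that require
  "arrhythmic at gene level" as a hard property should treat p > 0.1 as
  a screen, not proof of arrhythmicity.
* The umbrella test's null table is shared across features of a grid;
  heavily tied data are approximately handled (exact moments, tie-free
  reference).
* The robust pair test's permutation reference assumes comparable
  noise scale in the two series after centring.
* The splicing score detects a T-periodic event at T/2 of the score
  series by construction; the 24-h/12-h scan pair covers this, but a
  12-h event's score rhythm at 6 h would require adding that period to
  the scan list.
* Median polish is run to a 0.01 sweep tolerance (at most 10 sweeps),
  so polish-based invariances hold to that tolerance, not to machine
  precision.
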