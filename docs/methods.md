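# Methods

This note records the models, conventions and design choices behind
`epistate`, in the spirit of the methods documentation of statsmodels or
msprime: what is computed, under which assumptions, with which defaults,
and what the synthetic cohorts do and do not establish about real data.

## Coordinates and interval algebra

All coordinates are 0-based, half-open (BED convention); 1-based input
dialects (GFF3, Bismark coverage) are converted at the reader boundary.
The universal peak representation, `IntervalSet`, is a normalized
territory: per chromosome, intervals are sorted, non-overlapping and
non-bookended.  Overlapping or touching input records are merged on read
because every downstream statistic (co-occupancy, bivalency, occupancy
fractions, bin proportions) is defined on territory bp, not on records;
per-record names and scores are therefore not carried through
normalization (the raw-record reader preserves them when needed).
Normalization is idempotent and `total_bp` is invariant to record order —
both are property-tested, and all set operations are checked against
per-base boolean-array brute force on random 100 kb instances.

**TSS distance convention.** bedtools dialects differ by ±1 around
interval ends, so the convention is fixed explicitly: the distance from a
peak `[start, end)` to a TSS `t` is `max(0, start − t, t − end)` — zero
for overlap or a bookended touch, otherwise the gap in bp, minimized over
TSSs on the same chromosome.  Peaks on chromosomes without an annotated
TSS are flagged missing rather than erroring.

**Promoter windows** are strand-aware: `[tss − up, tss + down)` on the
plus strand, mirrored on the minus strand, clipped to the chromosome.  The
bivalency analysis uses ±2 kb; promoter-occupancy matrices default to
−2 kb/+300 bp, the convention for the sharp H3K4me3 promoter signal, and
−2/+2 kb is passed explicitly for broad marks.  A window entirely outside
the chromosome, or empty after clipping, is an error rather than a silent
zero-width region.

**Genome binning** (default 500 bp) reports the marked proportion of each
bin; the final short bin of a chromosome is normalized by its actual
width so that `Σ bin_fraction × bin_width` conserves territory bp exactly.
Restriction to autosomes is a caller-supplied chromosome filter, not
hard-coded.

## Promoter states and co-occupancy

A promoter is *bivalent* when its window overlaps ≥1 bp of both H3K4me3
and H3K27me3 peak territory (bedtools-intersect default semantics),
*active*/*repressed* with one mark only, else *unmarked*; the four counts
partition the gene universe exactly for every sample.  Bivalent *regions*
are the bp-intersection of the two marks.  The H2AK119Ub1 flag is defined
only for samples where the mark was profiled; ub-stratified summaries
exclude unprofiled samples rather than imputing.  Fusion-target promoters
enter as an input gene list; deriving targets from raw fusion ChIP-seq is
out of scope.

Co-occupancy of an anchor mark with every other mark is computed over
territory bp by default (`|A ∩ M| / |A|`); a peak-count convention (the
fraction of anchor peaks touching ≥1 peak of M) is available behind
`mode="count"` since published figures do not always state which was used.

Two-group mean contrasts use the Welch t test (unequal variances,
Welch–Satterthwaite degrees of freedom) via scipy.  Degenerate inputs are
defined explicitly: two zero-variance groups with equal means give t = 0,
p = 1; with unequal means, p = 0.

## Enhancer continuum

Raw region counts are normalized to reads-per-kb-per-million
(`x·10⁹ / (library_size · width)`, library size = sample row sum); a
zero-count sample is an error.  Differential regions replace DiffBind's
negative-binomial machinery with a self-contained, defined test: Welch t
on log2(signal + 1), Benjamini–Hochberg across regions, calls at
|log2FC| > 1 and q < 0.05 by default (all three are explicit parameters).
Its error control is verified by simulation: planted log2FC-3 regions are
recovered with observed false-discovery proportion ≤ 0.05-ish at q < 0.05,
and null matrices give uniform p-values (the planted-signal generator uses
log-normal noise, so the t reference distribution is essentially exact).

The continuum score is log10(mean normalized signal over region set 1)
− log10(mean over set 2) per sample — mean, not sum, so the score is
invariant to region-set size; the statistic is configurable because
published "signal intensity" is ambiguous between the two.  The score is
antisymmetric under swapping the sets and its sample ordering is invariant
to global rescaling.  Quartiles are rank-based with ties broken by stable
sample-id order (Q1 = top quarter).  TSS-distance distributions of two
peak sets are compared by the two-sample Kolmogorov–Smirnov test on the
distances, with right-continuous ECDFs returned for plotting.

## Methylome

Regional fractional methylation is the coverage-weighted mean
Σfᵢcᵢ / Σcᵢ.  The minimum-coverage filter (default 3×) is applied per CpG;
because "minimum coverage to filter regions" is ambiguous, a per-region
total-coverage variant is available (`per_region_total=True`).  Missing is
a legal value (NaN) wherever no CpG qualifies; raising the threshold can
only reduce the number of defined regions.  CpG strand collapsing is
assumed done upstream.  The Bismark coverage reader derives fraction and
coverage from the methylated/unmethylated counts, ignoring the rounded
percent column.

Shores are the islands dilated by the shore width minus island territory,
clipped and merged; the default width is 2000 bp, the field-standard
definition (the value is rarely stated in publications and is
configurable).  The shore gradient assigns each shore CpG its distance to
the nearest island edge (the first bp outside an island has distance 1)
and reports coverage-weighted means in `[0, bin)`, `[bin, 2·bin)`, …

## Survival analysis

Implemented directly because the exact conventions matter and are checked
against independent oracles (lifelines serves as a cross-check in the test
suite, never as the implementation):

* **Kaplan–Meier**: product-limit estimator, S(0) = 1, steps only at event
  times, censoring reduces the risk set without a step.  Verified against
  hand product-limit computation at every event time and against the
  empirical survival function when no censoring is present.
* **Log-rank**: at each event time, observed minus hypergeometric-expected
  events in group 1 with the usual variance; the statistic (ΣO−E)²/ΣV is
  referred to χ²₁.  Verified against a 10⁵-replicate label-permutation
  oracle.  The asymptotic p-value tracks the permutation p within ~0.02 at
  n = 30; the residual gap is the finite-sample error of the chi-square
  approximation itself (any asymptotic log-rank implementation shows it),
  not Monte-Carlo noise.
* **Cox proportional hazards**: partial-likelihood maximization by Newton
  iteration to gradient norm < 1e-8, Breslow tie handling (chosen for its
  closed-form risk-set sums; ties arise only through time rounding).
  Categorical covariates are one-hot encoded against a stated reference
  level (first sorted level by default).  Non-convergence within 100
  iterations is an error, and |β| > 15 — a hazard ratio beyond e¹⁵ — is
  diagnosed as a monotone likelihood (complete separation) rather than
  reported as an estimate.  Verified against a 1-D partial-likelihood grid
  search (1e-4 resolution), against lifelines, and by parameter recovery
  on simulated exponential survival.

The bivalency count enters Cox models as a raw continuous covariate by
default (log or scaled transforms are the caller's choice).

## Prognostic stratification and the proxy classifier

The bivH/bivL split is the exact variance-minimizing two-class partition
of the sorted bivalent counts (equivalently Otsu / 1-D 2-means), with the
higher-mean class labelled bivH; ties between cut points resolve to the
lowest cut, making the split deterministic and sample-order invariant.  A
fixed count threshold can override the data-driven split for clinical use,
where a frozen decision boundary is preferable to a cohort-dependent one.

Marker genes must be bivalent in ≥60% of bivH samples and active in ≥60%
of bivL samples (the majority fraction is exposed; published descriptions
give only the concept and the panel size), then pass BH q < 0.05 on a
Welch contrast of log2 expression, and are ranked by |log2FC|; the top 50
form the default panel.  The proxy classifier is a seeded random forest
(scikit-learn) on marker expression; its reported training performance is
a stratified cross-validated ROC AUC rather than resubstitution, and
predictions are deterministic given the seed.  The exact tuning grid of
the published model is not reproducible from its description; the seeded
default here is documented, not asserted as equivalent.

## Cohort clustering

Sample distance is 1 − Spearman correlation of feature profiles (range
[0, 2]), so clustering is invariant to any strictly monotone per-sample
transform — and, consequently, blind to pure level shifts between
samples; planted structure must differ in profile shape.  Agglomeration
is Ward.D2 via scipy's Lance–Williams implementation on the distance
input, checked against a hand-computed three-sample recurrence; flat
two-group labels come from cutting the tree at k = 2.  A zero-variance
sample profile has no rank correlation and raises an error naming the
sample.

Stability is assessed by ordinary bootstrap probabilities: features are
resampled with replacement (default 1000 replicates, ≥100 enforced), the
samples reclustered, and each original cluster scored by the percentage of
replicates containing the same membership; the top-split probability
scores the k = 2 bipartition, with 70% kept as the conventional reporting
threshold for stability.  Multiscale "approximately unbiased" corrections
(pvclust-style) are deliberately not applied — plain BP is what is
reported.  In bootstrap replicates a resampled profile that happens to be
constant is treated as rank-uncorrelated instead of erroring.  Variance
filters (top-fraction by variance, std > 1.25 × mean, low-signal-in-all-
samples) compose in the stated order; top_fraction = 1.0 is the identity.

## The synthetic cohort generator

Defaults are the study conditions the analyses assume, chosen once:
40 samples, 2000 genes on four 5-Mb chromosomes, a 25% bivalent-capable
promoter pool, planted bivalent counts of 120–200 (bivL) vs 380–460
(bivH), `resolution_strength` 1.0 (unselected pool promoters resolve to
the active state, reproducing the near-perfect directional
bivalent→active coupling seen in tumor cohorts), hazard ratio 4 at
baseline hazard 0.01/month with 20% uniform censoring, 50 planted switch
genes at +2 log2FC in bivL, 500 enhancer regions with 50 specific per
group at 2 log10 units of separation blended continuously per sample, and
island/shore/background methylation of 0.10 / linear ramp / 0.80 with
Poisson(30) coverage and binomial counts.  Peak widths are log-normal
with mark-specific medians (narrow H3K4me3, broad H3K27me3/H2AK119Ub1,
with a configurable broad-domain multiplier for H3K4me3).  Survival is
exponential for closed-form hazard control.

The genome is zoned: promoters occupy the first 80% of each chromosome
with peaks clipped so that a peak planted at one TSS can never reach a
neighboring promoter window — this makes the emitted peak files *exactly*
consistent with the ground-truth state table (verified by a round-trip
test through the readers and the classifier).  The remaining 20% holds
intergenic regulatory sites (which carry the H2AK119Ub1/active-mark
co-occurrence structure), CpG islands with their shores, and the enhancer
regions.  All randomness flows from the single spec seed through
`SeedSequence.spawn`, one child stream per stage, so emitted trees are
byte-identical across runs and stage-level tests are independently
reproducible; `emit` writes a sha256 manifest.

What the generator does *not* emulate — and hence what passing tests do
not establish about real data: read-level noise and ChIP-seq background,
peak-caller artefacts, correlated mark boundaries, copy-number and purity
effects, promoter-CpG methylation coupling (promoter methylation tables
are exercised on constructed fixtures), non-exponential hazards, and
cohort-level confounding between covariates.  The planted structure is
deliberately clean; the tests demonstrate correctness of the statistics
and recoverability of planted signal at stated effect sizes, not
performance on noisy tumors.

## Problem sizes

The default test-suite and acceptance-script problem sizes — 100 random
100-kb instances for the brute-force equivalences, 10⁵ permutations for
the log-rank oracle, 100/1000 replicates for power and calibration, 50
seeds for differential recovery and for the classifier permutation null —
were chosen to keep Monte-Carlo error comfortably below the asserted
margins while the whole suite runs in about a minute.
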