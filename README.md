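# epistate

Chromatin-state analytics for tumor cohorts profiled by histone-mark
ChIP-seq, whole-genome bisulfite sequencing, RNA abundance and clinical
follow-up.  The package was built for the kind of question raised by
fusion-driven sarcomas such as synovial sarcoma, where the SS18::SSX
oncoprotein rewires polycomb-marked chromatin: with few recurrent mutations,
the clinically relevant variation lives in the epigenome — in how many
promoters are *bivalent* (carrying both the activating H3K4me3 and the
repressive H3K27me3 mark), in how those bivalent promoters resolve toward an
active state, and in enhancer and methylation landscapes that trace cell of
origin.

It is a library for epigenomics analysts: every stage is a plain function
over standard containers (pandas frames, interval sets), with a thin CLI on
top and a fully seeded synthetic-cohort generator so the whole pipeline is
testable without any restricted-access data.

## What it computes

**Promoter chromatin states.** From per-sample MACS2-style peak files, a
promoter (window ±2 kb around the TSS, strand-aware) is called per sample as

* *bivalent* — ≥1 bp overlap with both H3K4me3 and H3K27me3 peak territory,
* *active* — H3K4me3 only, *repressed* — H3K27me3 only, else *unmarked*,

with an H2AK119Ub1 co-marking flag where that mark was profiled.  Bivalent
regions themselves are the bp-intersection of the two marks' territories.
All peak statistics are territory-based: overlapping input peaks are merged
(0-based half-open BED coordinates throughout).

**Co-occupancy and occupancy.** For an anchor mark A and any mark M, the
co-occupancy is |A ∩ M| / |A| in bp; genome occupancy, per-bin (500 bp)
marked proportions, peak-width distributions and promoter-occupancy matrices
(e.g. TSS −2 kb/+300 bp for H3K4me3) support cohort-level clustering.

**Prognostic bivalency stratification.** Per-sample bivalent-promoter counts
are split into bivalency-high (bivH) and bivalency-low (bivL) groups by an
exact variance-minimizing two-class split of the 1-D count distribution.
Survival is analysed with the Kaplan–Meier product-limit estimator, the
two-group log-rank test, and Cox proportional hazards
(λ(t|x) = λ₀(t)·exp(βᵀx), Breslow ties, Newton iteration) over covariates
such as sex, fusion variant, anatomic location and the bivalency group or
count.  The directionality of bivalency resolution is quantified as the
Pearson correlation between bivalent and H3K4me3-only counts across samples.

**Marker genes and proxy classifier.** Genes that switch from bivalent (in
bivH) to an expressed active state (in bivL) are selected by state-majority
eligibility plus differential expression (Welch t on log2 signal, BH), and a
seeded random-forest classifier on marker expression predicts the bivalency
group from expression alone, reporting a cross-validated ROC AUC.

**Enhancer continuum.** Candidate enhancer signal is RPKM-normalized;
group-specific regions are called with a defined two-group test (Welch t on
log2(signal+1), BH, |log2FC| and q thresholds); each sample's continuum
score is log10(mean signal over group-1 regions) − log10(mean over group-2
regions); quartiles of that score and TSS-distance ECDFs (two-sample KS)
characterize the distal/proximal enhancer axis.

**Methylome.** Fractional methylation of a region is the coverage-weighted
mean Σfᵢcᵢ/Σcᵢ over CpGs with coverage ≥ 3 (Bismark-style coverage input);
CGI shores are the ±2 kb flanks of islands, and the shore gradient bins
shore CpGs by distance to the island edge.

**Synthetic cohorts.** `epistate.simulate` plants all of the structure the
analysis assumes — promoter-state mixtures with a directional
bivalent→active continuum, hazard-coupled survival, blended enhancer
archetypes, island/shore/background methylomes, switch-gene expression —
and emits it as BED/TSV/coverage files with a checksum manifest, fully
reproducible from one seed.

## Worked example

```python
import epistate as ep
from epistate.simulate import CohortSpec, simulate_cohort

cohort = simulate_cohort(CohortSpec(seed=1))          # 40 samples, 2000 genes
table = ep.build_state_table(cohort.mark_sets.values(),
                             cohort.genes, cohort.layout)
profile = ep.split_biv_groups(ep.bivalency_counts(table))
print(profile.counts.join(profile.groups).head(4))

r = ep.resolution_correlation(profile)
print(f"bivalent vs active-only Pearson r = {r['bivalent_vs_active']:.3f}")

chi2, p = ep.logrank_test(cohort.survival, profile.groups.to_dict())
print(f"log-rank chi2 = {chi2:.2f}, p = {p:.2e}")
print(ep.cox_ph(cohort.survival, ["bivalency_count"]).round(4))
```

prints

```
      active  bivalent  repressed  unmarked group
S000    1036       382        223       359  bivH
S001    1209       185        231       375  bivL
S002    1288       124        227       361  bivL
S003    1228       194        206       372  bivL
bivalent vs active-only Pearson r = -0.993
log-rank chi2 = 13.49, p = 2.39e-04
                   coef  hazard_ratio      se      z       p
bivalency_count  0.0052        1.0052  0.0016  3.249  0.0012
```

Reading: each sample's promoters partition into the four states; the
data-driven split separates bivH from bivL tumors; the strong negative
correlation (−0.99) says that samples with fewer bivalent promoters have
correspondingly more H3K4me3-only promoters — directional resolution toward
the active state; and the planted survival disadvantage of the bivH group
is recovered by both the log-rank test and the Cox model (each extra
bivalent promoter multiplies the hazard by ≈1.005, i.e. ≈4× across the
observed count range).

The same pipeline is available from the shell:

```sh
epistate simulate --out cohort/
epistate bivalency cohort/ --out bivalency.tsv
epistate survive cohort/survival.tsv --out surv/
epistate markers cohort/ -k 50 --out markers.tsv
```

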