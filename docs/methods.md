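# Methods

## The problem

Tumors of a given cancer type often gain DNA methylation at CpG sites that
remain unmethylated in the matching normal tissue, in healthy tissue, and
in other cancer types. Such *cancer-type-specific hyper-methylated CpGs*
are attractive diagnostic markers: methylation fractions are bounded,
stable, and measurable on standard 450K-style arrays. `methylmark`
implements the full discovery workflow — differential methylation, CpG
island methylator phenotype (CIMP) calling, methylation–expression
correlation screens, a multi-cohort specificity cascade, and a progressive
logistic diagnostic — together with a synthetic-data generator that plants
every structure the workflow is meant to find.

## Site-level differential methylation

Methylation at probe *i* in sample *j* is the beta value
β = M / (M + U + offset), the methylated intensity over total intensity.
The default offset is 0 (the plain ratio); Illumina's conventional +100 is
available as a parameter. Probes on chrX/chrY, SNP-overlapping probes, and
probes with detection p > 0.01 in *strictly more than half* of samples are
excluded before analysis ("more than half" is read literally: failing in
exactly half retains the probe).

For each probe, tumor and normal groups are compared with the paired or
Welch (unequal-variance) t-test when beta values look normal, otherwise the
paired Wilcoxon signed-rank or Mann–Whitney rank-sum test. Normality is a
Kolmogorov–Smirnov check of the standardized values against N(0,1) at
α = 0.05; because a single family of tests should apply to one dataset,
the default is a *global* decision — a majority vote of per-probe K-S
checks over up to 500 evenly spaced probes — with per-call override.
Wilcoxon handling: zero differences dropped, exact null for n ≤ 25, normal
approximation with continuity correction above; all-zero-difference
vectors are reported as non-significant (p = 1).

A probe is a differentially methylated CpG (DMC) when
|Δβ| = |mean(tumor) − mean(normal)| > 0.2 and the Benjamini–Hochberg FDR
(computed over all tested probes) is < 0.01; the sign of Δβ gives the
hyper/hypo direction. Missing beta values use pairwise deletion; in paired
tests a pair with either member missing is dropped.

Region-level methylation is the arithmetic mean of the non-missing member
CpGs of a (gene, region) group, where regions are CpG-island-relative
(Island, N/S shores at 0–2 kb, N/S shelves at 2–4 kb) or TSS-relative
(TSS200, TSS1500, 5'UTR, FirstExon, Body, 3'UTR). Feature enrichment of
hyper vs hypo (or hyper vs all retained) CpGs uses Fisher's exact test on
the 2×2 feature-by-set table, reported with the sample odds ratio
OR = ad/bc and Woolf's log-OR 95% interval; when the reference set
overlaps the hyper set, the overlap is removed from the reference, so one
routine serves both contrasts. Zero cells give OR ∈ {0, ∞}, an unbounded
CI and a degenerate flag rather than a continuity correction.

## CIMP calling

CIMP candidates are CpGs with tumor standard deviation > 0.2 and normal
mean < 0.05 — variable across tumors, silent in normals. The cluster
number k is chosen by Monti-style consensus clustering: for each k in the
candidate range, samples are repeatedly subsampled (80%, 100 resamples by
default) and K-means-partitioned; the consensus matrix entry (i, j) is the
fraction of co-subsampled runs in which i and j co-clustered. The chosen k
minimizes PAC — the proportion of off-diagonal consensus entries strictly
inside (0.1, 0.9) — with ties going to the smallest k. Tumors are then
partitioned by K-means (k-means++ initialization, 20 restarts, fixed
seed), and the cluster with the highest mean beta over the selected CpGs
is the CIMP cluster (exact ties: lowest cluster index, with a warning).
Survival of CIMP vs non-CIMP samples is compared by Kaplan–Meier estimates
and the multi-group log-rank test (lifelines), using overall survival in
days with right censoring.

PAC is our concrete criterion for an otherwise under-specified "consensus
clustering" step; it is the standard modern choice but other consensus
summaries exist.

## Expression and cis/trans correlation

Differential expression is a deliberately simple caller — log2(CPM + 1)
with per-sample library-size normalization, per-gene Welch t-test, BH FDR,
|log2 FC| > 1 and FDR < 0.01 — standing in for a negative-binomial GLM
package, which is a called tool in this workflow rather than part of its
contribution; externally computed DE tables (gene, log2_fc, p, fdr) drop
in unchanged. Correlation screens compute Pearson r between a CpG's beta
and log2 CPM over matched samples, with the two-sided p from the
t-distribution on n − 2 df. *Cis* pairs a DMC with its own annotated gene;
*trans* pairs each DMC with every DEG except that gene. Calls are
Neg/Pos at p < 0.05, NS otherwise; constant vectors are NS with a
degenerate flag. Bias summaries stratify call fractions by (CpG direction
× gene direction × mode).

The expression scale for correlation (normalized log2 CPM rather than raw
counts) is our choice; raw-scale correlation would be dominated by library
size.

## Specificity cascade

Starting from all retained probes, a candidate marker must be
hyper-methylated (the same Δβ > 0.2, BH FDR < 0.01 rule, FDR computed
within each comparison over the current candidate set) in, successively:
target tumors vs matched normals (paired); target tumors vs normals
(unpaired); target tumors vs healthy tissue; and target tumors vs *every*
background cohort's tumors and normals separately. Stages short-circuit
for efficiency; surviving probes carry all stage flags for audit.
Reusing the single stated site-level rule for every comparison is the
least-surprising concretization; comparisons with fewer than 3 samples
are skipped with a warning and the panel marked partial. The cascade is
monotone — adding a background cohort can only shrink the final set — and
invariant to cohort processing order (each comparison only conditions on
the surviving candidate set, which shrinking comparisons reach in any
order only through intersection).

## Diagnostic model

Candidate markers are ranked by information gain
IG = H(y) − Σ_b p(b) H(y | b) in bits, with bins from equal-frequency
10-quantiles of the beta values (the discretization is our declared
choice; it is recorded in the model metadata). Progressive logistic models
include the top 1..k probes in ranking order. The fit minimizes the
per-observation objective −(1/n) Σ log-likelihood + (λ/2)‖w‖² with the
intercept unpenalized, by Newton/IRLS iterations to a 1e-8 coefficient
tolerance; λ = 1e-4 by default. The penalty guarantees a finite optimum
under perfect separation — the expected regime for markers pre-selected at
Δβ > 0.2 — and the per-observation scaling makes the fit invariant to
duplicating every sample. ROC/AUC use the Mann–Whitney rank formula with
half-credit for ties; cross-cohort screening reports the percentage of
each cohort/tissue group with predicted probability ≥ 0.5 (the threshold
is our choice). The penalized training log-likelihood is checked to be
non-decreasing in k, as nested models with fixed λ must be.

The reference workflow evaluated on an independent testing cohort from a
public repository; with synthetic data the package instead holds out a
seeded stratified 30% split of the target cohort as the testing set.
Beta values cross platforms unharmonized by design.

## The synthetic generator

`simulate` emulates, per probe class, the statistical structure the
pipeline assumes:

- **Baselines.** Per-probe mean μ drawn by CGI context — Island ~
  Beta(1.2, 10), shores/shelves ~ Beta(2, 6), open sea ~ Beta(5, 2.5) —
  giving the bimodal marginal typical of 450K arrays. Observed beta is
  Beta(μκ, (1 − μ)κ) with concentration κ = 50 by default (per-probe
  noise sd ≈ 0.03–0.07), bounded in [0, 1] by construction.
- **Design.** Default study conditions: a 50-pair target cohort, four
  background cohorts of 40 tumors / 20 normals, 30 healthy samples,
  20,000 probes with 5% SNP-flagged and 3% sex-chromosome probes. Paired
  samples share a patient id; pairing is exact-id match.
- **Markers.** Eight autosomal SNP-free TSS200 probes with distinct genes,
  baseline μ ∈ [0.02, 0.04], shifted by marker_delta = 0.4 in target
  tumors only.
- **Decoys.** 2% of probes are hyper in *every* cohort's tumors
  (+0.3): they clear the within-target stages and must be rejected by the
  background comparisons.
- **CIMP.** The block = markers + 100 extra CpGs that are hypervariable in
  all tumors (per-tumor iid Uniform(0, 0.6) shift, normal baseline
  ≤ 0.04); a 20% subset of target tumors gains a further
  cimp_delta = 0.3 across the block. The planted variability is what
  makes the sd > 0.2 selection rule able to find the block — the bimodal
  CIMP shift alone contributes sd ≈ 0.12 — and pan-cohort variability
  keeps the extra CpGs out of the final cascade panel. Because markers
  belong to the block, the realized target Δβ is marker_delta +
  cimp_fraction·cimp_delta ≈ 0.46 under the full default configuration.
- **Survival.** Exponential event times (baseline median 1500 days), CIMP
  hazard = hr × baseline (hr = 3 by default), a censor_rate fraction of
  samples censored at a uniform fraction of their event time.
- **Expression.** Negative-binomial counts (size 10), gene base means
  log-normal around 500. Marker genes: log mean = base +
  expr_coupling · beta at the promoter CpG (expr_coupling = −2), which
  plants the negative methylation–expression coupling; a disjoint set of
  40 genes gets an explicit ±2 log2-fold shift in tumors.
- **Intensities.** meth = βs, unmeth = (1 − β)s at scale s, so the
  beta computation round-trips exactly with noise off; detection-p
  failures plantable per probe or globally.

All draws flow from one seeded generator: identical configs give
bit-identical outputs, and the full pipeline re-run under the same config
is byte-reproducible.

What the generator does **not** emulate — and hence what green tests do
not certify on real data: Infinium type-I/II chemistry and dye bias, batch
effects, cell-type composition, spatial probe correlation along the
genome, copy-number interference with intensities, population structure in
SNP probes, and platform shifts between training and testing cohorts.
Recovery results on planted structure bound algorithmic correctness, not
real-world sensitivity.

## Numerical choices and degenerate inputs

- BH FDR via `statsmodels.stats.multitest`; adjusted values are monotone
  in raw p and never smaller.
- Constant vectors: normality check raises; correlations return NS with a
  degenerate flag; information gain raises on single-class labels or
  constant features.
- K-S normality uses standardized values against N(0,1); with estimated
  moments this is conservative (accepts normality slightly too often),
  which matches its screening role.
- Probes untestable for DMC status (fewer than 3 observations in a group)
  are reported `ns` with a reason rather than dropped.
- Fisher's p from `scipy.stats.fisher_exact`; the odds ratio reported is
  the unconditional sample OR, not scipy's conditional MLE.
- Tie rules everywhere are deterministic and documented: smallest k for
  PAC ties, lowest cluster index for CIMP mean ties, probe id for IG and
  FDR ties.

## Problem sizes used in the validation suite

The test-suite and the acceptance script exercise the generator at its
default study scale (20,000 probes, five cohorts, ~370 samples) for
marker-recovery runs across 20 (suite) / 10 (script) seeds, 5,000-probe
null panels for FDR calibration, 200 replicates for log-rank
calibration/power, and 1,000 independent pairs for the correlation null.
These sizes give Monte-Carlo margins comfortably below the asserted
tolerances while keeping a full run in the low minutes on one core.

## Known limitations

- The consensus-clustering criterion (PAC) and the IG discretization are
  declared choices where the underlying procedure is under-specified;
  alternatives (delta-area CDF criterion, MDL binning) may choose
  differently on borderline data.
- The DE caller is a t-test on log CPM, adequate for the planted
  large-effect simulations but not a substitute for count-model inference
  on real RNA-seq; use the external-table interface for fidelity runs.
- The cascade treats "significantly hyper vs another cohort" as a direct
  two-sample comparison at the site-level rule; requiring the other
  cohort's own Δβ to be small is a stricter alternative reading.
- No cross-platform normalization: testing-set beta values are consumed
  as-is.
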