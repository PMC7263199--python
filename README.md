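# methylmark

Discovery and evaluation of cancer-type-specific hyper-methylated CpG
diagnostic markers from multi-cohort 450K-style methylation profiles.

Tumors gain DNA methylation at CpGs that stay unmethylated in matched
normals, healthy tissue, and other cancer types. `methylmark` implements
the complete marker-discovery workflow for array methylation fractions
(β = M/(M+U), the methylated over total intensity):

- **preprocess** — β computation and probe exclusion (sex chromosomes,
  SNP probes, detection p > 0.01 in more than half of samples);
- **diffmeth** — site- and region-level differential methylation
  (paired/unpaired t or Wilcoxon tests chosen by a K-S normality screen;
  DMC rule |Δβ| > 0.2 and BH-FDR < 0.01) and Fisher-exact feature
  enrichment with sample OR and Woolf 95% CI;
- **cimp** — CpG island methylator phenotype: variable-CpG selection
  (tumor sd > 0.2, normal mean < 0.05), consensus clustering (Monti
  subsampling, PAC-minimizing k), K-means assignment, highest-methylation
  cluster = CIMP, Kaplan–Meier / log-rank survival comparison;
- **regulation** — differential expression (log2-CPM Welch t,
  |log2 FC| > 1, FDR < 0.01) and cis/trans Pearson correlation screens
  between DMC β values and gene expression;
- **markers** — the tissue-specificity cascade: a marker must be
  hyper-methylated in target tumors vs matched normals (paired and
  unpaired), vs healthy tissue, and vs every other cohort's tumors *and*
  normals;
- **diagnostic** — information-gain ranking (bits, quantile-binned),
  progressive ridge-penalized logistic models
  p(tumor) = σ(β₀ + Σ wᵢβᵢ), ROC/AUC by the Mann–Whitney rank formula,
  and cross-cohort misclassification screening;
- **simulate** — a seeded generator that plants every structure the
  workflow must find (target-specific markers, pan-cancer decoys, a CIMP
  subcluster with worse survival, methylation-coupled expression), so the
  whole pipeline runs and is testable with no external data.

## Worked example

Run the full pipeline on a planted synthetic study (three cohorts, one
healthy set, 8 planted markers at Δβ = 0.4):

```python
from methylmark import simulate
from methylmark.pipeline import PipelineConfig, run_all

sim = simulate.SimulationConfig(
    seed=7, n_probes=5000,
    cohorts=[("BRCA", 40, 40), ("CANC1", 30, 15), ("CANC2", 30, 15)],
    n_healthy=20, n_cimp_extra=80)
cfg = PipelineConfig(simulation=sim, seed=7, k_range=[2, 3, 4])
manifest = run_all(cfg, "demo_out")
c = manifest["counts"]
print(f"probes retained      : {c['probes_retained']}")
print(f"paired DMCs          : {c['dmcs_paired']} ({c['hyper']} hyper / {c['hypo']} hypo)")
print(f"CIMP: k={c['cimp_k']}, {c['cimp_samples']} samples, log-rank p={c['cimp_logrank_p']:.3g}")
print(f"final marker panel   : {c['final_markers']} CpGs")
print(f"marker recovery      : {c['marker_recovery']}")
```

prints

```
probes retained      : 4622
paired DMCs          : 188 (188 hyper / 0 hypo)
CIMP: k=2, 8 samples, log-rank p=0.0331
final marker panel   : 8 CpGs
marker recovery      : {'planted': 8, 'recovered': 8, 'false_positives': 0}
```

Reading: of 5,000 simulated probes, 4,622 survive probe filtering; 188
CpGs are hyper-methylated in target tumors (the 8 planted markers, the
planted pan-cancer decoys, and the hypervariable CIMP block); the
consensus-clustered tumor partition finds the planted high-methylation
subgroup (k = 2, 8 of 40 tumors) whose survival is significantly worse
(log-rank p = 0.033); and the specificity cascade cuts the 188 down to
exactly the 8 planted markers with no false positives. The progressive
logistic model reaches test AUC 1.0 from one CpG onward on this cleanly
separable data (`demo_out/progressive_auc.tsv`).

The same stages are available from the shell:

```bash
methylmark simulate --seed 7 --outdir data/
methylmark markers --beta data/beta.tsv --sheet data/sheet.tsv --target BRCA --out panel/
methylmark run --config pipeline.yaml --outdir out/
```

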