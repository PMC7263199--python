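"""Tissue-specificity cascade for target-cohort diagnostic CpGs.

Starting from all probes, a candidate must be hyper-methylated
(delta beta > 0.2, BH FDR < 0.01 within each comparison) in:

1. target tumors vs matched adjacent normals (paired test),
2. target tumors vs adjacent normals (unpaired test),
3. target tumors vs healthy tissue (unpaired), when healthy samples exist,
4. target tumors vs EVERY background cohort's tumors AND normals.

Stages short-circuit: a probe dropped at stage k is not tested later and
its later flags stay False.  Survivors of all stages form the final
marker panel.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from sklearn.metrics import adjusted_rand_score
from statsmodels.stats.multitest import multipletests

from methylmark.diffmeth import _row_pvalues, call_dmcs, decide_normality


@dataclass
class MarkerPanel:
    flags: pd.DataFrame           # per-probe stage flags + final
    final: list                   # probes surviving every stage
    stage_counts: dict            # stage name -> surviving count
    partial: bool = False         # True when a comparison was skipped
    skipped: list = field(default_factory=list)


def _hyper_probes(beta: pd.DataFrame, t_ids, n_ids, delta_min: float,
                  fdr_max: float, normal_dist: bool) -> pd.Index:
    """Probes hyper-methylated in t vs n (unpaired), BH within this comparison."""
    T = beta[list(t_ids)].to_numpy(dtype=float)
    N = beta[list(n_ids)].to_numpy(dtype=float)
    delta = np.nanmean(T, axis=1) - np.nanmean(N, axis=1)
    p = _row_pvalues(T, N, paired=False, normal_dist=normal_dist)
    fdr = multipletests(p, method="fdr_bh")[1]
    return beta.index[(delta > delta_min) & (fdr < fdr_max)]


def cascade_filter(beta: pd.DataFrame, sheet: pd.DataFrame, target: str,
                   delta_min: float = 0.2, fdr_max: float = 0.01,
                   healthy_tissue: str = "healthy",
                   normal_dist: bool | None = None) -> MarkerPanel:
    """Run the full specificity cascade on a combined multi-cohort beta matrix.

    ``sheet`` assigns every sample a cohort and tissue; the target cohort
    must have a paired tumor/normal design.  Background cohorts are all
    non-target cohorts with tumor samples; samples with ``healthy_tissue``
    tissue form the healthy comparison.  Background comparisons with
    fewer than 3 samples are skipped with a warning and the panel is
    marked partial.
    """
    sheet = sheet.loc[sheet.index.intersection(beta.columns)]
    target_t = sheet.index[(sheet["cohort"] == target) & (sheet["tissue"] == "tumor")]
    target_n = sheet.index[(sheet["cohort"] == target) & (sheet["tissue"] == "adjacent_normal")]
    if len(target_n) == 0:
        raise ValueError(f"target cohort {target!r} has no adjacent normal samples")
    if normal_dist is None:
        normal_dist = decide_normality(beta[list(target_t) + list(target_n)])

    flags = pd.DataFrame(index=beta.index)
    counts = {}

    paired_dmcs = call_dmcs(beta, sheet, mode="paired", cohort=target,
                            delta_min=delta_min, fdr_max=fdr_max,
                            normal_dist=normal_dist)
    stage1 = paired_dmcs.index[paired_dmcs["direction"] == "hyper"]
    flags["passed_paired"] = flags.index.isin(stage1)
    counts["paired"] = len(stage1)
    survivors = pd.Index(stage1)

    if len(survivors):
        stage2 = _hyper_probes(beta.loc[survivors], target_t, target_n,
                               delta_min, fdr_max, normal_dist)
    else:
        stage2 = pd.Index([])
    flags["passed_unpaired"] = flags.index.isin(stage2)
    counts["unpaired"] = len(stage2)
    survivors = stage2

    healthy = sheet.index[sheet["tissue"] == healthy_tissue]
    skipped = []
    partial = False
    if len(healthy) >= 3:
        if len(survivors):
            stage3 = _hyper_probes(beta.loc[survivors], target_t, healthy,
                                   delta_min, fdr_max, normal_dist)
        else:
            stage3 = pd.Index([])
        flags["passed_healthy"] = flags.index.isin(stage3)
        survivors = stage3
    else:
        if len(healthy):
            warnings.warn("healthy cohort has < 3 samples; comparison skipped",
                          stacklevel=2)
            skipped.append("healthy")
            partial = True
        flags["passed_healthy"] = flags.index.isin(survivors)
    counts["healthy"] = len(survivors)

    backgrounds = sorted(c for c in sheet["cohort"].unique()
                         if c != target and
                         (sheet.loc[sheet["cohort"] == c, "tissue"] == "tumor").any())
    for cohort in backgrounds:
        for tissue, tag in (("tumor", "tumor"), ("adjacent_normal", "normal")):
            col = f"passed_vs_{cohort}_{tag}"
            ids = sheet.index[(sheet["cohort"] == cohort) & (sheet["tissue"] == tissue)]
            if len(ids) < 3:
                warnings.warn(f"{cohort} {tissue}: < 3 samples, comparison skipped",
                              stacklevel=2)
                skipped.append(f"{cohort}:{tissue}")
                partial = True
                flags[col] = flags.index.isin(survivors)
                continue
            if len(survivors):
                passed = _hyper_probes(beta.loc[survivors], target_t, ids,
                                       delta_min, fdr_max, normal_dist)
            else:
                passed = pd.Index([])
            flags[col] = flags.index.isin(passed)
            survivors = passed
            counts[f"vs_{cohort}_{tag}"] = len(survivors)

    flags["final"] = flags.index.isin(survivors)
    counts["final"] = len(survivors)
    return MarkerPanel(flags=flags, final=sorted(survivors),
                       stage_counts=counts, partial=partial, skipped=skipped)


def rank_by_fdr(dmcs: pd.DataFrame, top_n: int = 200) -> list:
    """Most significant probes: FDR ascending, then |delta beta| descending, then id."""
    if top_n < 1:
        raise ValueError("top_n must be >= 1")
    if dmcs.empty:
        raise ValueError("empty DMC table")
    order = dmcs.reset_index(drop=True).assign(
        _abs=lambda d: d["delta_beta"].abs()).sort_values(
        ["fdr", "_abs", "probe_id"], ascending=[True, False, True])
    return order["probe_id"].head(top_n).tolist()


def hierarchical_separation(beta_subset: pd.DataFrame, labels: pd.Series):
    """Average-linkage clustering of samples and a tumor/normal separation score.

    Returns ``(linkage_matrix, score)`` where the score is the adjusted
    Rand index between the two-cluster cut of the dendrogram and the
    given labels (1.0 = perfect separation, ~0 = none).
    """
    labels = labels.loc[beta_subset.columns]
    if labels.nunique() < 2 or labels.value_counts().min() < 2:
        raise ValueError("need >= 2 samples in each of >= 2 label groups")
    X = beta_subset.to_numpy(dtype=float).T
    Z = linkage(X, method="average", metric="euclidean")
    cut = fcluster(Z, t=2, criterion="maxclust")
    return Z, float(adjusted_rand_score(labels.to_numpy(), cut))
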