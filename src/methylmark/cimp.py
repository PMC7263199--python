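"""CpG island methylator phenotype (CIMP) identification.

The procedure: select CpGs that are highly variable across tumors
(sd > 0.2) yet essentially unmethylated in adjacent normals
(mean < 0.05); choose the cluster number by Monti-style consensus
clustering (subsampled K-means, PAC criterion); partition tumors by
K-means on Euclidean distance; label the cluster with the highest mean
beta as CIMP; and compare survival between CIMP and non-CIMP samples by
Kaplan-Meier curves and the log-rank test.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import multivariate_logrank_test
from sklearn.cluster import KMeans


def select_variable_cpgs(tumor_beta: pd.DataFrame, normal_beta: pd.DataFrame,
                         sd_min: float = 0.2, normal_mean_max: float = 0.05) -> list:
    """CpGs with tumor standard deviation > sd_min and normal mean < normal_mean_max."""
    if not (0 <= sd_min <= 1 and 0 <= normal_mean_max <= 1):
        raise ValueError("thresholds must lie in [0, 1]")
    shared = tumor_beta.index.intersection(normal_beta.index)
    sd = tumor_beta.loc[shared].std(axis=1, ddof=1)
    nm = normal_beta.loc[shared].mean(axis=1)
    keep = (sd > sd_min) & (nm < normal_mean_max)
    return shared[keep].tolist()


@dataclass
class ConsensusProfile:
    k_range: list
    mean_consensus: dict      # k -> mean off-diagonal consensus
    pac: dict                 # k -> proportion of ambiguous clustering
    chosen_k: int
    consensus_matrices: dict = field(default_factory=dict, repr=False)


def consensus_cluster(beta_subset: pd.DataFrame, k_range,
                      n_resamples: int = 100, subsample_frac: float = 0.8,
                      seed: int = 0, pac_window=(0.1, 0.9)) -> ConsensusProfile:
    """Monti consensus clustering over samples with inner K-means.

    ``beta_subset`` is probes x samples; samples are clustered.  For each
    k, ``n_resamples`` random subsamples of ``subsample_frac`` of the
    samples are K-means-partitioned; the consensus matrix entry (i, j) is
    the fraction of co-subsampled runs in which i and j co-clustered.
    The chosen k minimizes the PAC score (fraction of off-diagonal
    consensus entries strictly inside ``pac_window``), ties broken by the
    smallest k.
    """
    X = beta_subset.to_numpy(dtype=float).T  # samples x features
    n = X.shape[0]
    k_range = sorted(int(k) for k in k_range)
    if n_resamples < 2:
        raise ValueError("n_resamples must be >= 2")
    if k_range[0] < 2 or k_range[-1] > n - 1:
        raise ValueError(f"k_range must lie within [2, {n - 1}] for {n} samples")
    rng = np.random.default_rng(seed)
    m = max(2, int(round(subsample_frac * n)))
    mean_consensus, pac, mats = {}, {}, {}
    for k in k_range:
        co = np.zeros((n, n))
        together = np.zeros((n, n))
        for _ in range(n_resamples):
            idx = rng.choice(n, size=m, replace=False)
            km = KMeans(n_clusters=k, n_init=5,
                        random_state=int(rng.integers(0, 2**31))).fit(X[idx])
            same = km.labels_[:, None] == km.labels_[None, :]
            together[np.ix_(idx, idx)] += 1.0
            co[np.ix_(idx, idx)] += same
        with np.errstate(invalid="ignore"):
            cons = np.where(together > 0, co / np.maximum(together, 1), 0.0)
        np.fill_diagonal(cons, 1.0)
        tri = cons[np.triu_indices(n, k=1)]
        lo, hi = pac_window
        pac[k] = float(np.mean((tri > lo) & (tri < hi)))
        mean_consensus[k] = float(tri.mean())
        mats[k] = cons
    chosen_k = min(k_range, key=lambda k: (pac[k], k))
    return ConsensusProfile(k_range=k_range, mean_consensus=mean_consensus,
                            pac=pac, chosen_k=chosen_k, consensus_matrices=mats)


def kmeans_cluster(beta_subset: pd.DataFrame, k: int, seed: int = 0,
                   n_init: int = 20) -> pd.Series:
    """K-means partition of samples (Euclidean distance over selected CpGs)."""
    X = beta_subset.to_numpy(dtype=float).T
    if k < 2:
        raise ValueError("k must be >= 2")
    if k > X.shape[0]:
        raise ValueError(f"k={k} exceeds the {X.shape[0]} samples")
    km = KMeans(n_clusters=k, n_init=n_init, random_state=seed).fit(X)
    return pd.Series(km.labels_, index=beta_subset.columns, name="cluster")


@dataclass
class CIMPResult:
    selected_probes: list
    k: int
    assignment: pd.Series
    cimp_cluster: int
    cimp_flags: pd.Series
    cluster_mean_beta: dict


def call_cimp(assignment: pd.Series, beta_subset: pd.DataFrame) -> CIMPResult:
    """Label the cluster with the highest mean beta (over selected CpGs) as CIMP.

    Exact ties go to the lowest cluster index with a warning.
    """
    clusters = sorted(assignment.unique())
    if len(clusters) < 2:
        raise ValueError("need >= 2 clusters to define a CIMP cluster")
    means = {int(c): float(beta_subset.loc[:, assignment.index[assignment == c]]
                           .to_numpy().mean()) for c in clusters}
    best = max(means.values())
    top = [c for c in sorted(means) if means[c] == best]
    if len(top) > 1:
        warnings.warn(f"cluster mean tie among {top}; taking the lowest index",
                      stacklevel=2)
    cimp_cluster = top[0]
    flags = assignment == cimp_cluster
    return CIMPResult(selected_probes=beta_subset.index.tolist(),
                      k=len(clusters), assignment=assignment,
                      cimp_cluster=cimp_cluster,
                      cimp_flags=flags.rename("cimp"),
                      cluster_mean_beta=means)


def km_logrank(sheet: pd.DataFrame, groups: pd.Series):
    """Kaplan-Meier curves per group and the multi-group log-rank test.

    Returns ``(curves, statistic, p)`` where ``curves`` maps each group
    label to a DataFrame of (timeline, survival probability).  Requires
    overall-survival days/events in the sheet for every grouped sample.
    """
    groups = groups.dropna()
    sub = sheet.loc[groups.index]
    if sub["os_days"].isna().any() or sub["os_event"].isna().any():
        raise ValueError("survival fields missing for some grouped samples")
    labels = groups.unique()
    if len(labels) < 2:
        raise ValueError("need >= 2 groups for the log-rank test")
    curves = {}
    for lab in labels:
        ids = groups.index[groups == lab]
        if len(ids) == 0:
            raise ValueError(f"group {lab!r} has no samples")
        kmf = KaplanMeierFitter()
        kmf.fit(sub.loc[ids, "os_days"], sub.loc[ids, "os_event"], label=str(lab))
        curves[lab] = pd.DataFrame({
            "time": kmf.survival_function_.index.to_numpy(),
            "survival": kmf.survival_function_.iloc[:, 0].to_numpy(),
        })
    res = multivariate_logrank_test(sub["os_days"], groups, sub["os_event"])
    return curves, float(res.test_statistic), float(res.p_value)
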