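"""Site- and region-level differential methylation, and genomic-feature enrichment.

Differentially methylated CpGs (DMCs) are called by paired/unpaired
t-tests (when beta values look normal by a Kolmogorov-Smirnov check) or
by Wilcoxon rank tests otherwise, with Benjamini-Hochberg FDR control
and the |delta beta| > 0.2, FDR < 0.01 rule:

    hyper:  delta_beta >  delta_min  and  fdr < fdr_max
    hypo:   delta_beta < -delta_min  and  fdr < fdr_max

Region-level methylation is the per-sample mean beta over the member
CpGs of a (gene, region) group; enrichment of hyper vs hypo CpGs in
genomic features uses Fisher's exact test with the sample odds ratio and
a Woolf log-OR confidence interval.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

CGI_REGIONS = ["Island", "NShore", "NShelf", "SShore", "SShelf"]
TSS_REGIONS = ["TSS200", "TSS1500", "5'UTR", "FirstExon", "Body", "3'UTR"]


# ---------------------------------------------------------------------------
# normality screening

def ks_normality(values, alpha: float = 0.05) -> bool:
    """One-sample Kolmogorov-Smirnov check of standardized values against N(0, 1).

    Returns True (consistent with normal) when the K-S p-value is >= alpha.
    Requires at least 8 non-missing values with nonzero variance.
    """
    v = np.asarray(values, dtype=float)
    v = v[~np.isnan(v)]
    if len(v) < 8:
        raise ValueError("need >= 8 non-missing values for the normality check")
    sd = v.std(ddof=1)
    if v.max() == v.min() or sd == 0:
        raise ValueError("constant vector: normality undefined at zero variance")
    z = (v - v.mean()) / sd
    return bool(stats.kstest(z, "norm").pvalue >= alpha)


def decide_normality(beta: pd.DataFrame, alpha: float = 0.05, max_probes: int = 500) -> bool:
    """Global normality decision: majority vote of per-probe K-S checks.

    Evaluates up to ``max_probes`` evenly spaced probes so the decision is
    deterministic and cheap on large matrices.
    """
    n = len(beta)
    idx = np.unique(np.linspace(0, n - 1, min(n, max_probes)).astype(int))
    votes = []
    for i in idx:
        try:
            votes.append(ks_normality(beta.iloc[i].to_numpy(), alpha=alpha))
        except ValueError:
            continue
    if not votes:
        return True
    return sum(votes) * 2 >= len(votes)


# ---------------------------------------------------------------------------
# site-level tests

def _paired_wilcoxon_rows(T: np.ndarray, N: np.ndarray) -> np.ndarray:
    """Row-wise paired Wilcoxon signed-rank p-values.

    Zero differences are dropped; exact null for n <= 25, normal
    approximation with continuity correction above.  Degenerate rows
    (all differences zero) get p = 1.
    """
    n = T.shape[1]
    if n > 25:
        with np.errstate(invalid="ignore"):
            res = stats.wilcoxon(T, N, axis=1, method="approx", correction=True,
                                 zero_method="wilcox", nan_policy="omit")
        p = np.asarray(res.pvalue, dtype=float)
        return np.where(np.isnan(p), 1.0, p)
    p = np.ones(T.shape[0])
    for i in range(T.shape[0]):
        d = T[i] - N[i]
        d = d[~np.isnan(d)]
        d = d[d != 0]
        if len(d) == 0:
            continue
        try:
            p[i] = stats.wilcoxon(d, method="exact").pvalue
        except ValueError:
            p[i] = stats.wilcoxon(d, method="approx", correction=True).pvalue
    return p


def _row_pvalues(T: np.ndarray, N: np.ndarray, paired: bool, normal_dist: bool) -> np.ndarray:
    if paired and normal_dist:
        p = stats.ttest_rel(T, N, axis=1, nan_policy="omit").pvalue
    elif paired:
        p = _paired_wilcoxon_rows(T, N)
    elif normal_dist:
        p = stats.ttest_ind(T, N, axis=1, equal_var=False, nan_policy="omit").pvalue
    else:
        p = stats.mannwhitneyu(T, N, axis=1, nan_policy="omit").pvalue
    p = np.asarray(p, dtype=float)
    return np.where(np.isnan(p), 1.0, p)


def test_site(tumor, normal, paired: bool, normal_dist: bool):
    """Single-CpG two-group comparison; returns ``(delta_beta, p_value)``.

    ``delta_beta = mean(tumor) - mean(normal)``; the test is the paired or
    Welch t-test under normality, otherwise the paired Wilcoxon
    signed-rank or Mann-Whitney rank-sum test.  Two-sided p throughout.
    """
    t = np.asarray(tumor, dtype=float)
    n = np.asarray(normal, dtype=float)
    if paired and len(t) != len(n):
        raise ValueError("paired test requires equal-length, patient-aligned vectors")
    if min((~np.isnan(t)).sum(), (~np.isnan(n)).sum()) < 3:
        raise ValueError("need >= 3 observations per group")
    delta = float(np.nanmean(t) - np.nanmean(n))
    p = float(_row_pvalues(t[None, :], n[None, :], paired, normal_dist)[0])
    return delta, p


def _paired_columns(sheet: pd.DataFrame, tumor_tissue: str, normal_tissue: str):
    tum = sheet[sheet["tissue"] == tumor_tissue]
    nor = sheet[sheet["tissue"] == normal_tissue]
    nor_by_patient = nor.drop_duplicates("patient_id").set_index("patient_id")
    shared = tum[tum["patient_id"].isin(nor_by_patient.index)]
    t_ids = shared["sample_id"].tolist()
    n_ids = nor_by_patient.loc[shared["patient_id"], "sample_id"].tolist()
    return t_ids, n_ids


def call_dmcs(beta: pd.DataFrame, sheet: pd.DataFrame, mode: str = "paired",
              cohort: str | None = None, tumor_tissue: str = "tumor",
              normal_tissue: str = "adjacent_normal",
              delta_min: float = 0.2, fdr_max: float = 0.01,
              normal_dist: bool | None = None) -> pd.DataFrame:
    """Call DMCs for every probe of ``beta``; returns one record per probe.

    ``mode`` selects the paired (patient-matched) or unpaired design.
    ``normal_dist=None`` triggers a global majority-vote K-S decision on
    the probe-level beta distributions; pass True/False to force the
    t-test or rank-test family.
    """
    if mode not in ("paired", "unpaired"):
        raise ValueError(f"mode must be 'paired' or 'unpaired', got {mode!r}")
    sub = sheet if cohort is None else sheet[sheet["cohort"] == cohort]
    if mode == "paired":
        t_ids, n_ids = _paired_columns(sub, tumor_tissue, normal_tissue)
        if len(t_ids) < 3:
            raise ValueError("paired mode requires >= 3 tumor/normal pairs")
    else:
        t_ids = sub.index[sub["tissue"] == tumor_tissue].tolist()
        n_ids = sub.index[sub["tissue"] == normal_tissue].tolist()
        if len(t_ids) < 3 or len(n_ids) < 3:
            raise ValueError("unpaired mode requires >= 3 samples per group "
                             f"(got {len(t_ids)} tumor, {len(n_ids)} normal)")
    T = beta[t_ids].to_numpy(dtype=float)
    N = beta[n_ids].to_numpy(dtype=float)
    if normal_dist is None:
        normal_dist = decide_normality(beta[t_ids + n_ids])

    delta = np.nanmean(T, axis=1) - np.nanmean(N, axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = _row_pvalues(T, N, mode == "paired", normal_dist)
    # probes that cannot be tested (too few observations) are reported ns
    testable = ((~np.isnan(T)).sum(axis=1) >= 3) & ((~np.isnan(N)).sum(axis=1) >= 3)
    fdr = np.full(len(p), np.nan)
    if testable.any():
        fdr[testable] = multipletests(p[testable], method="fdr_bh")[1]
    direction = np.where(
        testable & (fdr < fdr_max) & (delta > delta_min), "hyper",
        np.where(testable & (fdr < fdr_max) & (delta < -delta_min), "hypo", "ns"))
    test_name = ("paired_t" if mode == "paired" and normal_dist else
                 "wilcoxon_paired" if mode == "paired" else
                 "unpaired_t" if normal_dist else "wilcoxon_unpaired")
    out = pd.DataFrame({
        "probe_id": beta.index,
        "delta_beta": delta,
        "p_value": p,
        "fdr": fdr,
        "direction": direction,
        "test": test_name,
        "reason": np.where(testable, "", "insufficient_observations"),
    }).set_index("probe_id", drop=False)
    return out


# ---------------------------------------------------------------------------
# region level

def summarize_regions(beta: pd.DataFrame, annotation: pd.DataFrame,
                      scheme: str = "cgi") -> pd.DataFrame:
    """Per-sample mean beta over member CpGs of each (gene, region) group.

    ``scheme='cgi'`` groups by CpG-island relation (Island/shores/shelves);
    ``scheme='tss'`` groups by gene feature (TSS200 ... 3'UTR).  Probes
    without a gene, and open-sea/intergenic probes, are omitted.
    """
    if scheme == "cgi":
        col, valid = "cgi_relation", CGI_REGIONS
    elif scheme == "tss":
        col, valid = "feature", TSS_REGIONS
    else:
        raise ValueError(f"scheme must be 'cgi' or 'tss', got {scheme!r}")
    annot = annotation.loc[beta.index]
    keep = annot["gene"].notna() & annot[col].isin(valid)
    if not keep.any():
        raise ValueError("no probe maps to any (gene, region) group")
    grouped = beta.loc[keep].groupby(
        [annot.loc[keep, "gene"], annot.loc[keep, col]], observed=True).mean()
    grouped.index.names = ["gene", "region"]
    return grouped


def region_differential(regions: pd.DataFrame, sheet: pd.DataFrame,
                        delta_min: float = 0.2, fdr_max: float = 0.01,
                        normal_dist: bool = True):
    """Paired tumor-vs-normal test per region; returns ``(table, counts)``.

    ``counts`` maps each region class to its hyper/hypo/ns gene counts at
    the given thresholds.
    """
    t_ids, n_ids = _paired_columns(sheet, "tumor", "adjacent_normal")
    if len(t_ids) < 3:
        raise ValueError("region_differential requires a paired design; "
                         "use call_dmcs(mode='unpaired') for unpaired data")
    T = regions[t_ids].to_numpy(dtype=float)
    N = regions[n_ids].to_numpy(dtype=float)
    delta = np.nanmean(T, axis=1) - np.nanmean(N, axis=1)
    p = _row_pvalues(T, N, paired=True, normal_dist=normal_dist)
    fdr = multipletests(p, method="fdr_bh")[1]
    direction = np.where((fdr < fdr_max) & (delta > delta_min), "hyper",
                         np.where((fdr < fdr_max) & (delta < -delta_min), "hypo", "ns"))
    table = pd.DataFrame({"delta_beta": delta, "p_value": p, "fdr": fdr,
                          "direction": direction}, index=regions.index)
    counts = {
        region: {d: int((grp["direction"] == d).sum()) for d in ("hyper", "hypo", "ns")}
        for region, grp in table.groupby(level="region", observed=True)
    }
    return table, counts


# ---------------------------------------------------------------------------
# feature enrichment

@dataclass
class EnrichmentResult:
    feature: str
    table: tuple  # (a, b, c, d): (in, out of feature) x (hyper, reference-other)
    odds_ratio: float
    ci95: tuple
    p_value: float
    degenerate: bool = False


def feature_enrichment(hyper, reference, annotation: pd.DataFrame,
                       feature: str) -> EnrichmentResult:
    """Fisher's exact test for enrichment of a genomic feature among hyper CpGs.

    ``reference`` is the comparison probe set (hypo CpGs, or all retained
    CpGs); probes also present in ``hyper`` are excluded from it, so the
    same call serves both the hyper-vs-hypo and hyper-vs-all contrasts.
    OR is the sample odds ratio (a*d)/(b*c); the 95% CI is Woolf's
    log-OR interval.  Zero cells give OR of 0 or infinity with an
    unbounded CI and the degenerate flag set.
    """
    hyper = set(hyper)
    other = set(reference) - hyper
    if not hyper or not other:
        raise ValueError("both probe sets must be non-empty")
    col = "cgi_relation" if feature in set(CGI_REGIONS) | {"OpenSea"} else "feature"
    in_feat = set(annotation.index[annotation[col] == feature])
    if not in_feat:
        raise ValueError(f"feature {feature!r} absent from annotation")
    a = len(hyper & in_feat)
    b = len(hyper) - a
    c = len(other & in_feat)
    d = len(other) - c
    p = float(stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")[1])
    degenerate = 0 in (a, b, c, d)
    if b * c == 0:
        odds = np.inf if a * d > 0 else (0.0 if a == 0 or d == 0 else np.nan)
    else:
        odds = (a * d) / (b * c)
    if degenerate:
        ci = (0.0, np.inf)
    else:
        se = np.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
        log_or = np.log(odds)
        ci = (float(np.exp(log_or - 1.959963984540054 * se)),
              float(np.exp(log_or + 1.959963984540054 * se)))
    return EnrichmentResult(feature=feature, table=(a, b, c, d),
                            odds_ratio=float(odds), ci95=ci, p_value=p,
                            degenerate=degenerate)
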