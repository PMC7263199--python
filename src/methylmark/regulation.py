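"""Differential expression and methylation-expression correlation screens.

Differential expression is a deliberately simple caller: library-size
normalization to log2(CPM + 1), a per-gene Welch t-test, BH FDR, and the
|log2 FC| > 1, FDR < 0.01 rule.  An externally produced DE table with
columns (gene, log2_fc, p, fdr) can be dropped in instead.

Correlation screens pair differentially methylated CpGs with genes:
*cis* pairs a CpG with its own annotated gene, *trans* pairs it with
every differentially expressed gene except that one.  Both report the
Pearson coefficient between beta and log-scale expression with a
t-distribution p-value (n - 2 df); calls are Neg / Pos at p < 0.05, NS
otherwise.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests


def log2_cpm(counts: pd.DataFrame, pseudo: float = 1.0) -> pd.DataFrame:
    """log2(counts-per-million + pseudo), per sample library size."""
    lib = counts.sum(axis=0).astype(float)
    if (lib == 0).any():
        raise ValueError("sample with zero library size")
    return np.log2(counts.div(lib, axis=1) * 1e6 + pseudo)


def call_degs(counts: pd.DataFrame, sheet: pd.DataFrame,
              log2fc_min: float = 1.0, fdr_max: float = 0.01,
              tumor_tissue: str = "tumor",
              normal_tissue: str = "adjacent_normal") -> pd.DataFrame:
    """Welch-t differential expression on log2 CPM with BH FDR.

    ``log2_fc`` is the tumor-minus-normal difference of group mean
    log2(CPM + 1).  Genes with zero counts everywhere are reported ns
    with a reason.
    """
    t_ids = [s for s in counts.columns if sheet.loc[s, "tissue"] == tumor_tissue]
    n_ids = [s for s in counts.columns if sheet.loc[s, "tissue"] == normal_tissue]
    if len(t_ids) < 3 or len(n_ids) < 3:
        raise ValueError("need >= 3 samples per group")
    expr = log2_cpm(counts)
    T = expr[t_ids].to_numpy()
    N = expr[n_ids].to_numpy()
    lfc = T.mean(axis=1) - N.mean(axis=1)
    all_zero = (counts[t_ids + n_ids].to_numpy() == 0).all(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = stats.ttest_ind(T, N, axis=1, equal_var=False).pvalue
    p = np.where(np.isnan(p) | all_zero, 1.0, p)
    fdr = multipletests(p, method="fdr_bh")[1]
    direction = np.where(all_zero, "ns", np.where(
        (fdr < fdr_max) & (lfc > log2fc_min), "up",
        np.where((fdr < fdr_max) & (lfc < -log2fc_min), "down", "ns")))
    return pd.DataFrame({
        "gene": counts.index, "log2_fc": lfc, "p_value": p, "fdr": fdr,
        "direction": direction,
        "reason": np.where(all_zero, "all_zero_counts", ""),
    }).set_index("gene", drop=False)


def _pearson_records(beta_rows: pd.DataFrame, expr_rows: pd.DataFrame,
                     pairs: list, mode: str, alpha: float) -> pd.DataFrame:
    """Vectorized Pearson r and two-sided t p-value for (probe, gene) pairs."""
    samples = beta_rows.columns.intersection(expr_rows.columns)
    n = len(samples)
    if n < 10:
        raise ValueError(f"need >= 10 shared samples, got {n}")
    B = beta_rows[samples].to_numpy(dtype=float)
    E = expr_rows[samples].to_numpy(dtype=float)
    bi = {p: i for i, p in enumerate(beta_rows.index)}
    ei = {g: i for i, g in enumerate(expr_rows.index)}

    Bz = B - B.mean(axis=1, keepdims=True)
    Ez = E - E.mean(axis=1, keepdims=True)
    bsd = np.sqrt((Bz ** 2).sum(axis=1))
    esd = np.sqrt((Ez ** 2).sum(axis=1))
    rows = []
    for probe, gene in pairs:
        i, j = bi[probe], ei[gene]
        degenerate = bsd[i] == 0 or esd[j] == 0
        if degenerate:
            r, p = np.nan, 1.0
        else:
            r = float(np.dot(Bz[i], Ez[j]) / (bsd[i] * esd[j]))
            r = min(1.0, max(-1.0, r))
            if abs(r) == 1.0:
                p = 0.0
            else:
                t = r * np.sqrt((n - 2) / (1 - r * r))
                p = float(2 * stats.t.sf(abs(t), n - 2))
        call = "NS" if (p >= alpha or degenerate) else ("Neg" if r < 0 else "Pos")
        rows.append((probe, gene, mode, r, p, call, degenerate))
    return pd.DataFrame(rows, columns=["probe_id", "gene", "mode", "r",
                                       "p_value", "call", "degenerate"])


def cis_correlation(beta: pd.DataFrame, expr: pd.DataFrame,
                    annotation: pd.DataFrame, dmcs: pd.DataFrame,
                    alpha: float = 0.05) -> pd.DataFrame:
    """Correlate each DMC with its own annotated gene's expression.

    ``expr`` is a genes x samples log-scale matrix (see :func:`log2_cpm`);
    only DMC probes whose annotated gene is present are tested.
    """
    called = dmcs.index[dmcs["direction"].isin(["hyper", "hypo"])]
    pairs = []
    for probe in called:
        gene = annotation.loc[probe, "gene"] if probe in annotation.index else None
        if pd.notna(gene) and gene in expr.index and probe in beta.index:
            pairs.append((probe, gene))
    if not pairs:
        return _empty_correlations()
    probes = sorted({p for p, _ in pairs})
    genes = sorted({g for _, g in pairs})
    return _pearson_records(beta.loc[probes], expr.loc[genes], pairs, "cis", alpha)


def trans_correlation(beta: pd.DataFrame, expr: pd.DataFrame,
                      annotation: pd.DataFrame, dmcs: pd.DataFrame,
                      degs: pd.DataFrame, alpha: float = 0.05,
                      max_pairs: int | None = None, seed: int = 0) -> pd.DataFrame:
    """Correlate DMCs with differentially expressed genes, excluding cis pairs.

    The pair set is DMC x DEG minus each CpG's own annotated gene; when
    ``max_pairs`` is given, a seeded uniform subsample of pairs is tested.
    """
    called = [p for p in dmcs.index[dmcs["direction"].isin(["hyper", "hypo"])]
              if p in beta.index]
    de = [g for g in degs.index[degs["direction"].isin(["up", "down"])]
          if g in expr.index]
    pairs = []
    for probe in called:
        own = annotation.loc[probe, "gene"] if probe in annotation.index else None
        for gene in de:
            if pd.notna(own) and gene == own:
                continue
            pairs.append((probe, gene))
    if not pairs:
        return _empty_correlations()
    if max_pairs is not None and len(pairs) > max_pairs:
        rng = np.random.default_rng(seed)
        idx = rng.choice(len(pairs), size=max_pairs, replace=False)
        pairs = [pairs[i] for i in sorted(idx)]
    probes = sorted({p for p, _ in pairs})
    genes = sorted({g for _, g in pairs})
    return _pearson_records(beta.loc[probes], expr.loc[genes], pairs, "trans", alpha)


def _empty_correlations() -> pd.DataFrame:
    return pd.DataFrame(columns=["probe_id", "gene", "mode", "r",
                                 "p_value", "call", "degenerate"])


def bias_summary(records: pd.DataFrame, dmc_directions: pd.Series,
                 deg_directions: pd.Series) -> pd.DataFrame:
    """Fractions of Neg/Pos/NS calls per (CpG direction, gene direction, mode) stratum.

    Empty strata are simply absent.  Fractions in each row sum to 1.
    """
    if records.empty:
        raise ValueError("no correlation records to summarize")
    rec = records.copy()
    rec["dmc_direction"] = rec["probe_id"].map(dmc_directions)
    rec["deg_direction"] = rec["gene"].map(deg_directions)
    rows = []
    for (dmc_d, deg_d, mode), grp in rec.groupby(
            ["dmc_direction", "deg_direction", "mode"], dropna=False):
        n = len(grp)
        rows.append({
            "dmc_direction": dmc_d, "deg_direction": deg_d, "mode": mode,
            "n": n,
            "frac_neg": (grp["call"] == "Neg").sum() / n,
            "frac_pos": (grp["call"] == "Pos").sum() / n,
            "frac_ns": (grp["call"] == "NS").sum() / n,
        })
    return pd.DataFrame(rows)
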