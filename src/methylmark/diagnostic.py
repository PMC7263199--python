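"""Information-gain feature ranking, ridge-penalized logistic diagnosis, ROC evaluation.

The diagnostic model is a logistic regression on marker CpG beta values,
with probes entered progressively in information-gain order.  A small
L2 penalty (per-observation scaling) keeps the fit finite under perfect
separation, which is the expected regime for markers pre-selected at
delta beta > 0.2.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import rankdata


# ---------------------------------------------------------------------------
# information gain

def _entropy_bits(counts: np.ndarray) -> float:
    n = counts.sum()
    if n == 0:
        return 0.0
    p = counts[counts > 0] / n
    return float(-(p * np.log2(p)).sum())


def information_gain(values, labels, n_bins: int = 10) -> float:
    """Reduction in label entropy (bits) after quantile-binning the feature.

    Bins are equal-frequency quantiles of ``values``; IG =
    H(labels) - sum_b p(b) H(labels | bin b), log base 2.
    """
    v = np.asarray(values, dtype=float)
    y = np.asarray(labels)
    classes, y_idx = np.unique(y, return_inverse=True)
    if len(classes) < 2:
        raise ValueError("labels contain a single class")
    if len(np.unique(v)) < 2:
        raise ValueError("feature has < 2 distinct values")
    edges = np.unique(np.quantile(v, np.linspace(0, 1, n_bins + 1)))
    bins = np.clip(np.searchsorted(edges, v, side="right") - 1, 0, len(edges) - 2)
    h_y = _entropy_bits(np.bincount(y_idx))
    h_cond = 0.0
    for b in np.unique(bins):
        mask = bins == b
        h_cond += mask.mean() * _entropy_bits(np.bincount(y_idx[mask],
                                                          minlength=len(classes)))
    return max(0.0, h_y - h_cond)


def rank_features(beta_subset: pd.DataFrame, labels, n_bins: int = 10) -> pd.DataFrame:
    """Rank probes by information gain, descending; ties broken by probe id."""
    if len(beta_subset) < 1:
        raise ValueError("no probes to rank")
    y = np.asarray(labels)
    rows = [(probe, information_gain(beta_subset.loc[probe].to_numpy(), y, n_bins))
            for probe in beta_subset.index]
    out = pd.DataFrame(rows, columns=["probe_id", "ig"])
    return out.sort_values(["ig", "probe_id"], ascending=[False, True],
                           ignore_index=True)


# ---------------------------------------------------------------------------
# penalized logistic regression

@dataclass
class DiagnosticModel:
    included_probes: list
    intercept: float
    coefficients: np.ndarray
    l2_lambda: float = 1e-4
    decision_threshold: float = 0.5
    n_bins: int = 10
    ranked_probes: list = field(default_factory=list)  # (probe, ig) pairs

    def to_json(self, path: str | Path) -> None:
        obj = {
            "included_probes": list(self.included_probes),
            "intercept": float(self.intercept),
            "coefficients": [float(c) for c in self.coefficients],
            "l2_lambda": self.l2_lambda,
            "decision_threshold": self.decision_threshold,
            "n_bins": self.n_bins,
            "ranked_probes": [[p, float(g)] for p, g in self.ranked_probes],
        }
        Path(path).write_text(json.dumps(obj, indent=2) + "\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "DiagnosticModel":
        obj = json.loads(Path(path).read_text())
        return cls(included_probes=obj["included_probes"],
                   intercept=obj["intercept"],
                   coefficients=np.asarray(obj["coefficients"], dtype=float),
                   l2_lambda=obj["l2_lambda"],
                   decision_threshold=obj["decision_threshold"],
                   n_bins=obj.get("n_bins", 10),
                   ranked_probes=[tuple(p) for p in obj.get("ranked_probes", [])])


class ConvergenceError(RuntimeError):
    def __init__(self, message, last_iterate):
        super().__init__(message)
        self.last_iterate = last_iterate


def fit_logistic(X, y, l2_lambda: float = 1e-4, max_iter: int = 100,
                 tol: float = 1e-8) -> DiagnosticModel:
    """Ridge-penalized logistic regression by iteratively reweighted least squares.

    Minimizes ``-(1/n) sum loglik + (lambda/2) ||w||^2`` with the
    intercept unpenalized; the per-observation scaling makes the fit
    invariant to duplicating every sample.  Convergence: max coefficient
    change < ``tol`` within ``max_iter`` Newton steps, else a
    :class:`ConvergenceError` carrying the last iterate.
    """
    if isinstance(X, pd.DataFrame):
        probes = X.columns.tolist()
        Xa = X.to_numpy(dtype=float)
    else:
        Xa = np.asarray(X, dtype=float)
        probes = [f"x{j}" for j in range(Xa.shape[1])]
    ya = np.asarray(y, dtype=float).ravel()
    if set(np.unique(ya)) - {0.0, 1.0}:
        raise ValueError("y must be binary 0/1")
    if len(np.unique(ya)) < 2:
        raise ValueError("y contains a single class")
    n, p = Xa.shape
    Xd = np.hstack([np.ones((n, 1)), Xa])
    w = np.zeros(p + 1)
    pen = np.full(p + 1, l2_lambda)
    pen[0] = 0.0
    for _ in range(max_iter):
        eta = Xd @ w
        mu = 1.0 / (1.0 + np.exp(-eta))
        grad = -(Xd.T @ (ya - mu)) / n + pen * w
        s = np.clip(mu * (1.0 - mu), 1e-10, None)
        H = (Xd.T * s) @ Xd / n + np.diag(pen)
        step = np.linalg.solve(H, grad)
        w_new = w - step
        delta = np.max(np.abs(w_new - w))
        w = w_new
        if delta < tol:
            return DiagnosticModel(included_probes=probes, intercept=float(w[0]),
                                   coefficients=w[1:].copy(), l2_lambda=l2_lambda)
    raise ConvergenceError(f"IRLS did not converge in {max_iter} iterations", w)


def penalized_loglik(model: DiagnosticModel, X, y) -> float:
    """Per-observation penalized log-likelihood at the fitted parameters."""
    Xa = X.to_numpy(dtype=float) if isinstance(X, pd.DataFrame) else np.asarray(X, float)
    ya = np.asarray(y, dtype=float).ravel()
    eta = model.intercept + Xa @ model.coefficients
    ll = np.mean(ya * eta - np.log1p(np.exp(eta)))
    return float(ll - 0.5 * model.l2_lambda * np.sum(model.coefficients ** 2))


def predict(model: DiagnosticModel, X):
    """Posterior probabilities and class calls at the model's decision threshold."""
    if isinstance(X, pd.DataFrame):
        missing = [c for c in model.included_probes if c not in X.columns]
        if missing:
            raise KeyError(f"input is missing model probes: {missing}")
        Xa = X[model.included_probes].to_numpy(dtype=float)
        idx = X.index
    else:
        Xa = np.asarray(X, dtype=float)
        if Xa.shape[1] != len(model.included_probes):
            raise ValueError("column count does not match model probes")
        idx = pd.RangeIndex(Xa.shape[0])
    prob = 1.0 / (1.0 + np.exp(-(model.intercept + Xa @ model.coefficients)))
    prob = pd.Series(prob, index=idx, name="prob")
    return prob, (prob >= model.decision_threshold).rename("call")


# ---------------------------------------------------------------------------
# ROC

@dataclass
class ROCResult:
    thresholds: np.ndarray
    tpr: np.ndarray
    fpr: np.ndarray
    auc: float


def roc_auc(scores, labels) -> ROCResult:
    """ROC curve and AUC by the rank (Mann-Whitney) formula with half-credit ties."""
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels).astype(int)
    n_pos = int((y == 1).sum())
    n_neg = int((y == 0).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be present")
    ranks = rankdata(s)
    auc = (ranks[y == 1].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg)
    thresholds = np.r_[np.inf, np.unique(s)[::-1]]
    tpr = np.array([(s[y == 1] >= t).mean() for t in thresholds])
    fpr = np.array([(s[y == 0] >= t).mean() for t in thresholds])
    return ROCResult(thresholds=thresholds, tpr=tpr, fpr=fpr, auc=float(auc))


def progressive_evaluation(ranking, train, test, k_max: int,
                           l2_lambda: float = 1e-4) -> pd.DataFrame:
    """Fit top-k models for k = 1..k_max and report test AUC per k.

    ``ranking`` is an ordered probe list (best first); ``train`` and
    ``test`` are ``(X, y)`` with X as samples x probes DataFrames.  The
    penalized training log-likelihood is checked to be non-decreasing in
    k, as nested models with a fixed per-observation penalty must be.
    """
    ranking = list(ranking)
    if k_max > len(ranking):
        raise ValueError(f"k_max={k_max} exceeds ranking length {len(ranking)}")
    X_tr, y_tr = train
    X_te, y_te = test
    rows = []
    prev_ll = -np.inf
    for k in range(1, k_max + 1):
        cols = ranking[:k]
        model = fit_logistic(X_tr[cols], y_tr, l2_lambda=l2_lambda)
        ll = penalized_loglik(model, X_tr[cols], y_tr)
        if ll < prev_ll - 1e-8:
            raise AssertionError(f"training log-likelihood decreased at k={k}")
        prev_ll = ll
        prob, _ = predict(model, X_te[cols])
        rows.append({"k": k, "train_loglik": ll,
                     "auc": roc_auc(prob.to_numpy(), np.asarray(y_te)).auc})
    return pd.DataFrame(rows)


def cross_cohort_misclassification(model: DiagnosticModel, cohort_betas: dict) -> pd.DataFrame:
    """Percent of each cohort/tissue group classified as the target class.

    ``cohort_betas`` maps cohort -> {tissue: samples x probes DataFrame}.
    """
    rows = []
    for cohort, by_tissue in cohort_betas.items():
        for tissue, X in by_tissue.items():
            if len(X) == 0:
                raise ValueError(f"empty cohort group {cohort}/{tissue}")
            _, calls = predict(model, X)
            rows.append({"cohort": cohort, "tissue": tissue, "n": len(X),
                         "pct_target": 100.0 * calls.mean()})
    return pd.DataFrame(rows)
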