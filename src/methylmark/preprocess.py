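"""Beta computation from intensities and probe-level exclusion rules.

Probe filtering follows standard 450K practice: drop sex-chromosome
probes, SNP-overlapping probes, and probes whose detection p-value
exceeds 0.01 in strictly more than half of the samples.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

SEX_CHROMOSOMES = ("chrX", "chrY")


def compute_beta(meth, unmeth, offset: float = 0.0):
    """Methylation fraction beta = meth / (meth + unmeth + offset).

    Accepts scalars, arrays or DataFrames.  A zero denominator yields a
    missing value (NaN) rather than an error.  The default offset of 0 is
    the plain intensity ratio; Illumina's conventional +100 can be passed
    explicitly.
    """
    meth_a = np.asarray(meth, dtype=float) if not isinstance(meth, pd.DataFrame) else meth.to_numpy(float)
    unmeth_a = np.asarray(unmeth, dtype=float) if not isinstance(unmeth, pd.DataFrame) else unmeth.to_numpy(float)
    if np.nanmin(meth_a, initial=0) < 0 or np.nanmin(unmeth_a, initial=0) < 0:
        raise ValueError("intensities must be non-negative")
    if offset < 0:
        raise ValueError("offset must be non-negative")
    denom = meth_a + unmeth_a + offset
    with np.errstate(invalid="ignore", divide="ignore"):
        beta = np.where(denom > 0, meth_a / np.where(denom > 0, denom, 1.0), np.nan)
    if isinstance(meth, pd.DataFrame):
        return pd.DataFrame(beta, index=meth.index, columns=meth.columns)
    if np.isscalar(meth) and np.isscalar(unmeth):
        return float(beta)
    return beta


def filter_probes(beta: pd.DataFrame, annotation: pd.DataFrame,
                  detection_p: pd.DataFrame | None = None,
                  detp_max: float = 0.01, max_failed_frac: float = 0.5):
    """Apply the probe exclusion cascade; returns ``(retained_beta, report)``.

    Exclusion order: sex chromosomes, then SNP-flagged probes, then
    probes with detection p > ``detp_max`` in strictly more than
    ``max_failed_frac`` of samples.  Probe order is preserved; the report
    counts exclusions per rule.
    """
    missing = beta.index.difference(annotation.index)
    if len(missing):
        raise KeyError(f"probe {missing[0]!r} present in beta matrix but absent from annotation")
    annot = annotation.loc[beta.index]

    sex = annot["chrom"].isin(SEX_CHROMOSOMES).to_numpy()
    snp = annot["snp"].to_numpy(dtype=bool) & ~sex
    drop = sex | snp
    det = np.zeros(len(beta), dtype=bool)
    if detection_p is not None:
        detp = detection_p.reindex(index=beta.index, columns=beta.columns)
        failed = (detp.to_numpy() > detp_max).sum(axis=1)
        det = (failed > max_failed_frac * beta.shape[1]) & ~drop
        drop = drop | det
    report = {
        "n_input": int(len(beta)),
        "n_sex_chromosome": int(sex.sum()),
        "n_snp": int(snp.sum()),
        "n_detection_failed": int(det.sum()),
        "n_retained": int((~drop).sum()),
    }
    return beta.loc[~drop], report
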