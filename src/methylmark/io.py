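"""Plain-text readers/writers for the pipeline's tabular artifacts.

All matrices travel as TSV: beta matrices and count matrices with probes or
genes as rows and samples as columns; annotation manifests and sample
sheets as one row per probe/sample.  Ground truth and reports are JSON.
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd

ANNOTATION_COLUMNS = ["probe_id", "chrom", "pos", "cgi_relation", "gene", "feature", "snp"]
SHEET_COLUMNS = ["sample_id", "cohort", "tissue", "patient_id", "os_days", "os_event"]


def read_matrix(path: str | Path) -> pd.DataFrame:
    """Read a features x samples TSV matrix (first column = feature id)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.index.has_duplicates:
        dup = df.index[df.index.duplicated()][0]
        raise ValueError(f"duplicated feature id in {path}: {dup!r}")
    return df


def write_matrix(df: pd.DataFrame, path: str | Path, index_label: str = "probe_id") -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index_label=index_label, lineterminator="\n")


def read_annotation(path: str | Path) -> pd.DataFrame:
    annot = pd.read_csv(path, sep="\t", dtype={"snp": bool})
    missing = set(ANNOTATION_COLUMNS) - set(annot.columns)
    if missing:
        raise ValueError(f"annotation {path} missing columns: {sorted(missing)}")
    return annot.set_index("probe_id", drop=False)


def write_annotation(annot: pd.DataFrame, path: str | Path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    annot[ANNOTATION_COLUMNS].to_csv(path, sep="\t", index=False, lineterminator="\n")


def read_sheet(path: str | Path) -> pd.DataFrame:
    sheet = pd.read_csv(path, sep="\t")
    missing = {"sample_id", "cohort", "tissue"} - set(sheet.columns)
    if missing:
        raise ValueError(f"sample sheet {path} missing columns: {sorted(missing)}")
    for col in SHEET_COLUMNS:
        if col not in sheet.columns:
            sheet[col] = pd.NA
    return sheet.set_index("sample_id", drop=False)


def write_sheet(sheet: pd.DataFrame, path: str | Path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    sheet[SHEET_COLUMNS].to_csv(path, sep="\t", index=False, lineterminator="\n")


def write_json(obj, path: str | Path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True, default=_jsonable)
        fh.write("\n")


def read_json(path: str | Path):
    with open(path) as fh:
        return json.load(fh)


def _jsonable(obj):
    if isinstance(obj, (set, frozenset)):
        return sorted(obj)
    if hasattr(obj, "item"):  # numpy scalar
        return obj.item()
    if hasattr(obj, "tolist"):
        return obj.tolist()
    raise TypeError(f"not JSON serializable: {type(obj)}")
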