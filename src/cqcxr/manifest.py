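"""CheXpert-style manifest reading, writing and curation.

A manifest is a CSV table with one row per image: path, patient id, sex,
age, view columns (``Frontal/Lateral``, ``AP/PA``), a study-order column
and per-finding label columns whose values are ``1`` (positive), ``0``
(negative), ``-1`` (uncertain) or blank (unmentioned). The distinction
between blank, 0 and -1 is preserved verbatim through read/write
round-trips: label columns are kept as strings.

Curation mirrors the study protocol: keep each patient's first
chronological PA view, then balance classes by seeded undersampling of
the majority class. How uncertain (-1) labels are treated is an explicit
policy (``exclude`` by default); blanks count as negative.
"""

from __future__ import annotations

import warnings
from typing import Literal

import numpy as np
import pandas as pd

__all__ = [
    "read_manifest",
    "write_manifest",
    "binary_labels",
    "select_first_pa",
    "balance_undersample",
]

LABEL_VALUES = {"1", "0", "-1", ""}
UncertainPolicy = Literal["exclude", "as_negative", "as_positive"]

_CORE_COLUMNS = ["Path", "PatientID", "Frontal/Lateral", "AP/PA", "StudyOrder"]


def read_manifest(path) -> pd.DataFrame:
    """Read a manifest CSV, keeping label columns as strings (blank != 0)."""
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in ("Path", "PatientID") if c not in df.columns]
    if missing:
        raise ValueError(f"manifest lacks required columns: {missing}")
    if df["Path"].duplicated().any():
        raise ValueError("manifest paths must be unique")
    return df


def write_manifest(manifest: pd.DataFrame, path) -> None:
    df = manifest.copy()
    df.to_csv(path, index=False)


def binary_labels(
    manifest: pd.DataFrame,
    label_column: str = "Cardiomegaly",
    uncertain: UncertainPolicy = "exclude",
) -> tuple[pd.DataFrame, np.ndarray]:
    """Resolve a finding column to 0/1 labels under an uncertain policy.

    ``1`` is positive; ``0`` and blank are negative; ``-1`` follows the
    policy (rows dropped under ``exclude``). Returns the (possibly
    filtered) manifest and the aligned label vector.
    """
    col = manifest[label_column].astype(str).str.strip()
    bad = ~col.isin(LABEL_VALUES)
    if bad.any():
        # tolerate numeric formatting like "1.0"
        normalized = col.copy()
        num = pd.to_numeric(col[bad], errors="coerce")
        normalized[bad] = num.map(lambda v: "" if pd.isna(v) else str(int(v)))
        col = normalized
        if (~col.isin(LABEL_VALUES)).any():
            raise ValueError(f"unparseable values in column {label_column!r}")
    if uncertain == "exclude":
        keep = col != "-1"
        manifest = manifest.loc[keep]
        col = col[keep]
        y = (col == "1").to_numpy(dtype=int)
    elif uncertain == "as_negative":
        y = (col == "1").to_numpy(dtype=int)
    elif uncertain == "as_positive":
        y = col.isin(["1", "-1"]).to_numpy(dtype=int)
    else:
        raise ValueError(f"unknown uncertain policy {uncertain!r}")
    return manifest, y


def select_first_pa(manifest: pd.DataFrame) -> pd.DataFrame:
    """Keep each patient's first chronological frontal PA row.

    Rows with malformed view or study-order values are dropped with a
    warning; patients with no PA view are absent from the output.
    """
    for col in ("Frontal/Lateral", "AP/PA", "StudyOrder", "PatientID"):
        if col not in manifest.columns:
            raise ValueError(f"manifest lacks column {col!r}")
    df = manifest.copy()
    order = pd.to_numeric(df["StudyOrder"], errors="coerce")
    fl = df["Frontal/Lateral"].astype(str).str.strip().str.lower()
    ap = df["AP/PA"].astype(str).str.strip().str.upper()
    malformed = order.isna() | ~fl.isin(["frontal", "lateral"]) | ~ap.isin(["AP", "PA", ""])
    if malformed.any():
        warnings.warn(
            f"dropping {int(malformed.sum())} rows with malformed view/order values",
            stacklevel=2,
        )
        df, order, fl, ap = (x[~malformed] for x in (df, order, fl, ap))
    pa = (fl == "frontal") & (ap == "PA")
    df = df[pa]
    order = order[pa]
    df = df.assign(_order=order)
    first = df.sort_values("_order", kind="stable").groupby("PatientID", sort=False).head(1)
    return first.drop(columns="_order").sort_index()


def balance_undersample(
    manifest: pd.DataFrame,
    label_column: str = "Cardiomegaly",
    seed: int = 0,
    uncertain: UncertainPolicy = "exclude",
) -> pd.DataFrame:
    """Undersample the majority class (seeded) to the minority count."""
    df, y = binary_labels(manifest, label_column, uncertain)
    counts = np.bincount(y, minlength=2)
    if counts.min() == 0:
        raise ValueError("both classes must be present")
    rng = np.random.default_rng(seed)
    keep_idx = []
    minority = int(counts.argmin())
    for cls in (0, 1):
        cls_idx = np.flatnonzero(y == cls)
        if cls == minority:
            keep_idx.append(cls_idx)
        else:
            keep_idx.append(rng.choice(cls_idx, size=counts.min(), replace=False))
    keep = np.sort(np.concatenate(keep_idx))
    return df.iloc[keep]
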