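"""Cohort and longitudinal table I/O plus amyloid-scale harmonization.

Two tabular containers travel through the pipeline as pandas DataFrames:

``CohortTable``
    one row per subject with the three baseline predictors (cortical
    amyloid in centiloids, medial-temporal grey-matter density, APOE4
    carrier status) plus optional class / baseline-diagnosis labels.

``LongitudinalSeries``
    long format, one row per observation: ``subject_id, measure, time_yr,
    value`` where ``measure`` is an ROI name (tau-PET SUVR) or ``"PACC"``.

Amyloid harmonization maps tracer-native units (florbetapir SUVR, PiB DVR)
onto the common centiloid scale with the published linear conversions, so
cohorts acquired with different tracers are interchangeable by construction.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

CLASS_STABLE = "ClinicallyStable"
CLASS_DECLINING = "ClinicallyDeclining"
CLASS_ACS = "ACS"
CLASS_LABELS = (CLASS_STABLE, CLASS_DECLINING, CLASS_ACS)

BASELINE_DX = ("CN", "MCI")

#: the three baseline biological predictors fed to the classifier
FEATURE_COLUMNS = ("amyloid_centiloid", "mtl_gm_density", "apoe4")

COHORT_REQUIRED = ("subject_id",) + FEATURE_COLUMNS
SERIES_COLUMNS = ("subject_id", "measure", "time_yr", "value")

#: FBP SUVR threshold for amyloid positivity; 1.11 SUVR == 22.5 centiloids
#: under the FBP conversion, the canonical default threshold.
CENTILOID_POSITIVITY_THRESHOLD = 22.5

_FBP_SLOPE, _FBP_INTERCEPT = 196.9, -196.03
_PIB_SLOPE, _PIB_INTERCEPT = 142.73, -141.99


# ---------------------------------------------------------------------------
# centiloid harmonization

def fbp_suvr_to_centiloid(suvr):
    """Convert florbetapir (FBP) SUVR to centiloids: CL = SUVR*196.9 - 196.03."""
    suvr = np.asarray(suvr, dtype=float)
    if not np.all(np.isfinite(suvr)) or np.any(suvr <= 0):
        raise ValueError("FBP SUVR must be finite and positive")
    out = suvr * _FBP_SLOPE + _FBP_INTERCEPT
    return float(out) if out.ndim == 0 else out


def pib_dvr_to_centiloid(dvr):
    """Convert PiB DVR to centiloids: CL = DVR*142.73 - 141.99."""
    dvr = np.asarray(dvr, dtype=float)
    if not np.all(np.isfinite(dvr)) or np.any(dvr <= 0):
        raise ValueError("PiB DVR must be finite and positive")
    out = dvr * _PIB_SLOPE + _PIB_INTERCEPT
    return float(out) if out.ndim == 0 else out


def amyloid_positive(centiloid, threshold: float = CENTILOID_POSITIVITY_THRESHOLD):
    """Binary amyloid positivity: 1 iff centiloid >= threshold (inclusive)."""
    centiloid = np.asarray(centiloid, dtype=float)
    if not np.all(np.isfinite(centiloid)) or not np.isfinite(threshold):
        raise ValueError("inputs must be finite")
    out = (centiloid >= threshold).astype(int)
    return int(out) if out.ndim == 0 else out


# ---------------------------------------------------------------------------
# validation

def validate_cohort(df: pd.DataFrame, require_class: bool = False) -> pd.DataFrame:
    """Validate a CohortTable; returns the frame with canonical dtypes.

    Raises ``ValueError`` naming the missing column, duplicated subject or
    offending row for every contract violation.
    """
    for col in COHORT_REQUIRED:
        if col not in df.columns:
            raise ValueError(f"cohort table missing required column {col!r}")
    dup = df["subject_id"][df["subject_id"].duplicated()]
    if len(dup):
        raise ValueError(f"duplicate subject ids: {sorted(dup.unique())}")
    df = df.copy()
    df["subject_id"] = df["subject_id"].astype(str)
    for col in ("amyloid_centiloid", "mtl_gm_density"):
        df[col] = pd.to_numeric(df[col])
        bad = df.loc[~np.isfinite(df[col]), "subject_id"]
        if len(bad):
            raise ValueError(f"non-finite {col} for subjects {list(bad)}")
    df["apoe4"] = pd.to_numeric(df["apoe4"]).astype(int)
    if not df["apoe4"].isin([0, 1]).all():
        raise ValueError("apoe4 must be binary 0/1")
    if "class_label" in df.columns:
        labelled = df["class_label"].dropna()
        bad = labelled[~labelled.isin(CLASS_LABELS)]
        if len(bad):
            raise ValueError(f"unknown class labels: {sorted(bad.unique())}")
    elif require_class:
        raise ValueError("cohort table missing required column 'class_label'")
    if require_class and df["class_label"].isna().any():
        missing = df.loc[df["class_label"].isna(), "subject_id"]
        raise ValueError(f"class_label required but missing for subjects {list(missing)}")
    return df


def validate_series(df: pd.DataFrame) -> pd.DataFrame:
    """Validate a long-format LongitudinalSeries table.

    Per (subject, measure): times strictly increasing, first time 0,
    at least two timepoints.
    """
    for col in SERIES_COLUMNS:
        if col not in df.columns:
            raise ValueError(f"series table missing required column {col!r}")
    df = df.copy()
    df["subject_id"] = df["subject_id"].astype(str)
    df["time_yr"] = pd.to_numeric(df["time_yr"])
    df["value"] = pd.to_numeric(df["value"])
    if not np.all(np.isfinite(df[["time_yr", "value"]].to_numpy())):
        raise ValueError("series contains non-finite times or values")
    for (sid, measure), grp in df.groupby(["subject_id", "measure"], sort=False):
        t = grp["time_yr"].to_numpy()
        if len(t) < 2:
            raise ValueError(f"subject {sid} measure {measure}: fewer than 2 timepoints")
        if np.any(np.diff(t) <= 0):
            raise ValueError(f"subject {sid} measure {measure}: non-monotone times")
        if t[0] != 0:
            raise ValueError(f"subject {sid} measure {measure}: first time must be 0")
    return df


# ---------------------------------------------------------------------------
# CSV I/O (one dialect: comma-separated, UTF-8, header row)

_FLOAT_FMT = "%.12g"


def read_cohort(path: str | Path, require_class: bool = False) -> pd.DataFrame:
    return validate_cohort(pd.read_csv(path), require_class=require_class)


def write_cohort(df: pd.DataFrame, path: str | Path) -> None:
    validate_cohort(df).to_csv(path, index=False, float_format=_FLOAT_FMT)


def read_series(path: str | Path) -> pd.DataFrame:
    return validate_series(pd.read_csv(path))


def write_series(df: pd.DataFrame, path: str | Path) -> None:
    validate_series(df).to_csv(path, index=False, float_format=_FLOAT_FMT)


def baseline_values(series: pd.DataFrame) -> pd.DataFrame:
    """First-timepoint value per (subject, measure), wide: subject x measure."""
    series = series.sort_values("time_yr")
    first = series.groupby(["subject_id", "measure"], sort=False).first().reset_index()
    return first.pivot(index="subject_id", columns="measure", values="value")
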