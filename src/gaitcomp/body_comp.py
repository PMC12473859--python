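"""Bioimpedance body-composition records: ingestion, validation, summaries.

The column dictionary mirrors the standard InBody indicator abbreviations:

====== ========================================= ======
column meaning                                    unit
====== ========================================= ======
ICW    intracellular water                        L
ECW    extracellular water                        L
TBW    total body water (= ICW + ECW)             L
PM     protein mass                               kg
MM     mineral mass                               kg
FAT    body fat mass                              kg
SLM    soft lean mass                             kg
FFM    fat-free mass                              kg
SMM    skeletal muscle mass                       kg
DLM    dry lean mass                              kg
PBF    percent body fat                           %
BMI    body mass index (= weight / height(m)^2)   kg/m2
ECW_TBW extracellular / total body water          ratio
BFM_control body-fat-mass control recommendation  kg (may be negative)
FFM_control fat-free-mass control recommendation  kg
BCM    body cell mass                             kg
BMC    bone mineral content                       kg
VFA    visceral fat area                          cm2
BMR    basal metabolic rate                       kcal
TBW_FFM total body water / fat-free mass          %
SMI    skeletal muscle index                      kg/m2
====== ========================================= ======

plus demographics: ``participant_id``, ``sex`` (male/female), ``age`` (y),
``height`` (cm), ``weight`` (kg).  SMI is stored as measured, never
recomputed from SMM/height^2: device-reported SMI uses appendicular muscle
mass as the numerator, so recomputation from whole-body SMM would corrupt
the data.

Sarcopenia screening applies the AWGS 2019 cutoffs: at risk iff
SMI < 7.0 kg/m2 (male) or SMI < 5.7 kg/m2 (female), strict less-than.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from gaitcomp.errors import ParseError, SchemaError, ValidationError

#: The 21 indicator columns, in report order.
INDICATOR_COLUMNS = (
    "ICW", "ECW", "TBW", "PM", "MM", "FAT", "SLM", "FFM", "SMM", "DLM",
    "PBF", "BMI", "ECW_TBW", "BFM_control", "FFM_control", "BCM", "BMC",
    "VFA", "BMR", "TBW_FFM", "SMI",
)

DEMOGRAPHIC_COLUMNS = ("participant_id", "sex", "age", "height", "weight")

#: Indicators that must be non-negative (control recommendations may not be).
_NONNEGATIVE = tuple(c for c in INDICATOR_COLUMNS
                     if c not in ("BFM_control", "FFM_control"))

#: Accepted header aliases -> canonical column names.
COLUMN_ALIASES = {
    "ECW/TBW": "ECW_TBW",
    "TBW/FFM": "TBW_FFM",
    "BFM Control": "BFM_control",
    "FFM Control": "FFM_control",
    "DLMM": "DLM",
    "id": "participant_id",
    "gender": "sex",
}

#: Consistency tolerances, sized to absorb 1–3 decimal rounding of device
#: print-outs: water sum (L), ECW/TBW ratio, BMI (kg/m2).
WATER_TOL = 0.05
RATIO_TOL = 0.001
BMI_TOL = 0.3

#: AWGS 2019 skeletal-muscle-index cutoffs, kg/m2, strict less-than.
SMI_CUTOFFS = {"male": 7.0, "female": 5.7}


@dataclass(frozen=True)
class RecordViolation:
    """One failed consistency check on one record."""

    participant_id: str
    check: str
    detail: str


def read_body_comp(path, strict: bool = False,
                   ) -> tuple[pd.DataFrame, list[RecordViolation]]:
    """Read a body-composition CSV into a validated table.

    Header aliases from :data:`COLUMN_ALIASES` are accepted; unknown extra
    columns are carried through untouched.  Returns the table and the list
    of consistency violations; with ``strict=True`` any violation raises,
    otherwise each is emitted as a warning.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path)
    except pd.errors.ParserError as exc:
        raise ParseError(f"{path.name}: {exc}") from None
    df = df.rename(columns=COLUMN_ALIASES)
    missing = [c for c in DEMOGRAPHIC_COLUMNS + INDICATOR_COLUMNS
               if c not in df.columns]
    if missing:
        raise SchemaError(f"{path.name}: missing mandatory columns {missing}")
    for col in INDICATOR_COLUMNS + ("age", "height", "weight"):
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = coerced.isna() & df[col].notna()
        if bad.any():
            row = int(np.flatnonzero(bad)[0])
            raise ParseError(
                f"{path.name}: non-numeric value {df[col].iloc[row]!r} at "
                f"row {row + 2}, column {col!r}")
        df[col] = coerced
    df["participant_id"] = df["participant_id"].astype(str)
    violations = validate_body_comp(df)
    if violations and strict:
        raise ValidationError(
            "; ".join(f"{v.participant_id}: {v.check} ({v.detail})"
                      for v in violations))
    for v in violations:
        warnings.warn(f"{v.participant_id}: {v.check}: {v.detail}",
                      stacklevel=2)
    return df, violations


def validate_body_comp(df: pd.DataFrame) -> list[RecordViolation]:
    """Per-record consistency checks; returns violations, raises on hard errors.

    Hard errors (raise): unknown sex label, non-positive height.
    Soft checks (returned): water-sum identity |ICW+ECW-TBW| <= 0.05 L,
    ratio identity |ECW/TBW - ECW_TBW| <= 0.001, BMI recomputation within
    0.3 kg/m2, range checks (non-negative masses, PBF in [0,100], ECW_TBW
    in (0,1)).
    """
    bad_sex = ~df["sex"].isin(("male", "female"))
    if bad_sex.any():
        raise ValidationError(
            f"unknown sex labels {sorted(df.loc[bad_sex, 'sex'].unique())}")
    if (df["height"] <= 0).any():
        raise ValidationError("non-positive height")
    out: list[RecordViolation] = []

    def flag(mask: pd.Series, check: str, detail_fn) -> None:
        for _, row in df[mask.fillna(False)].iterrows():
            out.append(RecordViolation(row["participant_id"], check,
                                       detail_fn(row)))

    flag((df[list(_NONNEGATIVE)] < 0).any(axis=1), "negative_value",
         lambda r: "negative mass/volume/area")
    flag(~df["PBF"].between(0, 100), "pbf_range",
         lambda r: f"PBF={r['PBF']}")
    flag(~((df["ECW_TBW"] > 0) & (df["ECW_TBW"] < 1)), "ecw_tbw_range",
         lambda r: f"ECW_TBW={r['ECW_TBW']}")
    water_err = (df["ICW"] + df["ECW"] - df["TBW"]).abs()
    flag(water_err > WATER_TOL, "water_sum",
         lambda r: f"|ICW+ECW-TBW|="
                   f"{abs(r['ICW'] + r['ECW'] - r['TBW']):.3f} L")
    ratio_err = (df["ECW"] / df["TBW"] - df["ECW_TBW"]).abs()
    flag(ratio_err > RATIO_TOL, "ecw_tbw_ratio",
         lambda r: f"|ECW/TBW-stored|="
                   f"{abs(r['ECW'] / r['TBW'] - r['ECW_TBW']):.4f}")
    bmi_err = (df["weight"] / (df["height"] / 100.0) ** 2 - df["BMI"]).abs()
    flag(bmi_err > BMI_TOL, "bmi",
         lambda r: f"|weight/h^2-BMI|="
                   f"{abs(r['weight'] / (r['height'] / 100) ** 2 - r['BMI']):.2f}")
    return out


def write_body_comp(df: pd.DataFrame, path) -> None:
    """Write a body-composition table in the documented column order."""
    extra = [c for c in df.columns
             if c not in DEMOGRAPHIC_COLUMNS + INDICATOR_COLUMNS]
    cols = list(DEMOGRAPHIC_COLUMNS + INDICATOR_COLUMNS) + extra
    df[cols].to_csv(path, index=False)


def flag_sarcopenia_risk(record: Mapping) -> str:
    """AWGS 2019 screen for one record: 'at_risk' / 'not_at_risk' / 'unknown'.

    Male at risk iff SMI < 7.0 kg/m2; female iff SMI < 5.7 kg/m2 (strict).
    A missing SMI yields 'unknown' with a warning.
    """
    sex = record["sex"]
    if sex not in SMI_CUTOFFS:
        raise ValidationError(f"unknown sex label {sex!r}")
    smi = record["SMI"]
    if smi is None or (isinstance(smi, float) and np.isnan(smi)):
        warnings.warn(
            f"participant {record.get('participant_id', '?')!r}: SMI "
            f"missing, sarcopenia status unknown", stacklevel=2)
        return "unknown"
    return "at_risk" if smi < SMI_CUTOFFS[sex] else "not_at_risk"


def describe_indicators(df: pd.DataFrame) -> pd.DataFrame:
    """Per-indicator mean, sample std (n-1), min, max.

    A single record reports std 0 with a warning; an all-missing indicator
    is skipped with a warning.
    """
    if len(df) == 0:
        raise ValidationError("no records")
    rows = []
    for col in INDICATOR_COLUMNS:
        vals = df[col].dropna().to_numpy(dtype=float)
        if vals.size == 0:
            warnings.warn(f"indicator {col}: all values missing, skipped",
                          stacklevel=2)
            continue
        if vals.size == 1:
            warnings.warn(
                f"indicator {col}: single record, std reported as 0",
                stacklevel=2)
            std = 0.0
        else:
            std = float(vals.std(ddof=1))
        rows.append({
            "indicator": col,
            "mean": float(vals.mean()),
            "std": std,
            "min": float(vals.min()),
            "max": float(vals.max()),
        })
    return pd.DataFrame(rows)
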