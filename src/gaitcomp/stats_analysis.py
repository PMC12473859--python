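"""Statistical battery: normality screen, correlations, regressions, strata.

The correlation of a dynamic gait variable x and a static indicator y is the
Pearson product-moment coefficient

    r = sum((x_i - xbar)(y_i - ybar)) /
        sqrt(sum((x_i - xbar)^2) * sum((y_i - ybar)^2)),

with a two-sided p-value from the exact transform t = r sqrt(n-2)/sqrt(1-r^2)
on n-2 degrees of freedom — identically the slope t-statistic of the simple
OLS regression of y on x, an identity this module asserts in its tests.
Spearman's coefficient is Pearson on average ranks.  Significance markers
follow the conventional star rule: ``***`` p<0.001, ``**`` p<0.01, ``*``
p<0.05, blank otherwise; markers are always consistent with the computed p.

Missing data are handled pairwise-complete with the per-cell n recorded.
No multiple-testing correction is applied by default (exploratory
screening); Benjamini–Hochberg is available by flag.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
import scipy.stats
import statsmodels.api as sm
from statsmodels.stats.multitest import multipletests

from gaitcomp.errors import DegenerateDataError, ValidationError
from gaitcomp.body_comp import INDICATOR_COLUMNS

#: Dynamic variables correlated against every indicator.
DYNAMIC_VARIABLES = (
    "mean_directional_shift", "mean_displacement",
    "test2_1_score", "test2_2_score", "test2_score",
)

ALPHA = 0.05


def significance_marker(p: float) -> str:
    """Star marker for a p-value: *** <0.001, ** <0.01, * <0.05, else ''."""
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""


@dataclass(frozen=True)
class CorrelationCell:
    """One correlation: pair names, method, r, pairwise n, p, marker."""

    x: str
    y: str
    method: str
    r: float
    n: int
    p: float
    marker: str

    def formatted(self) -> str:
        """Render as ``r marker(p)``, e.g. ``0.561 *(0.019)``."""
        mark = f" {self.marker}" if self.marker else ""
        return f"{self.r:.3f}{mark}({self.p:.3f})"


@dataclass(frozen=True)
class RegressionRow:
    """Simple-OLS fit of one indicator: intercept, slope, t, p, marker."""

    variable: str
    intercept: float
    slope: float
    t_slope: float
    p: float
    marker: str
    n: int
    perfect_fit: bool = False


def _complete_pairs(x, y) -> tuple[np.ndarray, np.ndarray]:
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if x.shape != y.shape:
        raise ValidationError("x and y must have equal length")
    ok = np.isfinite(x) & np.isfinite(y)
    return x[ok], y[ok]


def _r_to_p(r: float, n: int) -> float:
    """Two-sided p from the exact t transform on n-2 df."""
    if abs(r) >= 1.0:
        return 0.0
    t = r * np.sqrt(n - 2) / np.sqrt(1.0 - r * r)
    return float(2.0 * scipy.stats.t.sf(abs(t), n - 2))


def pearson_r(x, y, x_name: str = "x", y_name: str = "y") -> CorrelationCell:
    """Pearson correlation on pairwise-complete observations.

    Requires at least 3 complete pairs and non-zero variance in both
    vectors.
    """
    xv, yv = _complete_pairs(x, y)
    n = xv.size
    if n < 3:
        raise DegenerateDataError(
            f"({x_name}, {y_name}): only {n} complete pairs, need >= 3")
    xc = xv - xv.mean()
    yc = yv - yv.mean()
    sx = float(np.sqrt((xc * xc).sum()))
    sy = float(np.sqrt((yc * yc).sum()))
    if sx == 0.0 or sy == 0.0:
        raise DegenerateDataError(
            f"({x_name}, {y_name}): zero variance, correlation undefined")
    r = float(np.clip((xc * yc).sum() / (sx * sy), -1.0, 1.0))
    p = _r_to_p(r, n)
    return CorrelationCell(x_name, y_name, "pearson", r, n, p,
                           significance_marker(p))


def spearman_r(x, y, x_name: str = "x", y_name: str = "y") -> CorrelationCell:
    """Spearman correlation: Pearson on average ranks (ties averaged)."""
    xv, yv = _complete_pairs(x, y)
    if xv.size < 3:
        raise DegenerateDataError(
            f"({x_name}, {y_name}): only {xv.size} complete pairs, need >= 3")
    rx = scipy.stats.rankdata(xv, method="average")
    ry = scipy.stats.rankdata(yv, method="average")
    cell = pearson_r(rx, ry, x_name, y_name)
    return replace(cell, method="spearman")


def shapiro_wilk_screen(df: pd.DataFrame,
                        variables: list[str] | None = None) -> pd.DataFrame:
    """Shapiro–Wilk normality screen, one row per variable.

    Columns: variable, mean, sd, skewness, kurtosis (excess), W, p, conforms
    (p > 0.05).  Variables with fewer than 3 non-missing values are skipped
    with a warning; constant vectors are flagged degenerate (W, p = NaN,
    conforms False).
    """
    variables = list(variables) if variables is not None else [
        c for c in df.columns if pd.api.types.is_numeric_dtype(df[c])]
    rows = []
    for var in variables:
        vals = df[var].dropna().to_numpy(dtype=float)
        if vals.size < 3:
            warnings.warn(f"{var}: n={vals.size} < 3, normality test "
                          f"skipped", stacklevel=2)
            continue
        row = {
            "variable": var,
            "mean": float(vals.mean()),
            "sd": float(vals.std(ddof=1)),
            "skewness": float(scipy.stats.skew(vals)),
            "kurtosis": float(scipy.stats.kurtosis(vals)),
        }
        if np.ptp(vals) == 0.0:
            warnings.warn(f"{var}: constant vector, normality degenerate",
                          stacklevel=2)
            row.update(W=np.nan, p=np.nan, conforms=False, degenerate=True)
        else:
            if vals.size > 5000:
                vals = vals[:5000]
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                W, p = scipy.stats.shapiro(vals)
            row.update(W=float(W), p=float(p), conforms=bool(p > ALPHA),
                       degenerate=False)
        rows.append(row)
    return pd.DataFrame(rows)


def simple_ols(y, x, variable: str = "x") -> RegressionRow:
    """Simple linear regression of y on one indicator x.

    Returns intercept, slope, the slope t-statistic on n-2 df and its
    two-sided p with star marker.  A perfect fit (zero residual) is flagged
    with t = +/- inf.
    """
    yv, xv = _complete_pairs(y, x)
    n = xv.size
    if n < 3:
        raise DegenerateDataError(f"{variable}: only {n} complete pairs")
    if np.ptp(xv) == 0.0:
        raise DegenerateDataError(f"{variable}: zero variance in regressor")
    fit = sm.OLS(yv, sm.add_constant(xv)).fit()
    intercept, slope = fit.params
    resid_ss = float(fit.ssr)
    if resid_ss <= 1e-12 * float(np.square(yv - yv.mean()).sum() + 1e-300):
        t = np.inf if slope > 0 else -np.inf
        p = 0.0
        perfect = True
    else:
        t = float(fit.tvalues[1])
        p = float(fit.pvalues[1])
        perfect = False
    return RegressionRow(variable, float(intercept), float(slope), float(t),
                         p, significance_marker(p), n, perfect)


def _join_tables(features: pd.DataFrame, indicators: pd.DataFrame,
                 scores: pd.DataFrame | None) -> pd.DataFrame:
    merged = features.merge(indicators, on="participant_id", how="outer",
                            indicator=True)
    unmatched = merged.loc[merged["_merge"] != "both", "participant_id"]
    merged = merged.drop(columns="_merge")
    if scores is not None:
        merged = merged.merge(scores, on="participant_id", how="left")
    if len(merged) - len(unmatched) < 3:
        raise ValidationError(
            f"join yields fewer than 3 complete rows; unmatched ids: "
            f"{sorted(unmatched.astype(str))}")
    return merged


def correlation_matrix(features: pd.DataFrame, indicators: pd.DataFrame,
                       scores: pd.DataFrame | None = None,
                       method: str = "pearson",
                       indicator_columns=INDICATOR_COLUMNS,
                       dynamic_variables: tuple[str, ...] | None = None,
                       normality: pd.DataFrame | None = None,
                       correct: bool = False) -> pd.DataFrame:
    """Correlation grid: dynamic variables x body-composition indicators.

    Tables are joined on participant_id; each cell uses pairwise-complete
    observations with its n recorded.  ``normality`` (a screen table) adds a
    ``normality_flag`` column marking cells whose indicator failed the
    screen.  ``correct=True`` appends Benjamini–Hochberg adjusted p-values
    (``p_adj``) without changing the markers, which always reflect raw p.
    """
    if method not in ("pearson", "spearman"):
        raise ValidationError(f"unknown method {method!r}")
    merged = _join_tables(features, indicators, scores)
    dyn = list(dynamic_variables if dynamic_variables is not None
               else [v for v in DYNAMIC_VARIABLES if v in merged.columns])
    corr = pearson_r if method == "pearson" else spearman_r
    failed = set()
    if normality is not None and len(normality):
        failed = set(normality.loc[~normality["conforms"], "variable"])
    cells = []
    for ind in indicator_columns:
        for dv in dyn:
            try:
                cell = corr(merged[dv], merged[ind], x_name=dv, y_name=ind)
            except DegenerateDataError as exc:
                warnings.warn(f"cell ({dv}, {ind}) degenerate: {exc}",
                              stacklevel=2)
                cells.append({
                    "indicator": ind, "dynamic": dv, "method": method,
                    "r": np.nan, "n": 0, "p": np.nan, "marker": "",
                    "formatted": "", "normality_flag": ind in failed,
                })
                continue
            cells.append({
                "indicator": ind, "dynamic": dv, "method": method,
                "r": cell.r, "n": cell.n, "p": cell.p,
                "marker": cell.marker, "formatted": cell.formatted(),
                "normality_flag": ind in failed,
            })
    out = pd.DataFrame(cells)
    if correct:
        out["p_adj"] = multipletests(out["p"], method="fdr_bh")[1]
    return out


def format_correlation_grid(cells: pd.DataFrame) -> pd.DataFrame:
    """Pivot a cell table into the printed report layout: one row per
    indicator, one ``r marker(p)`` column per dynamic variable."""
    return cells.pivot(index="indicator", columns="dynamic",
                       values="formatted").reindex(
        [i for i in INDICATOR_COLUMNS
         if i in set(cells["indicator"])])


def regression_table(features: pd.DataFrame, indicators: pd.DataFrame,
                     y: str = "mean_directional_shift",
                     variables=None) -> pd.DataFrame:
    """Per-indicator simple OLS with ``y`` as the dependent variable.

    Output mirrors the regression report: constant coefficient, variable
    coefficient, t-statistic, significance marker.
    """
    merged = _join_tables(features, indicators, None)
    if variables is None:
        variables = [c for c in INDICATOR_COLUMNS + ("age", "height",
                                                     "weight")
                     if c in merged.columns]
    rows = []
    for var in variables:
        rr = simple_ols(merged[y], merged[var], variable=var)
        rows.append({
            "variable": var, "intercept": rr.intercept, "slope": rr.slope,
            "t_statistic": rr.t_slope, "p": rr.p,
            "significance": rr.marker if rr.marker else "ns", "n": rr.n,
        })
    return pd.DataFrame(rows)


def stratified_analysis(features: pd.DataFrame, indicators: pd.DataFrame,
                        scores: pd.DataFrame | None = None,
                        stratum: str = "sex",
                        method: str = "pearson",
                        allowed_labels: tuple[str, ...] = ("male", "female"),
                        ) -> dict[str, dict]:
    """Per-stratum correlation grids plus distribution summaries.

    Returns ``{label: {"cells": grid, "summary": five-number summary of
    mean_directional_shift, "n": count, "low_n": bool}}``.  Strata with
    fewer than 3 members are skipped with an explicit small-sample warning;
    grids from strata of 3–9 members carry ``low_n=True``.
    """
    merged = _join_tables(features, indicators, scores)
    labels = merged[stratum].unique()
    unknown = [lab for lab in labels if lab not in allowed_labels]
    if unknown:
        raise ValidationError(f"unknown {stratum} labels {sorted(unknown)}")
    out: dict[str, dict] = {}
    for label in allowed_labels:
        sub = merged[merged[stratum] == label]
        if len(sub) < 3:
            warnings.warn(
                f"stratum {label!r}: n={len(sub)} < 3, skipped "
                f"(insufficient sample)", stacklevel=2)
            continue
        low_n = len(sub) < 10
        if low_n:
            warnings.warn(
                f"stratum {label!r}: n={len(sub)} is small; interpret "
                f"correlations with caution", stacklevel=2)
        shift = sub["mean_directional_shift"].dropna()
        q = np.percentile(shift, [0, 25, 50, 75, 100])
        dyn = [v for v in DYNAMIC_VARIABLES if v in sub.columns]
        corr = pearson_r if method == "pearson" else spearman_r
        cells = []
        for ind in INDICATOR_COLUMNS:
            for dv in dyn:
                try:
                    cell = corr(sub[dv], sub[ind], x_name=dv, y_name=ind)
                except DegenerateDataError:
                    continue
                cells.append({
                    "indicator": ind, "dynamic": dv, "method": method,
                    "r": cell.r, "n": cell.n, "p": cell.p,
                    "marker": cell.marker, "formatted": cell.formatted(),
                })
        out[label] = {
            "cells": pd.DataFrame(cells),
            "summary": {
                "min": float(q[0]), "q1": float(q[1]), "median": float(q[2]),
                "q3": float(q[3]), "max": float(q[4]),
            },
            "n": int(len(sub)),
            "low_n": low_n,
        }
    return out
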