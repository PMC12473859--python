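"""Percentile-threshold cleaning of per-frame center displacement.

Center-displacement distributions from pose-estimated gait are right-skewed
with a long tail: isolated frames with pixel jumps from frame freezing or
abrupt movements sit far above the bulk of the data.  Thresholding at a high
percentile (default the 95th) removes that tail without assuming symmetry,
unlike IQR-based rules.  Entries with displacement strictly exceeding the
threshold are removed from all downstream aggregation — including their
directional-shift values, since a corrupted displacement implies a corrupted
angle for the same frame pair.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from gaitcomp.errors import (
    DegenerateDataError,
    EmptyAfterFilterError,
    ParameterError,
)
from gaitcomp.gait_features import Dynamics

#: Percentiles reported by default; 95 is the cleaning standard, 90/99 are
#: retained for sensitivity analysis.
DEFAULT_PERCENTILES = (90.0, 95.0, 99.0)
DEFAULT_PERCENTILE = 95.0


@dataclass(frozen=True)
class ThresholdReport:
    """What a threshold filter did: cut-off, counts, scope."""

    percentile: float | None
    threshold: float
    n_total: int
    n_removed: int
    scope: str = "pooled"

    @property
    def removed_fraction(self) -> float:
        return self.n_removed / self.n_total if self.n_total else 0.0


def compute_percentile_thresholds(
    displacements: Sequence[float] | np.ndarray,
    percentiles: Sequence[float] = DEFAULT_PERCENTILES,
) -> dict[float, float]:
    """Percentile cut-offs of a displacement sample.

    Quantiles use linear interpolation between closest ranks; the returned
    map is monotone non-decreasing in percentile.
    """
    values = np.asarray(displacements, dtype=np.float64)
    if values.size == 0:
        raise DegenerateDataError("empty displacement sample")
    if np.any(~np.isfinite(values)) or np.any(values < 0):
        raise ParameterError("displacements must be finite and non-negative")
    percentiles = list(percentiles)
    for p in percentiles:
        if not 0 < p < 100:
            raise ParameterError(f"percentile {p} outside (0, 100)")
    cuts = np.percentile(values, percentiles)
    return {float(p): float(c) for p, c in zip(percentiles, cuts)}


def apply_threshold_filter(dyn: Dynamics, threshold: float,
                           percentile: float | None = None,
                           scope: str = "pooled",
                           ) -> tuple[Dynamics, ThresholdReport]:
    """Remove dynamics entries whose center displacement exceeds ``threshold``.

    "Exceeding" is strict: entries equal to the threshold are kept.  Removal
    applies to the whole entry (displacement and directional shift).
    Raises :class:`EmptyAfterFilterError` if nothing survives.
    """
    if threshold < 0:
        raise ParameterError(f"threshold must be >= 0, got {threshold}")
    keep = dyn.center_dis <= threshold
    n_total = len(dyn)
    n_removed = int(n_total - keep.sum())
    if n_removed == n_total:
        raise EmptyAfterFilterError(
            f"participant {dyn.participant_id!r}: threshold {threshold} "
            f"removed all {n_total} entries")
    filtered = Dynamics(
        participant_id=dyn.participant_id,
        frame_index=dyn.frame_index[keep],
        dx=dyn.dx[keep],
        dy=dyn.dy[keep],
        center_dis=dyn.center_dis[keep],
        theta=dyn.theta[keep],
    )
    report = ThresholdReport(
        percentile=percentile, threshold=float(threshold),
        n_total=n_total, n_removed=n_removed, scope=scope)
    return filtered, report


def pooled_threshold(dynamics: Iterable[Dynamics],
                     percentile: float = DEFAULT_PERCENTILE) -> float:
    """Cohort-level cut-off: one percentile over all participants' steps."""
    pooled = np.concatenate([d.center_dis for d in dynamics])
    return compute_percentile_thresholds(pooled, [percentile])[percentile]


def filter_cohort(dynamics: Sequence[Dynamics],
                  percentile: float = DEFAULT_PERCENTILE,
                  scope: str = "pooled",
                  ) -> tuple[list[Dynamics], list[ThresholdReport]]:
    """Filter every participant at a pooled or per-participant cut-off.

    ``scope='pooled'`` (default) computes one threshold from the cohort-wide
    displacement distribution; ``scope='per_participant'`` computes one per
    participant.
    """
    if scope not in ("pooled", "per_participant"):
        raise ParameterError(f"unknown scope {scope!r}")
    out, reports = [], []
    if scope == "pooled":
        cut = pooled_threshold(dynamics, percentile)
        for d in dynamics:
            f, r = apply_threshold_filter(d, cut, percentile, scope)
            out.append(f)
            reports.append(r)
    else:
        for d in dynamics:
            cut = compute_percentile_thresholds(
                d.center_dis, [percentile])[percentile]
            f, r = apply_threshold_filter(d, cut, percentile, scope)
            out.append(f)
            reports.append(r)
    return out, reports
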