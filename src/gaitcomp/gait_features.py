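"""Center-of-mass gait dynamics.

Per frame, the center of mass (CoM) is the unweighted mean of five upper-body
keypoints (nose, both shoulders, both hips).  Between consecutive frames the
center displacement is the Euclidean distance of the CoM in pixel space,

    center_dis_i = sqrt((x_i - x_{i-1})^2 + (y_i - y_{i-1})^2),

and the directional shift is the arctangent of the displacement ratio,

    theta_t = arctan((y_i - y_{i-1}) / (x_i - x_{i-1})),

with range (-pi/2, pi/2].  Per-participant aggregates report the mean and
sample variance of the directional shift and the mean displacement
(pixels/frame).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, NamedTuple

import numpy as np

from gaitcomp.errors import DegenerateDataError, ParameterError
from gaitcomp.pose_io import COM_KEYPOINT_INDICES, PoseSequence


@dataclass
class CoMTrajectory:
    """Per-frame CoM points for one participant, with a validity mask."""

    participant_id: str
    frame_index: np.ndarray
    x: np.ndarray
    y: np.ndarray
    valid: np.ndarray

    def __post_init__(self) -> None:
        self.frame_index = np.asarray(self.frame_index, dtype=np.int64)
        self.x = np.asarray(self.x, dtype=np.float64)
        self.y = np.asarray(self.y, dtype=np.float64)
        self.valid = np.asarray(self.valid, dtype=bool)

    def __len__(self) -> int:
        return len(self.frame_index)


class FrameDynamics(NamedTuple):
    """Dynamics of one consecutive-frame pair, indexed by the later frame."""

    frame_index: int
    dx: float
    dy: float
    center_dis: float
    theta: float


@dataclass
class Dynamics:
    """Array-backed list of :class:`FrameDynamics` for one participant."""

    participant_id: str
    frame_index: np.ndarray
    dx: np.ndarray
    dy: np.ndarray
    center_dis: np.ndarray
    theta: np.ndarray

    def __post_init__(self) -> None:
        self.frame_index = np.asarray(self.frame_index, dtype=np.int64)
        for name in ("dx", "dy", "center_dis", "theta"):
            setattr(self, name, np.asarray(getattr(self, name), np.float64))

    def __len__(self) -> int:
        return len(self.frame_index)

    def __iter__(self):
        for i in range(len(self)):
            yield self[i]

    def __getitem__(self, i: int) -> FrameDynamics:
        return FrameDynamics(
            int(self.frame_index[i]), float(self.dx[i]), float(self.dy[i]),
            float(self.center_dis[i]), float(self.theta[i]))


@dataclass(frozen=True)
class GaitFeatureSet:
    """Per-participant aggregate gait features."""

    participant_id: str
    mean_directional_shift: float
    var_directional_shift: float
    mean_displacement: float
    n_frames_used: int
    mode: str
    filter_threshold: float | None = None


def compute_com(seq: PoseSequence) -> CoMTrajectory:
    """CoM per frame: unweighted mean of the five selected keypoints.

    Frames where any CoM keypoint coordinate is still missing after repair
    are marked invalid and excluded from downstream dynamics.
    """
    com = seq.xy[:, np.array(COM_KEYPOINT_INDICES), :]
    valid = np.isfinite(com).all(axis=(1, 2))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        center = com.mean(axis=1)
    return CoMTrajectory(
        participant_id=seq.participant_id,
        frame_index=seq.frame_index,
        x=center[:, 0],
        y=center[:, 1],
        valid=valid,
    )


def directional_shift(dx: np.ndarray, dy: np.ndarray,
                      angle: str = "ratio") -> np.ndarray:
    """Directional shift of each step.

    ``angle='ratio'`` (default) is arctan(dy/dx) on (-pi/2, pi/2], with the
    degenerate step convention theta = +pi/2 if dx == 0 and dy > 0, -pi/2 if
    dy < 0, and 0 for a zero step.  ``angle='atan2'`` uses the full
    quadrant-aware angle on (-pi, pi].
    """
    dx = np.asarray(dx, float)
    dy = np.asarray(dy, float)
    if angle == "atan2":
        return np.arctan2(dy, dx)
    if angle != "ratio":
        raise ParameterError(f"unknown angle convention {angle!r}")
    with np.errstate(divide="ignore", invalid="ignore"):
        theta = np.arctan(dy / dx)
    zero_dx = dx == 0
    theta = np.where(zero_dx, np.sign(dy) * np.pi / 2, theta)
    return np.where(zero_dx & (dy == 0), 0.0, theta)


def compute_dynamics(com: CoMTrajectory, angle: str = "ratio") -> Dynamics:
    """Step dynamics for every consecutive valid frame pair.

    Pairs that span an invalid (dropped) point, or a jump in frame_index,
    produce no entry: gaps are not bridged, so displacement is never
    inflated across them.
    """
    if int(com.valid.sum()) < 2:
        raise DegenerateDataError(
            f"participant {com.participant_id!r}: fewer than 2 valid CoM "
            f"points")
    ok = com.valid[1:] & com.valid[:-1] & (np.diff(com.frame_index) == 1)
    dx = np.diff(com.x)[ok]
    dy = np.diff(com.y)[ok]
    if dx.size == 0:
        raise DegenerateDataError(
            f"participant {com.participant_id!r}: no consecutive valid "
            f"frame pairs")
    return Dynamics(
        participant_id=com.participant_id,
        frame_index=com.frame_index[1:][ok],
        dx=dx,
        dy=dy,
        center_dis=np.hypot(dx, dy),
        theta=directional_shift(dx, dy, angle=angle),
    )


def aggregate_features(dyn: Dynamics, mode: str = "angular",
                       filter_threshold: float | None = None,
                       ) -> GaitFeatureSet:
    """Aggregate step dynamics into one feature row.

    ``mode='angular'`` (default): mean_directional_shift is the mean of
    |theta| in radians; ``mode='horizontal'``: the mean of |dx| in
    pixels/frame.  var_directional_shift is the matching sample variance
    (n-1 denominator); a single entry reports variance 0 with a warning.
    """
    if mode not in ("angular", "horizontal"):
        raise ParameterError(f"unknown shift mode {mode!r}")
    if len(dyn) == 0:
        raise DegenerateDataError(
            f"participant {dyn.participant_id!r}: no dynamics left to "
            f"aggregate (filter_threshold={filter_threshold!r})")
    shift = np.abs(dyn.theta) if mode == "angular" else np.abs(dyn.dx)
    if len(dyn) == 1:
        warnings.warn(
            f"participant {dyn.participant_id!r}: single dynamics entry; "
            f"variance reported as 0", stacklevel=2)
        var = 0.0
    else:
        var = float(shift.var(ddof=1))
    return GaitFeatureSet(
        participant_id=dyn.participant_id,
        mean_directional_shift=float(shift.mean()),
        var_directional_shift=var,
        mean_displacement=float(dyn.center_dis.mean()),
        n_frames_used=len(dyn),
        mode=mode,
        filter_threshold=filter_threshold,
    )


def path_density(trajectories: Iterable[CoMTrajectory], bins: int = 50,
                 ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """2-D histogram of pooled valid CoM points across a cohort.

    Returns ``(counts, x_edges, y_edges)``; counts sum to the number of
    pooled points.
    """
    if bins < 1:
        raise ParameterError(f"bins must be >= 1, got {bins}")
    xs, ys = [], []
    for com in trajectories:
        xs.append(com.x[com.valid])
        ys.append(com.y[com.valid])
    x = np.concatenate(xs) if xs else np.empty(0)
    y = np.concatenate(ys) if ys else np.empty(0)
    if x.size == 0:
        raise DegenerateDataError("no valid CoM points to bin")
    counts, xe, ye = np.histogram2d(x, y, bins=bins)
    return counts, xe, ye
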