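"""Synthetic cohort generator.

Emulates the joint structure the analysis assumes, so every pipeline stage is
testable without access to raw recordings:

* a latent mobility factor per participant couples, via a single-factor
  model, the body-composition indicators (calibrated to the published
  cohort's means/SDs) to the dispersion of the center-of-mass directional
  shift — muscle and water indicators positively, fat indicators negatively;
* pose sequences are rendered as a CoM walk whose per-step direction carries
  the planted shift level and a sinusoid-driven sway sign pattern, with
  keypoints placed around the CoM by anthropometric offsets plus jitter;
* heavy-tailed displacement outliers (multiplicative spikes on isolated
  frames, mimicking pixel jumps from frame freezing) are injected at a
  configurable rate, producing the right-skewed long-tailed displacement
  distribution the percentile filter targets;
* keypoint confidences are drawn so per-participant means fall in 0.59–0.68
  and maxima in 0.77–0.83, with occasional low-confidence dropouts that
  exercise the interpolation repair;
* 4-m walk times are inversely related to latent mobility.

Internal identities hold exactly by construction: TBW is drawn and split
into ECW = ratio * TBW and ICW = TBW - ECW (so the water-sum and ratio
checks pass with zero warnings), and weight = BMI * (height/100)^2.

All randomness flows from one seed through named substreams, so each data
modality can be regenerated independently.
"""

from __future__ import annotations

import dataclasses
import json
import math
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from gaitcomp.errors import ParameterError
from gaitcomp.pose_io import (
    COM_KEYPOINT_INDICES,
    N_KEYPOINTS,
    PoseSequence,
    write_pose_sequence,
)

#: Indicator population parameters (mean, SD) on device units.
INDICATOR_PARAMS: dict[str, tuple[float, float]] = {
    "ICW": (21.216, 3.863),
    "ECW": (13.8, 2.446),
    "TBW": (35.016, 6.288),
    "PM": (9.163, 1.67),
    "MM": (3.246, 0.575),
    "FAT": (11.811, 5.794),
    "SLM": (44.721, 8.066),
    "FFM": (47.416, 8.507),
    "SMM": (25.653, 5.025),
    "DLM": (12.4, 2.227),
    "PBF": (19.7, 8.228),
    "BMI": (22.695, 2.933),
    "ECW_TBW": (0.394, 0.007),
    "BFM_control": (-2.421, 5.507),
    "FFM_control": (1.679, 2.525),
    "BCM": (30.384, 5.534),
    "BMC": (2.687, 0.465),
    "VFA": (46.316, 21.765),
    "BMR": (1394.368, 183.521),
    "TBW_FFM": (73.789, 0.38),
    "SMI": (8.132, 1.322),
}

#: Default planted correlations between latent mobility and each indicator:
#: muscle/lean indicators ~ +0.5, water ~ +0.41..0.50, fat ~ -0.05..-0.26.
DEFAULT_PLANTED_RHO: dict[str, float] = {
    "ICW": 0.409,
    "ECW": 0.480,
    "TBW": 0.493,
    "PM": 0.494,
    "MM": 0.485,
    "FAT": -0.045,
    "SLM": 0.495,
    "FFM": 0.493,
    "SMM": 0.496,
    "DLM": 0.492,
    "PBF": -0.256,
    "BMI": 0.261,
    "ECW_TBW": -0.122,
    "BFM_control": -0.005,
    "FFM_control": -0.296,
    "BCM": 0.497,
    "BMC": 0.447,
    "VFA": -0.132,
    "BMR": 0.493,
    "TBW_FFM": 0.174,
    "SMI": 0.561,
}

#: Indicators realized through identities rather than direct factor draws;
#: their achieved correlation follows from TBW and the water ratio, so they
#: are excluded from exact parameter-recovery checks.
DERIVED_INDICATORS = ("ICW", "ECW")

#: Lower clip bounds for indicators whose Gaussian tail would cross zero.
_CLIP_LO = {"FAT": 0.3, "PBF": 0.5, "VFA": 1.0, "FFM_control": 0.0}


def _floor_attenuation(mu: float, sd: float, lo: float) -> float:
    """Correlation attenuation caused by flooring a Gaussian at ``lo``.

    For Y = max(X, lo) with X ~ N(mu, sd^2) and alpha = (mu - lo)/sd,
    Stein's lemma gives cov(m, Y) = rho * sd * Phi(alpha) while the SD of Y
    shrinks, so corr(m, Y) = rho * Phi(alpha)/sd(W) with W = max(Z, -alpha).
    The generator divides the target correlation by this factor so the
    planted value is achieved on the observed (floored) scale.
    """
    from scipy.stats import norm

    a = (mu - lo) / sd
    phi, cdf = norm.pdf(a), norm.cdf(a)
    e_w = -a * (1.0 - cdf) + phi
    e_w2 = a * a * (1.0 - cdf) + cdf - a * phi
    sd_w = math.sqrt(max(e_w2 - e_w * e_w, 1e-12))
    return cdf / sd_w

#: Skeleton template: keypoint offsets from body center, pixels (x right,
#: y down).  The five CoM keypoints are re-centered so their mean is zero.
_TEMPLATE = np.array([
    (0, -58),                # nose
    (-6, -64), (6, -64),     # eyes
    (-12, -60), (12, -60),   # ears
    (-24, -36), (24, -36),   # shoulders
    (-34, -8), (34, -8),     # elbows
    (-40, 18), (40, 18),     # wrists
    (-16, 32), (16, 32),     # hips
    (-17, 84), (17, 84),     # knees
    (-18, 134), (18, 134),   # ankles
], dtype=float)
_com = np.array(COM_KEYPOINT_INDICES)
_TEMPLATE -= _TEMPLATE[_com].mean(axis=0)


@dataclass(frozen=True)
class SynthCohortConfig:
    """Study conditions for the generator.

    Defaults mirror the published cohort: 19 participants (3 female),
    ~300 frames of 30-fps frontal walking per participant, directional
    shift level 0.36 +/- 0.15 rad across participants, ~5% abnormal
    (outlier) frames, confidence means 0.59-0.68 with maxima 0.77-0.83.
    """

    n_participants: int = 19
    seed: int = 0
    n_frames: int = 300
    fps: float = 30.0
    image_size: tuple[int, int] = (1280, 720)
    female_fraction: float = 3 / 19

    planted_rho: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_PLANTED_RHO))
    indicator_params: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(INDICATOR_PARAMS))

    # directional-shift population: per-participant mean |theta| (radians)
    shift_mean: float = 0.36
    shift_sd: float = 0.15
    shift_bounds: tuple[float, float] = (0.03, 1.1)

    # CoM forward step length, pixels/frame
    step_mean_px: float = 4.0
    step_sd_px: float = 0.8
    step_min_px: float = 0.5

    # outlier injection: multiplicative displacement spikes
    outlier_rate: float = 0.05
    outlier_scale: tuple[float, float] = (3.0, 15.0)

    # keypoint confidence model
    conf_mean_range: tuple[float, float] = (0.61, 0.67)
    conf_sd: float = 0.06
    conf_max_range: tuple[float, float] = (0.77, 0.83)
    conf_floor: float = 0.35
    low_conf_rate: float = 0.02
    low_conf_range: tuple[float, float] = (0.05, 0.25)

    # keypoint placement jitter, pixels
    jitter_px: float = 0.3

    # walk-speed model, m/s (elderly usual pace)
    speed_base: float = 0.85
    speed_slope: float = 0.12
    speed_noise: float = 0.05
    trial_time_noise: float = 0.15

    # reduced-path measurement noise on mean_directional_shift, radians
    shift_measurement_sd: float = 0.015

    def __post_init__(self) -> None:
        if self.n_participants < 1:
            raise ParameterError("n_participants must be >= 1")
        if not 0 <= self.outlier_rate <= 1:
            raise ParameterError("outlier_rate must be in [0, 1]")
        if not 0 <= self.low_conf_rate <= 1:
            raise ParameterError("low_conf_rate must be in [0, 1]")
        for name, rho in self.planted_rho.items():
            if not abs(rho) < 1:
                raise ParameterError(
                    f"planted correlation for {name!r} is {rho}; the "
                    f"implied covariance with the latent factor is not "
                    f"positive definite unless |rho| < 1")
        unknown = set(self.planted_rho) - set(self.indicator_params)
        if unknown:
            raise ParameterError(f"planted_rho for unknown indicators "
                                 f"{sorted(unknown)}")


@dataclass
class SynthCohort:
    """Generated data bundle plus the ground truth that produced it."""

    config: SynthCohortConfig
    poses: list[PoseSequence]
    body: pd.DataFrame
    trials: pd.DataFrame
    truth: pd.DataFrame


def _substream(seed: int, name: str) -> np.random.Generator:
    """Named substream: independent generator derived from (seed, name)."""
    return np.random.default_rng(
        np.random.SeedSequence([int(seed), zlib.crc32(name.encode())]))


def _participant_ids(n: int) -> list[str]:
    width = max(3, len(str(n)))
    return [f"P{i + 1:0{width}d}" for i in range(n)]


def _draw_indicators(cfg: SynthCohortConfig, m: np.ndarray,
                     rng: np.random.Generator) -> pd.DataFrame:
    """Single-factor indicator table; identities enforced exactly."""
    n = len(m)
    cols: dict[str, np.ndarray] = {}
    direct = [k for k in cfg.indicator_params if k not in DERIVED_INDICATORS]
    for name in direct:
        mu, sd = cfg.indicator_params[name]
        rho = cfg.planted_rho.get(name, 0.0)
        if name in _CLIP_LO and rho != 0.0:
            rho = rho / _floor_attenuation(mu, sd, _CLIP_LO[name])
        eps = rng.standard_normal(n)
        vals = mu + sd * (rho * m + np.sqrt(1.0 - rho * rho) * eps)
        if name in _CLIP_LO:
            vals = np.maximum(vals, _CLIP_LO[name])
        cols[name] = vals
    # water identities: ECW = ratio * TBW, ICW = TBW - ECW
    cols["ECW"] = cols["ECW_TBW"] * cols["TBW"]
    cols["ICW"] = cols["TBW"] - cols["ECW"]
    # demographics; weight derived so the BMI identity holds exactly
    height = np.round(rng.normal(161.82, 8.19, n), 1)
    age = np.clip(rng.normal(77.88, 7.76, n), 60, 89)
    weight = cols["BMI"] * (height / 100.0) ** 2
    n_female = int(round(cfg.female_fraction * n))
    sex = np.array(["male"] * n, dtype=object)
    sex[rng.permutation(n)[:n_female]] = "female"
    df = pd.DataFrame({
        "participant_id": _participant_ids(n),
        "sex": sex,
        "age": np.round(age, 1),
        "height": np.round(height, 1),
        "weight": weight,
    })
    for name in INDICATOR_PARAMS:
        df[name] = cols[name]
    return df


def _draw_trials(cfg: SynthCohortConfig, m: np.ndarray,
                 rng: np.random.Generator) -> tuple[pd.DataFrame, np.ndarray]:
    n = len(m)
    speed = np.clip(
        cfg.speed_base + cfg.speed_slope * m
        + cfg.speed_noise * rng.standard_normal(n),
        0.4, 1.8)
    base = 4.0 / speed
    t1 = np.maximum(base + cfg.trial_time_noise * rng.standard_normal(n), 1.0)
    t2 = np.maximum(base + cfg.trial_time_noise * rng.standard_normal(n), 1.0)
    trials = pd.DataFrame({
        "participant_id": _participant_ids(n),
        "time_1": np.round(t1, 2),
        "time_2": np.round(t2, 2),
    })
    return trials, speed


def _render_pose(cfg: SynthCohortConfig, pid: str, mu_shift: float,
                 rng: np.random.Generator) -> PoseSequence:
    """One participant's keypoint sequence from a planted shift level."""
    nf = cfg.n_frames
    ns = nf - 1
    t = np.arange(ns)
    # per-step directional shift: magnitude uniform on [0.6, 1.4] * mu
    # (so E|theta| = mu exactly in expectation), sign from a sway sinusoid
    mag = mu_shift * (0.6 + 0.8 * rng.random(ns))
    sway = np.sin(2 * np.pi * 0.9 * t / cfg.fps + rng.uniform(0, 2 * np.pi))
    sign = np.sign(sway + 0.5 * rng.standard_normal(ns))
    sign[sign == 0] = 1.0
    theta = sign * mag
    # forward step length with multiplicative outlier spikes
    step = np.maximum(
        np.abs(rng.normal(cfg.step_mean_px, cfg.step_sd_px, ns)),
        cfg.step_min_px)
    spikes = rng.random(ns) < cfg.outlier_rate
    step = np.where(
        spikes, step * rng.uniform(*cfg.outlier_scale, ns), step)
    dx = step * np.cos(theta)
    dy = step * np.sin(theta)
    x = 150.0 + np.concatenate([[0.0], np.cumsum(dx)])
    y = 300.0 + np.concatenate([[0.0], np.cumsum(dy)])
    com = np.stack([x, y], axis=1)
    xy = com[:, None, :] + _TEMPLATE[None, :, :] \
        + rng.normal(0.0, cfg.jitter_px, (nf, N_KEYPOINTS, 2))
    # confidences: participant-level base, hard cap, occasional dropouts
    base = rng.uniform(*cfg.conf_mean_range)
    cap = rng.uniform(*cfg.conf_max_range)
    scores = np.clip(rng.normal(base, cfg.conf_sd, (nf, N_KEYPOINTS)),
                     cfg.conf_floor, cap)
    low = rng.random((nf, N_KEYPOINTS)) < cfg.low_conf_rate
    scores = np.where(low, rng.uniform(*cfg.low_conf_range,
                                       (nf, N_KEYPOINTS)), scores)
    # a low-confidence detection carries corrupted coordinates
    xy = np.where(low[:, :, None],
                  xy + rng.normal(0.0, 40.0, (nf, N_KEYPOINTS, 2)), xy)
    return PoseSequence(
        participant_id=pid,
        frame_index=np.arange(nf, dtype=np.int64),
        xy=xy,
        scores=scores,
        fps=cfg.fps,
        image_size=cfg.image_size,
    )


def generate_cohort(cfg: SynthCohortConfig) -> SynthCohort:
    """Generate pose sequences, body-composition records, walk trials and
    the ground-truth latent table for one cohort.  Deterministic in
    ``cfg.seed``."""
    n = cfg.n_participants
    m = _substream(cfg.seed, "latent").standard_normal(n)
    body = _draw_indicators(cfg, m, _substream(cfg.seed, "indicators"))
    trials, speed = _draw_trials(cfg, m, _substream(cfg.seed, "trials"))
    mu = np.clip(cfg.shift_mean + cfg.shift_sd * m, *cfg.shift_bounds)
    ids = _participant_ids(n)
    poses = [
        _render_pose(cfg, ids[i], mu[i], _substream(cfg.seed, f"pose:{i}"))
        for i in range(n)
    ]
    truth = pd.DataFrame({
        "participant_id": ids,
        "latent_mobility": m,
        "target_mean_directional_shift": mu,
        "walk_speed_m_s": speed,
        "sex": body["sex"],
    })
    return SynthCohort(config=cfg, poses=poses, body=body, trials=trials,
                       truth=truth)


def generate_null_cohort(cfg: SynthCohortConfig) -> SynthCohort:
    """Same generator with every planted correlation forced to zero, so
    indicators are independent of mobility (type-I calibration)."""
    null_cfg = dataclasses.replace(
        cfg, planted_rho={k: 0.0 for k in cfg.planted_rho})
    return generate_cohort(null_cfg)


def generate_feature_table(cfg: SynthCohortConfig) -> pd.DataFrame:
    """Reduced path: the per-participant feature/indicator/score table
    without rendering keypoint sequences.

    ``mean_directional_shift`` is the planted per-participant level plus
    Gaussian measurement noise matching the dispersion the full pipeline
    exhibits at the default frame count.  Used for replicate-heavy
    calibration studies where only the joint structure of the aggregated
    table matters.
    """
    n = cfg.n_participants
    m = _substream(cfg.seed, "latent").standard_normal(n)
    body = _draw_indicators(cfg, m, _substream(cfg.seed, "indicators"))
    trials, _ = _draw_trials(cfg, m, _substream(cfg.seed, "trials"))
    mu = np.clip(cfg.shift_mean + cfg.shift_sd * m, *cfg.shift_bounds)
    meas = _substream(cfg.seed, "shift-measurement")
    out = body.copy()
    out["mean_directional_shift"] = mu + cfg.shift_measurement_sd * \
        meas.standard_normal(n)
    out["time_1"] = trials["time_1"]
    out["time_2"] = trials["time_2"]
    return out


def write_cohort(cohort: SynthCohort, outdir, pose_format: str = "json",
                 ) -> dict[str, object]:
    """Write the cohort in the same formats the readers consume.

    Returns a manifest of written paths.  The ground truth goes to a JSON
    sidecar.
    """
    from gaitcomp.body_comp import write_body_comp

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    posedir = outdir / "poses"
    posedir.mkdir(exist_ok=True)
    pose_paths = []
    for seq in cohort.poses:
        p = posedir / f"{seq.participant_id}.{pose_format}"
        write_pose_sequence(seq, p, pose_format)
        pose_paths.append(str(p))
    body_path = outdir / "body_composition.csv"
    write_body_comp(cohort.body, body_path)
    trials_path = outdir / "walk_trials.csv"
    cohort.trials.to_csv(trials_path, index=False)
    truth_path = outdir / "ground_truth.json"
    truth_path.write_text(json.dumps({
        "config": {
            k: (list(v) if isinstance(v, tuple) else v)
            for k, v in dataclasses.asdict(cohort.config).items()
        },
        "derived_indicators": list(DERIVED_INDICATORS),
        "participants": cohort.truth.to_dict(orient="records"),
    }, indent=1))
    return {
        "poses": pose_paths,
        "body": str(body_path),
        "trials": str(trials_path),
        "truth": str(truth_path),
    }
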