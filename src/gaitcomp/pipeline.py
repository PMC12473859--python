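"""End-to-end orchestration: ingest -> repair -> features -> filter ->
scoring -> statistics -> report bundle.

A run is fully described by a :class:`RunConfig` (inputs or a synthetic
cohort, thresholds, modes, seed).  The same config and seed always produce a
byte-identical machine-readable bundle; the manifest records versions, the
config hash, per-stage counts (frames read / repaired / dropped / filtered)
and a content hash of every artifact.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from gaitcomp.errors import GaitCompError, ParameterError
from gaitcomp.pose_io import (
    DEFAULT_MAX_GAP,
    DEFAULT_MIN_SCORE,
    PoseSequence,
    interpolate_missing,
    read_pose_sequence,
    summarize_confidence,
)
from gaitcomp.gait_features import (
    aggregate_features,
    compute_com,
    compute_dynamics,
    path_density,
)
from gaitcomp.outlier_filter import (
    DEFAULT_PERCENTILE,
    compute_percentile_thresholds,
    filter_cohort,
)
from gaitcomp.body_comp import describe_indicators, read_body_comp
from gaitcomp.sppb_scoring import (
    DEFAULT_CUTPOINTS,
    read_walk_trials,
    score_walk_table,
)
from gaitcomp.stats_analysis import (
    correlation_matrix,
    format_correlation_grid,
    regression_table,
    shapiro_wilk_screen,
    stratified_analysis,
)
from gaitcomp.synth_cohort import SynthCohortConfig, generate_cohort


@dataclass(frozen=True)
class RunConfig:
    """One pipeline run: inputs, thresholds, modes, outputs, seed.

    Defaults follow the method's standard choices: keypoint validity
    threshold 0.3, gaps up to 5 frames interpolated, pooled 95th-percentile
    outlier cleaning, angular shift mode, Pearson plus Spearman reporting,
    no multiplicity correction.
    """

    # inputs: either a directory of pose files + tables, or synthetic
    pose_dir: str | None = None
    pose_format: str | None = None
    body_csv: str | None = None
    trials_csv: str | None = None
    synth: SynthCohortConfig | None = None

    min_score: float = DEFAULT_MIN_SCORE
    max_gap: int = DEFAULT_MAX_GAP
    percentile: float = DEFAULT_PERCENTILE
    scope: str = "pooled"
    shift_mode: str = "angular"
    angle: str = "ratio"
    cutpoints: tuple[tuple[float, int], ...] = DEFAULT_CUTPOINTS
    methods: tuple[str, ...] = ("pearson", "spearman")
    stratify: bool = True
    correct: bool = False
    density_bins: int = 50
    outdir: str = "gaitcomp_run"
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        doc = yaml.safe_load(Path(path).read_text()) or {}
        if "synth" in doc and doc["synth"] is not None:
            synth = doc["synth"]
            for key in ("shift_bounds", "outlier_scale", "conf_mean_range",
                        "conf_max_range", "low_conf_range", "image_size"):
                if key in synth:
                    synth[key] = tuple(synth[key])
            if "planted_rho" not in synth and "seed" not in synth:
                synth.setdefault("seed", doc.get("seed", 0))
            doc["synth"] = SynthCohortConfig(**synth)
        if "cutpoints" in doc:
            doc["cutpoints"] = tuple(
                (float(b), int(s)) for b, s in doc["cutpoints"])
        if "methods" in doc:
            doc["methods"] = tuple(doc["methods"])
        return cls(**doc)

    def config_hash(self) -> str:
        blob = json.dumps(dataclasses.asdict(self), sort_keys=True,
                          default=str).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


@dataclass
class ReportBundle:
    """In-memory results of a run plus the paths of written artifacts."""

    features: pd.DataFrame
    confidence: pd.DataFrame
    walk_scores: pd.DataFrame
    body: pd.DataFrame
    thresholds: dict[float, float]
    threshold_reports: pd.DataFrame
    normality: pd.DataFrame
    correlations: dict[str, pd.DataFrame]
    regression: pd.DataFrame
    stratified: dict[str, dict]
    density: tuple[np.ndarray, np.ndarray, np.ndarray]
    manifest: dict
    paths: dict[str, str] = field(default_factory=dict)


def extract_features(poses: list[PoseSequence],
                     min_score: float = DEFAULT_MIN_SCORE,
                     max_gap: int = DEFAULT_MAX_GAP,
                     percentile: float = DEFAULT_PERCENTILE,
                     scope: str = "pooled",
                     shift_mode: str = "angular",
                     angle: str = "ratio",
                     ) -> dict:
    """Repair, differentiate, filter and aggregate a set of pose sequences.

    Returns a dict with the per-participant feature table (configured mode
    and the alternate mode), confidence summaries, sensitivity thresholds
    at the 90/95/99th percentiles, per-participant filter reports, repaired
    CoM trajectories and stage counts.
    """
    repaired, logs, coms, dynamics, confs = [], [], [], [], []
    for seq in poses:
        fixed, log = interpolate_missing(seq, min_score, max_gap)
        repaired.append(fixed)
        logs.append(log)
        confs.append(summarize_confidence(seq))
        com = compute_com(fixed)
        coms.append(com)
        dynamics.append(compute_dynamics(com, angle=angle))
    pooled = np.concatenate([d.center_dis for d in dynamics])
    thresholds = compute_percentile_thresholds(pooled)
    if percentile not in thresholds:
        thresholds.update(compute_percentile_thresholds(pooled, [percentile]))
    filtered, reports = filter_cohort(dynamics, percentile, scope)
    alt_mode = "horizontal" if shift_mode == "angular" else "angular"
    rows, alt_rows = [], []
    for dyn, rep in zip(filtered, reports):
        for mode, acc in ((shift_mode, rows), (alt_mode, alt_rows)):
            fs = aggregate_features(dyn, mode=mode,
                                    filter_threshold=rep.threshold)
            acc.append(dataclasses.asdict(fs))
    counts = {
        "participants": len(poses),
        "frames_read": int(sum(len(s) for s in poses)),
        "frames_repaired": int(sum(len(l.repaired_frames) for l in logs)),
        "frames_dropped": int(sum(len(l.dropped_frames) for l in logs)),
        "dynamics_total": int(sum(r.n_total for r in reports)),
        "dynamics_removed": int(sum(r.n_removed for r in reports)),
    }
    return {
        "features": pd.DataFrame(rows),
        "features_alt": pd.DataFrame(alt_rows),
        "confidence": pd.DataFrame(
            [dataclasses.asdict(c) for c in confs]),
        "thresholds": thresholds,
        "reports": pd.DataFrame([{
            "participant_id": d.participant_id,
            **dataclasses.asdict(r)} for d, r in zip(filtered, reports)]),
        "coms": coms,
        "dynamics": filtered,
        "repair_logs": logs,
        "counts": counts,
    }


def _load_inputs(cfg: RunConfig):
    if cfg.synth is not None:
        cohort = generate_cohort(cfg.synth)
        return cohort.poses, cohort.body, cohort.trials
    if not (cfg.pose_dir and cfg.body_csv and cfg.trials_csv):
        raise ParameterError(
            "config must provide either synth or pose_dir+body_csv+"
            "trials_csv")
    pose_dir = Path(cfg.pose_dir)
    paths = sorted(p for p in pose_dir.iterdir()
                   if p.suffix.lower() in (".json", ".csv"))
    if not paths:
        raise GaitCompError(f"no pose files found under {pose_dir}")
    poses = [read_pose_sequence(p, cfg.pose_format) for p in paths]
    body, _ = read_body_comp(cfg.body_csv)
    trials = read_walk_trials(cfg.trials_csv)
    return poses, body, trials


def _write_json(path: Path, obj) -> None:
    path.write_text(json.dumps(obj, sort_keys=True, indent=1, default=str))


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(cfg: RunConfig) -> ReportBundle:
    """Execute a full run and write the report bundle under ``cfg.outdir``."""
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    poses, body, trials = _load_inputs(cfg)

    ext = extract_features(poses, cfg.min_score, cfg.max_gap,
                           cfg.percentile, cfg.scope, cfg.shift_mode,
                           cfg.angle)
    features = ext["features"]
    scores = score_walk_table(trials, cfg.cutpoints)
    indicator_summary = describe_indicators(body)
    merged_all = body.merge(
        features[["participant_id", "mean_directional_shift"]],
        on="participant_id", how="inner")
    normality = shapiro_wilk_screen(
        merged_all.drop(columns=["participant_id", "sex"]))
    correlations: dict[str, pd.DataFrame] = {}
    for method in cfg.methods:
        correlations[method] = correlation_matrix(
            features, body, scores, method=method, normality=normality,
            correct=cfg.correct)
    regression = regression_table(features, body)
    stratified = (stratified_analysis(features, body, scores)
                  if cfg.stratify else {})
    density = path_density(ext["coms"], cfg.density_bins)

    paths: dict[str, str] = {}

    def save_df(name: str, df: pd.DataFrame, index=False) -> None:
        p = outdir / f"{name}.csv"
        df.to_csv(p, index=index)
        paths[name] = str(p)

    save_df("features", features)
    save_df("features_alt_mode", ext["features_alt"])
    save_df("confidence_summary", ext["confidence"])
    save_df("threshold_reports", ext["reports"])
    save_df("walk_scores", scores)
    save_df("indicator_summary", indicator_summary)
    save_df("normality", normality)
    for method, cells in correlations.items():
        save_df(f"correlation_cells_{method}", cells)
        save_df(f"correlation_table_{method}",
                format_correlation_grid(cells), index=True)
    save_df("regression", regression)
    for label, entry in stratified.items():
        save_df(f"correlation_cells_{label}", entry["cells"])
    _write_json(outdir / "stratified_summary.json", {
        label: {"summary": entry["summary"], "n": entry["n"],
                "low_n": entry["low_n"]}
        for label, entry in stratified.items()})
    paths["stratified_summary"] = str(outdir / "stratified_summary.json")
    counts, xe, ye = density
    dens = pd.DataFrame(counts.astype(int))
    dens.to_csv(outdir / "path_density.csv", index=False)
    paths["path_density"] = str(outdir / "path_density.csv")
    _write_json(outdir / "path_density_edges.json",
                {"x_edges": xe.tolist(), "y_edges": ye.tolist()})
    paths["path_density_edges"] = str(outdir / "path_density_edges.json")
    _write_json(outdir / "correlation.json", {
        method: cells.to_dict(orient="records")
        for method, cells in correlations.items()})
    paths["correlation_json"] = str(outdir / "correlation.json")
    _write_json(outdir / "regression.json",
                regression.to_dict(orient="records"))
    paths["regression_json"] = str(outdir / "regression.json")
    repair_lines = []
    for log in ext["repair_logs"]:
        repair_lines.extend(log.lines())
    (outdir / "repair.log").write_text("\n".join(repair_lines) + "\n")
    paths["repair_log"] = str(outdir / "repair.log")

    from importlib.metadata import version as _dist_version
    try:
        pkg_version = _dist_version("gaitcomp")
    except Exception:
        pkg_version = "unknown"
    manifest = {
        "package_version": pkg_version,
        "seed": cfg.seed,
        "config": dataclasses.asdict(cfg),
        "config_hash": cfg.config_hash(),
        "percentile_thresholds": {str(k): v
                                  for k, v in ext["thresholds"].items()},
        "stage_counts": ext["counts"],
        "artifact_sha256": {},
    }
    for name, p in sorted(paths.items()):
        manifest["artifact_sha256"][name] = _sha256(Path(p))
    _write_json(outdir / "manifest.json", manifest)
    paths["manifest"] = str(outdir / "manifest.json")

    return ReportBundle(
        features=features,
        confidence=ext["confidence"],
        walk_scores=scores,
        body=body,
        thresholds=ext["thresholds"],
        threshold_reports=ext["reports"],
        normality=normality,
        correlations=correlations,
        regression=regression,
        stratified=stratified,
        density=density,
        manifest=manifest,
        paths=paths,
    )
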