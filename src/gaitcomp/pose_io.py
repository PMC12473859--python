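"""Reading, validating and repairing pose-keypoint time series.

A sequence is the per-frame output of a PoseNet-style 2-D pose estimator:
17 COCO-numbered keypoints per frame, each an (x, y) pixel coordinate with a
confidence score in [0, 1].  Coordinates use image-pixel convention: origin
top-left, x rightward, y downward; frame indices are 0-based.

Two on-disk formats are supported and round-trip losslessly:

* JSON — object with keys ``participant_id``, ``fps``, ``image_size``
  ``[width, height]`` and ``frames``, a list of
  ``{"frame_index": int, "keypoints": [[x, y, score] * 17]}``; missing
  values are ``null``.
* long CSV — one row per (frame, keypoint) with columns
  ``frame,keypoint,x,y,score``; missing values are empty cells.

The center-of-mass (CoM) computation downstream uses five keypoints:
nose (0), left shoulder (5), right shoulder (6), left hip (11),
right hip (12).  Only these are repaired by :func:`interpolate_missing`;
confidence summaries pool their scores.
"""

from __future__ import annotations

import csv
import json
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import NamedTuple

import numpy as np

from gaitcomp.errors import (
    DegenerateDataError,
    ParseError,
    SchemaError,
    UnrecoverableSequenceError,
    ValidationError,
)

#: COCO-style keypoint numbering used by PoseNet-family estimators.
KEYPOINT_NAMES = (
    "nose", "left_eye", "right_eye", "left_ear", "right_ear",
    "left_shoulder", "right_shoulder", "left_elbow", "right_elbow",
    "left_wrist", "right_wrist", "left_hip", "right_hip",
    "left_knee", "right_knee", "left_ankle", "right_ankle",
)

N_KEYPOINTS = 17

#: Keypoints whose unweighted mean defines the center of mass, in fixed order.
COM_KEYPOINT_INDICES = (0, 5, 6, 11, 12)

#: Default confidence below which a keypoint is treated as missing.
DEFAULT_MIN_SCORE = 0.3

#: Default longest gap (frames) bridged by linear interpolation.
DEFAULT_MAX_GAP = 5


class Keypoint(NamedTuple):
    """One detected body point: COCO index, pixel coordinates, confidence."""

    index: int
    x: float
    y: float
    score: float

    @property
    def name(self) -> str:
        return KEYPOINT_NAMES[self.index]


class PoseFrame(NamedTuple):
    """A single frame: 17 keypoints, one per COCO index."""

    frame_index: int
    keypoints: tuple[Keypoint, ...]


@dataclass
class PoseSequence:
    """Ordered per-frame keypoint sets for one participant.

    Internally array-backed for speed: ``xy`` has shape (n_frames, 17, 2),
    ``scores`` shape (n_frames, 17); NaN marks a missing value.
    """

    participant_id: str
    frame_index: np.ndarray
    xy: np.ndarray
    scores: np.ndarray
    fps: float = 30.0
    image_size: tuple[int, int] = (1280, 720)

    def __post_init__(self) -> None:
        self.frame_index = np.asarray(self.frame_index, dtype=np.int64)
        self.xy = np.asarray(self.xy, dtype=np.float64)
        self.scores = np.asarray(self.scores, dtype=np.float64)
        n = len(self.frame_index)
        if self.xy.shape != (n, N_KEYPOINTS, 2):
            raise ValidationError(
                f"xy shape {self.xy.shape} != {(n, N_KEYPOINTS, 2)}")
        if self.scores.shape != (n, N_KEYPOINTS):
            raise ValidationError(
                f"scores shape {self.scores.shape} != {(n, N_KEYPOINTS)}")
        if n and np.any(np.diff(self.frame_index) <= 0):
            raise ValidationError(
                f"frame_index not strictly increasing for "
                f"participant {self.participant_id!r}")
        if self.fps <= 0:
            raise ValidationError("fps must be > 0")
        with np.errstate(invalid="ignore"):
            bad = (self.scores < 0) | (self.scores > 1)
        if np.any(bad):
            i, k = np.argwhere(bad)[0]
            raise ValidationError(
                f"score outside [0,1] at frame {self.frame_index[i]} "
                f"keypoint {k}")

    def __len__(self) -> int:
        return len(self.frame_index)

    @property
    def n_frames(self) -> int:
        return len(self.frame_index)

    def frame(self, i: int) -> PoseFrame:
        """Positional access returning a validated :class:`PoseFrame` view."""
        kps = tuple(
            Keypoint(k, self.xy[i, k, 0], self.xy[i, k, 1], self.scores[i, k])
            for k in range(N_KEYPOINTS)
        )
        return PoseFrame(int(self.frame_index[i]), kps)

    def frames(self):
        return [self.frame(i) for i in range(len(self))]

    def copy(self) -> "PoseSequence":
        return replace(
            self,
            frame_index=self.frame_index.copy(),
            xy=self.xy.copy(),
            scores=self.scores.copy(),
        )


@dataclass(frozen=True)
class ConfidenceSummary:
    """Five-number summary of the pooled CoM-keypoint confidences."""

    participant_id: str
    mean: float
    median: float
    max: float
    q1: float
    q3: float

    def __post_init__(self) -> None:
        if not (0 <= self.q1 <= self.median <= self.q3 <= self.max <= 1):
            raise ValidationError(
                f"confidence summary ordering violated for "
                f"{self.participant_id!r}")


@dataclass
class RepairLog:
    """Record of every frame touched by :func:`interpolate_missing`."""

    participant_id: str
    #: (frame_index, keypoint_index) pairs whose coordinates were interpolated
    repaired: list[tuple[int, int]] = field(default_factory=list)
    #: (frame_index, keypoint_index) pairs left missing (gap too long / edge)
    dropped: list[tuple[int, int]] = field(default_factory=list)

    @property
    def dropped_frames(self) -> list[int]:
        return sorted({f for f, _ in self.dropped})

    @property
    def repaired_frames(self) -> list[int]:
        return sorted({f for f, _ in self.repaired})

    def lines(self) -> list[str]:
        out = [f"# repair log participant={self.participant_id}"]
        out += [f"repaired\t{f}\t{k}" for f, k in self.repaired]
        out += [f"dropped\t{f}\t{k}" for f, k in self.dropped]
        return out

    def write(self, path) -> None:
        Path(path).write_text("\n".join(self.lines()) + "\n")


def _infer_format(path: Path, fmt: str | None) -> str:
    if fmt is not None:
        if fmt not in ("json", "csv"):
            raise SchemaError(f"unknown pose format {fmt!r}")
        return fmt
    suffix = path.suffix.lower().lstrip(".")
    if suffix in ("json", "csv"):
        return suffix
    raise SchemaError(f"cannot infer pose format from {path.name!r}")


def _num(value, *, frame, fld):
    """Parse an optional numeric cell; '' / None -> NaN."""
    if value is None or value == "":
        return math.nan
    try:
        out = float(value)
    except (TypeError, ValueError):
        raise ParseError(
            f"non-numeric value {value!r} for field {fld!r} at frame {frame}"
        ) from None
    if math.isinf(out):
        raise ParseError(f"non-finite {fld!r} at frame {frame}")
    return out


def read_pose_sequence(path, fmt: str | None = None,
                       participant_id: str | None = None) -> PoseSequence:
    """Read a keypoint sequence from JSON or long CSV.

    Frames are sorted by ``frame_index``; duplicate frame indices, keypoint
    indices outside 0–16, or frames without exactly 17 keypoints raise.
    ``participant_id`` overrides any id stored in the file (CSV stores none).
    """
    path = Path(path)
    fmt = _infer_format(path, fmt)
    if fmt == "json":
        return _read_json(path, participant_id)
    return _read_csv(path, participant_id)


def _read_json(path: Path, participant_id: str | None) -> PoseSequence:
    try:
        doc = json.loads(path.read_text())
    except json.JSONDecodeError as exc:
        raise ParseError(f"{path.name}: invalid JSON: {exc}") from None
    if not isinstance(doc, dict) or "frames" not in doc:
        raise SchemaError(f"{path.name}: expected object with 'frames'")
    pid = participant_id or str(doc.get("participant_id", path.stem))
    records = []
    for rec in doc["frames"]:
        try:
            fidx = int(rec["frame_index"])
            kps = rec["keypoints"]
        except (KeyError, TypeError, ValueError):
            raise ParseError(
                f"{path.name}: malformed frame record {rec!r:.80}") from None
        if len(kps) != N_KEYPOINTS:
            raise SchemaError(
                f"{path.name}: frame {fidx} has {len(kps)} keypoints, "
                f"expected {N_KEYPOINTS}")
        row = np.empty((N_KEYPOINTS, 3))
        for k, triple in enumerate(kps):
            if len(triple) != 3:
                raise ParseError(
                    f"{path.name}: frame {fidx} keypoint {k}: "
                    f"expected [x, y, score]")
            row[k, 0] = _num(triple[0], frame=fidx, fld="x")
            row[k, 1] = _num(triple[1], frame=fidx, fld="y")
            row[k, 2] = _num(triple[2], frame=fidx, fld="score")
        records.append((fidx, row))
    image_size = tuple(doc.get("image_size", (1280, 720)))
    return _assemble(pid, records, float(doc.get("fps", 30.0)), image_size,
                     path.name)


def _read_csv(path: Path, participant_id: str | None) -> PoseSequence:
    rows: dict[int, np.ndarray] = {}
    seen: dict[int, set[int]] = {}
    with path.open(newline="") as fh:
        reader = csv.DictReader(fh)
        required = {"frame", "keypoint", "x", "y", "score"}
        if reader.fieldnames is None or not required <= set(reader.fieldnames):
            raise SchemaError(
                f"{path.name}: CSV header must contain {sorted(required)}")
        for lineno, rec in enumerate(reader, start=2):
            try:
                fidx = int(rec["frame"])
                k = int(rec["keypoint"])
            except ValueError:
                raise ParseError(
                    f"{path.name}:{lineno}: non-integer frame/keypoint"
                ) from None
            if not 0 <= k < N_KEYPOINTS:
                raise ParseError(
                    f"{path.name}:{lineno}: keypoint index {k} outside "
                    f"0–{N_KEYPOINTS - 1}")
            row = rows.setdefault(fidx, np.full((N_KEYPOINTS, 3), np.nan))
            ks = seen.setdefault(fidx, set())
            if k in ks:
                raise ValidationError(
                    f"{path.name}:{lineno}: duplicate keypoint {k} in "
                    f"frame {fidx}")
            ks.add(k)
            row[k, 0] = _num(rec["x"], frame=fidx, fld="x")
            row[k, 1] = _num(rec["y"], frame=fidx, fld="y")
            row[k, 2] = _num(rec["score"], frame=fidx, fld="score")
    for fidx, ks in seen.items():
        if len(ks) != N_KEYPOINTS:
            raise SchemaError(
                f"{path.name}: frame {fidx} has {len(ks)} keypoints, "
                f"expected {N_KEYPOINTS}")
    pid = participant_id or path.stem
    return _assemble(pid, sorted(rows.items()), 30.0, (1280, 720), path.name)


def _assemble(pid, records, fps, image_size, fname) -> PoseSequence:
    indices = [f for f, _ in records]
    if len(set(indices)) != len(indices):
        dup = sorted({f for f in indices if indices.count(f) > 1})
        raise ValidationError(f"{fname}: duplicate frame_index {dup}")
    records = sorted(records)
    frame_index = np.array([f for f, _ in records], dtype=np.int64)
    data = (np.stack([r for _, r in records])
            if records else np.empty((0, N_KEYPOINTS, 3)))
    return PoseSequence(
        participant_id=pid,
        frame_index=frame_index,
        xy=data[:, :, :2],
        scores=data[:, :, 2],
        fps=fps,
        image_size=tuple(image_size),
    )


def write_pose_sequence(seq: PoseSequence, path, fmt: str | None = None) -> None:
    """Write ``seq`` to JSON or long CSV (inverse of :func:`read_pose_sequence`)."""
    path = Path(path)
    fmt = _infer_format(path, fmt)

    def opt(v: float):
        return None if math.isnan(v) else v

    if fmt == "json":
        doc = {
            "participant_id": seq.participant_id,
            "fps": seq.fps,
            "image_size": list(seq.image_size),
            "frames": [
                {
                    "frame_index": int(seq.frame_index[i]),
                    "keypoints": [
                        [opt(seq.xy[i, k, 0]), opt(seq.xy[i, k, 1]),
                         opt(seq.scores[i, k])]
                        for k in range(N_KEYPOINTS)
                    ],
                }
                for i in range(len(seq))
            ],
        }
        path.write_text(json.dumps(doc))
    else:
        with path.open("w", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(["frame", "keypoint", "x", "y", "score"])
            for i in range(len(seq)):
                for k in range(N_KEYPOINTS):
                    writer.writerow([
                        int(seq.frame_index[i]), k,
                        _fmt_cell(seq.xy[i, k, 0]),
                        _fmt_cell(seq.xy[i, k, 1]),
                        _fmt_cell(seq.scores[i, k]),
                    ])


def _fmt_cell(v: float) -> str:
    return "" if math.isnan(v) else repr(float(v))


def select_com_keypoints(frame: PoseFrame) -> list[Keypoint]:
    """Return the five CoM keypoints (nose, shoulders, hips) in fixed order."""
    return [frame.keypoints[k] for k in COM_KEYPOINT_INDICES]


def interpolate_missing(seq: PoseSequence,
                        min_score: float = DEFAULT_MIN_SCORE,
                        max_gap: int = DEFAULT_MAX_GAP,
                        ) -> tuple[PoseSequence, RepairLog]:
    """Linearly interpolate low-confidence CoM keypoints; drop long gaps.

    A CoM keypoint is invalid when its score is below ``min_score``, its
    score is missing, or a coordinate is non-finite.  Invalid runs of at
    most ``max_gap`` frames flanked by valid frames are filled per keypoint
    and per coordinate by linear interpolation in frame_index; longer runs
    and runs touching either end of the sequence are left missing (NaN
    coordinates) and flagged dropped.  Frames outside logged gaps are never
    altered.
    """
    if max_gap < 0:
        raise ValidationError("max_gap must be >= 0")
    out = seq.copy()
    log = RepairLog(seq.participant_id)
    com = np.array(COM_KEYPOINT_INDICES)
    with np.errstate(invalid="ignore"):
        valid = (seq.scores[:, com] >= min_score) & \
            np.isfinite(seq.xy[:, com]).all(axis=2)
    # precondition: at least two frames with all five CoM keypoints valid
    if int(valid.all(axis=1).sum()) < 2:
        raise UnrecoverableSequenceError(
            f"participant {seq.participant_id!r}: fewer than 2 frames with "
            f"all CoM keypoints at score >= {min_score}")
    t = seq.frame_index.astype(float)
    for j, k in enumerate(com):
        mask = valid[:, j]
        bad = np.flatnonzero(~mask)
        if bad.size == 0:
            continue
        good = np.flatnonzero(mask)
        # contiguous runs of invalid positions
        runs = np.split(bad, np.flatnonzero(np.diff(bad) > 1) + 1)
        for run in runs:
            lo, hi = run[0], run[-1]
            has_left = lo > 0 and mask[lo - 1]
            has_right = hi < len(seq) - 1 and mask[hi + 1]
            if len(run) <= max_gap and has_left and has_right:
                for c in range(2):
                    out.xy[run, k, c] = np.interp(
                        t[run], t[good], seq.xy[good, k, c])
                log.repaired += [(int(seq.frame_index[i]), int(k))
                                 for i in run]
            else:
                out.xy[run, k, :] = np.nan
                log.dropped += [(int(seq.frame_index[i]), int(k))
                                for i in run]
    return out, log


def summarize_confidence(seq: PoseSequence) -> ConfidenceSummary:
    """Five-number summary over the pooled scores of the five CoM keypoints.

    Quantiles use linear interpolation between closest ranks.  Missing
    scores are ignored; an all-missing sequence raises.
    """
    if len(seq) == 0:
        raise DegenerateDataError("empty sequence")
    pooled = seq.scores[:, np.array(COM_KEYPOINT_INDICES)].ravel()
    pooled = pooled[np.isfinite(pooled)]
    if pooled.size == 0:
        raise DegenerateDataError(
            f"participant {seq.participant_id!r}: all CoM scores missing")
    q1, med, q3 = np.percentile(pooled, [25, 50, 75])
    return ConfidenceSummary(
        participant_id=seq.participant_id,
        mean=float(pooled.mean()),
        median=float(med),
        max=float(pooled.max()),
        q1=float(q1),
        q3=float(q3),
    )
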