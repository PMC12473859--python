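"""SPPB 4-m walking test scoring.

Participants walk a straight 4-m path at a normal pace; the time is measured
twice and each trial, plus the mean time, is scored 0–4 (greater = better).
The default cut points are the standard SPPB 4-m gait-speed categories:

    time <= 4.82 s  -> 4
    4.83 – 6.20 s   -> 3
    6.21 – 8.70 s   -> 2
    time > 8.70 s   -> 1
    unable/missing  -> 0

The cut-point table is fully overridable via run configuration.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import pandas as pd

from gaitcomp.errors import SchemaError, ValidationError

#: (upper time bound in seconds, score); times above the last bound score 1.
DEFAULT_CUTPOINTS: tuple[tuple[float, int], ...] = (
    (4.82, 4),
    (6.20, 3),
    (8.70, 2),
)

WALK_DISTANCE_M = 4.0


@dataclass(frozen=True)
class WalkScore:
    """Per-trial and combined (mean-time) scores for one participant."""

    participant_id: str
    score_1: int
    score_2: int
    score_combined: int
    mean_time: float


def _score_time(time_s: float | None,
                cutpoints: Sequence[tuple[float, int]]) -> int:
    if time_s is None or (isinstance(time_s, float) and math.isnan(time_s)):
        return 0
    if time_s <= 0:
        raise ValidationError(f"non-positive walk time {time_s}")
    for bound, score in cutpoints:
        if time_s <= bound:
            return score
    return 1


def score_walk(participant_id: str,
               time_1: float | None, time_2: float | None,
               cutpoints: Sequence[tuple[float, int]] = DEFAULT_CUTPOINTS,
               ) -> WalkScore:
    """Score both trials and the mean time of one participant.

    The combined score is computed on the mean of the present trial times;
    with both trials missing every score is 0 (unable to complete) and
    mean_time is NaN.
    """
    cutpoints = sorted(cutpoints)
    missing_1 = time_1 is None or (isinstance(time_1, float)
                                   and math.isnan(time_1))
    missing_2 = time_2 is None or (isinstance(time_2, float)
                                   and math.isnan(time_2))
    present = [t for t, m in ((time_1, missing_1), (time_2, missing_2))
               if not m]
    mean_time = sum(present) / len(present) if present else math.nan
    return WalkScore(
        participant_id=participant_id,
        score_1=_score_time(None if missing_1 else time_1, cutpoints),
        score_2=_score_time(None if missing_2 else time_2, cutpoints),
        score_combined=_score_time(None if not present else mean_time,
                                   cutpoints),
        mean_time=mean_time,
    )


def read_walk_trials(path) -> pd.DataFrame:
    """Read a trials CSV with columns participant_id, time_1, time_2."""
    df = pd.read_csv(path)
    required = {"participant_id", "time_1", "time_2"}
    if not required <= set(df.columns):
        raise SchemaError(
            f"trials CSV must contain columns {sorted(required)}")
    df["participant_id"] = df["participant_id"].astype(str)
    return df


def score_walk_table(trials: pd.DataFrame,
                     cutpoints: Sequence[tuple[float, int]] = DEFAULT_CUTPOINTS,
                     ) -> pd.DataFrame:
    """Score a trials table; output columns mirror the walking-test report
    (test2_1_score, test2_2_score, test2_score)."""
    rows = []
    for _, rec in trials.iterrows():
        ws = score_walk(rec["participant_id"], rec["time_1"], rec["time_2"],
                        cutpoints)
        rows.append({
            "participant_id": ws.participant_id,
            "test2_1_score": ws.score_1,
            "test2_2_score": ws.score_2,
            "test2_score": ws.score_combined,
            "test2_mean_time": ws.mean_time,
        })
    return pd.DataFrame(rows)
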