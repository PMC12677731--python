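"""Per-subject aggregation of walking-bout metrics.

Daily aggregation (steps/day over valid wear days) and weekly aggregation
(distribution statistics over all bouts pooled across the measurement
period): habitual values as histogram modes, fast values as 95th
percentiles, maximum bout distance, and the four bout-duration categories
(<=10 s, >10-30 s, >30-60 s, >60 s).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .bouts import WalkingBout
from .recording_io import DayRecord

DURATION_EDGES = (10.0, 30.0, 60.0)  # s, right-closed on the lower category
N_CATEGORIES = 4


@dataclass
class AggregationConfig:
    cadence_bin: float = 2.0  # steps/min
    speed_bin: float = 0.05  # m/s
    steps_per_bout: str = "n_ic"  # or "n_intervals"
    weekly_valid_days_only: bool = False


@dataclass
class SubjectSummary:
    mean_daily_steps: float
    fast_cadence: float
    habitual_cadence: float
    fast_speed: float
    habitual_speed: float
    max_bout_distance: float
    cat_proportions: tuple[float, float, float, float]
    cat_minutes: tuple[float, float, float, float]
    n_valid_days: int
    n_bouts: int


def bout_steps(bout: WalkingBout, convention: str = "n_ic") -> int:
    """Steps contributed by a bout: every IC counts by default."""
    return bout.n_steps if convention == "n_ic" else bout.n_steps - 1


def mean_daily_steps(
    bouts: list[WalkingBout],
    days: list[DayRecord],
    steps_per_bout: str = "n_ic",
) -> float:
    """Mean of per-day step sums over valid days; NaN when none are valid."""
    valid = {d.day_index for d in days if d.is_valid}
    if not valid:
        return math.nan
    per_day = {k: 0.0 for k in valid}
    for b in bouts:
        if b.day_index in valid:
            per_day[b.day_index] += bout_steps(b, steps_per_bout)
    return float(np.mean(list(per_day.values())))


def percentile95(values) -> float:
    """95th percentile with linear interpolation between order statistics."""
    values = np.asarray(list(values), dtype=float)
    if values.size == 0:
        return math.nan
    return float(np.percentile(values, 95.0, method="linear"))


def mode_estimate(values, bin_width: float) -> float:
    """Histogram mode: midpoint of the fullest zero-anchored bin.

    Ties break toward the lower bin.
    """
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    values = np.asarray(list(values), dtype=float)
    if values.size == 0:
        return math.nan
    idx = np.floor(values / bin_width).astype(int)
    counts = np.bincount(idx - idx.min())
    best = int(np.argmax(counts)) + int(idx.min())
    return (best + 0.5) * bin_width


def duration_category(duration_s: float) -> int:
    """0-based duration category; boundaries belong to the lower category."""
    for i, edge in enumerate(DURATION_EDGES):
        if duration_s <= edge:
            return i
    return N_CATEGORIES - 1


def duration_category_summary(bouts: list[WalkingBout]) -> tuple[tuple, tuple]:
    """(proportions, minutes) across the four bout-duration categories."""
    minutes = [0.0] * N_CATEGORIES
    counts = [0] * N_CATEGORIES
    for b in bouts:
        c = duration_category(b.duration)
        counts[c] += 1
        minutes[c] += b.duration / 60.0
    n = len(bouts)
    props = tuple(c / n for c in counts) if n else (math.nan,) * N_CATEGORIES
    return props, tuple(minutes)


def max_bout_distance(bouts: list[WalkingBout]) -> float:
    if not bouts:
        return math.nan
    return float(max(b.distance for b in bouts))


def build_subject_summary(
    bouts: list[WalkingBout],
    days: list[DayRecord],
    config: AggregationConfig = AggregationConfig(),
) -> SubjectSummary:
    """All per-subject gait outcome variables.

    Weekly aggregation pools bouts across the entire measurement period;
    only the daily step count is restricted to valid days.
    """
    weekly = bouts
    if config.weekly_valid_days_only:
        valid = {d.day_index for d in days if d.is_valid}
        weekly = [b for b in bouts if b.day_index in valid]
    cadences = [b.cadence for b in weekly]
    speeds = [b.speed for b in weekly]
    props, minutes = duration_category_summary(weekly)
    return SubjectSummary(
        mean_daily_steps=mean_daily_steps(bouts, days, config.steps_per_bout),
        fast_cadence=percentile95(cadences),
        habitual_cadence=mode_estimate(cadences, config.cadence_bin) if cadences else math.nan,
        fast_speed=percentile95(speeds),
        habitual_speed=mode_estimate(speeds, config.speed_bin) if speeds else math.nan,
        max_bout_distance=max_bout_distance(weekly),
        cat_proportions=props,
        cat_minutes=minutes,
        n_valid_days=sum(d.is_valid for d in days),
        n_bouts=len(weekly),
    )


SUMMARY_COLUMNS = [
    "subject_id",
    "mean_daily_steps",
    "fast_cadence",
    "habitual_cadence",
    "fast_speed",
    "habitual_speed",
    "max_bout_distance",
    "prop_le10s",
    "prop_10_30s",
    "prop_30_60s",
    "prop_gt60s",
    "min_le10s",
    "min_10_30s",
    "min_30_60s",
    "min_gt60s",
    "n_valid_days",
    "n_bouts",
]


def summary_to_frame(subject_id: str, s: SubjectSummary) -> pd.DataFrame:
    row = {
        "subject_id": subject_id,
        "mean_daily_steps": s.mean_daily_steps,
        "fast_cadence": s.fast_cadence,
        "habitual_cadence": s.habitual_cadence,
        "fast_speed": s.fast_speed,
        "habitual_speed": s.habitual_speed,
        "max_bout_distance": s.max_bout_distance,
        "prop_le10s": s.cat_proportions[0],
        "prop_10_30s": s.cat_proportions[1],
        "prop_30_60s": s.cat_proportions[2],
        "prop_gt60s": s.cat_proportions[3],
        "min_le10s": s.cat_minutes[0],
        "min_10_30s": s.cat_minutes[1],
        "min_30_60s": s.cat_minutes[2],
        "min_gt60s": s.cat_minutes[3],
        "n_valid_days": s.n_valid_days,
        "n_bouts": s.n_bouts,
    }
    return pd.DataFrame([row], columns=SUMMARY_COLUMNS)
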