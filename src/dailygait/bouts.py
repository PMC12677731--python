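"""Walking-bout assembly and per-bout gait metrics.

A walking bout is a maximal run of >= 2 consecutive steps where each
inter-step gap is at most 1.5 s plus the average step duration so far.
Per-bout metrics: duration (first-to-last initial contact), cadence
(interval-based step frequency), mean step length from the
inverted-pendulum model, speed = cadence/60 x step length, and
distance = duration x speed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.integrate import cumulative_trapezoid
from scipy.signal import detrend

from .errors import DegenerateBoutError

G_MPS2 = 9.81

#: fixed slack added to the adaptive inter-step gap threshold, seconds
GAP_SLACK_S = 1.5


@dataclass
class PendulumParams:
    """Inverted-pendulum step-length model parameters."""

    l: float = 0.90  # m, sensor height above ground (pendulum length)
    K: float = 1.25  # correction factor for the pendulum underestimation
    leg_fraction: float = 0.53  # l = leg_fraction x body height when derived
    hp_cutoff: float = 0.1  # Hz, drift removal alternative to linear detrend

    def __post_init__(self):
        if self.l <= 0 or self.K <= 0:
            raise ValueError("l and K must be positive")

    @classmethod
    def from_height(cls, body_height_cm: float, **kw) -> "PendulumParams":
        return cls(l=0.01 * body_height_cm * kw.pop("leg_fraction", 0.53), **kw)


@dataclass
class WalkingBout:
    step_times: list[float]
    n_steps: int
    start: float
    end: float
    duration: float
    cadence: float  # steps/min
    mean_step_length: float  # m
    speed: float  # m/s
    distance: float  # m
    day_index: int = 0
    step_lengths: list[float] = field(default_factory=list, repr=False)


def assemble_bouts(step_times: list[float], default_step: float = 0.7) -> list[list[float]]:
    """Group sorted step times into maximal bouts of >= 2 steps.

    A step joins the current bout when the gap from the previous step is at
    most ``GAP_SLACK_S`` plus the running mean of the bout's previous step
    intervals (``default_step`` before the first interval is known).
    Singleton groups are discarded.
    """
    step_times = list(step_times)
    groups: list[list[float]] = []
    cur: list[float] = []
    for t in step_times:
        if not cur:
            cur = [t]
            continue
        intervals = np.diff(cur)
        mean_step = float(intervals.mean()) if intervals.size else default_step
        if t - cur[-1] <= GAP_SLACK_S + mean_step:
            cur.append(t)
        else:
            if len(cur) >= 2:
                groups.append(cur)
            cur = [t]
    if len(cur) >= 2:
        groups.append(cur)
    return groups


def compute_bout_timing(step_times: list[float]) -> tuple[float, float]:
    """Duration (first-to-last IC) and interval-based cadence in steps/min."""
    if len(step_times) < 2:
        raise DegenerateBoutError("a bout requires at least 2 step times")
    duration = step_times[-1] - step_times[0]
    if duration <= 0 or np.any(np.diff(step_times) <= 0):
        raise DegenerateBoutError("step times must be strictly increasing")
    cadence = 60.0 * (len(step_times) - 1) / duration
    return duration, cadence


def step_length_from_excursion(h: float, l: float, K: float) -> float:
    """Closed-form inverted-pendulum step length K * 2 * sqrt(2*l*h - h^2)."""
    return K * 2.0 * np.sqrt(max(0.0, 2.0 * l * h - h * h))


def vertical_excursion(acc_v_seg: np.ndarray, rate: float) -> float:
    """Peak-to-peak vertical displacement from one step's acceleration (g).

    Doubly integrates the gravity/drift-corrected segment; drift is removed
    by mean subtraction before integration and linear detrending of velocity
    and position (the short-window equivalent of a high-pass filter).
    """
    a = np.asarray(acc_v_seg, dtype=float) * G_MPS2
    if len(a) < 3:
        return 0.0
    a = a - a.mean()
    v = cumulative_trapezoid(a, dx=1.0 / rate, initial=0.0)
    v = detrend(v, type="linear")
    p = cumulative_trapezoid(v, dx=1.0 / rate, initial=0.0)
    # remove the line through the endpoints: displacement is cyclic between
    # consecutive initial contacts, and a least-squares detrend would bias
    # the excursion of the within-step oscillation
    p = p - (p[0] + (p[-1] - p[0]) * np.linspace(0.0, 1.0, len(p)))
    return float(np.ptp(p))


def estimate_step_lengths(
    acc_v: np.ndarray,
    rate: float,
    step_times: list[float],
    params: PendulumParams = PendulumParams(),
    t0: float = 0.0,
) -> list[float]:
    """Per-step lengths from the inverted-pendulum model.

    One length per step interval (n step times give n-1 lengths). ``t0`` is
    the recording time of ``acc_v[0]`` so bout-local segments can be used.
    Steps whose excursion h would reach the pendulum length are clamped to
    0.9 l with a warning.
    """
    acc_v = np.asarray(acc_v, dtype=float)
    lengths = []
    for a, b in zip(step_times[:-1], step_times[1:]):
        i0 = int(round((a - t0) * rate))
        i1 = int(round((b - t0) * rate))
        i0 = max(0, min(i0, len(acc_v) - 1))
        i1 = max(i0 + 1, min(i1, len(acc_v) - 1))
        h = vertical_excursion(acc_v[i0 : i1 + 1], rate)
        if h >= params.l:
            warnings.warn(
                f"vertical excursion h={h:.3f} m exceeds pendulum length "
                f"l={params.l:.3f} m; clamping",
                stacklevel=2,
            )
            h = 0.9 * params.l
        lengths.append(step_length_from_excursion(h, params.l, params.K))
    return lengths


def summarize_bout(
    step_times: list[float],
    step_lengths: list[float],
    day_index: int = 0,
) -> WalkingBout:
    """Build a WalkingBout; speed and distance follow by definition."""
    duration, cadence = compute_bout_timing(step_times)
    if len(step_lengths) != len(step_times) - 1:
        raise ValueError("expected one step length per step interval")
    mean_len = float(np.mean(step_lengths))
    speed = cadence / 60.0 * mean_len
    return WalkingBout(
        step_times=list(step_times),
        n_steps=len(step_times),
        start=step_times[0],
        end=step_times[-1],
        duration=duration,
        cadence=cadence,
        mean_step_length=mean_len,
        speed=speed,
        distance=duration * speed,
        day_index=day_index,
        step_lengths=list(step_lengths),
    )


def bouts_to_frame(subject_id: str, bouts: list[WalkingBout]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "subject_id": subject_id,
                "day": b.day_index,
                "start_s": b.start,
                "duration_s": b.duration,
                "n_steps": b.n_steps,
                "cadence_spm": b.cadence,
                "mean_step_length_m": b.mean_step_length,
                "speed_mps": b.speed,
                "distance_m": b.distance,
            }
            for b in bouts
        ],
        columns=[
            "subject_id",
            "day",
            "start_s",
            "duration_s",
            "n_steps",
            "cadence_spm",
            "mean_step_length_m",
            "speed_mps",
            "distance_m",
        ],
    )
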