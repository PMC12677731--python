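"""Recording I/O, signal resampling, temperature-based wear detection and
valid-day classification.

The canonical on-disk format is a plain CSV with columns
``t,acc_v,acc_ap,acc_ml[,temp]`` (``t`` in seconds from recording start,
acceleration in g, temperature in degrees Celsius) plus a JSON sidecar
(same path with ``.json`` extension) holding ``subject_id``,
``start_time`` (ISO-8601) and the nominal sampling ``rate``.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, replace
from datetime import date, datetime, timedelta
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import EmptyInputError, FormatError, SamplingError

REQUIRED_COLUMNS = ("t", "acc_v", "acc_ap", "acc_ml")

#: hours of wear required for a day to count as valid
VALID_DAY_HOURS = 18.0
SECONDS_PER_DAY = 86400.0


@dataclass
class Recording:
    """Multi-day triaxial acceleration (+ optional temperature) series.

    Acceleration is in g; axes are vertical, antero-posterior and
    medio-lateral as mounted on the lower back.
    """

    subject_id: str
    rate: float
    start_time: datetime
    acc_v: np.ndarray
    acc_ap: np.ndarray
    acc_ml: np.ndarray
    temperature: np.ndarray | None = None
    temp_rate: float | None = None

    def __post_init__(self):
        if self.rate <= 0:
            raise ValueError("rate must be positive")
        n = len(self.acc_v)
        if len(self.acc_ap) != n or len(self.acc_ml) != n:
            raise ValueError("acceleration axes must have equal length")
        for name in ("acc_v", "acc_ap", "acc_ml"):
            a = np.asarray(getattr(self, name), dtype=float)
            if np.isnan(a).any():
                raise ValueError(f"{name} contains missing values")
            setattr(self, name, a)
        if self.temperature is not None:
            self.temperature = np.asarray(self.temperature, dtype=float)
            if self.temp_rate is None:
                self.temp_rate = self.rate

    @property
    def n_samples(self) -> int:
        return len(self.acc_v)

    @property
    def duration(self) -> float:
        """Total duration in seconds (n samples at ``rate``)."""
        return self.n_samples / self.rate

    def norm(self) -> np.ndarray:
        """Euclidean norm of the three acceleration axes, in g."""
        return np.sqrt(self.acc_v**2 + self.acc_ap**2 + self.acc_ml**2)


@dataclass(frozen=True)
class WearInterval:
    """Worn / non-worn span in seconds from recording start."""

    start: float
    end: float
    worn: bool

    def __post_init__(self):
        if self.end <= self.start:
            raise ValueError("end must exceed start")

    @property
    def duration(self) -> float:
        return self.end - self.start


@dataclass(frozen=True)
class DayRecord:
    """Per-calendar-day wear summary."""

    date: date
    wear_hours: float
    is_valid: bool
    day_index: int = 0


@dataclass(frozen=True)
class WearParams:
    """Thresholds for the event-based temperature wear detector."""

    smooth_window_s: float = 300.0
    temp_threshold_c: float = 27.0
    slope_threshold_c_per_min: float = 0.1
    slope_sustain_s: float = 120.0
    min_segment_s: float = 600.0
    missing_fallback_worn: bool = True


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(".json")


def write_recording(rec: Recording, path: str | Path) -> Path:
    """Write a recording as CSV + JSON sidecar; returns the CSV path."""
    path = Path(path)
    t = np.arange(rec.n_samples) / rec.rate
    frame = pd.DataFrame(
        {"t": t, "acc_v": rec.acc_v, "acc_ap": rec.acc_ap, "acc_ml": rec.acc_ml}
    )
    if rec.temperature is not None:
        # temperature is stored on its own (usually coarser) grid, padded
        # with blanks to the acceleration length
        temp = np.full(rec.n_samples, np.nan)
        temp[: len(rec.temperature)] = rec.temperature
        frame["temp"] = temp
    frame.to_csv(path, index=False, float_format="%.9g")
    meta = {
        "subject_id": rec.subject_id,
        "start_time": rec.start_time.isoformat(),
        "rate": rec.rate,
    }
    if rec.temp_rate is not None:
        meta["temp_rate"] = rec.temp_rate
    _sidecar_path(path).write_text(json.dumps(meta, indent=2))
    return path


def read_recording(path: str | Path, rate_tolerance: float = 0.01) -> Recording:
    """Read a recording from the documented CSV dialect.

    The sampling rate is inferred from the time column and checked for
    uniformity: the median inter-sample interval must be within
    ``rate_tolerance`` (relative) of every observed interval.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    frame = pd.read_csv(path)
    missing = [c for c in REQUIRED_COLUMNS if c not in frame.columns]
    if missing:
        raise FormatError(f"missing required column(s): {', '.join(missing)}")
    t = frame["t"].to_numpy(dtype=float)
    if len(t) < 2:
        raise FormatError("recording must contain at least 2 samples")
    dt = np.diff(t)
    med = float(np.median(dt))
    if med <= 0:
        raise SamplingError("time column is not strictly increasing")
    if np.abs(dt - med).max() > rate_tolerance * med:
        raise SamplingError(
            "non-uniform sampling: inter-sample intervals deviate from the "
            f"median ({med:.6g} s) by more than {rate_tolerance:.0%}"
        )
    rate = 1.0 / med

    meta = {}
    sidecar = _sidecar_path(path)
    if sidecar.exists():
        meta = json.loads(sidecar.read_text())
        if "rate" in meta and abs(meta["rate"] - rate) > rate_tolerance * rate:
            raise SamplingError(
                f"inferred rate {rate:.4g} disagrees with declared rate "
                f"{meta['rate']:.4g}"
            )
        rate = float(meta.get("rate", rate))

    temperature = temp_rate = None
    if "temp" in frame.columns:
        temp = frame["temp"].to_numpy(dtype=float)
        temperature = temp[~np.isnan(temp)]
        temp_rate = float(meta.get("temp_rate", rate))
        if temperature.size == 0:
            temperature = None
            temp_rate = None

    start_time = datetime.fromisoformat(meta["start_time"]) if "start_time" in meta else datetime(2000, 1, 1)
    return Recording(
        subject_id=str(meta.get("subject_id", path.stem)),
        rate=rate,
        start_time=start_time,
        acc_v=frame["acc_v"].to_numpy(dtype=float),
        acc_ap=frame["acc_ap"].to_numpy(dtype=float),
        acc_ml=frame["acc_ml"].to_numpy(dtype=float),
        temperature=temperature,
        temp_rate=temp_rate,
    )


def resample_recording(rec: Recording, target_rate: float, kind: str = "linear") -> Recording:
    """Resample each acceleration axis independently to ``target_rate``.

    Linear interpolation by default; ``kind='cubic'`` switches to a cubic
    spline. Duration is preserved within one sample period. The temperature
    channel keeps its own rate and is passed through unchanged.
    """
    if target_rate <= 0:
        raise ValueError("target_rate must be positive")
    if rec.n_samples == 0:
        raise EmptyInputError("cannot resample an empty recording")
    if target_rate == rec.rate:
        return replace(rec)

    t_old = np.arange(rec.n_samples) / rec.rate
    n_new = int(round((rec.n_samples - 1) * target_rate / rec.rate)) + 1
    t_new = np.arange(n_new) / target_rate
    t_new = np.minimum(t_new, t_old[-1])  # guard tail rounding

    def interp(y):
        if kind == "cubic":
            from scipy.interpolate import CubicSpline

            return CubicSpline(t_old, y)(t_new)
        return np.interp(t_new, t_old, y)

    return replace(
        rec,
        rate=float(target_rate),
        acc_v=interp(rec.acc_v),
        acc_ap=interp(rec.acc_ap),
        acc_ml=interp(rec.acc_ml),
    )


def _runs(mask: np.ndarray) -> list[tuple[int, int, bool]]:
    """Maximal runs of a boolean array as (start, stop, value), stop exclusive."""
    edges = np.flatnonzero(np.diff(mask.astype(np.int8))) + 1
    bounds = np.concatenate(([0], edges, [len(mask)]))
    return [
        (int(a), int(b), bool(mask[a])) for a, b in zip(bounds[:-1], bounds[1:])
    ]


def _merge_short_runs(mask: np.ndarray, min_len: int) -> np.ndarray:
    """Absorb runs shorter than ``min_len`` into their surrounding state."""
    mask = mask.copy()
    while True:
        runs = _runs(mask)
        if len(runs) <= 1:
            return mask
        short = [(b - a, i) for i, (a, b, _) in enumerate(runs) if b - a < min_len]
        if not short:
            return mask
        _, i = min(short)
        a, b, v = runs[i]
        mask[a:b] = ~v


def detect_wear(
    temperature: np.ndarray | None,
    temp_rate: float,
    duration: float | None = None,
    params: WearParams = WearParams(),
) -> list[WearInterval]:
    """Partition a recording into worn / non-worn intervals from temperature.

    The temperature series is smoothed with a centered moving average and a
    sample is classified worn when the smoothed temperature exceeds the skin
    threshold or shows a sustained positive slope (donning event). Segments
    shorter than ``min_segment_s`` are merged into their neighbours.

    An absent or all-missing temperature channel yields one interval covering
    the whole recording (worn by default) and a loud warning.
    """
    if temperature is not None:
        temperature = np.asarray(temperature, dtype=float)
    if temperature is None or temperature.size == 0 or np.isnan(temperature).all():
        if duration is None:
            raise EmptyInputError("duration required when temperature is missing")
        warnings.warn(
            "temperature channel missing; treating entire recording as "
            f"{'worn' if params.missing_fallback_worn else 'not worn'}",
            stacklevel=2,
        )
        return [WearInterval(0.0, duration, params.missing_fallback_worn)]

    if duration is None:
        duration = temperature.size / temp_rate
    temp = pd.Series(temperature).interpolate(limit_direction="both").to_numpy()

    win = max(1, int(round(params.smooth_window_s * temp_rate)))
    kernel = np.ones(win) / win
    pad = win // 2
    padded = np.pad(temp, pad, mode="edge")
    smooth = np.convolve(padded, kernel, mode="same")[pad : pad + temp.size]

    worn = smooth >= params.temp_threshold_c
    if temp.size > 1:
        slope = np.gradient(smooth) * temp_rate * 60.0  # degC / min
        hot = slope >= params.slope_threshold_c_per_min
        sustain = max(1, int(round(params.slope_sustain_s * temp_rate)))
        for a, b, v in _runs(hot):
            if v and b - a >= sustain:
                worn[a:b] = True

    worn = _merge_short_runs(worn, max(1, int(round(params.min_segment_s * temp_rate))))

    scale = duration / temp.size
    intervals = [
        WearInterval(a * scale, b * scale, v) for a, b, v in _runs(worn)
    ]
    # force exact coverage of [0, duration]
    last = intervals[-1]
    if last.end != duration:
        intervals[-1] = WearInterval(last.start, duration, last.worn)
    return intervals


def day_wear_summary(
    intervals: list[WearInterval],
    start_time: datetime,
    duration: float,
    day_seconds: float = SECONDS_PER_DAY,
    valid_fraction: float = VALID_DAY_HOURS / 24.0,
) -> list[DayRecord]:
    """Apportion worn time to calendar days and apply the valid-day rule.

    Days run local-midnight-to-midnight from ``start_time``. ``day_seconds``
    shrinks the day length for desk-scale synthetic recordings (boundaries
    then count from recording start); the validity threshold scales with it
    so the default corresponds to >= 18 h of wear in a 24 h day.
    """
    if day_seconds == SECONDS_PER_DAY:
        midnight = datetime.combine(start_time.date(), datetime.min.time())
        offset = (start_time - midnight).total_seconds()
    else:
        offset = 0.0
    first_day = start_time.date()
    n_days = int(np.ceil((offset + duration) / day_seconds))
    worn = [(iv.start, iv.end) for iv in intervals if iv.worn]

    records = []
    for k in range(n_days):
        lo = k * day_seconds - offset
        hi = lo + day_seconds
        secs = sum(max(0.0, min(e, hi) - max(s, lo)) for s, e in worn)
        records.append(
            DayRecord(
                date=first_day + timedelta(days=k),
                wear_hours=secs / 3600.0,
                is_valid=secs >= valid_fraction * day_seconds - 1e-9,
                day_index=k,
            )
        )
    return records


def day_index_of(t: float, start_time: datetime, day_seconds: float = SECONDS_PER_DAY) -> int:
    """Index of the day containing recording time ``t`` (seconds)."""
    if day_seconds == SECONDS_PER_DAY:
        midnight = datetime.combine(start_time.date(), datetime.min.time())
        t = t + (start_time - midnight).total_seconds()
    return int(t // day_seconds)


def wear_intervals_to_frame(intervals: list[WearInterval]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "start_s": [iv.start for iv in intervals],
            "end_s": [iv.end for iv in intervals],
            "worn": [int(iv.worn) for iv in intervals],
        }
    )


def day_records_to_frame(days: list[DayRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "day_index": [d.day_index for d in days],
            "date": [d.date.isoformat() for d in days],
            "wear_hours": [d.wear_hours for d in days],
            "is_valid": [int(d.is_valid) for d in days],
        }
    )
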