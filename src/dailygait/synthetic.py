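"""Synthetic accelerometer recordings and cohort tables with ground truth.

The vertical channel is built from the same inverted-pendulum geometry the
analysis inverts: each step contributes one period of a smooth sinusoidal
centre-of-mass arc whose excursion h solves K*2*sqrt(2*l*h - h^2) = target
step length, plus a short landing transient at every initial contact. The
arc phase is chosen so that the positive peaks of the detector's transformed
signal coincide with the labelled initial-contact times.

Cohort tables are drawn from the multiplicative gamma-error regression
model, so the fitting module can be validated by parameter recovery.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import datetime

import numpy as np
import pandas as pd

from .bouts import PendulumParams, step_length_from_excursion
from .errors import ProtocolError
from .recording_io import Recording, WearInterval

G_MPS2 = 9.81


@dataclass
class BoutSpec:
    start: float  # s
    n_steps: int  # number of initial contacts
    cadence: float  # steps/min
    step_length: float  # m

    @property
    def step_period(self) -> float:
        return 60.0 / self.cadence

    @property
    def end(self) -> float:
        return self.start + (self.n_steps - 1) * self.step_period

    def ic_times(self) -> np.ndarray:
        return self.start + self.step_period * np.arange(self.n_steps)


@dataclass
class GaitProtocol:
    duration: float  # s
    bouts: list[BoutSpec] = field(default_factory=list)
    worn_intervals: list[tuple[float, float]] | None = None  # None = worn throughout
    noise_sd: float = 0.02  # g
    body_height: float = 168.8  # cm
    ic_spike_amp: float = 0.3  # g
    seed: int = 0
    pendulum: PendulumParams = field(default_factory=PendulumParams)

    def __post_init__(self):
        spans = sorted((b.start, b.end) for b in self.bouts)
        for (s0, e0), (s1, _) in zip(spans[:-1], spans[1:]):
            if s1 < e0:
                raise ProtocolError("bouts overlap")
        for b in self.bouts:
            if not (30 < b.cadence < 200):
                raise ProtocolError(f"cadence {b.cadence} outside (30, 200) steps/min")
            if b.step_length >= 2.0:
                raise ProtocolError("step length must be below 2 m")
            if b.n_steps < 2:
                raise ProtocolError("a bout requires at least 2 steps")
            if b.end > self.duration:
                raise ProtocolError("bout extends past the recording")


@dataclass
class GroundTruth:
    ic_times_per_bout: list[np.ndarray]
    bout_durations: list[float]
    bout_cadences: list[float]
    bout_step_lengths: list[float]
    bout_speeds: list[float]
    bout_distances: list[float]
    daily_steps: dict[int, int]
    worn_intervals: list[tuple[float, float]]

    @property
    def ic_times(self) -> np.ndarray:
        if not self.ic_times_per_bout:
            return np.array([])
        return np.concatenate(self.ic_times_per_bout)


def excursion_for_step_length(step_length: float, params: PendulumParams) -> float:
    """Invert K*2*sqrt(2*l*h - h^2) = step_length for the smaller root h."""
    s = step_length / (2.0 * params.K)
    if s >= params.l:
        raise ProtocolError(
            f"step length {step_length} m unreachable for pendulum length {params.l} m"
        )
    return params.l - np.sqrt(params.l**2 - s**2)


def _add_bout_signal(acc_v: np.ndarray, rate: float, bout: BoutSpec, protocol: GaitProtocol):
    t_len = len(acc_v)
    h = excursion_for_step_length(bout.step_length, protocol.pendulum)
    omega = 2 * np.pi / bout.step_period
    # extend a quarter step period on both sides with a linear taper so the
    # smoothed transform stays symmetric at the bout edges without leaking
    # an extra detectable cycle
    half = bout.step_period / 4.0
    i0 = max(0, int(round((bout.start - half) * rate)))
    i1 = min(t_len, int(round((bout.end + half) * rate)) + 1)
    t = np.arange(i0, i1) / rate - bout.start
    taper = np.ones_like(t)
    lead = t < 0
    tail = t > bout.end - bout.start
    taper[lead] = 1.0 + t[lead] / half
    taper[tail] = 1.0 - (t[tail] - (bout.end - bout.start)) / half
    taper = np.clip(taper, 0.0, 1.0)
    # z(t) = (h/2) sin(omega t)  ->  a = -z'' ... sign folded into the sine
    acc_v[i0:i1] += -(h / 2.0) * omega**2 * np.sin(omega * t) / G_MPS2 * taper
    # landing transient at every IC: mostly biphasic (small net impulse, so
    # the double-integrated displacement stays dominated by the CoM arc)
    # with a modest unipolar component that keeps sub-3.2 Hz energy
    spike_n = max(4, int(round(0.05 * rate)))
    phase = np.arange(spike_n) / spike_n
    spike = protocol.ic_spike_amp * (np.sin(2 * np.pi * phase) + 0.3 * np.sin(np.pi * phase))
    for tc in bout.ic_times():
        j = int(round(tc * rate))
        if j + spike_n <= t_len:
            acc_v[j : j + spike_n] += spike


def _temperature_series(
    duration: float,
    worn: list[tuple[float, float]],
    temp_rate: float,
    rng: np.random.Generator,
    tau: float = 120.0,
) -> np.ndarray:
    n = max(1, int(round(duration * temp_rate)))
    t = np.arange(n) / temp_rate
    is_worn = np.zeros(n, dtype=bool)
    for s, e in worn:
        is_worn[(t >= s) & (t < e)] = True
    target = np.where(is_worn, 32.0, 21.0)
    temp = np.empty(n)
    temp[0] = target[0]
    decay = np.exp(-1.0 / (tau * temp_rate))
    for i in range(1, n):
        temp[i] = target[i] + (temp[i - 1] - target[i]) * decay
    return temp + rng.normal(0.0, 0.05, n)


def synthesize_recording(
    protocol: GaitProtocol,
    rate: float = 100.0,
    temp_rate: float = 1.0,
    subject_id: str = "synthetic",
    start_time: datetime = datetime(2021, 6, 1, 0, 0),
    day_seconds: float = 86400.0,
) -> tuple[Recording, GroundTruth]:
    """Render a protocol to a Recording plus its exact ground truth."""
    rng = np.random.default_rng(protocol.seed)
    n = int(round(protocol.duration * rate))
    acc_v = np.ones(n)  # gravity baseline, g
    acc_ap = np.zeros(n)
    acc_ml = np.zeros(n)

    for bout in protocol.bouts:
        _add_bout_signal(acc_v, rate, bout, protocol)
        # mild antero-posterior / lateral walking content
        i0 = int(round(bout.start * rate))
        i1 = min(n, int(round(bout.end * rate)) + 1)
        t = np.arange(i0, i1) / rate - bout.start
        omega = 2 * np.pi / bout.step_period
        acc_ap[i0:i1] += 0.05 * np.sin(omega * t + 0.7)
        acc_ml[i0:i1] += 0.05 * np.sin(omega * t / 2.0)

    if protocol.noise_sd > 0:
        acc_v = acc_v + rng.normal(0.0, protocol.noise_sd, n)
        acc_ap = acc_ap + rng.normal(0.0, protocol.noise_sd, n)
        acc_ml = acc_ml + rng.normal(0.0, protocol.noise_sd, n)

    worn = protocol.worn_intervals or [(0.0, protocol.duration)]
    temperature = _temperature_series(protocol.duration, worn, temp_rate, rng)

    rec = Recording(
        subject_id=subject_id,
        rate=rate,
        start_time=start_time,
        acc_v=acc_v,
        acc_ap=acc_ap,
        acc_ml=acc_ml,
        temperature=temperature,
        temp_rate=temp_rate,
    )

    daily: dict[int, int] = {}
    for b in protocol.bouts:
        day = int(b.start // day_seconds)
        daily[day] = daily.get(day, 0) + b.n_steps
    truth = GroundTruth(
        ic_times_per_bout=[b.ic_times() for b in protocol.bouts],
        bout_durations=[b.end - b.start for b in protocol.bouts],
        bout_cadences=[b.cadence for b in protocol.bouts],
        bout_step_lengths=[b.step_length for b in protocol.bouts],
        bout_speeds=[b.cadence / 60.0 * b.step_length for b in protocol.bouts],
        bout_distances=[
            (b.end - b.start) * b.cadence / 60.0 * b.step_length for b in protocol.bouts
        ],
        daily_steps=daily,
        worn_intervals=list(worn),
    )
    return rec, truth


# ---------------------------------------------------------------------------
# multi-day ("week") generator


@dataclass
class WeekConfig:
    n_days: int = 7
    day_seconds: float = 1200.0  # desk-scale compressed day
    rate: float = 100.0
    mean_bouts_per_day: float = 10.0
    category_probs: tuple = (0.63, 0.25, 0.08, 0.04)  # <=10 / 10-30 / 30-60 / >60 s
    cadence_mean: float = 100.0
    cadence_sd: float = 10.0
    step_length_mean: float = 0.6
    step_length_sd: float = 0.08
    noise_sd: float = 0.02
    nonwear_day_prob: float = 0.15  # chance a day gets a long non-wear block
    nonwear_fraction: float = 0.4  # of that day (makes it invalid: > 6/24)
    min_gap: float = 5.0  # s between bouts


def synthesize_week(config: WeekConfig = WeekConfig(), seed: int = 0):
    """Multi-day protocol with bout structure drawn from ``config``.

    Returns (Recording, GroundTruth, GaitProtocol). Days are compressed to
    ``day_seconds`` so a full "week" stays desk-scale; pass
    ``day_seconds=86400`` for real days.
    """
    rng = np.random.default_rng(seed)
    cat_bounds = [(2.0, 10.0), (10.0, 30.0), (30.0, 60.0), (60.0, 120.0)]
    duration = config.n_days * config.day_seconds
    bouts: list[BoutSpec] = []
    worn: list[tuple[float, float]] = []
    pend = PendulumParams()

    cursor_nonwear: list[tuple[float, float]] = []
    for day in range(config.n_days):
        day_start = day * config.day_seconds
        day_end = day_start + config.day_seconds
        nonwear = None
        if rng.random() < config.nonwear_day_prob:
            nw_len = config.nonwear_fraction * config.day_seconds
            nw_start = day_end - nw_len
            nonwear = (nw_start, day_end)
            cursor_nonwear.append(nonwear)
        n_bouts = rng.poisson(config.mean_bouts_per_day)
        cursor = day_start + config.min_gap
        for _ in range(n_bouts):
            cat = rng.choice(4, p=np.asarray(config.category_probs) / np.sum(config.category_probs))
            lo, hi = cat_bounds[cat]
            dur = float(rng.uniform(lo, hi))
            cadence = float(np.clip(rng.normal(config.cadence_mean, config.cadence_sd), 60, 140))
            step_len = float(
                np.clip(rng.normal(config.step_length_mean, config.step_length_sd), 0.3, 0.8)
            )
            period = 60.0 / cadence
            n_steps = max(2, int(round(dur / period)) + 1)
            start = cursor + float(rng.uniform(0, 2 * config.min_gap))
            end = start + (n_steps - 1) * period
            limit = nonwear[0] if nonwear else day_end
            if end + config.min_gap > limit:
                break
            bouts.append(BoutSpec(start=start, n_steps=n_steps, cadence=cadence, step_length=step_len))
            cursor = end + config.min_gap

    # worn = complement of the non-wear blocks
    edges = [0.0]
    for s, e in sorted(cursor_nonwear):
        edges += [s, e]
    edges.append(duration)
    worn = [(a, b) for a, b in zip(edges[0::2], edges[1::2]) if b > a]

    protocol = GaitProtocol(
        duration=duration,
        bouts=bouts,
        worn_intervals=worn,
        noise_sd=config.noise_sd,
        seed=seed,
        pendulum=pend,
    )
    rec, truth = synthesize_recording(
        protocol, rate=config.rate, day_seconds=config.day_seconds
    )
    return rec, truth, protocol


# ---------------------------------------------------------------------------
# cohort generator


@dataclass
class MetricModel:
    beta0: float
    beta1: float
    beta_p: float
    phi: float


DEFAULT_METRIC_MODELS: dict[str, dict[str, MetricModel]] = {
    "mean_daily_steps": {
        "female": MetricModel(8.7, -0.02, 1.6, 0.25),
        "male": MetricModel(8.8, -0.015, 1.7, 0.25),
    },
    "fast_speed": {
        "female": MetricModel(0.18, -0.02, 1.2, 0.04),
        "male": MetricModel(0.26, -0.02, 1.2, 0.04),
    },
    "habitual_speed": {
        "female": MetricModel(-0.1, -0.02, 1.2, 0.05),
        "male": MetricModel(0.0, -0.02, 1.2, 0.05),
    },
    "fast_cadence": {
        "female": MetricModel(4.69, -0.002, 1.3, 0.01),
        "male": MetricModel(4.64, -0.002, 1.3, 0.01),
    },
    "habitual_cadence": {
        "female": MetricModel(4.53, -0.002, 1.5, 0.01),
        "male": MetricModel(4.46, -0.002, 1.5, 0.01),
    },
    "max_bout_distance": {
        "female": MetricModel(6.6, -0.05, 1.3, 0.6),
        "male": MetricModel(6.9, -0.04, 1.4, 0.6),
    },
}


@dataclass
class CohortSimParams:
    n_per_sex: int = 300
    seed: int = 0
    covariate_kind: str = "age"  # metrics generated from this covariate
    metric_models: dict = field(default_factory=lambda: DEFAULT_METRIC_MODELS)
    age_scale: float = 6.0  # exponential scale above 70, truncated at 100
    age_max: float = 100.0


def _draw_ages(n: int, rng: np.random.Generator, scale: float, age_max: float) -> np.ndarray:
    ages = 70.0 + rng.exponential(scale, size=2 * n + 64)
    ages = ages[ages < age_max][:n]
    while len(ages) < n:
        extra = 70.0 + rng.exponential(scale, size=n)
        ages = np.concatenate([ages, extra[extra < age_max]])[:n]
    return ages


def _draw_sppb(ages: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    mean = 12.0 / (1.0 + np.exp((ages - 92.0) / 6.0))
    return np.clip(np.round(mean + rng.normal(0, 1.5, len(ages))), 0, 12).astype(int)


def synthesize_cohort(params: CohortSimParams = CohortSimParams()):
    """Cohort table drawn from the multiplicative gamma-error model.

    Each metric is exp(beta0 + beta1 * x**beta_p) * g with g ~ Gamma(mean 1,
    variance phi) and x the shifted covariate. Returns (DataFrame, truth
    dict keyed by (metric, sex)).
    """
    rng = np.random.default_rng(params.seed)
    frames = []
    truth = {}
    for sex in ("female", "male"):
        ages = _draw_ages(params.n_per_sex, rng, params.age_scale, params.age_max)
        sppb = _draw_sppb(ages, rng)
        x = (ages - 70.0) if params.covariate_kind == "age" else (12.0 - sppb)
        data = {
            "subject_id": [f"{sex[0]}{i:04d}" for i in range(params.n_per_sex)],
            "age": ages,
            "sex": sex,
            "sppb": sppb,
        }
        for metric, by_sex in params.metric_models.items():
            m = by_sex[sex]
            mu = np.exp(m.beta0 + m.beta1 * np.power(x, m.beta_p))
            g = rng.gamma(shape=1.0 / m.phi, scale=m.phi, size=params.n_per_sex)
            data[metric] = mu * g
            truth[(metric, sex)] = m
        frames.append(pd.DataFrame(data))
    return pd.concat(frames, ignore_index=True), truth
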