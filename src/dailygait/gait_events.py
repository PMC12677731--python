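"""Gait event detection from lower-back acceleration.

Two detectors:

* :func:`detect_initial_contacts` — foot initial contacts from the vertical
  acceleration: detrend, low-pass filter, numerical integration to vertical
  velocity, smoothing with a Mexican-hat (second-derivative-of-Gaussian)
  wavelet kernel; contacts are the positive peaks between consecutive
  zero-crossings of the transformed signal.
* :func:`detect_step_peaks` — candidate step peaks from the detrended,
  FIR low-pass filtered (3.2 Hz) acceleration norm, gated by adaptive
  amplitude and peak-to-peak duration thresholds.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import signal
from scipy.integrate import cumulative_trapezoid

G_MPS2 = 9.81


@dataclass(frozen=True)
class InitialContact:
    time: float  # s from recording start


@dataclass(frozen=True)
class StepPeak:
    time: float  # s
    amplitude: float  # g above local baseline


@dataclass(frozen=True)
class ICDetectorParams:
    detrend_window: float = 1.0  # s, centered moving average
    lowpass_cutoff: float = 10.0  # Hz, zero-phase 4th-order
    highpass_cutoff: float = 0.1  # Hz, drift removal after integration
    wavelet_scale: float = 0.11  # s, Gaussian sigma of the smoothing wavelet
    min_amplitude: float = 0.008  # m/s, floor on transformed-peak height
    min_separation: float = 0.25  # s, closer peaks resolved by amplitude

    def __post_init__(self):
        if min(self.detrend_window, self.lowpass_cutoff, self.wavelet_scale) <= 0:
            raise ValueError("detector parameters must be positive")


@dataclass(frozen=True)
class StepDetectorParams:
    fir_cutoff: float = 3.2  # Hz
    amp_floor: float = 0.01  # g
    amp_fraction: float = 0.4  # of rolling median peak amplitude
    amp_window: float = 5.0  # s of history for the rolling median
    noise_mult: float = 2.5  # x estimated in-band noise sd, adaptive floor
    pp_min: float = 0.35  # s
    pp_max: float = 2.3  # s

    def __post_init__(self):
        if not (0 < self.pp_min < self.pp_max):
            raise ValueError("require 0 < pp_min < pp_max")
        if not (0 < self.amp_fraction <= 1):
            raise ValueError("amp_fraction must be in (0, 1]")


def moving_average_detrend(x: np.ndarray, rate: float, window_s: float) -> np.ndarray:
    """Subtract a centered moving average (edge-padded)."""
    win = max(1, int(round(window_s * rate)))
    if win <= 1 or win >= len(x):
        return x - np.mean(x)
    kernel = np.ones(win) / win
    pad = win // 2
    padded = np.pad(x, pad, mode="edge")
    baseline = np.convolve(padded, kernel, mode="same")[pad : pad + len(x)]
    return x - baseline


def mexican_hat_kernel(sigma_s: float, rate: float) -> np.ndarray:
    """Mexican-hat kernel (negated second derivative of a Gaussian).

    Normalised so that convolving a unit sine at the kernel's best frequency
    (omega = sqrt(2)/sigma) returns approximately unit amplitude, which keeps
    the transformed signal on the scale of the input.
    """
    sigma = sigma_s * rate
    half = int(np.ceil(5 * sigma))
    t = np.arange(-half, half + 1) / sigma
    psi = (1 - t**2) * np.exp(-(t**2) / 2)
    # response to sin(omega t): (omega sigma)^2 exp(-(omega sigma)^2/2) * sqrt(2 pi) sigma
    gain = 2.0 * np.exp(-1.0) * np.sqrt(2 * np.pi) * sigma
    return psi / gain


def ic_transform(acc_v: np.ndarray, rate: float, params: ICDetectorParams) -> np.ndarray:
    """Transform vertical acceleration (g) to the IC detection signal (m/s)."""
    x = moving_average_detrend(np.asarray(acc_v, dtype=float), rate, params.detrend_window)
    nyq = rate / 2.0
    if params.lowpass_cutoff < nyq:
        sos = signal.butter(4, params.lowpass_cutoff / nyq, "low", output="sos")
        x = signal.sosfiltfilt(sos, x)
    v = cumulative_trapezoid(x * G_MPS2, dx=1.0 / rate, initial=0.0)
    if params.highpass_cutoff > 0:
        sos = signal.butter(2, params.highpass_cutoff / nyq, "high", output="sos")
        v = signal.sosfiltfilt(sos, v)
    kernel = mexican_hat_kernel(params.wavelet_scale, rate)
    return np.convolve(v, kernel, mode="same")


def detect_initial_contacts(
    acc_v: np.ndarray,
    rate: float,
    params: ICDetectorParams = ICDetectorParams(),
) -> list[InitialContact]:
    """Detect initial contacts as positive peaks between zero-crossings of
    the transformed vertical acceleration."""
    acc_v = np.asarray(acc_v, dtype=float)
    if len(acc_v) < 2 * rate:
        warnings.warn("signal shorter than filter warm-up; no ICs detected", stacklevel=2)
        return []
    w = ic_transform(acc_v, rate, params)

    pos = w > 0
    idx = np.flatnonzero(np.diff(pos.astype(np.int8)))
    bounds = np.concatenate(([0], idx + 1, [len(w)]))
    cand: list[int] = []
    for a, b in zip(bounds[:-1], bounds[1:]):
        if not pos[a]:
            continue
        if a == 0 or b == len(w):  # open-ended segment: no flanking crossings
            continue
        i = a + int(np.argmax(w[a:b]))
        if w[i] >= params.min_amplitude:
            cand.append(i)

    # peaks closer than min_separation are resolved by amplitude
    order = sorted(range(len(cand)), key=lambda i: -w[cand[i]])
    min_gap = params.min_separation * rate
    kept: list[int] = []
    for i in order:
        if all(abs(cand[i] - cand[j]) >= min_gap for j in kept):
            kept.append(i)
    return [InitialContact(time=cand[i] / rate) for i in sorted(kept)]


def _fir_lowpass(x: np.ndarray, rate: float, cutoff: float) -> np.ndarray:
    """Linear-phase FIR low-pass with group delay compensated."""
    numtaps = int(round(rate)) | 1  # ~1 s of taps, odd for integer delay
    taps = signal.firwin(numtaps, cutoff, fs=rate)
    y = np.convolve(np.pad(x, numtaps // 2, mode="edge"), taps, mode="same")
    return y[numtaps // 2 : numtaps // 2 + len(x)]


def detect_step_peaks(
    acc_norm: np.ndarray,
    rate: float,
    params: StepDetectorParams = StepDetectorParams(),
) -> list[StepPeak]:
    """Detect step-related peaks in the acceleration norm.

    Candidates are local maxima of the detrended, 3.2 Hz FIR-filtered norm.
    Candidates closer than ``pp_min`` are resolved in favour of the larger
    amplitude; surviving peaks must exceed an adaptive amplitude threshold
    of ``max(amp_floor, amp_fraction x rolling median of recent accepted
    peak amplitudes)``.
    """
    acc_norm = np.asarray(acc_norm, dtype=float)
    if len(acc_norm) < 2:
        return []
    x = moving_average_detrend(acc_norm, rate, 1.0)
    xf = _fir_lowpass(x, rate, params.fir_cutoff)

    # broadband noise level from the residual the low-pass removed, scaled
    # to the in-band noise sd that survives the filter
    resid = x - xf
    sigma_raw = 1.4826 * float(np.median(np.abs(resid - np.median(resid))))
    sigma_inband = sigma_raw * np.sqrt(4.0 * params.fir_cutoff / rate)
    floor = max(params.amp_floor, params.noise_mult * sigma_inband)
    x = xf

    cand, props = signal.find_peaks(x, height=floor)
    if cand.size == 0:
        return []
    amps = props["peak_heights"]

    # non-maximum suppression within pp_min, larger amplitude wins
    order = np.argsort(-amps, kind="stable")
    keep = np.ones(cand.size, dtype=bool)
    min_gap = params.pp_min * rate
    accepted: list[int] = []
    for i in order:
        if any(abs(cand[i] - cand[j]) < min_gap for j in accepted):
            keep[i] = False
        else:
            accepted.append(i)

    out: list[StepPeak] = []
    recent: list[tuple[float, float]] = []  # (time, amplitude) of accepted
    for i in np.flatnonzero(keep):
        t = cand[i] / rate
        hist = [a for (tt, a) in recent if t - tt <= params.amp_window]
        thresh = floor
        if hist:
            thresh = max(thresh, params.amp_fraction * float(np.median(hist)))
        if amps[i] >= thresh:
            out.append(StepPeak(time=t, amplitude=float(amps[i])))
            recent.append((t, float(amps[i])))
    return out


def activity_regions(
    peak_times: list[float],
    min_peaks: int = 3,
    max_gap: float = 3.5,
    margin: float = 0.3,
) -> list[tuple[float, float]]:
    """Candidate walking regions from chained step peaks.

    Peaks closer than ``max_gap`` chain into one region; chains shorter than
    ``min_peaks`` are discarded as isolated transients. Regions are padded
    by ``margin`` on both sides.
    """
    regions = []
    chain: list[float] = []
    for t in list(peak_times) + [float("inf")]:
        if chain and t - chain[-1] > max_gap:
            if len(chain) >= min_peaks:
                regions.append((chain[0] - margin, chain[-1] + margin))
            chain = []
        if np.isfinite(t):
            chain.append(t)
    return regions


def events_to_frame(subject_id: str, ics: list[InitialContact], peaks: list[StepPeak]) -> pd.DataFrame:
    rows = [
        {"subject_id": subject_id, "time_s": ic.time, "amplitude_g": np.nan, "kind": "ic"}
        for ic in ics
    ] + [
        {"subject_id": subject_id, "time_s": p.time, "amplitude_g": p.amplitude, "kind": "step_peak"}
        for p in peaks
    ]
    return pd.DataFrame(rows, columns=["subject_id", "time_s", "amplitude_g", "kind"])
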