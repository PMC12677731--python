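"""Independent reference implementations used to check the package."""

from __future__ import annotations

import numpy as np

GAP_SLACK = 1.5


def oracle_assemble_bouts(times, default_step=0.7):
    """Brute-force maximal grouping under the inter-step gap predicate.

    A candidate group is re-validated from scratch for every extension
    (quadratic), instead of the package's running-state scan.
    """

    def valid(seq):
        if len(seq) < 2:
            return False
        for k in range(1, len(seq)):
            prev = np.diff(seq[:k])
            mean_step = float(prev.mean()) if prev.size else default_step
            if seq[k] - seq[k - 1] > GAP_SLACK + mean_step:
                return False
        return True

    times = list(times)
    groups = []
    i = 0
    while i < len(times):
        best_j = i + 1
        for j in range(i + 2, len(times) + 1):
            if valid(times[i:j]):
                best_j = j
            else:
                break
        if best_j - i >= 2:
            groups.append(times[i:best_j])
        i = best_j
    return groups


def match_f1(detected, truth, window=0.15):
    """Greedy one-to-one matching F1 between detected and true event times."""
    detected = list(detected)
    used = set()
    matched = 0
    for t in truth:
        best = None
        for i, d in enumerate(detected):
            if i in used or abs(d - t) > window:
                continue
            if best is None or abs(d - t) < abs(detected[best] - t):
                best = i
        if best is not None:
            used.add(best)
            matched += 1
    if not detected or len(truth) == 0:
        return 0.0
    precision = matched / len(detected)
    recall = matched / len(truth)
    if precision + recall == 0:
        return 0.0
    return 2 * precision * recall / (precision + recall)


def oracle_percentile(values, q):
    """Sort-and-interpolate percentile (1-based position 1 + q*(n-1))."""
    v = sorted(values)
    pos = q / 100.0 * (len(v) - 1)
    lo = int(np.floor(pos))
    hi = int(np.ceil(pos))
    frac = pos - lo
    return v[lo] * (1 - frac) + v[hi] * frac


def oracle_histogram_mode(values, bin_width):
    """Zero-anchored histogram mode, ties to the lower bin."""
    idx = [int(np.floor(v / bin_width)) for v in values]
    counts = {}
    for i in idx:
        counts[i] = counts.get(i, 0) + 1
    best = min(sorted(counts), key=lambda i: (-counts[i], i))
    return (best + 0.5) * bin_width


def walking_noise_sd(protocol_factory, snr_db, rate=100.0):
    """Noise sd giving the requested SNR vs the noise-free walking rms."""
    from dailygait.synthetic import synthesize_recording

    proto = protocol_factory(0.0)
    rec, truth = synthesize_recording(proto, rate=rate)
    ics = truth.ic_times
    i0 = int(ics[0] * rate)
    i1 = int(ics[-1] * rate)
    rms = np.sqrt(np.mean((rec.acc_v[i0:i1] - 1.0) ** 2))
    if np.isinf(snr_db):
        return 0.0
    return rms / 10 ** (snr_db / 20.0)
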