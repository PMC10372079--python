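"""Head-twitch response (HTR) detection from head-mounted accelerometer data.

A head twitch is a rapid lateral head rotation that shows up as a brief
8-32 Hz burst on the mediolateral accelerometer axis.  The detector
downsamples to 200 Hz, bandpass filters with a zero-phase order-100 FIR,
rectifies, and smooths with a unit-area Gaussian (sigma = 50 ms) to form an
HTR index in g; peaks above 0.4 g separated by more than a 1-s dead time are
events.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import List

import numpy as np
from scipy import signal as sps

__all__ = ["HtrParams", "HtrEvent", "htr_index", "detect_htr", "evaluate_detector", "DetectorMetrics"]


@dataclass(frozen=True)
class HtrParams:
    target_fs: float = 200.0  # Hz
    passband: tuple = (8.0, 32.0)  # Hz
    fir_order: int = 100
    gauss_sigma: float = 0.050  # s
    threshold: float = 0.4  # g
    dead_time: float = 1.0  # s

    def __post_init__(self):
        lo, hi = self.passband
        if not (0 < lo < hi < self.target_fs / 2):
            raise ValueError("passband must lie inside (0, target_fs/2)")


@dataclass(frozen=True)
class HtrEvent:
    time: float  # s, index peak
    index_value: float  # g


def htr_index(accel_ml, fs, params: HtrParams = HtrParams()):
    """HTR index series from the mediolateral acceleration trace.

    Returns ``(times, index)`` on the 200 Hz grid.  The Gaussian smoothing
    kernel is truncated at +/-4 sigma and normalized so that a sustained
    in-band oscillation of amplitude A g yields an index of ~A g (unit area
    times pi/2, compensating the 2/pi mean of rectification).
    """
    x = np.asarray(accel_ml, dtype=float)
    if fs < params.target_fs:
        raise ValueError("accelerometer rate below the 200 Hz analysis rate")
    if fs > params.target_fs:
        q = fs / params.target_fs
        if abs(q - round(q)) < 1e-9:
            x = sps.decimate(x, int(round(q)), zero_phase=True)
        else:
            from fractions import Fraction

            fr = Fraction(params.target_fs / fs).limit_denominator(1000)
            x = sps.resample_poly(x, fr.numerator, fr.denominator)
    fs = params.target_fs
    if len(x) <= 3 * params.fir_order:
        raise ValueError("trace shorter than the filter transient")
    taps = sps.firwin(params.fir_order + 1, list(params.passband), pass_zero=False, fs=fs)
    bp = sps.filtfilt(taps, [1.0], x)
    sigma_n = params.gauss_sigma * fs
    half = int(np.ceil(4 * sigma_n))
    k = np.exp(-0.5 * ((np.arange(-half, half + 1)) / sigma_n) ** 2)
    # unit-area kernel times pi/2: the mean of a rectified sinusoid is 2/pi of
    # its amplitude, so the index reads the burst amplitude in g
    k *= (np.pi / 2.0) / k.sum()
    index = np.convolve(np.abs(bp), k, mode="same")
    times = np.arange(len(index)) / fs
    return times, index


def detect_htr(times, index, params: HtrParams = HtrParams()) -> List[HtrEvent]:
    """Greedy peak picking on the HTR index with a dead-time exclusion.

    Local maxima above threshold are accepted in descending height; any
    candidate within the dead time of an accepted event is discarded, so twin
    twitches closer than the dead time merge into the larger one.
    """
    peaks, props = sps.find_peaks(index, height=params.threshold)
    if peaks.size == 0:
        return []
    order = np.argsort(props["peak_heights"])[::-1]
    accepted = []
    for i in order:
        t = times[peaks[i]]
        if all(abs(t - a) > params.dead_time for a in accepted):
            accepted.append(t)
    accepted.sort()
    lookup = {times[p]: index[p] for p in peaks}
    return [HtrEvent(time=float(t), index_value=float(lookup[t])) for t in accepted]


@dataclass
class DetectorMetrics:
    tpr: float  # matched / true events
    fp_rate: float  # unmatched detections / detections
    fp_per_min: float
    n_matched: int
    n_truth: int
    n_detected: int


def evaluate_detector(event_times, truth_times, tol=0.2, duration_s=None) -> DetectorMetrics:
    """Greedy one-to-one matching of detections to ground-truth twitch times.

    Each truth time is matched to the nearest unused detection within ``tol``
    seconds.  TPR = matched/truth; the false-positive rate is reported both
    per detection and per minute (when ``duration_s`` is given).
    """
    det = sorted(float(t) for t in event_times)
    truth = sorted(float(t) for t in truth_times)
    used = [False] * len(det)
    matched = 0
    for t in truth:
        best, best_d = None, tol
        for i, d in enumerate(det):
            if used[i]:
                continue
            dist = abs(d - t)
            if dist <= best_d:
                best, best_d = i, dist
        if best is not None:
            used[best] = True
            matched += 1
    n_det = len(det)
    n_fp = n_det - matched
    return DetectorMetrics(
        tpr=matched / len(truth) if truth else float("nan"),
        fp_rate=n_fp / n_det if n_det else 0.0,
        fp_per_min=n_fp / (duration_s / 60.0) if duration_s else float("nan"),
        n_matched=matched,
        n_truth=len(truth),
        n_detected=n_det,
    )
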