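"""Parametric HFO detection on fractal-normalized spectra.

A Gaussian-plus-line model is fitted to the rhythmicity spectrum S_dB(f)::

    y(f) = a1 * exp(-((f - a2) / a3)^2) + a4 * f + a5

a1 is the peak height (dB), a2 the peak frequency (Hz), a3 the width (Hz),
a4/a5 a linear background.  A window counts as a positive HFO detection when
the fit is good (R^2 above threshold) and all parameters fall inside
physiological bounds; detection rates per session are then summarized into
prevalence classes.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import curve_fit

from .irasa import SpectralFrame

__all__ = [
    "HfoFit",
    "DetectionCriteria",
    "peak_model",
    "fit_peak_model",
    "detection_rate",
    "prevalence_class",
    "median_hfo_frequency",
    "DEFAULT_FIT_BAND",
]

# The parameter bounds require the peak inside 90-170 Hz; the surrounding
# 70-200 Hz band gives the linear term leverage on both sides.
DEFAULT_FIT_BAND = (70.0, 200.0)


def peak_model(f, a1, a2, a3, a4, a5):
    return a1 * np.exp(-(((f - a2) / a3) ** 2)) + a4 * f + a5


@dataclass(frozen=True)
class DetectionCriteria:
    """Bounds for a positive HFO detection (strict inequalities)."""

    r2_min: float = 0.2
    a1_range: tuple = (2.0, 100.0)  # dB
    a2_range: tuple = (90.0, 170.0)  # Hz
    a3_range: tuple = (1.0, 20.0)  # Hz
    a4_range: tuple = (-1.0, 1.0)  # dB/Hz
    a5_range: tuple = (-10.0, 10.0)  # dB

    def check(self, params, r2) -> bool:
        a1, a2, a3, a4, a5 = params
        return bool(
            r2 > self.r2_min
            and self.a1_range[0] < a1 < self.a1_range[1]
            and self.a2_range[0] < a2 < self.a2_range[1]
            and self.a3_range[0] < a3 < self.a3_range[1]
            and self.a4_range[0] < a4 < self.a4_range[1]
            and self.a5_range[0] < a5 < self.a5_range[1]
        )


@dataclass
class HfoFit:
    a1: float
    a2: float
    a3: float
    a4: float
    a5: float
    r2: float
    detected: bool
    valid: bool = True

    @property
    def params(self):
        return (self.a1, self.a2, self.a3, self.a4, self.a5)


_A2_JITTER = (0.0, -10.0, 10.0, -5.0, 5.0)  # deterministic multi-start sequence


def fit_peak_model(s_db, freqs, fit_band=DEFAULT_FIT_BAND, criteria=DetectionCriteria()) -> HfoFit:
    """Nonlinear least-squares fit of the Gaussian+line model to one spectrum.

    Initialization places the peak at the argmax of S_dB inside the a2 bounds
    and the line through the band edges; five multi-starts jitter the initial
    peak frequency and the best residual wins.  Non-convergence of every start
    yields an invalid, non-detected fit.
    """
    s_db = np.asarray(s_db, dtype=float)
    freqs = np.asarray(freqs, dtype=float)
    band = (freqs >= fit_band[0]) & (freqs <= fit_band[1])
    f = freqs[band]
    y = s_db[band]
    if f.size < 20:
        raise ValueError("need at least 20 frequency points in the fit band")

    inner = (f > criteria.a2_range[0]) & (f < criteria.a2_range[1])
    f_inner = f[inner] if np.any(inner) else f
    y_inner = y[inner] if np.any(inner) else y
    a4_0 = (y[-1] - y[0]) / (f[-1] - f[0])
    a5_0 = y[0] - a4_0 * f[0]
    a2_0 = float(f_inner[np.argmax(y_inner)])
    a1_0 = float(max(y_inner.max() - (a4_0 * a2_0 + a5_0), 0.5))

    sstot = float(np.sum((y - y.mean()) ** 2))
    best = None
    lo = [-100.0, fit_band[0], 0.2, -50.0, -200.0]
    hi = [200.0, fit_band[1], 100.0, 50.0, 200.0]
    for jitter in _A2_JITTER:
        p0 = [a1_0, float(np.clip(a2_0 + jitter, *fit_band)), 5.0, a4_0, a5_0]
        try:
            popt, _ = curve_fit(peak_model, f, y, p0=p0, bounds=(lo, hi), maxfev=5000)
        except (RuntimeError, ValueError):
            continue
        ssres = float(np.sum((y - peak_model(f, *popt)) ** 2))
        if best is None or ssres < best[1]:
            best = (popt, ssres)
    if best is None:
        return HfoFit(np.nan, np.nan, np.nan, np.nan, np.nan, 0.0, detected=False, valid=False)
    popt, ssres = best
    r2 = 1.0 - ssres / sstot if sstot > 0 else 1.0
    detected = criteria.check(popt, r2)
    return HfoFit(*[float(p) for p in popt], r2=float(r2), detected=detected)


def detection_rate(frames, fit_band=DEFAULT_FIT_BAND, criteria=DetectionCriteria()):
    """Fraction of spectral frames with a positive detection.

    Each frame is expected to be a (per-window) structure-averaged spectrum.
    Returns ``(rate, fits)``.
    """
    if not frames:
        raise ValueError("detection_rate requires at least one frame")
    fits = []
    for fr in frames:
        if isinstance(fr, SpectralFrame):
            fits.append(fit_peak_model(fr.S_dB, fr.freqs, fit_band, criteria))
        else:  # (freqs, s_db) pair
            fits.append(fit_peak_model(fr[1], fr[0], fit_band, criteria))
    rate = float(np.mean([f.detected for f in fits]))
    return rate, fits


def prevalence_class(session_rates) -> str:
    """Classify per-session detection rates for one (structure, condition).

    persistent: >90% detections in >1/3 of sessions; prevalent: >50%
    detections in >1/3 of sessions; absent: >5% detections in <5% of
    sessions; occasional otherwise.  Checked in that order, so the classes
    are exhaustive and mutually exclusive.
    """
    rates = np.asarray(session_rates, dtype=float)
    if rates.size == 0:
        raise ValueError("prevalence_class requires at least one session rate")
    if np.mean(rates > 0.9) > 1.0 / 3.0:
        return "persistent"
    if np.mean(rates > 0.5) > 1.0 / 3.0:
        return "prevalent"
    if np.mean(rates > 0.05) < 0.05:
        return "absent"
    return "occasional"


def median_hfo_frequency(fits) -> float:
    """Median fitted peak frequency over the detected fits of a recording.

    This is the narrowband center used for phase analysis; with no detections
    there is no HFO band, so the caller should skip phase analysis.
    """
    a2 = [f.a2 for f in fits if f.detected]
    if not a2:
        raise ValueError("no detected HFO fits; skip phase analysis for this recording")
    return float(np.median(a2))
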