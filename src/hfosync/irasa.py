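"""Fractal/oscillatory spectral separation (IRASA) and the fractal-normalized
rhythmicity spectrum.

The power spectrum of each 50%-overlapping 8-s window is split into a total
PSD ``S`` and an arrhythmic "fractal" component ``S_fractal`` estimated by
irregular resampling: for each non-integer factor h, the signal is resampled
by h and by 1/h, the geometric mean of the two PSDs is taken (which leaves a
power-law spectrum invariant while displacing narrowband peaks), and the
median over the h-set removes the displaced peaks.  Rhythmicity is expressed
in decibels relative to the fractal background::

    S_dB(f) = 10 * log10( S(f) / S_fractal(f) )

so 0 dB means no rhythmic excess.

Numerical choices: the total PSD is a Hann-tapered, mean-detrended
periodogram at the native 1/window_s resolution; the fractal component —
smooth in frequency by assumption — is estimated with Welch sub-segmenting
(lower variance, coarser grid) and interpolated onto the fine grid in
log-log coordinates.
"""
from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction

import numpy as np
from scipy import signal as sps

from .session import Epoch

__all__ = ["SpectralFrame", "irasa", "average_spectrum", "DEFAULT_HSET"]

# Resampling factor set of the original IRASA formulation.
DEFAULT_HSET = tuple(np.round(np.arange(1.1, 1.95, 0.05), 2))

_PSD_FLOOR = 1e-20


@dataclass
class SpectralFrame:
    """One spectral estimate: total and fractal PSD plus the dB_fractal ratio."""

    freqs: np.ndarray  # Hz
    S: np.ndarray  # total PSD, uV^2/Hz
    S_fractal: np.ndarray  # fractal PSD, uV^2/Hz
    t_center: float  # s, window center

    @property
    def S_dB(self) -> np.ndarray:
        return 10.0 * np.log10(np.maximum(self.S, _PSD_FLOOR) / np.maximum(self.S_fractal, _PSD_FLOOR))


def _fractal_psd(x, fs, hset, nperseg):
    """Median-over-h geometric-mean PSD of h- and 1/h-resampled copies.

    Returns (freqs, psd) on the Welch grid of ``nperseg``, valid up to
    fs / (2 * max(hset)).
    """
    geos = []
    f_ref = None
    for h in hset:
        frac = Fraction(h).limit_denominator(20)
        up, down = frac.numerator, frac.denominator
        x_up = sps.resample_poly(x, up, down)
        x_dn = sps.resample_poly(x, down, up)
        f_u, p_u = sps.welch(x_up, fs=fs, window="hann", nperseg=min(nperseg, len(x_up)))
        f_d, p_d = sps.welch(x_dn, fs=fs, window="hann", nperseg=min(nperseg, len(x_dn)))
        if f_ref is None:
            f_ref = f_u
        if len(p_u) != len(f_ref):
            p_u = np.interp(f_ref, f_u, p_u)
        if len(p_d) != len(f_ref):
            p_d = np.interp(f_ref, f_d, p_d)
        geos.append(np.sqrt(np.maximum(p_u, _PSD_FLOOR) * np.maximum(p_d, _PSD_FLOOR)))
    return f_ref, np.median(np.asarray(geos), axis=0)


def irasa(x, fs, window_s=8.0, overlap=0.5, hset=DEFAULT_HSET, fractal_seg_s=2.0):
    """Windowed IRASA spectrogram of a single-channel signal.

    Parameters
    ----------
    x : array
        Signal in microvolts.
    fs : float
        Sampling rate, Hz; should be at least 4x the highest analysis
        frequency so the resampled copies retain the band of interest.
    window_s, overlap :
        Spectrogram windowing (8-s windows, 50% overlap by default; grid
        spacing 1/window_s = 0.125 Hz).
    hset : sequence of float
        Irregular resampling factors.
    fractal_seg_s : float
        Welch sub-segment length used for the fractal component.

    Returns
    -------
    list of SpectralFrame, one per window, ``t_center`` at window centers.
    """
    x = np.asarray(x, dtype=float)
    nwin = int(round(window_s * fs))
    if len(x) < nwin:
        raise ValueError("signal shorter than one spectral window")
    step = max(1, int(round(nwin * (1.0 - overlap))))
    nseg = int(round(fractal_seg_s * fs))
    hmax = max(hset)
    frames = []
    for start in range(0, len(x) - nwin + 1, step):
        w = x[start : start + nwin]
        w = w - w.mean()
        f_fine, S = sps.periodogram(w, fs=fs, window="hann")
        f_fine, S = f_fine[1:], S[1:]  # drop DC
        f_c, frac = _fractal_psd(w, fs, hset, nseg)
        # keep only the band where all resampled copies carry signal
        valid = (f_c > 0) & (f_c <= fs / (2.0 * hmax))
        logf_c = np.log(f_c[valid])
        logp_c = np.log(np.maximum(frac[valid], _PSD_FLOOR))
        # log-log interpolation; linear extrapolation continues the power law
        logp = np.interp(np.log(f_fine), logf_c, logp_c)
        tail = np.log(f_fine) > logf_c[-1]
        if np.any(tail) and len(logf_c) > 4:
            slope = (logp_c[-1] - logp_c[-5]) / (logf_c[-1] - logf_c[-5])
            logp[tail] = logp_c[-1] + slope * (np.log(f_fine[tail]) - logf_c[-1])
        S_fractal = np.exp(logp)
        frames.append(
            SpectralFrame(freqs=f_fine, S=S, S_fractal=S_fractal, t_center=(start + nwin / 2.0) / fs)
        )
    return frames


def average_spectrum(frames, epoch: Epoch | None = None, injection_time: float = 0.0) -> SpectralFrame:
    """Average spectral frames in the linear power domain.

    ``S`` and ``S_fractal`` are averaged arithmetically across windows and the
    dB ratio is recomputed from the means.  With ``epoch`` given, only windows
    whose center time falls inside ``[injection_time + epoch.start,
    injection_time + epoch.end)`` contribute.
    """
    if epoch is not None:
        t0, t1 = injection_time + epoch.start, injection_time + epoch.end
        frames = [fr for fr in frames if t0 <= fr.t_center < t1]
    if not frames:
        raise ValueError("no spectral frames within the requested epoch")
    S = np.mean([fr.S for fr in frames], axis=0)
    S_fractal = np.mean([fr.S_fractal for fr in frames], axis=0)
    t = float(np.mean([fr.t_center for fr in frames]))
    return SpectralFrame(freqs=frames[0].freqs, S=S, S_fractal=S_fractal, t_center=t)
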