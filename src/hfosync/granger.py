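"""Bivariate spectral Granger causality between LFP pairs.

A VAR model is fitted by least squares to short windows pooled as trials
(regressors never cross a window boundary), and Geweke's frequency-domain
causality is computed from the VAR transfer function::

    f_{x->y}(w) = ln( S_yy(w) / (S_yy(w) - (Sig_xx - Sig_xy^2/Sig_yy) |H_yx(w)|^2) )

where H = (I - sum_k A_k e^{-iwk})^{-1} and Sig is the residual covariance.
Signals are expected at ~1 kHz so that a 5th-order model over 500-ms windows
can express structure around 150 Hz.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

__all__ = ["VarFit", "GcSpectrum", "fit_var_windows", "gc_spectrum", "var_psd", "band_summary", "simulate_var"]


@dataclass
class VarFit:
    coeffs: np.ndarray  # (order, 2, 2); x_t = sum_k A_k x_{t-k} + eps
    sigma: np.ndarray  # residual covariance (2, 2)
    fs: float
    order: int
    n_windows: int

    def spectral_radius(self) -> float:
        p = self.order
        companion = np.zeros((2 * p, 2 * p))
        for k in range(p):
            companion[0:2, 2 * k : 2 * k + 2] = self.coeffs[k]
        if p > 1:
            companion[2:, :-2] = np.eye(2 * (p - 1))
        return float(np.max(np.abs(np.linalg.eigvals(companion))))


@dataclass
class GcSpectrum:
    freqs: np.ndarray
    gc_xy: np.ndarray  # causality x -> y
    gc_yx: np.ndarray  # causality y -> x


def fit_var_windows(x, y, fs, window_s=0.5, order=5) -> VarFit:
    """Least-squares VAR fit pooling non-overlapping windows as trials.

    Each window is linearly detrended; lagged regressors are built within
    windows only, and the residual covariance is pooled over all windows.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    nwin = int(round(window_s * fs))
    n_windows = len(x) // nwin
    if n_windows < 20:
        raise ValueError("need at least 20 windows for a stable VAR fit")
    rows_X, rows_Y = [], []
    for w in range(n_windows):
        seg = np.stack(
            [
                sps.detrend(x[w * nwin : (w + 1) * nwin]),
                sps.detrend(y[w * nwin : (w + 1) * nwin]),
            ]
        )  # (2, nwin)
        for t in range(order, nwin):
            rows_Y.append(seg[:, t])
            rows_X.append(seg[:, t - order : t][:, ::-1].T.reshape(-1))  # lag 1..order, each (x,y)
    X = np.asarray(rows_X)  # (n, 2*order)
    Y = np.asarray(rows_Y)  # (n, 2)
    gram = X.T @ X
    cond = np.linalg.cond(gram)
    if not np.isfinite(cond) or cond > 1e12:
        raise ValueError("ill-conditioned VAR regression; consider downsampling the signals")
    B = np.linalg.solve(gram, X.T @ Y)  # (2*order, 2)
    resid = Y - X @ B
    sigma = resid.T @ resid / (len(Y) - 2 * order)
    coeffs = np.empty((order, 2, 2))
    for k in range(order):
        coeffs[k] = B[2 * k : 2 * k + 2, :].T  # A_k maps state(t-k-1) -> state(t)
    return VarFit(coeffs=coeffs, sigma=sigma, fs=fs, order=order, n_windows=n_windows)


def _transfer(var_fit: VarFit, freqs):
    """Transfer function H(w) = (I - sum A_k e^{-iwk})^{-1} on a frequency grid."""
    w = 2.0 * np.pi * np.asarray(freqs, float) / var_fit.fs
    H = np.empty((len(w), 2, 2), dtype=complex)
    for i, wi in enumerate(w):
        A = np.eye(2, dtype=complex)
        for k in range(var_fit.order):
            A -= var_fit.coeffs[k] * np.exp(-1j * wi * (k + 1))
        H[i] = np.linalg.inv(A)
    return H


def var_psd(var_fit: VarFit, freqs):
    """Model-implied one-sided PSD matrix S(f) = 2/fs * H Sig H^* on the grid."""
    H = _transfer(var_fit, freqs)
    S = H @ var_fit.sigma @ np.conj(np.transpose(H, (0, 2, 1)))
    return 2.0 / var_fit.fs * S


def gc_spectrum(var_fit: VarFit, freqs=None) -> GcSpectrum:
    """Geweke's bivariate frequency-domain causality in both directions."""
    if var_fit.spectral_radius() >= 1.0:
        raise ValueError("unstable VAR model (spectral radius >= 1)")
    if freqs is None:
        freqs = np.arange(1.0, var_fit.fs / 2.0, 1.0)
    freqs = np.asarray(freqs, dtype=float)
    H = _transfer(var_fit, freqs)
    sig = var_fit.sigma
    S = H @ sig @ np.conj(np.transpose(H, (0, 2, 1)))
    S_xx = np.real(S[:, 0, 0])
    S_yy = np.real(S[:, 1, 1])
    # conditional noise powers
    c_x = sig[0, 0] - sig[0, 1] ** 2 / sig[1, 1]  # x-noise not predictable from y-noise
    c_y = sig[1, 1] - sig[0, 1] ** 2 / sig[0, 0]
    gc_xy = np.log(S_yy / np.maximum(S_yy - c_x * np.abs(H[:, 1, 0]) ** 2, 1e-300))
    gc_yx = np.log(S_xx / np.maximum(S_xx - c_y * np.abs(H[:, 0, 1]) ** 2, 1e-300))
    return GcSpectrum(freqs=freqs, gc_xy=np.maximum(gc_xy, 0.0), gc_yx=np.maximum(gc_yx, 0.0))


def _highest_peak(freqs, gc, f_range=None):
    """Highest local maximum of a causality spectrum; None if no peak."""
    if f_range is not None:
        m = (freqs >= f_range[0]) & (freqs <= f_range[1])
        freqs, gc = freqs[m], gc[m]
    idx, _ = sps.find_peaks(gc)
    if idx.size == 0:
        return None
    best = idx[np.argmax(gc[idx])]
    return float(freqs[best]), float(gc[best])


def band_summary(pair_spectra, hfo_freq, peak_min=0.2, gamma_band=(25.0, 75.0), f_range=None):
    """Structure-pair summary of Granger causality spectra.

    ``pair_spectra`` is a list of ``((struct_x, struct_y), GcSpectrum)``.
    For each ordered structure pair the median height of the highest spectral
    peak is taken over electrode pairs whose peak exceeds ``peak_min``;
    the mean causality in the HFO band (hfo_freq +/- 10 Hz) and the gamma
    band is also reported, along with the pooled peak-frequency histogram.
    Pairs with no qualifying peak are recorded as missing.
    """
    hfo_band = (hfo_freq - 10.0, hfo_freq + 10.0)
    peaks = {}
    bands = {}
    peak_freqs = []
    for (sx, sy), spec in pair_spectra:
        for direction, gc in ((f"{sx}->{sy}", spec.gc_xy), (f"{sy}->{sx}", spec.gc_yx)):
            pk = _highest_peak(spec.freqs, gc, f_range)
            if pk is not None and pk[1] >= peak_min:
                peaks.setdefault(direction, []).append(pk[1])
                peak_freqs.append(pk[0])
            hfo_m = (spec.freqs >= hfo_band[0]) & (spec.freqs <= hfo_band[1])
            gam_m = (spec.freqs >= gamma_band[0]) & (spec.freqs <= gamma_band[1])
            bands.setdefault(direction, []).append(
                (float(gc[hfo_m].mean()) if hfo_m.any() else np.nan,
                 float(gc[gam_m].mean()) if gam_m.any() else np.nan)
            )
    summary = {}
    directions = set(peaks) | set(bands)
    for d in directions:
        hfo_means = [b[0] for b in bands.get(d, [])]
        gam_means = [b[1] for b in bands.get(d, [])]
        summary[d] = {
            "median_peak": float(np.median(peaks[d])) if d in peaks else None,  # None = missing
            "n_qualifying": len(peaks.get(d, [])),
            "mean_gc_hfo_band": float(np.nanmean(hfo_means)) if hfo_means else np.nan,
            "mean_gc_gamma_band": float(np.nanmean(gam_means)) if gam_means else np.nan,
        }
    return summary, np.asarray(peak_freqs)


def simulate_var(coeffs, sigma, n_samples, seed=0, burn=500):
    """Simulate a bivariate VAR given coefficient matrices and noise covariance."""
    coeffs = np.asarray(coeffs, dtype=float)
    order = coeffs.shape[0]
    rng = np.random.default_rng(seed)
    L = np.linalg.cholesky(np.asarray(sigma, float))
    eps = rng.standard_normal((n_samples + burn, 2)) @ L.T
    out = np.zeros((n_samples + burn, 2))
    for t in range(order, n_samples + burn):
        acc = eps[t].copy()
        for k in range(order):
            acc += coeffs[k] @ out[t - k - 1]
        out[t] = acc
    return out[burn:, 0], out[burn:, 1]
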