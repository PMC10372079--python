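"""Spike-train analysis: firing-rate standardization and modulation tests,
waveform-based cell-type classification, spike-HFO entrainment, and the
Bhattacharyya distance between population-modulation clusters.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy.stats import binomtest, mannwhitneyu

from .circstats import circ_summary, rayleigh_test, vonmises_fit, wrap_angle
from .session import Epoch

__all__ = [
    "RateModulation",
    "WaveformFeatures",
    "EntrainmentResult",
    "bin_counts",
    "standardize_rates",
    "unit_modulation",
    "population_modulation_pvalue",
    "waveform_features",
    "fuzzy_kmeans",
    "classify_cells",
    "spike_entrainment",
    "bhattacharyya",
]

MODULATION_ALPHA = 0.01
ENTRAINMENT_ALPHA = 0.001


def bin_counts(spike_times, t0, t1, bin_s=10.0):
    """Spike counts in consecutive ``bin_s`` bins covering [t0, t1)."""
    n_bins = int(np.floor((t1 - t0) / bin_s))
    if n_bins < 1:
        raise ValueError("epoch shorter than one bin")
    edges = t0 + bin_s * np.arange(n_bins + 1)
    counts, _ = np.histogram(np.asarray(spike_times, float), bins=edges)
    return counts


@dataclass
class RateModulation:
    z_baseline: np.ndarray  # per-bin standardized rate, baseline epoch
    z_drug: np.ndarray
    mean_z_drug: float
    p_value: float
    mod_class: str  # {"up", "down", "none"}
    excluded: bool = False
    reason: str = ""


def standardize_rates(spike_times, injection_time, baseline: Epoch, drug: Epoch, bin_s=10.0):
    """Standardized per-bin firing rates: z = (rate - mean_base) / sd_base.

    Spike times are binned in 10-s bins within each epoch; baseline mean and
    SD define the z transform applied to both epochs.  A unit with zero
    baseline SD cannot be standardized and is excluded with a reason code.
    Returns ``(z_baseline, z_drug)`` or ``(None, reason)``.
    """
    base = bin_counts(spike_times, injection_time + baseline.start, injection_time + baseline.end, bin_s)
    dr = bin_counts(spike_times, injection_time + drug.start, injection_time + drug.end, bin_s)
    if len(base) < 10 or len(dr) < 10:
        return None, "fewer than 10 bins in an epoch"
    mu, sd = base.mean(), base.std(ddof=0)
    if sd == 0:
        return None, "zero baseline SD"
    return ((base - mu) / sd, (dr - mu) / sd), ""


def unit_modulation(spike_times, injection_time, baseline: Epoch, drug: Epoch,
                    bin_s=10.0, alpha=MODULATION_ALPHA) -> RateModulation:
    """Rate-modulation class of one unit (Wilcoxon rank-sum on 10-s counts).

    "up" when the drug-epoch median count is significantly above baseline at
    ``alpha``, "down" when below, "none" otherwise.
    """
    base = bin_counts(spike_times, injection_time + baseline.start, injection_time + baseline.end, bin_s)
    dr = bin_counts(spike_times, injection_time + drug.start, injection_time + drug.end, bin_s)
    z, reason = standardize_rates(spike_times, injection_time, baseline, drug, bin_s)
    if z is None:
        return RateModulation(np.array([]), np.array([]), np.nan, np.nan, "none", excluded=True, reason=reason)
    z_base, z_drug = z
    p = float(mannwhitneyu(dr, base, alternative="two-sided", method="asymptotic").pvalue)
    if p < alpha:
        mod = "up" if np.median(dr) > np.median(base) else "down"
        if np.median(dr) == np.median(base):
            mod = "up" if dr.mean() > base.mean() else "down"
    else:
        mod = "none"
    return RateModulation(z_base, z_drug, float(z_drug.mean()), p, mod)


def population_modulation_pvalue(n_modulated, n_units, alpha=MODULATION_ALPHA):
    """Binomial tail probability that at least ``n_modulated`` of ``n_units``
    are flagged in one direction by chance (chance = alpha/2 per tail)."""
    return float(binomtest(n_modulated, n_units, p=alpha / 2.0, alternative="greater").pvalue)


@dataclass
class WaveformFeatures:
    valley_width: float  # ms, FWHM
    peak_width: float  # ms, FWHM
    peak_to_valley: float  # ms
    reliable: bool = True


def _fwhm(t, y, i_ext):
    """FWHM around extremum index ``i_ext`` by linear interpolation at the
    half-extremum crossings (y must be positive at the extremum)."""
    half = y[i_ext] / 2.0
    left = np.nonzero(y[: i_ext + 1] <= half)[0]
    right = np.nonzero(y[i_ext:] <= half)[0]
    if left.size == 0 or right.size == 0:
        return float("nan")
    i = left[-1]
    tl = np.interp(half, [y[i], y[i + 1]], [t[i], t[i + 1]])
    j = i_ext + right[0]
    tr = np.interp(half, [y[j], y[j - 1]], [t[j], t[j - 1]])
    return float(tr - tl)


def waveform_features(waveform, wf_fs) -> WaveformFeatures:
    """Valley width, peak width (both FWHM, ms) and peak-to-valley time.

    Assumes the standard negative-first extracellular convention: a dominant
    valley followed by a repolarization peak.  A monophasic waveform (no
    positive peak after the valley) yields features flagged unreliable.
    """
    w = np.asarray(waveform, dtype=float)
    t = np.arange(len(w)) / wf_fs * 1e3  # ms
    i_valley = int(np.argmin(w))
    after = w[i_valley:]
    if after.size < 3 or after.max() <= 0:
        return WaveformFeatures(float("nan"), float("nan"), float("nan"), reliable=False)
    i_peak = i_valley + int(np.argmax(after))
    valley_width = _fwhm(t, -w, i_valley)
    peak_width = _fwhm(t, w, i_peak)
    return WaveformFeatures(
        valley_width=valley_width,
        peak_width=peak_width,
        peak_to_valley=float(t[i_peak] - t[i_valley]),
        reliable=np.isfinite(valley_width) and np.isfinite(peak_width),
    )


def fuzzy_kmeans(X, k=2, m=2.0, n_restarts=10, max_iter=300, tol=1e-8, seed=0):
    """Fuzzy c-means clustering (fuzzifier m), best of ``n_restarts`` seeded
    restarts by objective.  Returns (memberships n x k, centers k x d)."""
    X = np.asarray(X, dtype=float)
    n = len(X)
    best = None
    for r in range(n_restarts):
        rng = np.random.default_rng(seed + r)
        U = rng.dirichlet(np.ones(k), size=n)
        for _ in range(max_iter):
            Um = U**m
            centers = (Um.T @ X) / Um.sum(axis=0)[:, None]
            d2 = ((X[:, None, :] - centers[None, :, :]) ** 2).sum(axis=2)
            d2 = np.maximum(d2, 1e-12)
            inv = d2 ** (-1.0 / (m - 1.0))
            U_new = inv / inv.sum(axis=1, keepdims=True)
            if np.max(np.abs(U_new - U)) < tol:
                U = U_new
                break
            U = U_new
        obj = float(((U**m) * d2).sum())
        if best is None or obj < best[0]:
            best = (obj, U, centers)
    return best[1], best[2]


def classify_cells(features, membership_min=0.75, seed=0):
    """Putative cell-type labels from waveform features.

    ``features`` is an (n_units, n_features) array whose last column must be
    the peak-to-valley time (narrow-spiking cells are putative interneurons).
    Features are z-scored and partitioned with 2-cluster fuzzy k-means; units
    whose maximum membership does not exceed ``membership_min`` are labeled
    "X" (unclassified).  Returns an array of labels in {"PC", "IN", "X"}.
    """
    X = np.asarray(features, dtype=float)
    if len(X) < 20:
        raise ValueError("classify_cells requires at least 20 units")
    sd = X.std(axis=0, ddof=0)
    if np.any(sd == 0):
        raise ValueError("degenerate features: zero variance column")
    Z = (X - X.mean(axis=0)) / sd
    U, _ = fuzzy_kmeans(Z, k=2, seed=seed)
    hard = np.argmax(U, axis=1)
    # cluster with the smaller mean peak-to-valley time = narrow-spiking = IN
    p2v = X[:, -1]
    means = [p2v[hard == c].mean() if np.any(hard == c) else np.inf for c in (0, 1)]
    in_cluster = int(np.argmin(means))
    labels = np.where(hard == in_cluster, "IN", "PC")
    labels = np.where(U.max(axis=1) > membership_min, labels, "X")
    return labels


@dataclass
class EntrainmentResult:
    unit_id: str
    mu: float  # preferred phase, rad, trough-at-zero convention
    kappa: float
    rayleigh_p: float
    entrained: bool
    n_spikes: int
    skipped: bool = False
    reason: str = ""


def spike_entrainment(spike_times, phase_by_channel, fs, unit_electrode,
                      eligible_channels=None, unit_id="", min_spikes=50,
                      alpha=ENTRAINMENT_ALPHA) -> EntrainmentResult:
    """Entrainment of one unit to the HFO phase of its own structure.

    ``phase_by_channel`` maps channel_id -> instantaneous phase series (same
    sample grid, trough-at-zero).  To avoid spike leakage into the phase
    estimate, the unit's own electrode is excluded; the spike phase is the
    circular mean of the remaining same-structure channels' phases at each
    spike time.  Entrainment is a Rayleigh test at ``alpha``.
    """
    if eligible_channels is None:
        eligible_channels = [c for c in phase_by_channel if c != unit_electrode]
    eligible_channels = [c for c in eligible_channels if c != unit_electrode]
    if not eligible_channels:
        return EntrainmentResult(unit_id, np.nan, np.nan, np.nan, False, 0,
                                 skipped=True, reason="no eligible channel")
    n_samples = len(phase_by_channel[eligible_channels[0]])
    idx = np.round(np.asarray(spike_times, float) * fs).astype(int)
    idx = idx[(idx >= 0) & (idx < n_samples)]
    if idx.size < min_spikes:
        return EntrainmentResult(unit_id, np.nan, np.nan, np.nan, False, int(idx.size),
                                 skipped=True, reason="too few spikes")
    z = np.zeros(idx.size, dtype=complex)
    for ch in eligible_channels:
        z += np.exp(1j * np.asarray(phase_by_channel[ch])[idx])
    phases = wrap_angle(np.angle(z))
    mu, kappa = vonmises_fit(phases)
    p = rayleigh_test(phases)
    return EntrainmentResult(unit_id, mu, kappa, p, bool(p < alpha), int(idx.size))


def bhattacharyya(points_a, points_b):
    """Bhattacharyya distance between two point clouds under Gaussian moments.

    D_B = 1/8 (mu_a - mu_b)^T Sbar^{-1} (mu_a - mu_b)
          + 1/2 ln( |Sbar| / sqrt(|Sa| |Sb|) ),   Sbar = (Sa + Sb) / 2

    computed from the sample means and covariances.
    """
    A = np.asarray(points_a, dtype=float)
    B = np.asarray(points_b, dtype=float)
    if A.shape[0] < 3 or B.shape[0] < 3 or A.shape[1] < 2:
        raise ValueError("need >=3 points per cluster in >=2 dimensions")
    mu_a, mu_b = A.mean(axis=0), B.mean(axis=0)
    Sa = np.cov(A, rowvar=False)
    Sb = np.cov(B, rowvar=False)
    Sbar = (Sa + Sb) / 2.0
    sign, logdet_bar = np.linalg.slogdet(Sbar)
    if sign <= 0:
        raise ValueError("singular pooled covariance; consider regularizing the features")
    d = mu_a - mu_b
    term1 = float(d @ np.linalg.solve(Sbar, d)) / 8.0
    _, logdet_a = np.linalg.slogdet(Sa)
    _, logdet_b = np.linalg.slogdet(Sb)
    term2 = 0.5 * (logdet_bar - 0.5 * (logdet_a + logdet_b))
    return term1 + term2
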