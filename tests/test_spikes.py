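import numpy as np
import pytest

from hfosync.session import Epoch
from hfosync.spikes import (
    bhattacharyya,
    bin_counts,
    classify_cells,
    population_modulation_pvalue,
    spike_entrainment,
    standardize_rates,
    unit_modulation,
    waveform_features,
)

BASE = Epoch("baseline", -1800.0, 0.0)
DRUG = Epoch("drug", 0.0, 1800.0)
INJ = 1800.0


def _poisson_train(rate_base, rate_drug, duration=3600.0, seed=0):
    rng = np.random.default_rng(seed)
    n1 = rng.poisson(rate_base * 1800.0)
    n2 = rng.poisson(rate_drug * 1800.0)
    return np.sort(np.concatenate([rng.uniform(0, 1800, n1), rng.uniform(1800, 3600, n2)]))


def test_standardization_identity():
    spk = _poisson_train(2.0, 2.0, seed=1)
    (z_base, z_drug), _ = standardize_rates(spk, INJ, BASE, DRUG)
    assert z_base.mean() == pytest.approx(0.0, abs=1e-12)
    assert z_base.std() == pytest.approx(1.0, abs=1e-12)
    assert abs(z_drug.mean()) < 0.3  # null case


def test_poisson_step_z_magnitude():
    """lambda 2 -> 4 Hz: mean drug z per 10-s bin is (40-20)/sqrt(20) ~ 4.5."""
    zs = []
    for seed in range(8):
        (_, z_drug), _ = standardize_rates(_poisson_train(2.0, 4.0, seed=seed), INJ, BASE, DRUG)
        zs.append(z_drug.mean())
    assert np.mean(zs) == pytest.approx(20.0 / np.sqrt(20.0), abs=0.7)


def test_zero_baseline_sd_excluded():
    z, reason = standardize_rates(np.array([2000.0, 2500.0]), INJ, BASE, DRUG)
    assert z is None and "zero baseline SD" in reason
    rm = unit_modulation(np.array([2000.0, 2500.0]), INJ, BASE, DRUG)
    assert rm.excluded


def test_modulation_type1_calibration():
    """Null Poisson units are flagged at ~1% (alpha=0.01)."""
    flagged = 0
    n_units = 2000
    rng = np.random.default_rng(5)
    for i in range(n_units):
        spk = _poisson_train(2.0, 2.0, seed=1000 + i)
        rm = unit_modulation(spk, INJ, BASE, DRUG)
        flagged += rm.mod_class != "none"
    assert flagged / n_units == pytest.approx(0.01, abs=0.006)


def test_modulation_power_and_direction():
    """lambda 1 -> 3 Hz over 180+180 bins is always detected as 'up'."""
    for seed in range(25):
        rm = unit_modulation(_poisson_train(1.0, 3.0, seed=seed), INJ, BASE, DRUG)
        assert rm.mod_class == "up"
    down = unit_modulation(_poisson_train(3.0, 1.0, seed=99), INJ, BASE, DRUG)
    assert down.mod_class == "down"


def test_population_binomial_tail():
    """40 of 100 units down at alpha=0.01 is overwhelmingly above the 0.5%
    per-tail chance level."""
    assert population_modulation_pvalue(40, 100) < 1e-10
    assert population_modulation_pvalue(1, 100) > 0.05


def test_waveform_gaussian_valley_fwhm():
    wf_fs = 32000.0
    t = np.arange(int(0.004 * wf_fs)) / wf_fs
    sigma = 1e-4  # 0.1 ms
    w = -np.exp(-0.5 * ((t - 0.0015) / sigma) ** 2) + 0.4 * np.exp(-0.5 * ((t - 0.0025) / 2e-4) ** 2)
    f = waveform_features(w, wf_fs)
    assert f.valley_width == pytest.approx(2.3548 * 0.1, abs=0.01)
    assert f.peak_to_valley == pytest.approx(1.0, abs=0.05)


def test_waveform_time_stretch_equivariance():
    wf_fs = 32000.0
    t = np.arange(int(0.006 * wf_fs)) / wf_fs
    base = -np.exp(-0.5 * ((t - 0.0015) / 1e-4) ** 2) + 0.4 * np.exp(-0.5 * ((t - 0.0025) / 2e-4) ** 2)
    f1 = waveform_features(base, wf_fs)
    f2 = waveform_features(base, wf_fs / 2.0)  # same samples read at half rate = 2x stretch
    assert f2.valley_width == pytest.approx(2 * f1.valley_width, rel=1e-6)
    assert f2.peak_width == pytest.approx(2 * f1.peak_width, rel=1e-6)
    assert f2.peak_to_valley == pytest.approx(2 * f1.peak_to_valley, rel=1e-6)


def test_monophasic_waveform_flagged():
    wf_fs = 32000.0
    t = np.arange(96) / wf_fs
    w = -np.exp(-0.5 * ((t - 0.0015) / 1e-4) ** 2)
    assert not waveform_features(w, wf_fs).reliable


def test_classify_separated_clusters():
    rng = np.random.default_rng(0)
    a = rng.multivariate_normal([0.25, 0.3, 0.25], np.diag([0.002, 0.002, 0.002]), 40)  # narrow = IN
    b = rng.multivariate_normal([0.45, 0.6, 0.60], np.diag([0.002, 0.002, 0.002]), 40)  # broad = PC
    X = np.vstack([a, b])
    labels = classify_cells(X)
    truth = np.array(["IN"] * 40 + ["PC"] * 40)
    classified = labels != "X"
    assert np.mean(labels[classified] == truth[classified]) >= 0.95
    assert np.mean(~classified) < 0.10


def test_classify_ambiguous_point_is_x():
    rng = np.random.default_rng(1)
    a = rng.normal(-2.0, 0.3, (30, 2))
    b = rng.normal(2.0, 0.3, (30, 2))
    mid = np.zeros((1, 2))  # equidistant from both centroids
    X = np.vstack([a, b, mid])
    X = np.column_stack([X, X[:, 0]])  # last column acts as peak-to-valley
    labels = classify_cells(X)
    assert labels[-1] == "X"


def test_classify_errors():
    with pytest.raises(ValueError, match="at least 20"):
        classify_cells(np.zeros((5, 3)))
    X = np.random.default_rng(2).normal(size=(30, 3))
    X[:, 1] = 1.0
    with pytest.raises(ValueError, match="zero variance"):
        classify_cells(X)


def test_entrainment_leakage_exclusion_and_min_spikes():
    phases = {0: np.zeros(1000), 1: np.zeros(1000)}
    res = spike_entrainment(np.linspace(0, 0.9, 100), {0: np.zeros(1000)}, 1000.0, unit_electrode=0)
    assert res.skipped and "no eligible" in res.reason
    res2 = spike_entrainment(np.linspace(0, 0.9, 10), phases, 1000.0, unit_electrode=0)
    assert res2.skipped and "too few" in res2.reason


def test_entrainment_recovers_preference():
    """Spikes drawn with a phase preference against a rotating phase are
    recovered with the correct preferred phase."""
    from scipy.stats import vonmises as sv

    rng = np.random.default_rng(4)
    fs = 1000.0
    n = 500_000
    phase = np.mod(2 * np.pi * 150.0 * np.arange(n) / fs + np.pi, 2 * np.pi) - np.pi
    # sample spike phases from vM(-2, 0.3), then place each spike on a sample
    # with the matching phase value
    target = sv.rvs(0.3, loc=-2.0, size=5000, random_state=rng)
    target = np.mod(target + np.pi, 2 * np.pi) - np.pi
    # map each target phase to the nearest phase value on the sample lattice
    lattice, first_idx = np.unique(np.round(phase[:4000], 9), return_index=True)
    d = np.abs(np.mod(target[:, None] - lattice[None, :] + np.pi, 2 * np.pi) - np.pi)
    spikes = np.sort(first_idx[np.argmin(d, axis=1)] / fs)
    res = spike_entrainment(spikes, {0: phase, 1: phase}, fs, unit_electrode=9,
                            eligible_channels=[0, 1])
    assert res.mu == pytest.approx(-2.0, abs=0.15)
    assert res.kappa == pytest.approx(0.3, abs=0.06)
    assert res.entrained


def _exact_moment_cloud(mu, cov, n, seed):
    """Sample cloud affinely corrected to have exactly the target moments."""
    rng = np.random.default_rng(seed)
    X = rng.standard_normal((n, len(mu)))
    X -= X.mean(axis=0)
    W = np.linalg.cholesky(np.linalg.inv(np.cov(X, rowvar=False)))
    L = np.linalg.cholesky(np.asarray(cov, float))
    return (X @ W) @ L.T + np.asarray(mu, float)


def test_bhattacharyya_closed_forms():
    A = _exact_moment_cloud([0, 0], np.eye(2), 5000, 1)
    B = _exact_moment_cloud([2, 0], np.eye(2), 5000, 2)
    C = _exact_moment_cloud([0, 0], 4 * np.eye(2), 5000, 3)
    assert bhattacharyya(A, A) == pytest.approx(0.0, abs=1e-12)
    assert bhattacharyya(A, B) == pytest.approx(0.5, abs=1e-9)
    assert bhattacharyya(A, C) == pytest.approx(np.log(2.5 / 2.0), abs=1e-9)


def test_bhattacharyya_symmetry_and_affine_invariance():
    rng = np.random.default_rng(7)
    A = rng.multivariate_normal([0, 1], [[2, 0.5], [0.5, 1]], 500)
    B = rng.multivariate_normal([1, -1], [[1, -0.2], [-0.2, 3]], 500)
    d = bhattacharyya(A, B)
    assert d == pytest.approx(bhattacharyya(B, A), rel=1e-12)
    M = np.array([[1.5, 0.3], [-0.2, 0.8]])
    shift = np.array([3.0, -4.0])
    d2 = bhattacharyya(A @ M.T + shift, B @ M.T + shift)
    assert d2 == pytest.approx(d, rel=1e-9)
    with pytest.raises(ValueError):
        bhattacharyya(A[:2], B)


def test_bin_counts():
    counts = bin_counts(np.array([0.5, 5.0, 15.0, 25.0]), 0.0, 30.0, bin_s=10.0)
    np.testing.assert_array_equal(counts, [2, 1, 1])
    with pytest.raises(ValueError):
        bin_counts(np.array([1.0]), 0.0, 5.0, bin_s=10.0)
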