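import numpy as np
import pytest
from scipy import signal as sps
from scipy.stats import vonmises as scipy_vonmises

from hfosync.circstats import wrap_angle
from hfosync.phase import (
    amplitude_autocorr,
    amplitude_crosscorr,
    analytic,
    narrowband,
    phase_pair,
    structure_phase_map,
)
from hfosync.synth import HfoConfig, gen_fractal_noise, gen_hfo_component

FS = 2000.0


def test_passband_identity_and_stopband():
    t = np.arange(int(4 * FS)) / FS
    x = np.cos(2 * np.pi * 150.0 * t)
    y = narrowband(x, FS, 150.0, 5.0)
    core = slice(int(FS), int(3 * FS))
    ratio = np.abs(sps.hilbert(y)[core]).mean()
    assert 0.99 < ratio < 1.01
    # designed-filter frequency response: > 20 dB down at +/-40 Hz (two passes)
    taps = sps.firwin(65, [145.0, 155.0], pass_zero=False, window="hamming", fs=FS)
    w, h = sps.freqz(taps, worN=8192, fs=FS)
    for f_test in (110.0, 190.0):
        att_db = -20 * np.log10(np.abs(h[np.argmin(np.abs(w - f_test))])) * 2
    assert att_db > 20.0
    with pytest.raises(ValueError):
        narrowband(x, FS, 998.0, 5.0)


def test_zero_phase_impulse_symmetry():
    x = np.zeros(4001)
    x[2000] = 1.0
    y = narrowband(x, FS, 150.0, 5.0)
    np.testing.assert_allclose(y, y[::-1], atol=1e-12)


def test_trough_at_zero_convention():
    # 125 Hz at 2 kHz puts the cosine troughs exactly on samples
    t = np.arange(int(4 * FS)) / FS
    A = 3.0
    x = A * np.cos(2 * np.pi * 125.0 * t)
    a = analytic(x, 125.0)
    core = slice(int(FS), int(3 * FS))
    assert a.amplitude[core].mean() == pytest.approx(A, rel=0.01)
    # at signal minima the phase is 0; at maxima it is pi
    minima = sps.argrelmin(x[core], order=2)[0] + core.start
    maxima = sps.argrelmax(x[core], order=2)[0] + core.start
    assert np.max(np.abs(wrap_angle(a.phase[minima]))) < 0.05
    assert np.max(np.abs(wrap_angle(a.phase[maxima] - np.pi))) < 0.05
    # instantaneous frequency on the analytic phase
    dphi = np.diff(np.unwrap(a.phase[core]))
    assert dphi.mean() * FS / (2 * np.pi) == pytest.approx(125.0, abs=0.5)


def test_all_zero_input_flagged():
    a = analytic(np.zeros(1000), 150.0)
    assert not a.defined and np.all(a.amplitude == 0)


def test_envelope_recovery_fwhm():
    """A Gaussian spindle of 50 ms FWHM is recovered within 5 ms."""
    t = np.arange(int(2 * FS)) / FS
    sigma = 0.050 / 2.3548
    env = np.exp(-0.5 * ((t - 1.0) / sigma) ** 2)
    x = env * np.cos(2 * np.pi * 150.0 * t)
    a = analytic(x, 150.0)
    half = a.amplitude.max() / 2
    width_ms = np.sum(a.amplitude > half) / FS * 1e3
    assert width_ms == pytest.approx(50.0, abs=5.0)


def test_amplitude_autocorr_band(lag_session):
    """Measured amplitude-autocorrelation FWHM of 50 ms synthetic spindles
    falls in the 32-68 ms descriptive band."""
    sess, gt = lag_session
    x = sess.lfp_channel(0)[int(40 * FS):]
    a = analytic(narrowband(x, FS, 150.0, 5.0), 150.0)
    acf = amplitude_autocorr(a.amplitude, FS, min_median_uv=5.0)
    assert 32.0 <= acf.peak_fwhm_ms <= 68.0


def test_autocorr_white_noise_delta():
    rng = np.random.default_rng(0)
    acf = amplitude_autocorr(rng.standard_normal(int(120 * FS)), FS, min_median_uv=0.0)
    assert acf.acf[len(acf.acf) // 2] == pytest.approx(1.0)
    assert np.max(np.abs(acf.acf[np.abs(acf.lags_ms) > 10])) < 0.05


def test_autocorr_theta_modulation_side_peaks():
    """A 7 Hz amplitude modulation yields autocorrelation side peaks at
    +/- 1/7 s ~ 143 ms."""
    t = np.arange(int(120 * FS)) / FS
    amp = 1.0 + 0.8 * np.cos(2 * np.pi * 7.0 * t)
    acf = amplitude_autocorr(amp, FS, min_median_uv=0.0, max_lag_s=0.25)
    mid = len(acf.acf) // 2
    right = acf.acf[mid + int(0.1 * FS):]
    side = np.argmax(right) + int(0.1 * FS)
    assert side / FS * 1e3 == pytest.approx(142.9, abs=5.0)


def test_crosscorr_identical_independent_and_mixed():
    rng = np.random.default_rng(1)
    cfg = HfoConfig(amplitude=60.0, amplitude_comodulation=0.8, spindle_rate=12.0)
    sig, gt = gen_hfo_component(cfg, 2, FS, 240.0, seed=3, groups=["a", "b"])
    noise = np.stack([gen_fractal_noise(2.0, 1000.0, FS, 240.0, rng) for _ in range(2)])
    amps = [analytic(narrowband(sig[k] + noise[k], FS, 150.0, 5.0), 150.0).amplitude for k in range(2)]
    pk, lags, ccf = amplitude_crosscorr(amps[0], amps[0], FS, min_median_uv=5.0)
    assert pk == pytest.approx(1.0, abs=1e-6)
    assert lags[np.argmax(ccf)] == 0.0
    pk_mix, _, _ = amplitude_crosscorr(amps[0], amps[1], FS, min_median_uv=5.0)
    assert pk_mix == pytest.approx(0.8, abs=0.1)
    cfg0 = HfoConfig(amplitude=60.0, amplitude_comodulation=0.0, spindle_rate=12.0)
    sig0, _ = gen_hfo_component(cfg0, 2, FS, 240.0, seed=4, groups=["a", "b"])
    amps0 = [analytic(narrowband(sig0[k] + noise[k], FS, 150.0, 5.0), 150.0).amplitude for k in range(2)]
    pk0, _, _ = amplitude_crosscorr(amps0[0], amps0[1], FS, min_median_uv=5.0)
    assert abs(pk0) < 0.1
    with pytest.raises(ValueError, match="excluded"):
        amplitude_crosscorr(np.ones(int(60 * FS)), np.ones(int(60 * FS)), FS, min_median_uv=15.0)


def test_phase_pair_identities():
    rng = np.random.default_rng(2)
    phi = rng.uniform(-np.pi, np.pi, 5000)
    same = phase_pair(phi, phi)
    assert same.dphi == pytest.approx(0.0, abs=1e-12)
    assert same.r == pytest.approx(1.0)
    assert not same.inverted
    flipped = phase_pair(phi, wrap_angle(phi - np.pi))
    assert abs(flipped.dphi) == pytest.approx(np.pi, abs=1e-9)
    assert flipped.inverted  # kappa is huge for an exact flip
    jitter = scipy_vonmises.rvs(5.0, size=5000, random_state=rng)
    lagged = phase_pair(wrap_angle(phi + 0.3 + jitter), phi)
    assert lagged.dphi == pytest.approx(0.30, abs=0.03)


def test_phase_pair_antisymmetry_and_swap_invariance():
    rng = np.random.default_rng(3)
    pi_ = rng.uniform(-np.pi, np.pi, 3000)
    pj = wrap_angle(pi_ + scipy_vonmises.rvs(3.0, loc=2.7, size=3000, random_state=rng))
    ab = phase_pair(pi_, pj)
    ba = phase_pair(pj, pi_)
    assert wrap_angle(ab.dphi + ba.dphi) == pytest.approx(0.0, abs=1e-9)
    assert ab.inverted == ba.inverted
    assert ab.kappa == pytest.approx(ba.kappa, rel=1e-9)


def test_phase_pair_gating_and_stability():
    phi = np.zeros(100)
    ps = phase_pair(phi, phi, min_gated=1000)
    assert not ps.stable
    gate = np.zeros(100, bool)
    ps0 = phase_pair(phi, phi, gate)
    assert ps0.n_samples == 0 and not ps0.stable


def test_structure_phase_map_sign_and_exclusion():
    from hfosync.phase import PhasePairStats

    mk = lambda dphi, r, si, sj: PhasePairStats((0, 1), dphi, r, 5.0, False, 1000, structures=(si, sj))
    stats = [
        mk(-0.2, 0.9, "OB", "vStr"),  # phi_OB - phi_vStr = -0.2 -> vStr leads by 0.2
        mk(-0.2, 0.9, "OB", "vStr"),
        mk(0.2, 0.9, "vStr", "OB"),  # orientation swapped, same physics
        mk(0.5, 0.3, "OB", "vStr"),  # r < 0.5: excluded
    ]
    lag_map, retained = structure_phase_map(stats, "OB", r_min=0.5)
    assert lag_map["vStr"]["median_lag"] == pytest.approx(0.2, abs=1e-12)
    assert lag_map["vStr"]["n_pairs"] == 3
    assert len(retained) == 3
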