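import numpy as np
import pytest
from scipy import signal as sps

from hfosync.circstats import circ_summary, wrap_angle
from hfosync.phase import amplitude_autocorr, analytic, narrowband
from hfosync.synth import (
    HfoConfig,
    SpikeConfig,
    gen_fractal_noise,
    gen_hfo_component,
    gen_session,
    preset,
)


def _welch_slope(x, fs, f_lo=1.0, f_hi=None):
    f, P = sps.welch(x, fs, nperseg=8192)
    f_hi = f_hi or fs / 4
    m = (f >= f_lo) & (f <= f_hi)
    return np.polyfit(np.log10(f[m]), np.log10(P[m]), 1)[0]


@pytest.mark.parametrize("beta,tol", [(0.0, 0.1), (2.0, 0.1)])
def test_fractal_slope(beta, tol):
    """Log-log regression on the averaged periodogram recovers the slope."""
    x = gen_fractal_noise(beta, 100.0, 1000.0, 600.0, seed=1)
    assert _welch_slope(x, 1000.0) == pytest.approx(-beta, abs=tol)


def test_fractal_determinism_and_errors():
    a = gen_fractal_noise(1.5, 10.0, 1000.0, 10.0, seed=42)
    b = gen_fractal_noise(1.5, 10.0, 1000.0, 10.0, seed=42)
    np.testing.assert_array_equal(a, b)
    with pytest.raises(ValueError, match="4096"):
        gen_fractal_noise(1.0, 1.0, 1000.0, 1.0, seed=0)
    with pytest.raises(ValueError):
        gen_fractal_noise(5.0, 1.0, 1000.0, 10.0, seed=0)


def test_hfo_envelope_acf_matches_config():
    """The generated envelope's autocorrelation FWHM equals the configured
    value (bump width is defined through the autocorrelation)."""
    cfg = HfoConfig(spindle_rate=8.0, amplitude=20.0, channel_gain_sd=0.0)
    sig, gt = gen_hfo_component(cfg, 1, 2000.0, 240.0, seed=3)
    acf = amplitude_autocorr(gt.envelope[0], 2000.0, min_median_uv=0.0)
    assert acf.peak_fwhm_ms == pytest.approx(50.0, abs=5.0)


def test_hfo_zero_lag_and_inversion():
    cfg = HfoConfig(amplitude=20.0, phase_lags=None, inverted_channels=frozenset({2}),
                    channel_gain_sd=0.0)
    sig, gt = gen_hfo_component(cfg, 3, 2000.0, 120.0, seed=4)
    d01 = circ_summary(wrap_angle(gt.phase[0] - gt.phase[1]))
    assert abs(d01.mean_angle) < 0.02
    d02 = circ_summary(wrap_angle(gt.phase[0] - gt.phase[2]))
    assert abs(d02.mean_angle) == pytest.approx(np.pi, abs=0.05)
    with pytest.raises(ValueError, match="Nyquist"):
        gen_hfo_component(HfoConfig(carrier_freq=1500.0), 1, 2000.0, 60.0, seed=0)


def test_ground_truth_envelope_alignment():
    """Envelope recovered through the narrowband/Hilbert chain correlates
    > 0.95 with the generated envelope at high SNR."""
    cfg = HfoConfig(amplitude=40.0, spindle_rate=8.0, channel_gain_sd=0.0)
    sig, gt = gen_hfo_component(cfg, 1, 2000.0, 240.0, seed=5)
    x = sig[0] + gen_fractal_noise(2.0, 1000.0, 2000.0, 240.0, seed=6)
    a = analytic(narrowband(x, 2000.0, 150.0, 5.0), 150.0)
    assert np.corrcoef(a.amplitude, gt.envelope[0])[0, 1] > 0.95


def test_component_additivity():
    """Variance of the composite LFP is close to the sum of component
    variances (components are independent)."""
    cfg = preset("5HT2A", duration=60.0, injection_time=10.0, structures={"vStr": 2},
                 spikes=SpikeConfig(n_units={}), seed=9)
    sess, gt = gen_session(cfg)
    frac = gen_fractal_noise(cfg.fractal_beta, cfg.fractal_scale, cfg.fs, cfg.duration, seed=1)
    var_parts = frac.var() + cfg.gamma_amplitude**2 + gt.envelope[0].var() / 2 + gt.envelope[0].mean() ** 2 / 2
    assert sess.lfp[0].var() == pytest.approx(var_parts, rel=0.25)


def test_session_determinism():
    cfg = preset("NMDA", duration=30.0, injection_time=10.0, structures={"vStr": 2},
                 spikes=SpikeConfig(n_units={"PC": 1}), seed=33)
    s1, _ = gen_session(cfg)
    s2, _ = gen_session(cfg)
    np.testing.assert_array_equal(s1.lfp, s2.lfp)
    np.testing.assert_array_equal(s1.units[0].spike_times, s2.units[0].spike_times)


def test_presets_carry_class_frequencies():
    assert preset("5HT2A").hfo.carrier_freq == 127.0
    assert preset("NMDA").hfo.carrier_freq == 143.0
    assert preset("amphetamine").hfo.amplitude == 0.0
    with pytest.raises(ValueError):
        preset("unknown")


def test_spike_phase_distribution_matches_config():
    """Realized spike phases against the true HFO phase are von Mises with
    the configured parameters (thinning construction)."""
    from hfosync.circstats import vonmises_fit

    cfg = preset("5HT2A", duration=300.0, injection_time=10.0, structures={"vStr": 1},
                 hfo=HfoConfig(spindle_rate=12.0, carrier_freq=150.0),
                 spikes=SpikeConfig(base_rate=20.0, kappa=0.5, preferred_phase=1.0,
                                    n_units={"PC": 1}),
                 rate_modulation={"PC": 1.0}, seed=10)
    sess, gt = gen_session(cfg)
    u = sess.units[0]
    idx = np.clip(np.round(u.spike_times * cfg.fs).astype(int), 0, gt.phase.shape[1] - 1)
    mu, kappa = vonmises_fit(gt.phase[u.electrode][idx])
    assert mu == pytest.approx(1.0, abs=0.1)
    assert kappa == pytest.approx(0.5, abs=0.07)


def test_accel_contains_twitch_bursts(small_session):
    sess, gt = small_session
    assert sess.accel is None or sess.accel.shape[0] == 3
    # presets without events have empty twitch truth
    assert gt.twitch_times.size == 0
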