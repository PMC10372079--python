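import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from hfosync.hfo import (
    DetectionCriteria,
    detection_rate,
    fit_peak_model,
    median_hfo_frequency,
    peak_model,
    prevalence_class,
)

FREQS = np.arange(70.0, 200.125, 0.125)


def test_exact_model_recovery():
    y = peak_model(FREQS, 10.0, 150.0, 8.0, 0.0, 0.0)
    fit = fit_peak_model(y, FREQS)
    assert fit.params == pytest.approx((10, 150, 8, 0, 0), abs=1e-6)
    assert fit.r2 == pytest.approx(1.0)
    assert fit.detected


def test_out_of_band_peak_rejected():
    y = peak_model(FREQS, 10.0, 80.0, 8.0, 0.0, 0.0)
    fit = fit_peak_model(y, FREQS)
    assert fit.a2 == pytest.approx(80.0, abs=0.5)
    assert not fit.detected


def test_noisy_recovery():
    """With 0.5 dB Gaussian noise the peak frequency is recovered within
    1 Hz in at least 95 of 100 replicates."""
    rng = np.random.default_rng(0)
    hits = 0
    for _ in range(100):
        y = peak_model(FREQS, 10.0, 150.0, 8.0, 0.01, 0.5) + rng.normal(0, 0.5, FREQS.size)
        hits += abs(fit_peak_model(y, FREQS).a2 - 150.0) <= 1.0
    assert hits >= 95


def test_criteria_boundaries_are_strict():
    crit = DetectionCriteria()
    ok = (10.0, 150.0, 8.0, 0.0, 0.0)
    assert crit.check(ok, r2=0.5)
    assert not crit.check(ok, r2=0.2)  # strict r2 > 0.2
    for i, boundary in enumerate([(2.0, 100.0), (90.0, 170.0), (1.0, 20.0), (-1.0, 1.0), (-10.0, 10.0)]):
        for b in boundary:
            p = list(ok)
            p[i] = b
            assert not crit.check(tuple(p), r2=0.5), f"param a{i+1} at bound {b} must fail"
        inside = list(ok)
        inside[i] = (boundary[0] + boundary[1]) / 2.0
        assert crit.check(tuple(inside), r2=0.5)


def test_constant_offset_moves_only_a5():
    y = peak_model(FREQS, 10.0, 150.0, 8.0, 0.1, 1.0)
    f1 = fit_peak_model(y, FREQS)
    f2 = fit_peak_model(y + 3.0, FREQS)
    assert f2.a5 == pytest.approx(f1.a5 + 3.0, abs=1e-4)
    assert f2.params[:4] == pytest.approx(f1.params[:4], abs=1e-4)


def test_detection_monotone_in_height():
    rng = np.random.default_rng(1)
    noise = rng.normal(0, 0.5, FREQS.size)
    detected_small = fit_peak_model(peak_model(FREQS, 3.0, 150, 8, 0, 0) + noise, FREQS).detected
    detected_large = fit_peak_model(peak_model(FREQS, 30.0, 150, 8, 0, 0) + noise, FREQS).detected
    if detected_small:
        assert detected_large


def test_detection_rate_on_gated_windows():
    """HFO present in exactly half the windows yields a rate near 0.5."""
    rng = np.random.default_rng(2)
    frames = []
    for w in range(60):
        y = rng.normal(0, 1.0, FREQS.size)
        if w % 2 == 0:
            y += peak_model(FREQS, 12.0, 150.0, 8.0, 0.0, 0.0)
        frames.append((FREQS, y))
    rate, fits = detection_rate(frames)
    assert rate == pytest.approx(0.5, abs=0.05)
    assert median_hfo_frequency(fits) == pytest.approx(150.0, abs=1.0)


def test_prevalence_worked_examples():
    assert prevalence_class([0.95, 0.92, 0.1]) == "persistent"
    assert prevalence_class([0.6]) == "prevalent"
    assert prevalence_class([0.03] * 20) == "absent"
    assert prevalence_class([0.3, 0.2, 0.1]) == "occasional"
    with pytest.raises(ValueError):
        prevalence_class([])


@settings(deadline=None, max_examples=200, derandomize=True)
@given(st.lists(st.floats(0.0, 1.0), min_size=1, max_size=30))
def test_prevalence_exhaustive_and_exclusive(rates):
    """Every rate vector maps to exactly one class, and the class is
    consistent with an independent restatement of the rules."""
    r = np.asarray(rates)
    cls = prevalence_class(r)
    assert cls in {"persistent", "prevalent", "occasional", "absent"}
    frac_gt = lambda x: np.mean(r > x)
    if frac_gt(0.9) > 1 / 3:
        assert cls == "persistent"
    elif frac_gt(0.5) > 1 / 3:
        assert cls == "prevalent"
    elif frac_gt(0.05) < 0.05:
        assert cls == "absent"
    else:
        assert cls == "occasional"


def test_median_frequency_basics():
    from hfosync.hfo import HfoFit

    fits = [HfoFit(5, a2, 5, 0, 0, 0.9, detected=True) for a2 in (148.0, 150.0, 152.0)]
    assert median_hfo_frequency(fits) == 150.0
    single = [HfoFit(5, 127.0, 5, 0, 0, 0.9, detected=True)]
    assert median_hfo_frequency(single) == 127.0
    with pytest.raises(ValueError, match="skip phase"):
        median_hfo_frequency([HfoFit(5, 150.0, 5, 0, 0, 0.1, detected=False)])
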