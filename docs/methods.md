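# Methods

This note documents the models implemented in `hfosync`, the synthetic data
they are validated on, and the numerical choices that are not forced by the
underlying science.

## Recording model and epochs

A session is multichannel LFP (µV, channels × samples, t = 0 at recording
start), per-channel anatomical labels, sorted spike units, an optional
3-axis head accelerometer (g; rows AP/ML/DV), and drug metadata with an
explicit injection time in seconds. Analysis epochs are windows relative to
injection; the defaults follow the convention of averaging −35 to −5 min for
baseline and +30 to +60 min for the drug state. All epoch windows are
configurable, and scaled-down sessions simply pass shorter windows with the
same pre/post logic.

Bipolar derivations are formed from all unique same-structure electrode
pairs, signed (lower channel id) − (higher channel id). The sign convention
is arbitrary but consistent; downstream quantities use power or
phase-difference magnitudes, so only consistency matters.

## Spectral separation and HFO detection

Per 8-s Hann-tapered, mean-detrended window (50% overlap, 0.125 Hz grid) the
total PSD is a periodogram and the fractal component is estimated by
irregular resampling: for each h in {1.1, 1.15, …, 1.9} the signal is
resampled by h and 1/h (rational-factor polyphase), the geometric mean of
the two PSDs is taken — which preserves any power law exactly while
displacing narrowband peaks — and the median over the h-set removes the
displaced peaks. Two estimator choices matter:

* The fractal PSD is computed with Welch sub-segments (2 s) inside each
  window and interpolated onto the fine grid in log–log coordinates. The
  fractal component is smooth by definition, so it does not need the fine
  resolution, and single-periodogram geometric means would be biased low by
  Γ(1.5)² ≈ 0.79 (about +1 dB in the ratio); sub-segment averaging removes
  nearly all of that bias (measured residual ≈ 0.35 dB on pure 1/f² noise).
* Frequencies above fs/(2·h_max) have no valid resampled content and the
  fractal estimate is extrapolated log-linearly there; analyses stay below
  200 Hz at fs ≥ 1 kHz, where no extrapolation occurs.

The peak model y(f) = a1·exp(−((f−a2)/a3)²) + a4·f + a5 is fitted by
bounded nonlinear least squares over 70–200 Hz (the detection bounds on a2
are 90–170 Hz; the wider band gives the linear term leverage). Five
multi-starts jitter the initial a2 by {0, ∓10, ∓5} Hz (deterministic
sequence); the best residual wins; non-convergence of all starts yields an
invalid, non-detected fit. Detection criteria are strict inequalities and
configurable. Prevalence classes are checked in the order persistent →
prevalent → absent → occasional, which makes the partition exhaustive and
mutually exclusive.

A property worth knowing: because the fit is performed in dB, strong peaks
appear wider than the linear-domain bandwidth of the oscillation (log
compression of the skirts), and the fitted a2 sits slightly (~1 Hz) above
the true carrier on a falling fractal background. Both effects are shared
by any Gaussian-in-dB fitting procedure and stay well inside the detection
bounds at realistic amplitudes.

## Phase, amplitude, and inversion

The narrowband filter is a 64th-order Hamming FIR (±5 Hz around the median
fitted HFO frequency) applied forward–backward; at 2 kHz its stopband
attenuation at ±40 Hz exceeds 100 dB after the double pass. Phase uses a
trough-at-zero convention, φ = wrap(arg z + π), so a cosine trough maps to
0 and a peak to π. Amplitude correlations use 60-s windows on the
mean-subtracted instantaneous amplitude; channels below a 15 µV median
amplitude are flagged excluded (threshold configurable — synthetic tests
use 5 µV, matching the lower detectable-pair screen).

Pairwise phase statistics are the circular mean, resultant length and von
Mises κ (Best–Fisher inversion of the resultant length, capped at 1e3, no
small-sample bias correction) of the gated difference series. The default
gate keeps samples where both channels exceed their own median amplitude;
gating off reproduces the literal whole-period convention. Inversion is
|Δφ| > 3π/4 with κ > 1. Structure lag maps report the median lag of
cross-structure pairs against a reference structure (positive = leads),
with pairs of r < 0.5 excluded and a Wilcoxon signed-rank test against
zero median.

Note a measurement-physics limitation: a ±5 Hz analysis band cannot track a
carrier that wanders by more than a few Hz, which attenuates measured κ by
∼8% at a 5 Hz wander SD. Entrainment-recovery validation therefore uses a
near-steady carrier (1 Hz wander) so that the estimator, not the band
mismatch, is under test.

## Spike analysis

Rates are 10-s bin counts z-scored by the baseline mean/SD (zero baseline
SD excludes the unit with a reason code); modulation is a two-sided
rank-sum test on the counts at α = 0.01, with the direction from the median
(mean on median ties). Population excess of modulated cells uses a binomial
tail at chance = α/2 per direction. Waveform features are valley FWHM, peak
FWHM and peak-to-valley time with linear interpolation at half-extremum
crossings; classification is fuzzy k-means (k = 2, fuzzifier m = 2,
z-scored features, 10 deterministic restarts), labels X below 0.75
membership, and the narrow-spiking cluster (smaller mean peak-to-valley) is
the putative interneuron group. Spike phases are the per-spike circular
mean over same-structure channels excluding the unit's own electrode
(spike-leakage exclusion); entrainment requires ≥ 50 spikes (configurable)
and Rayleigh p < 0.001 using the finite-n corrected Z approximation. The
Bhattacharyya distance uses sample moments in the standard Gaussian closed
form.

## Head-twitch detection

Mediolateral acceleration is decimated to 200 Hz, bandpassed 8–32 Hz
(order-100 zero-phase FIR), rectified and convolved with a Gaussian
(σ = 50 ms, truncated ±4σ). The kernel is normalized to unit area times
π/2 so the index estimates the in-band oscillation *amplitude* in g (plain
rectification loses the factor 2/π); under this calibration a sustained
0.8 g lateral oscillation reads ≈ 0.8 g and the 0.4 g threshold separates
twitches from 0.1 g movement noise by an order of magnitude. Peaks are
accepted greedily in descending height with a 1-s dead time. Validation
reports both the true-positive rate against ground-truth twitch times
(greedy one-to-one matching, 200 ms tolerance) and false positives per
detection and per minute.

## Granger causality

A bivariate VAR(5) is fitted by least squares to 500-ms windows pooled as
trials (linear detrend per window; regressors never cross window
boundaries; pooled residual covariance). Geweke's spectral causality is
computed from the transfer function H = (I − ΣA_k e^{−iωk})^{−1}:
f_{x→y}(ω) = ln(S_yy / (S_yy − (Σ_xx − Σ_xy²/Σ_yy)|H_yx|²)). Signals are
analyzed at ~1 kHz so a 5th-order model can express ~150 Hz structure;
stability (companion spectral radius < 1) is enforced. Band summaries take
the highest local maximum per spectrum (no smoothing, 1 Hz grid), keep
peaks ≥ 0.2, and report median peak heights per directed structure pair
plus mean causality in the HFO band (median HFO frequency ±10 Hz) and the
25–75 Hz gamma band; directions with no qualifying peak are reported as
missing.

Shared zero-lag signals (exactly the synchrony regime this pipeline
detects) can produce spurious directed asymmetries between channels of
unequal SNR; directed conclusions should therefore rest on explicit
coupling controls, as in the validation suite, where the fitted spectra
agree with the analytic Geweke spectrum of the true coefficients within a
few percent.

## Synthetic sessions: what they emulate

Each channel is a sum of independent 1/f^β fractal noise (spectrally shaped
white noise, exact slope control, spectrum flattened below 1 Hz; β = 2,
1000 µV²/Hz at 1 Hz by default), bandpassed gamma noise (30–80 Hz, 10 µV
RMS), and the HFO component. The HFO component is a shared cosine carrier
whose frequency wanders as an Ornstein–Uhlenbeck process (τ = 2 s, SD 5 Hz
within a session — class presets carry the mean frequencies 127 / 143 /
137 Hz; the larger published spreads are across-recording variability),
multiplied by spindle envelopes: Poisson-onset Gaussian bumps (8 /s on
drug, 5% of that rate pre-injection) with a soft tanh saturation at 1.5× the
nominal 40 µV amplitude. Bump width is parameterized through the
*amplitude-autocorrelation FWHM* (default 50 ms; bump FWHM = 50/√2 ms)
because that autocorrelation is the measured quantity; the ±5 Hz
measurement chain itself broadens the measured value to ~55 ms at 2 kHz.
Envelopes are fully shared within a structure up to per-channel gains;
across structures they mix a shared and a private spindle train so the
envelope correlation equals the configured coefficient. Per-channel gains
are spread deterministically in log-amplitude across a structure (lognormal
σ = 0.4 with a small random part) — electrodes sit at staggered distances
from the local dipole, and without gain diversity bipolar pairs would
cancel the HFO identically. Configured per-channel phase lags are exact
(inverted channels get +π), so lag-recovery truth is sharp.

Spike trains are per-sample Bernoulli thinnings of a rate
λ(t) = base · drug-factor(t) · exp(κ cos(φ(t) − μ))/I₀(κ) against the true
phase of the unit's electrode, with a 1-ms dead time; the realized phase
distribution is von Mises(μ, κ) by construction (verified to ±0.005 in κ at
n = 3×10⁴). Spikes land exactly on the generating sample — sub-sample
jitter would alias ~0.24 rad of carrier phase at 150 Hz. The accelerometer
is 50 Hz-lowpassed noise (0.1 g) plus 250-ms Hanning-windowed 15 Hz bursts
(0.8 g) on the ML axis at the configured twitch times.

Defaults are the study conditions; durations in tests and analysis scripts
are scaled (typically 260–1800 s sessions with 100–500 s epochs, stated in
each script) with every rate, amplitude and effect size left at its
default.

What the generator does *not* emulate: biophysical HFO generation,
theta-phase comodulation of the envelope (available as a config but off by
default since it is reported only for some electrodes), movement artifacts,
electrode drift, spike-sorting errors, and cross-frequency coupling.
Passing tests therefore demonstrate that the estimators recover the
quantities they claim to measure under the assumed signal model — not that
the model captures every property of in-vivo recordings.

## Known limitations

* κ estimates carry no finite-n bias correction; at n < 100 spikes they are
  biased upward.
* The Gaussian-in-dB peak fit inherits a ~1 Hz upward frequency bias on
  steep fractal backgrounds (see above).
* Bivariate (pairwise) Granger causality only; no conditional or
  spectral-factorization variants.
* The HDF5 container is a minimal layout, not NWB; an adapter would be
  straightforward since the layout is documented in `hfosync.session`.
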