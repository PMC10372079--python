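"""Synthetic multi-structure recording sessions with full ground truth.

The generator emulates the statistical structure the analysis pipeline
assumes so every stage can be validated against known truth:

* a 1/f^beta fractal background per channel (spectrally shaped white noise),
* broadband gamma activity (bandpassed noise),
* spindle-modulated HFO carriers: a shared carrier with slow
  Ornstein-Uhlenbeck frequency wander (which reproduces cross-structure
  frequency co-modulation by construction), per-structure spindle envelopes
  whose correlation across structures is controlled by a mixing coefficient,
  per-channel phase lags and optional phase-inverted channels,
* Poisson spike trains thinned by a von Mises phase gain against the true
  HFO phase of the unit's electrode (so the realized phase distribution is
  von Mises with the configured concentration in expectation), with
  class-dependent multiplicative drug rate modulation,
* 3-axis accelerometer traces with Hanning-windowed 8-32 Hz bursts at the
  configured head-twitch times.

Spindle bumps are Gaussian; the configured ``envelope_fwhm`` is the FWHM of
the *amplitude autocorrelation* the analysis measures, so individual bumps
use sigma = fwhm / (2.355 * sqrt(2)).
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict, Optional, Sequence

import numpy as np
from scipy import signal as sps
from scipy.special import i0

from .circstats import wrap_angle
from .session import ChannelMeta, Session, SpikeUnit

__all__ = [
    "HfoConfig",
    "SpikeConfig",
    "HtrConfig",
    "SynthConfig",
    "GroundTruth",
    "gen_fractal_noise",
    "gen_gamma",
    "gen_hfo_component",
    "gen_session",
    "preset",
]

_FWHM_PER_SIGMA = 2.0 * np.sqrt(2.0 * np.log(2.0))  # 2.3548


@dataclass
class HfoConfig:
    carrier_freq: float = 150.0  # Hz
    carrier_sd: float = 5.0  # Hz, within-session frequency wander (OU process)
    carrier_tau: float = 2.0  # s, wander correlation time
    spindle_rate: float = 8.0  # spindle onsets per second (drug state)
    baseline_rate_factor: float = 0.05  # sporadic spindles before injection
    envelope_fwhm: float = 0.050  # s, amplitude-autocorrelation FWHM
    amplitude: float = 40.0  # uV carrier amplitude at envelope peak
    phase_lags: Optional[Sequence[float]] = None  # rad per channel, default 0
    inverted_channels: frozenset = frozenset()  # channel indices with extra pi lag
    amplitude_comodulation: float = 0.8  # envelope correlation across structures
    channel_gain_sd: float = 0.4  # lognormal sigma of per-channel amplitude gain
    envelope_saturation: float = 1.5  # soft cap (x amplitude) on overlapping spindles
    # (electrodes sit at different distances from the local dipole, so nearby
    # channels see different HFO amplitudes; without this diversity the
    # bipolar derivation would cancel the HFO exactly)

    def __post_init__(self):
        if not 0.0 <= self.amplitude_comodulation <= 1.0:
            raise ValueError("amplitude_comodulation must be in [0, 1]")
        if self.amplitude < 0 or self.spindle_rate < 0:
            raise ValueError("rates and amplitudes must be non-negative")


@dataclass
class SpikeConfig:
    base_rate: float = 4.0  # Hz
    kappa: float = 0.3  # von Mises concentration of phase preference
    preferred_phase: float = -2.0  # rad before the HFO trough (trough = 0)
    n_units: Dict[str, int] = field(default_factory=lambda: {"PC": 2, "IN": 2})


@dataclass
class HtrConfig:
    event_times: Sequence[float] = ()  # s
    burst_freq: float = 15.0  # Hz, inside the 8-32 Hz detection band
    burst_amp: float = 0.8  # g
    burst_dur: float = 0.250  # s, Hanning window length (a twitch spans several shakes)
    noise_sd: float = 0.1  # g

    def __post_init__(self):
        if self.burst_amp < 0 or self.noise_sd < 0:
            raise ValueError("rates and amplitudes must be non-negative")


@dataclass
class SynthConfig:
    fs: float = 2000.0
    duration: float = 5700.0  # s: 35 min pre-injection + 60 min post
    injection_time: float = 2100.0  # s
    structures: Dict[str, int] = field(default_factory=lambda: {"OB": 2, "vStr": 4, "mPFC": 4})
    fractal_beta: float = 2.0
    fractal_scale: float = 1000.0  # uV^2/Hz at 1 Hz
    gamma_band: tuple = (30.0, 80.0)
    gamma_amplitude: float = 10.0  # uV RMS
    hfo: HfoConfig = field(default_factory=HfoConfig)
    spikes: SpikeConfig = field(default_factory=SpikeConfig)
    htr: HtrConfig = field(default_factory=HtrConfig)
    fs_accel: float = 400.0
    # multiplicative drug effect on firing rate per cell class
    rate_modulation: Dict[str, float] = field(default_factory=lambda: {"PC": 0.5, "IN": 0.5})
    drug: str = "LSD"
    drug_class: str = "5HT2A"
    seed: int = 0


@dataclass
class GroundTruth:
    envelope: np.ndarray  # channels x samples, uV (carrier amplitude)
    phase: np.ndarray  # channels x samples, rad, trough-at-zero
    channel_lags: np.ndarray  # rad, per channel (pi added for inverted)
    carrier_freq: np.ndarray  # Hz, instantaneous shared carrier frequency
    units: list = field(default_factory=list)  # dicts: unit_id, mu, kappa, cell_type, rate_factor
    twitch_times: np.ndarray = field(default_factory=lambda: np.empty(0))
    spindle_onsets: Dict[str, np.ndarray] = field(default_factory=dict)


def gen_fractal_noise(beta, scale, fs, duration, seed):
    """Gaussian noise with one-sided PSD ``scale * f^-beta`` (f in Hz).

    Spectral shaping of white noise in the Fourier domain gives exact slope
    control; below 1 Hz the spectrum is flattened to keep the variance
    finite.  ``seed`` may be an int or a Generator.
    """
    if not 0.0 <= beta <= 3.0:
        raise ValueError("beta must be in [0, 3]")
    n = int(round(duration * fs))
    if n < 2**12:
        raise ValueError("duration*fs < 4096 samples: too short for spectral shaping")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    white = rng.standard_normal(n)
    X = np.fft.rfft(white)
    f = np.fft.rfftfreq(n, d=1.0 / fs)
    f_eff = np.maximum(f, 1.0)
    gain = np.sqrt(scale * fs / 2.0) * f_eff ** (-beta / 2.0)
    gain[0] = 0.0
    return np.fft.irfft(X * gain, n=n)


def gen_gamma(band, amplitude_rms, fs, n, rng):
    """Bandpassed white noise scaled to a target RMS amplitude."""
    if amplitude_rms == 0:
        return np.zeros(n)
    sos = sps.butter(4, band, btype="bandpass", fs=fs, output="sos")
    x = sps.sosfilt(sos, rng.standard_normal(n))
    return x * (amplitude_rms / max(x.std(), 1e-12))


def _spindle_envelope(rate, fs, n, sigma_s, rng, rate_factor=None):
    """Sum of unit Gaussian bumps at Poisson onsets; optionally a per-sample
    rate multiplier.  Returns (envelope, onset_times)."""
    lam = np.full(n, rate / fs)
    if rate_factor is not None:
        lam = lam * rate_factor
    onsets = np.nonzero(rng.random(n) < lam)[0]
    train = np.zeros(n)
    train[onsets] = 1.0
    half = int(np.ceil(4 * sigma_s * fs))
    t = np.arange(-half, half + 1) / fs
    kernel = np.exp(-0.5 * (t / sigma_s) ** 2)
    env = sps.fftconvolve(train, kernel, mode="same")
    return env, onsets / fs


def _carrier_phase(hfo: HfoConfig, fs, n, rng):
    """Shared carrier with OU frequency wander; returns (theta, freq_hz)."""
    a = np.exp(-1.0 / (hfo.carrier_tau * fs))
    innov = rng.standard_normal(n) * hfo.carrier_sd * np.sqrt(1.0 - a**2)
    x0 = rng.standard_normal() * hfo.carrier_sd
    dev, _ = sps.lfilter([1.0], [1.0, -a], innov, zi=np.array([a * x0]))
    freq = hfo.carrier_freq + dev
    theta = 2.0 * np.pi * np.cumsum(freq) / fs
    return theta, freq


def gen_hfo_component(hfo: HfoConfig, n_channels, fs, duration, seed,
                      groups: Optional[Sequence[str]] = None, rate_factor=None):
    """Multichannel spindle-modulated HFO carrier with ground truth.

    ``groups`` assigns each channel to a structure; channels in the same
    group share a spindle envelope, and envelopes of different groups are
    mixtures of a shared and a private spindle train so their correlation
    equals ``amplitude_comodulation``.  Channel ``k`` gets phase lag
    ``phase_lags[k]`` (plus pi if listed in ``inverted_channels``).

    Returns ``(signals, GroundTruth)`` with signals in uV.
    """
    if hfo.carrier_freq >= fs / 2.0:
        raise ValueError("carrier frequency must be below Nyquist")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n = int(round(duration * fs))
    if groups is None:
        groups = ["all"] * n_channels
    lags = np.zeros(n_channels) if hfo.phase_lags is None else np.asarray(hfo.phase_lags, float)
    lags = lags.copy()
    for k in hfo.inverted_channels:
        lags[k] = wrap_angle(lags[k] + np.pi)

    sigma_s = hfo.envelope_fwhm / (_FWHM_PER_SIGMA * np.sqrt(2.0))
    theta, freq = _carrier_phase(hfo, fs, n, rng)

    rho = hfo.amplitude_comodulation
    env_shared, onsets_shared = _spindle_envelope(hfo.spindle_rate, fs, n, sigma_s, rng, rate_factor)
    group_env = {}
    onsets = {"shared": onsets_shared}
    sat = hfo.envelope_saturation
    for g in dict.fromkeys(groups):
        env_priv, onsets_g = _spindle_envelope(hfo.spindle_rate, fs, n, sigma_s, rng, rate_factor)
        mix = np.sqrt(rho) * env_shared + np.sqrt(1.0 - rho) * env_priv
        # soft saturation: overlapping spindles do not sum without bound
        group_env[g] = sat * np.tanh(mix / sat)
        onsets[g] = onsets_g

    # within-structure amplitude profile: electrodes sit at staggered distances
    # from the local dipole, so gains are spread deterministically across the
    # group (guaranteeing bipolar pairs do not cancel) with a small random part
    gains = np.empty(n_channels)
    group_idx = {}
    for k, g in enumerate(groups):
        group_idx.setdefault(g, []).append(k)
    for g, idx in group_idx.items():
        spread = np.linspace(-1.0, 1.0, len(idx)) if len(idx) > 1 else np.zeros(1)
        gains[idx] = np.exp(hfo.channel_gain_sd * (spread + 0.25 * rng.standard_normal(len(idx))))
    signals = np.empty((n_channels, n))
    envelope = np.empty((n_channels, n))
    phase = np.empty((n_channels, n))
    for k in range(n_channels):
        env = hfo.amplitude * gains[k] * group_env[groups[k]]
        signals[k] = env * np.cos(theta + lags[k])
        envelope[k] = env
        phase[k] = wrap_angle(np.mod(theta + lags[k], 2 * np.pi) + np.pi)
    gt = GroundTruth(
        envelope=envelope,
        phase=phase,
        channel_lags=lags,
        carrier_freq=freq,
        spindle_onsets=onsets,
    )
    return signals, gt


def _spike_train(rate_series, fs, rng, dead_time=0.001):
    """Inhomogeneous Poisson spike times by per-sample Bernoulli thinning.

    Spikes are placed exactly on the generating sample (so the spike phase is
    the phase that produced it) and a refractory dead time is enforced.
    """
    p = np.minimum(rate_series / fs, 1.0)
    hits = np.nonzero(rng.random(len(p)) < p)[0]
    times = hits / fs
    if len(times) > 1:
        keep = np.concatenate([[True], np.diff(times) > dead_time])
        times = times[keep]
    return times


def _waveform_template(cell_type, wf_fs, rng):
    """Biphasic extracellular template: negative valley then positive peak.

    PC templates are broad (peak-to-valley ~0.6 ms), IN narrow (~0.25 ms).
    """
    n = int(round(0.003 * wf_fs))
    t = np.arange(n) / wf_fs * 1e3  # ms
    if cell_type == "IN":
        t_valley, s_valley, t_peak, s_peak, a_peak = 0.8, 0.08, 1.05, 0.12, 0.35
    else:
        t_valley, s_valley, t_peak, s_peak, a_peak = 0.8, 0.15, 1.40, 0.30, 0.45
    jit = 1.0 + 0.08 * rng.standard_normal()
    w = -100.0 * np.exp(-0.5 * ((t - t_valley) / (s_valley * jit)) ** 2)
    w += 100.0 * a_peak * np.exp(-0.5 * ((t - t_peak * jit) / (s_peak * jit)) ** 2)
    return w + rng.standard_normal(n) * 1.0


def gen_session(config: SynthConfig):
    """Compose a full synthetic :class:`Session` with aligned ground truth.

    LFP = fractal + gamma + HFO; HFO spindle rate is gated so the baseline
    period has sporadic spindles and the post-injection period persistent
    ones.  Spike trains are thinned against each unit's channel's true HFO
    phase, with the class rate factor applied after injection.  The
    accelerometer trace is lowpassed noise plus 8-32 Hz bursts at the
    configured twitch times (mediolateral axis).
    """
    rng = np.random.default_rng(config.seed)
    fs = config.fs
    n = int(round(config.duration * fs))
    channels = []
    groups = []
    cid = 0
    for struct, n_ch in config.structures.items():
        for j in range(n_ch):
            channels.append(
                ChannelMeta(channel_id=cid, structure=struct, hemisphere="left" if j % 2 == 0 else "right",
                            electrode_group=len(groups))
            )
            groups.append(struct)
            cid += 1
    n_channels = len(channels)

    # post-injection gating of the spindle rate
    t = np.arange(n) / fs
    rate_factor = np.where(t >= config.injection_time, 1.0, config.hfo.baseline_rate_factor)

    hfo_sig, gt = gen_hfo_component(
        config.hfo, n_channels, fs, config.duration, rng, groups=groups, rate_factor=rate_factor
    )
    lfp = np.empty((n_channels, n))
    for k in range(n_channels):
        lfp[k] = (
            gen_fractal_noise(config.fractal_beta, config.fractal_scale, fs, config.duration, rng)
            + gen_gamma(config.gamma_band, config.gamma_amplitude, fs, n, rng)
            + hfo_sig[k]
        )

    # spike units: thinning against the true phase of the unit's electrode
    units = []
    kappa = config.spikes.kappa
    mu = config.spikes.preferred_phase
    gain_norm = i0(kappa)
    uid = 0
    for struct, n_ch in config.structures.items():
        struct_ch = [c.channel_id for c in channels if c.structure == struct]
        for cell_type, n_units in config.spikes.n_units.items():
            for j in range(n_units):
                electrode = struct_ch[(j + (0 if cell_type == "PC" else 1)) % len(struct_ch)]
                factor = config.rate_modulation.get(cell_type, 1.0)
                rate = np.full(n, config.spikes.base_rate)
                rate[t >= config.injection_time] *= factor
                if kappa > 0:
                    rate = rate * np.exp(kappa * np.cos(gt.phase[electrode] - mu)) / gain_norm
                times = _spike_train(rate, fs, rng)
                wf_fs = 32000.0
                units.append(
                    SpikeUnit(
                        unit_id=f"u{uid:03d}",
                        spike_times=times,
                        electrode=electrode,
                        structure=struct,
                        waveform=_waveform_template(cell_type, wf_fs, rng),
                        wf_fs=wf_fs,
                    )
                )
                gt.units.append(
                    {"unit_id": f"u{uid:03d}", "mu": mu, "kappa": kappa, "cell_type": cell_type,
                     "structure": struct, "rate_factor": factor, "base_rate": config.spikes.base_rate}
                )
                uid += 1

    # accelerometer: lowpassed noise + twitch bursts on the ML axis
    n_acc = int(round(config.duration * config.fs_accel))
    sos = sps.butter(2, 50.0, btype="lowpass", fs=config.fs_accel, output="sos")
    accel = np.stack([sps.sosfilt(sos, rng.standard_normal(n_acc)) for _ in range(3)])
    accel *= config.htr.noise_sd / max(accel.std(), 1e-12)
    burst_n = int(round(config.htr.burst_dur * config.fs_accel))
    window = np.hanning(burst_n)
    tt = np.arange(burst_n) / config.fs_accel
    burst = config.htr.burst_amp * window * np.sin(2 * np.pi * config.htr.burst_freq * tt)
    for ev in config.htr.event_times:
        i0_ = int(round((ev - config.htr.burst_dur / 2.0) * config.fs_accel))
        if 0 <= i0_ and i0_ + burst_n <= n_acc:
            accel[1, i0_ : i0_ + burst_n] += burst
    gt.twitch_times = np.asarray(config.htr.event_times, dtype=float)

    session = Session(
        lfp=lfp,
        fs_lfp=fs,
        channels=channels,
        units=units,
        accel=accel,
        fs_accel=config.fs_accel,
        injection_time=config.injection_time,
        drug=config.drug,
        drug_class=config.drug_class,
    )
    return session, gt


def preset(drug_class: str, **overrides) -> SynthConfig:
    """Study-condition presets by drug class.

    ``"5HT2A"``: 127 Hz carrier, broad rate suppression, head twitches.
    ``"NMDA"``: 143 Hz carrier, interneuron excitation / principal-cell
    suppression, no twitches.  ``"amphetamine"``: no HFO, boosted gamma.
    ``"baseline-only"``: sporadic HFOs throughout, no drug effect.
    """
    if drug_class == "5HT2A":
        cfg = SynthConfig(
            hfo=HfoConfig(carrier_freq=127.0),
            rate_modulation={"PC": 0.5, "IN": 0.5},
            drug="LSD",
            drug_class="5HT2A",
        )
    elif drug_class == "NMDA":
        cfg = SynthConfig(
            hfo=HfoConfig(carrier_freq=143.0),
            rate_modulation={"PC": 0.7, "IN": 1.5},
            drug="ketamine",
            drug_class="NMDA",
        )
    elif drug_class == "amphetamine":
        cfg = SynthConfig(
            hfo=HfoConfig(amplitude=0.0),
            gamma_amplitude=20.0,
            rate_modulation={"PC": 1.5, "IN": 0.7},
            drug="amphetamine",
            drug_class="amphetamine",
        )
    elif drug_class == "baseline-only":
        cfg = SynthConfig(
            hfo=HfoConfig(carrier_freq=137.0, baseline_rate_factor=1.0, spindle_rate=0.4),
            rate_modulation={"PC": 1.0, "IN": 1.0},
            drug="none",
            drug_class="baseline-only",
        )
    else:
        raise ValueError(f"unknown preset '{drug_class}'")
    return replace(cfg, **overrides)
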