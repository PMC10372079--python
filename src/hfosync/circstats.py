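"""Circular statistics primitives.

Phase angles are always kept in (-pi, pi].  The von Mises concentration
parameter kappa is estimated from the resultant length with the standard
piecewise Best–Fisher approximation; no finite-sample bias correction is
applied (documented limitation).
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "wrap_angle",
    "CircularSummary",
    "circ_summary",
    "vonmises_fit",
    "rayleigh_test",
]

_KAPPA_CAP = 1e3


def wrap_angle(a):
    """Wrap angles to (-pi, pi]; values at exactly -pi resolve to +pi."""
    a = np.asarray(a, dtype=float)
    w = np.mod(a + np.pi, 2.0 * np.pi) - np.pi
    w = np.where(w == -np.pi, np.pi, w)
    if w.ndim == 0:
        return float(w)
    return w


@dataclass(frozen=True)
class CircularSummary:
    """First-moment summary of a sample of angles.

    mean_angle is undefined (NaN, ``mean_defined=False``) when the resultant
    length is numerically zero.
    """

    mean_angle: float
    resultant_length: float
    kappa: float
    n: int
    mean_defined: bool = True


def _kappa_from_r(r):
    """Best–Fisher piecewise inversion of the mean resultant length."""
    r = np.asarray(r, dtype=float)
    small = 2.0 * r + r**3 + 5.0 * r**5 / 6.0
    with np.errstate(divide="ignore"):
        mid = -0.4 + 1.39 * r + 0.43 / (1.0 - r)
        large = 1.0 / (r**3 - 4.0 * r**2 + 3.0 * r)
    k = np.where(r < 0.53, small, np.where(r < 0.85, mid, large))
    k = np.where(r >= 1.0, _KAPPA_CAP, k)
    return np.minimum(np.abs(k), _KAPPA_CAP)


def circ_summary(angles, axis=-1) -> CircularSummary:
    """Circular mean, resultant length and kappa of a sample of angles.

    For 1-D input returns a :class:`CircularSummary`; for n-D input returns a
    tuple of arrays ``(mu, r, kappa)`` reduced along ``axis``.
    """
    angles = np.asarray(angles, dtype=float)
    if angles.size == 0:
        raise ValueError("circ_summary requires at least one angle")
    if not np.all(np.isfinite(angles)):
        raise ValueError("angles must be finite")
    z = np.exp(1j * angles).mean(axis=axis)
    r = np.abs(z)
    mu = wrap_angle(np.angle(z))
    kappa = _kappa_from_r(r)
    if angles.ndim > 1:
        return mu, r, kappa
    n = angles.shape[-1] if angles.ndim else 1
    defined = bool(r >= 1e-12)
    return CircularSummary(
        mean_angle=float(mu) if defined else float("nan"),
        resultant_length=float(r),
        kappa=float(kappa) if defined else 0.0,
        n=int(n),
        mean_defined=defined,
    )


def vonmises_fit(angles):
    """Moment-based von Mises fit ``(mu, kappa)``.

    Requires at least 10 samples; kappa is capped at 1e3.
    """
    angles = np.asarray(angles, dtype=float)
    if angles.size < 10:
        raise ValueError("vonmises_fit requires n >= 10 angles")
    s = circ_summary(angles)
    return s.mean_angle, s.kappa


def rayleigh_test(angles, axis=-1):
    """Rayleigh test of circular uniformity.

    Uses the standard Z statistic with the finite-n series correction
    ``p = exp(sqrt(1 + 4n + 4(n^2 - R^2)) - (1 + 2n))``.  Accepts an array of
    replicate samples and reduces along ``axis``.
    """
    angles = np.asarray(angles, dtype=float)
    n = angles.shape[axis]
    if n < 10:
        raise ValueError("rayleigh_test requires n >= 10 angles")
    z = np.exp(1j * angles).mean(axis=axis)
    r = np.abs(z)
    R = n * r
    p = np.exp(np.sqrt(1.0 + 4.0 * n + 4.0 * (n**2 - R**2)) - (1.0 + 2.0 * n))
    p = np.minimum(p, 1.0)
    if angles.ndim == 1:
        return float(p)
    return p
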