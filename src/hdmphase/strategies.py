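"""Phasing strategies expressed as per-reflection amplitude weights.

The conventional full-resolution scheme uses all working amplitudes from the
first cycle (weights identically 1).  The resolution-weighted scheme applies
a time-varying Gaussian low-pass filter

    |Fobs,w(h)| = exp(-2 (pi sigma_w S_h)^2) |Fobs(h)|,

with S_h = 1/d_h, so that early iterations see mostly low-resolution data
(locating the molecular envelope) and high-resolution detail is fed in as
sigma_w ramps linearly to zero.  The genetic scheme layers a population on
top of either weight schedule (see :mod:`hdmphase.genetic`).
"""

from __future__ import annotations

import numpy as np

from .core import ReflectionSet

__all__ = ["resolution_weights", "sigma_w_schedule"]


def resolution_weights(rs: ReflectionSet, sigma_w: float) -> np.ndarray:
    """Gaussian low-pass weights exp(-2 (pi sigma_w s_h)^2) in (0, 1].

    ``sigma_w = 0`` gives all-ones weights, i.e. the conventional scheme.
    """
    if sigma_w < 0:
        raise ValueError("sigma_w must be >= 0")
    if sigma_w == 0.0:
        return np.ones(len(rs))
    return np.exp(-2.0 * (np.pi * sigma_w * rs.s) ** 2)


def sigma_w_schedule(it: int, n_ramp: int, sigma_w_start: float) -> float:
    """Linear decrease of the filter radius from sigma_w_start to 0.

    Reaches 0 at iteration ``n_ramp`` and stays there; an all-zero schedule
    (``sigma_w_start = 0``) reproduces the conventional scheme bit-for-bit.
    """
    if n_ramp <= 0 or it >= n_ramp:
        return 0.0
    return float(sigma_w_start * (1.0 - max(it, 0) / n_ramp))
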