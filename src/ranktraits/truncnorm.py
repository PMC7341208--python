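"""Vectorized truncated-normal sampling.

The liability sweep draws, every iteration, one truncated normal per ranked
record, so this primitive dominates the sampler's cost.  Draws use the
inverse-CDF method with a symmetry flip that keeps the computation in the
lower tail (where ndtr/ndtri are accurate); intervals whose probability mass
falls below ``MASS_FLOOR`` are routed to a rejection sampler that stays exact
arbitrarily far into the tails.
"""

from __future__ import annotations

import numpy as np
from scipy.special import ndtr, ndtri

MASS_FLOOR = 1e-10


def _robert_tail(rng: np.random.Generator, a: float) -> float:
    """One draw of Z | Z > a for large a > 0 (Robert 1995, exponential proposal)."""
    lam = 0.5 * (a + np.sqrt(a * a + 4.0))
    while True:
        z = a + rng.exponential() / lam
        if rng.random() <= np.exp(-0.5 * (z - lam) ** 2):
            return z


def _tail_interval(rng: np.random.Generator, a: float, b: float) -> float:
    """One standard-normal draw on (a, b) when Phi(b) - Phi(a) underflows.

    The interval then lies deep in one tail; by symmetry assume b <= 0 is the
    end nearer the mode.  Mass further than ~30/|b| below b is negligible, so
    the interval can be clipped and a uniform proposal with envelope at b used.
    """
    flip = False
    if a + b > 0:  # reflect into the lower tail
        a, b, flip = -b, -a, True
    if np.isinf(a):
        z = -_robert_tail(rng, -b)
    else:
        a = max(a, b - 30.0 / max(-b, 1.0))
        while True:
            z = rng.uniform(a, b)
            if np.log(rng.random() + 1e-300) <= 0.5 * (b * b - z * z):
                break
    return -z if flip else z


def sample_truncnorm(
    mu: np.ndarray,
    sigma: np.ndarray | float,
    lower: np.ndarray | float,
    upper: np.ndarray | float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Draw elementwise from N(mu, sigma^2) truncated to (lower, upper).

    Bounds may be ±inf.  Arrays broadcast against ``mu``.
    """
    mu = np.asarray(mu, dtype=np.float64)
    sigma = np.broadcast_to(np.asarray(sigma, dtype=np.float64), mu.shape)
    a = (np.asarray(lower, dtype=np.float64) - mu) / sigma
    b = (np.asarray(upper, dtype=np.float64) - mu) / sigma
    a, b = np.broadcast_to(a, mu.shape).copy(), np.broadcast_to(b, mu.shape).copy()
    if np.any(b < a):
        raise ValueError("truncated-normal upper bound below lower bound")

    # reflect intervals centred above 0 into the lower tail
    with np.errstate(invalid="ignore"):
        mid = a + b
    flip = np.where(np.isnan(mid), False, mid > 0)
    a_w = np.where(flip, -b, a)
    b_w = np.where(flip, -a, b)

    pa = ndtr(a_w)
    pb = ndtr(b_w)
    mass = pb - pa
    u = pa + rng.random(mu.shape) * mass
    with np.errstate(invalid="ignore"):
        z = ndtri(np.clip(u, 1e-300, 1.0))

    bad = ~np.isfinite(z) | (mass < MASS_FLOOR)
    if np.any(bad):
        for idx in np.argwhere(bad):
            i = tuple(idx)
            z[i] = _tail_interval(rng, float(a_w[i]), float(b_w[i]))
    z = np.where(flip, -z, z)
    return mu + sigma * z
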