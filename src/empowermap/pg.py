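"""Exact Pólya-Gamma PG(1, z) sampling (Devroye rejection method).

The Gibbs sampler for the multinomial logit model augments each
Bernoulli(logistic) partial likelihood with a latent omega ~ PG(1, psi),
which makes every conditional update Gaussian.  Only the unit shape
parameter is needed here (one multinomial trial per respondent), so this
module implements the exact alternating-series rejection sampler for
J*(1, z) of Devroye (1986) / Polson, Scott & Windle (2013), with the
identity PG(1, z) = J*(1, z/2) / 4.

The scalar kernel is JIT-compiled with numba and driven by numba's
internal Mersenne-Twister state, seeded explicitly on every vectorised
call so that draws are reproducible from a single integer seed.

Moment identities used by the test suite:
    E[PG(1, z)]   = tanh(z/2) / (2 z)       (z != 0;  1/4 at z = 0)
    Var[PG(1, 0)] = 1/24
"""

from __future__ import annotations

import math

import numpy as np
from numba import njit

_TRUNC = 0.64  # series crossover point t of the alternating bound
_SQRT2 = math.sqrt(2.0)


@njit(cache=False)
def _norm_cdf(x):
    return 0.5 * math.erfc(-x / _SQRT2)


@njit(cache=False)
def _a_coef(n, x):
    """n-th term of the alternating series bounding the J*(1) density at x."""
    np5 = n + 0.5
    if x > _TRUNC:
        return math.pi * np5 * math.exp(-np5 * np5 * math.pi * math.pi * x / 2.0)
    return (
        math.pi
        * np5
        * math.pow(2.0 / (math.pi * x), 1.5)
        * math.exp(-2.0 * np5 * np5 / x)
    )


@njit(cache=False)
def _mass_texpon(z):
    """Probability that the proposal draws from the exponential tail (x > t)."""
    fz = math.pi * math.pi / 8.0 + z * z / 2.0
    b = math.sqrt(1.0 / _TRUNC) * (_TRUNC * z - 1.0)
    a = -math.sqrt(1.0 / _TRUNC) * (_TRUNC * z + 1.0)
    x0 = math.log(fz) + fz * _TRUNC
    # log-scale to survive large |z|; each term is x0 -+ z + log Phi(.)
    xb = x0 - z
    pb = _norm_cdf(b)
    xa = x0 + z
    pa = _norm_cdf(a)
    qdivp = 0.0
    if pb > 0.0:
        t = xb + math.log(pb)
        qdivp += math.exp(t) if t < 700.0 else math.inf
    if pa > 0.0:
        t = xa + math.log(pa)
        qdivp += math.exp(t) if t < 700.0 else math.inf
    qdivp *= 4.0 / math.pi
    return 1.0 / (1.0 + qdivp)


@njit(cache=False)
def _rtigauss(z):
    """Inverse-Gaussian(mu=1/z, lambda=1) truncated to (0, TRUNC)."""
    z = abs(z)
    t = _TRUNC
    x = t + 1.0
    if z < 1.0 / t:  # mu > t: sample truncated inverse-chi^2, tilt by exp
        alpha = 0.0
        while np.random.uniform(0.0, 1.0) > alpha:
            e1 = np.random.exponential(1.0)
            e2 = np.random.exponential(1.0)
            while e1 * e1 > 2.0 * e2 / t:
                e1 = np.random.exponential(1.0)
                e2 = np.random.exponential(1.0)
            x = t / ((1.0 + t * e1) * (1.0 + t * e1))
            alpha = math.exp(-0.5 * z * z * x)
    else:
        mu = 1.0 / z
        while x > t:
            y = np.random.standard_normal()
            y = y * y
            muy = mu * y
            x = mu + 0.5 * mu * muy - 0.5 * mu * math.sqrt(4.0 * muy + muy * muy)
            if np.random.uniform(0.0, 1.0) > mu / (mu + x):
                x = mu * mu / x
    return x


@njit(cache=False)
def _sample_pg1(psi):
    """One exact draw from PG(1, psi)."""
    z = abs(psi) * 0.5
    fz = math.pi * math.pi / 8.0 + z * z / 2.0
    while True:
        if np.random.uniform(0.0, 1.0) < _mass_texpon(z):
            x = _TRUNC + np.random.exponential(1.0) / fz
        else:
            x = _rtigauss(z)
        s = _a_coef(0, x)
        y = np.random.uniform(0.0, 1.0) * s
        n = 0
        while True:
            n += 1
            if n % 2 == 1:
                s -= _a_coef(n, x)
                if y <= s:
                    return x / 4.0
            else:
                s += _a_coef(n, x)
                if y > s:
                    break


@njit(cache=False)
def _pg1_seeded(psi, seed):
    np.random.seed(seed)
    out = np.empty(psi.size)
    for i in range(psi.size):
        out[i] = _sample_pg1(psi[i])
    return out


def polya_gamma(psi, seed: int) -> np.ndarray:
    """Vector of independent PG(1, psi_i) draws, reproducible from ``seed``."""
    psi = np.ascontiguousarray(np.asarray(psi, dtype=np.float64).ravel())
    if not np.all(np.isfinite(psi)):
        raise ValueError("polya_gamma requires finite tilting parameters")
    return _pg1_seeded(psi, np.uint32(seed % (2**32 - 1)))
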