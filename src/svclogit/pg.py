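"""Exact Polya-Gamma PG(1, z) sampling (Devroye alternating-series method).

The Bernoulli-logit likelihood becomes conditionally Gaussian after
augmenting each record with omega ~ PG(1, eta): the Gibbs sampler then only
ever needs conjugate Gaussian and Gamma updates.  PG(1, z) is sampled
exactly as J*(1, z/2) / 4, where J* is the tilted Jacobi distribution,
using the alternating-series rejection sampler with a truncated-exponential
/ truncated-inverse-Gaussian proposal split at t = 0.64.

The inner loops are numba-jitted; `pg_draw` seeds numba's RNG so draws are
reproducible for a given (z, seed) pair.

Useful identities (used in tests): E[PG(1,z)] = tanh(z/2) / (2 z) and
Var[PG(1,z)] = (sinh(z) - z) / (4 z^3 cosh^2(z/2)).
"""

from __future__ import annotations

import math

import numpy as np
from numba import njit

_TRUNC = 0.64


@njit(cache=True)
def _a_coef(n: int, x: float) -> float:
    # n-th term of the alternating series for the Jacobi density at x
    if x > _TRUNC:
        return math.pi * (n + 0.5) * math.exp(-((n + 0.5) ** 2) * math.pi ** 2 * x / 2.0)
    return (
        math.pi
        * (n + 0.5)
        * (2.0 / (math.pi * x)) ** 1.5
        * math.exp(-2.0 * (n + 0.5) ** 2 / x)
    )


@njit(cache=True)
def _log_norm_cdf(x: float) -> float:
    return math.log(0.5 * math.erfc(-x / math.sqrt(2.0)) + 1e-300)

@njit(cache=True)
def _mass_texpon(z: float) -> float:
    # probability that the proposal uses the exponential (x > t) branch
    t = _TRUNC
    fz = math.pi ** 2 / 8.0 + z * z / 2.0
    b = math.sqrt(1.0 / t) * (t * z - 1.0)
    a = -math.sqrt(1.0 / t) * (t * z + 1.0)
    x0 = math.log(fz) + fz * t
    xb = x0 - z + _log_norm_cdf(b)
    xa = x0 + z + _log_norm_cdf(a)
    qdivp = 4.0 / math.pi * (math.exp(xb) + math.exp(xa))
    return 1.0 / (1.0 + qdivp)


@njit(cache=True)
def _rtigauss(z: float) -> float:
    # inverse-Gaussian IG(1/z, 1) truncated to (0, t]
    t = _TRUNC
    x = t + 1.0
    if z < 1.0 / t:
        # small z: chi-square-like rejection on the truncated region
        alpha = 0.0
        while np.random.random() > alpha:
            e1 = np.random.exponential(1.0)
            e2 = np.random.exponential(1.0)
            while e1 * e1 > 2.0 * e2 / t:
                e1 = np.random.exponential(1.0)
                e2 = np.random.exponential(1.0)
            x = t / ((1.0 + t * e1) ** 2)
            alpha = math.exp(-0.5 * z * z * x)
    else:
        mu = 1.0 / z
        while x > t:
            y = np.random.normal() ** 2
            half_mu = 0.5 * mu
            mu_y = mu * y
            x = mu + half_mu * mu_y - half_mu * math.sqrt(4.0 * mu_y + mu_y * mu_y)
            if np.random.random() > mu / (mu + x):
                x = mu * mu / x
    return x


@njit(cache=True)
def _pg1(z: float) -> float:
    # one exact PG(1, z) draw; z may be any real
    z = abs(z) * 0.5
    fz = math.pi ** 2 / 8.0 + z * z / 2.0
    while True:
        if np.random.random() < _mass_texpon(z):
            x = _TRUNC + np.random.exponential(1.0) / fz
        else:
            x = _rtigauss(z)
        s = _a_coef(0, x)
        y = np.random.random() * s
        n = 0
        while True:
            n += 1
            if n % 2 == 1:
                s -= _a_coef(n, x)
                if y <= s:
                    return 0.25 * x
            else:
                s += _a_coef(n, x)
                if y > s:
                    break


@njit(cache=True)
def _pg_vector(z: np.ndarray, seed: int) -> np.ndarray:
    np.random.seed(seed)
    out = np.empty(z.shape[0])
    for i in range(z.shape[0]):
        out[i] = _pg1(z[i])
    return out


def pg_draw(z: np.ndarray, seed: int) -> np.ndarray:
    """Draw omega_i ~ PG(1, z_i) elementwise, reproducibly for a seed."""
    z = np.ascontiguousarray(np.asarray(z, dtype=np.float64).ravel())
    return _pg_vector(z, int(seed) % (2 ** 31 - 1))


def pg_mean(z: np.ndarray) -> np.ndarray:
    """E[PG(1, z)] = tanh(z/2) / (2 z), with the z -> 0 limit 1/4."""
    z = np.asarray(z, dtype=float)
    out = np.full(z.shape, 0.25)
    nz = np.abs(z) > 1e-8
    out = np.where(nz, np.tanh(np.where(nz, z, 1.0) / 2.0) / (2.0 * np.where(nz, z, 1.0)), out)
    return out


def pg_var(z: np.ndarray) -> np.ndarray:
    """Var[PG(1, z)]; the z -> 0 limit is 1/24."""
    z = np.asarray(z, dtype=float)
    out = np.full(z.shape, 1.0 / 24.0)
    nz = np.abs(z) > 1e-6
    zs = np.where(nz, z, 1.0)
    v = (np.sinh(zs) - zs) / (4.0 * zs ** 3 * np.cosh(zs / 2.0) ** 2)
    return np.where(nz, v, out)
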