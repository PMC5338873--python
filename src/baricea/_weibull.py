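"""Proportional-hazards Weibull machinery shared by the cohort generator and the estimators.

The hazard is defined on the *age* timescale with origin at 20 years (the youngest model
entry age).  For a person with covariate linear predictor ``lp``::

    h(a) = (k / sigma) * ((a - 20) / sigma)**(k - 1) * exp(q(a)) * exp(lp)

where ``k`` is the Weibull shape, ``sigma = exp(log_scale)`` the scale in years, and
``q(a) = coef_age * z + coef_age_sq * z**2`` with ``z = (a - 50) / 10`` a log-quadratic
age modulation of the baseline.  With ``q == 0`` this is a standard Weibull; the general
case keeps the proportional-hazards factorisation ``H(a | x) = H0(a) * exp(lp)`` so that
cumulative hazards need only one baseline integral per parameter vector.

Entry into observation at age ``a0`` is handled by left truncation: all integrals are
over ``[a0, a1]``.  Integrals use Gauss-Legendre quadrature after the substitution
``v = ((a - 20)/sigma)**k``, which removes the power-law endpoint behaviour and makes
the integrand ``exp(q(a(v)))`` smooth.
"""

from __future__ import annotations

from functools import lru_cache

import numpy as np

AGE_ORIGIN = 20.0
_AGE_CENTER = 50.0
_AGE_SCALE = 10.0
_GL_NODES = 32


@lru_cache(maxsize=8)
def _leggauss(n: int):
    x, w = np.polynomial.legendre.leggauss(n)
    return x, w


def age_z(age):
    """Centred/scaled age used by the quadratic covariates: (age - 50) / 10."""
    return (np.asarray(age, dtype=float) - _AGE_CENTER) / _AGE_SCALE


def age_modulation(age, coef_age: float, coef_age_sq: float):
    """q(a): log-quadratic modulation of the baseline hazard."""
    z = age_z(age)
    return coef_age * z + coef_age_sq * z * z


def log_baseline_hazard(age, shape: float, sigma: float, coef_age: float, coef_age_sq: float):
    """log rho(a) of the baseline hazard; ``age`` may be an array (> AGE_ORIGIN)."""
    a = np.asarray(age, dtype=float)
    t = np.maximum(a - AGE_ORIGIN, 1e-12)
    return (
        np.log(shape / sigma)
        + (shape - 1.0) * np.log(t / sigma)
        + age_modulation(a, coef_age, coef_age_sq)
    )


def _segment_cum(a0, a1, shape, sigma, coef_age, coef_age_sq, n_nodes):
    """Single-panel Gauss-Legendre in v = ((a-20)/sigma)**shape; adequate only for
    short age segments (used by the fine inversion grid)."""
    v0 = (np.maximum(a0 - AGE_ORIGIN, 0.0) / sigma) ** shape
    v1 = (np.maximum(a1 - AGE_ORIGIN, 0.0) / sigma) ** shape
    x, w = _leggauss(n_nodes)
    half = 0.5 * (v1 - v0)
    mid = 0.5 * (v1 + v0)
    v = mid[..., None] + half[..., None] * x
    a = AGE_ORIGIN + sigma * np.maximum(v, 0.0) ** (1.0 / shape)
    integrand = np.exp(age_modulation(a, coef_age, coef_age_sq))
    return half * (integrand @ w)


def baseline_cum_hazard(
    a0,
    a1,
    shape: float,
    sigma: float,
    coef_age: float = 0.0,
    coef_age_sq: float = 0.0,
    n_nodes: int = 16,
    n_panels: int = 5,
):
    """Integral of the baseline hazard over [a0, a1] (vectorised over a0/a1).

    Exact closed form when the age modulation is absent.  Otherwise composite
    Gauss-Legendre in t = log v with v = ((a-20)/sigma)**shape: log spacing keeps the
    panel-wise exponent variation bounded even for large shapes, where a single panel
    in v faces a power-law integrand spanning many decades and can be badly (and,
    inside an optimiser, exploitably) wrong.
    """
    a0 = np.asarray(a0, dtype=float)
    a1 = np.asarray(a1, dtype=float)
    v0 = (np.maximum(a0 - AGE_ORIGIN, 0.0) / sigma) ** shape
    v1 = (np.maximum(a1 - AGE_ORIGIN, 0.0) / sigma) ** shape
    if coef_age == 0.0 and coef_age_sq == 0.0:
        return v1 - v0
    out = np.zeros(np.broadcast(v0, v1).shape)
    swap = v1 < v0  # allow reversed limits (signed integral)
    lo = np.where(swap, v1, v0)
    hi = np.where(swap, v0, v1)
    # Head piece [lo, floor): a(v) is essentially constant there, so the integrand is.
    floor = np.maximum(hi * 1e-14, 1e-300)
    head_hi = np.minimum(np.maximum(lo, floor), hi)
    a_head = AGE_ORIGIN + sigma * np.maximum(head_hi, 0.0) ** (1.0 / shape)
    out += np.exp(age_modulation(a_head, coef_age, coef_age_sq)) * np.maximum(head_hi - lo, 0.0)
    t0 = np.log(np.maximum(lo, floor))
    t1 = np.log(np.maximum(hi, floor))
    x, w = _leggauss(n_nodes)
    step = (t1 - t0) / n_panels
    for j in range(n_panels):
        p0 = t0 + j * step
        half = 0.5 * step
        mid = p0 + half
        t = mid[..., None] + half[..., None] * x
        v = np.exp(t)
        a = AGE_ORIGIN + sigma * v ** (1.0 / shape)
        integrand = np.exp(age_modulation(a, coef_age, coef_age_sq)) * v  # dv = v dt
        out += half * (integrand @ w)
    return np.where(swap, -out, out)


def baseline_inverse_grid(
    shape: float,
    sigma: float,
    coef_age: float = 0.0,
    coef_age_sq: float = 0.0,
    age_max: float = 110.0,
    n_grid: int = 3601,
):
    """(age_grid, cum_grid) for inverting H0 by interpolation; cum_grid is monotone."""
    age_grid = np.linspace(AGE_ORIGIN, age_max, n_grid)
    seg = _segment_cum(age_grid[:-1], age_grid[1:], shape, sigma, coef_age, coef_age_sq, n_nodes=8)
    cum = np.concatenate([[0.0], np.cumsum(seg)])
    return age_grid, cum


def invert_baseline(target, shape: float, sigma: float, coef_age: float = 0.0,
                    coef_age_sq: float = 0.0, grid=None):
    """Age a with H0(a) = target (vectorised); np.inf beyond the tabulated range.

    ``grid`` is an optional precomputed ``baseline_inverse_grid`` result.
    """
    target = np.asarray(target, dtype=float)
    if coef_age == 0.0 and coef_age_sq == 0.0:
        return AGE_ORIGIN + sigma * np.maximum(target, 0.0) ** (1.0 / shape)
    if grid is None:
        grid = baseline_inverse_grid(shape, sigma, coef_age, coef_age_sq)
    age_grid, cum = grid
    out = np.interp(target, cum, age_grid, right=np.inf)
    return out
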