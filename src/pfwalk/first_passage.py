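"""First-passage mathematics of the drifted random walk between absorbing thresholds.

A dormant primordial follicle (PF) is modelled by a scalar "stress activity"
``X(t)`` performing a drifted random walk between a growth threshold at 0 and a
death threshold at ``L``.  In the continuum limit the walk is a Brownian motion
with diffusivity ``D`` (units 1/yr) and downward drift ``V`` (units 1/yr), and
the follicle leaves the reserve at the first time the walk exits ``(0, L)``.

This module provides

* the discrete <-> continuous parameter maps (step size / time step / up
  probability versus ``D`` and ``V``),
* the closed-form exit-time survival function ``S(t) = P(tau > t)`` for
  ``L = inf`` (an inverse-Gaussian-type law), evaluated in a numerically
  stable way,
* the expected reserve ``E[F(t)] = N * S(t)`` and the age at which it crosses
  the menopause threshold,
* the finite-``L`` two-sided survival (eigenfunction series) and the
  probability of hitting the death threshold before the growth threshold.

All activities are dimensionless; time is in years.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, replace

import numpy as np
from scipy.optimize import brentq
from scipy.special import erfc, erfcx

__all__ = [
    "ContinuousParams",
    "DiscreteParams",
    "InvalidParameterError",
    "params_from_discrete",
    "discrete_from_params",
    "survival",
    "survival_grid",
    "expected_reserve",
    "anm_from_curve",
    "finite_L_survival",
    "hit_upper_probability",
]


class InvalidParameterError(ValueError):
    """Raised when model parameters violate their invariants."""


@dataclass(frozen=True)
class ContinuousParams:
    """Physical parameters of the continuous walk.

    Parameters
    ----------
    D
        Diffusivity (1/yr); variance scale of the stochastic fluctuations.
    V
        Drift (1/yr); deterministic rate of decrease of the activity.
        ``V > 0`` means the walk tends toward the growth threshold at 0.
    x0
        Initial activity; the activity scale is arbitrary, so 1 by convention.
    L
        Death threshold (> x0); ``inf`` (the default) removes the upper
        boundary, which is the regime used for the human decay curve.
    """

    D: float = 0.004
    V: float = 0.051
    x0: float = 1.0
    L: float = math.inf

    def __post_init__(self) -> None:
        if not self.D > 0:
            raise InvalidParameterError(f"D must be > 0, got {self.D}")
        if not self.L > 0:
            raise InvalidParameterError(f"L must be > 0, got {self.L}")
        if not 0 < self.x0 < self.L:
            raise InvalidParameterError(
                f"x0 must lie in (0, L); got x0={self.x0}, L={self.L}"
            )

    def with_drift(self, V: float) -> "ContinuousParams":
        return replace(self, V=float(V))


@dataclass(frozen=True)
class DiscreteParams:
    """Parameters of the discrete walk: step ``dx``, time step ``dt`` (years),
    and probability ``p`` of an upward step."""

    dx: float
    dt: float
    p: float

    def __post_init__(self) -> None:
        if not self.dx > 0:
            raise InvalidParameterError(f"dx must be > 0, got {self.dx}")
        if not self.dt > 0:
            raise InvalidParameterError(f"dt must be > 0, got {self.dt}")
        if not 0.0 <= self.p <= 1.0:
            raise InvalidParameterError(f"p must be in [0, 1], got {self.p}")


def params_from_discrete(disc: DiscreteParams) -> ContinuousParams:
    """Map discrete-walk parameters to the continuum (D, V).

    ``D = dx^2 / (2 dt)`` and ``V = (2 dx / dt) (1/2 - p)``; an up-biased walk
    (``p > 1/2``) gives negative drift.  Thresholds are not part of the map and
    are returned at their defaults (``x0 = 1``, ``L = inf``).
    """
    D = disc.dx**2 / (2.0 * disc.dt)
    V = (2.0 * disc.dx / disc.dt) * (0.5 - disc.p)
    return ContinuousParams(D=D, V=V)


def discrete_from_params(D: float, V: float, dt: float) -> DiscreteParams:
    """Invert :func:`params_from_discrete` using the convention
    ``dx = sqrt(2 D dt)``.

    Raises
    ------
    InvalidParameterError
        If the implied up-probability falls outside [0, 1], i.e. the drift is
        too strong for the step size; the message names the maximal |V|
        admissible for this (D, dt).
    """
    if not D > 0:
        raise InvalidParameterError(f"D must be > 0, got {D}")
    if not dt > 0:
        raise InvalidParameterError(f"dt must be > 0, got {dt}")
    dx = math.sqrt(2.0 * D * dt)
    p = 0.5 - V * dt / (2.0 * dx)
    if not 0.0 <= p <= 1.0:
        vmax = dx / dt  # |V| at which p hits 0 or 1
        raise InvalidParameterError(
            f"drift V={V} incompatible with D={D}, dt={dt}: "
            f"requires |V| <= {vmax:.6g} (got p={p:.6g})"
        )
    return DiscreteParams(dx=dx, dt=dt, p=p)


def _survival_unbounded(t: np.ndarray, D: float, V: float, x0: float) -> np.ndarray:
    """Stable evaluation of P(tau_0 > t) for the L = inf problem.

    The naive form ``(1/2)[1 + erf((x0-Vt)/s) - e^{Vx0/D}(1 - erf((x0+Vt)/s))]``
    with ``s = sqrt(4Dt)`` overflows through ``e^{Vx0/D}``.  Writing
    ``a = (x0-Vt)/s`` and ``b = (x0+Vt)/s`` one has ``b^2 - a^2 = Vx0/D``, so
    ``e^{Vx0/D} erfc(b) = erfcx(b) e^{-a^2}``, which is stable for any V >= 0.
    For ``b < 0`` (strong upward drift at large t) ``erfcx`` itself would
    overflow; the identity ``erfcx(b) = 2 e^{b^2} - erfcx(-b)`` gives the
    stable branch used there.
    """
    t = np.asarray(t, dtype=float)
    out = np.ones(t.shape, dtype=float)
    pos = t > 0
    if not np.any(pos):
        return out
    tt = t[pos]
    s = np.sqrt(4.0 * D * tt)
    a = (x0 - V * tt) / s
    b = (x0 + V * tt) / s
    ea2 = np.exp(-a * a)
    val = np.empty_like(tt)
    bn = b < 0
    bp = ~bn
    val[bp] = 0.5 * (erfc(-a[bp]) - erfcx(b[bp]) * ea2[bp])
    if np.any(bn):
        # e^{Vx0/D} < 1 here, so the rearranged form stays finite
        val[bn] = 0.5 * (
            erfc(-a[bn]) - 2.0 * np.exp(V * x0 / D) + erfcx(-b[bn]) * ea2[bn]
        )
    out[pos] = np.clip(val, 0.0, 1.0)
    return out


def survival_grid(t, D: float, V, x0: float = 1.0) -> np.ndarray:
    """Vectorised ``P(tau > t)`` over broadcastable age and drift arrays.

    Used for populations where every subject carries her own drift: ``t`` of
    shape (m,) against ``V`` of shape (n, 1) yields an (n, m) survival matrix.
    Same stabilised evaluation as :func:`survival`.
    """
    t = np.asarray(t, dtype=float)
    V = np.asarray(V, dtype=float)
    if np.any(t < 0):
        raise ValueError("ages must be >= 0")
    t_b, V_b = np.broadcast_arrays(t, V)
    out = np.ones(t_b.shape, dtype=float)
    pos = t_b > 0
    tt, vv = t_b[pos], V_b[pos]
    s = np.sqrt(4.0 * D * tt)
    a = (x0 - vv * tt) / s
    b = (x0 + vv * tt) / s
    ea2 = np.exp(-a * a)
    val = np.empty_like(tt)
    bn = b < 0
    bp = ~bn
    val[bp] = 0.5 * (erfc(-a[bp]) - erfcx(b[bp]) * ea2[bp])
    if np.any(bn):
        val[bn] = 0.5 * (
            erfc(-a[bn]) - 2.0 * np.exp(vv[bn] * x0 / D) + erfcx(-b[bn]) * ea2[bn]
        )
    out[pos] = np.clip(val, 0.0, 1.0)
    return out


def survival(t, params: ContinuousParams):
    """Survival function ``S(t) = P(tau > t)`` of the reserve-exit time for
    ``L = inf``.

    ``S(0) = 1`` exactly; for ``V > 0`` the walk is absorbed at the growth
    threshold almost surely and ``S(t) -> 0``.  Accepts scalars or arrays of
    ages (years).

    Raises
    ------
    ValueError
        For negative ages.
    """
    if not math.isinf(params.L):
        return finite_L_survival(t, params)
    t_arr = np.asarray(t, dtype=float)
    if np.any(t_arr < 0):
        raise ValueError("ages must be >= 0")
    out = _survival_unbounded(t_arr, params.D, params.V, params.x0)
    if np.isscalar(t) or t_arr.ndim == 0:
        return float(out.reshape(-1)[0])
    return out


def expected_reserve(t, N: float, params: ContinuousParams):
    """Expected number of follicles remaining at age ``t``: ``N * S(t)``."""
    if not N > 0:
        raise InvalidParameterError(f"N must be > 0, got {N}")
    s = survival(t, params)
    return N * s if np.isscalar(s) else N * np.asarray(s)


def anm_from_curve(
    N: float,
    params: ContinuousParams,
    threshold: float = 1000.0,
    *,
    bracket_max: float = 200.0,
    xtol: float = 1e-6,
) -> float:
    """Age at which the expected decay curve first falls to ``threshold``.

    This is the model's age at natural menopause (ANM) for a woman with
    starting supply ``N``: the unique root of ``N S(t) = threshold`` (unique
    because the curve is strictly decreasing once t > 0).

    Returns 0.0 with a warning if the reserve already starts below the
    threshold.
    """
    if threshold <= 0:
        raise ValueError(f"threshold must be > 0, got {threshold}")
    if threshold >= N:
        warnings.warn(
            "starting supply does not exceed the menopause threshold; ANM = 0",
            stacklevel=2,
        )
        return 0.0

    def f(t: float) -> float:
        return expected_reserve(t, N, params) - threshold

    hi = bracket_max
    while f(hi) > 0:
        hi *= 2.0
        if hi > 1e6:
            raise RuntimeError("could not bracket the threshold crossing")
    return float(brentq(f, 0.0, hi, xtol=xtol))


_SERIES_TOL = 1e-12
_SERIES_MAX_TERMS = 10_000


def finite_L_survival(t, params: ContinuousParams, *, block: int = 64):
    """Survival of the two-sided exit problem on ``(0, L)``.

    Separation of variables for the forward equation
    ``p_t = D p_xx + V p_x`` with absorbing ends gives

    ``S(t) = (2/L) e^{V x0/(2D)} sum_n sin(n pi x0/L) e^{-lam_n t}
             k_n (1 - (-1)^n e^{-V L/(2D)}) / (beta^2 + k_n^2)``

    with ``k_n = n pi / L``, ``beta = V/(2D)`` and
    ``lam_n = D k_n^2 + V^2/(4D)``.  The series is summed in blocks until a
    whole block is below 1e-12 in magnitude, capped at 10^4 terms; it
    converges to the unbounded-domain law as ``L`` grows.
    """
    D, V, x0, L = params.D, params.V, params.x0, params.L
    if not np.isfinite(L):
        raise InvalidParameterError("finite_L_survival requires a finite L")
    t_arr = np.atleast_1d(np.asarray(t, dtype=float))
    if np.any(t_arr < 0):
        raise ValueError("ages must be >= 0")

    beta = V / (2.0 * D)
    pref = (2.0 / L) * math.exp(beta * x0)
    decay0 = V * V / (4.0 * D)
    e_bL = math.exp(-beta * L)

    out = np.zeros_like(t_arr)
    active = t_arr > 0
    n0 = 1
    while np.any(active) and n0 <= _SERIES_MAX_TERMS:
        n = np.arange(n0, min(n0 + block, _SERIES_MAX_TERMS + 1))
        k = n * math.pi / L
        coef = (
            pref
            * np.sin(k * x0)
            * k
            * (1.0 - ((-1.0) ** n) * e_bL)
            / (beta * beta + k * k)
        )
        lam = D * k * k + decay0
        terms = coef[None, :] * np.exp(-np.outer(t_arr[active], lam))
        out[active] += terms.sum(axis=1)
        # a time is converged once every term of its block is tiny
        conv = np.abs(terms).max(axis=1) < _SERIES_TOL
        idx = np.flatnonzero(active)
        active[idx[conv]] = False
        n0 += block
    if np.any(active):
        warnings.warn(
            "eigenfunction series did not converge within 1e4 terms for some "
            "ages; values may be inaccurate at very small t",
            stacklevel=2,
        )
    out = np.clip(out, 0.0, 1.0)
    out[t_arr == 0] = 1.0
    if np.isscalar(t) or np.asarray(t).ndim == 0:
        return float(out[0])
    return out


def hit_upper_probability(params: ContinuousParams) -> float:
    """Probability that the walk reaches the death threshold ``L`` before the
    growth threshold at 0, from the scale function of the drifted diffusion:

    ``P(hit L first) = (e^{V x0 / D} - 1) / (e^{V L / D} - 1)``

    evaluated stably (log space for strong confining drift; the limit
    ``x0 / L`` at ``V = 0``).  For the fitted human parameters and ``L = 2``
    this is ~``e^{-V/D}`` ~ 3e-6: follicle death before growth activation is
    negligible, which is why the one-sided law suffices.
    """
    D, V, x0, L = params.D, params.V, params.x0, params.L
    if not np.isfinite(L):
        return 0.0 if V >= 0 else 1.0 - math.exp(V * x0 / D)
    if V == 0.0:
        return x0 / L
    u0, uL = V * x0 / D, V * L / D
    if max(abs(u0), abs(uL)) < 30.0:
        return math.expm1(u0) / math.expm1(uL)
    if V > 0:
        # (e^{u0}-1)/(e^{uL}-1) = e^{u0-uL} (1-e^{-u0})/(1-e^{-uL})
        return math.exp(u0 - uL) * (-math.expm1(-u0)) / (-math.expm1(-uL))
    # V < 0 with large magnitude: both expm1 terms -> -1
    return math.expm1(u0) / math.expm1(uL)
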