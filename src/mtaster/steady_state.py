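"""Steady-state partitioning of tubulin between monomer and polymer.

Dynamic instability is coarse-grained as diffusion-with-drift of the
microtubule plus end: drift ``b = k (c - c_c)`` (µm/min) and diffusion
``a`` (µm²/min).  With N nucleation sites sharing a finite pool, the
stationary length density of a single microtubule is a (truncated)
exponential ``p(x) ∝ exp(b x / a)``, and the free concentration c is
pinned by conservation:

    c + N * E[x | c] / (lambda * N_A * V)  =  c_t .

When growth is unrestricted (R → ∞) this conservation law is quadratic
in the normalized concentration deficit ``u = (c_c - c)/(c_t - c_c)``:

    u (1 + u) = N / nu ,      u = (sqrt(1 + 4 N / nu) - 1) / 2 ,

whose small-N linearization is ``u ≈ N / nu``.  For length bounded by R
(microtubules abutting the cell margin) the conservation equation is
solved numerically; unoccupied nucleation sites count as microtubules of
zero length, giving a reflecting boundary at x = 0.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq

from .params import TubulinParameters, derived_constants, dimers_per_uM

__all__ = [
    "SteadyState",
    "drift",
    "length_density",
    "mean_length_bounded",
    "steady_c_exact",
    "steady_c_linear",
    "steady_c_bounded",
    "conservation_residual",
]


@dataclass(frozen=True)
class SteadyState:
    """Solved steady state for a given nucleation capacity.

    ``c`` free tubulin (µM); ``b`` end drift (µm/min); ``mean_length``
    (µm, may be inf in degenerate limits); ``R`` is None for unbounded
    growth; ``method`` is 'exact', 'linear' or 'bounded'.
    """

    c: float
    b: float
    mean_length: float
    N: float
    method: str
    R: float | None = None


def drift(c: float, params: TubulinParameters) -> float:
    """Mean elongation rate b = k (c - c_c) of a microtubule end, µm/min.

    Negative drift (shrinkage on average, balanced by the reflecting
    nucleation sites) is the generic sub-critical-pool regime and is
    perfectly meaningful.
    """
    return params.k * (c - params.c_c)


def _mean_factor(t: float) -> float:
    """g(t) = 1/(1 - exp(-t)) - 1/t, the mean of x/R under p ∝ exp(t x/R)
    on [0, 1].  Smooth through t = 0 with g(0) = 1/2."""
    if abs(t) < 1e-6:
        # series: 1/2 + t/12 - t^3/720 + ...
        return 0.5 + t / 12.0
    if t < -700.0:   # exp(-t) overflows; 1/(1-exp(-t)) -> 0
        return -1.0 / t
    if t > 700.0:    # exp(-t) underflows
        return 1.0 - 1.0 / t
    return 1.0 / (-math.expm1(-t)) - 1.0 / t


def mean_length_bounded(beta: float, R: float) -> float:
    """Mean of the truncated-exponential length density exp(beta*x) on [0, R]."""
    return R * _mean_factor(beta * R)


def length_density(x, c: float, params: TubulinParameters, R: float | None = None):
    """Stationary length density p(x) (µm⁻¹) at free concentration c.

    Unbounded (R is None): p(x) = (-b/a) exp(b x / a), which requires
    b < 0 — i.e. the steady-state concentration must lie below the
    critical one.  Bounded: the exponential truncated to [0, R] and
    renormalized, with the b → 0 limit 1/R taken analytically.

    Accepts scalar or array x; x must lie in [0, R] (or x >= 0 when
    unbounded).
    """
    x = np.asarray(x, dtype=float)
    b = drift(c, params)
    beta = b / params.a
    if R is None:
        if b >= 0:
            raise ValueError(
                "unbounded length density requires negative drift: the "
                "steady-state concentration must be lower than the critical one"
            )
        if np.any(x < 0):
            raise ValueError("length x must be non-negative")
        out = -beta * np.exp(beta * x)
    else:
        if R <= 0:
            raise ValueError("length bound R must be positive")
        if np.any((x < 0) | (x > R)):
            raise ValueError("length x must lie in [0, R]")
        t = beta * R
        if abs(t) < 1e-12:
            out = np.full_like(x, 1.0 / R)
        else:
            out = beta * np.exp(beta * x) / math.expm1(t)
    return out if out.shape else float(out)


def _polymer_uM(c: float, N: float, R: float | None, params: TubulinParameters) -> float:
    """Concentration (µM) locked in polymer at free concentration c."""
    if N == 0:
        return 0.0
    b = drift(c, params)
    beta = b / params.a
    if R is None:
        if beta >= 0:
            return math.inf
        mean = -1.0 / beta
    else:
        mean = mean_length_bounded(beta, R)
    total_length = N * mean
    return total_length / params.lambda_dimer / dimers_per_uM(params)


def conservation_residual(
    c: float, N: float, params: TubulinParameters, R: float | None = None
) -> float:
    """F(c) = c + polymer(c) - c_t (µM); zero at a true steady state.

    F is strictly increasing in c, so its root is unique.  In the
    unbounded variant F is +inf for c >= c_c with N > 0 (polymer mass
    diverges), which preserves the sign convention at the c_t endpoint.
    """
    return c + _polymer_uM(c, N, R, params) - params.c_t


def steady_c_exact(N: float, params: TubulinParameters) -> SteadyState:
    """Closed-form steady state for unrestricted microtubule growth.

    The normalized deficit u = (c_c - c)/(c_t - c_c) solves
    u (1 + u) = N/nu; the physical root (c below critical) is

        u = (sqrt(1 + 4 N / nu) - 1) / 2 .

    The other root would put c above critical, where the unbounded
    exponential density does not exist.  At N = 0 the limit value
    c = c_c is returned (with exactly zero nucleators the conservation
    answer would be c = c_t; the limit is the physically continuous
    choice for vanishingly few nucleators).
    """
    if N < 0:
        raise ValueError("nucleation capacity N must be non-negative")
    params.require_supercritical()
    dc = derived_constants(params)
    r = N / dc.nu
    # u = (sqrt(1+4r)-1)/2 in the cancellation-free form 2r/(1+sqrt(1+4r))
    u = 2.0 * r / (1.0 + math.sqrt(1.0 + 4.0 * r))
    c = params.c_c - (params.c_t - params.c_c) * u
    b = drift(c, params)
    mean = math.inf if b == 0 else -params.a / b
    return SteadyState(c=c, b=b, mean_length=mean, N=N, method="exact", R=None)


def steady_c_linear(N: float, params: TubulinParameters) -> SteadyState:
    """Linearized steady state, valid for N small compared with nu.

    (c_c - c)/(c_t - c_c) = N / nu — the tangent of the exact law at
    N = 0, whose slope there is -1/nu.
    """
    if N < 0:
        raise ValueError("nucleation capacity N must be non-negative")
    params.require_supercritical()
    dc = derived_constants(params)
    u = N / dc.nu
    c = params.c_c - (params.c_t - params.c_c) * u
    b = drift(c, params)
    mean = math.inf if b == 0 else -params.a / b
    return SteadyState(c=c, b=b, mean_length=mean, N=N, method="linear", R=None)


def steady_c_bounded(
    N: float, R: float, params: TubulinParameters, rtol: float = 1e-12
) -> SteadyState:
    """Numerical steady state with microtubule length bounded by R.

    Solves the conservation equation F(c) = 0 on [0, c_t] by bracketed
    root finding; F is strictly increasing so the root is unique.  With
    zero nucleators the conservation answer c = c_t is returned exactly.
    """
    if N < 0:
        raise ValueError("nucleation capacity N must be non-negative")
    if R <= 0:
        raise ValueError("length bound R must be positive")
    if N == 0:
        return SteadyState(
            c=params.c_t, b=drift(params.c_t, params),
            mean_length=0.0, N=0.0, method="bounded", R=R,
        )
    f = lambda c: conservation_residual(c, N, params, R)
    f0 = f(0.0)
    if f0 > 0:
        raise RuntimeError(
            "no steady state in [0, c_t]: equilibrium polymer exceeds the "
            "total tubulin supply even at zero free concentration "
            f"(F(0) = {f0:.3g} µM > 0)"
        )
    c = brentq(f, 0.0, params.c_t, xtol=1e-15, rtol=max(rtol, 4e-16))
    b = drift(c, params)
    mean = mean_length_bounded(b / params.a, R)
    return SteadyState(c=c, b=b, mean_length=mean, N=N, method="bounded", R=R)
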