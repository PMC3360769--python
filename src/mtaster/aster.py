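"""Planar radial aster: spatial microtubule density and organelle capture.

A centrosome with nucleation capacity N sits at the origin of a flat
(effectively two-dimensional) cytoplasm.  The number of microtubules
crossing the circumference of radius x equals the number longer than x;
dividing by the circumference 2*pi*x gives the spatial density

    m(x) = N exp(-N x / xi) / (2 pi x)        [µm⁻¹]

where the linearized steady state ties the exponential decay length to
xi / N.  The only kinetic parameter left in m is the critical
concentration (through xi): the density profile is controlled by xi and
N alone.

Because m rises with N near the centrosome but the accompanying length
shortening depresses it far away, m(x, N) has an interior maximum in N
at N_c = xi / x — the optimal nucleation capacity for covering distance
x.  An organelle of diameter d_o at distance x is "captured" when at
least one microtubule crosses the arc of length d_o there; for randomly
directed microtubules the crossing count is Poisson with mean m(x)*d_o,
so P(x) = 1 - exp(-m(x) d_o).
"""

from __future__ import annotations

import warnings

import numpy as np

from .params import TubulinParameters, derived_constants
from .steady_state import steady_c_exact

__all__ = [
    "planar_density",
    "density_dN",
    "optimal_nucleation",
    "capture_probability",
]


def _check_x(x) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    if np.any(x <= 0):
        raise ValueError("distance x must be strictly positive (density diverges at the centrosome)")
    return x


def planar_density(x, N: float, params: TubulinParameters, linearized: bool = True):
    """Microtubule density m(x) (µm⁻¹) at radial distance x (µm).

    With ``linearized=True`` (default) the small-N/nu steady state is
    used, m = N exp(-N x / xi) / (2 pi x).  With ``linearized=False``
    the exact steady-state drift sets the decay length instead; the
    difference is negligible whenever N << nu and is itself a useful
    diagnostic of the linearization.
    """
    x = _check_x(x)
    if N < 0:
        raise ValueError("nucleation capacity N must be non-negative")
    if N == 0:
        out = np.zeros_like(x)
        return out if out.shape else 0.0
    if linearized:
        xi = derived_constants(params).xi
        decay = N / xi
    else:
        ss = steady_c_exact(N, params)
        decay = -ss.b / params.a
    out = N * np.exp(-decay * x) / (2.0 * np.pi * x)
    return out if out.shape else float(out)


def density_dN(x, N: float, params: TubulinParameters):
    """Sensitivity ∂m/∂N (µm⁻¹) of the planar density to nucleation.

    Equals exp(-N x / xi) (1 - N x / xi) / (2 pi x): positive below
    N = xi/x, zero at it, negative beyond — more nucleation helps near
    the centrosome and hurts far away.
    """
    x = _check_x(x)
    if N < 0:
        raise ValueError("nucleation capacity N must be non-negative")
    xi = derived_constants(params).xi
    s = N * x / xi
    out = np.exp(-s) * (1.0 - s) / (2.0 * np.pi * x)
    return out if out.shape else float(out)


def optimal_nucleation(x, params: TubulinParameters):
    """Nucleation capacity N_c = xi / x maximizing the density at distance x."""
    x = _check_x(x)
    xi = derived_constants(params).xi
    out = xi / x
    return out if out.shape else float(out)


def capture_probability(
    x, N: float, d_o: float, params: TubulinParameters, linearized: bool = True
):
    """Probability that an organelle of diameter d_o at distance x touches
    at least one aster microtubule: P = 1 - exp(-m(x) d_o).

    The organelle is represented by the arc of length d_o it subtends on
    the circumference at x; the Poisson crossing model assumes d_o small
    against x and the mean microtubule length.
    """
    if d_o <= 0:
        raise ValueError("organelle diameter d_o must be positive")
    x = _check_x(x)
    if np.any(d_o > x / 5):
        warnings.warn(
            "organelle diameter d_o is not small against the distance x; "
            "the arc-crossing approximation degrades",
            stacklevel=2,
        )
    m = planar_density(x, N, params, linearized=linearized)
    out = -np.expm1(-np.asarray(m) * d_o)
    return out if out.shape else float(out)
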