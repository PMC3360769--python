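"""Capture of the female pronucleus by sperm asters in the Beroe ovata egg.

The egg is a sphere of diameter d_e whose microtubules and organelles
live in a thin cortical shell (ectoplasm) of thickness h; microtubules
run along the surface, so the planar aster theory carries over with the
circumference 2*pi*x replaced by the geodesic circumference
pi*d_e*sin(2x/d_e).  The free-tubulin pool is shared between N_f
acentrosomal (female) microtubules and the sperm aster(s); all of them
deplete the pool, but only the microtubules radiating from a given
sperm centrosome contribute to that aster's spatial density:

    m_e(x) = N_own exp(-N_total x / xi) / (pi d_e sin(2 x / d_e))

with N_own = N_m, N_total = N_f + N_m for a single sperm aster, and
N_own = N_a, N_total = N_f + n N_a when n sperm each nucleate N_a.

The single female pronucleus enters at a uniformly random point on the
sphere, so its geodesic distance x from a given sperm centrosome has
density sin(2x/d_e)/d_e on [0, pi d_e / 2].  Capture at distance x is
Poisson with mean m_e(x) d_f (d_f the pronucleus diameter), and the
total capture probability integrates over the entry position:

    P_t = ∫ (1 - exp(-m_e(x) d_f)) sin(2x/d_e)/d_e dx .

Microtubules longer than half the egg circumference are excluded from
the model (none are observed), so x is confined to (0, pi d_e / 2).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.integrate import quad
from scipy.optimize import minimize_scalar

from .params import (
    EggGeometry,
    TubulinParameters,
    beroe_egg,
    beroe_geometry,
    derived_constants,
    ectoplasm_volume,
)

__all__ = [
    "EggScenario",
    "CaptureResult",
    "Optimum",
    "spherical_density",
    "distance_pdf",
    "total_capture",
    "per_aster_capture",
    "optimal_sperm_nucleation",
]

#: plausibility band for microtubule counts in the egg
_PLAUSIBLE_N = (1e2, 1e6)


@dataclass(frozen=True)
class EggScenario:
    """Geometry plus tubulin parameters of a spherical-ectoplasm egg.

    The tubulin volume V is the ectoplasmic shell volume computed from
    the geometry unless an explicit parameter set is supplied.
    """

    geometry: EggGeometry = field(default_factory=beroe_geometry)
    params: TubulinParameters = field(default_factory=beroe_egg)

    @classmethod
    def from_geometry(
        cls, geometry: EggGeometry, kinetics: TubulinParameters | None = None
    ) -> "EggScenario":
        base = kinetics if kinetics is not None else beroe_egg()
        params = TubulinParameters(
            lambda_dimer=base.lambda_dimer, a=base.a, k=base.k,
            c_c=base.c_c, c_t=base.c_t, V=ectoplasm_volume(geometry),
        )
        return cls(geometry=geometry, params=params)

    @property
    def xi(self) -> float:
        return derived_constants(self.params).xi

    @property
    def x_max(self) -> float:
        """Largest admissible geodesic distance: half the circumference."""
        return math.pi * self.geometry.d_e / 2.0


@dataclass(frozen=True)
class CaptureResult:
    """Integrated capture probability with the quadrature error estimate."""

    probability: float
    quad_error: float


@dataclass(frozen=True)
class Optimum:
    """Result of maximizing a capture probability over nucleation capacity.

    When the objective is flat near its maximum over more than a decade
    of N (``plateau`` True), ``argmax`` is the geometric midpoint of the
    plateau interval — a single representative value with honest
    uncertainty — rather than a spuriously precise point.
    """

    argmax: float
    p_max: float
    plateau: bool
    plateau_interval: tuple[float, float]


def _warn_plausibility(**counts: float) -> None:
    lo, hi = _PLAUSIBLE_N
    for name, value in counts.items():
        if value > 0 and not (lo <= value <= hi):
            warnings.warn(
                f"{name} = {value:g} lies outside the plausible band "
                f"[{lo:g}, {hi:g}] for microtubule counts in the egg",
                stacklevel=3,
            )


def spherical_density(x, N_own: float, N_total: float, scenario: EggScenario):
    """Surface density (µm⁻¹) of one aster's microtubules at geodesic
    distance x (µm) from its centrosome.

    N_own microtubules radiate from this centrosome; N_total >= N_own is
    the pool-depleting total (all asters plus acentrosomal microtubules).
    Valid for 0 < x < pi d_e / 2.
    """
    x = np.asarray(x, dtype=float)
    if N_own < 0 or N_total < N_own:
        raise ValueError("need 0 <= N_own <= N_total")
    d_e = scenario.geometry.d_e
    if np.any(x <= 0) or np.any(x >= math.pi * d_e / 2):
        raise ValueError(
            "geodesic distance x must lie strictly inside (0, pi*d_e/2); "
            "microtubules longer than half the egg circumference are excluded"
        )
    if N_own == 0:
        out = np.zeros_like(x)
        return out if out.shape else 0.0
    xi = scenario.xi
    out = N_own * np.exp(-N_total * x / xi) / (math.pi * d_e * np.sin(2.0 * x / d_e))
    return out if out.shape else float(out)


def distance_pdf(x, geometry: EggGeometry):
    """Probability density (µm⁻¹) of the geodesic distance between two
    independently uniform points on the egg sphere: sin(2x/d_e)/d_e on
    [0, pi d_e / 2]."""
    x = np.asarray(x, dtype=float)
    d_e = geometry.d_e
    if np.any(x < 0) or np.any(x > math.pi * d_e / 2):
        raise ValueError("x must lie in [0, pi*d_e/2]")
    out = np.sin(2.0 * x / d_e) / d_e
    return out if out.shape else float(out)


def _capture_integral(N_own: float, N_total: float, scenario: EggScenario) -> CaptureResult:
    d_e = scenario.geometry.d_e
    d_f = scenario.geometry.d_f
    xi = scenario.xi
    x_max = math.pi * d_e / 2.0
    if N_own == 0:
        return CaptureResult(probability=0.0, quad_error=0.0)

    def integrand(x: float) -> float:
        if x <= 0.0 or x >= x_max:
            return 0.0  # pdf vanishes at the poles faster than m diverges
        m = N_own * math.exp(-N_total * x / xi) / (math.pi * d_e * math.sin(2.0 * x / d_e))
        return -math.expm1(-m * d_f) * math.sin(2.0 * x / d_e) / d_e

    # the integrand localizes near the centrosome for large N_total:
    # seed the subdivision with the decay length
    decay = xi / N_total if N_total > 0 else x_max
    pts = sorted({min(max(p, x_max * 1e-9), x_max * (1 - 1e-9))
                  for p in (decay, 5 * decay, x_max / 2)})
    value, err = quad(integrand, 0.0, x_max, points=pts, epsabs=1e-12,
                      epsrel=1e-8, limit=200)
    value = min(max(value, 0.0), 1.0)
    return CaptureResult(probability=value, quad_error=err)


def total_capture(N_m: float, N_f: float, scenario: EggScenario | None = None) -> CaptureResult:
    """Probability P_t that the female pronucleus is captured by a single
    sperm aster of N_m microtubules, with N_f acentrosomal microtubules
    competing for the tubulin pool."""
    if scenario is None:
        scenario = EggScenario()
    if N_m < 0 or N_f < 0:
        raise ValueError("microtubule counts must be non-negative")
    _warn_plausibility(N_m=N_m, N_f=N_f)
    return _capture_integral(N_m, N_f + N_m, scenario)


def per_aster_capture(
    N_a: float, n: int, N_f: float, scenario: EggScenario | None = None
) -> CaptureResult:
    """Probability P_a that the pronucleus is captured by one given aster
    out of n, each nucleating N_a microtubules (physiological polyspermy).

    All n asters plus the N_f female microtubules deplete the pool; only
    the given aster's N_a microtubules count toward its density.  With
    n = 1 this reduces exactly to :func:`total_capture`.
    """
    if scenario is None:
        scenario = EggScenario()
    if n < 1 or int(n) != n:
        raise ValueError("sperm count n must be a positive integer")
    if N_a < 0 or N_f < 0:
        raise ValueError("microtubule counts must be non-negative")
    _warn_plausibility(N_a=N_a, N_f=N_f)
    return _capture_integral(N_a, N_f + n * N_a, scenario)


def optimal_sperm_nucleation(
    n: int,
    N_f: float,
    scenario: EggScenario | None = None,
    search_range: tuple[float, float] = (1.0, 8.0),
    points_per_decade: int = 25,
    plateau_tol: float = 1e-3,
) -> Optimum:
    """Nucleation capacity per sperm aster that maximizes its own capture
    probability P_a.

    A log-spaced grid scan (``points_per_decade`` points per decade of N
    over ``search_range``, given as log10 bounds) locates the maximum;
    if the near-optimal set {N : P >= P_max - plateau_tol} spans more
    than one decade the objective is reported as a plateau (broad range
    of equally good capacities), otherwise the argmax is refined by
    bounded scalar minimization between the neighbouring grid points.
    """
    if scenario is None:
        scenario = EggScenario()
    lo, hi = search_range
    if not hi > lo:
        raise ValueError("search_range must be an increasing (log10_lo, log10_hi) pair")
    npts = max(2, int(round((hi - lo) * points_per_decade)) + 1)
    logN = np.linspace(lo, hi, npts)
    grid = 10.0 ** logN
    with warnings.catch_warnings():
        # the scan crosses the plausibility band edges by design
        warnings.simplefilter("ignore", UserWarning)
        p = np.array([per_aster_capture(N, n, N_f, scenario).probability for N in grid])
    p_max = float(p.max())
    if p_max <= 0.0:
        return Optimum(
            argmax=10.0 ** ((lo + hi) / 2.0), p_max=0.0, plateau=True,
            plateau_interval=(grid[0], grid[-1]),
        )
    near = p >= p_max - plateau_tol
    lo_N, hi_N = float(grid[near].min()), float(grid[near].max())
    if hi_N / lo_N > 10.0:
        return Optimum(
            argmax=math.sqrt(lo_N * hi_N), p_max=p_max, plateau=True,
            plateau_interval=(lo_N, hi_N),
        )
    i = int(p.argmax())
    lo_b = logN[max(i - 1, 0)]
    hi_b = logN[min(i + 1, npts - 1)]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", UserWarning)
        res = minimize_scalar(
            lambda lg: -per_aster_capture(10.0 ** lg, n, N_f, scenario).probability,
            bounds=(lo_b, hi_b), method="bounded",
            options={"xatol": 1e-6},
        )
    argmax = 10.0 ** float(res.x)
    p_ref = float(-res.fun)
    if p_ref < p_max:  # refinement can't do worse than the grid
        argmax, p_ref = float(grid[i]), p_max
    return Optimum(argmax=argmax, p_max=p_ref, plateau=False,
                   plateau_interval=(lo_N, hi_N))
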