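"""Physical parameters, unit system, and derived natural constants.

The tubulin system of a cell is described by six primitive constants:

``lambda_dimer``
    length of microtubule lattice added per tubulin alpha-beta dimer (µm),
``a``
    apparent diffusion coefficient of the dynamic microtubule ends
    (µm²/min) — the second statistical moment of dynamic instability
    viewed as a stochastic length process,
``k``
    elongation rate constant (µm·min⁻¹·µM⁻¹),
``c_c``
    critical free-tubulin concentration (µM) at which net elongation
    vanishes,
``c_t``
    total tubulin concentration (µM),
``V``
    cytoplasmic volume (litres).

Steady-state behaviour of the whole aster is governed not by these six
numbers individually but by three compound constants:

* ``xi`` (µm) — the total microtubule length the cell would hold if the
  free tubulin pool sat exactly at the critical concentration;
* ``chi = a / (k (c_t - c_c))`` (µm) — a natural unit of mean microtubule
  length;
* ``nu = xi / chi`` (dimensionless) — the natural unit of centrosome
  nucleation capacity.

They satisfy the identity ``nu * chi == xi`` exactly.

Internal unit convention: lengths in µm, time in min, concentrations in
µM; volumes are litres and converted at the boundary only.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

__all__ = [
    "AVOGADRO",
    "UM3_PER_L",
    "SubCriticalError",
    "TubulinParameters",
    "DerivedConstants",
    "EggGeometry",
    "ectoplasm_volume",
    "derived_constants",
    "dimers_per_uM",
    "generic_cell",
    "beroe_geometry",
    "beroe_egg",
    "preset",
]

AVOGADRO = 6.02214076e23
#: number of cubic micrometres in one litre
UM3_PER_L = 1e15


class SubCriticalError(ValueError):
    """Raised when an operation requires c_t > c_c but the parameter set
    is sub-critical (no polymerizable tubulin above the critical level)."""


@dataclass(frozen=True)
class TubulinParameters:
    """Kinetic and cellular constants of the tubulin system.

    A sub-critical set (``c_t <= c_c``) is representable — solvers that
    need a polymerizable pool raise :class:`SubCriticalError` themselves.
    """

    lambda_dimer: float  # µm of lattice per dimer
    a: float             # µm²/min
    k: float             # µm·min⁻¹·µM⁻¹
    c_c: float           # µM
    c_t: float           # µM
    V: float             # litres

    def __post_init__(self) -> None:
        for name in ("lambda_dimer", "a", "k", "c_c", "c_t", "V"):
            value = getattr(self, name)
            if not (value > 0) or not math.isfinite(value):
                raise ValueError(f"{name} must be strictly positive, got {value!r}")

    @property
    def subcritical(self) -> bool:
        """True when no tubulin is available above the critical level."""
        return self.c_t <= self.c_c

    def require_supercritical(self) -> None:
        if self.c_t <= self.c_c:
            raise SubCriticalError(
                f"c_t = {self.c_t} µM does not exceed c_c = {self.c_c} µM; "
                "no nontrivial polymer steady state exists"
            )


@dataclass(frozen=True)
class DerivedConstants:
    """Compound constants governing the aster steady state.

    ``nu * chi == xi`` holds to machine precision; all three are zero in
    the degenerate case ``c_t == c_c`` (empty polymerizable pool, where
    the mean-length unit chi loses its meaning).
    """

    nu: float                     # dimensionless
    xi: float                     # µm
    chi: float                    # µm
    dimers_above_critical: float  # count


@dataclass(frozen=True)
class EggGeometry:
    """Spherical egg with a thin microtubule-bearing cortical shell.

    ``d_e`` egg diameter (µm), ``h`` ectoplasm thickness (µm), ``d_f``
    female pronucleus diameter (µm).  The thin-shell treatment assumes
    ``h`` is small against ``d_e``; a warning is emitted past d_e/20.
    """

    d_e: float
    h: float
    d_f: float

    def __post_init__(self) -> None:
        for name in ("d_e", "h", "d_f"):
            value = getattr(self, name)
            if not (value > 0) or not math.isfinite(value):
                raise ValueError(f"{name} must be strictly positive, got {value!r}")
        if self.d_f >= self.d_e:
            raise ValueError("pronucleus diameter d_f must be smaller than egg diameter d_e")
        if self.h > self.d_e / 20:
            warnings.warn(
                f"ectoplasm thickness h = {self.h} µm is not small against "
                f"d_e = {self.d_e} µm; the thin-shell approximation degrades",
                stacklevel=2,
            )


def ectoplasm_volume(geometry: EggGeometry) -> float:
    """Volume of the thin cortical shell, pi * d_e**2 * h, in litres.

    The shell is treated as a surface of area pi*d_e**2 times thickness h
    (curvature corrections are O(h/d_e)).
    """
    return math.pi * geometry.d_e**2 * geometry.h / UM3_PER_L


def dimers_per_uM(params: TubulinParameters) -> float:
    """Number of tubulin dimers held in the volume V per µM of concentration."""
    return 1e-6 * AVOGADRO * params.V


def derived_constants(params: TubulinParameters) -> DerivedConstants:
    """Compute nu, xi, chi and the polymerizable dimer count.

    Raises
    ------
    SubCriticalError
        if ``c_t < c_c``; at exact equality the degenerate all-zero
        result is returned.
    """
    if params.c_t < params.c_c:
        raise SubCriticalError(
            f"c_t = {params.c_t} µM is below c_c = {params.c_c} µM; "
            "nu and xi are undefined"
        )
    excess = params.c_t - params.c_c  # µM
    if excess == 0.0:
        return DerivedConstants(nu=0.0, xi=0.0, chi=0.0, dimers_above_critical=0.0)
    dimers = excess * dimers_per_uM(params)
    xi = params.lambda_dimer * dimers
    chi = params.a / (params.k * excess)
    return DerivedConstants(nu=xi / chi, xi=xi, chi=chi, dimers_above_critical=dimers)


# ---------------------------------------------------------------------------
# Presets
# ---------------------------------------------------------------------------

#: Generic cultured animal cell.
_GENERIC = dict(lambda_dimer=0.612e-3, a=7.5, k=1.0, c_c=11.5, c_t=25.0)


def generic_cell() -> TubulinParameters:
    """Parameter set for a generic cultured animal cell (V = 4 pL)."""
    return TubulinParameters(V=4e-12, **_GENERIC)


def beroe_geometry() -> EggGeometry:
    """Geometry of the Beroe ovata egg: 1 mm diameter, 5 µm ectoplasm,
    15 µm female pronucleus."""
    return EggGeometry(d_e=1000.0, h=5.0, d_f=15.0)


def beroe_egg() -> TubulinParameters:
    """Tubulin parameters for the Beroe egg: kinetics as in the generic
    cell, volume equal to the ectoplasmic shell volume (15.7 nL)."""
    return TubulinParameters(V=ectoplasm_volume(beroe_geometry()), **_GENERIC)


def preset(name: str) -> TubulinParameters:
    """Look up a named parameter preset ('generic' or 'beroe')."""
    if name == "generic":
        return generic_cell()
    if name == "beroe":
        return beroe_egg()
    raise KeyError(f"unknown preset {name!r}; available: 'generic', 'beroe'")
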