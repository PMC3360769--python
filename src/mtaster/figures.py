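"""Tidy tables behind the model's standard illustration curves.

Each generator returns a pandas DataFrame with one row per grid point
and one column per curve, using the canonical parameter combinations:

fig1   steady-state c versus N, exact law and its linearization
       (generic cell);
fig2   planar density profile m(x) for N in {100, 1000, 2000};
fig3   optimal nucleation capacity N_c(x) = xi / x;
fig4   organelle capture P(x) for (N, d_o) in {100, 2000} x {1, 2} µm;
fig5   Beroe total capture P_t(N_m) for N_f in {1e2, 1e5, 3e5, 1e6};
fig6   per-aster capture P_a(N_a) for n in {1, 3, 6, 9} at
       N_f in {1e5 (panel A), 3e5 (panel B)}.

The tables, not rendered plots, are the contract: byte-stable CSV at
full double precision feeds any downstream plotting.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .aster import capture_probability, optimal_nucleation, planar_density
from .beroe import EggScenario, total_capture, per_aster_capture
from .params import TubulinParameters, derived_constants, generic_cell
from .steady_state import steady_c_exact, steady_c_linear

__all__ = ["figure_data", "FIGURE_IDS"]

FIGURE_IDS = ("fig1", "fig2", "fig3", "fig4", "fig5", "fig6")


def _fig1(params: TubulinParameters, points: int) -> pd.DataFrame:
    nu = derived_constants(params).nu
    # out to N = nu the linearization visibly departs from the exact law
    N = np.concatenate([[0.0], np.geomspace(nu * 1e-6, nu, points - 1)])
    rows = {
        "N": N,
        "N_over_nu": N / nu,
        "c_exact_uM": [steady_c_exact(n, params).c for n in N],
        "c_linear_uM": [steady_c_linear(n, params).c for n in N],
    }
    return pd.DataFrame(rows)


def _x_grid(params: TubulinParameters, points: int) -> np.ndarray:
    xi = derived_constants(params).xi
    return np.geomspace(xi * 1e-6, xi * 2e-3, points)


def _fig2(params: TubulinParameters, points: int) -> pd.DataFrame:
    x = _x_grid(params, points)
    out = pd.DataFrame({"x_um": x})
    for N in (100, 1000, 2000):
        out[f"m_per_um_N{N}"] = planar_density(x, N, params)
    return out


def _fig3(params: TubulinParameters, points: int) -> pd.DataFrame:
    x = _x_grid(params, points)
    xi = derived_constants(params).xi
    return pd.DataFrame({
        "x_um": x,
        "x_over_xi": x / xi,
        "N_c": optimal_nucleation(x, params),
    })


def _fig4(params: TubulinParameters, points: int) -> pd.DataFrame:
    x = _x_grid(params, points)
    out = pd.DataFrame({"x_um": x})
    for N in (100, 2000):
        for d_o in (1.0, 2.0):
            with np.errstate(all="ignore"):
                import warnings as _w
                with _w.catch_warnings():
                    _w.simplefilter("ignore")  # small-x arc warning on a sweep grid
                    out[f"P_N{N}_do{d_o:g}"] = capture_probability(x, N, d_o, params)
    return out


def _fig5(scenario: EggScenario, points: int) -> pd.DataFrame:
    import warnings as _w
    N_m = np.geomspace(1e2, 1e6, points)
    out = pd.DataFrame({"N_m": N_m})
    with _w.catch_warnings():
        _w.simplefilter("ignore")
        for N_f in (1e2, 1e5, 3e5, 1e6):
            out[f"P_t_Nf{N_f:.0e}"] = [
                total_capture(nm, N_f, scenario).probability for nm in N_m
            ]
    return out


def _fig6(scenario: EggScenario, points: int) -> pd.DataFrame:
    import warnings as _w
    N_a = np.geomspace(1e2, 1e6, points)
    out = pd.DataFrame({"N_a": N_a})
    with _w.catch_warnings():
        _w.simplefilter("ignore")
        for N_f, panel in ((1e5, "A"), (3e5, "B")):
            for n in (1, 3, 6, 9):
                out[f"P_a_{panel}_n{n}"] = [
                    per_aster_capture(na, n, N_f, scenario).probability for na in N_a
                ]
    return out


def figure_data(
    figure_id: str,
    params: TubulinParameters | None = None,
    scenario: EggScenario | None = None,
    points: int = 200,
) -> pd.DataFrame:
    """Data table for one of the standard figures (see module docstring).

    fig1-fig4 use ``params`` (default: generic cell); fig5-fig6 use
    ``scenario`` (default: Beroe egg).
    """
    if figure_id not in FIGURE_IDS:
        raise KeyError(f"unknown figure id {figure_id!r}; expected one of {FIGURE_IDS}")
    if figure_id in ("fig1", "fig2", "fig3", "fig4"):
        p = params if params is not None else generic_cell()
        return {"fig1": _fig1, "fig2": _fig2, "fig3": _fig3, "fig4": _fig4}[figure_id](p, points)
    sc = scenario if scenario is not None else EggScenario()
    return {"fig5": _fig5, "fig6": _fig6}[figure_id](sc, points)
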