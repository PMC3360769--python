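"""Stochastic oracle: reflected drift-diffusion of microtubule lengths.

Each microtubule length x(t) follows the two-parameter coarse-graining
of dynamic instability,

    dx = b(c) dt + sqrt(2 a) dW ,

reflected at x = 0 (an unoccupied nucleation site is a microtubule of
zero length) and optionally at a length bound R.  The noise amplitude
sqrt(2 a dt) is fixed by requiring the stationary density of the
reflected process to be ∝ exp(b x / a), the exponential law the
analytical theory rests on.

Pool feedback: after every Euler-Maruyama step the free concentration is
recomputed from conservation, c = c_t - polymer.  Simulating all N
microtubules of an egg-scale aster is wasteful, so an ensemble of
M << N microtubules is simulated and its polymer mass scaled by N/M;
this preserves the mean-field coupling (the pool couples to the
ensemble only through its mean) at desk-scale cost, while ensemble
fluctuations are those of M, not N, chains.

This module exists to verify the analytical steady state and length
distribution independently; it shares no code path with the solvers it
checks.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .params import TubulinParameters, dimers_per_uM
from .steady_state import steady_c_bounded, steady_c_exact

__all__ = ["SimConfig", "SimResult", "simulate", "compare_to_analytic"]


@dataclass(frozen=True)
class SimConfig:
    """Monte-Carlo run configuration.

    M simulated microtubules stand in for the N real ones (pool feedback
    scaled by N/M); ``burn_in`` is the fraction of the run discarded
    before averaging; ``c_clamp`` fixes the free concentration (µM) and
    disables pool feedback, decoupling the chains for distributional
    tests.
    """

    M: int = 500
    dt: float = 1e-3          # min
    t_total: float = 200.0    # min
    burn_in: float = 0.5
    seed: int = 1
    R: float | None = None    # µm
    c_clamp: float | None = None  # µM
    record_every: int = 10    # steps between recorded samples

    def __post_init__(self) -> None:
        if self.M < 1:
            raise ValueError("M must be >= 1")
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if not 0 <= self.burn_in < 1:
            raise ValueError("burn_in must lie in [0, 1)")
        if self.R is not None and self.R <= 0:
            raise ValueError("length bound R must be positive")
        if self.record_every < 1:
            raise ValueError("record_every must be >= 1")


@dataclass(frozen=True)
class SimResult:
    """Stationary summaries of one run.

    ``c_mean``/``c_se``: time-averaged free concentration (µM) with a
    block-bootstrap-free standard error from non-overlapping block
    means.  ``lengths``: the post-burn-in final snapshot of the M
    microtubule lengths (µm) — independent draws when c is clamped.
    ``mean_length_se`` is the across-ensemble standard error of
    ``mean_length``.  ``polymer_fraction`` is the fraction of total
    tubulin in polymer at the end of the run.
    """

    c_mean: float
    c_se: float
    lengths: np.ndarray
    mean_length: float
    mean_length_se: float
    polymer_fraction: float
    diagnostics: dict = field(default_factory=dict)

    def __eq__(self, other) -> bool:  # dataclass eq breaks on arrays
        if not isinstance(other, SimResult):
            return NotImplemented
        return (
            self.c_mean == other.c_mean
            and self.c_se == other.c_se
            and np.array_equal(self.lengths, other.lengths)
            and self.mean_length == other.mean_length
            and self.mean_length_se == other.mean_length_se
            and self.polymer_fraction == other.polymer_fraction
            and self.diagnostics == other.diagnostics
        )


def _block_se(series: np.ndarray, n_blocks: int = 20) -> float:
    """Standard error of the series mean from non-overlapping block means
    (blocks long against the correlation time make this consistent)."""
    n_blocks = min(n_blocks, len(series))
    if n_blocks < 2:
        return float("nan")
    usable = (len(series) // n_blocks) * n_blocks
    blocks = series[:usable].reshape(n_blocks, -1).mean(axis=1)
    return float(blocks.std(ddof=1) / math.sqrt(n_blocks))


def simulate(params: TubulinParameters, N: float, config: SimConfig) -> SimResult:
    """Run the reflected Euler-Maruyama ensemble and return stationary
    summaries.  Deterministic for a fixed seed.

    Raises
    ------
    RuntimeError
        if pool feedback drives c below zero (the time step is too large
        for the chosen N).
    """
    if N < 0:
        raise ValueError("N must be non-negative")
    rng = np.random.default_rng(config.seed)
    M, dt = config.M, config.dt
    n_steps = int(round(config.t_total / dt))
    start = int(math.ceil(config.burn_in * n_steps))
    sigma = math.sqrt(2.0 * params.a * dt)
    scale = (N / M) if N > 0 else 0.0
    # µM of polymer per µm of real total length
    uM_per_um = 1.0 / (params.lambda_dimer * dimers_per_uM(params))
    clamped = config.c_clamp is not None

    x = np.zeros(M)
    c = float(config.c_clamp) if clamped else params.c_t
    c_samples: list[float] = []
    n_rec = 0

    for step in range(n_steps):
        b = params.k * (c - params.c_c)
        x += b * dt + sigma * rng.standard_normal(M)
        np.abs(x, out=x)  # reflect at 0
        if config.R is not None:
            over = x > config.R
            if over.any():
                x[over] = 2.0 * config.R - x[over]  # reflect at R
                np.abs(x, out=x)  # guard pathological dt
        if not clamped:
            c = params.c_t - scale * float(x.sum()) * uM_per_um
            if c < 0.0:
                raise RuntimeError(
                    f"free concentration driven below zero at step {step}; "
                    "reduce dt (or M is too small for this N)"
                )
        if step >= start and (step - start) % config.record_every == 0:
            c_samples.append(c)
            n_rec += 1

    c_arr = np.array(c_samples) if c_samples else np.array([c])
    mean_len = float(x.mean())
    polymer = scale * float(x.sum()) * uM_per_um
    return SimResult(
        c_mean=float(c_arr.mean()),
        c_se=_block_se(c_arr),
        lengths=x.copy(),
        mean_length=mean_len,
        mean_length_se=float(x.std(ddof=1) / math.sqrt(M)) if M > 1 else float("nan"),
        polymer_fraction=polymer / params.c_t,
        diagnostics={
            "n_steps": n_steps,
            "n_recorded": n_rec,
            "clamped": clamped,
            "scale": scale,
            "drift_final": params.k * (c - params.c_c),
        },
    )


def compare_to_analytic(
    params: TubulinParameters, N: float, config: SimConfig, n_se: float = 3.0
) -> dict:
    """Run the simulator with pool feedback and test its time-averaged c
    against the analytical steady state (exact solver when unbounded,
    numerical solver when a length bound is set).

    Returns a structured report with the z-score and a pass flag at the
    ``n_se``-standard-error level.
    """
    if config.c_clamp is not None:
        raise ValueError("comparison requires pool feedback (c_clamp must be None)")
    result = simulate(params, N, config)
    if config.R is None:
        analytic = steady_c_exact(N, params)
    else:
        analytic = steady_c_bounded(N, config.R, params)
    if N == 0:
        z = 0.0 if result.c_mean == params.c_t else math.inf
        c_ref = params.c_t  # conservation answer with no nucleators
    else:
        c_ref = analytic.c
        z = (result.c_mean - c_ref) / result.c_se if result.c_se > 0 else math.inf
    return {
        "c_sim": result.c_mean,
        "c_se": result.c_se,
        "c_analytic": c_ref,
        "z": z,
        "passed": abs(z) <= n_se,
        "method": analytic.method,
        "mean_length_sim": result.mean_length,
        "mean_length_analytic": analytic.mean_length,
        "diagnostics": result.diagnostics,
    }
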