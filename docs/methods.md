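# Methods

## Model and assumptions

Microtubule dynamic instability is represented by its diffusion-with-
drift approximation: the plus-end position performs Brownian motion
with drift `b = k (c − c_c)` (µm/min) and diffusion coefficient `a`
(µm²/min), the first and second statistical moments of the length
process. This two-parameter picture is valid on the cell scale, where
individual growth/catastrophe episodes are short against the times of
interest; it cannot resolve phenomena that depend on the four- or
eight-parameter dynamic-instability structure (explicitly out of scope
here, as are first-contact-time distributions and pronucleus motility
mechanics).

N nucleation sites at the centrosome behave as a reflecting boundary at
zero length: an unoccupied site is a microtubule of length zero. The
stationary length density is then exponential, `p(x) ∝ exp(bx/a)`,
requiring `b < 0` (free concentration below critical) when growth is
unrestricted; with a geometric bound R the density is the truncated
exponential on [0, R] with reflecting ends, and `b` of either sign is
admissible.

Closing the system with tubulin conservation,
`c + N·E[x|c] / (λ N_A V) = c_t`, gives:

* **unbounded growth** — a quadratic in the normalized deficit
  `u = (c_c − c)/(c_t − c_c)`: `u(1+u) = N/ν`, solved in closed form by
  `u = (√(1+4N/ν) − 1)/2` (the other root puts c above critical, where
  the exponential density does not exist);
* **linearized** — `u = N/ν`, the tangent at N = 0 (slope −1/ν),
  accurate to better than 1% in the deficit for N ≤ 0.01 ν;
* **bounded** — a strictly increasing scalar conservation residual
  solved by Brent's method on [0, c_t] (relative tolerance 1e−12,
  tighter than the 1e−10 required; the bracket always contains the root
  unless the demanded polymer exceeds the total supply, which raises).

All downstream density and capture formulas use the linearized steady
state, justified because realistic nucleation capacities (≤10⁶) are
orders of magnitude below ν (1.4·10⁸ for the *Beroe* egg, 3.6·10⁴ for
the generic cell); `planar_density(..., linearized=False)` substitutes
the exact solution as a diagnostic of that approximation.

### N = 0 convention

The unbounded closed form tends to c = c_c as N → 0⁺, while exactly
zero nucleators leave the whole pool free (c = c_t). `steady_c_exact`
returns the limit value c_c (continuity of the analytical family);
`steady_c_bounded` returns the conservation answer c_t. Both choices
are documented on the functions.

## Parameters

| symbol | meaning | default | unit |
|---|---|---|---|
| λ | lattice length per tubulin dimer | 6.12e−4 | µm |
| a | end diffusion coefficient | 7.5 | µm²/min |
| k | elongation rate constant | 1.0 | µm·min⁻¹·µM⁻¹ |
| c_c | critical concentration | 11.5 | µM |
| c_t | total tubulin | 25.0 | µM |
| V | cytoplasmic volume | 4e−12 (generic) / 1.571e−8 (Beroe) | L |
| d_e, h, d_f | egg diameter, ectoplasm thickness, pronucleus diameter | 1000, 5, 15 | µm |

The Beroe volume is the thin cortical shell π d_e² h (15.7 nL): both
the microtubules and the unpolymerized tubulin are taken to be confined
to the ectoplasm, making the egg geometrically similar to a thinly
spread cultured cell. N is treated as a continuous non-negative real
throughout — nucleation capacity, not an integer count. Microtubule
counts outside [10², 10⁶] in the egg warn (plausibility band) but are
not rejected.

## Capture model

An organelle of diameter d_o at distance x is captured when at least
one microtubule crosses the arc of length d_o it subtends; for randomly
directed microtubules the crossing count is Poisson with mean m(x)·d_o.
The representation is a 1-D arc, not a 2-D disc — accurate when d_o is
small against x and the mean length (a warning fires for d_o > x/5).
On the egg, the pronucleus diameter d_f plays the role of d_o, the
geodesic circumference replaces 2πx, and microtubules longer than half
the circumference are excluded (the domain of x is the open interval
(0, πd_e/2); the capture integrand is set to its limit 0 at both
endpoints, where the position density vanishes faster than the density
diverges). Acentrosomal and competitor-aster microtubules deplete the
pool (total-N exponent) but never add to a given aster's density, and
are assumed to share the exponential length statistics of nucleated
microtubules.

The capture integral uses adaptive quadrature (`scipy.integrate.quad`,
relative tolerance 1e−8, subdivision limit 200) with break points
seeded at the density decay length ξ/N_total, where the integrand
localizes for large total nucleation; the returned quadrature error
estimate is part of the result.

## Optimization over nucleation capacity

`optimal_sperm_nucleation` scans a log grid (25 points per decade over
log₁₀N ∈ [1, 8] by default). If the near-optimal set
{N : P ≥ P_max − 10⁻³} spans more than one decade, the objective is a
plateau: the interval is reported and the argmax is its geometric
midpoint — one representative value with honest uncertainty, since any
point of the plateau is operationally optimal. Otherwise the argmax is
refined by bounded scalar minimization (in log₁₀N, tolerance 1e−6)
between the neighbouring grid points. A flat-zero objective returns
the full search range as plateau with maximum 0.

## Stochastic oracle

The simulator advances M microtubule lengths by Euler–Maruyama,
`Δx = b(c)Δt + √(2aΔt)·z`, with reflection by folding at 0 (and at R
when bounded); the noise amplitude √(2a) is fixed so that the reflected
process's stationary density is exp(bx/a), the law the analytic theory
uses — this resolves the √a-vs-√(2a) convention ambiguity by
construction, and the exponential-distribution test enforces it. After
each step the free concentration is recomputed from conservation, with
polymer mass scaled by N/M so that M simulated chains reproduce the
pool feedback of N real ones (valid because the pool couples only
through the ensemble mean; ensemble fluctuations are those of M
chains, so standard errors refer to the simulated, not the physical,
ensemble). Defaults: M = 500, dt = 10⁻³ min, t_total = 200 min,
burn-in 0.5, seed 1. Unit tests run shorter (t_total 20–80 min) to
keep the suite fast; the full-scale run lives in the acceptance test.
The time-average standard error uses 20 non-overlapping block means
(block length ≫ the pool correlation time, ≈0.4 min for the generic
cell at N = 0.1ν). A dt too large for the chosen N can drive c < 0 and
raises with that advice. Identical seeds give bit-identical results.

What a green stochastic test establishes: the analytic steady state and
exponential length law are consistent with the two-parameter reflected
drift-diffusion process at the 3-standard-error level. It does not
validate the diffusion-with-drift approximation itself against real
dynamic instability, spatial capture events, or pre-steady-state
transients.

## Degenerate and edge cases

* c_t < c_c raises `SubCriticalError`; at exact equality ν = ξ = χ = 0
  is returned (empty-pool degenerate case — χ's formula diverges there,
  but as a mean-length unit it has no meaning without a polymerizable
  pool, and νχ = ξ holds trivially).
* The bounded length-density takes the b → 0 limit 1/R analytically
  (series switch at |bR/a| < 10⁻¹²); the truncated-exponential mean
  uses asymptotic branches for |bR/a| > 700 to avoid overflow.
* x = 0 is excluded from density evaluations (the 1/x divergence at the
  centrosome is physical).

## Known limitations

* The planar theory is strictly two-dimensional; no 3-D aster geometry.
* Capture is a static Poisson crossing criterion: no first-contact
  times, no motor kinetics, no pronucleus trajectories.
* Pre-steady-state behaviour (e.g. the advantage of early-entering
  sperm) is outside the steady-state framework.
* The published capture-probability curves carry no printed numeric
  values; the test suite checks the property claims those curves
  illustrate (plateau of near-certain capture, unique crowded-egg
  maximum, optimum decreasing with sperm count) rather than digitized
  curve values.
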