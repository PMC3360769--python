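"""Spherical-ectoplasm egg model: densities, capture integrals, optima."""

import math
import warnings

import numpy as np
import pytest

import mtaster as mt


@pytest.fixture(autouse=True)
def _silence_plausibility_warnings():
    # sweeps deliberately cross the plausibility band edges
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", UserWarning)
        yield


class TestSphericalDensity:
    def test_reduces_to_planar_near_centrosome(self, egg, generic):
        """For x << d_e the geodesic circumference tends to 2*pi*x and the
        spherical density matches the planar one (same xi, no competitors)."""
        x = 0.05  # µm, 2x/d_e = 1e-4
        planar = mt.planar_density(x, 1e4, egg.params)
        spherical = mt.spherical_density(x, 1e4, 1e4, egg)
        assert spherical == pytest.approx(planar, rel=1e-8)

    def test_equator_denominator(self, egg):
        """At the equator sin(2x/d_e) = 1, so the circumference is pi*d_e."""
        x = math.pi * egg.geometry.d_e / 4
        m = mt.spherical_density(x, 1e4, 1.01e4, egg)
        expected = 1e4 * math.exp(-1.01e4 * x / egg.xi) / (math.pi * egg.geometry.d_e)
        assert m == pytest.approx(expected, rel=1e-12)

    def test_competitors_deplete_but_do_not_contribute(self, egg):
        """Raising N_total at fixed N_own only attenuates the exponential."""
        x = 200.0
        alone = mt.spherical_density(x, 1e4, 1e4, egg)
        crowded = mt.spherical_density(x, 1e4, 5e5, egg)
        assert crowded < alone
        ratio = crowded / alone
        assert ratio == pytest.approx(math.exp(-(5e5 - 1e4) * x / egg.xi), rel=1e-10)

    def test_domain_excludes_antipode(self, egg):
        half = math.pi * egg.geometry.d_e / 2
        with pytest.raises(ValueError, match="half the egg circumference"):
            mt.spherical_density(half, 1e3, 1e3, egg)
        with pytest.raises(ValueError):
            mt.spherical_density(0.0, 1e3, 1e3, egg)
        with pytest.raises(ValueError):
            mt.spherical_density(100.0, 1e4, 1e3, egg)  # N_total < N_own


class TestDistancePdf:
    def test_normalized_with_poles_and_mode(self, egg):
        geom = egg.geometry
        x = np.linspace(0.0, math.pi * geom.d_e / 2, 40001)
        pdf = mt.distance_pdf(x, geom)
        assert np.trapezoid(pdf, x) == pytest.approx(1.0, abs=1e-8)
        assert pdf[0] == 0.0 and pdf[-1] == pytest.approx(0.0, abs=1e-12)
        assert x[pdf.argmax()] == pytest.approx(math.pi * geom.d_e / 4, rel=1e-3)

    def test_out_of_range(self, egg):
        with pytest.raises(ValueError):
            mt.distance_pdf(-1.0, egg.geometry)
        with pytest.raises(ValueError):
            mt.distance_pdf(math.pi * egg.geometry.d_e, egg.geometry)


class TestTotalCapture:
    def test_no_aster_no_capture(self, egg):
        assert mt.total_capture(0.0, 1e4, egg).probability == 0.0

    def test_guaranteed_capture_regime(self, egg):
        """Few female microtubules, ample sperm aster: capture is near certain."""
        res = mt.total_capture(1e4, 1e2, egg)
        assert res.probability > 0.99
        assert res.quad_error < 1e-6

    def test_quadrature_against_fixed_grid(self, egg):
        """The adaptive integral agrees with a dense trapezoid evaluation."""
        N_m, N_f = 3e4, 3e5
        x = np.linspace(1e-6, math.pi * egg.geometry.d_e / 2 - 1e-6, 200001)
        m = mt.spherical_density(x, N_m, N_f + N_m, egg)
        integrand = -np.expm1(-m * egg.geometry.d_f) * mt.distance_pdf(x, egg.geometry)
        ref = np.trapezoid(integrand, x)
        res = mt.total_capture(N_m, N_f, egg)
        assert res.probability == pytest.approx(ref, rel=1e-6)

    def test_increasing_in_pronucleus_size(self, egg):
        """A larger pronucleus subtends a longer arc and is easier to capture."""
        small = mt.EggScenario.from_geometry(mt.EggGeometry(d_e=1000, h=5, d_f=10))
        large = mt.EggScenario.from_geometry(mt.EggGeometry(d_e=1000, h=5, d_f=20))
        assert (mt.total_capture(1e5, 3e5, large).probability
                > mt.total_capture(1e5, 3e5, small).probability)

    def test_crowded_egg_suppresses_capture(self, egg):
        """With N_f = 1e6 female microtubules the sperm aster can no longer
        guarantee capture at any nucleation capacity."""
        peak = max(
            mt.total_capture(N_m, 1e6, egg).probability
            for N_m in np.geomspace(1e2, 1e6, 33)
        )
        assert peak <= 0.5


class TestPerAsterCapture:
    def test_single_sperm_reduces_to_total(self, egg):
        a = mt.per_aster_capture(2e4, 1, 1e5, egg)
        b = mt.total_capture(2e4, 1e5, egg)
        assert a.probability == pytest.approx(b.probability, rel=1e-12)

    def test_equivalent_total_formulation(self, egg):
        """P_a(N_a, n) equals P_t(N_a) with the other n-1 asters folded into
        the competitor count — identical by construction."""
        pa = mt.per_aster_capture(1e4, 4, 2e5, egg).probability
        pt = mt.total_capture(1e4, 2e5 + 3e4, egg).probability
        assert pa == pytest.approx(pt, rel=1e-12)

    @pytest.mark.parametrize("N_a", [1e3, 1e4, 1e5])
    def test_strictly_decreasing_in_sperm_count(self, egg, N_a):
        probs = [mt.per_aster_capture(N_a, n, 1e5, egg).probability
                 for n in (1, 2, 4, 8, 16)]
        assert all(p1 > p2 for p1, p2 in zip(probs, probs[1:]))

    def test_vanishes_for_many_sperm(self, egg):
        assert mt.per_aster_capture(1e4, 5000, 1e5, egg).probability < 1e-3

    def test_validation(self, egg):
        with pytest.raises(ValueError):
            mt.per_aster_capture(1e4, 0, 1e5, egg)
        with pytest.raises(ValueError):
            mt.per_aster_capture(-1.0, 1, 1e5, egg)


class TestOptimalSpermNucleation:
    def test_uncrowded_egg_has_broad_plateau(self, egg):
        """N_f = 1e2: a wide band of nucleation capacities all give P ~ 1;
        reported as a plateau spanning more than a decade."""
        opt = mt.optimal_sperm_nucleation(1, 1e2, egg)
        lo, hi = opt.plateau_interval
        assert opt.plateau
        assert opt.p_max > 0.999
        assert hi / lo > 10
        assert lo <= 2e3 and hi >= 1e5
        assert lo <= opt.argmax <= hi
        assert opt.argmax == pytest.approx(math.sqrt(lo * hi))

    def test_crowded_egg_has_unique_maximum(self, egg):
        """N_f = 1e6: the objective has a uniquely defined interior maximum."""
        opt = mt.optimal_sperm_nucleation(1, 1e6, egg)
        assert not opt.plateau
        assert opt.p_max <= 0.5
        assert 1e4 < opt.argmax < 1e6  # interior of the search range

    def test_optimum_decreases_with_sperm_number(self, egg):
        """N_f = 3e5: competition lowers each sperm's optimal capacity."""
        arg = {n: mt.optimal_sperm_nucleation(n, 3e5, egg).argmax for n in (1, 3, 9)}
        assert arg[9] < arg[3] < arg[1]

    def test_flat_zero_objective(self, egg):
        """With an absurd sperm count every capacity gives P ~ 0; the full
        search range is reported as the plateau."""
        opt = mt.optimal_sperm_nucleation(10**6, 1e6, egg, search_range=(5.0, 7.0))
        assert opt.plateau
        assert opt.p_max < 1e-6
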