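"""Spray-axis validity, ideal size ranges, dose and improvement estimates."""

import math

import numpy as np
import pytest

import nasodose as nd
from nasodose.delivery_analysis import round_api
from nasodose.errors import DomainError, InterpolationError, PlacementError
from nasodose.product_model import BUILTIN_PRODUCTS
from nasodose.spray_transport import DepositionCurve
from nasodose.stokes_scaling import SizeRange

FLONASE = BUILTIN_PRODUCTS["Flonase"]
NASACORT = BUILTIN_PRODUCTS["Nasacort"]


def _curve(eff_by_diameter, protocol="IU", flow=15.0):
    d = np.arange(1.0, 25.0)
    eff = np.array([eff_by_diameter.get(int(x), 0.0) for x in d])
    return DepositionCurve(protocol, flow, "left", d, eff, 100, 0)


class TestAxes:
    def test_cu_axis_is_vertical_with_lateral_anchor(self, model, cu):
        assert np.allclose(cu.direction, [0.0, 0.0, 1.0])
        offset = cu.origin - model.nostril_centroid
        r0 = float(model.radius_m[0])
        # anchored a third of the lateral-septal width from the lateral wall
        assert np.linalg.norm(offset) == pytest.approx(r0 / 3.0)
        assert offset @ model.lateral_unit > 0
        assert cu.insertion_depth_mm == 5.0

    def test_iu_axis_passes_all_three_criteria(self, model, iu):
        rep = nd.validate_iu_axis(iu, model)
        assert rep.intersects_nasopharynx
        assert rep.avoids_septum
        assert rep.lateral_wall_posterior
        assert rep.valid

    def test_septum_crossing_axis_fails(self, model):
        medial = -model.lateral_unit
        aim = 0.97 * np.array(model.tangents[150]) + 0.25 * medial
        ax = nd.SprayAxis("IU", model.nostril_centroid, aim)
        rep = nd.validate_iu_axis(ax, model)
        assert not rep.avoids_septum
        assert not rep.valid

    def test_anterior_exit_axis_fails_lateral_criterion(self, model, cu):
        # the upright CU axis exits through the anterior roof
        rep = nd.validate_iu_axis(
            nd.SprayAxis("CU", model.nostril_centroid, cu.direction), model
        )
        assert not rep.lateral_wall_posterior
        assert rep.first_wall_s < 0.2

    def test_origin_off_nostril_plane_raises(self, model, iu):
        shifted = nd.SprayAxis(
            "IU", iu.origin + 0.002 * model.nostril_normal, iu.direction
        )
        with pytest.raises(PlacementError):
            nd.validate_iu_axis(shifted, model)


class TestIdealSizeRange:
    def test_threshold_selection(self):
        rng = nd.ideal_size_range(_curve({12: 0.03, 13: 0.05}))
        assert (rng.d_min_um, rng.d_max_um) == (12.0, 13.0)
        assert not rng.empty

    def test_all_below_cutoff_flags_empty(self):
        assert nd.ideal_size_range(_curve({12: 0.01})).empty

    def test_single_qualifying_size(self):
        rng = nd.ideal_size_range(_curve({17: 0.02}))
        assert rng.d_min_um == rng.d_max_um == 17.0

    def test_monotone_in_cutoff(self, sim_curves):
        curve = sim_curves[("IU", 15.0)]
        prev = None
        for cutoff in (0.01, 0.02, 0.05, 0.1):
            rng = nd.ideal_size_range(curve, cutoff)
            if rng.empty:
                break
            if prev is not None:
                assert rng.d_min_um >= prev.d_min_um
                assert rng.d_max_um <= prev.d_max_um
            prev = rng


class TestGenericRange:
    def test_mean_of_extrema(self):
        rngs = [
            SizeRange(7, 16, 30.0),
            SizeRange(8, 17, 30.0),
        ]
        gen = nd.generic_range(rngs)
        assert (gen.d_min_um, gen.d_max_um) == (7.5, 16.5)

    def test_eight_case_average(self):
        rng = np.random.default_rng(3)
        mins = rng.uniform(4, 9, 8)
        maxs = mins + rng.uniform(5, 12, 8)
        gen = nd.generic_range(
            [SizeRange(lo, hi, 15.0) for lo, hi in zip(mins, maxs)]
        )
        assert gen.d_min_um == pytest.approx(mins.mean())
        assert gen.d_max_um == pytest.approx(maxs.mean())

    def test_single_range_is_itself(self):
        gen = nd.generic_range([SizeRange(5, 11, 30.0)])
        assert (gen.d_min_um, gen.d_max_um) == (5.0, 11.0)

    def test_permutation_invariant(self):
        rngs = [SizeRange(5, 11, 30.0), SizeRange(9, 24, 30.0), SizeRange(7, 14, 30.0)]
        a = nd.generic_range(rngs)
        b = nd.generic_range(rngs[::-1])
        assert (a.d_min_um, a.d_max_um) == (b.d_min_um, b.d_max_um)

    def test_empty_input_raises(self):
        with pytest.raises(DomainError):
            nd.generic_range([])


class TestWeightedDeposition:
    def test_constant_efficiency_factorizes(self):
        eta = 0.37
        curve = _curve({k: eta for k in range(1, 25)})
        expected = eta * FLONASE.shot_mass_mg * FLONASE.distribution.mass_fraction(1, 24)
        assert nd.weighted_deposition(curve, FLONASE) == pytest.approx(expected, rel=1e-9)

    def test_zero_curve_gives_zero(self):
        assert nd.weighted_deposition(_curve({}), FLONASE) == 0.0

    def test_bounded_by_in_range_mass(self, sim_curves):
        for curve in sim_curves.values():
            dep = nd.weighted_deposition(curve, FLONASE)
            bound = FLONASE.shot_mass_mg * FLONASE.distribution.mass_fraction(1, 24)
            assert 0.0 <= dep <= bound + 1e-12

    def test_monte_carlo_oracle(self):
        """Quadrature matches mass-weighted Monte-Carlo within 3 s.e."""
        rng_curve = _curve({k: 0.5 * np.exp(-((k - 13) ** 2) / 18.0) for k in range(1, 25)})
        n = 10**6
        rng = np.random.default_rng(99)
        draws = FLONASE.distribution.sample_mass_weighted(n, rng)
        eff = rng_curve.interpolator()(draws)
        mc = FLONASE.shot_mass_mg * eff.mean()
        se = FLONASE.shot_mass_mg * eff.std() / math.sqrt(n)
        assert abs(nd.weighted_deposition(rng_curve, FLONASE) - mc) < 3 * se

    def test_uncovered_interval_raises(self):
        d = np.arange(5.0, 25.0)
        curve = DepositionCurve("IU", 15.0, "left", d, np.zeros(d.size), 10, 0)
        with pytest.raises(InterpolationError):
            nd.weighted_deposition(curve, FLONASE)


class TestApiMass:
    @pytest.mark.parametrize(
        "deposited,product,expected",
        [
            (1.9187, FLONASE, 0.96),
            (0.0495, FLONASE, 0.025),
            (1.8450, NASACORT, 0.92),
            (0.0482, NASACORT, 0.024),
        ],
    )
    def test_printed_delivery_estimates(self, deposited, product, expected):
        assert round_api(nd.api_mass(deposited, product)) == expected

    def test_linear_in_deposited_mass(self):
        assert nd.api_mass(3.0, FLONASE) == pytest.approx(3 * nd.api_mass(1.0, FLONASE))

    def test_zero_and_negative(self):
        assert nd.api_mass(0.0, FLONASE) == 0.0
        with pytest.raises(DomainError):
            nd.api_mass(-1.0, FLONASE)


class TestImprovement:
    def test_printed_flonase_pair(self):
        assert nd.improvement_oom(1.9187, 0.0495) == pytest.approx(1.588, abs=5e-4)

    def test_equal_masses_zero(self):
        assert nd.improvement_oom(1.0, 1.0) == 0.0

    def test_hundredfold_is_two(self):
        assert nd.improvement_oom(5.0, 0.05) == pytest.approx(2.0)

    def test_zero_cu_flagged_infinite_and_excluded(self):
        assert math.isinf(nd.improvement_oom(1.0, 0.0))
        with pytest.warns(UserWarning, match="excluded"):
            s = nd.summarize_improvement([(1.0, 0.01), (1.0, 0.0)])
        assert s.n == 1
        assert s.n_excluded == 1

    def test_summary_mean_and_sample_sd(self):
        pairs = [(10.0, 1.0), (100.0, 1.0), (1000.0, 1.0)]
        s = nd.summarize_improvement(pairs)
        assert s.mean == pytest.approx(2.0)
        assert s.sd == pytest.approx(1.0)  # sample (n-1) standard deviation
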