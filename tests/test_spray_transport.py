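"""Droplet injection, forces and Lagrangian tracking."""

import math

import numpy as np
import pytest

import nasodose as nd
from nasodose.errors import ConfigurationError, PlacementError
from nasodose.spray_transport import (
    DepositionCurve,
    DropletState,
    SprayInjection,
    deposition_curve,
)


@pytest.fixture()
def still_air():
    return nd.FlowField(rate_lpm=0.0)


@pytest.fixture()
def continuum():
    # zero mean free path: Cc = 1, for closed-form comparisons
    return nd.PhysicalConstants(mean_free_path=0.0)


class TestConeInjection:
    def test_default_cluster_speed_and_cone(self, model, iu):
        inj = SprayInjection(origin=iu.nozzle_tip, axis=iu.direction)
        cloud = nd.cone_injection(inj, model)
        assert len(cloud) == 3000
        speeds = np.linalg.norm(cloud.velocities, axis=1)
        assert np.allclose(speeds, 10.0, rtol=1e-12)
        cosang = cloud.velocities @ inj.axis / speeds
        assert np.all(np.degrees(np.arccos(np.clip(cosang, -1, 1))) <= 27.93 + 1e-9)

    def test_zero_half_angle_degenerates_to_axis(self, model, iu):
        inj = SprayInjection(
            origin=iu.nozzle_tip, axis=iu.direction, cone_half_angle_deg=0.0,
            n_droplets=50,
        )
        cloud = nd.cone_injection(inj, model)
        assert np.allclose(cloud.velocities / 10.0, inj.axis, atol=1e-12)

    def test_origin_outside_lumen_raises(self, model):
        inj = SprayInjection(origin=np.array([0.0, 0.05, 0.0]), axis=np.array([1.0, 0, 0]))
        with pytest.raises(PlacementError):
            nd.cone_injection(inj, model)

    def test_seed_reproducibility(self, iu):
        inj = SprayInjection(origin=iu.nozzle_tip, axis=iu.direction, seed=7, n_droplets=200)
        a = nd.cone_injection(inj)
        b = nd.cone_injection(inj)
        assert np.array_equal(a.velocities, b.velocities)

    @pytest.mark.parametrize(
        "kwargs", [{"speed_mps": 0.0}, {"n_droplets": 0}, {"cone_half_angle_deg": 95.0}]
    )
    def test_invalid_injection_rejected(self, iu, kwargs):
        with pytest.raises(ConfigurationError):
            SprayInjection(origin=iu.nozzle_tip, axis=iu.direction, **kwargs)


class TestForces:
    def test_drag_zero_at_zero_slip(self, flow15):
        a = nd.drag_force([1.0, 2.0, 3.0], [1.0, 2.0, 3.0], 10.0, 1500.0, flow15)
        assert np.allclose(a, 0.0)

    def test_relaxation_time_value(self):
        # tau = rho D^2 Cc / (18 mu) for a 10-um droplet of 1.5 g/mL
        assert nd.relaxation_time(10.0, 1500.0, 1.0) == pytest.approx(4.566e-4, rel=1e-3)

    def test_relaxation_time_quadratic_in_diameter(self):
        assert nd.relaxation_time(20.0) == pytest.approx(4 * nd.relaxation_time(10.0))

    def test_slip_correction_behaviour(self):
        cc1 = nd.slip_correction(1.0)
        cc10 = nd.slip_correction(10.0)
        assert cc1 > cc10 > 1.0
        assert nd.slip_correction(1000.0) == pytest.approx(1.0, abs=1e-3)

    def test_saffman_zero_shear_and_zero_slip(self, flow15):
        zero_grad = np.zeros((3, 3))
        assert np.allclose(nd.saffman_lift([1, 0, 0], zero_grad, 10, 1500, flow15), 0)
        grad = np.zeros((3, 3))
        grad[0, 1] = 100.0
        assert np.allclose(nd.saffman_lift([0, 0, 0], grad, 10, 1500, flow15), 0)

    def test_saffman_simple_shear_matches_textbook_formula(self, flow15):
        """Magnitude agrees with Saffman's 1965 result for simple shear."""
        shear = 300.0  # du_x/dy, 1/s
        slip = 0.5     # m/s along x
        d_um = 10.0
        rho_d = 1500.0
        grad = np.zeros((3, 3))
        grad[0, 1] = shear
        a = nd.saffman_lift([slip, 0, 0], grad, d_um, rho_d, flow15)
        # independent oracle: F = 6.46 mu (D/2)^2 |w| sqrt(G/nu), per droplet mass
        mu = flow15.air_viscosity
        nu = flow15.kinematic_viscosity
        d = d_um * 1e-6
        force = 6.46 * mu * (d / 2) ** 2 * slip * math.sqrt(shear / nu)
        mass = rho_d * math.pi * d**3 / 6
        assert np.linalg.norm(a) == pytest.approx(force / mass, rel=1e-3)
        # lagging droplet in positive shear migrates toward faster fluid (+y)
        assert a[1] > 0


class TestStepDroplet:
    def test_pure_drag_speed_decays(self, model, still_air, continuum):
        p0 = model.centerline[300].copy()
        st = DropletState(position=p0, velocity=np.array([0.0, 2.0, 0.0]), diameter_um=10)
        g_free = nd.PhysicalConstants(g_magnitude=0.0, mean_free_path=0.0)
        speeds = [np.linalg.norm(st.velocity)]
        for _ in range(20):
            st = nd.step_droplet(st, model, still_air, g_free, 1e-4)
            speeds.append(np.linalg.norm(st.velocity))
            if st.status != "airborne":
                break
        assert all(b < a for a, b in zip(speeds, speeds[1:]))

    @pytest.mark.parametrize("d_um", [1.0, 5.0, 10.0, 24.0])
    def test_terminal_velocity_closed_form(self, model, still_air, d_um):
        """Settling speed matches v_t = rho_D D^2 g Cc / (18 mu) within 1%."""
        constants = nd.PhysicalConstants()
        cc = nd.slip_correction(d_um, constants.mean_free_path)
        v_t = 1500.0 * (d_um * 1e-6) ** 2 * 9.81 * cc / (18 * still_air.air_viscosity)
        st = DropletState(position=model.centerline[300].copy(),
                          velocity=np.zeros(3), diameter_um=d_um)
        for _ in range(200):
            st = nd.step_droplet(st, model, still_air, constants, 1e-4)
            if st.status != "airborne":
                break
        assert np.linalg.norm(st.velocity) == pytest.approx(v_t, rel=0.01)

    def test_spec_terminal_velocity_example(self, model, still_air, continuum):
        # 10-um droplet with Cc = 1 settles at 4.48e-3 m/s
        st = DropletState(position=model.centerline[300].copy(),
                          velocity=np.zeros(3), diameter_um=10.0)
        for _ in range(100):
            st = nd.step_droplet(st, model, still_air, continuum, 1e-4)
        assert np.linalg.norm(st.velocity) == pytest.approx(4.48e-3, rel=0.01)

    def test_started_outside_lumen_immediately_trapped(self, model, flow15):
        st = DropletState(position=np.array([0.0, 0.03, 0.0]),
                          velocity=np.zeros(3), diameter_um=10.0)
        st = nd.step_droplet(st, model, flow15, None, 1e-4)
        assert st.status == "trapped"
        assert st.trap_time == 0.0

    def test_status_transition_monotone(self, model, flow15):
        st = DropletState(position=np.array([0.0, 0.03, 0.0]),
                          velocity=np.zeros(3), diameter_um=10.0)
        st = nd.step_droplet(st, model, flow15, None, 1e-4)
        again = nd.step_droplet(st, model, flow15, None, 1e-4)
        assert again is st  # trapped states never revert


class TestDepositionCurve:
    def test_counts_conserved_and_reproducible(self, model, flow15, iu):
        tmpl = SprayInjection(origin=np.zeros(3), axis=np.array([1.0, 0, 0]), n_droplets=60)
        kwargs = dict(diameters_um=[8.0, 14.0, 20.0], seed=5)
        c1 = deposition_curve(iu, model, flow15, tmpl, **kwargs)
        c2 = deposition_curve(iu, model, flow15, tmpl, **kwargs)
        assert np.array_equal(c1.efficiency, c2.efficiency)
        cols = ["trapped_nasopharynx", "trapped_other", "escaped_outlet",
                "escaped_front", "airborne"]
        assert (c1.counts[cols].sum(axis=1) == 60).all()

    def test_full_grid_conservation(self, sim_curves, template):
        """Trapped + escaped + airborne droplets account for every release."""
        cols = ["trapped_nasopharynx", "trapped_other", "escaped_outlet",
                "escaped_front", "airborne"]
        for curve in sim_curves.values():
            assert (curve.counts[cols].sum(axis=1) == template.n_droplets).all()
            assert np.all((curve.efficiency >= 0) & (curve.efficiency <= 1))

    def test_csv_round_trip(self, tmp_path, sim_curves):
        curve = sim_curves[("IU", 15.0)]
        path = tmp_path / "curve.csv"
        curve.to_csv(path)
        header = path.read_text().splitlines()[0]
        assert header == "protocol,flow_lpm,side,diameter_um,efficiency,n_droplets,seed"
        back = DepositionCurve.from_csv(path)
        assert np.allclose(back.efficiency, curve.efficiency)
        assert back.protocol == curve.protocol

    def test_invalid_curve_rejected(self):
        with pytest.raises(ConfigurationError):
            DepositionCurve("IU", 15.0, "left", [2.0, 1.0], [0.1, 0.2], 10, 0)
        with pytest.raises(ConfigurationError):
            DepositionCurve("IU", 15.0, "left", [1.0, 2.0], [0.1, 1.2], 10, 0)
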