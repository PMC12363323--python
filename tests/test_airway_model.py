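"""Idealized airway geometry and analytic inhalation flow field."""

import numpy as np
import pytest
from numpy.polynomial.legendre import leggauss

import nasodose as nd
from nasodose.errors import ConfigurationError, DomainError


def _section_frame(model, s_target):
    idx = int(np.argmin(np.abs(model.arc_frac - s_target)))
    s, _, c, t = model.locate(model.centerline[idx])
    e1 = np.cross(t, [0.0, 1.0, 0.0])
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(t, e1)
    return s, c, t, e1, e2


class TestGeometry:
    def test_default_model(self, model):
        assert model.region_bounds["nasopharynx"][0] == pytest.approx(0.85)
        assert model.head_tilt_deg == 22.5
        assert model.length_m == pytest.approx(0.10)
        # nasopharynx is the terminal interval; regions partition [0, 1]
        bounds = sorted(model.region_bounds.values())
        assert bounds[0][0] == 0.0
        for (lo1, hi1), (lo2, hi2) in zip(bounds, bounds[1:]):
            assert hi1 == lo2
        assert bounds[-1][1] >= 1.0
        assert np.all(model.radius_m > 0)

    def test_zero_tilt_nostril_normal_vertical(self):
        m = nd.build_idealized_airway(tilt_deg=0.0)
        assert np.allclose(m.nostril_normal, [0.0, 0.0, 1.0])

    def test_centerline_arclength_parameterized(self, model):
        seg = np.linalg.norm(np.diff(model.centerline, axis=0), axis=1)
        ds = np.diff(model.arc_frac) * model.length_m
        assert np.allclose(seg, ds, rtol=1e-4)

    def test_gravity_vector_magnitude(self, constants):
        assert np.linalg.norm(constants.g_vector) == 9.81

    @pytest.mark.parametrize(
        "kwargs",
        [
            {"length_m": -0.1},
            {"radius_profile_mm": ((0.0, 4.0), (1.0, -1.0))},
            {"nasopharynx_start_s": 1.5},
        ],
    )
    def test_invalid_config_raises(self, kwargs):
        with pytest.raises(ConfigurationError):
            nd.build_idealized_airway(**kwargs)

    def test_unknown_config_key_rejected(self):
        with pytest.raises(ConfigurationError, match="unknown"):
            nd.build_idealized_airway({"lenght_m": 0.1})

    def test_geometry_determinism_bitwise(self):
        a = nd.build_idealized_airway()
        b = nd.build_idealized_airway()
        assert np.array_equal(a.centerline, b.centerline)
        assert np.array_equal(a.radius_m, b.radius_m)


class TestFlowField:
    def test_centerline_speed_is_twice_mean(self, model, flow15):
        s, c, t, _, _ = _section_frame(model, 0.5)
        r = float(model.radius_at(s))
        u = nd.velocity_at(model, flow15, c)
        assert np.linalg.norm(u) == pytest.approx(2 * flow15.q_m3s / (np.pi * r * r))
        # parallel to the centerline tangent
        assert np.dot(u, t) == pytest.approx(np.linalg.norm(u))

    def test_wall_point_no_slip(self, model, flow15):
        s, c, t, e1, _ = _section_frame(model, 0.5)
        r = float(model.radius_at(s))
        u = nd.velocity_at(model, flow15, c + r * e1)
        assert np.allclose(u, 0.0, atol=1e-12)

    def test_outside_lumen_raises(self, model, flow15):
        with pytest.raises(DomainError):
            nd.velocity_at(model, flow15, model.nostril_centroid + np.array([0, 0.05, 0]))

    @pytest.mark.parametrize("rate", [15.0, 30.0])
    def test_flux_conservation_ten_stations(self, model, rate):
        """Volumetric flux through cross-sections equals Q to 1e-6 relative."""
        flow = nd.FlowField(rate_lpm=rate)
        xg, wg = leggauss(16)
        n_theta = 8
        for s_t in np.linspace(0.05, 0.95, 10):
            s, c, t, e1, e2 = _section_frame(model, s_t)
            r = float(model.radius_at(s))
            flux = 0.0
            for k in range(n_theta):
                th = 2 * np.pi * k / n_theta
                ray = np.cos(th) * e1 + np.sin(th) * e2
                for x, w in zip(xg, wg):
                    rho = 0.5 * (x + 1.0) * r
                    u = nd.velocity_at(model, flow, c + rho * ray)
                    flux += w * (u @ t) * rho * (0.5 * r) * (2 * np.pi / n_theta)
            assert abs(flux - flow.q_m3s) / flow.q_m3s < 1e-6


class TestClassifyPoint:
    def test_centerline_midpoint(self, model):
        _, _, c, _ = model.locate(model.centerline[len(model.arc_frac) // 2])
        cls = nd.classify_point(model, c)
        assert cls.region == "mid"
        assert cls.wall_distance == pytest.approx(float(model.radius_at(cls.s)))

    def test_far_point_negative_wall_distance(self, model):
        cls = nd.classify_point(model, np.array([0.0, 1.0, 0.0]))
        assert cls.wall_distance < -0.9

    def test_terminal_band_is_nasopharynx(self, model):
        _, _, c, _ = model.locate(model.centerline[-5])
        assert nd.classify_point(model, c).region == "nasopharynx"

    def test_random_interior_points_consistent(self, model):
        """classify_point agrees with region_bounds on sampled interior points."""
        rng = np.random.default_rng(1234)
        n_ok = 0
        for _ in range(1000):
            s_t = rng.uniform(0.01, 0.99)
            _, _, c, t = model.locate(
                model.centerline[int(round(s_t * (len(model.arc_frac) - 1)))]
            )
            e1 = np.cross(t, [0.0, 1.0, 0.0])
            e1 /= np.linalg.norm(e1)
            e2 = np.cross(t, e1)
            s_c = nd.classify_point(model, c).s
            r = float(model.radius_at(s_c))
            rho = rng.uniform(0.0, 0.8 * r)
            th = rng.uniform(0.0, 2 * np.pi)
            p = c + rho * (np.cos(th) * e1 + np.sin(th) * e2)
            cls = nd.classify_point(model, p)
            assert cls.wall_distance > 0
            # region should match the sampled station away from boundaries
            edges = [b for se in model.region_bounds.values() for b in se]
            if min(abs(s_c - e) for e in edges) > 0.01:
                assert cls.region == model.region_of(s_c)
                n_ok += 1
        assert n_ok > 800


class TestTransform:
    def test_rigid_rotation_consistency(self, model, flow15):
        from scipy.spatial.transform import Rotation

        rot = Rotation.from_euler("xyz", [10, 25, -40], degrees=True).as_matrix()
        m2 = model.transformed(rot)
        p = model.centerline[300] + 1e-3 * np.array([0.3, 0.2, -0.1])
        c1 = nd.classify_point(model, p)
        c2 = nd.classify_point(m2, rot @ p)
        assert c1.s == pytest.approx(c2.s, abs=1e-9)
        assert c1.wall_distance == pytest.approx(c2.wall_distance, abs=1e-12)
        u1 = nd.velocity_at(model, flow15, p)
        u2 = nd.velocity_at(m2, flow15, rot @ p)
        assert np.allclose(rot @ u1, u2, atol=1e-12)
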