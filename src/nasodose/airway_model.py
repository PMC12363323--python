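"""Parametric idealized nasal passage with an analytic inhalation flow field.

The model is a reduced-order stand-in for a CT-reconstructed nasal cavity:
a single curved tube of varying circular cross-section running from the
nostril plane to the nasopharyngeal outlet.  The centerline has three parts,

* a short anterior bend (nasal vestibule / valve) turning the inlet
  direction -- tilted posteriorly off the vertical -- into the horizontal,
* a long, straight, nearly horizontal main passage, and
* a posterior bend turning downward into the nasopharynx,

so that the contrast between a vertically held spray ("current use") and an
axis aimed through the passage at the nasopharynx ("improved use") is
governed by axis alignment relative to the bends, which is the mechanism
that matters for inertia-dominated spray droplets.

The inhalation flow is quasi-one-dimensional and laminar: on every
cross-section the axial velocity is a parabolic (Poiseuille) profile scaled
so the volumetric flux equals the prescribed inhalation rate.  Geometry is
stored in the laboratory frame with gravity along -z; the forward head tilt
is applied as a rigid rotation of the whole model.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping, NamedTuple

import numpy as np
from scipy.interpolate import PchipInterpolator

from .errors import ConfigurationError, DomainError

#: Default tube radius control points as (arc-length fraction, radius in mm).
#: A slight constriction near the nasal valve, a wider main passage, and a
#: flaring posterior end where the cavity opens into the nasopharynx.
DEFAULT_RADIUS_PROFILE_MM: tuple[tuple[float, float], ...] = (
    (0.00, 4.2),
    (0.06, 4.0),
    (0.20, 4.4),
    (0.60, 4.2),
    (0.85, 3.5),
    (0.92, 3.6),
    (1.00, 5.5),
)

REGION_NAMES = ("vestibule", "anterior", "mid", "nasopharynx")


@dataclass(frozen=True)
class AirwayConfig:
    """Geometry parameters for :func:`build_idealized_airway`.

    Lengths are metres except ``radius_profile_mm`` (millimetres, matching
    the external config convention of explicit unit suffixes).
    """

    length_m: float = 0.10
    radius_profile_mm: tuple[tuple[float, float], ...] = DEFAULT_RADIUS_PROFILE_MM
    tilt_deg: float = 22.5
    nasopharynx_start_s: float = 0.85
    inlet_angle_deg: float = 30.0       # inlet tangent, posterior of vertical
    bend1_radius_m: float = 0.006       # vestibule bend
    bend2_radius_m: float = 0.006       # nasopharyngeal bend
    bend2_turn_deg: float = 80.0        # downward turn into the nasopharynx
    septal_offset_m: float = 0.0025     # septal safety plane, medial of axis
    septal_extent_s: float = 0.30       # arc fraction where the septum ends
    side: str = "left"
    n_samples: int = 600

    def validate(self) -> None:
        if self.length_m <= 0:
            raise ConfigurationError("airway length must be positive")
        if not self.radius_profile_mm:
            raise ConfigurationError("radius profile needs control points")
        for s, r in self.radius_profile_mm:
            if not 0.0 <= s <= 1.0:
                raise ConfigurationError(f"radius control point s={s} outside [0, 1]")
            if r <= 0:
                raise ConfigurationError(f"non-positive radius control point r={r} mm")
        if not 0.0 < self.nasopharynx_start_s < 1.0:
            raise ConfigurationError("nasopharynx_start_s must lie in (0, 1)")
        if self.side not in ("left", "right"):
            raise ConfigurationError("side must be 'left' or 'right'")
        arc1 = self.bend1_radius_m * np.deg2rad(90.0 - self.inlet_angle_deg)
        arc2 = self.bend2_radius_m * np.deg2rad(self.bend2_turn_deg)
        if arc1 + arc2 >= self.length_m:
            raise ConfigurationError("bends longer than total centerline length")


@dataclass(frozen=True)
class FlowField:
    """Steady inhalation flow through the airway.

    ``rate_lpm`` is the inhaled volumetric flow in litres per minute; air
    properties default to warmed inspired air.
    """

    rate_lpm: float = 15.0
    air_density: float = 1.204          # kg/m^3
    air_viscosity: float = 1.825e-5     # kg/(m s)

    @property
    def q_m3s(self) -> float:
        return self.rate_lpm * 1e-3 / 60.0

    @property
    def kinematic_viscosity(self) -> float:
        return self.air_viscosity / self.air_density


@dataclass(frozen=True)
class PhysicalConstants:
    """Body-force and gas constants used by the droplet tracker."""

    g_magnitude: float = 9.81           # m/s^2, straight down in the lab frame
    mean_free_path: float = 6.6e-8      # m, for the Cunningham slip factor

    @property
    def g_vector(self) -> np.ndarray:
        return np.array([0.0, 0.0, -self.g_magnitude])


class PointClassification(NamedTuple):
    region: str
    s: float
    wall_distance: float  # m; negative when the point is outside the lumen


@dataclass(frozen=True)
class _CenterlinePieces:
    """Closed-form arc/line/arc centerline parameters (head frame)."""

    phi0: float       # inlet tangent angle from +z toward +x
    r1: float         # vestibule bend radius
    l1: float
    xa: float         # junction A->B
    za: float
    l2: float
    xb: float         # junction B->C
    r2: float
    phi_end: float
    length: float

    def locate(self, q: np.ndarray):
        """Nearest centerline point to head-frame ``q``.

        Returns (s, distance, closest point, unit tangent), all exact for
        the analytic arc-line-arc centerline.
        """
        best = None
        # piece A: arc of radius r1, angles [phi0, pi/2], center (r1 cos phi0, 0, -r1 sin phi0)
        for (cx, cz, rad, plo, phi_hi, s_off) in (
            (self.r1 * np.cos(self.phi0), -self.r1 * np.sin(self.phi0),
             self.r1, self.phi0, np.pi / 2.0, 0.0),
            (self.xb, self.za - self.r2, self.r2, np.pi / 2.0, self.phi_end,
             self.l1 + self.l2),
        ):
            vx = q[0] - cx
            vz = q[2] - cz
            rho = math.hypot(vx, vz)
            if rho < 1e-15:
                phi = plo
            else:
                phi = math.atan2(vz, -vx)  # arc point direction is (-cos, +sin)
                if phi < 0:
                    phi += 2.0 * np.pi
            phi = min(max(phi, plo), phi_hi)
            px = cx - rad * np.cos(phi)
            pz = cz + rad * np.sin(phi)
            d = math.sqrt((q[0] - px) ** 2 + q[1] ** 2 + (q[2] - pz) ** 2)
            s = (s_off + rad * (phi - plo)) / self.length
            tan = np.array([np.sin(phi), 0.0, np.cos(phi)])
            cand = (d, s, np.array([px, 0.0, pz]), tan)
            if best is None or d < best[0]:
                best = cand
        # piece B: straight segment
        t = min(max(q[0] - self.xa, 0.0), self.l2)
        d = math.sqrt((q[0] - (self.xa + t)) ** 2 + q[1] ** 2 + (q[2] - self.za) ** 2)
        if d < best[0]:
            best = (
                d,
                (self.l1 + t) / self.length,
                np.array([self.xa + t, 0.0, self.za]),
                np.array([1.0, 0.0, 0.0]),
            )
        d, s, point, tan = best
        return s, d, point, tan


@dataclass
class AirwayModel:
    """Sampled idealized airway in the laboratory frame."""

    centerline: np.ndarray          # (N, 3) m
    tangents: np.ndarray            # (N, 3) unit vectors
    arc_frac: np.ndarray            # (N,) arc-length fraction in [0, 1]
    radius_m: np.ndarray            # (N,) local tube radius
    length_m: float
    head_tilt_deg: float
    rotation: np.ndarray            # (3, 3) head -> lab rotation
    region_bounds: dict
    nostril_centroid: np.ndarray
    nostril_normal: np.ndarray
    septal_point: np.ndarray
    septal_normal: np.ndarray
    septal_extent_s: float
    lateral_sign: float
    config: AirwayConfig
    pieces: _CenterlinePieces = field(repr=False, default=None)
    _radius_interp: PchipInterpolator = field(repr=False, default=None)

    # -- geometry queries ---------------------------------------------------
    def radius_at(self, s) -> np.ndarray | float:
        """Tube radius (m) at arc-length fraction ``s``."""
        return self._radius_interp(np.clip(s, 0.0, 1.0)) * 1e-3

    def region_of(self, s: float) -> str:
        for name, (lo, hi) in self.region_bounds.items():
            if lo <= s < hi:
                return name
        return "nasopharynx" if s >= 1.0 else "vestibule"

    @property
    def lateral_unit(self) -> np.ndarray:
        """Unit vector pointing from the septal toward the lateral wall."""
        return self.rotation @ np.array([0.0, self.lateral_sign, 0.0])

    @property
    def outlet_point(self) -> np.ndarray:
        return self.centerline[-1]

    @property
    def outlet_normal(self) -> np.ndarray:
        return self.tangents[-1]

    def locate(self, position) -> tuple[float, float, np.ndarray, np.ndarray]:
        """Exact nearest-centerline projection of a laboratory-frame point.

        Returns (arc fraction s, distance, closest point, unit tangent),
        computed in closed form on the analytic arc-line-arc centerline
        (the sampled polyline is used only by the transport kernels).
        """
        q = self.rotation.T @ np.asarray(position, dtype=float)
        s, d, point, tan = self.pieces.locate(q)
        return s, d, self.rotation @ point, self.rotation @ tan

    def geometry_arrays(self):
        """Contiguous arrays consumed by the numba transport kernels."""
        return (
            np.ascontiguousarray(self.centerline),
            np.ascontiguousarray(self.tangents),
            np.ascontiguousarray(self.arc_frac),
            np.ascontiguousarray(self.radius_m),
        )

    def transformed(self, rot: np.ndarray) -> "AirwayModel":
        """Rigidly rotate the whole model (used for equivariance checks)."""
        rot = np.asarray(rot, dtype=float)
        return replace(
            self,
            centerline=self.centerline @ rot.T,
            tangents=self.tangents @ rot.T,
            rotation=rot @ self.rotation,
            nostril_centroid=rot @ self.nostril_centroid,
            nostril_normal=rot @ self.nostril_normal,
            septal_point=rot @ self.septal_point,
            septal_normal=rot @ self.septal_normal,
        )


def _rotation_forward_tilt(tilt_deg: float) -> np.ndarray:
    """Rotation pitching the head forward by ``tilt_deg`` about +y.

    Head frame: +x posterior, +y lateral, +z up.  A forward tilt moves the
    anterior direction (-x) downward.
    """
    th = np.deg2rad(-tilt_deg)
    c, s = np.cos(th), np.sin(th)
    return np.array([[c, 0.0, s], [0.0, 1.0, 0.0], [-s, 0.0, c]])


def _centerline_head_frame(cfg: AirwayConfig, s_grid: np.ndarray):
    """Sample centerline points and tangents in the (untilted) head frame."""
    phi0 = np.deg2rad(cfg.inlet_angle_deg)
    arc1 = cfg.bend1_radius_m * (np.pi / 2.0 - phi0)
    arc3 = cfg.bend2_radius_m * np.deg2rad(cfg.bend2_turn_deg)
    arc2 = cfg.length_m - arc1 - arc3

    # Junction offsets.
    xa = cfg.bend1_radius_m * (np.cos(phi0))
    za = cfg.bend1_radius_m * (1.0 - np.sin(phi0))
    xb = xa + arc2

    pts = np.empty((s_grid.size, 3))
    tans = np.empty_like(pts)
    for i, s in enumerate(s_grid):
        l = s * cfg.length_m
        if l <= arc1:  # vestibule bend: tangent angle phi from +z toward +x
            phi = phi0 + l / cfg.bend1_radius_m
            pts[i] = (
                cfg.bend1_radius_m * (np.cos(phi0) - np.cos(phi)),
                0.0,
                cfg.bend1_radius_m * (np.sin(phi) - np.sin(phi0)),
            )
            tans[i] = (np.sin(phi), 0.0, np.cos(phi))
        elif l <= arc1 + arc2:  # straight main passage
            pts[i] = (xa + (l - arc1), 0.0, za)
            tans[i] = (1.0, 0.0, 0.0)
        else:  # nasopharyngeal bend, turning downward
            phi = np.pi / 2.0 + (l - arc1 - arc2) / cfg.bend2_radius_m
            pts[i] = (
                xb - cfg.bend2_radius_m * np.cos(phi),
                0.0,
                za + cfg.bend2_radius_m * (np.sin(phi) - 1.0),
            )
            tans[i] = (np.sin(phi), 0.0, np.cos(phi))
    return pts, tans


def build_idealized_airway(
    params: AirwayConfig | Mapping | None = None, **overrides
) -> AirwayModel:
    """Construct the idealized airway model.

    ``params`` may be an :class:`AirwayConfig`, a mapping using the external
    config keys (``length_m``, ``radius_profile`` as [s, r_mm] pairs,
    ``tilt_deg``, ``nasopharynx_start_s``, ...), or None for defaults.
    Deterministic: identical parameters yield bitwise-identical samples.
    """
    if params is None:
        cfg = AirwayConfig(**overrides)
    elif isinstance(params, AirwayConfig):
        cfg = replace(params, **overrides) if overrides else params
    else:
        kw = dict(params)
        if "radius_profile" in kw:  # external spelling
            kw["radius_profile_mm"] = tuple(
                (float(s), float(r)) for s, r in kw.pop("radius_profile")
            )
        if "radius_profile_mm" in kw:
            kw["radius_profile_mm"] = tuple(
                (float(s), float(r)) for s, r in kw["radius_profile_mm"]
            )
        unknown = set(kw) - {f for f in AirwayConfig.__dataclass_fields__}
        if unknown:
            raise ConfigurationError(f"unknown airway config keys: {sorted(unknown)}")
        kw.update(overrides)
        cfg = AirwayConfig(**kw)
    cfg.validate()

    s_grid = np.linspace(0.0, 1.0, cfg.n_samples)
    pts, tans = _centerline_head_frame(cfg, s_grid)

    rot = _rotation_forward_tilt(cfg.tilt_deg)
    pts = pts @ rot.T
    tans = tans @ rot.T

    knots = np.array(sorted(cfg.radius_profile_mm, key=lambda p: p[0]))
    if knots[0, 0] > 0.0 or knots[-1, 0] < 1.0:
        # extend flat to the ends so radius_at is total on [0, 1]
        rows = []
        if knots[0, 0] > 0.0:
            rows.append([0.0, knots[0, 1]])
        rows.extend(knots.tolist())
        if knots[-1, 0] < 1.0:
            rows.append([1.0, knots[-1, 1]])
        knots = np.array(rows)
    interp = PchipInterpolator(knots[:, 0], knots[:, 1])
    radius_m = interp(s_grid) * 1e-3
    if np.any(radius_m <= 0):
        raise ConfigurationError("interpolated radius profile dips to zero")

    npx = cfg.nasopharynx_start_s
    region_bounds = {
        "vestibule": (0.0, 0.10),
        "anterior": (0.10, 0.45),
        "mid": (0.45, npx),
        "nasopharynx": (npx, 1.0 + 1e-12),
    }

    phi0 = np.deg2rad(cfg.inlet_angle_deg)
    arc1 = cfg.bend1_radius_m * (np.pi / 2.0 - phi0)
    arc3 = cfg.bend2_radius_m * np.deg2rad(cfg.bend2_turn_deg)
    pieces = _CenterlinePieces(
        phi0=phi0,
        r1=cfg.bend1_radius_m,
        l1=arc1,
        xa=cfg.bend1_radius_m * np.cos(phi0),
        za=cfg.bend1_radius_m * (1.0 - np.sin(phi0)),
        l2=cfg.length_m - arc1 - arc3,
        xb=cfg.bend1_radius_m * np.cos(phi0) + cfg.length_m - arc1 - arc3,
        r2=cfg.bend2_radius_m,
        phi_end=np.pi / 2.0 + np.deg2rad(cfg.bend2_turn_deg),
        length=cfg.length_m,
    )

    lat = 1.0 if cfg.side == "left" else -1.0
    septal_point = rot @ np.array([0.0, -lat * cfg.septal_offset_m, 0.0])
    septal_normal = rot @ np.array([0.0, lat, 0.0])

    return AirwayModel(
        centerline=pts,
        tangents=tans,
        arc_frac=s_grid,
        radius_m=radius_m,
        length_m=cfg.length_m,
        head_tilt_deg=cfg.tilt_deg,
        rotation=rot,
        region_bounds=region_bounds,
        nostril_centroid=pts[0].copy(),
        nostril_normal=rot @ np.array([0.0, 0.0, 1.0]),
        septal_point=septal_point,
        septal_normal=septal_normal,
        septal_extent_s=cfg.septal_extent_s,
        lateral_sign=lat,
        config=cfg,
        pieces=pieces,
        _radius_interp=interp,
    )


def velocity_at(model: AirwayModel, flow: FlowField, position) -> np.ndarray:
    """Air velocity (m/s) at a point inside the lumen.

    Parabolic axial profile on the local cross-section, scaled so the
    section flux equals the inhalation rate; zero at the wall.  Raises
    :class:`DomainError` outside the lumen.
    """
    s, dist, _, tangent = model.locate(position)
    r = float(model.radius_at(s))
    if dist - r > 1e-9:
        raise DomainError("position outside the airway lumen")
    umax = 2.0 * flow.q_m3s / (np.pi * r * r)
    return umax * max(0.0, 1.0 - (dist / r) ** 2) * tangent


def classify_point(model: AirwayModel, position) -> PointClassification:
    """Nearest arc-length fraction, region and signed wall distance.

    Total function: points outside the lumen return a negative wall
    distance.
    """
    s, dist, _, _ = model.locate(position)
    r = float(model.radius_at(s))
    return PointClassification(model.region_of(s), float(s), r - dist)


def export_stl(model: AirwayModel, path, n_theta: int = 32) -> None:
    """Export the tube surface as binary STL (visualization only)."""
    import trimesh

    P, T = model.centerline, model.tangents
    n = P.shape[0]
    verts = np.empty((n * n_theta, 3))
    ref = np.array([0.0, 1.0, 0.0])
    theta = np.linspace(0.0, 2 * np.pi, n_theta, endpoint=False)
    for i in range(n):
        t = T[i]
        e1 = np.cross(t, ref)
        e1 /= np.linalg.norm(e1)
        e2 = np.cross(t, e1)
        ring = (
            P[i]
            + model.radius_m[i]
            * (np.cos(theta)[:, None] * e1 + np.sin(theta)[:, None] * e2)
        )
        verts[i * n_theta : (i + 1) * n_theta] = ring
    faces = []
    for i in range(n - 1):
        for j in range(n_theta):
            a = i * n_theta + j
            b = i * n_theta + (j + 1) % n_theta
            c = a + n_theta
            d = b + n_theta
            faces.append([a, b, d])
            faces.append([a, d, c])
    mesh = trimesh.Trimesh(vertices=verts, faces=np.array(faces), process=False)
    mesh.export(path, file_type="stl")
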