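"""Lagrangian tracking of sprayed droplets in the idealized airway.

Inert droplets are released as a solid-cone point injection and integrated
with a classical Runge-Kutta (RK4) scheme under Stokes drag (with
Cunningham slip correction), gravity and Saffman-Mei shear lift, against
the quasi-1D laminar inhalation field.  Walls trap droplets at first
crossing (no-slip trap boundary condition); the posterior outlet plane and
the nostril plane are open.

The per-diameter nasopharyngeal deposition fraction of a released cluster
is the central output (:func:`deposition_curve`).  One-way momentum
coupling only; Brownian motion and evaporation are neglected, consistent
with the O(0.1 s) transport times involved.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

from . import _kernels
from .airway_model import AirwayModel, FlowField, PhysicalConstants, classify_point
from .errors import ConfigurationError, IntegrationError, PlacementError

DEFAULT_DIAMETERS_UM = tuple(range(1, 25))
DEFAULT_DT_S = 1e-4
DEFAULT_T_MAX_S = 0.25

#: stable protocol identifiers used for counter-based seeding
PROTOCOL_IDS = {"CU": 0, "IU": 1, "PD1": 2, "PD2": 3, "PD3": 4, "PD4": 5, "PD5": 6}

_STATUS_NAMES = {0: "airborne", 1: "trapped", 2: "escaped", 3: "escaped_front"}


def slip_correction(diameter_um: float, mean_free_path: float = 6.6e-8) -> float:
    """Cunningham slip correction factor (Millikan fit).

    Cc = 1 + (2*lambda/D) * (1.257 + 0.4 * exp(-1.1 * D / (2*lambda))).
    """
    d = diameter_um * 1e-6
    if d <= 0:
        raise ConfigurationError("diameter must be positive")
    if mean_free_path <= 0:
        return 1.0  # continuum limit
    kn2 = 2.0 * mean_free_path / d
    return 1.0 + kn2 * (1.257 + 0.4 * math.exp(-1.1 / kn2))


def relaxation_time(
    diameter_um: float,
    density_kg_m3: float = 1500.0,
    slip_factor: float = 1.0,
    air_viscosity: float = 1.825e-5,
) -> float:
    """Droplet momentum response time tau = rho_D * D^2 * Cc / (18 mu)."""
    d = diameter_um * 1e-6
    return density_kg_m3 * d * d * slip_factor / (18.0 * air_viscosity)


@dataclass(frozen=True)
class SprayInjection:
    """Solid-cone point injection of a monodispersed droplet cluster."""

    origin: np.ndarray                  # nozzle tip, m
    axis: np.ndarray                    # unit spray direction
    cone_half_angle_deg: float = 27.93
    speed_mps: float = 10.0
    n_droplets: int = 3000
    diameter_um: float = 10.0
    density_kg_m3: float = 1500.0
    seed: int = 0

    def __post_init__(self):
        ax = np.asarray(self.axis, dtype=float)
        nrm = np.linalg.norm(ax)
        if nrm == 0:
            raise ConfigurationError("spray axis must be a nonzero vector")
        object.__setattr__(self, "axis", ax / nrm)
        object.__setattr__(self, "origin", np.asarray(self.origin, dtype=float))
        if not 0.0 <= self.cone_half_angle_deg < 90.0:
            raise ConfigurationError("cone half-angle must lie in [0, 90) degrees")
        if self.speed_mps <= 0:
            raise ConfigurationError("spray speed must be positive")
        if self.n_droplets < 1:
            raise ConfigurationError("need at least one droplet")
        if self.diameter_um <= 0 or self.density_kg_m3 <= 0:
            raise ConfigurationError("diameter and density must be positive")


@dataclass
class DropletState:
    """State of a single tracked droplet."""

    position: np.ndarray
    velocity: np.ndarray
    diameter_um: float
    density_kg_m3: float = 1500.0
    status: str = "airborne"            # airborne | trapped | escaped | escaped_front
    region: str | None = None
    trap_time: float | None = None
    time: float = 0.0


@dataclass
class DropletCloud:
    """Array-of-struct view of a released cluster (positions, velocities)."""

    positions: np.ndarray               # (n, 3)
    velocities: np.ndarray              # (n, 3)
    diameter_um: float
    density_kg_m3: float

    def __len__(self) -> int:
        return self.positions.shape[0]

    def states(self) -> list[DropletState]:
        return [
            DropletState(
                self.positions[i].copy(),
                self.velocities[i].copy(),
                self.diameter_um,
                self.density_kg_m3,
            )
            for i in range(len(self))
        ]


def _cone_rng(inj: SprayInjection) -> np.random.Generator:
    # counter-based generator so clusters are independent of execution order
    ss = np.random.SeedSequence(
        int(inj.seed), spawn_key=(int(round(inj.diameter_um * 1000)),)
    )
    return np.random.Generator(np.random.Philox(ss))


def cone_injection(inj: SprayInjection, model: AirwayModel | None = None) -> DropletCloud:
    """Initial droplet states for a solid-cone injection.

    Directions are uniform over the solid angle of the cone about
    ``inj.axis`` (so the cone is "solid", not an annulus); every droplet
    starts at the nozzle tip with speed ``inj.speed_mps``.  Reproducible
    for a fixed seed.  With a model supplied, an origin outside the lumen
    raises :class:`PlacementError`.
    """
    if model is not None:
        cls = classify_point(model, inj.origin)
        if cls.wall_distance <= 0:
            raise PlacementError(
                f"spray origin {inj.origin} lies outside the lumen "
                f"(wall distance {cls.wall_distance:.2e} m)"
            )
    rng = _cone_rng(inj)
    n = inj.n_droplets
    cos_max = math.cos(math.radians(inj.cone_half_angle_deg))
    cosu = rng.uniform(cos_max, 1.0, size=n)
    phi = rng.uniform(0.0, 2.0 * np.pi, size=n)
    sinu = np.sqrt(np.clip(1.0 - cosu**2, 0.0, None))

    a = inj.axis
    ref = np.array([0.0, 0.0, 1.0]) if abs(a[2]) < 0.9 else np.array([0.0, 1.0, 0.0])
    e1 = np.cross(a, ref)
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(a, e1)
    dirs = (
        cosu[:, None] * a
        + sinu[:, None] * (np.cos(phi)[:, None] * e1 + np.sin(phi)[:, None] * e2)
    )
    velocities = inj.speed_mps * dirs
    positions = np.broadcast_to(inj.origin, (n, 3)).copy()
    return DropletCloud(positions, velocities, inj.diameter_um, inj.density_kg_m3)


def drag_force(
    droplet_velocity,
    flow_velocity,
    diameter_um: float,
    density_kg_m3: float,
    air: FlowField,
    slip_factor: float = 1.0,
) -> np.ndarray:
    """Stokes drag per unit droplet mass (m/s^2), linear in slip velocity."""
    tau = relaxation_time(diameter_um, density_kg_m3, slip_factor, air.air_viscosity)
    return (np.asarray(flow_velocity, float) - np.asarray(droplet_velocity, float)) / tau


def saffman_lift(
    slip_velocity,
    velocity_gradient,
    diameter_um: float,
    density_kg_m3: float,
    air: FlowField,
) -> np.ndarray:
    """Saffman-Mei shear lift per unit droplet mass (m/s^2).

    Generalized-shear form: a = 2 K nu^0.5 rho / (rho_D D (d:d)^0.25) d.w,
    with d the flow deformation tensor and w the slip velocity; reduces to
    Saffman's 1965 result in simple shear and vanishes with either the
    shear or the slip.
    """
    w = np.asarray(slip_velocity, dtype=float)
    grad = np.asarray(velocity_gradient, dtype=float)
    d = 0.5 * (grad + grad.T)
    dd = float(np.sum(d * d))
    if dd == 0.0 or not np.any(w):
        return np.zeros(3)
    nu = air.kinematic_viscosity
    coeff = (
        2.0
        * _kernels._SAFFMAN_K
        * math.sqrt(nu)
        * air.air_density
        / (density_kg_m3 * diameter_um * 1e-6)
    )
    return coeff * (d @ w) / dd**0.25


def _n_substeps(dt: float, tau: float) -> int:
    return int(min(512, max(1, math.ceil(dt / tau))))


def _lift_coeff(diameter_um, density, air, include_lift):
    if not include_lift:
        return 0.0
    return (
        2.0
        * _kernels._SAFFMAN_K
        * math.sqrt(air.kinematic_viscosity)
        * air.air_density
        / (density * diameter_um * 1e-6)
    )


def step_droplet(
    state: DropletState,
    model: AirwayModel,
    flow: FlowField,
    constants: PhysicalConstants | None = None,
    dt: float = DEFAULT_DT_S,
    *,
    include_lift: bool = True,
    n_sub: int | None = None,
) -> DropletState:
    """Advance one droplet by one flow time step (RK4 with sub-stepping).

    Status transitions are monotone: trapped and escaped states are
    returned unchanged.  A wall crossing within the step traps the droplet
    at the crossing point's region; crossing the outlet plane escapes it.
    """
    if state.status != "airborne":
        return state
    if dt <= 0:
        raise ConfigurationError("dt must be positive")
    constants = constants or PhysicalConstants()
    cc = slip_correction(state.diameter_um, constants.mean_free_path)
    tau = relaxation_time(state.diameter_um, state.density_kg_m3, cc, flow.air_viscosity)
    nsub = n_sub or _n_substeps(dt, tau)
    P, T, S, R = model.geometry_arrays()
    g = constants.g_vector
    lc = _lift_coeff(state.diameter_um, state.density_kg_m3, flow, include_lift)
    status, s_evt, t_evt, px, py, pz, vx, vy, vz = _kernels.track_one(
        np.ascontiguousarray(state.position, dtype=float),
        np.ascontiguousarray(state.velocity, dtype=float),
        tau,
        flow.q_m3s,
        P, T, S, R,
        g[0], g[1], g[2],
        lc,
        flow.kinematic_viscosity,
        dt,
        dt,            # advance exactly one flow step
        nsub,
        1e-6,
    )
    if status == -1:
        raise IntegrationError(
            f"non-finite droplet state (D={state.diameter_um} um, t={state.time})"
        )
    new = replace(
        state,
        position=np.array([px, py, pz]),
        velocity=np.array([vx, vy, vz]),
        time=state.time + dt,
    )
    if status == 1:
        new.status = "trapped"
        new.region = model.region_of(s_evt)
        new.trap_time = state.time + t_evt
    elif status == 2:
        new.status = "escaped"
        new.trap_time = state.time + t_evt
    elif status == 3:
        new.status = "escaped_front"
        new.trap_time = state.time + t_evt
    return new


@dataclass
class ClusterResult:
    """Final bookkeeping for a tracked monodispersed cluster."""

    status: np.ndarray                 # kernel status codes per droplet
    s_event: np.ndarray                # arc fraction of trap/escape
    t_event: np.ndarray
    diameter_um: float
    nasopharynx_start_s: float

    @property
    def n(self) -> int:
        return self.status.size

    @property
    def n_trapped_nasopharynx(self) -> int:
        return int(
            np.sum((self.status == 1) & (self.s_event >= self.nasopharynx_start_s))
        )

    @property
    def n_trapped_other(self) -> int:
        return int(
            np.sum((self.status == 1) & (self.s_event < self.nasopharynx_start_s))
        )

    @property
    def n_escaped_outlet(self) -> int:
        return int(np.sum(self.status == 2))

    @property
    def n_escaped_front(self) -> int:
        return int(np.sum(self.status == 3))

    @property
    def n_airborne(self) -> int:
        return int(np.sum(self.status == 0))

    def counts(self) -> dict:
        return {
            "trapped_nasopharynx": self.n_trapped_nasopharynx,
            "trapped_other": self.n_trapped_other,
            "escaped_outlet": self.n_escaped_outlet,
            "escaped_front": self.n_escaped_front,
            "airborne": self.n_airborne,
        }

    def efficiency(self, count_outflow: bool = False) -> float:
        dep = self.n_trapped_nasopharynx
        if count_outflow:
            dep += self.n_escaped_outlet
        return dep / self.n

    def mean_trap_s(self) -> float:
        """Mean deposition arc-length fraction of wall-trapped droplets."""
        mask = self.status == 1
        if not mask.any():
            return float("nan")
        return float(np.mean(self.s_event[mask]))


def simulate_cluster(
    inj: SprayInjection,
    model: AirwayModel,
    flow: FlowField,
    constants: PhysicalConstants | None = None,
    *,
    dt: float = DEFAULT_DT_S,
    t_max: float = DEFAULT_T_MAX_S,
    include_lift: bool = True,
) -> ClusterResult:
    """Release and track one monodispersed cluster to its final statuses."""
    constants = constants or PhysicalConstants()
    cloud = cone_injection(inj, model)
    cc = slip_correction(inj.diameter_um, constants.mean_free_path)
    tau = relaxation_time(inj.diameter_um, inj.density_kg_m3, cc, flow.air_viscosity)
    P, T, S, R = model.geometry_arrays()
    g = constants.g_vector
    lc = _lift_coeff(inj.diameter_um, inj.density_kg_m3, flow, include_lift)
    status, s_event, t_event = _kernels.track_cluster(
        np.ascontiguousarray(cloud.positions),
        np.ascontiguousarray(cloud.velocities),
        tau,
        flow.q_m3s,
        P, T, S, R,
        g[0], g[1], g[2],
        lc,
        flow.kinematic_viscosity,
        dt,
        t_max,
        _n_substeps(dt, tau),
        1e-6,
    )
    if np.any(status == -1):
        raise IntegrationError(
            f"non-finite droplet states at D={inj.diameter_um} um "
            f"({int(np.sum(status == -1))} droplets)"
        )
    return ClusterResult(
        status, s_event, t_event, inj.diameter_um,
        model.region_bounds["nasopharynx"][0],
    )


@dataclass
class DepositionCurve:
    """Nasopharyngeal deposition efficiency per droplet diameter."""

    protocol: str
    flow_lpm: float
    side: str
    diameters_um: np.ndarray
    efficiency: np.ndarray
    n_droplets: int
    seed: int
    counts: pd.DataFrame | None = field(default=None, repr=False)

    def __post_init__(self):
        self.diameters_um = np.asarray(self.diameters_um, dtype=float)
        self.efficiency = np.asarray(self.efficiency, dtype=float)
        if self.diameters_um.size != self.efficiency.size:
            raise ConfigurationError("diameter and efficiency grids differ in length")
        if np.any(np.diff(self.diameters_um) <= 0):
            raise ConfigurationError("diameters must be strictly increasing")
        if np.any((self.efficiency < 0) | (self.efficiency > 1)):
            raise ConfigurationError("efficiencies must lie in [0, 1]")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "protocol": self.protocol,
                "flow_lpm": self.flow_lpm,
                "side": self.side,
                "diameter_um": self.diameters_um,
                "efficiency": self.efficiency,
                "n_droplets": self.n_droplets,
                "seed": self.seed,
            }
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "DepositionCurve":
        df = pd.read_csv(path)
        required = {"protocol", "flow_lpm", "side", "diameter_um", "efficiency",
                    "n_droplets", "seed"}
        missing = required - set(df.columns)
        if missing:
            raise ConfigurationError(f"curve CSV missing columns: {sorted(missing)}")
        df = df.sort_values("diameter_um")
        return cls(
            protocol=str(df["protocol"].iloc[0]),
            flow_lpm=float(df["flow_lpm"].iloc[0]),
            side=str(df["side"].iloc[0]),
            diameters_um=df["diameter_um"].to_numpy(float),
            efficiency=df["efficiency"].to_numpy(float),
            n_droplets=int(df["n_droplets"].iloc[0]),
            seed=int(df["seed"].iloc[0]),
        )

    def interpolator(self):
        """Linear interpolant of efficiency vs diameter, 0 outside the grid."""
        d, e = self.diameters_um, self.efficiency

        def f(x):
            x = np.asarray(x, dtype=float)
            return np.where(
                (x < d[0]) | (x > d[-1]), 0.0, np.interp(x, d, e)
            )

        return f


def _case_seed(base_seed: int, protocol: str, flow_lpm: float, side: str) -> int:
    pid = PROTOCOL_IDS.get(protocol, 7)
    ss = np.random.SeedSequence(
        int(base_seed),
        spawn_key=(pid, int(round(flow_lpm * 10)), 0 if side == "left" else 1),
    )
    return int(ss.generate_state(1, np.uint32)[0])


def deposition_curve(
    axis,
    model: AirwayModel,
    flow: FlowField,
    template: SprayInjection | None = None,
    diameters_um: Sequence[float] = DEFAULT_DIAMETERS_UM,
    *,
    constants: PhysicalConstants | None = None,
    seed: int = 0,
    dt: float = DEFAULT_DT_S,
    t_max: float = DEFAULT_T_MAX_S,
    count_outflow: bool = False,
    include_lift: bool = True,
) -> DepositionCurve:
    """Nasopharyngeal deposition-efficiency curve for one spray axis.

    ``axis`` is a :class:`~nasodose.delivery_analysis.SprayAxis`; the
    nozzle tip sits ``insertion_depth_mm`` beyond the nostril-plane anchor
    along the axis direction.  A cluster is released per diameter; the
    efficiency is the fraction trapped in the nasopharynx band (droplets
    still airborne at ``t_max`` count as non-deposited).  A fixed seed
    yields an identical curve; each (case, diameter) cluster draws from its
    own counter-based stream.
    """
    template = template or SprayInjection(
        origin=np.zeros(3), axis=np.array([1.0, 0.0, 0.0])
    )
    origin = (
        np.asarray(axis.origin, dtype=float)
        + axis.insertion_depth_mm * 1e-3 * np.asarray(axis.direction, dtype=float)
    )
    diameters = np.asarray(sorted(diameters_um), dtype=float)
    case_seed = _case_seed(seed, axis.protocol, flow.rate_lpm, getattr(axis, "side", "left"))
    eff = np.empty(diameters.size)
    rows = []
    for k, d in enumerate(diameters):
        inj = replace(
            template,
            origin=origin,
            axis=np.asarray(axis.direction, dtype=float),
            diameter_um=float(d),
            seed=case_seed,
        )
        res = simulate_cluster(
            inj, model, flow, constants, dt=dt, t_max=t_max, include_lift=include_lift
        )
        eff[k] = res.efficiency(count_outflow)
        rows.append({"diameter_um": d, **res.counts()})
    counts = pd.DataFrame(rows)
    return DepositionCurve(
        protocol=axis.protocol,
        flow_lpm=flow.rate_lpm,
        side=getattr(axis, "side", "left"),
        diameters_um=diameters,
        efficiency=eff,
        n_droplets=template.n_droplets,
        seed=seed,
        counts=counts,
    )


def trace_droplet(
    state: DropletState,
    model: AirwayModel,
    flow: FlowField,
    constants: PhysicalConstants | None = None,
    *,
    dt: float = DEFAULT_DT_S,
    t_max: float = DEFAULT_T_MAX_S,
    droplet_id: int = 0,
) -> pd.DataFrame:
    """Record a single droplet trajectory (debugging aid)."""
    rows = []
    t = 0.0
    while t <= t_max and state.status == "airborne":
        rows.append(
            {
                "droplet_id": droplet_id,
                "t_s": t,
                "x_m": state.position[0],
                "y_m": state.position[1],
                "z_m": state.position[2],
                "status": state.status,
            }
        )
        state = step_droplet(state, model, flow, constants, dt)
        t += dt
    rows.append(
        {
            "droplet_id": droplet_id,
            "t_s": t,
            "x_m": state.position[0],
            "y_m": state.position[1],
            "z_m": state.position[2],
            "status": state.status,
        }
    )
    return pd.DataFrame(rows)
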