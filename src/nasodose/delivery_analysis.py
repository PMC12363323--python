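"""Spray-axis protocols and nasopharyngeal dose estimation.

Covers the head-line computations of the pipeline:

* construction of the "current use" (CU, upright bottle) and "improved
  use" (IU, near-horizontal axis aimed through the nasopharynx) spray
  axes, and the three IU validity criteria;
* ideal droplet size ranges from deposition curves (efficiency cutoff),
  and their averaging into a generic range across cases;
* distribution-weighted deposited formulation mass per pump, the derived
  active pharmaceutical ingredient (API) mass, and the IU-over-CU
  improvement expressed in orders of magnitude.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from decimal import ROUND_HALF_EVEN, Decimal
from typing import Iterable, Sequence

import numpy as np
from scipy.integrate import quad

from .airway_model import AirwayModel, classify_point
from .errors import DomainError, InterpolationError, PlacementError
from .product_model import SprayProduct
from .spray_transport import DepositionCurve
from .stokes_scaling import SizeRange

POSTERIOR_WALL_S = 0.5   # "posterior part" threshold for IU criterion (iii)


@dataclass(frozen=True)
class SprayAxis:
    """A spray axis anchored on the nostril plane."""

    protocol: str                   # CU | IU | PD1..PD5
    origin: np.ndarray              # anchor point on the nostril plane, m
    direction: np.ndarray           # unit vector into the airway
    insertion_depth_mm: float = 5.0
    side: str = "left"

    def __post_init__(self):
        d = np.asarray(self.direction, dtype=float)
        n = np.linalg.norm(d)
        if n == 0:
            raise DomainError("axis direction must be nonzero")
        object.__setattr__(self, "direction", d / n)
        object.__setattr__(self, "origin", np.asarray(self.origin, dtype=float))
        if self.insertion_depth_mm <= 0:
            raise DomainError("insertion depth must be positive")

    @property
    def nozzle_tip(self) -> np.ndarray:
        return self.origin + self.insertion_depth_mm * 1e-3 * self.direction


@dataclass(frozen=True)
class IUAxisReport:
    """Per-criterion outcome of the IU axis validity test."""

    intersects_nasopharynx: bool     # (i) extended axis reaches the target
    avoids_septum: bool              # (ii) does not cut the septal plane
    lateral_wall_posterior: bool     # (iii) first wall hit posterior & lateral
    first_wall_s: float | None = None

    @property
    def valid(self) -> bool:
        return (
            self.intersects_nasopharynx
            and self.avoids_septum
            and self.lateral_wall_posterior
        )


def _centerline_at(model: AirwayModel, s: float) -> np.ndarray:
    return np.array(
        [np.interp(s, model.arc_frac, model.centerline[:, k]) for k in range(3)]
    )


def _march_ray(model: AirwayModel, origin, direction, t_end=0.20, step=2e-4):
    """Sample classifications along a ray (total: continues past wall exits)."""
    ts = np.arange(0.0, t_end, step)
    pts = origin[None, :] + ts[:, None] * direction[None, :]
    out = [classify_point(model, p) for p in pts]
    return ts, pts, out


def first_wall_hit(model: AirwayModel, origin, direction):
    """(t, s, point) of the ray's first lumen exit, or None if none found."""
    ts, pts, cls = _march_ray(model, np.asarray(origin, float), np.asarray(direction, float))
    inside = np.array([c.wall_distance > 0 for c in cls])
    if not inside[0]:
        return None
    for k in range(1, len(ts)):
        if not inside[k]:
            lo, hi = ts[k - 1], ts[k]
            for _ in range(40):
                mid = 0.5 * (lo + hi)
                c = classify_point(model, origin + mid * direction)
                if c.wall_distance > 0:
                    lo = mid
                else:
                    hi = mid
            p = origin + hi * direction
            return hi, classify_point(model, p).s, p
    return None


def validate_iu_axis(axis: SprayAxis, model: AirwayModel) -> IUAxisReport:
    """Check the three IU placement criteria for a spray axis.

    (i) the extended axis intersects the nasopharynx region; (ii) it does
    not cut through the septal plane over the septum's anterior extent
    (while still inside the lumen); (iii) its first wall intersection is on
    the lateral side in the posterior part of the passage.
    """
    origin = np.asarray(axis.origin, dtype=float)
    off_plane = abs(float((origin - model.nostril_centroid) @ model.nostril_normal))
    if off_plane > 1e-6:
        raise PlacementError("axis origin does not lie on the nostril plane")
    direction = np.asarray(axis.direction, dtype=float)

    hit = first_wall_hit(model, origin, direction)
    t_wall = hit[0] if hit else np.inf

    # (i) ray passes through the nasopharynx region volume
    ts, pts, cls = _march_ray(model, origin, direction)
    lo_np = model.region_bounds["nasopharynx"][0]
    intersects = any(
        c.wall_distance > 0 and c.s >= lo_np for c in cls
    )

    # (ii) septal-plane crossing while inside the lumen, over the septum extent
    side_vals = (pts - model.septal_point) @ model.septal_normal
    crosses = False
    for k in range(len(ts)):
        if ts[k] >= t_wall:
            break
        if side_vals[k] < 0 and cls[k].s <= model.septal_extent_s:
            crosses = True
            break

    # (iii) first wall hit: posterior and on the lateral side
    lateral_ok = False
    s_hit = None
    if hit is not None:
        _, s_hit, p_hit = hit
        lateral_comp = float((p_hit - _centerline_at(model, s_hit)) @ model.lateral_unit)
        lateral_ok = s_hit >= POSTERIOR_WALL_S and lateral_comp > 0
    return IUAxisReport(
        intersects_nasopharynx=bool(intersects),
        avoids_septum=not crosses,
        lateral_wall_posterior=bool(lateral_ok),
        first_wall_s=s_hit,
    )


def cu_axis(model: AirwayModel, insertion_depth_mm: float = 5.0) -> SprayAxis:
    """Current-use axis: upright bottle, anchored off-center laterally.

    The direction is vertical in the laboratory frame (the patient tilts
    the head forward instead); the anchor sits at one-third of the
    lateral-to-septal width away from the lateral wall, with a shallow
    5-mm nozzle insertion.
    """
    r0 = float(model.radius_m[0])
    anchor = model.nostril_centroid + (r0 / 3.0) * model.lateral_unit
    return SprayAxis(
        protocol="CU",
        origin=anchor,
        direction=np.array([0.0, 0.0, 1.0]),
        insertion_depth_mm=insertion_depth_mm,
        side="left" if model.lateral_sign > 0 else "right",
    )


def iu_axis(
    model: AirwayModel,
    target_s: float = 0.92,
    lateral_tilt_deg: float = 2.0,
    insertion_depth_mm: float = 5.0,
) -> SprayAxis:
    """Improved-use axis: aimed from the nostril centroid at the nasopharynx.

    The axis points at the centerline of the nasopharynx band and is tilted
    slightly toward the lateral (cheek) side, which keeps it clear of the
    septal safety plane.  In the default geometry the returned axis
    satisfies all three IU criteria (see :func:`validate_iu_axis`).
    """
    aim = _centerline_at(model, target_s) - model.nostril_centroid
    aim /= np.linalg.norm(aim)
    direction = aim + math.tan(math.radians(lateral_tilt_deg)) * model.lateral_unit
    return SprayAxis(
        protocol="IU",
        origin=model.nostril_centroid.copy(),
        direction=direction,
        insertion_depth_mm=insertion_depth_mm,
        side="left" if model.lateral_sign > 0 else "right",
    )


# ---------------------------------------------------------------------------
# size ranges


def ideal_size_range(curve: DepositionCurve, cutoff: float = 0.02) -> SizeRange:
    """[min, max] droplet diameters whose efficiency reaches the cutoff.

    Returns an empty-flagged range when no diameter qualifies.
    """
    mask = curve.efficiency >= cutoff
    if not mask.any():
        return SizeRange(
            d_min_um=float("nan"), d_max_um=float("nan"),
            flow_lpm=curve.flow_lpm, cutoff=cutoff, empty=True,
        )
    d = curve.diameters_um[mask]
    return SizeRange(
        d_min_um=float(d.min()), d_max_um=float(d.max()),
        flow_lpm=curve.flow_lpm, cutoff=cutoff,
    )


def generic_range(ranges: Sequence[SizeRange]) -> SizeRange:
    """Mean of the per-case minima and maxima across non-empty ranges."""
    usable = [r for r in ranges if not r.empty]
    if not usable:
        raise DomainError("need at least one non-empty size range")
    flows = {r.flow_lpm for r in usable}
    cuts = {r.cutoff for r in usable}
    return SizeRange(
        d_min_um=float(np.mean([r.d_min_um for r in usable])),
        d_max_um=float(np.mean([r.d_max_um for r in usable])),
        flow_lpm=flows.pop() if len(flows) == 1 else float("nan"),
        cutoff=cuts.pop() if len(cuts) == 1 else float("nan"),
    )


# ---------------------------------------------------------------------------
# dose estimation


@dataclass(frozen=True)
class DeliveryEstimate:
    """Per-pump nasopharyngeal delivery for one product and protocol."""

    product: str
    protocol: str
    deposited_mass_mg: float
    api_mcg: float
    curve_provenance: dict = field(default_factory=dict)


def weighted_deposition(
    curve: DepositionCurve,
    product: SprayProduct,
    interval_um: tuple[float, float] = (1.0, 24.0),
) -> float:
    """Deposited formulation mass (mg per pump) at the nasopharynx.

    shot_mass * integral of efficiency(x) * mass_pdf(x) over the tracked
    size interval; efficiency is linearly interpolated on the curve grid
    and taken as zero outside it (droplets beyond the tracked range deposit
    anteriorly and miss the target).
    """
    a, b = interval_um
    d = curve.diameters_um
    if d[0] > a or d[-1] < b:
        raise InterpolationError(
            f"curve grid [{d[0]}, {d[-1]}] um does not cover [{a}, {b}] um"
        )
    eff = curve.interpolator()
    pdf = product.distribution.mass_pdf
    total = 0.0
    knots = np.unique(np.concatenate([[a, b], d[(d > a) & (d < b)]]))
    for lo, hi in zip(knots[:-1], knots[1:]):
        val, _ = quad(lambda x: eff(x) * pdf(x), lo, hi, limit=200)
        total += val
    return float(product.shot_mass_mg * total)


def api_mass(deposited_mg: float, product: SprayProduct) -> float:
    """API mass (mcg) delivered with a deposited formulation mass (mg)."""
    if deposited_mg < 0:
        raise DomainError("deposited mass cannot be negative")
    return deposited_mg * product.api_mcg_per_mg


def round_api(value_mcg: float, sig_figures: int = 2) -> float:
    """Round an API mass for reporting (half-even, default 2 significant
    figures, the convention of the printed estimates)."""
    if value_mcg == 0:
        return 0.0
    exp = math.floor(math.log10(abs(value_mcg)))
    q = Decimal(1).scaleb(exp - sig_figures + 1)
    return float(Decimal(repr(value_mcg)).quantize(q, rounding=ROUND_HALF_EVEN))


def estimate_delivery(
    curve: DepositionCurve,
    product: SprayProduct,
    interval_um: tuple[float, float] = (1.0, 24.0),
) -> DeliveryEstimate:
    """Distribution-weighted per-pump delivery estimate for one curve."""
    deposited = weighted_deposition(curve, product, interval_um)
    return DeliveryEstimate(
        product=product.name,
        protocol=curve.protocol,
        deposited_mass_mg=deposited,
        api_mcg=api_mass(deposited, product),
        curve_provenance={
            "flow_lpm": curve.flow_lpm,
            "side": curve.side,
            "n_droplets": curve.n_droplets,
            "seed": curve.seed,
        },
    )


def improvement_oom(iu, cu) -> float:
    """IU-over-CU improvement in orders of magnitude, log10(m_IU / m_CU).

    Accepts :class:`DeliveryEstimate` objects or plain deposited masses.
    A zero CU mass yields +inf (flagged, excluded from summaries).
    """
    m_iu = getattr(iu, "deposited_mass_mg", iu)
    m_cu = getattr(cu, "deposited_mass_mg", cu)
    if m_iu < 0 or m_cu < 0:
        raise DomainError("deposited masses cannot be negative")
    if m_cu == 0:
        return math.inf
    return math.log10(m_iu / m_cu)


@dataclass(frozen=True)
class ImprovementSummary:
    mean: float
    sd: float
    n: int
    n_excluded: int = 0


def summarize_improvement(pairs: Iterable[tuple]) -> ImprovementSummary:
    """Mean and sample standard deviation of improvement over case pairs."""
    ooms = [improvement_oom(iu, cu) for iu, cu in pairs]
    finite = [o for o in ooms if math.isfinite(o)]
    n_excl = len(ooms) - len(finite)
    if n_excl:
        warnings.warn(
            f"excluded {n_excl} case(s) with zero CU deposition from the "
            "improvement summary",
            stacklevel=2,
        )
    if not finite:
        raise DomainError("no finite improvement values to summarize")
    arr = np.asarray(finite)
    sd = float(np.std(arr, ddof=1)) if arr.size > 1 else float("nan")
    return ImprovementSummary(float(np.mean(arr)), sd, arr.size, n_excl)
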