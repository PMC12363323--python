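"""Spray-axis perturbation ("tolerance") sensitivity analysis.

User-robustness of the improved-use (IU) orientation is probed by tilting
the spray axis slightly: a 1-mm-radius circle is drawn perpendicular to
the axis at 5 or 10 mm from the nostril-plane centroid, five equidistant
peripheral points are placed on it, and each centroid-to-point line defines
a perturbed direction (PD 1-5, tilted arctan(1/5) = 11.31 deg or
arctan(1/10) = 5.71 deg off the base axis).  Congruity between the IU
deposition curve and each PD curve over the tracked size grid is measured
with Pearson's correlation coefficient and its significance.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import NamedTuple, Sequence

import numpy as np
from scipy import stats

from .airway_model import AirwayModel, FlowField
from .delivery_analysis import SprayAxis, IUAxisReport, iu_axis, validate_iu_axis
from .errors import ConfigurationError, DomainError, PlacementError
from .spray_transport import (
    DEFAULT_DIAMETERS_UM,
    DEFAULT_DT_S,
    DEFAULT_T_MAX_S,
    DepositionCurve,
    SprayInjection,
    deposition_curve,
)

ALLOWED_OFFSETS_MM = (5.0, 10.0)


@dataclass(frozen=True)
class PerturbationSet:
    """The five perturbed spray axes around a base IU axis."""

    base_axis: SprayAxis
    circle_radius_mm: float
    offset_mm: float
    phase_deg: float
    axes: tuple[SprayAxis, ...]
    validity: tuple[IUAxisReport, ...]

    @property
    def tilt_deg(self) -> float:
        return math.degrees(math.atan(self.circle_radius_mm / self.offset_mm))


def perturbed_directions(
    base: SprayAxis,
    model: AirwayModel,
    offset_mm: float = 5.0,
    radius_mm: float = 1.0,
    phase_deg: float = 0.0,
) -> PerturbationSet:
    """Construct the five perturbed directions around ``base``.

    The azimuthal phase of the five circle points is arbitrary; it is
    exposed as ``phase_deg`` (0 puts the first point toward the lateral
    side).  Axes failing the IU validity criteria are reported in
    ``validity`` rather than dropped: with the strongly idealized
    single-tube geometry a downward- or medially-tilted perturbation can
    legitimately fail a criterion that its anatomical counterpart passed.
    """
    if float(offset_mm) not in ALLOWED_OFFSETS_MM:
        raise ConfigurationError(
            f"offset must be one of {ALLOWED_OFFSETS_MM} mm (tested perturbation levels)"
        )
    anchor = np.asarray(base.origin, dtype=float)
    if np.linalg.norm(anchor - model.nostril_centroid) > 1e-9:
        raise PlacementError("perturbations require the base axis anchored at the centroid")
    b = np.asarray(base.direction, dtype=float)

    lat = model.lateral_unit
    e1 = lat - (lat @ b) * b
    n1 = np.linalg.norm(e1)
    if n1 < 1e-12:
        raise PlacementError("base axis parallel to the lateral direction")
    e1 /= n1
    e2 = np.cross(b, e1)

    center = anchor + offset_mm * 1e-3 * b
    axes = []
    reports = []
    for k in range(5):
        th = math.radians(phase_deg + 72.0 * k)
        point = center + radius_mm * 1e-3 * (math.cos(th) * e1 + math.sin(th) * e2)
        direction = point - anchor
        ax = SprayAxis(
            protocol=f"PD{k + 1}",
            origin=anchor.copy(),
            direction=direction,
            insertion_depth_mm=5.0,
            side=base.side,
        )
        axes.append(ax)
        reports.append(validate_iu_axis(ax, model))
    return PerturbationSet(
        base_axis=base,
        circle_radius_mm=float(radius_mm),
        offset_mm=float(offset_mm),
        phase_deg=float(phase_deg),
        axes=tuple(axes),
        validity=tuple(reports),
    )


class CorrelationResult(NamedTuple):
    r: float
    p: float
    n: int
    defined: bool


def pearson_with_p(
    curve_a: DepositionCurve,
    curve_b: DepositionCurve,
    method: str = "t",
    n_resamples: int = 9999,
    seed: int = 0,
) -> CorrelationResult:
    """Pearson correlation between two deposition curves, with p-value.

    ``method='t'`` uses the two-sided t-distribution test with n-2 degrees
    of freedom; ``method='permutation'`` uses a permutation null
    (Monte-Carlo, seeded).  Zero variance in either curve yields an
    undefined-correlation flag instead of a coefficient.
    """
    if curve_a.diameters_um.size != curve_b.diameters_um.size or np.any(
        curve_a.diameters_um != curve_b.diameters_um
    ):
        raise DomainError("curves must share an identical diameter grid")
    x = curve_a.efficiency
    y = curve_b.efficiency
    n = x.size
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return CorrelationResult(float("nan"), float("nan"), n, False)
    if method == "t":
        res = stats.pearsonr(x, y)
    elif method == "permutation":
        res = stats.pearsonr(
            x,
            y,
            method=stats.PermutationMethod(
                n_resamples=n_resamples, rng=np.random.default_rng(seed)
            ),
        )
    else:
        raise ConfigurationError("method must be 't' or 'permutation'")
    return CorrelationResult(float(res.statistic), float(res.pvalue), n, True)


@dataclass(frozen=True)
class CorrelationPair:
    pd_id: str
    r: float
    p: float
    n: int
    defined: bool
    robust: bool


@dataclass(frozen=True)
class CorrelationReport:
    """Congruity of each perturbed-direction curve with the IU curve."""

    pairs: tuple[CorrelationPair, ...]
    r_threshold: float = 0.5
    alpha: float = 0.05

    @property
    def n_robust(self) -> int:
        return sum(p.robust for p in self.pairs)

    @property
    def majority_robust(self) -> bool:
        return self.n_robust > len(self.pairs) / 2

    def median_r(self) -> float:
        vals = [p.r for p in self.pairs if p.defined]
        return float(np.median(vals)) if vals else float("nan")


def tolerance_report(
    iu_curve: DepositionCurve,
    pd_curves: Sequence[DepositionCurve],
    r_threshold: float = 0.5,
    alpha: float = 0.05,
    method: str = "t",
) -> CorrelationReport:
    """Correlate the IU curve with each PD curve and flag robustness.

    A pair is robust when r exceeds ``r_threshold`` and the correlation is
    significant at ``alpha``; undefined correlations (flat curves) are
    flagged non-robust.
    """
    pairs = []
    for c in pd_curves:
        res = pearson_with_p(iu_curve, c, method=method)
        robust = res.defined and res.r > r_threshold and res.p < alpha
        pairs.append(
            CorrelationPair(c.protocol, res.r, res.p, res.n, res.defined, robust)
        )
    return CorrelationReport(tuple(pairs), r_threshold, alpha)


def run_sensitivity(
    model: AirwayModel,
    flow: FlowField,
    *,
    offset_mm: float = 5.0,
    radius_mm: float = 1.0,
    phase_deg: float = 0.0,
    seed: int = 0,
    n_droplets: int = 3000,
    diameters_um: Sequence[float] = DEFAULT_DIAMETERS_UM,
    dt: float = DEFAULT_DT_S,
    t_max: float = DEFAULT_T_MAX_S,
    base: SprayAxis | None = None,
    method: str = "t",
):
    """Simulate IU and PD deposition curves and report their congruity.

    Returns ``(iu_curve, pd_curves, perturbation_set, report)``.
    """
    base = base or iu_axis(model)
    pset = perturbed_directions(base, model, offset_mm, radius_mm, phase_deg)
    template = SprayInjection(
        origin=np.zeros(3), axis=np.array([1.0, 0.0, 0.0]), n_droplets=n_droplets
    )
    iu_curve = deposition_curve(
        base, model, flow, template, diameters_um, seed=seed, dt=dt, t_max=t_max
    )
    pd_curves = [
        deposition_curve(
            ax, model, flow, template, diameters_um, seed=seed, dt=dt, t_max=t_max
        )
        for ax in pset.axes
    ]
    report = tolerance_report(iu_curve, pd_curves, method=method)
    return iu_curve, pd_curves, pset, report
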