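"""Stokes-number scaling of ideal droplet sizes across inhalation rates.

The Stokes number St = U rho_D D^2 Cc / (18 mu d) compares the droplet
response time to the characteristic time of the carrier air moving at
speed U through a flux section of diameter d.  Holding the geometry (and
hence d, and U proportional to the flow rate Q) fixed, constancy of St
implies the scaling law D2/D1 = sqrt(Q1/Q2), which lets a deposition-ideal
size range identified at one inhalation rate be projected to another.

The printed scaling law drops the slip factor Cc (valid when Cc is
size-independent); :func:`slip_corrected_scale_diameter` additionally
solves the St equality with the Cunningham correction included, for
side-by-side comparison.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

from scipy.optimize import brentq

from .errors import DomainError
from .spray_transport import slip_correction


@dataclass(frozen=True)
class StokesContext:
    """Inputs of the Stokes number, all SI."""

    air_speed: float                 # U, m/s: flow rate / flux area
    droplet_density: float           # rho_D, kg/m^3
    droplet_diameter: float          # D, m
    slip_factor: float = 1.0         # Cc, dimensionless >= 1
    air_viscosity: float = 1.825e-5  # mu, kg/(m s)
    section_diameter: float = 0.01   # d, m

    def validate(self) -> None:
        for name in (
            "air_speed",
            "droplet_density",
            "droplet_diameter",
            "slip_factor",
            "air_viscosity",
            "section_diameter",
        ):
            if getattr(self, name) <= 0:
                raise DomainError(f"{name} must be positive")
        if self.slip_factor < 1.0:
            raise DomainError("slip factor must be >= 1")


def stokes_number(ctx: StokesContext) -> float:
    """St = U rho_D D^2 Cc / (18 mu d)."""
    ctx.validate()
    return (
        ctx.air_speed
        * ctx.droplet_density
        * ctx.droplet_diameter**2
        * ctx.slip_factor
        / (18.0 * ctx.air_viscosity * ctx.section_diameter)
    )


def scale_diameter(d1_um: float, q1_lpm: float, q2_lpm: float) -> float:
    """Project a droplet diameter across flow rates: D2 = D1 sqrt(Q1/Q2).

    Follows from St invariance with U proportional to Q and Cc held fixed.
    Involutive: projecting back with the rates swapped recovers D1.
    """
    if d1_um <= 0 or q1_lpm <= 0 or q2_lpm <= 0:
        raise DomainError("diameter and flow rates must be positive")
    return d1_um * math.sqrt(q1_lpm / q2_lpm)


def slip_corrected_scale_diameter(
    d1_um: float,
    q1_lpm: float,
    q2_lpm: float,
    mean_free_path: float = 6.6e-8,
) -> float:
    """Project a diameter keeping St constant with Cunningham slip included.

    Solves Q2 * D2^2 * Cc(D2) = Q1 * D1^2 * Cc(D1) numerically.  For
    micron-and-above droplets the result differs from
    :func:`scale_diameter` by well under a micron.
    """
    if d1_um <= 0 or q1_lpm <= 0 or q2_lpm <= 0:
        raise DomainError("diameter and flow rates must be positive")
    target = q1_lpm * d1_um**2 * slip_correction(d1_um, mean_free_path)

    def f(d2):
        return q2_lpm * d2**2 * slip_correction(d2, mean_free_path) - target

    hi = d1_um * math.sqrt(max(q1_lpm / q2_lpm, 1.0)) * 2.0 + 1.0
    lo = d1_um * math.sqrt(min(q1_lpm / q2_lpm, 1.0)) * 0.25
    return float(brentq(f, lo, hi, xtol=1e-12, rtol=1e-14))


@dataclass(frozen=True)
class SizeRange:
    """Droplet size range [d_min, d_max] (um) tied to an inhalation rate."""

    d_min_um: float
    d_max_um: float
    flow_lpm: float
    cutoff: float = 0.02
    empty: bool = False

    def __post_init__(self):
        if not self.empty:
            if self.d_min_um <= 0 or self.d_max_um < self.d_min_um:
                raise DomainError("require 0 < d_min <= d_max")

    def rounded(self, ndigits: int = 2) -> "SizeRange":
        return replace(
            self,
            d_min_um=round(self.d_min_um, ndigits),
            d_max_um=round(self.d_max_um, ndigits),
        )


def project_range(size_range: SizeRange, q_target_lpm: float) -> SizeRange:
    """Project an ideal size range to another inhalation rate via St scaling."""
    if size_range.empty:
        return replace(size_range, flow_lpm=q_target_lpm)
    return SizeRange(
        d_min_um=scale_diameter(size_range.d_min_um, size_range.flow_lpm, q_target_lpm),
        d_max_um=scale_diameter(size_range.d_max_um, size_range.flow_lpm, q_target_lpm),
        flow_lpm=q_target_lpm,
        cutoff=size_range.cutoff,
    )
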