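"""Parametric deposition-curve fixtures.

Generates synthetic nasopharyngeal deposition curves with the qualitative
structure of the simulated ones -- a single Gaussian bump in diameter for
an aligned (IU-like) axis and a near-flat, much smaller bump for an
upright (CU-like) axis -- so the downstream dose and sensitivity analyses
can be exercised without running the transport simulator.  The bump shape
is a fixture choice, not a physical claim.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np

from .errors import ConfigurationError
from .spray_transport import DEFAULT_DIAMETERS_UM, DepositionCurve

#: IU/CU peak parameters quoted for a representative simulated case
#: (46.5% at 13 um for IU vs 0.53% at 14 um for CU at 15 L/min).
PAPER_IU_TEMPLATE = dict(peak_efficiency=0.465, peak_diameter_um=13.0, width_um=4.0)
PAPER_CU_TEMPLATE = dict(peak_efficiency=0.0053, peak_diameter_um=14.0, width_um=4.0)


@dataclass(frozen=True)
class CurveTemplate:
    """Gaussian-bump template for a synthetic deposition curve."""

    peak_efficiency: float
    peak_diameter_um: float
    width_um: float = 4.0
    noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if not 0.0 <= self.peak_efficiency <= 1.0:
            raise ConfigurationError("peak efficiency must lie in [0, 1]")
        if self.width_um <= 0:
            raise ConfigurationError("width must be positive")
        if self.noise_sd < 0:
            raise ConfigurationError("noise sd cannot be negative")


def make_curve(
    template: CurveTemplate,
    protocol: str = "IU",
    flow_lpm: float = 15.0,
    side: str = "left",
    diameters_um: Sequence[float] = DEFAULT_DIAMETERS_UM,
) -> DepositionCurve:
    """Synthesize one deposition curve from a template.

    efficiency(x) = peak * exp(-(x - x_peak)^2 / (2 width^2)) plus
    Gaussian noise (sd ``noise_sd``), clipped to [0, 1]; deterministic for
    a fixed template seed.  With ``noise_sd=0`` the curve is the exact
    closed form.
    """
    d = np.asarray(sorted(diameters_um), dtype=float)
    eff = template.peak_efficiency * np.exp(
        -((d - template.peak_diameter_um) ** 2) / (2.0 * template.width_um**2)
    )
    if template.noise_sd > 0:
        rng = np.random.Generator(np.random.Philox(np.random.SeedSequence(template.seed)))
        eff = eff + rng.normal(0.0, template.noise_sd, size=d.size)
    return DepositionCurve(
        protocol=protocol,
        flow_lpm=flow_lpm,
        side=side,
        diameters_um=d,
        efficiency=np.clip(eff, 0.0, 1.0),
        n_droplets=0,          # synthetic: no droplets were tracked
        seed=template.seed,
    )


def make_case_set(
    iu_template: CurveTemplate,
    cu_template: CurveTemplate,
    n_cases: int,
    seed: int = 0,
    peak_jitter_um: float = 0.75,
    efficiency_jitter_rel: float = 0.05,
    flow_lpm: float = 15.0,
    diameters_um: Sequence[float] = DEFAULT_DIAMETERS_UM,
) -> list[tuple[DepositionCurve, DepositionCurve]]:
    """Paired IU/CU curve collections emulating a multi-case study.

    Each case jitters the template peak location (additively, sd
    ``peak_jitter_um``) and peak efficiency (multiplicatively, log-sd
    ``efficiency_jitter_rel``) so case-to-case variation propagates into
    the downstream improvement summary.  Deterministic per seed.
    """
    if n_cases < 1:
        raise ConfigurationError("need at least one case")
    out = []
    root = np.random.SeedSequence(seed)
    for k, child in enumerate(root.spawn(n_cases)):
        rng = np.random.Generator(np.random.Philox(child))
        pair = []
        for tmpl, proto in ((iu_template, "IU"), (cu_template, "CU")):
            peak_d = tmpl.peak_diameter_um + rng.normal(0.0, peak_jitter_um)
            peak_e = min(
                1.0,
                tmpl.peak_efficiency * float(np.exp(rng.normal(0.0, efficiency_jitter_rel))),
            )
            jittered = replace(
                tmpl,
                peak_diameter_um=peak_d,
                peak_efficiency=peak_e,
                seed=int(child.generate_state(1, np.uint32)[0]) + (0 if proto == "IU" else 1),
            )
            pair.append(
                make_curve(jittered, protocol=proto, flow_lpm=flow_lpm,
                           diameters_um=diameters_um)
            )
        out.append(tuple(pair))
    return out
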