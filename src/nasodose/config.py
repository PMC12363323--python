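"""Run configuration and the end-to-end pipeline driver.

A single YAML document configures a run; unknown keys are rejected and
every default reproduces the study's stated spray protocol parameters
(27.93 deg cone half-angle, 10 m/s injection, 3,000 droplets per cluster,
5-mm insertion, 1.5 g/mL formulation, 2% efficiency cutoff).  The
pipeline writes plain-text artifacts (CSV curves, a JSON report) stamped
with the configuration hash and seeds, and is byte-deterministic for a
fixed configuration.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .airway_model import FlowField, build_idealized_airway
from .delivery_analysis import (
    cu_axis,
    estimate_delivery,
    generic_range,
    ideal_size_range,
    improvement_oom,
    iu_axis,
    summarize_improvement,
)
from .errors import ConfigurationError
from .product_model import get_product, load_registry
from .sensitivity import run_sensitivity
from .spray_transport import (
    DEFAULT_DIAMETERS_UM,
    SprayInjection,
    deposition_curve,
)
from .stokes_scaling import project_range
from .synthetic_fixtures import (
    PAPER_CU_TEMPLATE,
    PAPER_IU_TEMPLATE,
    CurveTemplate,
    make_case_set,
)


def _take(d: dict, allowed: dict, section: str) -> dict:
    unknown = set(d) - set(allowed)
    if unknown:
        raise ConfigurationError(f"unknown keys in '{section}': {sorted(unknown)}")
    out = dict(allowed)
    out.update(d)
    return out


@dataclass
class RunConfig:
    """Validated run configuration with study-protocol defaults."""

    mode: str = "simulate"                  # simulate | fixtures
    airway: dict = field(default_factory=dict)
    flow: dict = field(default_factory=lambda: {"rate_lpm": 15.0})
    spray: dict = field(
        default_factory=lambda: {
            "protocol": "IU",
            "cone_half_angle_deg": 27.93,
            "speed_mps": 10.0,
            "n_droplets": 3000,
            "insertion_mm": 5.0,
            "density_kg_m3": 1500.0,
        }
    )
    analysis: dict = field(
        default_factory=lambda: {
            "cutoff": 0.02,
            "products": ["Flonase", "Nasacort"],
            "project_to_lpm": None,
            "product_registry": None,
        }
    )
    sensitivity: dict = field(
        default_factory=lambda: {
            "enabled": False,
            "offset_mm": 5.0,
            "radius_mm": 1.0,
            "phase_deg": 0.0,
        }
    )
    simulation: dict = field(
        default_factory=lambda: {
            "dt_s": 1.0e-4,
            "t_max_s": 0.25,
            "diameters_um": list(DEFAULT_DIAMETERS_UM),
            "count_outflow": False,
        }
    )
    fixtures: dict = field(
        default_factory=lambda: {
            "iu": dict(PAPER_IU_TEMPLATE),
            "cu": dict(PAPER_CU_TEMPLATE),
            "n_cases": 8,
            "noise_sd": 0.0,
        }
    )
    seeds: dict = field(default_factory=lambda: {"base": 42})

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        data = dict(data or {})
        defaults = cls()
        unknown = set(data) - set(defaults.__dataclass_fields__)
        if unknown:
            raise ConfigurationError(f"unknown top-level config keys: {sorted(unknown)}")
        cfg = cls(
            mode=data.get("mode", defaults.mode),
            airway=dict(data.get("airway", {})),
            flow=_take(data.get("flow", {}), defaults.flow, "flow"),
            spray=_take(data.get("spray", {}), defaults.spray, "spray"),
            analysis=_take(data.get("analysis", {}), defaults.analysis, "analysis"),
            sensitivity=_take(
                data.get("sensitivity", {}), defaults.sensitivity, "sensitivity"
            ),
            simulation=_take(
                data.get("simulation", {}), defaults.simulation, "simulation"
            ),
            fixtures=_take(data.get("fixtures", {}), defaults.fixtures, "fixtures"),
            seeds=_take(data.get("seeds", {}), defaults.seeds, "seeds"),
        )
        if cfg.mode not in ("simulate", "fixtures"):
            raise ConfigurationError("mode must be 'simulate' or 'fixtures'")
        if not cfg.analysis["products"]:
            raise ConfigurationError("analysis.products must name at least one product")
        return cfg

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()) or {})

    def to_dict(self) -> dict:
        return asdict(self)

    def config_hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def _injection_template(cfg: RunConfig) -> SprayInjection:
    sp = cfg.spray
    return SprayInjection(
        origin=np.zeros(3),
        axis=np.array([1.0, 0.0, 0.0]),
        cone_half_angle_deg=float(sp["cone_half_angle_deg"]),
        speed_mps=float(sp["speed_mps"]),
        n_droplets=int(sp["n_droplets"]),
        density_kg_m3=float(sp["density_kg_m3"]),
    )


def _range_dict(r) -> dict:
    if r.empty:
        return {"empty": True, "flow_lpm": r.flow_lpm, "cutoff": r.cutoff}
    return {
        "empty": False,
        "d_min_um": round(r.d_min_um, 2),
        "d_max_um": round(r.d_max_um, 2),
        "flow_lpm": r.flow_lpm,
        "cutoff": r.cutoff,
    }


def run_pipeline(config: RunConfig, out_dir) -> dict:
    """Execute the configured pipeline and write its artifacts.

    Returns the report dictionary (also written to ``report.json``).
    Artifacts: deposition-curve CSVs, ``report.json`` and ``run.log``,
    each stamped with the config hash and base seed.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seed = int(config.seeds["base"])
    log_lines = [
        f"nasodose {__version__}",
        f"config_hash {config.config_hash()}",
        f"seed {seed}",
        f"mode {config.mode}",
    ]
    registry = (
        load_registry(config.analysis["product_registry"])
        if config.analysis.get("product_registry")
        else None
    )
    products = [get_product(name, registry) for name in config.analysis["products"]]
    cutoff = float(config.analysis["cutoff"])

    pairs = []  # (iu_curve, cu_curve) per case
    sens_result = None
    if config.mode == "simulate":
        model = build_idealized_airway(config.airway)
        flow = FlowField(rate_lpm=float(config.flow["rate_lpm"]))
        sim = config.simulation
        template = _injection_template(config)
        insertion = float(config.spray["insertion_mm"])
        axes = {
            "IU": iu_axis(model, insertion_depth_mm=insertion),
            "CU": cu_axis(model, insertion_depth_mm=insertion),
        }
        curves = {}
        for name, ax in axes.items():
            log_lines.append(f"simulate {name} flow={flow.rate_lpm}")
            curves[name] = deposition_curve(
                ax,
                model,
                flow,
                template,
                sim["diameters_um"],
                seed=seed,
                dt=float(sim["dt_s"]),
                t_max=float(sim["t_max_s"]),
                count_outflow=bool(sim["count_outflow"]),
            )
            curves[name].to_csv(out / f"curve_{name.lower()}.csv")
        pairs.append((curves["IU"], curves["CU"]))
        if config.sensitivity["enabled"]:
            log_lines.append("sensitivity")
            _, _, _, report = run_sensitivity(
                model,
                flow,
                offset_mm=float(config.sensitivity["offset_mm"]),
                radius_mm=float(config.sensitivity["radius_mm"]),
                phase_deg=float(config.sensitivity["phase_deg"]),
                seed=seed,
                n_droplets=template.n_droplets,
                diameters_um=sim["diameters_um"],
                dt=float(sim["dt_s"]),
                t_max=float(sim["t_max_s"]),
            )
            sens_result = [
                {"pd_id": p.pd_id, "r": p.r, "p": p.p, "n": p.n, "robust": p.robust}
                for p in report.pairs
            ]
    else:  # fixtures mode: no transport simulation
        fx = config.fixtures
        iu_t = CurveTemplate(**{**fx["iu"], "noise_sd": float(fx["noise_sd"])})
        cu_t = CurveTemplate(**{**fx["cu"], "noise_sd": float(fx["noise_sd"])})
        log_lines.append(f"fixtures n_cases={fx['n_cases']}")
        pairs = make_case_set(
            iu_t,
            cu_t,
            int(fx["n_cases"]),
            seed=seed,
            flow_lpm=float(config.flow["rate_lpm"]),
        )
        for k, (ciu, ccu) in enumerate(pairs):
            ciu.to_csv(out / f"case{k:02d}_curve_iu.csv")
            ccu.to_csv(out / f"case{k:02d}_curve_cu.csv")

    # --- analysis over curve pairs -------------------------------------
    iu_ranges = [ideal_size_range(ciu, cutoff) for ciu, _ in pairs]
    ranges_block = {"iu_per_case": [_range_dict(r) for r in iu_ranges]}
    nonempty = [r for r in iu_ranges if not r.empty]
    if nonempty:
        gen = generic_range(nonempty)
        ranges_block["generic"] = _range_dict(gen)
        q_to = config.analysis.get("project_to_lpm")
        if q_to:
            ranges_block["projected"] = _range_dict(project_range(gen, float(q_to)))

    product_block = {}
    for product in products:
        per_case = []
        for ciu, ccu in pairs:
            # weight over the tracked size span (the full 1-24 um grid by
            # default; reduced grids integrate over what they cover)
            interval = (
                max(1.0, float(ciu.diameters_um[0])),
                min(24.0, float(ciu.diameters_um[-1])),
            )
            est_iu = estimate_delivery(ciu, product, interval)
            est_cu = estimate_delivery(ccu, product, interval)
            per_case.append(
                {
                    "deposited_iu_mg": est_iu.deposited_mass_mg,
                    "deposited_cu_mg": est_cu.deposited_mass_mg,
                    "api_iu_mcg": est_iu.api_mcg,
                    "api_cu_mcg": est_cu.api_mcg,
                    "improvement_oom": improvement_oom(est_iu, est_cu),
                }
            )
        block = {"per_case": per_case}
        finite = [
            c["improvement_oom"]
            for c in per_case
            if np.isfinite(c["improvement_oom"])
        ]
        if finite:
            s = summarize_improvement(
                [
                    (c["deposited_iu_mg"], c["deposited_cu_mg"])
                    for c in per_case
                    if np.isfinite(c["improvement_oom"])
                ]
            )
            block["improvement_mean_oom"] = s.mean
            block["improvement_sd_oom"] = s.sd
            block["n_cases"] = s.n
        block["n_infinite_improvement"] = len(per_case) - len(finite)
        product_block[product.name] = block

    report = {
        "nasodose_version": __version__,
        "config_hash": config.config_hash(),
        "seed": seed,
        "mode": config.mode,
        "flow_lpm": float(config.flow["rate_lpm"]),
        "size_ranges": ranges_block,
        "products": product_block,
    }
    if sens_result is not None:
        report["sensitivity"] = sens_result

    (out / "report.json").write_text(json.dumps(report, indent=2, sort_keys=True))
    (out / "run.log").write_text("\n".join(log_lines) + "\n")
    return report
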