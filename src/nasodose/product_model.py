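"""Log-normal droplet size distributions of commercial spray products.

The sprayed mass is distributed over droplet diameters x (um) with the
log-normal probability density

    m(x) = 1 / (sqrt(2 pi) x ln(sigma_g)) *
           exp(-(ln x - ln x50)^2 / (2 ln(sigma_g)^2)),

where x50 is the mass median diameter (half the shot mass is in droplets
smaller than x50) and sigma_g > 1 the geometric standard deviation.  The
corresponding droplet *count* distribution follows by dividing the mass
density by the droplet mass (spherical droplets of constant formulation
density), which is again log-normal with count median x50 *
exp(-3 ln(sigma_g)^2) (the Hatch-Choate conversion).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import numpy as np
import yaml
from scipy.stats import norm

from .errors import ConfigurationError, DomainError

DEFAULT_FORMULATION_DENSITY = 1500.0  # kg/m^3 (1.5 g/mL)


@dataclass(frozen=True)
class SizeDistribution:
    """Log-normal mass distribution of droplet diameters (um)."""

    x50_um: float
    sigma_g: float

    def __post_init__(self):
        if self.x50_um <= 0:
            raise ConfigurationError("x50 must be positive")
        if self.sigma_g <= 1.0:
            raise ConfigurationError("sigma_g must exceed 1")

    @property
    def _mu(self) -> float:
        return math.log(self.x50_um)

    @property
    def _sig(self) -> float:
        return math.log(self.sigma_g)

    # -- mass-weighted quantities ------------------------------------------
    def mass_pdf(self, x_um):
        """Mass probability density (per um) at diameter ``x_um``."""
        x = np.asarray(x_um, dtype=float)
        if np.any(x <= 0):
            raise DomainError("diameter must be positive")
        z = (np.log(x) - self._mu) / self._sig
        out = np.exp(-0.5 * z * z) / (math.sqrt(2.0 * math.pi) * x * self._sig)
        return out if out.ndim else float(out)

    def mass_cdf(self, x_um):
        x = np.asarray(x_um, dtype=float)
        if np.any(x <= 0):
            raise DomainError("diameter must be positive")
        out = norm.cdf((np.log(x) - self._mu) / self._sig)
        return out if out.ndim else float(out)

    def mass_fraction(self, a_um: float, b_um: float) -> float:
        """Fraction of sprayed mass in diameters [a, b] um (closed form)."""
        if not 0 < a_um < b_um:
            raise DomainError("require 0 < a < b")
        return float(self.mass_cdf(b_um) - self.mass_cdf(a_um))

    def sample_mass_weighted(self, n: int, rng: np.random.Generator):
        """Draw droplet diameters with probability proportional to mass."""
        return np.exp(rng.normal(self._mu, self._sig, size=n))

    # -- count-weighted quantities -----------------------------------------
    @property
    def count_median_um(self) -> float:
        """Count median diameter, x50 * exp(-3 ln^2 sigma_g)."""
        return math.exp(self._mu - 3.0 * self._sig**2)

    def _inv_cubed_partial(self, a_um: float, b_um: float) -> float:
        # E[X^-3; a<X<b] for the mass-weighted log-normal, closed form
        mu3 = self._mu - 3.0 * self._sig**2
        pref = math.exp(-3.0 * self._mu + 4.5 * self._sig**2)
        return pref * float(
            norm.cdf((math.log(b_um) - mu3) / self._sig)
            - norm.cdf((math.log(a_um) - mu3) / self._sig)
        )

    def count_density(self, x_um, interval_um: tuple[float, float] = (1.0, 24.0)):
        """Relative count density at ``x_um``, normalized over ``interval_um``.

        Proportional to mass_pdf(x) / x^3 (sphere mass-to-number
        conversion); integrates to 1 over the stated interval.
        """
        a, b = interval_um
        if not 0 < a < b:
            raise DomainError("normalization interval must satisfy 0 < a < b")
        x = np.asarray(x_um, dtype=float)
        if np.any(x <= 0):
            raise DomainError("diameter must be positive")
        raw = self.mass_pdf(x) / x**3
        out = raw / self._inv_cubed_partial(a, b)
        return out if np.ndim(out) else float(out)

    def count_in_range(
        self,
        a_um: float,
        b_um: float,
        shot_mass_mg: float = 1.0,
        density_kg_m3: float = DEFAULT_FORMULATION_DENSITY,
    ) -> float:
        """Absolute droplet count with diameters in [a, b] um per shot.

        Divides the mass in each size class by the spherical droplet mass
        rho * pi x^3 / 6; closed form through the log-normal moments.
        """
        if not 0 < a_um < b_um:
            raise DomainError("require 0 < a < b")
        if shot_mass_mg <= 0:
            raise DomainError("shot mass must be positive")
        rho_g_per_um3 = density_kg_m3 * 1e-15  # kg/m^3 -> g/um^3
        shot_g = shot_mass_mg * 1e-3
        return shot_g * 6.0 / (math.pi * rho_g_per_um3) * self._inv_cubed_partial(a_um, b_um)


@dataclass(frozen=True)
class SprayProduct:
    """A commercial spray product: size distribution plus pump metering."""

    name: str
    distribution: SizeDistribution
    shot_mass_mg: float
    api_mcg_per_mg: float

    def __post_init__(self):
        if self.shot_mass_mg <= 0:
            raise ConfigurationError("shot mass must be positive")
        if self.api_mcg_per_mg < 0:
            raise ConfigurationError("API concentration cannot be negative")


def _registry_from_entries(entries) -> dict[str, SprayProduct]:
    reg = {}
    for e in entries:
        missing = {"name", "x50_um", "sigma_g", "shot_mass_mg", "api_mcg_per_mg"} - set(e)
        if missing:
            raise ConfigurationError(f"product entry missing keys: {sorted(missing)}")
        reg[e["name"]] = SprayProduct(
            name=e["name"],
            distribution=SizeDistribution(float(e["x50_um"]), float(e["sigma_g"])),
            shot_mass_mg=float(e["shot_mass_mg"]),
            api_mcg_per_mg=float(e["api_mcg_per_mg"]),
        )
    return reg


def load_registry(path: str | Path | None = None) -> dict[str, SprayProduct]:
    """Load a product registry YAML; defaults to the built-in registry."""
    if path is None:
        text = resources.files("nasodose").joinpath("data/products.yaml").read_text()
    else:
        text = Path(path).read_text()
    return _registry_from_entries(yaml.safe_load(text))


BUILTIN_PRODUCTS = load_registry()


def get_product(name: str, registry: dict[str, SprayProduct] | None = None) -> SprayProduct:
    reg = registry or BUILTIN_PRODUCTS
    try:
        return reg[name]
    except KeyError:
        raise ConfigurationError(
            f"unknown product {name!r}; available: {sorted(reg)}"
        ) from None
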