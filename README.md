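# nasodose

Reduced-order modelling of intranasal spray targeting of the
**nasopharynx** — the region at the back of the nose that is both a
topical drug-delivery target and the dominant initial infection site for
SARS-like respiratory viruses.  The package is aimed at respiratory
drug-delivery researchers and device designers who want a desk-scale,
fully scriptable analogue of the CT + CFD pipelines used to study how
spray-axis orientation, droplet size and inhalation rate control
nasopharyngeal dose.

Two spray usage protocols are contrasted throughout:

* **CU (current use)** — bottle held upright, head tilted 22.5° forward,
  axis near the lateral wall (the standard package-insert instruction);
* **IU (improved use)** — axis nearly horizontal at the nostril, aimed
  through the passage at the nasopharynx, tilted slightly toward the
  cheek.

## What the package computes

1. **Idealized airway + analytic flow** — a curved tube with named
   regions (vestibule, anterior, mid, nasopharynx) and a mass-conserving
   parabolic (laminar) inhalation field at 15 or 30 L/min, standing in
   for CT-based geometry and LES airflow.
2. **Lagrangian droplet transport** — solid-cone injections of 3,000
   monodispersed droplets (1–24 μm, 10 m/s, 27.93° half-angle, 5-mm
   insertion, 1.5 g/mL) integrated with RK4 under Stokes drag with
   Cunningham slip, gravity and Saffman lift, with trap walls — yielding
   per-diameter nasopharyngeal **deposition-efficiency curves**.
3. **Stokes-number scaling** — St = U ρ_D D² C_c / (18 μ d); with
   geometry fixed, D₂/D₁ = √(Q₁/Q₂) projects deposition-ideal size
   ranges across inhalation rates (e.g. [5, 11] μm at 30 L/min →
   [7.07, 15.56] μm at 15 L/min).
4. **Spray-product model** — log-normal droplet mass distribution
   m(x) = exp(−(ln x − ln x₅₀)²/(2 ln²σ_g)) / (√(2π) x ln σ_g), with
   mass↔count conversion; Flonase (x₅₀ = 37.16 μm, σ_g = 2.080) and
   Nasacort (43.81 μm, 1.994) built in.
5. **Dose analysis** — distribution-weighted deposited formulation mass
   per pump, API mass, IU-over-CU improvement in orders of magnitude,
   and ideal/generic size ranges at a 2% efficiency cutoff.
6. **Tolerance sensitivity** — five perturbed spray directions from the
   1-mm-circle construction, with Pearson correlation (and p-values)
   between perturbed and IU deposition curves.

See `docs/methods.md` for the model, its assumptions and limitations —
in particular, the idealized geometry reproduces orderings, trends and
correlations, not the deposition magnitudes of a real airway.

## Worked example

```python
import numpy as np
import nasodose as nd
from nasodose.spray_transport import SprayInjection

model = nd.build_idealized_airway()          # 22.5 deg head tilt applied
flow = nd.FlowField(rate_lpm=15)
iu, cu = nd.iu_axis(model), nd.cu_axis(model)
print("IU axis valid:", nd.validate_iu_axis(iu, model).valid)

template = SprayInjection(origin=np.zeros(3), axis=np.array([1.0, 0, 0]),
                          n_droplets=500)
curve_iu = nd.deposition_curve(iu, model, flow, template, seed=42)
curve_cu = nd.deposition_curve(cu, model, flow, template, seed=42)
k = int(np.argmax(curve_iu.efficiency))
print(f"IU peak: {100*curve_iu.efficiency[k]:.1f}% at {curve_iu.diameters_um[k]:.0f} um")

rng = nd.ideal_size_range(curve_iu, cutoff=0.02)
proj = nd.project_range(rng, 30.0).rounded()
flonase = nd.get_product("Flonase")
dep_iu = nd.weighted_deposition(curve_iu, flonase)
print(f"ideal IU range: [{rng.d_min_um:.0f}, {rng.d_max_um:.0f}] um; "
      f"projected to 30 L/min: [{proj.d_min_um}, {proj.d_max_um}] um")
print(f"Flonase IU delivery {dep_iu:.4f} mg/pump, "
      f"API {nd.round_api(nd.api_mass(dep_iu, flonase))} mcg")
```

prints (500 droplets per diameter, seed 42):

```
IU axis valid: True
IU peak: 23.2% at 15 um
ideal IU range: [11, 24] um; projected to 30 L/min: [7.78, 16.97] um
Flonase IU delivery 3.0091 mg/pump, API 1.5 mcg
```

i.e. the aligned IU axis deposits a peak of ~23% of mid-size droplets in
the nasopharynx band; weighting by Flonase's droplet-mass distribution
gives ~3 mg of formulation (≈1.5 μg API) delivered per pump.  The same
run with the upright CU axis deposits essentially nothing posteriorly
(every droplet traps on the anterior roof or bypasses the nose), the
idealized-geometry version of the orders-of-magnitude CU/IU contrast.

A command-line interface mirrors the library:

```sh
nasodose scale --dmin 5 --dmax 11 --from-flow 30 --to-flow 15
nasodose simulate --protocol IU --flow 15 --out curve_iu.csv --seed 42
nasodose dose --curve curve_iu.csv --curve-cu curve_cu.csv --report dose.json
nasodose sensitivity --offset-mm 5 --seeds 3 --out tolerance.csv
nasodose run --config run.yaml --out-dir out/
```

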