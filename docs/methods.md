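# Methods

`nasodose` is a desk-scale, reduced-order model of intranasal spray
targeting of the nasopharynx — the region at the back of the nose that is
both a preferred topical drug target and the dominant initial infection
site for SARS-like respiratory viruses.  Anatomically accurate studies of
this problem couple CT-derived airway reconstructions with large-eddy
airflow simulation; those layers are deliberately out of scope here.
This package replaces them with an idealized geometry and an analytic
laminar flow field, and implements, on top of that substitute, the full
chain of defined computations: Lagrangian droplet tracking with trap
walls, deposition-efficiency curves per droplet size, Stokes-number size
scaling across inhalation rates, log-normal spray-product mass
distributions, distribution-weighted nasopharyngeal dose and API
estimates, and spray-axis perturbation (tolerance) analysis.

## Idealized airway and inhalation field

The nasal passage is a single curved tube of circular cross-section with
an analytic arc–line–arc centerline (total length 0.10 m by default):

1. a vestibule bend (radius 6 mm) turning the inlet direction — 30° off
   the vertical, tilted posteriorly — into the horizontal;
2. a straight main passage;
3. a sharper posterior bend (radius 6 mm, 80° turn) heading
   posterior-inferior into the nasopharynx.

The tube radius follows a shape-preserving (PCHIP) interpolant through
control points, default 4.2 mm at the nostril, a slight valve
constriction, ~4.2–4.4 mm through the main passage, a posterior
constriction to 3.5 mm where the passage turns down (the analogue of the
choana, which accelerates the flow into the nasopharynx), then a flare to
5.5 mm at the outlet.  Named regions partition arc length: vestibule
[0, 0.10), anterior [0.10, 0.45), mid [0.45, 0.85), nasopharynx
[0.85, 1.0].  The whole model is rotated 22.5° forward (the recommended
head tilt) into a laboratory frame whose −z axis is gravity.

Airflow is steady, laminar and quasi-one-dimensional: on each
cross-section the axial velocity is a parabolic profile scaled so the
section flux equals the inhalation rate Q (15 or 30 L/min), with no slip
at the wall.  Nearest-centerline projection is computed in closed form on
the analytic centerline, so the flux-conservation property holds to
quadrature precision at every station.  The single passage carries the
full metered inhalation rate.  Limitations inherited from this choice:
no secondary flows, no turbulence (the higher flow rate is turbulent in
real anatomies), no inter-nostril flow split, and a geometric radial
velocity component of zero even where the radius tapers.

## Spray protocols

* **Current use (CU)** — bottle upright: the axis is vertical in the
  laboratory frame, anchored on the nostril plane a third of the
  lateral–septal width from the lateral wall, with a 5-mm nozzle
  insertion.
* **Improved use (IU)** — the axis is aimed from the nostril-plane
  centroid at the centerline of the nasopharynx band (default arc
  fraction 0.92) and tilted 2° toward the lateral (cheek) side.  The
  validity test implements the three placement criteria: (i) the
  extended axis intersects the nasopharynx region; (ii) it does not cut
  an anterior septal safety plane (2.5 mm medial of the centerline,
  spanning the anterior 30% of the passage — the clinically relevant
  anterior septum) while inside the lumen; (iii) its first wall
  intersection is lateral and posterior (arc fraction ≥ 0.5).  The
  default IU axis passes all three.
* **Perturbed directions (PD 1–5)** — a 1-mm-radius circle is placed
  perpendicular to the IU axis at 5 or 10 mm from the centroid; the five
  equidistant circle points define axes tilted arctan(1/5) = 11.31° or
  arctan(1/10) = 5.71° off the base.  In a single 4-mm tube an 11.31°
  tilt displaces the ray ~17 mm at the nasopharynx, so perturbed axes
  can legitimately fail criteria that their anatomical counterparts
  passed; validity is therefore reported per axis, never enforced.

## Droplet transport

Droplets are inert spheres (formulation density 1.5 g/mL) released as a
solid-cone point injection: 3,000 monodispersed droplets per cluster,
directions uniform over the solid angle of a 27.93° half-angle cone,
initial speed 10 m/s, nozzle tip 5 mm past the nostril-plane anchor.
The equation of motion integrates Stokes drag with Cunningham slip
correction, gravity, and Saffman–Mei shear lift (generalized deformation
form, with the local shear taken as the dominant radial derivative of
the parabolic profile).  Droplet Reynolds numbers reach O(5) briefly
after injection, where linear Stokes drag under-damps slightly; this is
accepted for consistency with the drag law stated above.

Integration is classical RK4 with a flow time step of 1e−4 s over a
0.25-s horizon.  Because the drag relaxation time τ = ρ_D D² Cc / 18 μ
of a 1-μm droplet (~5 μs) is far below the flow step, each flow step is
divided into ⌈dt/τ⌉ sub-steps (capped at 512), keeping RK4 inside its
stability region and resolving the relaxation.  Walls trap droplets at
the first crossing, located by bisection to 1e−6 m; the outlet plane and
the nostril plane are open (escape downstream to the lungs, or forward
out of the nose).  Droplets still airborne at the horizon count as
non-deposited.  One-way momentum coupling; Brownian motion, evaporation
and wall films are neglected (transport times are O(0.1 s)).

**Deposition accounting.**  Nasopharyngeal deposition efficiency is the
fraction of the released cluster trapped in the terminal nasopharynx
band.  Droplets exiting the outlet are tallied separately and not
counted by default: in a laminar field every near-tracer droplet of
every protocol eventually exits, so counting outflow would report ~100%
"deposition" at 1–5 μm for both protocols and erase the characteristic
single-peaked IU / near-zero CU structure; physically, sub-10-μm
droplets that reach the outlet bypass the nose into the lower airway.
`count_outflow=True` restores the alternative rig-style accounting in
which outflow past the nasopharynx is counted as delivery.

The capture mechanism in this geometry is inertial drift in the
posterior bend: a droplet crossing a bend of turn angle θ at local speed
u drifts ~τ·u·θ toward the outer wall, so capture peaks for mid-size
droplets (~10–17 μm at 15 L/min, shifting smaller at 30 L/min, the
direction the Stokes scaling law predicts), while small droplets follow
the flow out the outlet and large droplets impact anteriorly during the
ballistic phase.  The upright CU axis deposits almost everything on the
anterior vestibule roof.  The simulated curves reproduce these
qualitative structures; the magnitudes of an anatomical airway (e.g. a
46.5% peak) are not claimed and not reproducible without the CT/LES
layers.

Randomness is counter-based (Philox streams keyed by protocol, flow,
side and diameter), so curves are bit-reproducible and independent of
execution order.  The tracking kernels are numba-compiled and work on a
600-point sampled polyline of the centerline (geometric error < 1 μm).

## Stokes scaling

St = U ρ_D D² Cc / (18 μ d), with U the flow rate divided by flux area
and d the flux-section diameter.  With geometry fixed and U ∝ Q,
constancy of St gives D₂/D₁ = √(Q₁/Q₂), used to project
deposition-ideal size ranges between inhalation rates; the projection is
involutive and reported to 2 decimal places.  The printed scaling law
drops Cc; a slip-corrected variant solves Q·D²·Cc(D) = const numerically
and is reported side by side (the difference is < 1% above 5 μm).  Note
the projection of a 24-μm limit by √(30/15) yields 33.94 μm *at the
lower rate* when applied literally; the source labels that projection
with the higher rate, an inconsistency we follow literally and document
rather than resolve.

## Product model and dose

Sprayed mass is log-normal in droplet diameter (mass median x₅₀,
geometric standard deviation σ_g); closed forms via the error function
cover the density, CDF, interval mass fractions, and the count
distribution (Hatch–Choate: count median = x₅₀·exp(−3 ln²σ_g), spheres
at constant formulation density).  Built-in products: Flonase
(x₅₀ = 37.16 μm, σ_g = 2.080, 104.51 mg/pump, 0.5 μg API per mg) and
Nasacort (43.81 μm, 1.994, 97.64 mg/pump, 0.5 μg/mg).

Per-pump nasopharyngeal delivery weights the deposition curve by the
mass density: shot_mass × ∫ η(x) m(x) dx over the tracked 1–24 μm range,
with η linearly interpolated on the integer-micron grid and zero outside
it (larger droplets deposit anteriorly and miss the target).  API mass
is deposited mass × concentration; reported values are rounded half-even
to 2 significant figures, the convention of the published estimates
(0.96, 0.025, 0.92, 0.024 μg).  The IU-over-CU improvement statistic is
log₁₀ of the deposited-mass ratio, summarized across cases by mean and
sample (n−1) standard deviation; zero CU deposition flags an infinite
improvement that is excluded from summaries with a warning.

## Sensitivity analysis

Congruity between the IU deposition curve and each PD curve is measured
by Pearson's r over the shared 24-point size grid, with a two-sided
p-value from the t-distribution (n−2 degrees of freedom) or, optionally,
a seeded Monte-Carlo permutation null.  A pair is robust when r > 0.5
and p < 0.05.  The azimuthal phase of the five circle points is
arbitrary; it is exposed (`phase_deg`, default 0 = first point lateral)
and affects individual axes but not the statistical summary materially.
Because the idealized model has one passage, the 5-mm/10-mm offsets are
run parameters rather than left/right-nostril assignments.

## Synthetic curve fixtures

A Gaussian bump in diameter (peak efficiency, peak diameter, width, plus
optional truncated-Gaussian noise, clipped to [0, 1]) emulates the
single-peaked IU and near-zero CU curves; case sets jitter peak location
and height to mimic subject/nostril/flow variation.  These fixtures
exercise the dose and congruity analyses without the simulator; passing
them demonstrates the correctness of the downstream arithmetic, not the
transport physics.

## Problem sizes and numerical defaults

The test suite runs the simulator at 400 droplets per cluster (120–250
in multi-seed property checks); the acceptance script uses the full
3,000.  Defaults elsewhere: dt = 1e−4 s, horizon 0.25 s, wall-crossing
tolerance 1e−6 m, 600 centerline samples, efficiency cutoff 2% for ideal
size ranges.  All geometric defaults are free parameters of the
idealization, chosen once for anatomical plausibility and fixed;
dimensions of real airways are not represented.

## Known limitations

* Deposition magnitudes are those of a smooth circular tube, not a
  nose; only orderings, trends and correlations are meaningful.
* Laminar quasi-1D flow under-disperses droplets compared with real
  (partly turbulent) nasal flow, which is why the simulated CU curve is
  essentially zero rather than merely two orders of magnitude below IU.
* The septum and the left/right distinction are abstracted into a
  safety plane and a mirror flag.
* Stokes drag is linear; no Reynolds correction at injection speeds.
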