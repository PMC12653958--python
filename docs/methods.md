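# Methods

This note documents the models implemented in `medialknee`, the parameter
choices that matter, and what the synthetic cohort does and does not
emulate.

## Elastic-foundation contact model

The medial tibiofemoral compartment is reduced to a rigid analytic femoral
surface pressed into a bed of independent nonlinear springs representing
the cartilage layer on the tibial plateau.

**Geometry.** The femoral condyle has two convex sagittal arcs — anterior
radius 35.0 mm, posterior radius 18.9 mm — and one convex frontal arc
(default 20.8 mm). The tibial plateau is concave in both planes: 21 mm
frontal radius and, in this implementation, a 36.5 mm sagittal radius.
Because every arc is circular and rotation about the flexion axis maps a
circular arc onto itself, flexion enters the surface only through arc
selection: the anterior (flatter, more conforming) arc below the
transition flexion (default 30°), the posterior arc at or above it. This
makes the loaded footprint — and hence strain at a given force — a step
function of flexion; trials near the threshold should be interpreted with
that in mind.

**Calibration of the unprinted radii.** The frontal femoral radius and the
sagittal tibial concavity are not published for this model family. They
control contact conformity, and with them set to 20.8 mm and 36.5 mm the
model carries a typical healthy-walking load (2.68 BW on a 69.31 kg body,
≈1.82 kN) at a peak strain of 0.196 and peak stress of 2.09 MPa, matching
the operating range reported for cohort means in comparable studies
(strain ≈ 0.2, stress ≈ 2.4–2.6 MPa). These two values were fixed once at
that operating point and are exposed in `KneeGeometry` for sensitivity
work. A flat sagittal tibia is *not* viable here: force balance would then
require peak strains near 0.5 at the same load, far outside the reported
range.

**Mesh.** 111 × 66 elements at 0.5 mm spacing (7326 elements, ≈1832 mm²).
Meniscal coverage (46 % of the plateau) is assigned to the outermost
elements by normalised Chebyshev distance from the centre; whole tie
groups are kept so the covered band is mirror-symmetric in both anatomical
planes, which can overshoot the target fraction by up to one rim of
elements (46.9 % on the default mesh).

**Constitutive law and moduli.** Each element follows
σ = −E·ln(1 − ε), the standard nonlinear elastic-foundation law whose
stress diverges at full compression. "Log" is the natural logarithm: the
reported stress/strain operating pairs for this model family
(e.g. 2.40 MPa at ε = 0.21) back-solve to E ≈ 10.2 MPa under ln,
consistent with the 10.1 MPa covered-tibial modulus, and to no published
modulus under log10. For the same reason the default per-element modulus
rule is `"tibial"` — the springs represent the tibial cartilage layer
(10.1 MPa beneath the meniscus, 4.0 MPa uncovered), with the femoral layer
treated as rigid. Two alternatives are selectable in `CartilageMaterial`:
`"series"` (harmonic mean of femoral and tibial layer moduli, two springs
in series) and `"arithmetic"`. The meniscus modulus (1.3 MPa) and the
Poisson ratio (0.45) are carried as metadata only: an independent-spring
foundation has no lateral coupling and no meniscal hoop-load path, so
neither quantity enters the force computation.

**Solver.** Total force is strictly increasing in axis depth, so the
equilibrium is unique. It is bracketed between the unloaded height (first
surface contact) and the depth at which the most compressed element
reaches the strain cap (0.995), then located by bisection to a 0.5 N
residual (configurable; the oracle tests solve to 1e−10 N). Targets beyond
the strain cap raise an error reporting the maximum achievable force.
Halving the element spacing changes peak stress by well under 2 % at fixed
force.

## Failure-with-repair model

Failure is a volume-scaled Weibull process in time, driven by peak
elementwise compressive strain (configurable to another scalar by passing
it directly) and by the daily number of loading cycles.

**Loading cycles.** Daily cycles default to *steps*: 2 × daily distance /
stride length, ≈7000/day at 6.0 km and a 1.71 m stride — the consistent
reading of a 6 km ≈ 7000-steps-per-day regimen. The literal
distance/stride (strides) reading halves this and is selectable via
`cycle_count="strides"`; it doubles every time-to-failure.

**Time to failure.** t_f = c_p · T_cycle · (c_w ε)^(−b) with c_p = 1.0,
c_w = 1.03, b = 12.9, and T_cycle the loading period in years
(1 / cycles-per-year, 365.25 days/year). The ε^(−12.9) sensitivity is the
dominant feature of the whole chain: a 10 % strain difference moves t_f by
a factor of ~3.4.

**Failure probability and density.** P_fail(t) = 1 − exp[−(V/V_ref) ·
(t/t_f)^(k/b)] with k = 14.3 and V_ref = 78.5 mm³ (the 5 mm diameter ×
4 mm fatigue-specimen volume that calibrated the constants). The density
used for the repair integral is the exact time derivative of this CDF; a
printed prefactor form circulating for this density is dimensionally
inconsistent and is not used.

**Stressed volume.** Weibull volume scaling assumes a uniformly stressed
volume. A bed-of-springs solution is not uniformly strained, so the
default (`volume_rule="weibull"`) is the weakest-link effective volume

    V_eff = Σ_i V_i (ε_i / ε_peak)^k,

which is exactly equivalent to treating each element as an independent
Weibull specimen at its own strain and multiplying survival
probabilities. On the default mesh at 2.68 BW this gives V_eff ≈ 2050 mm³
against a total loaded volume of ≈9160 mm³. The literal
`volume_rule="total"` (loaded area × thickness) is retained but drives
V/V_ref to ~100 and saturates every participant's failure probability
near 1, which is not a useful operating regime.

**Repair.** P_repair(t) = 1 − exp[−(t/5.0)^5.2]. The default convention
evaluates the repair survivor at absolute time ("absolute"): the
with-repair curve is ∫₀ᵀ f(t)·(1 − P_repair(t)) dt, accumulated as exact
per-interval density mass times the midpoint survivor (this reproduces
the no-repair CDF to machine precision when repair is disabled, and
halving the 0.01-year grid step changes the terminal value by <1e−4).
The alternative `repair_convention="since_damage"` starts each damage
event's repair clock at the event, P(T) = ∫₀ᵀ f(t)·(1 − P_repair(T−t)) dt,
computed by discrete convolution; note this quantity is the probability of
*being* in an unrepaired-failed state at T and is not monotone in T. Both
conventions assume repair fully erases damage, which overestimates
recovery.

At the default operating point the chain yields 37-year repair-adjusted
failure probabilities with cohort means around 20–33 % (seed-dependent) —
the same order as epidemiological medial-knee-osteoarthritis incidence by
the mid-50s (~10–14 %) but at the upper end, reflecting the steep strain
sensitivity and this model's effective-volume scale.

## Synthetic cohort

The generator emulates the *outputs* of a motion-capture +
musculoskeletal-simulation front end for 15 participants × 4 conditions
(neutral, toe-in, toe-out, lateral wedge insoles) × 5 trials. Each scalar
feature is drawn as condition mean + participant intercept + trial noise;
the intercept carries a fraction (default 0.7) of the feature SD and is
shared across conditions, inducing a within-participant trial-level
correlation of ≈0.49 across conditions. Condition means and SDs default
to published cohort values for peak force (2.68/2.51/2.43/2.69 BW),
stride length, walking velocity, CoP offset and foot progression angle.
Two features are not published and were set once: the stance-mean force is
back-derived from published cumulative load × stride length (e.g.
0.85 × 1.71 = 1.4535 BW for neutral), and the knee flexion angle at peak
force is N(20°, 5°) in every condition — a typical early-stance value; its
upper tail interacts with the 30° arc-transition step noted above.
Features are mutually independent given the intercepts (no published
covariance structure to emulate); draws violating physical bounds
(non-positive force/stride/velocity, stance-mean force above peak) are
resampled, not clipped. Gaussian marginals, no participant-by-condition
interaction, and no muscle-level or metabolic outputs are generated —
passing tests therefore demonstrate the computational chain and its
statistics under this idealised structure, not the richness of real
motion-capture data.

The CoP fixture (`generate_cop_trajectory`) is a straight-line path whose
heading equals the requested foot progression angle (positive toe-out),
with optional lateral Gaussian noise; it exists to exercise the
endpoint-based angle estimator, whose sampling SD at 2 mm noise over a
180 mm excursion is ≈0.9°.

## Statistics

Outcomes are aggregated trial → participant mean → condition before any
testing (the repeated-measures order; trial-level fitting would mix
within- and between-participant variance). Each outcome is fitted with a
linear mixed model — condition fixed effect, participant random
intercept, REML — which on balanced one-row-per-cell data is exactly the
compound-symmetry covariance of classical repeated-measures analysis.
All six pairwise contrasts are Wald-tested (normal reference; measured
type-I error 0.054 at α = 0.05 over 1000 null cohorts, within the
0.05 ± 0.02 calibration band). Cohen's d uses the paired-difference SD:
published effect sizes of ~1 for ~0.25 BW differences against ~0.47 BW
cross-sectional SDs are only attainable with a within-subject
denominator. No multiple-testing correction is applied by default (Holm
is available); singular fits fall back to paired t-tests with a warning.

## Problem sizes

Default analyses run a 300-trial cohort (≈300 bisection solves on the
7326-element mesh, ~2 s), 20-replicate ordering studies (~40 s), and
1000-cohort null calibrations (~20 s). The Monte-Carlo cross-check of the
repair integral uses 2 × 10⁶ draws.

## Known limitations

- No translational femoral kinematics, no lateral compartment, no
  finite-element continuum mechanics, no meniscal load path.
- The arc-transition step makes strain discontinuous in flexion at the
  threshold; a tangency-blended condyle would remove this but is not
  published for this model family.
- The two calibrated radii (frontal femoral, sagittal tibial) are
  interpretations, as is the tibial-layer modulus rule and the
  weakest-link effective volume; all are exposed as configuration.
- Lifetime risk inherits every upstream idealisation through an ε^14.3
  nonlinearity: small strain biases produce large probability biases, so
  between-condition comparisons are far more trustworthy than absolute
  probabilities.
- No biological covariates (inflammation, adipokines, sex, age) enter the
  failure model.
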