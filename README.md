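# medialknee

Medial tibiofemoral contact mechanics and probabilistic lifetime
cartilage-failure modelling for gait studies.

## The problem

Medial knee osteoarthritis is strongly linked to the mechanical loading of
the medial tibiofemoral compartment during walking. Gait modifications —
toe-in walking, toe-out walking, lateral wedge insoles — aim to reduce that
loading, but their value is ultimately a question about *lifetime* tissue
risk, not a single trial's forces. `medialknee` implements the desk-side
computational chain that turns per-trial gait features (peak medial
compressive force in bodyweights, knee flexion angle at peak force, stride
length) into cartilage stress and strain, a projected probability of
cartilage failure over 37 years of daily walking, and repeated-measures
comparisons across gait conditions. A synthetic-cohort generator stands in
for the motion-capture and musculoskeletal-simulation front end, emulating
a 15-participant × 4-condition × 5-trial repeated-measures study.

It is intended for biomechanics researchers who want a tested, reusable
implementation of this modelling chain to run on their own gait-feature
tables or on synthetic cohorts.

## The model

**Contact.** The medial compartment is an elastic foundation ("bed of
springs"): a rigid femoral condyle — two convex sagittal arcs (35.0 mm
anterior, 18.9 mm posterior, selected by a flexion threshold) and a convex
frontal arc — resting in a concave tibial plateau (21 mm frontal arc),
meshed into 7326 spring elements at 0.5 mm spacing with a 5.0 mm unloaded
cartilage thickness. Each element obeys the logarithmic law

    σ = −E · ln(1 − ε),    ε = compression / thickness,

with the modulus set by meniscal coverage (10.1 MPa beneath the meniscus,
covering 46 % of the plateau; 4.0 MPa uncovered). The flexion axis is
lowered from the unloaded height by bisection until the summed spring
force matches the target medial compressive force.

**Failure.** Cartilage fatigue is a volume-scaled Weibull process driven
by peak compressive strain ε and daily loading cycles (2 × 6.0 km / stride
length):

    t_f  = c_p · T_cycle · (c_w ε)^(−b),
    P_fail(t) = 1 − exp[−(V/V_ref) · (t/t_f)^(k/b)],
    P_repair(t) = 1 − exp[−(t/t_rep)^r],

with k = 14.3, b = 12.9, c_w = 1.03, c_p = 1.0, V_ref = 78.5 mm³,
t_rep = 5.0 y, r = 5.2. The repair-adjusted failure probability integrates
the failure density against the probability that repair has not yet
occurred, over a 37-year horizon.

**Statistics.** Outcomes are aggregated trial → participant mean →
condition, compared with a linear mixed-effects model (condition fixed
effect, participant random intercept ≡ compound symmetry, REML) and paired
Cohen's d.

## Worked example

```python
from medialknee import (solve_contact, time_to_failure, p_fail_with_repair,
                        CohortConfig, CartilageLifetimeModel)

# one trial: cohort-mean neutral walking, 2.68 BW on a 69.31 kg body
sol = solve_contact(2.68 * 69.31 * 9.81, flexion_angle=20.0)
print(sol.peak_strain, sol.peak_stress)      # 0.196, 2.09 MPa

t_f = time_to_failure(sol.peak_strain, stride_length=1.71)
res = p_fail_with_repair(sol.effective_volume(), t_f)
print(100 * res.terminal_with_repair)        # 19.2 %

# whole synthetic cohort, statsmodels-style
results = CartilageLifetimeModel.from_synthetic(CohortConfig(seed=1)).fit()
print(results.condition_means("p_fail_with_repair_pct"))
print(results.summary())
```

The single-trial solve gives a peak compressive strain of 0.196 and peak
stress of 2.09 MPa — the neighbourhood of reported cohort means for
healthy walking (≈0.22 and ≈2.6 MPa) — and a 37-year repair-adjusted
failure probability of 19.2 % (88.5 % had the tissue no capacity to
repair). The cohort run (seed 1) prints per-condition terminal failure
probabilities of 28.7 % (neutral), 18.1 % (toe-in), 20.7 % (toe-out) and
34.8 % (lateral insoles): both foot-progression modifications unload the
medial compartment relative to neutral gait, lateral insoles do not, and
the contrast table marks the neutral-vs-toe-in and neutral-vs-toe-out
force differences significant (p < 1e-4, paired d ≈ 1.0–1.9).

A thin CLI wraps the same stages:

```bash
medialknee simulate-cohort --seed 1 --out cohort.csv
medialknee run-pipeline --cohort cohort.csv --out results/
medialknee contact-solve --force-bw 2.68 --body-mass 69.31 --flexion 20
```

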