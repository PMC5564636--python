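# Methods

## Scope and model overview

`irinopbpk` simulates the disposition of intravenously infused irinotecan
(CPT-11), its active metabolite SN-38 and the inactive glucuronide SN-38G
in a whole-body physiologically based pharmacokinetic (PBPK) model of a
tumor-bearing adult, and evaluates the simulation against a published
sparse clinical plasma dataset. The pipeline is: reference anatomy →
tissue partition coefficients → linear multi-organ ODE system →
calibration of the unquantified clearances → non-compartmental analysis
(NCA) → virtual-population percentile bands and a predicted-vs-observed
error report.

## Whole-body model

Fourteen compartments per chemical species: lung, heart, brain, muscle,
adipose, skin, bone, liver, spleen, gut, kidney, arterial and venous blood
pools, and a tumor. Circulation is venous blood → lung → arterial blood →
systemic organs → venous blood; spleen and gut drain through the liver
(portal flow). Every tissue is perfusion-limited:

    V_i dC_i/dt = Q_i (C_art − C_i / Kp_i)

with amounts in μmol, volumes in L, flows in L/min, time in minutes
internally (the user-facing grid is hours, matching clinical sampling
conventions). Plasma and blood are treated as one well-mixed reference
medium (blood:plasma ratio 1); the venous pool concentration is the
reported "plasma" concentration.

The liver is well-stirred: hepatic elimination acts on the unbound
venous-equilibrium concentration `fu · C_liv/Kp_liv` through

* a lumped CPT-11 → SN-38 intrinsic clearance (carboxylesterase plus the
  indirect CYP3A4 route),
* a lumped SN-38 → SN-38G intrinsic clearance (UGT1A1/1A6/1A9),
* a biliary clearance specified per kg body weight (transport-protein
  mediated canalicular excretion is folded into this term).

Each metabolic flux reappears mole-for-mole in the product species' liver
compartment, so total moles are conserved across the cascade. The kidney
filters unbound drug at `CL_R = gfr_fraction × GFR × fu`. Enterohepatic
recirculation is off: biliary and renal effluxes accumulate in terminal
bile/urine states, which is what makes the mass-balance audit exact.

Default dosing is 350 mg/m² (DuBois–DuBois BSA) infused over 30 min into
venous blood, with a flat-dose alternative (`total_dose`) because the
source description carries both conventions; the choice is an explicit
config field and is never silently resolved.

### Integration

All processes are first order, so the state equation is linear and
time-invariant with a piecewise-constant infusion input,
`x' = A x + b·u(t)`. The default integrator propagates the augmented
system exactly with matrix exponentials over each output interval
(`scipy.linalg.expm`, with caching of the propagator for repeated step
sizes). This has no truncation error: mass balance holds to ~1e-14 of the
dose and a 1276-point simulation of the 48-state system takes ~20 ms. An
adaptive stiff solver (LSODA, rtol 1e-8 / atol 1e-10 μmol, split at the
infusion stop) is kept behind `method="lsoda"` as an independent
cross-check — the test suite verifies the two agree — and as the natural
path for any future saturable extension. `simulate` additionally audits
`|body burden + eliminated − infused| ≤ 0.5% of dose` at every output
point and raises if violated.

## Partition coefficients

The source for the compound data does not state a Kp method, so the
package uses a documented composition-based (tissue-homogenate) formula in
the Poulin–Theil family:

    Kp = fu_p · (f_water + D_vo · f_lipid) / fu_t
    fu_t = 1 / (1 + r · (1 − fu_p)/fu_p),      r = 0 by default
    log10 D_vo = 1.115 · logP − 1.35

`f_water`/`f_lipid` are the fractional water and total-lipid content of
each organ and `D_vo` is the neutral-oil:water distribution coefficient
estimated from octanol lipophilicity by the standard vegetable-oil
regression. With the default `r = 0`, tissue affinity is carried entirely
by the lipid term and plasma protein binding by `fu_p`; for an unbound
compound against a pure-water tissue the formula reduces exactly to
Kp = 1. The same lipid affinity applies to every organ (no
adipose-specific solvent), which keeps Kp a deterministic function of the
tabulated compound parameters and the composition table, monotone in logP,
and adipose-dominant for lipophilic species.

Two variants were considered and rejected on the observed data: a
tissue-binding correction (`r = 0.5`) uniformly inflates Kp and makes the
terminal phase far too slow, and the classic split treatment (octanol P
for lean tissues, ionization-corrected oil D for adipose) yields a steady-
state volume near 1000 L with muscle outranking adipose — inconsistent
with the modest distribution the clinical profile implies. The shipped
formula gives CPT-11 Vss ≈ 225 L and a terminal half-life ≈ 12 h, the
right order for this drug.

Ionization itself is computed by two-site Henderson–Hasselbalch on the
tabulated acid/base pKa pair, treating the sites as independent (the
microstate assignment is not published; this is an explicit assumption).
It feeds the speciation report, not the Kp values.

## Lactone/carboxylate speciation

Camptothecins interconvert between the active closed lactone and the open
hydroxy-carboxylate. No quantitative in-vivo equilibrium constants are
available, so the lactone fraction is a Hill sigmoid of pH with
configurable midpoint (default 6.5) and slope (default 1): carboxylate
dominates at pH 4–6, lactone above pH 7, consistent with the qualitative
chemistry. Speciation is deliberately a *reporting* quantity: it does not
feed back into Kp or clearances, so simulated PK is pH-invariant by
construction — the pH scan re-runs the simulation per scenario and the
resulting PK parameters are bit-identical while the reported lactone
fractions track the scenario pH. This mirrors the pH-insensitivity finding
the model is meant to reproduce; it also means the package cannot predict
a genuine pH–PK interaction if one exists.

## Reference anatomy and virtual population

Organ volumes, flow fractions of cardiac output and water/lipid content
follow ICRP-style reference-adult compilations (reference male 73 kg /
176 cm, CO 6.0 L/min, GFR 110 ml/min; female 60 kg / 163 cm, CO 5.4 L/min,
GFR 95 ml/min; composition values as used by homogenate partition
models). Flow fractions are renormalized at build time so systemic flows
sum exactly to cardiac output; the lung carries the whole pulmonary flow.

Anthropometric scaling: structural organs scale with the BMI-preserving
height-predicted weight `W_norm = W_ref (H/H_ref)²`; weight excess over
`W_norm` is assigned to adipose volume (1 kg ≈ 1 L, floor 0.5 L). Organ
flows scale with organ volume and cardiac output is recomputed as their
sum, so the flow-balance invariant holds for every generated individual.
GFR scales with BSA/1.73. The tumor is a small, poorly perfused, acidic
add-on compartment (0.1 L, 0.01 L/min, pH 6.8 by default, all
configurable) — the published model gives no tumor dimensions.

Population generation (default 100 subjects, 50% female) draws weight
(CV 15%) and height (CV 5%) log-normally around the sex-specific
reference, plus independent log-normal perturbations of organ volumes
(10%), flows (10%) and GFR (20%) — typical PBPK population settings, all
exposed in the spec. Sex counts follow deterministic rounding of the
female fraction; the seed is mandatory, making generation a pure function
of the spec.

## Calibration

The published sources name the metabolic routes but not their rates, so
the two lumped intrinsic clearances — and, by default, the biliary
clearance — are fitted to the observed two-species plasma dataset. Loss is
the residual sum of squares in log-concentration space with both species
weighted equally (observed concentrations span two decades; log residuals
weight the tail and the peak evenly). Optimization runs bounded
trust-region least squares in log-parameter space from a log-spaced
multistart grid (5 points per axis for one free parameter, 3 for two, 2
for three, trimmed 10% from the bounds), taking the best local optimum;
everything is deterministic. Bounds default to (1e-3, 10) L/min for the
CPT-11→SN-38 clearance, (1e-2, 100) L/min for SN-38→SN-38G, and
(0.27, 27) ml/min/kg — an order-of-magnitude bracket around the tabulated
2.70 — for biliary clearance. Points at or below a configurable
quantification limit are excluded, never imputed.

With biliary fixed at the tabulated 2.70 ml/min/kg the model cannot clear
CPT-11 fast enough to match the observed AUC (error ≈ 117%), which is why
biliary is free by default; the fit lands near 12 ml/min/kg, within the
documented plausibility bracket. Self-consistency: fitting noiseless
self-generated data recovers all three clearances to well under 1%; with
10% log-normal noise the median relative error over 20 replicates is
≈ 9–12% per parameter.

## Non-compartmental analysis

Units follow the clinical reporting convention for this drug: AUC in
μmol·min/l (hours-to-minutes conversion inside the trapezoid), Cmax in
μmol/l, times in hours, λz in 1/h, clearance in ml/min/kg, volumes in
ml/kg.

* AUC to the last sample: linear trapezoid (the log-linear variant exists
  behind a flag). This choice is validated by reproducing the published
  experimental SN-38 value 26.74 μmol·min/l exactly.
* Cmax/tmax: maximum observed value, ties broken by earliest time; on
  simulated profiles the default 0.02 h output grid resolves tmax beyond
  two-decimal reporting.
* λz: least-squares regression of log concentration on time over the last
  3 points by default, or an automatic suffix search (length ≥ 3, after
  the peak) maximizing adjusted R². Half-life = ln 2/λz.
* AUC∞ = AUC_tend + C_last/λz; MRT = AUMC∞/AUC∞ − τ/2 with trapezoidal
  AUMC and mono-exponential tail closure; CL = dose/AUC∞ normalized per
  kg; Vz = CL/λz, Vss = CL·MRT.
* Degenerate inputs degrade explicitly: a profile too sparse for a
  terminal fit yields NaN for every λz-derived field (no exception), a
  single point leaves only Cmax/tmax/C_tend; dose-derived fields are NaN
  without dose-and-weight context, and for formed metabolites (no
  administered dose of their own). Exact duplicate rows are dropped on
  dataset construction, making NCA invariant to duplicated samples.

The published CPT-11 experimental AUC_tend (1504.96) exceeds the linear
trapezoid of the printed samples (1444.97) by ≈ 60 μmol·min/l, possibly a
pre-first-sample area term; the package reports the trapezoid of the data
as printed. The experimental half-life is printed as non-finite in the
comparison tables and is treated as not-available on the observed side.

## Evaluation

Population summary: pointwise 5th/50th/95th percentile curves using linear
interpolation between order statistics (numpy's "linear" quantile — the
definition is stated because the source is silent), plus NCA per subject
and NCA of the pointwise-median curve. The median profile is
median-of-curves; per-subject parameter medians are also available from
the per-subject table.

Percent predictive error is `100 × |observed − predicted| / observed`,
the convention recovered by reproducing all six published error values
from their printed predicted/observed pairs (printed errors are truncated
at the last digit, e.g. 13.576 → 13.57, and comparisons tolerate this).

For the predicted-vs-observed report the population-median curve is first
re-sampled (linear interpolation) onto the observed sampling times, and
NCA runs on that sparse version. Rationale: an 11-sample clinical design
starting 94 min after dosing can never catch the simulated infusion-end
peak, so comparing full-curve NCA against sparse-design NCA would count
the unobserved 0–1.56 h segment as model error. Re-sampling compares like
with like. The half-life row carries a predicted value only.

## Synthetic data

The generator produces noisy sparse datasets from known ground truth:
mono-exponential (volume + rate with closed-form infusion input),
bi-exponential (bolus coefficient/exponent pairs convolved with the
infusion window), or a forward run of the assembled whole-body model.
Residual error is multiplicative log-normal with σ² = ln(1 + CV²) —
concentrations stay positive and the error is proportional, matching the
two-decade dynamic range of sparse oncology PK data. The default sampling
schedule copies the observed 11-time design (1.56–25.5 h), so NCA and
calibration are exercised under realistic sparsity. The generator does not
emulate below-quantification censoring, sampling-time errors, or
between-occasion variability, so recovery results bound performance under
idealized residual error only.

## Problem sizes and determinism

The test suite and the acceptance script use the full default sizes: a
100-subject population on the 0.02 h output grid, 8-start calibration to
the observed dataset, a 20-replicate noise-recovery study (single-start
per replicate from the bounds' log-center), and a 1000-replicate check of
the noise generator. The exact integrator keeps the whole suite in the
tens of seconds. All randomness flows through explicit integer seeds
(numpy `default_rng`); repeated runs are bit-identical, and the CLI stamps
every artifact with the config hash and seed.

## Known limitations

* **Early distribution.** The observed profile falls from 11.6 to
  6.25 μmol/l between 1.56 h and 1.66 h — a ~7-min half-time still active
  64 min after the stated 30-min infusion ends. A smooth perfusion-limited
  linear system cannot produce that; reproducing it needs either
  permeability-limited tissue uptake (out of scope here) or an infusion
  that ends near 1.5 h. Consequently the calibrated model underpredicts
  the first observed CPT-11 sample by ~50% while matching both species'
  AUC and the SN-38 peak closely; setting `infusion_duration: 90` in the
  regimen config removes most of the discrepancy and is consistent with
  the observed tmax of 1.56 h, but the shipped default keeps the stated
  30 min.
* All kinetics are linear: no Michaelis–Menten saturation, no
  transporter or enzyme DDI, no UGT1A1 polymorphism subpopulations.
* SN-38G compound parameters are assumptions (documented in the shipped
  file), as no public parameter table exists for the glucuronide.
* Biliary clearance is assumed plasma-referenced; whether the tabulated
  value is blood- or plasma-referenced is not stated in the source.
* The population covariate model is anthropometric only (no age effects
  on flows or enzyme abundances, no renal/hepatic impairment).
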