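# Methods

## Problem and model

Pseudouridine 5′-phosphate (ΨMP) can be made from UMP in one pot by two
enzymes: a purine/pyrimidine nucleotide 5′-phosphate nucleosidase
(PpnN, EC 3.2.2.10, or its faster R341A-Y347A variant "RY") that hydrolyses
UMP into uracil (Ura) and ribose 5-phosphate (Rib5P), and the ΨMP
C-glycosidase YeiN (EC 4.2.1.70) run in the condensation direction,
Rib5P + Ura → ΨMP + H₂O. The nucleosidase is competitively inhibited by its
own product Rib5P, so the cascade is designed around *kinetic pull*: YeiN in
mass excess removes Rib5P faster than it accumulates.

### Nucleosidase rate law

    v₁ = Vmax · [UMP] / ( Km · (1 + [Rib5P]/Ki) + [UMP] ),   Vmax = kcat · [E]

[E] is the molar concentration of enzyme *subunits* (mass concentration ÷
subunit molar mass); oligomeric state is ignored because the constants are
per subunit. Characterized parameter presets:

| preset   | kcat (s⁻¹) | Km (mM) | Ki (mM) | subunit mass (Da) |
|----------|-----------|---------|---------|-------------------|
| WT_PPNN  | 2.6       | 1.1     | 0.1     | 51,794            |
| RY       | 13.4      | 15.5    | 1.2     | 51,440            |

### Hydrolysis ODE and its closed form

For hydrolysis alone, dS/dt = −v₁(S, P) with P = S0 − S by mass balance.
Separation of variables gives the implicit solution

    t(S) = [ Km·(1 + S0/Ki)·ln(S0/S) + (1 − Km/Ki)·(S0 − S) ] / Vmax,

which degenerates to the integrated Michaelis–Menten relation as Ki → ∞.
This closed form is the independent oracle for the numerical integrator: the
test suite inverts it by bracketed root finding and requires agreement to
≤1e-6 relative error over 100 random parameter sets.

### YeiN rate law (assumption)

Only a single operating point is characterized for YeiN: 7.0 U/mg at 15 mM
of each substrate. We therefore adopt an independent two-substrate
saturation form

    v₂ = Vmax · R/(Km_R + R) · U/(Km_U + U)

with **assumed** Km values of 1 mM for each substrate, irreversible (the
condensation equilibrium strongly favours ΨMP; the reverse direction is not
modelled and the `reversible` flag is rejected). kcat is calibrated so the
model reproduces 7.0 U/mg exactly at the 15/15 mM anchor, giving
kcat ≈ 4.37 s⁻¹ for the default Kms. Conclusions that depend on the *shape*
of the YeiN saturation curve (not just its anchor value) are therefore
assumption-laden; the cascade-level claims tested here (final yield, the
ratio-sweep plateau) are insensitive to the exact Kms because YeiN runs far
above 1 mM of both substrates for most of the reaction.

### Cascade ODE

States (UMP, Rib5P, Ura, ΨMP), with
d[UMP]/dt = −v₁, d[Rib5P]/dt = d[Ura]/dt = v₁ − v₂, d[ΨMP]/dt = v₂.
Two mass balances (UMP + Ura + ΨMP = UMP₀ and UMP + Rib5P + ΨMP = UMP₀)
hold along the trajectory and are asserted to solver tolerance.

## Numerical choices

* Integrator: `scipy.integrate.solve_ivp` with the implicit Radau method,
  rtol 1e-8, atol 1e-10 mM, dense output. Product inhibition makes the late
  phase mildly stiff; an explicit method would need tiny steps there.
* Concentrations are clipped at 0 before rate evaluation instead of using
  solver events; with the tolerances above the excursions are ≤1e-10 mM.
* Temperature, pH and Mn²⁺ are not state variables; all parameters refer to
  the 40 °C / pH 7.5 operating point.
* Unit convention: concentrations mM, time min, rates mM/min; kcat is stored
  in s⁻¹ and multiplied by 60 exactly once, at the Vmax boundary.

## Estimation

* All fits are unweighted nonlinear least squares on rates (or on the UMP
  trace for progress curves), the convention of the standard kinetics
  packages the experimental analysis mirrors; optional weighting is out of
  scope.
* Parameters are optimised on the log scale, which enforces positivity
  without bound constraints. Initial guesses: Vmax₀ = 1.2 × max observed
  rate, Km₀ = S nearest half of Vmax₀, Ki₀ = Km₀/10 — robust on hyperbolic
  data.
* Identifiability: a dataset with no inhibited points cannot pin Ki; the
  global fitter then falls back to Michaelis–Menten and flags the result.
  A progress-curve Ki estimate ≥ 1000·Km is reported as "no inhibition
  detectable" rather than as a finite constant.
* Uncertainty: asymptotic standard errors from the log-scale Jacobian
  (delta method), plus an optional percentile bootstrap over points.
  With the default six-point series the percentile bootstrap *undercovers*
  (≈85% observed at nominal 95%) — a known small-sample artefact of
  resampling so few design points; on the full 18-point substrate ×
  inhibitor grid coverage is ≥90%, which is what the suite asserts.
* Initial-rate extraction from raw time courses uses the customary
  <20%-conversion rule: a linear fit over the prefix of points below 20%
  conversion, at least 3 points. Note that for a strongly product-inhibited
  enzyme even the <20% window is curved; the helper is only unbiased when
  product inhibition is negligible over the window.

## Synthetic data

The generator emulates initial-rate grids and progress curves from the rate
law at the preset parameters, with per-point independent multiplicative
Gaussian noise truncated at zero. Default CV 0.16, taken from the replicate
spread of the activity assay (9.8 ± 1.6 U/mg, n = 6). Default grids:
S ∈ {0.5, 1, 2, 5, 15, 30} mM (wild type) and {2, 5, 10, 20, 40, 80} mM
(RY), spanning each Km; inhibitor levels {0, 2, 10} mM. The true assay
grids are unpublished, so these are declared stand-ins. What the generator
does *not* emulate: HPLC peak integration, sampling/quench artefacts,
enzyme inactivation, pipetting covariance between points. A green
recovery test therefore establishes correctness of the fitting machinery
under the stated noise model, not robustness to real-world systematics.
Cascade generation warns above 1500 mM initial UMP (the observed solubility
limit).

## Process metrics

Yield, space-time yield (molar and mass), mass-based TON, E-factor and
scale-up volume are plain algebra over a `ReactionOutcome`; the interest is
in the accounting conventions:

* Product molar mass: anhydrous free acid, 324.18 g/mol, for all mass
  metrics (this reproduces the published 294 g/L/h ↔ 906 mM/h pair, the
  TON ≈ 103 g/g and the 3.1 L/kg volume); the disodium salt, 368.15 g/mol,
  only for gravimetric yield of the isolated solid (1.60 g = 4.35 mmol).
* E-factor: waste mass per product mass, enzymes excluded and water included
  by default, both toggleable. The gram-scale ledger counts water by
  difference to the 5.0 mL final volume at 1 g/mL (E ≈ 2.1); counting the
  full 5.0 mL gives E ≈ 3.3. The published 3.0 falls inside this accounting
  bracket; the exact waste inventory behind it is not reproducible from the
  text, so the suite asserts the bracket, not the value.
* The route table checker treats printed values as rounded to their last
  digit and flags derived fields that do not round-trip (e.g. the narrative
  900 mM/h against the tabulated 294 g/L/h, which implies 906 mM/h). It
  flags, never corrects.

## Documented discrepancies (not resolved)

* **Apparent-Km fold-changes.** Pure competitive inhibition predicts
  Km_app(I)/Km_app(0) = 1 + I/Ki: 101-fold (wild type) and 9.33-fold (RY) at
  10 mM Rib5P. The empirically reported folds are 40 and 6.7 — inconsistent
  with the globally fitted Ki under the purely competitive model. The suite
  asserts the model's predictions; the empirical numbers presumably reflect
  finite substrate ranges and noise in the per-level fits.
* **Catalytic efficiency rounding.** kcat/Km for the wild type is
  2.6/1.1 = 2.36, which rounds to 2.4 at one decimal but is reported as 2.3
  (truncation). The pipeline reports 2.4.

## Known limitations

* No thermodynamic/reversible model of the YeiN reaction; no Mn²⁺,
  temperature or pH dependence; no allosteric (ppGpp) regulation model.
* Enzyme inactivation is not modelled (activity was stable over the relevant
  horizon in the characterization).
* The metrics module does no cost modelling or life-cycle assessment beyond
  the E-factor.
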