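# Methods

## The problem

Differential scanning fluorimetry (DSF / ThermoFluor / thermal shift assay)
monitors protein unfolding through a dye that fluoresces when bound to the
exposed hydrophobic core of the unfolded state. Ligands that bind the folded
protein shift the melting transition to higher temperature, so DSF is a cheap
and popular binding *detector* — but the magnitude of the T_m shift does not
convert simply into a dissociation constant, because K_d itself changes with
temperature across the transition.

This package implements the *isothermal* analysis of such data: instead of
tracking T_m across ligand concentrations (a "horizontal slice" of the curve
family), it reads the fraction of unfolded protein f_u at one fixed
temperature from every curve (a "vertical slice"). At fixed temperature the
system is a pair of coupled two-state equilibria,

    U + L  <=K_U=>  F + L  <=K_d=>  FL

with K_U = [U]/[F] (unfolding of the *unbound* protein) and
K_d = [F][L]/[FL]. Mass balance gives a quadratic for the free ligand [L],
whose unique non-negative root yields

    f_u([L]_T) = 1 / (1 + (1/K_U) (1 + [L]/K_d)).

Fitting this to f_u against the total ligand concentration yields K_d and K_U
at the slice temperature with no thermodynamic parameters at all.

## Closed-form midpoint relation

Defining EC50 as the total ligand concentration at which f_u falls to half
its ligand-free value f_u0 = K_U/(1+K_U), the model implies — exactly, with
no weak-binding approximation —

    EC50 = K_d / (1 - f_u0) + [P]_T / 2,
    K_d  = (1 - f_u0) (EC50 - [P]_T / 2).

This is property-tested against the full model at 1e-10 absolute tolerance
over randomized parameters. It also exposes the method's hard limit: when
K_d << [P]_T, EC50 -> [P]_T/2 regardless of affinity (stoichiometric
titration). The fitter flags fits with EC50 <= [P]_T and reports
K_d < (1-f_u0)([P]_T/2) as an upper bound instead of a point estimate.

## Per-curve models

Fraction unfolded is read off each melt curve via one of two fits:

* **Boltzmann sigmoid** — f_u(T) = 1/(1+exp((Tm-T)/a)); empirical, used for
  midpoint location and baseline normalization.
* **Thermodynamic model** — K_U(T) = exp(-dG_U/RT) with the integrated
  Gibbs-Helmholtz form dG_U(T) = dH_U (1 - T/Tm) - dCp_U (Tm - T + T ln(T/Tm));
  dH_U and Tm free, dCp_U held fixed (it is under-determined by a single melt
  curve; supply it from calorimetry or a buried-surface-area estimate —
  4 kcal/mol/K is the documented example value used throughout the tests).

Raw traces carry linear dye baselines: Y(T) = (1-f_u)(m_F T + b_F) +
f_u (m_U T + b_U). Because the dye's temperature response does not depend on
ligand, the pipeline shares the two slopes m_F, m_U globally across a plate
while keeping Tm, dH_U (or a) and the intercepts per-curve. On simulated
normalized data both models extract f_u values agreeing within 0.02 near the
transition, so the choice is a matter of taste for slicing purposes.

Units: file I/O and all user-facing temperatures are Celsius (the instrument
convention); thermodynamic expressions run in kelvin (offset 273.15).
R = 1.987204e-3 kcal/(mol K) to match kcal-based enthalpies.

## Simulator

`simulate.SimSpec` generates the validation data. Defaults emulate a
well-behaved MBP-like system: Tm = 50 °C, dH_U = 120 kcal/mol, dCp_U =
4 kcal/mol/K, K_d(Tm) = 1 µM, dH_b = -10 kcal/mol, dCp_b = -0.5 kcal/mol/K,
[P]_T = 2 µM; grid Tm ± 15 °C in 0.25 °C steps; ladder of 12 concentrations
(0 plus a two-fold dilution series 0.49–500 µM). Binding's temperature
dependence uses the integrated Gibbs-Helmholtz / van't Hoff form with
constant dCp_b anchored by dG_b(Tm) = R Tm ln K_d(Tm) (unbinding
convention). Noise is i.i.d. Gaussian added on the normalized 0–1 scale,
with per-curve substreams derived deterministically from one seed; at
sigma = 0 output is bit-identical across seeds.

What the simulator does *not* emulate — hence what passing tests do not
demonstrate about real plates: aggregation and irreversible unfolding
(the falling post-transition signal common in SYPRO data; a
truncate-after-maximum preprocessing flag exists but no model), dye–protein
interaction and dye depletion, folding intermediates, destabilizing ligands,
non-1:1 stoichiometry, and pipetting/dilution error structure (noise is
homoscedastic and uncorrelated).

## Numerical choices

* Free ligand: subtraction-free quadratic root; complex concentration [FL]
  by the analogous Morrison form, so mass balance holds to ~1e-15 relative.
* Curve fits: trust-region least squares (tolerances 1e-12, max 5000
  evaluations). Tm seeded at the maximum of dY/dT; a at 1 °C; dH_U at
  100 kcal/mol; baselines by linear regression on the outer 15% of points.
  Fits failing to converge, with non-positive dH_U, or with Tm outside the
  observed range raise a flagged error — never a silent wrong value.
* Isothermal fit: least squares in log10(K_d), log10(K_U) (positivity and
  scale); K_U seeded from the zero-ligand point via f_u0/(1-f_u0); K_d
  seeded from a 4-parameter logistic EC50 estimate through the closed form.
  Weights 1/sem² when replicate standard errors exist, unweighted otherwise.
  Standard errors from the Jacobian covariance (delta method to linear
  scale); an optional seeded residual bootstrap is available.
* Model f_u outputs are clipped to [0,1]; normalized raw signals are not
  clipped, preserving residual structure.
* The Hill/4PL estimate places the zero-ligand point at a pseudo-
  concentration two decades below the smallest dose and is used only for
  initialization and triage, never for the reported K_d.

## Design decisions on open ground

* K_U may be fit jointly with K_d (default, needs a zero-ligand point and
  ≥ 4 distinct concentrations) or fixed from the ligand-free melt curve
  (`fix_K_U`); both modes are exposed because each anchors K_U differently
  and they should agree within error when the data are consistent.
* Replicates are fit independently per well; the isothermal slice aggregates
  f_u as mean ± standard error across wells sharing a ligand concentration.
* A conventional dTm-versus-ligand table is emitted for continuity with
  T_m-shift reporting but never feeds the K_d estimate.
* Monotonicity caveat: K_U(T) has a cold-denaturation branch below the
  temperature of maximal stability T_s = Tm exp(-dH_U/(dCp_U Tm)); f_u rises
  monotonically with T only above T_s. For melt-transition-scale parameters
  T_s sits far below the fitted window.

## Expected accuracy and problem sizes

All validation is simulator-based (the original wet-lab plates are not
shipped); each quantity below is recomputed by the test suite or
`scripts/acceptance.py` at run time.

* Noiseless recovery: simulate with the defaults above, fit every curve,
  slice at 50 °C, fit the coupled equilibria — K_d and K_U return within
  ~1% of truth (the residual bias reflects fitting ligand-shifted curves
  with a ligand-free two-state model, and matches the behaviour of the
  published analysis this package reimplements).
* Noise robustness: 100 seeds per noise level on the same conditions give
  median relative K_d errors of roughly 2% at sigma = 0.01, 8% at 0.05, and
  15% at 0.1 — accurate up to noise levels beyond typical experimental
  scatter, degrading visibly at sigma = 0.1.
* The robustness study uses 100 seeds x 3 noise levels x 12 curves of 121
  points each; the full suite runs in well under a minute on one core.

## Limitations

Affinities are only measurable near the protein's T_m (shiftable with
chemical denaturant, whose use changes no mathematics here). Very tight
binders (K_d << [P]_T) are bounded, not measured. Extrapolating K_d to
other temperatures via van't Hoff requires binding enthalpies this analysis
does not determine and is out of scope. The two-state assumptions for both
folding and binding are load-bearing: intermediates or secondary sites bias
K_d in ways the fit diagnostics cannot always reveal.
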