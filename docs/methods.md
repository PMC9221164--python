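# Methods

## Models

### Michaelis–Menten fitting

Initial rates are fitted to v = v_max·S/(K_M + S) by unweighted nonlinear
least squares (`scipy.optimize.least_squares`, Levenberg–Marquardt) on the
raw residuals v_i − v̂_i. Both parameters are optimized on a log scale,
which enforces positivity without bound constraints and behaves well when
the optimizer probes small K_M. Initial guesses are analytic:
v_max⁰ = 1.1 × max(v), and K_M⁰ is the substrate level at half of v_max⁰,
linearly interpolated on the sorted curve (nearest point when noise makes
the curve non-monotone). Replicate points at the same S enter as separate
residuals rather than being averaged, so replicate scatter properly
penalizes the fit. An optional 1/v weighting (relative residuals) is
available for data whose error scales with the signal; it is off by
default because unweighted fitting is the convention for reducing-sugar
assays with roughly constant CV over the usable range and few points near
zero rate.

At least 4 distinct substrate levels are required and constant rates are
rejected: with fewer levels or a flat response, K_M is unidentifiable and
any returned number would be noise.

The turnover number uses k_cat = v_max·M·10⁻³/60: a specific activity in
µmol·min⁻¹·mg⁻¹ equals 10⁻³ mol·min⁻¹·g⁻¹, so multiplying by the molecular
mass (g·mol⁻¹) gives events per enzyme per minute. It is computed only when
a molecular mass is supplied; the published value for BsXyn10 (49 s⁻¹) is
~5% above this arithmetic (46.8 s⁻¹ from 58.6 µmol·min⁻¹·mg⁻¹ × 47.89 kDa)
and is retained as reported metadata in `enzytherm.reference`, never as
output.

### Arrhenius and Eyring analysis

The activation energy is −R times the OLS slope of ln(rate) on 1/T
(`scipy.stats.linregress`; with two points this is the exact secant). By
design only the ascending limb of a temperature-activity profile should
enter (`RateTemperatureSeries.restrict`): rates past the optimum reflect
denaturation and would flatten the apparent slope.

Transition-state parameters at a reference temperature T:
ΔH* = E_a − R·T; ΔG* from inverting the Eyring equation,
ΔG* = −R·T·ln(k·h/(k_B·T)); ΔS* = (ΔH* − ΔG*)/T. Because ΔS* is assembled
from the other two, the Gibbs identity ΔG* = ΔH* − T·ΔS* holds to rounding
by construction — the test suite asserts it to 1 J·mol⁻¹ on every emitted
parameter set. Rate constants entering the Eyring expression must be s⁻¹;
per-minute inactivation constants are divided by 60 at exactly one place
(inside `deactivation_params`), which is the convention that reproduces
the published inactivation free energies.

The temperature quotient is computed as Q10 = exp(10·E_a/(R·T²)), the
differential form of the Arrhenius law integrated over a 10 K step at T.
The form sometimes printed in the literature, antilog(E_a·10/(R·T)),
overflows for realistic activation energies (the exponent is ≈140 for
E_a ≈ 40 kJ·mol⁻¹ at 333 K) and cannot be what any reported Q10 ≈ 1.5
means; the T² form reproduces such values exactly.

Substrate-binding and transition-state-formation free energies follow
ΔG*(E−S) = −R·T·ln(1/K_M) = R·T·ln K_M and ΔG*(E−T) = −R·T·ln(k_cat/K_M),
with K_M in the assay's g·L⁻¹ setting the implicit standard state. For the
BsXyn10 inputs these formulas give 1.9 and −8.9 kJ·mol⁻¹; the values
published for this enzyme (6.0 and −18.2, and likewise ΔG* = 57.6) are not
reproducible from the printed k_cat and K_M under any evident unit
convention, so the package computes the formulas as written and treats
those three published numbers as unverifiable.

### Thermal inactivation

ln(A_t/A_0) = −k_d·t is fitted per temperature through the origin:
slope = Σ t·ln f / Σ t², the maximum-likelihood slope when f(0) = 1 is
exact by definition. A free-intercept variant is available as a diagnostic
for lag phases. Samples with residual fraction ≤ 0 (activity at or below
the assay floor, typical for late samples at 70–80 °C) cannot enter a log
fit; they are excluded, not clamped, and the exclusion count is reported on
the fit. Derived times are t½ = ln2/k_d and D = ln10/k_d, so
D/t½ = ln10/ln2 ≈ 3.3219 identically — asserted universally in the tests.

E_a,d comes from the same Arrhenius regression applied to the per-
temperature k_d panel (the unit of k_d shifts only the intercept).
Deactivation thermodynamics reuse the activation relations with E_a,d and
k_d; k_d is stored in its native min⁻¹ and converted to s⁻¹ only inside the
Eyring inversion. The non-covalent-bond estimate divides ΔH*_D by
5.4 kJ·mol⁻¹, the approximate energy to pull a –CH₂ moiety out of a
hydrophobic contact; it is a scale argument, not a structural measurement.

### XO profiling

DP distributions are percentages of total mass concentration (g·L⁻¹), the
quantity HPAEC calibration yields; a molar variant would weight short
oligomers up by 1/DP and is intentionally not the default. The
reducing-end series Σ_DP conc(DP)/DP counts one reducing end per oligomer
in monomer-equivalent units; the optional ×150.13/132.11 factor restates
anhydro-unit mass as free-xylose mass, matching how reducing-sugar assays
are calibrated. For pure depolymerization this series can only grow —
every cleavage creates a reducing end — which is the mass-balance audit
used on both synthetic and real courses.

## Physical constants and conventions

R = 8.314 J·mol⁻¹·K⁻¹, k_B = 1.38×10⁻²³ J·K⁻¹, h = 6.626×10⁻³⁴ J·s —
three-significant-figure values, deliberately not CODATA, so derived
energies round bit-stably to the 0.1 kJ·mol⁻¹ precision of the reference
tables. Celsius→Kelvin uses the integer offset 273 by default (the
convention of thermostability tables that list 40 °C as 313 K); 273.15 is
available via `RunConfig`/CLI flag. Rendered reports give energies in
kJ·mol⁻¹ to one decimal and half-lives/D-values in whole minutes; all
internal computation is double precision in J·mol⁻¹.

## Synthetic data

The generator emulates the three assay shapes with multiplicative
(CV-style) noise, x·(1+ε), ε ~ N(0, cv) — the error structure implied by
"± SD of triplicates" reporting where scatter scales with the signal.
Defaults are the characterized BsXyn10 conditions: K_M = 1.96 g·L⁻¹,
v_max = 58.6 µmol·min⁻¹·mg⁻¹, E_a = 39.8 kJ·mol⁻¹, E_a,d = 195.4 kJ·mol⁻¹
with the Arrhenius intercept anchored so k_d(313 K) = 2.0×10⁻⁴ min⁻¹,
noise CV 5%, eight substrate levels spanning 0.5–20 g·L⁻¹, and a
40–80 °C decay panel sampled at eight times spanning ~3 half-lives per
temperature (dense where decay is fast, as a bench protocol would place
aliquots). Decay fractions are clipped at 0 to emulate the assay floor;
the fitting stage excludes such points exactly as it would for real data.
All draws are deterministic under a seed.

The XO generator solves a consecutive first-order cascade
X_n → X_{n−1} + X_1 (X_2 → 2·X_1) exactly via `scipy.linalg.expm` on molar
concentrations, reporting masses with anhydro-unit weights (DP × 132.11),
so total mass is conserved to machine precision. Default rates rise with
DP (longer chains are cut faster), putting X3/X4 on top among oligomers at
24 h. A structural caveat: because every cascade step releases a monomer,
the scheme over-produces X1 relative to a true endo-attack pattern (which
excises mid-DP products directly from internal bonds and can leave X1 near
5%); the generated profiles are therefore shape fixtures for the profiling
code, not simulations of endo-xylanase regioselectivity. Likewise the
generator draws i.i.d. noise per point — it does not emulate within-batch
correlation, substrate heterogeneity, or enzyme loss during handling, so
passing recovery tests demonstrate estimator correctness under the stated
noise model, not robustness to structured experimental error.

## Numerical choices and edge cases

- A perfectly temperature-independent rate series short-circuits to
  E_a = 0 with r² = 1 rather than regressing on zero variance.
- Through-origin r² is defined against Σ(ln f)² (no mean-centering), the
  standard definition for regression without intercept.
- S = 0 points carry no information about (K_M, v_max) under the model and
  are dropped from the fit residuals.
- Estimated k_d must be positive; a non-decaying course is an error, not a
  negative half-life.
- Fit failures raise exceptions carrying the last iterate rather than
  returning silently bad parameters.

## Problem sizes

Recovery studies in the test suite use 200 simulated datasets for the
Michaelis–Menten median-error bound and 40–100 seeds for the decay-panel
bounds — enough for stable medians while keeping the full suite in a few
seconds of CPU.

## Known limitations

Single-phase first-order inactivation only: biphasic decays and reversible
(Lumry–Eyring) unfolding are out of scope, as are substrate-inhibition and
Hill kinetics, molar K_M for polymeric substrates, and enthalpy–entropy
compensation analysis. The published ΔG*, ΔG*(E−S) and ΔG*(E−T) for the
reference enzyme are not reproducible from its printed k_cat and K_M (see
above) and are therefore not targets anywhere in the package.
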