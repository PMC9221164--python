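# enzytherm

Kinetic and thermodynamic characterization of enzymes from plain CSV assay
data, built around the workflow used to characterize thermotolerant
glycoside hydrolases — in particular the *Bacillus safensis* GH10
endo-xylanase (BsXyn10) acting on oat spelt xylan. It is aimed at enzyme
biochemists who have initial-rate, temperature-activity, and thermal-decay
measurements and want the standard derived constants, with a synthetic-data
generator that makes every stage testable against known ground truth.

## What it computes

**Michaelis–Menten kinetics.** Initial rates v at substrate concentrations
S (g·L⁻¹ — xylan is polymeric, so molar units are avoided) are fitted by
nonlinear least squares to v = v_max·S/(K_M + S), with K_M and v_max kept
positive by a log-parameterization. Given the molecular mass M, the
turnover number is k_cat = v_max·M·10⁻³/60 (s⁻¹) and the catalytic
efficiency k_cat/K_M.

**Activation thermodynamics of catalysis.** An Arrhenius plot of ln v_max
against 1/T over the ascending limb of the temperature profile gives the
activation energy E_a = −slope·R. Transition-state theory then yields, at a
reference temperature T:

- ΔH\* = E_a − R·T
- ΔG\* = −R·T·ln(k·h/(k_B·T)) — the Eyring equation inverted for a rate
  constant k in s⁻¹
- ΔS\* = (ΔH\* − ΔG\*)/T
- Q10 = exp(10·E_a/(R·T²)), the rate increase per 10 K
- ΔG\*(E−S) = R·T·ln K_M and ΔG\*(E−T) = −R·T·ln(k_cat/K_M)

**Thermal-inactivation kinetics.** Residual activity decays first-order,
ln(A_t/A_0) = −k_d·t; k_d is fitted per temperature by a regression forced
through the origin (the model has no intercept). From k_d follow the
half-life t½ = ln2/k_d, the decimal-reduction time D = ln10/k_d, the
deactivation energy E_a,d from the Arrhenius plot of ln k_d vs 1/T, and the
deactivation thermodynamics ΔH\*_D, ΔG\*_D, ΔS\*_D (same relations as above
with k_d in place of k_cat). ΔH\*_D/5.4 kJ·mol⁻¹ estimates the average
number of non-covalent contacts disrupted on the way to the unfolding
transition state.

**Xylooligosaccharide profiling.** HPAEC time courses of X1–X6 (xylose to
xylohexaose, g·L⁻¹) are summarized as mass-percent DP distributions and a
reducing-end xylose-equivalent series for mass-balance auditing.

## Worked example

Simulate a thermal-decay panel (40–80 °C, 2% multiplicative noise) and run
the full thermostability analysis:

```sh
enzytherm simulate decay --seed 11 --noise-cv 0.02 --out demo
enzytherm inactivation demo/decay.csv
```

prints (first row shown):

```json
{
  "Ea_d_kJ_per_mol": 195.474543306099,
  "bonds_broken": 35.7,
  "rows": [
    {
      "D_min": 11527,
      "Ea_d_kJ_per_mol": 195.5,
      "T_K": 313.0,
      "dG_D_kJ_per_mol": 109.6,
      "dH_D_kJ_per_mol": 192.9,
      "dS_D_J_per_mol_K": 266.0,
      "half_life_min": 3470,
      "kd_per_min": 0.00019976336961383427
    }
  ]
}
```

The generator's ground truth is E_a,d = 195.4 kJ·mol⁻¹ with
k_d(313 K) = 2.0×10⁻⁴ min⁻¹: the fitted panel recovers it to 0.04%, and at
313 K the enzyme has a half-life of ~3470 min (~58 h) with a free energy of
inactivation of 109.6 kJ·mol⁻¹. `bonds_broken: 35.7` is the mean ΔH\*_D
divided by 5.4 kJ·mol⁻¹ per hydrophobic contact.

The packaged reference panel renders the published-style eight-column
stability table directly:

```sh
enzytherm report --style table5
```

```
T_K  kd_per_min  half_life_min  D_min  Ea_d_kJ_per_mol  dG_D_kJ_per_mol  dS_D_J_per_mol_K  dH_D_kJ_per_mol
313      0.0002           3466  11513            195.3            109.6             265.6            192.7
323      0.0022            315   1047            195.3            106.7             265.9            192.6
333       0.028             25     82            195.3            103.1             268.7            192.6
343        0.27              3      9            195.3             99.8             270.2            192.5
353        0.72              1      3            195.3             99.9               262            192.4
```

Kinetics work the same way from a CSV of initial rates:

```sh
enzytherm simulate mm --seed 11 --out demo
enzytherm fit-mm demo/mm.csv --mw 47890
```

```json
{
  "KM_g_per_L": 1.8385221077647995,
  "converged": true,
  "efficiency_L_per_s_g": 25.133594247699634,
  "kcat_per_s": 46.20866867198597,
  "n_points": 8,
  "sse": 9.213280456708265,
  "vmax_umol_min_mg": 57.893508463544755
}
```

— a 5%-noise draw from the BsXyn10 ground truth (K_M = 1.96 g·L⁻¹,
v_max = 58.6 µmol·min⁻¹·mg⁻¹) recovered to within 7% and 2% respectively;
with the 47.89 kDa molecular mass the turnover number lands near the
enzyme's ≈46.8 s⁻¹.

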