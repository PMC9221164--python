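"""Published characterization values for the *B. safensis* ATHUBA63 GH10
xylanase (BsXyn10) on oat spelt xylan.

These printed values serve as inputs and cross-checks for the pipeline:
the kinetic constants feed the thermodynamic calculations, and the
thermal-inactivation rate-constant panel is the worked example for the
deactivation analysis. Energies are stored in J·mol⁻¹.
"""

from __future__ import annotations

#: Michaelis constant on oat spelt xylan, g·L⁻¹ (60 °C, pH 7).
KM = 1.96

#: Maximal specific activity, µmol·min⁻¹·(mg protein)⁻¹.
VMAX = 58.6

#: Published turnover number, s⁻¹. Direct unit arithmetic from VMAX and
#: the molecular mass gives ≈ 46.8 s⁻¹; the published 49 s⁻¹ is ~5% higher
#: (conversion convention not stated) and is kept as reported metadata.
KCAT_REPORTED = 49.0

#: Calculated molecular mass of the enzyme, g·mol⁻¹ (47.89 kDa).
MOLECULAR_MASS = 47890.0

#: Activation energy of xylan hydrolysis from the Arrhenius plot, J·mol⁻¹.
EA = 39.8e3

#: Deactivation energy from the Arrhenius plot of ln kd vs 1/T, J·mol⁻¹.
EA_D = 195.4e3

#: Optimum reaction temperature, K (60 °C with the integer 273 offset).
T_OPT = 333.0

#: Thermal-inactivation rate constants kd (min⁻¹) by temperature (K),
#: 40–80 °C panel.
KD_PANEL: dict[float, float] = {
    313.0: 2.0e-4,
    323.0: 2.2e-3,
    333.0: 2.8e-2,
    343.0: 2.7e-1,
    353.0: 7.2e-1,
}

#: Substrate specificity, percent of the oat-spelt-xylan rate.
SUBSTRATE_RELATIVE_ACTIVITY: dict[str, float] = {
    "arabinoxylan": 222.8,
    "oat spelt xylan": 100.0,
    "birchwood xylan": 83.7,
    "beechwood xylan": 88.5,
    "arabinan": 0.5,
    "carboxymethyl cellulose": 0.0,
    "avicel": 0.0,
}

#: Approximate XO mass distribution after 24 h of oat spelt xylan
#: hydrolysis, percent per DP (X1..X6); sums to ~99 as published.
XO_PERCENT_24H: dict[str, float] = {
    "X1": 5.0,
    "X2": 18.0,
    "X3": 32.0,
    "X4": 29.0,
    "X5": 12.0,
    "X6": 3.0,
}
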