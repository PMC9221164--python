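"""First-order thermal-inactivation kinetics and deactivation thermodynamics.

Residual activity after heat exposure decays as At/A0 = exp(−kd·t); the
inactivation rate constant kd (min⁻¹) is the negative slope of ln(At/A0)
against time, a regression forced through the origin because the model has
no intercept (At = A0 at t = 0 by definition). From kd follow the half-life
t½ = ln2/kd and the decimal-reduction time D = ln10/kd.

Across a temperature panel, the Arrhenius plot of ln kd vs 1/T gives the
deactivation energy Ea_d, and per temperature the Eyring relation (with kd
converted to s⁻¹) gives ΔH*_D = Ea_d − R·T, ΔG*_D = −R·T·ln(kd·h/(kB·T))
and ΔS*_D = (ΔH*_D − ΔG*_D)/T.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .activation_thermo import ArrheniusFit, arrhenius_fit, gibbs_from_rate, RateTemperatureSeries
from .constants import NONCOVALENT_BOND_ENERGY, R

LN2 = math.log(2.0)
LN10 = math.log(10.0)


@dataclass
class DecayTimeCourse:
    """Residual-activity fractions At/A0 over incubation time at one
    temperature T (K). Times in minutes; fractions dimensionless, nominally
    in [0, 1] with a small tolerance for assay noise above 1."""

    T: float
    t: np.ndarray
    residual_fraction: np.ndarray

    def __post_init__(self):
        self.t = np.asarray(self.t, dtype=float)
        self.residual_fraction = np.asarray(self.residual_fraction, dtype=float)
        if self.t.shape != self.residual_fraction.shape or self.t.ndim != 1:
            raise ValueError("t and residual_fraction must be 1-D arrays of equal length")
        if not self.T > 0:
            raise ValueError("temperature must be positive (Kelvin)")
        if np.any(self.t < 0):
            raise ValueError("times must be non-negative")
        if np.any(self.residual_fraction > 1.15):
            raise ValueError("residual fractions far above 1 are not a decay course")


@dataclass
class InactivationFit:
    """Per-temperature inactivation parameters: kd (min⁻¹), half-life and
    D-value (min), r² of the through-origin log-linear fit, and the number
    of samples actually used (fully inactivated points, fraction ≤ 0, are
    excluded from the log fit)."""

    T: float
    kd: float
    half_life: float
    D_value: float
    r_squared: float
    n_points_used: int
    n_points_excluded: int = 0


@dataclass
class DeactivationRow:
    """Deactivation thermodynamics at one temperature (J·mol⁻¹, J·mol⁻¹·K⁻¹)."""

    T: float
    dH_D: float
    dG_D: float
    dS_D: float


@dataclass
class DeactivationThermo:
    """Temperature panel of deactivation thermodynamics plus the global
    Arrhenius deactivation energy and the bond-count estimate."""

    per_T: list[DeactivationRow]
    Ea_d: float
    bonds_broken: float


def fit_inactivation(course: DecayTimeCourse, through_origin: bool = True) -> InactivationFit:
    """Estimate kd from a residual-activity time course.

    The default regression of ln(At/A0) on t is anchored at the origin,
    slope = Σ t·ln f / Σ t², since the first-order model fixes f(0) = 1.
    ``through_origin=False`` frees the intercept (useful to diagnose lag
    phases), still reporting kd as minus the slope. Samples with
    residual_fraction ≤ 0 (activity below the assay floor) cannot enter a
    log fit; they are dropped and counted in ``n_points_excluded``.
    """
    usable = course.residual_fraction > 0
    n_excluded = int(np.sum(~usable))
    t = course.t[usable]
    f = course.residual_fraction[usable]
    informative = t > 0  # the t=0, f=1 anchor carries no slope information
    if int(np.sum(informative)) < (1 if through_origin else 2):
        raise ValueError("too few usable (t>0, fraction>0) samples to fit kd")

    y = np.log(f)
    if through_origin:
        slope = float(np.sum(t * y) / np.sum(t * t))
        resid = y - slope * t
        ss_tot = float(np.sum(y * y))
    else:
        slope, intercept = np.polyfit(t, y, 1)
        resid = y - (slope * t + intercept)
        ss_tot = float(np.sum((y - y.mean()) ** 2))
    kd = -float(slope)
    if not kd > 0:
        raise ValueError("estimated kd is non-positive; activity did not decay")
    r2 = 1.0 - float(np.sum(resid**2)) / ss_tot if ss_tot > 0 else 1.0
    return InactivationFit(
        T=course.T,
        kd=kd,
        half_life=half_life(kd),
        D_value=decimal_reduction(kd),
        r_squared=r2,
        n_points_used=int(t.size),
        n_points_excluded=n_excluded,
    )


def half_life(kd: float) -> float:
    """Time (min) to 50% residual activity: ln2/kd."""
    if not kd > 0:
        raise ValueError("kd must be positive")
    return LN2 / kd


def decimal_reduction(kd: float) -> float:
    """D-value (min): time to 10% residual activity, ln10/kd."""
    if not kd > 0:
        raise ValueError("kd must be positive")
    return LN10 / kd


def deactivation_energy(fits: list[InactivationFit]) -> ArrheniusFit:
    """Arrhenius deactivation energy from a panel of per-temperature kd.

    OLS of ln kd on 1/T over the panel; Ea_d = −slope·R. The unit of kd
    only moves the intercept.
    """
    if len(fits) < 2:
        raise ValueError("need kd at ≥ 2 temperatures")
    series = RateTemperatureSeries(
        T=np.array([f.T for f in fits]), rate=np.array([f.kd for f in fits])
    )
    return arrhenius_fit(series)


def deactivation_params(Ea_d: float, fit: InactivationFit) -> DeactivationRow:
    """Deactivation thermodynamics at one temperature.

    kd is stored in min⁻¹ (the assay's native unit) and converted to s⁻¹
    only inside the Eyring expression.
    """
    T = fit.T
    dH = Ea_d - R * T
    dG = gibbs_from_rate(fit.kd / 60.0, T)
    dS = (dH - dG) / T
    return DeactivationRow(T=T, dH_D=dH, dG_D=dG, dS_D=dS)


def bonds_broken(dH_D: float) -> float:
    """Average number of non-covalent interactions disrupted on the way to
    the unfolding transition state: ΔH*_D divided by ~5.4 kJ·mol⁻¹ per
    –CH₂ hydrophobic contact."""
    if dH_D < 0:
        raise ValueError("deactivation enthalpy must be non-negative")
    return dH_D / NONCOVALENT_BOND_ENERGY


def deactivation_table(fits: list[InactivationFit]) -> DeactivationThermo:
    """Full thermostability summary for a temperature panel: per-T rows of
    (ΔH*_D, ΔG*_D, ΔS*_D), the global Ea_d, and the bond-count estimate
    from the mean deactivation enthalpy."""
    ea = deactivation_energy(fits).Ea
    rows = [deactivation_params(ea, f) for f in sorted(fits, key=lambda f: f.T)]
    mean_dH = float(np.mean([r.dH_D for r in rows]))
    return DeactivationThermo(per_T=rows, Ea_d=ea, bonds_broken=bonds_broken(mean_dH))
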