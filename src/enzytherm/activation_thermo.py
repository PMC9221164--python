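"""Arrhenius analysis and transition-state (Eyring) thermodynamics.

An Arrhenius plot of ln(rate) against 1/T gives the activation energy Ea of
catalysis from the slope (Ea = −slope·R). Transition-state theory then
yields the activation enthalpy, free energy and entropy at a reference
temperature via the Eyring equation

    k = (kB·T/h) · exp(−ΔG*/(R·T)),

together with the temperature quotient Q10, the free energy of substrate
binding ΔG*(E−S) = −R·T·ln(1/KM) and the free energy of transition-state
formation ΔG*(E−T) = −R·T·ln(kcat/KM).

All rate constants entering the Eyring expression must be in s⁻¹; energies
are computed in J·mol⁻¹.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .constants import H, KB, R


@dataclass
class RateTemperatureSeries:
    """Rates (any consistent unit) observed at a set of temperatures (K)."""

    T: np.ndarray
    rate: np.ndarray

    def __post_init__(self):
        self.T = np.asarray(self.T, dtype=float)
        self.rate = np.asarray(self.rate, dtype=float)
        if self.T.shape != self.rate.shape or self.T.ndim != 1:
            raise ValueError("T and rate must be 1-D arrays of equal length")
        if np.any(self.T <= 0):
            raise ValueError("temperatures must be positive (Kelvin)")
        if np.any(self.rate <= 0):
            raise ValueError("rates must be positive for a log-linear fit")
        if len(np.unique(self.T)) < 2:
            raise ValueError("need at least 2 distinct temperatures")

    def restrict(self, t_max: float) -> "RateTemperatureSeries":
        """Keep only points with T ≤ t_max (the ascending limb of a
        temperature-activity profile; rates past the optimum reflect
        denaturation, not activation, and would bias Ea)."""
        keep = self.T <= t_max
        return RateTemperatureSeries(self.T[keep], self.rate[keep])


@dataclass
class ArrheniusFit:
    """Result of an Arrhenius regression: Ea (J·mol⁻¹), intercept ln A,
    and the coefficient of determination of the ln(rate) vs 1/T line."""

    Ea: float
    lnA: float
    r_squared: float


@dataclass
class ActivationThermo:
    """Transition-state parameters at a reference temperature T_ref (K).

    dH, dG in J·mol⁻¹; dS in J·mol⁻¹·K⁻¹. Satisfies dG = dH − T_ref·dS by
    construction. dG_ES (substrate binding) and dG_ET (transition-state
    formation) are present when KM / kcat were supplied.
    """

    T_ref: float
    dH: float
    dG: float
    dS: float
    Q10: float
    dG_ES: float | None = None
    dG_ET: float | None = None


def arrhenius_fit(series: RateTemperatureSeries) -> ArrheniusFit:
    """Ordinary least squares of ln(rate) on 1/T; Ea = −slope·R.

    With exactly two points the fit is the closed-form secant and r² = 1.
    The unit of the rate only shifts the intercept, never the slope.
    """
    x = 1.0 / series.T
    y = np.log(series.rate)
    if np.allclose(y, y[0]):
        # perfectly temperature-independent rate
        return ArrheniusFit(Ea=0.0, lnA=float(y[0]), r_squared=1.0)
    res = stats.linregress(x, y)
    return ArrheniusFit(
        Ea=float(-res.slope * R),
        lnA=float(res.intercept),
        r_squared=float(res.rvalue**2),
    )


def q10(Ea: float, T: float) -> float:
    """Temperature quotient: rate increase per 10 K rise at temperature T.

    Computed as exp(10·Ea/(R·T²)), the differential form of the Arrhenius
    law: d ln k/dT = Ea/(R·T²), integrated over a 10 K interval at T.
    Equals 1 exactly when Ea = 0.
    """
    if not (math.isfinite(Ea) and math.isfinite(T)) or T <= 0:
        raise ValueError("Ea and T must be finite with T > 0")
    return math.exp(10.0 * Ea / (R * T * T))


def gibbs_from_rate(k_rate: float, T: float) -> float:
    """Free energy of activation (J·mol⁻¹) from a first-order rate constant.

    Inverts the Eyring equation: ΔG* = −R·T·ln(k·h/(kB·T)). ``k_rate``
    must be in s⁻¹ (divide a per-minute constant by 60 first).
    """
    if not k_rate > 0:
        raise ValueError("rate constant must be positive")
    if not T > 0:
        raise ValueError("temperature must be positive")
    return -R * T * math.log(k_rate * H / (KB * T))


def rate_from_gibbs(dG: float, T: float) -> float:
    """Eyring forward direction: k = (kB·T/h)·exp(−ΔG*/(R·T)), in s⁻¹."""
    return KB * T / H * math.exp(-dG / (R * T))


def binding_free_energy(KM: float, T: float) -> float:
    """Free energy of substrate binding, −R·T·ln(Ka) with Ka = 1/KM.

    Simplifies to R·T·ln(KM); KM in the assay's concentration unit sets
    the (implicit) standard state.
    """
    if not KM > 0:
        raise ValueError("KM must be positive")
    return R * T * math.log(KM)


def transition_free_energy(kcat: float, KM: float, T: float) -> float:
    """Free energy of transition-state formation, −R·T·ln(kcat/KM)."""
    if not (kcat > 0 and KM > 0):
        raise ValueError("kcat and KM must be positive")
    return -R * T * math.log(kcat / KM)


def activation_params(
    Ea: float,
    k_rate: float,
    T: float,
    KM: float | None = None,
    kcat: float | None = None,
) -> ActivationThermo:
    """Assemble the full transition-state parameter set at temperature T.

    dH = Ea − R·T; dG from the Eyring inversion of ``k_rate`` (s⁻¹);
    dS = (dH − dG)/T, so the Gibbs identity dG = dH − T·dS holds exactly.
    When KM (g·L⁻¹) and kcat (s⁻¹) are given, the binding and
    transition-state formation free energies are included.
    """
    dH = Ea - R * T
    dG = gibbs_from_rate(k_rate, T)
    dS = (dH - dG) / T
    return ActivationThermo(
        T_ref=T,
        dH=dH,
        dG=dG,
        dS=dS,
        Q10=q10(Ea, T),
        dG_ES=binding_free_energy(KM, T) if KM is not None else None,
        dG_ET=(
            transition_free_energy(kcat, KM, T)
            if (KM is not None and kcat is not None)
            else None
        ),
    )
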