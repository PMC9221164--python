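"""Michaelis–Menten kinetics: nonlinear initial-rate fitting and derived
catalytic constants.

Substrate concentrations are in g·L⁻¹ (the natural unit for a polymeric
substrate such as xylan, where a molar concentration is ill-defined) and
rates are specific activities in µmol·min⁻¹·(mg protein)⁻¹.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares


class FitError(RuntimeError):
    """Raised when a kinetic fit cannot be performed or did not converge."""

    def __init__(self, message: str, last_iterate: tuple | None = None):
        super().__init__(message)
        self.last_iterate = last_iterate


@dataclass(frozen=True)
class EnzymeInfo:
    """Identity and molecular mass of the enzyme under study.

    molecular_mass is in g·mol⁻¹ (Da); required to convert a specific
    activity into a turnover number.
    """

    molecular_mass: float
    name: str = ""

    def __post_init__(self):
        if not self.molecular_mass > 0:
            raise ValueError("molecular_mass must be positive")


@dataclass
class MMDataset:
    """Initial-rate data: substrate concentration S (g·L⁻¹) vs specific
    activity v (µmol·min⁻¹·mg⁻¹), measured at one temperature and pH.
    """

    S: np.ndarray
    v: np.ndarray
    temperature: float | None = None  # K
    pH: float | None = None

    def __post_init__(self):
        self.S = np.asarray(self.S, dtype=float)
        self.v = np.asarray(self.v, dtype=float)
        if self.S.shape != self.v.shape or self.S.ndim != 1:
            raise ValueError("S and v must be 1-D arrays of equal length")
        if np.any(self.S < 0):
            raise ValueError("substrate concentrations must be non-negative")
        if np.any(self.v < 0):
            raise ValueError("rates must be non-negative")

    @property
    def n_distinct_S(self) -> int:
        return len(np.unique(self.S))


@dataclass
class MMFit:
    """Michaelis–Menten fit result.

    KM is in g·L⁻¹, vmax in µmol·min⁻¹·mg⁻¹; kcat (s⁻¹) and catalytic
    efficiency kcat/KM (L·s⁻¹·g⁻¹) are populated only when a molecular
    mass was available.
    """

    KM: float
    vmax: float
    sse: float
    converged: bool
    kcat: float | None = None
    efficiency: float | None = None
    n_points: int = 0

    def with_enzyme(self, enzyme: EnzymeInfo) -> "MMFit":
        """Return a copy with kcat and kcat/KM derived from ``enzyme``."""
        kcat = turnover_number(self.vmax, enzyme)
        return MMFit(
            KM=self.KM,
            vmax=self.vmax,
            sse=self.sse,
            converged=self.converged,
            kcat=kcat,
            efficiency=kcat / self.KM,
            n_points=self.n_points,
        )


def michaelis_menten(S, vmax, KM):
    """The rectangular hyperbola v = vmax·S/(KM + S)."""
    S = np.asarray(S, dtype=float)
    return vmax * S / (KM + S)


def _initial_guess(S: np.ndarray, v: np.ndarray) -> tuple[float, float]:
    # vmax0 slightly above the largest observed rate; KM0 from the substrate
    # level at half of vmax0, linearly interpolated on the sorted curve.
    vmax0 = 1.1 * float(np.max(v))
    order = np.argsort(S)
    Ss, vs = S[order], v[order]
    half = vmax0 / 2.0
    if np.all(np.diff(vs) > 0):
        km0 = float(np.interp(half, vs, Ss))
    else:  # noisy, non-monotone curve: substrate level nearest half-saturation
        km0 = float(Ss[np.argmin(np.abs(vs - half))])
    if km0 <= 0:
        km0 = float(np.median(Ss[Ss > 0])) if np.any(Ss > 0) else 1.0
    return vmax0, km0


def fit_michaelis_menten(
    data: MMDataset,
    enzyme: EnzymeInfo | None = None,
    weighted: bool = False,
) -> MMFit:
    """Least-squares fit of the Michaelis–Menten model to initial-rate data.

    Minimizes Σ(vᵢ − vmax·Sᵢ/(KM+Sᵢ))² over (KM, vmax), both constrained
    positive through a log-parameterization. Replicate points at the same S
    enter as separate residuals. With ``weighted=True`` residuals are scaled
    by 1/v (relative-error weighting); the default is unweighted.

    Parameters
    ----------
    data : MMDataset
        At least 4 distinct substrate levels with non-constant rates.
    enzyme : EnzymeInfo, optional
        When given, kcat and kcat/KM are populated on the returned fit.

    Raises
    ------
    FitError
        For degenerate data (too few levels, constant rates) or a
        non-converged optimizer; the exception carries the last iterate.
    """
    if data.n_distinct_S < 4:
        raise FitError(
            f"need at least 4 distinct substrate levels, got {data.n_distinct_S}"
        )
    if np.allclose(data.v, data.v[0]):
        raise FitError("rates are constant across substrate levels; KM is unidentifiable")

    mask = data.S > 0
    S, v = data.S[mask], data.v[mask]
    if weighted:
        pos = v > 0
        S, v = S[pos], v[pos]

    vmax0, km0 = _initial_guess(S, v)

    def residuals(theta):
        vmax, km = np.exp(theta)
        r = v - michaelis_menten(S, vmax, km)
        return r / v if weighted else r

    sol = least_squares(residuals, x0=np.log([vmax0, km0]), method="lm")
    vmax_hat, km_hat = np.exp(sol.x)
    if not sol.success:
        raise FitError(
            f"Michaelis-Menten fit did not converge: {sol.message}",
            last_iterate=(km_hat, vmax_hat),
        )
    sse = float(np.sum((v - michaelis_menten(S, vmax_hat, km_hat)) ** 2))
    fit = MMFit(
        KM=float(km_hat),
        vmax=float(vmax_hat),
        sse=sse,
        converged=True,
        n_points=int(S.size),
    )
    return fit.with_enzyme(enzyme) if enzyme is not None else fit


def turnover_number(vmax: float, enzyme: EnzymeInfo) -> float:
    """Turnover number kcat (s⁻¹) from a specific activity and molecular mass.

    vmax in µmol·min⁻¹·mg⁻¹ equals 10⁻³ mol·min⁻¹·g⁻¹; multiplying by the
    molecular mass (g·mol⁻¹) gives catalytic events per enzyme per minute,
    and dividing by 60 per second:

        kcat = vmax × M × 10⁻³ / 60
    """
    if not vmax > 0:
        raise ValueError("vmax must be positive")
    return vmax * 1e-3 * enzyme.molecular_mass / 60.0


def relative_activity(
    rates: dict[str, float], reference_label: str
) -> dict[str, float]:
    """Express activities as percent of a reference condition.

    The reference maps to exactly 100; every other label to
    100 × activity / reference.
    """
    if reference_label not in rates:
        raise KeyError(f"reference label {reference_label!r} not in rates")
    ref = rates[reference_label]
    if not ref > 0:
        raise ValueError("reference activity must be positive")
    return {label: 100.0 * a / ref for label, a in rates.items()}
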