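"""CSV schemas, run configuration, and report rendering.

One flat CSV per assay type, header row mandatory, decimal point ``.``:

- ``mm.csv``      — ``substrate_g_per_L, rate_umol_min_mg`` (+ optional
  ``temperature_C, pH``)
- ``rates_vs_T.csv`` — ``temperature_C, rate, rate_unit`` with
  ``rate_unit`` one of ``per_s | per_min | umol_min_mg``
- ``decay.csv``   — ``temperature_C, time_min, residual_activity_pct``
  (percent of initial; several temperatures per file)
- ``xo.csv``      — ``time_h, X1..X6`` in g·L⁻¹

Reports render the activation-thermodynamics summary and the eight-column
thermostability table (T, kd, t½, D, Ea_d, ΔG*_D, ΔS*_D, ΔH*_D) at fixed
precision: energies in kJ·mol⁻¹ to one decimal, entropies to one decimal,
times rounded to whole minutes.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .constants import celsius_to_kelvin
from .hydrolysis_profile import DP_LABELS, XOTimeCourse
from .inactivation_thermo import DecayTimeCourse, DeactivationThermo, InactivationFit
from .activation_thermo import ActivationThermo, RateTemperatureSeries
from .mm_kinetics import MMDataset, MMFit

RATE_UNITS = ("per_s", "per_min", "umol_min_mg")


@dataclass
class RunConfig:
    """Pipeline-wide conventions."""

    kelvin_offset: float = 273.0
    rate_unit: str = "umol_min_mg"
    through_origin: bool = True
    energy_decimals: int = 1  # kJ·mol⁻¹ precision in rendered tables
    seed: int = 0

    def __post_init__(self):
        if self.kelvin_offset not in (273.0, 273.15):
            raise ValueError("kelvin_offset must be 273 or 273.15")
        if self.rate_unit not in RATE_UNITS:
            raise ValueError(f"rate_unit must be one of {RATE_UNITS}")


class SchemaError(ValueError):
    """A CSV file does not match its expected schema."""


def _read_csv(path, required: tuple[str, ...]) -> pd.DataFrame:
    try:
        df = pd.read_csv(path)
    except pd.errors.EmptyDataError:
        raise SchemaError(f"{path}: file is empty") from None
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required column(s) {', '.join(missing)}")
    for col in required:
        bad = pd.to_numeric(df[col], errors="coerce").isna() & df[col].notna()
        if bad.any():
            line = int(bad.idxmax()) + 2  # 1-based, plus header row
            raise SchemaError(f"{path}: non-numeric value in {col!r} at line {line}")
        df[col] = pd.to_numeric(df[col])
    if df.empty:
        raise SchemaError(f"{path}: no data rows")
    return df


def read_mm_csv(path) -> MMDataset:
    df = _read_csv(path, ("substrate_g_per_L", "rate_umol_min_mg"))
    temp = ph = None
    if "temperature_C" in df.columns:
        temp = celsius_to_kelvin(float(df["temperature_C"].iloc[0]))
    if "pH" in df.columns:
        ph = float(df["pH"].iloc[0])
    return MMDataset(
        S=df["substrate_g_per_L"].to_numpy(),
        v=df["rate_umol_min_mg"].to_numpy(),
        temperature=temp,
        pH=ph,
    )


def read_rates_csv(path, kelvin_offset: float = 273.0) -> RateTemperatureSeries:
    df = _read_csv(path, ("temperature_C", "rate"))
    if "rate_unit" in df.columns:
        units = set(df["rate_unit"].astype(str))
        bad = units - set(RATE_UNITS)
        if bad:
            raise SchemaError(f"{path}: unknown rate_unit value(s) {sorted(bad)}")
        if len(units) > 1:
            raise SchemaError(f"{path}: mixed rate units within one series")
    T = np.array([celsius_to_kelvin(tc, kelvin_offset) for tc in df["temperature_C"]])
    return RateTemperatureSeries(T=T, rate=df["rate"].to_numpy())


def read_decay_csv(path, kelvin_offset: float = 273.0) -> list[DecayTimeCourse]:
    """One decay course per distinct temperature, fractions from percent.

    Percent values slightly above 100 (assay noise) are accepted; values
    above 115 are rejected by the course invariant.
    """
    df = _read_csv(path, ("temperature_C", "time_min", "residual_activity_pct"))
    courses = []
    for tc, grp in df.groupby("temperature_C", sort=True):
        courses.append(
            DecayTimeCourse(
                T=celsius_to_kelvin(float(tc), kelvin_offset),
                t=grp["time_min"].to_numpy(),
                residual_fraction=grp["residual_activity_pct"].to_numpy() / 100.0,
            )
        )
    return courses


def read_xo_csv(path) -> XOTimeCourse:
    df = _read_csv(path, ("time_h",) + DP_LABELS)
    return XOTimeCourse(
        times=df["time_h"].to_numpy(), conc=df[list(DP_LABELS)].to_numpy()
    )


# ---------------------------------------------------------------------------
# writers (inverse of the readers; used by the simulator)

def write_mm_csv(data: MMDataset, path) -> None:
    df = pd.DataFrame(
        {"substrate_g_per_L": data.S, "rate_umol_min_mg": data.v}
    )
    if data.temperature is not None:
        df["temperature_C"] = data.temperature - 273.0
    if data.pH is not None:
        df["pH"] = data.pH
    df.to_csv(path, index=False)


def write_decay_csv(panel: list[DecayTimeCourse], path, kelvin_offset: float = 273.0) -> None:
    frames = [
        pd.DataFrame(
            {
                "temperature_C": c.T - kelvin_offset,
                "time_min": c.t,
                "residual_activity_pct": 100.0 * c.residual_fraction,
            }
        )
        for c in panel
    ]
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def write_xo_csv(course: XOTimeCourse, path) -> None:
    df = pd.DataFrame(course.conc, columns=list(DP_LABELS))
    df.insert(0, "time_h", course.times)
    df.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# reports

def mm_fit_to_dict(fit: MMFit) -> dict:
    return {
        "KM_g_per_L": fit.KM,
        "vmax_umol_min_mg": fit.vmax,
        "kcat_per_s": fit.kcat,
        "efficiency_L_per_s_g": fit.efficiency,
        "sse": fit.sse,
        "n_points": fit.n_points,
        "converged": fit.converged,
    }


def activation_to_dict(thermo: ActivationThermo) -> dict:
    d = {
        "T_K": thermo.T_ref,
        "Q10": round(thermo.Q10, 1),
        "dH_kJ_per_mol": round(thermo.dH / 1e3, 1),
        "dG_kJ_per_mol": round(thermo.dG / 1e3, 1),
        "dS_J_per_mol_K": round(thermo.dS, 1),
    }
    if thermo.dG_ES is not None:
        d["dG_ES_kJ_per_mol"] = round(thermo.dG_ES / 1e3, 1)
    if thermo.dG_ET is not None:
        d["dG_ET_kJ_per_mol"] = round(thermo.dG_ET / 1e3, 1)
    return d


def stability_table(
    fits: list[InactivationFit], thermo: DeactivationThermo
) -> list[dict]:
    """Eight-column thermostability rows, one per temperature, at the
    table's reporting precision (whole minutes; 0.1 kJ·mol⁻¹)."""
    rows = []
    by_T = {r.T: r for r in thermo.per_T}
    for f in sorted(fits, key=lambda f: f.T):
        r = by_T[f.T]
        rows.append(
            {
                "T_K": f.T,
                "kd_per_min": f.kd,
                "half_life_min": round(f.half_life),
                "D_min": round(f.D_value),
                "Ea_d_kJ_per_mol": round(thermo.Ea_d / 1e3, 1),
                "dG_D_kJ_per_mol": round(r.dG_D / 1e3, 1),
                "dS_D_J_per_mol_K": round(r.dS_D, 1),
                "dH_D_kJ_per_mol": round(r.dH_D / 1e3, 1),
            }
        )
    return rows


def render_report(results: dict | list, style: str = "json") -> str:
    """Deterministic, locale-independent rendering of a result payload.

    ``json`` emits canonical JSON (sorted keys, no locale formatting);
    ``table`` lays a list of row dicts out as aligned plain text.
    """
    if results is None or (hasattr(results, "__len__") and len(results) == 0):
        raise ValueError("empty results")
    if style == "json":
        return json.dumps(results, indent=2, sort_keys=True)
    if style == "table":
        rows = results if isinstance(results, list) else [results]
        cols = list(rows[0].keys())
        cells = [[_fmt(r[c]) for c in cols] for r in rows]
        widths = [max(len(c), *(len(row[i]) for row in cells)) for i, c in enumerate(cols)]
        lines = ["  ".join(c.rjust(w) for c, w in zip(cols, widths))]
        lines += ["  ".join(v.rjust(w) for v, w in zip(row, widths)) for row in cells]
        return "\n".join(lines)
    raise ValueError(f"unknown report style {style!r}")


def _fmt(x) -> str:
    if isinstance(x, float):
        return f"{x:.6g}"
    return str(x)
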