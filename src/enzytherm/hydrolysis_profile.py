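"""Xylooligosaccharide (XO) product profiling.

An endo-xylanase releases xylose (X1) through xylohexaose (X6) from xylan;
HPAEC quantifies each degree of polymerization (DP) as a mass concentration
in g·L⁻¹ over the hydrolysis time course. This module summarizes such
courses: the DP distribution (percent of total XO mass at a chosen time)
and a reducing-end xylose-equivalent series used as a mass-balance audit.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

DP_LABELS = ("X1", "X2", "X3", "X4", "X5", "X6")

#: Mass ratio of free xylose (150.13 g·mol⁻¹) to an anhydroxylose unit
#: (132.11 g·mol⁻¹): the water gained on hydrolytic cleavage.
ANHYDRO_CORRECTION = 150.13 / 132.11


@dataclass
class XOTimeCourse:
    """Concentrations (g·L⁻¹) of X1–X6 at each sampling time (h).

    ``conc`` has shape (n_times, 6); column j holds the DP j+1 species.
    """

    times: np.ndarray
    conc: np.ndarray

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.conc = np.asarray(self.conc, dtype=float)
        if self.conc.ndim != 2 or self.conc.shape != (self.times.size, 6):
            raise ValueError("conc must have shape (n_times, 6) for X1..X6")
        if np.any(self.conc < 0):
            raise ValueError("concentrations must be non-negative")


@dataclass
class DPDistribution:
    """Percent of total XO mass per DP at one time; sums to 100."""

    time: float
    percent: dict[str, float]


def dp_distribution(course: XOTimeCourse, at_time: float) -> DPDistribution:
    """Mass-percent distribution over X1–X6 at a sampled time.

    Percentages are on mass concentration (matching HPAEC quantification);
    they sum to 100 by construction.
    """
    matches = np.flatnonzero(np.isclose(course.times, at_time))
    if matches.size == 0:
        raise ValueError(f"time {at_time} h not present in the course")
    row = course.conc[matches[0]]
    total = row.sum()
    if not total > 0:
        raise ValueError(f"no product mass at time {at_time} h")
    return DPDistribution(
        time=at_time,
        percent={lab: 100.0 * c / total for lab, c in zip(DP_LABELS, row)},
    )


def xylose_equivalents(
    course: XOTimeCourse, anhydro_correction: bool = False
) -> np.ndarray:
    """Reducing-end equivalents per time point, in monomer-equivalent g·L⁻¹.

    Each oligomer carries one reducing end, so the series is
    Σ_DP conc(DP)/DP — optionally scaled by 150/132 to express anhydro-unit
    mass as free-xylose mass, the convention of reducing-sugar assays.
    For a pure depolymerization (no sugar consumption) the series is
    monotone non-decreasing: every cleavage creates a reducing end.
    """
    dps = np.arange(1, 7, dtype=float)
    eq = course.conc @ (1.0 / dps)
    if anhydro_correction:
        eq = eq * ANHYDRO_CORRECTION
    return eq


def total_mass(course: XOTimeCourse) -> np.ndarray:
    """Total XO mass concentration per time point (g·L⁻¹); conserved by a
    depolymerization expressed in anhydro-unit masses."""
    return course.conc.sum(axis=1)
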