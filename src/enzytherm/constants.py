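"""Physical constants and temperature conversion.

Constants are pinned to three significant figures (the precision used
throughout the characterization literature this package reproduces) rather
than full CODATA values, so that derived thermodynamic quantities round
stably to the tabulated precision.
"""

from __future__ import annotations

#: Universal gas constant, J·mol⁻¹·K⁻¹.
R = 8.314

#: Boltzmann constant, J·K⁻¹.
KB = 1.38e-23

#: Planck constant, J·s.
H = 6.626e-34

#: Energy to disrupt one non-covalent (hydrophobic, –CH₂) interaction,
#: J·mol⁻¹; used to translate a deactivation enthalpy into an average
#: number of bonds broken en route to the unfolding transition state.
NONCOVALENT_BOND_ENERGY = 5400.0

#: Default Celsius→Kelvin offset. Integer 273 matches the convention of
#: thermostability tables that list 40 °C as 313 K; pass 273.15 for the
#: exact offset.
KELVIN_OFFSET = 273.0


def celsius_to_kelvin(temp_c: float, offset: float = KELVIN_OFFSET) -> float:
    """Convert °C to K. ``offset`` must be 273 or 273.15."""
    if offset not in (273.0, 273.15):
        raise ValueError(f"kelvin offset must be 273 or 273.15, got {offset!r}")
    return temp_c + offset
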