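"""Unit conversions shared across the fermentation modules.

Extracellular sugars and citrate are tracked in g/L, phosphate in mM,
fluxes in mmol gDW^-1 h^-1, biomass in gDW/L. All gram/mole conversions
are centralised here so threshold comparisons (e.g. the 5 mM glucose
switch) are consistent everywhere.
"""

from __future__ import annotations

# Anhydrous molar masses, g/mol.
MOLAR_MASS_G_PER_MOL: dict[str, float] = {
    "glucose": 180.16,
    "xylose": 150.13,
    "citrate": 192.12,
    "phosphate": 94.97,
}


def g_per_l_to_mm(conc_g_l: float, species: str) -> float:
    """Convert a g/L concentration to mM."""
    return conc_g_l / MOLAR_MASS_G_PER_MOL[species] * 1000.0


def mm_to_g_per_l(conc_mm: float, species: str) -> float:
    """Convert a mM concentration to g/L."""
    return conc_mm * MOLAR_MASS_G_PER_MOL[species] / 1000.0


def flux_to_g_per_l(flux_mmol_gdw_h: float, biomass_gdw_l: float,
                    dt_h: float, species: str) -> float:
    """Concentration change (g/L) from a specific flux over one Euler step."""
    return (flux_mmol_gdw_h * biomass_gdw_l * dt_h
            * MOLAR_MASS_G_PER_MOL[species] / 1000.0)
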