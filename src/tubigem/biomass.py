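"""Biomass objective construction from measured macromolecular composition.

The measured composition gives bulk fractions (g/gDW) of seven components:
DNA, protein, lipid, cell wall, RNA, ash and a soluble pool. A monomer
table splits each macromolecule into monomers with molar fractions and
residue masses (g/mmol); the biomass reaction coefficient of monomer *j*
in component *k* is::

    fraction_k * molfrac_jk / residue_mass_jk      [mmol gDW^-1]

(negative, i.e. consumed), producing one unit of dry-weight biomass.
Growth-associated ATP hydrolysis is added with a configurable coefficient.
Trace vitamins/cofactors are deliberately excluded: they do not contribute
measurably to dry weight.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .core import Reaction
from .formulas import element_count, molar_mass

__all__ = [
    "COMPONENTS", "BiomassComposition", "MonomerEntry", "MonomerTable",
    "composition_total", "build_biomass_reaction", "phosphorus_content",
    "FILAMENTOUS_COMPOSITION", "PELLETED_COMPOSITION",
    "read_composition_csv", "write_composition_csv",
]

COMPONENTS = ("DNA", "protein", "lipid", "cell_wall", "RNA", "ash", "pool")


@dataclass
class BiomassComposition:
    """Bulk macromolecule fractions in g/gDW with optional uncertainties."""

    fractions: dict[str, float]
    sd: dict[str, float] = field(default_factory=dict)
    morphology: str = "pelleted"

    def __post_init__(self) -> None:
        if self.morphology not in ("filamentous", "pelleted"):
            raise ValueError(f"unknown morphology {self.morphology!r}")
        negative = {k: v for k, v in self.fractions.items() if v < 0}
        if negative:
            raise ValueError(f"negative fractions: {negative}")
        total = sum(self.fractions.values())
        if total > 1.05:
            raise ValueError(f"fractions sum to {total:.4f} > 1.05 g/gDW")

    def scaled(self, alpha: float) -> "BiomassComposition":
        return BiomassComposition(
            fractions={k: alpha * v for k, v in self.fractions.items()},
            sd=dict(self.sd), morphology=self.morphology)


def composition_total(composition: BiomassComposition) -> float:
    """Arithmetic sum of the seven component fractions (g/gDW)."""
    missing = [c for c in COMPONENTS if c not in composition.fractions]
    if missing:
        raise ValueError(f"composition missing component(s): {missing}")
    return sum(composition.fractions[c] for c in COMPONENTS)


# Measured composition of A. tubingensis DJU120 (g/gDW). RNA, ash and pool
# are carried over from the reference A. niger biomass equation and have no
# measured uncertainty.
FILAMENTOUS_COMPOSITION = BiomassComposition(
    fractions={"DNA": 0.0022, "protein": 0.1279, "lipid": 0.20,
               "cell_wall": 0.43, "RNA": 0.00604, "ash": 0.0750,
               "pool": 0.1310},
    sd={"DNA": 0.0001, "protein": 0.0110, "lipid": 0.02, "cell_wall": 0.02},
    morphology="filamentous")

PELLETED_COMPOSITION = BiomassComposition(
    fractions={"DNA": 0.0028, "protein": 0.1424, "lipid": 0.11,
               "cell_wall": 0.48, "RNA": 0.00604, "ash": 0.0750,
               "pool": 0.1310},
    sd={"DNA": 0.0002, "protein": 0.017, "lipid": 0.01, "cell_wall": 0.03},
    morphology="pelleted")

#: printed totals (g/gDW) for the two measured columns
PRINTED_TOTALS = {"filamentous": 0.9685, "pelleted": 0.9481}


@dataclass
class MonomerEntry:
    metabolite_id: str
    mol_fraction: float
    residue_mass: float | None  # g/mmol
    formula: str | None = None

    def p_atoms(self) -> int:
        return element_count(self.formula, "P") if self.formula else 0


@dataclass
class MonomerTable:
    """Monomer splits per macromolecule component."""

    entries: dict[str, list[MonomerEntry]]

    def __post_init__(self) -> None:
        for component, rows in self.entries.items():
            total = sum(e.mol_fraction for e in rows)
            if abs(total - 1.0) > 1e-6:
                raise ValueError(
                    f"monomer molar fractions for {component!r} sum to "
                    f"{total:.6f}, expected 1")

    @classmethod
    def single_monomer(cls, mapping: dict[str, tuple[str, str]]) -> "MonomerTable":
        """One pseudo-monomer per component, residue mass from its formula.

        ``mapping``: component -> (metabolite_id, formula).
        """
        entries = {
            comp: [MonomerEntry(met_id, 1.0, molar_mass(formula) / 1000.0, formula)]
            for comp, (met_id, formula) in mapping.items()}
        return cls(entries=entries)


def build_biomass_reaction(composition: BiomassComposition,
                           monomers: MonomerTable,
                           reaction_id: str = "BIOMASS",
                           biomass_metabolite: str = "biomass_c",
                           gam_atp: float = 30.0,
                           atp_id: str = "atp_c", adp_id: str = "adp_c",
                           pi_id: str = "pi_c", h2o_id: str = "h2o_c",
                           ) -> Reaction:
    """Assemble the biomass pseudo-reaction from composition and monomers.

    ``gam_atp`` is the growth-associated maintenance coefficient
    (mmol ATP hydrolysed per gDW formed).
    """
    total = composition_total(composition)
    if not 0.9 <= total <= 1.05:
        raise ValueError(
            f"composition total {total:.4f} g/gDW outside [0.9, 1.05]; "
            "re-measure or rescale before building a biomass equation")
    stoich: dict[str, float] = {}
    for component in COMPONENTS:
        fraction = composition.fractions[component]
        if fraction == 0.0:
            continue
        if component not in monomers.entries:
            raise ValueError(f"monomer table lacks component {component!r}")
        for entry in monomers.entries[component]:
            if entry.residue_mass is None or entry.residue_mass <= 0:
                raise ValueError(
                    f"monomer {entry.metabolite_id!r} ({component}) has no "
                    "residue mass")
            coeff = fraction * entry.mol_fraction / entry.residue_mass
            stoich[entry.metabolite_id] = stoich.get(entry.metabolite_id, 0.0) - coeff
    if gam_atp:
        stoich[atp_id] = stoich.get(atp_id, 0.0) - gam_atp
        stoich[h2o_id] = stoich.get(h2o_id, 0.0) - gam_atp
        stoich[adp_id] = stoich.get(adp_id, 0.0) + gam_atp
        stoich[pi_id] = stoich.get(pi_id, 0.0) + gam_atp
    stoich[biomass_metabolite] = 1.0
    return Reaction(id=reaction_id, name="biomass synthesis",
                    stoichiometry=stoich, lower_bound=0.0, upper_bound=1000.0,
                    subsystem="biomass")


#: P atoms of the default currency metabolites (GAM turnover nets to zero)
_CURRENCY_P_ATOMS = {"atp_c": 3, "adp_c": 2, "pi_c": 1, "h2o_c": 0}


def phosphorus_content(reaction: Reaction, monomers: MonomerTable,
                       currency_p_atoms: dict[str, int] | None = None) -> float:
    """Net phosphorus drawn into biomass, mmol P per gDW.

    Signed sum of coefficient x P-atoms over the reaction's metabolites,
    negated, so the GAM currency cycle (ATP -> ADP + Pi) cancels exactly
    and only monomer incorporation remains. P counts come from the monomer
    table formulas; ``currency_p_atoms`` covers the GAM metabolites.
    """
    p_by_met: dict[str, int] = dict(currency_p_atoms or _CURRENCY_P_ATOMS)
    for rows in monomers.entries.values():
        for entry in rows:
            p_by_met[entry.metabolite_id] = entry.p_atoms()
    net = 0.0
    for met_id, coeff in reaction.stoichiometry.items():
        net -= coeff * p_by_met.get(met_id, 0)
    return net


def read_composition_csv(path: str | Path, morphology: str = "pelleted",
                         ) -> BiomassComposition:
    """Read a (component, fraction[, sd]) CSV."""
    df = pd.read_csv(path)
    fractions = dict(zip(df["component"], df["fraction"].astype(float)))
    sd = {}
    if "sd" in df.columns:
        sd = {c: float(s) for c, s in zip(df["component"], df["sd"])
              if pd.notna(s)}
    return BiomassComposition(fractions=fractions, sd=sd, morphology=morphology)


def write_composition_csv(composition: BiomassComposition, path: str | Path) -> None:
    rows = [{"component": c, "fraction": composition.fractions.get(c),
             "sd": composition.sd.get(c)} for c in COMPONENTS]
    pd.DataFrame(rows).to_csv(path, index=False)
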