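"""Model summary statistics in the style of published GSMM comparisons.

A reaction is counted in a compartment when any participant resides
there, so a transport reaction contributes to both of its endpoint
compartments ("reactions taking place in X + transport reactions").
Metabolites live in exactly one compartment, so compartment metabolite
counts sum to the total.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

from .core import COMPARTMENTS, MetabolicModel

__all__ = ["ModelStatistics", "model_statistics"]


@dataclass
class ModelStatistics:
    model_id: str
    total_reactions: int = 0
    total_metabolites: int = 0
    total_genes: int = 0
    #: reactions with >= 1 participant in the compartment (transport counted
    #: in every compartment it touches)
    reactions_by_compartment: dict[str, int] = field(default_factory=dict)
    metabolites_by_compartment: dict[str, int] = field(default_factory=dict)
    #: transporters keyed by sorted compartment pair, e.g. "c|m"
    transporters_by_pair: dict[str, int] = field(default_factory=dict)
    exchange_reactions: int = 0
    #: distinct maximal all-of (complex) gene sets across all GPRs
    enzyme_complexes: int = 0

    def to_dict(self) -> dict:
        return {
            "model_id": self.model_id,
            "total_reactions": self.total_reactions,
            "total_metabolites": self.total_metabolites,
            "total_genes": self.total_genes,
            "reactions_by_compartment": dict(self.reactions_by_compartment),
            "metabolites_by_compartment": dict(self.metabolites_by_compartment),
            "transporters_by_pair": dict(self.transporters_by_pair),
            "exchange_reactions": self.exchange_reactions,
            "enzyme_complexes": self.enzyme_complexes,
        }

    def to_json(self, indent: int = 2) -> str:
        return json.dumps(self.to_dict(), indent=indent)

    def to_table(self) -> str:
        """Aligned text table, one row per statistic."""
        rows: list[tuple[str, int]] = [
            ("Reactions, total", self.total_reactions),
        ]
        for comp, name in COMPARTMENTS.items():
            rows.append((f"Reactions in {name} (+ transport)",
                         self.reactions_by_compartment.get(comp, 0)))
        rows.append(("Exchange reactions", self.exchange_reactions))
        for pair, n in sorted(self.transporters_by_pair.items()):
            rows.append((f"Transporters {pair}", n))
        rows.append(("Metabolites, total", self.total_metabolites))
        for comp, name in COMPARTMENTS.items():
            rows.append((f"Metabolites in {name}",
                         self.metabolites_by_compartment.get(comp, 0)))
        rows.append(("Genes, total", self.total_genes))
        rows.append(("Enzyme complexes", self.enzyme_complexes))
        width = max(len(label) for label, _ in rows)
        return "\n".join(f"{label:<{width}}  {value:>6d}" for label, value in rows)


def model_statistics(model: MetabolicModel) -> ModelStatistics:
    """Compute the summary statistics of a model. Deterministic."""
    stats = ModelStatistics(model_id=model.id)
    stats.total_reactions = len(model.reactions)
    stats.total_metabolites = len(model.metabolites)
    stats.total_genes = len(model.genes)

    rxn_by_comp: dict[str, int] = {}
    transp: dict[str, int] = {}
    n_exchange = 0
    complexes: set[frozenset[str]] = set()
    for rxn in model.reactions:
        comps = model.reaction_compartments(rxn)
        for comp in comps:
            rxn_by_comp[comp] = rxn_by_comp.get(comp, 0) + 1
        if len(comps) >= 2:
            key = "|".join(sorted(comps))
            transp[key] = transp.get(key, 0) + 1
        if model.is_exchange(rxn):
            n_exchange += 1
        if rxn.gpr is not None:
            complexes |= rxn.gpr.complexes()
    stats.reactions_by_compartment = rxn_by_comp
    stats.transporters_by_pair = transp
    stats.exchange_reactions = n_exchange
    stats.enzyme_complexes = len(complexes)

    met_by_comp: dict[str, int] = {}
    for met in model.metabolites:
        met_by_comp[met.compartment] = met_by_comp.get(met.compartment, 0) + 1
    stats.metabolites_by_compartment = met_by_comp
    return stats
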