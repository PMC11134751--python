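"""Core containers for compartmentalised stoichiometric models.

The model representation is deliberately plain: frozen-ish dataclasses
holding metabolites, reactions (stoichiometry as metabolite-id -> signed
coefficient), a gene set, Boolean GPRs and an objective reaction.
Conversion to and from :class:`cobra.Model` lives in :mod:`tubigem.io`;
everything numerical (LP) is delegated there.
"""

from __future__ import annotations

import copy as _copy
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np

from .gpr import GprExpression

#: canonical compartment ids -> names; four compartments: extracellular,
#: cytosol, mitochondria, peroxisome.
COMPARTMENTS: dict[str, str] = {
    "e": "extracellular",
    "c": "cytosol",
    "m": "mitochondria",
    "x": "peroxisome",
}


class ModelValidationError(ValueError):
    """Raised when a model violates a structural invariant."""


@dataclass
class Metabolite:
    id: str
    name: str = ""
    compartment: str = "c"
    formula: str | None = None
    charge: int | None = None

    def __post_init__(self) -> None:
        if self.compartment not in COMPARTMENTS:
            raise ModelValidationError(
                f"metabolite {self.id!r}: unknown compartment "
                f"{self.compartment!r} (expected one of {sorted(COMPARTMENTS)})")


@dataclass
class Reaction:
    id: str
    stoichiometry: dict[str, float]
    name: str = ""
    lower_bound: float = 0.0
    upper_bound: float = 1000.0
    subsystem: str = ""
    gpr: GprExpression | None = None

    def __post_init__(self) -> None:
        if not self.stoichiometry:
            raise ModelValidationError(f"reaction {self.id!r}: empty stoichiometry")
        if self.lower_bound > self.upper_bound:
            raise ModelValidationError(
                f"reaction {self.id!r}: lower bound {self.lower_bound} exceeds "
                f"upper bound {self.upper_bound}")

    @property
    def reversible(self) -> bool:
        return self.lower_bound < 0 < self.upper_bound

    @property
    def reactants(self) -> dict[str, float]:
        return {m: -c for m, c in self.stoichiometry.items() if c < 0}

    @property
    def products(self) -> dict[str, float]:
        return {m: c for m, c in self.stoichiometry.items() if c > 0}


@dataclass
class MetabolicModel:
    """A compartmentalised stoichiometric network with bounds and GPRs."""

    id: str = "model"
    metabolites: list[Metabolite] = field(default_factory=list)
    reactions: list[Reaction] = field(default_factory=list)
    genes: set[str] = field(default_factory=set)
    objective: str | None = None

    def __post_init__(self) -> None:
        self.validate()

    # -- lookups ---------------------------------------------------------
    def metabolite(self, met_id: str) -> Metabolite:
        try:
            return self._met_index[met_id]
        except KeyError:
            raise KeyError(f"no metabolite {met_id!r} in model {self.id!r}") from None

    def reaction(self, rxn_id: str) -> Reaction:
        try:
            return self._rxn_index[rxn_id]
        except KeyError:
            raise KeyError(f"no reaction {rxn_id!r} in model {self.id!r}") from None

    @property
    def metabolite_ids(self) -> list[str]:
        return [m.id for m in self.metabolites]

    @property
    def reaction_ids(self) -> list[str]:
        return [r.id for r in self.reactions]

    @property
    def compartments(self) -> set[str]:
        return {m.compartment for m in self.metabolites}

    # -- structural queries ---------------------------------------------
    def reaction_compartments(self, rxn: Reaction) -> set[str]:
        return {self.metabolite(m).compartment for m in rxn.stoichiometry}

    def is_exchange(self, rxn: Reaction) -> bool:
        """Boundary pseudo-reaction: a single extracellular metabolite."""
        if len(rxn.stoichiometry) != 1:
            return False
        met_id = next(iter(rxn.stoichiometry))
        return self.metabolite(met_id).compartment == "e"

    def is_boundary(self, rxn: Reaction) -> bool:
        """Single-metabolite boundary (exchange, demand or sink)."""
        return len(rxn.stoichiometry) == 1

    def is_transport(self, rxn: Reaction) -> bool:
        """True iff the participants span at least two compartments."""
        return len(self.reaction_compartments(rxn)) >= 2

    @property
    def exchange_ids(self) -> list[str]:
        return [r.id for r in self.reactions if self.is_exchange(r)]

    # -- mutation helpers ------------------------------------------------
    def add_reaction(self, rxn: Reaction) -> None:
        for met_id in rxn.stoichiometry:
            if met_id not in self._met_index:
                raise ModelValidationError(
                    f"reaction {rxn.id!r} references undeclared metabolite {met_id!r}")
        if rxn.id in self._rxn_index:
            raise ModelValidationError(f"duplicate reaction id {rxn.id!r}")
        if rxn.gpr is not None:
            self.genes |= set(rxn.gpr.genes())
        self.reactions.append(rxn)
        self._rxn_index[rxn.id] = rxn

    def remove_reactions(self, rxn_ids: Iterable[str]) -> None:
        drop = set(rxn_ids)
        missing = drop - set(self._rxn_index)
        if missing:
            raise KeyError(f"cannot remove unknown reactions: {sorted(missing)}")
        self.reactions = [r for r in self.reactions if r.id not in drop]
        self._rxn_index = {r.id: r for r in self.reactions}

    def remove_orphan_metabolites(self) -> list[str]:
        """Drop metabolites no longer referenced by any reaction."""
        used = {m for r in self.reactions for m in r.stoichiometry}
        orphans = [m.id for m in self.metabolites if m.id not in used]
        if orphans:
            self.metabolites = [m for m in self.metabolites if m.id in used]
            self._met_index = {m.id: m for m in self.metabolites}
        return orphans

    def copy(self) -> "MetabolicModel":
        return _copy.deepcopy(self)

    # -- numerics ---------------------------------------------------------
    def stoichiometric_matrix(self) -> np.ndarray:
        """Dense S matrix, metabolites x reactions, in declaration order."""
        met_pos = {m: i for i, m in enumerate(self.metabolite_ids)}
        S = np.zeros((len(self.metabolites), len(self.reactions)))
        for j, rxn in enumerate(self.reactions):
            for met_id, coeff in rxn.stoichiometry.items():
                S[met_pos[met_id], j] = coeff
        return S

    # -- validation --------------------------------------------------------
    def validate(self) -> None:
        met_ids = [m.id for m in self.metabolites]
        if len(met_ids) != len(set(met_ids)):
            dupes = sorted({i for i in met_ids if met_ids.count(i) > 1})
            raise ModelValidationError(f"duplicate metabolite ids: {dupes}")
        rxn_ids = [r.id for r in self.reactions]
        if len(rxn_ids) != len(set(rxn_ids)):
            dupes = sorted({i for i in rxn_ids if rxn_ids.count(i) > 1})
            raise ModelValidationError(f"duplicate reaction ids: {dupes}")
        self._met_index = {m.id: m for m in self.metabolites}
        self._rxn_index = {r.id: r for r in self.reactions}
        undeclared = sorted({
            met_id for r in self.reactions for met_id in r.stoichiometry
            if met_id not in self._met_index})
        if undeclared:
            raise ModelValidationError(
                f"reactions reference undeclared metabolites: {undeclared}")
        for r in self.reactions:
            if r.gpr is not None:
                self.genes |= set(r.gpr.genes())
        if self.objective is not None and self.objective not in self._rxn_index:
            raise ModelValidationError(
                f"objective {self.objective!r} does not resolve to a reaction")


@dataclass
class FluxSolution:
    """Outcome of one LP solve.

    ``status`` is one of ``optimal``, ``infeasible``, ``unbounded``;
    ``objective_value`` and ``fluxes`` are meaningful only when optimal.
    """

    status: str
    objective_value: float | None = None
    fluxes: Mapping[str, float] | None = None

    @property
    def optimal(self) -> bool:
        return self.status == "optimal"
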