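"""Model-QC procedures used during manual curation of a draft GSMM.

Covers dead-end metabolite detection and pruning, flagging of generic
(R-group) reactions, elemental balance checking, biomass-precursor
producibility and blocked-reaction detection. Pruning is purely
topological and conservative: the objective and exchange reactions are
never removed, and removal iterates to a fixed point.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .core import MetabolicModel
from .fba import InfeasibleModelError, apply_medium, optimize, to_cobra
from .formulas import FormulaError, is_generic_formula, parse_formula

__all__ = [
    "find_dead_ends", "prune_dead_ends", "DeadEndReport",
    "find_generic_reactions", "check_mass_balance", "BalanceReport",
    "precursor_producibility", "find_blocked_reactions",
    "PRODUCIBILITY_TOLERANCE",
]

#: flux above which a precursor counts as producible (LP noise floor),
#: mmol gDW^-1 h^-1
PRODUCIBILITY_TOLERANCE = 1e-6


def find_dead_ends(model: MetabolicModel) -> set[str]:
    """Metabolites that can only be produced or only consumed.

    A reversible reaction counts as both producer and consumer of every
    participant; single-metabolite boundary reactions (exchanges, demands)
    likewise count as both. A metabolite whose only reaction is a single
    internal reaction is also a dead end even when that reaction is
    reversible — one reversible connection offers no net sink.
    """
    produced: set[str] = set()
    consumed: set[str] = set()
    n_reactions: dict[str, int] = {}
    has_boundary: dict[str, bool] = {}
    for rxn in model.reactions:
        boundary = model.is_boundary(rxn)
        for met_id in rxn.stoichiometry:
            n_reactions[met_id] = n_reactions.get(met_id, 0) + 1
            has_boundary[met_id] = has_boundary.get(met_id, False) or boundary
    for rxn in model.reactions:
        boundary = model.is_boundary(rxn)
        for met_id, coeff in rxn.stoichiometry.items():
            forward_role = "produced" if coeff > 0 else "consumed"
            if boundary or rxn.reversible:
                produced.add(met_id)
                consumed.add(met_id)
            elif rxn.upper_bound > 0 and forward_role == "produced":
                produced.add(met_id)
            elif rxn.upper_bound > 0 and forward_role == "consumed":
                consumed.add(met_id)
            elif rxn.upper_bound <= 0 and rxn.lower_bound < 0:
                # reverse-only reaction: roles flip
                (consumed if forward_role == "produced" else produced).add(met_id)
    all_mets = set(model.metabolite_ids)
    referenced = {m for r in model.reactions for m in r.stoichiometry}
    single_connection = {m for m, n in n_reactions.items()
                         if n == 1 and not has_boundary[m]}
    # unreferenced metabolites are trivially dead
    return ((referenced - (produced & consumed)) | single_connection
            | (all_mets - referenced))


@dataclass
class DeadEndReport:
    dead_end_metabolites: set[str] = field(default_factory=set)
    removable_reactions: set[str] = field(default_factory=set)
    iterations: int = 0


def prune_dead_ends(model: MetabolicModel,
                    protected: set[str] | None = None,
                    ) -> tuple[MetabolicModel, DeadEndReport]:
    """Iteratively remove reactions that touch dead-end metabolites.

    Any reaction with a dead-end participant can carry no steady-state
    flux, so removal never changes the FBA optimum. The objective reaction
    and all exchanges are protected; if the objective itself touches a
    dead end the model is broken upstream and pruning refuses.

    The input model is not modified.
    """
    protected = set(protected or ())
    if model.objective is not None:
        protected.add(model.objective)
    protected |= {r.id for r in model.reactions if model.is_boundary(r)}

    pruned = model.copy()
    report = DeadEndReport()
    while True:
        dead = find_dead_ends(pruned)
        removable = [
            r.id for r in pruned.reactions
            if r.id not in protected and any(m in dead for m in r.stoichiometry)]
        if model.objective is not None:
            objective_rxn = pruned.reaction(model.objective)
            touched = sorted(m for m in objective_rxn.stoichiometry if m in dead)
            if touched:
                raise ValueError(
                    f"objective reaction {model.objective!r} touches dead-end "
                    f"metabolites {touched}; refusing to prune — gap-fill first")
        if not removable:
            break
        report.iterations += 1
        report.dead_end_metabolites |= dead
        report.removable_reactions |= set(removable)
        pruned.remove_reactions(removable)
        pruned.remove_orphan_metabolites()
    return pruned, report


def find_generic_reactions(model: MetabolicModel) -> set[str]:
    """Reactions touching a metabolite without an exact mass.

    Generic means: no formula at all, or a formula with an R-group/asterisk
    placeholder (e.g. the R-COOH pseudo fatty acids of draft models).
    """
    generic_mets = {m.id for m in model.metabolites if is_generic_formula(m.formula)}
    return {r.id for r in model.reactions
            if any(m in generic_mets for m in r.stoichiometry)}


@dataclass
class BalanceReport:
    """Per-reaction elemental imbalances; balanced reactions are omitted."""

    imbalances: dict[str, dict[str, float]] = field(default_factory=dict)
    skipped: dict[str, str] = field(default_factory=dict)
    n_balanced: int = 0

    @property
    def n_unbalanced(self) -> int:
        return len(self.imbalances)


def check_mass_balance(model: MetabolicModel, atol: float = 1e-9) -> BalanceReport:
    """Net elemental imbalance of every internal reaction.

    Boundary pseudo-reactions and the biomass/objective reaction are
    intentionally unbalanced and listed as skipped, as are reactions with
    unparseable or generic formulas.
    """
    report = BalanceReport()
    for rxn in model.reactions:
        if model.is_boundary(rxn):
            report.skipped[rxn.id] = "boundary reaction"
            continue
        if rxn.id == model.objective or "biomass" in rxn.id.lower():
            report.skipped[rxn.id] = "biomass/objective reaction"
            continue
        net: dict[str, float] = {}
        skip_reason = None
        for met_id, coeff in rxn.stoichiometry.items():
            formula = model.metabolite(met_id).formula
            try:
                counts = parse_formula(formula) if formula else None
            except FormulaError as exc:
                skip_reason = f"metabolite {met_id}: {exc}"
                break
            if counts is None:
                skip_reason = f"metabolite {met_id}: missing formula"
                break
            for el, n in counts.items():
                net[el] = net.get(el, 0.0) + coeff * n
        if skip_reason is not None:
            report.skipped[rxn.id] = skip_reason
            continue
        net = {el: v for el, v in net.items() if abs(v) > atol}
        if net:
            report.imbalances[rxn.id] = net
        else:
            report.n_balanced += 1
    return report


def precursor_producibility(model: MetabolicModel,
                            medium: dict[str, float] | set[str],
                            tolerance: float = PRODUCIBILITY_TOLERANCE,
                            ) -> dict[str, bool]:
    """Can each biomass substrate be synthesised on the given medium?

    For every metabolite consumed by the biomass (objective) reaction a
    temporary demand is opened and its maximal flux tested by FBA. The
    input model is untouched.
    """
    if model.objective is None:
        raise ValueError(f"model {model.id!r} has no biomass/objective reaction")
    biomass = model.reaction(model.objective)
    precursors = sorted(biomass.reactants)
    constrained = apply_medium(model, medium)
    cmodel = to_cobra(constrained)
    result: dict[str, bool] = {}
    for met_id in precursors:
        with cmodel:
            demand = cmodel.add_boundary(cmodel.metabolites.get_by_id(met_id),
                                         type="demand")
            cmodel.objective = demand
            flux = cmodel.slim_optimize(error_value=0.0)
        result[met_id] = bool(flux > tolerance)
    return result


def find_blocked_reactions(model: MetabolicModel,
                           medium: dict[str, float] | set[str] | None = None,
                           ) -> set[str]:
    """Reactions whose FVA flux range is {0} on the given medium."""
    from cobra.flux_analysis import find_blocked_reactions as _cobra_blocked

    import math

    constrained = apply_medium(model, medium) if medium is not None else model
    cmodel = to_cobra(constrained)
    if math.isnan(cmodel.slim_optimize(error_value=float("nan"))):
        raise InfeasibleModelError(
            f"model {model.id!r} is infeasible on the given medium "
            f"(LP status: infeasible)")
    return set(_cobra_blocked(cmodel))
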