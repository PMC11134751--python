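"""Flux balance analysis: LP optimisation, FVA, gene deletions and
Biolog-style growth phenotyping.

The LP itself — maximise c'v subject to S v = 0, lb <= v <= ub — is solved
through cobra/optlang (GLPK). Gene deletions use the package's own Boolean
GPR semantics: a reaction is disabled when its GPR evaluates false under
the reduced gene set.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .core import FluxSolution, MetabolicModel
from .formulas import element_count, is_generic_formula
from .gpr import GprExpression, evaluate_gpr
from .io import to_cobra

__all__ = [
    "optimize", "flux_variability", "evaluate_gpr", "single_gene_deletion",
    "growth_on_source", "phenotype_array", "PhenotypeComparison",
    "apply_medium", "carbon_exchanges", "NO_EXCHANGE",
    "DEFAULT_UPTAKE_RATE", "DEFAULT_GROWTH_THRESHOLD",
]

#: sentinel returned by growth_on_source when the model lacks an uptake route
NO_EXCHANGE = "no_exchange"

#: single-carbon-source uptake rate used for phenotype simulation,
#: mmol gDW^-1 h^-1
DEFAULT_UPTAKE_RATE = 10.0

#: predicted-growth threshold on the FBA optimum, h^-1
DEFAULT_GROWTH_THRESHOLD = 1e-3


class InfeasibleModelError(RuntimeError):
    """Raised when an operation requires a feasible base model."""


def optimize(model: MetabolicModel, objective: str | None = None,
             direction: str = "max") -> FluxSolution:
    """Solve the FBA linear program.

    Infeasibility/unboundedness is reported in ``FluxSolution.status``,
    never raised.
    """
    if direction not in ("max", "min"):
        raise ValueError(f"direction must be 'max' or 'min', got {direction!r}")
    cmodel = to_cobra(model)
    if objective is not None:
        model.reaction(objective)  # KeyError for unknown ids
        cmodel.objective = objective
    elif model.objective is None:
        raise ValueError("model has no objective and none was given")
    cmodel.objective_direction = direction
    solution = cmodel.optimize(raise_error=False)
    status = solution.status
    if status not in ("optimal", "infeasible", "unbounded"):
        # optlang reports e.g. "undefined" for GLPK unbounded duals
        status = "infeasible" if solution.objective_value is None else status
    if status != "optimal":
        return FluxSolution(status=status)
    return FluxSolution(status="optimal",
                        objective_value=float(solution.objective_value),
                        fluxes=dict(solution.fluxes))


def flux_variability(model: MetabolicModel, reactions: list[str] | None = None,
                     fraction_of_optimum: float = 1.0) -> dict[str, tuple[float, float]]:
    """Per-reaction flux minima/maxima at a fixed fraction of the optimum."""
    if not 0.0 <= fraction_of_optimum <= 1.0:
        raise ValueError("fraction_of_optimum must lie in [0, 1]")
    from cobra.flux_analysis import flux_variability_analysis

    import math

    cmodel = to_cobra(model)
    if math.isnan(cmodel.slim_optimize(error_value=float("nan"))):
        raise InfeasibleModelError(
            f"base model {model.id!r} is infeasible; FVA undefined")
    fva = flux_variability_analysis(
        cmodel, reaction_list=reactions,
        fraction_of_optimum=fraction_of_optimum)
    return {rid: (float(row["minimum"]), float(row["maximum"]))
            for rid, row in fva.iterrows()}


def _disabled_reactions(model: MetabolicModel, removed_genes: set[str]) -> list[str]:
    present = model.genes - removed_genes
    return [r.id for r in model.reactions
            if r.gpr is not None and not r.gpr.evaluate(present)]


def single_gene_deletion(model: MetabolicModel, gene: str) -> FluxSolution:
    """FBA after knocking out one gene via the GPR rules.

    Reactions whose GPR evaluates false without the gene get bounds (0, 0);
    the input model is left untouched.
    """
    if gene not in model.genes:
        raise KeyError(f"gene {gene!r} not in model {model.id!r}")
    knockout = model.copy()
    for rid in _disabled_reactions(model, {gene}):
        rxn = knockout.reaction(rid)
        rxn.lower_bound = 0.0
        rxn.upper_bound = 0.0
    return optimize(knockout)


def carbon_exchanges(model: MetabolicModel) -> list[str]:
    """Exchange reactions whose metabolite contains carbon."""
    out = []
    for rid in model.exchange_ids:
        met_id = next(iter(model.reaction(rid).stoichiometry))
        formula = model.metabolite(met_id).formula
        if formula is None or is_generic_formula(formula):
            continue
        if element_count(formula, "C") > 0:
            out.append(rid)
    return out


def apply_medium(model: MetabolicModel, medium: dict[str, float] | set[str],
                 default_uptake: float = DEFAULT_UPTAKE_RATE) -> MetabolicModel:
    """Return a copy with exchange uptake limited to the given medium.

    ``medium`` maps exchange ids to maximal uptake rates (a bare set uses
    ``default_uptake`` for every member). All other exchanges keep secretion
    but lose uptake.
    """
    if not isinstance(medium, dict):
        medium = {rid: default_uptake for rid in medium}
    unknown = set(medium) - set(model.reaction_ids)
    if unknown:
        raise KeyError(f"medium references unknown exchanges: {sorted(unknown)}")
    constrained = model.copy()
    for rid in constrained.exchange_ids:
        rxn = constrained.reaction(rid)
        rxn.lower_bound = -abs(medium[rid]) if rid in medium else max(rxn.lower_bound, 0.0)
    return constrained


def growth_on_source(model: MetabolicModel, source_exchange: str,
                     uptake_rate: float = DEFAULT_UPTAKE_RATE,
                     growth_threshold: float = DEFAULT_GROWTH_THRESHOLD):
    """Predict growth on a single carbon source.

    All carbon exchanges are closed, the given one is opened at
    ``uptake_rate``, and growth is called on the FBA optimum. Returns
    True/False, or the :data:`NO_EXCHANGE` sentinel when the model has no
    uptake route for the source.
    """
    if source_exchange not in set(model.reaction_ids):
        return NO_EXCHANGE
    constrained = model.copy()
    for rid in carbon_exchanges(constrained):
        rxn = constrained.reaction(rid)
        rxn.lower_bound = max(rxn.lower_bound, 0.0)
    src = constrained.reaction(source_exchange)
    src.lower_bound = -abs(uptake_rate)
    solution = optimize(constrained)
    if not solution.optimal:
        return False
    return solution.objective_value > growth_threshold


@dataclass
class PhenotypeComparison:
    """Observed vs predicted growth calls per carbon source."""

    records: pd.DataFrame = field(default_factory=pd.DataFrame)

    CATEGORIES = ("TP", "TN", "FP", "FN", "no_exchange")

    def summary(self) -> dict[str, int]:
        counts = {c: 0 for c in self.CATEGORIES}
        if not self.records.empty:
            for cat, n in self.records["category"].value_counts().items():
                counts[cat] = int(n)
        return counts

    @property
    def n_observed_positive(self) -> int:
        if self.records.empty:
            return 0
        return int(self.records["observed"].sum())

    @property
    def n_sources(self) -> int:
        return len(self.records)

    def to_dataframe(self) -> pd.DataFrame:
        return self.records.copy()


def _categorise(observed: bool, predicted) -> str:
    if predicted == NO_EXCHANGE:
        return "no_exchange"
    if observed and predicted:
        return "TP"
    if not observed and not predicted:
        return "TN"
    if observed and not predicted:
        return "FN"
    return "FP"


def phenotype_array(model: MetabolicModel, observations: dict[str, bool],
                    exchange_map: dict[str, str] | None = None,
                    uptake_rate: float = DEFAULT_UPTAKE_RATE,
                    growth_threshold: float = DEFAULT_GROWTH_THRESHOLD,
                    ) -> PhenotypeComparison:
    """Compare observed growth calls with single-source FBA predictions.

    ``exchange_map`` maps source names to exchange reaction ids; by default
    a source named ``src`` is looked up as ``EX_src_e``.
    """
    rows = []
    for source, observed in observations.items():
        exch = (exchange_map or {}).get(source, f"EX_{source}_e")
        predicted = growth_on_source(model, exch, uptake_rate, growth_threshold)
        rows.append({
            "source": source,
            "exchange": exch,
            "observed": bool(observed),
            "predicted": None if predicted == NO_EXCHANGE else bool(predicted),
            "category": _categorise(bool(observed), predicted),
        })
    df = pd.DataFrame(rows, columns=["source", "exchange", "observed",
                                     "predicted", "category"])
    return PhenotypeComparison(records=df)
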