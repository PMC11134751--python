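"""Model input/output: SBML (via cobra/libsbml) and a tabular dialect.

The tabular dialect mirrors the supplementary-workbook style of published
fungal genome-scale models: three tables (reactions, metabolites, genes)
either as CSV files in a directory or as sheets of one XLSX workbook.
Reaction equations are human-editable strings such as::

    glc__D[e] -> glc__D[c]
    2 nadh[m] + o2[m] + 4 adp[m] + 4 pi[m] <=> ...

with ``[e]/[c]/[m]/[x]`` compartment suffixes; internally metabolite ids
carry an underscore suffix (``glc__D_e``).
"""

from __future__ import annotations

import re
from pathlib import Path

import pandas as pd

from .core import COMPARTMENTS, MetabolicModel, Metabolite, ModelValidationError, Reaction
from .gpr import parse_gpr

__all__ = [
    "read_sbml", "write_sbml", "read_tabular_model", "write_tabular_model",
    "to_cobra", "from_cobra", "parse_reaction_equation", "format_reaction_equation",
]


class TabularParseError(ValueError):
    """Raised for malformed tabular model files; carries the row number."""


# ---------------------------------------------------------------------------
# cobra conversion
# ---------------------------------------------------------------------------

def to_cobra(model: MetabolicModel):
    """Convert to a :class:`cobra.Model` (used for LP solving and SBML I/O)."""
    import cobra

    cmodel = cobra.Model(model.id)
    mets = {}
    for met in model.metabolites:
        cm = cobra.Metabolite(
            met.id, name=met.name or met.id, compartment=met.compartment,
            formula=met.formula, charge=met.charge)
        mets[met.id] = cm
    cmodel.add_metabolites(list(mets.values()))
    crxns = []
    for rxn in model.reactions:
        cr = cobra.Reaction(rxn.id, name=rxn.name or rxn.id,
                            subsystem=rxn.subsystem,
                            lower_bound=rxn.lower_bound,
                            upper_bound=rxn.upper_bound)
        crxns.append(cr)
    cmodel.add_reactions(crxns)
    for rxn, cr in zip(model.reactions, crxns):
        cr.add_metabolites({mets[m]: c for m, c in rxn.stoichiometry.items()})
        if rxn.gpr is not None:
            cr.gene_reaction_rule = rxn.gpr.to_string()
    # genes that appear in no GPR still belong to the model's gene set
    orphan_genes = model.genes - {g.id for g in cmodel.genes}
    if orphan_genes:
        import cobra.core

        cmodel.genes += [cobra.core.Gene(g) for g in sorted(orphan_genes)]
    if model.objective is not None:
        cmodel.objective = model.objective
    return cmodel


def from_cobra(cmodel) -> MetabolicModel:
    """Convert a :class:`cobra.Model` into a :class:`MetabolicModel`."""
    from cobra.util.solver import linear_reaction_coefficients

    metabolites = []
    for cm in cmodel.metabolites:
        comp = cm.compartment if cm.compartment in COMPARTMENTS else None
        if comp is None:
            comp = _guess_compartment(cm.compartment)
        metabolites.append(Metabolite(
            id=cm.id, name=cm.name or cm.id, compartment=comp,
            formula=cm.formula or None, charge=cm.charge))
    reactions = []
    for cr in cmodel.reactions:
        rule = cr.gene_reaction_rule
        reactions.append(Reaction(
            id=cr.id, name=cr.name or cr.id, subsystem=cr.subsystem or "",
            stoichiometry={m.id: c for m, c in cr.metabolites.items()},
            lower_bound=cr.lower_bound, upper_bound=cr.upper_bound,
            gpr=parse_gpr(rule) if rule else None))
    objective = None
    coeffs = linear_reaction_coefficients(cmodel)
    if coeffs:
        objective = max(coeffs, key=lambda r: abs(coeffs[r])).id
    genes = {g.id for g in cmodel.genes}
    return MetabolicModel(id=cmodel.id or "model", metabolites=metabolites,
                          reactions=reactions, genes=genes, objective=objective)


_COMPARTMENT_ALIASES = {
    "extracellular": "e", "external": "e", "e0": "e",
    "cytosol": "c", "cytoplasm": "c", "c0": "c",
    "mitochondria": "m", "mitochondrion": "m",
    "peroxisome": "x", "peroxisomal": "x",
}


def _guess_compartment(raw: str | None) -> str:
    if raw is None:
        raise ModelValidationError("metabolite without compartment")
    key = raw.strip().lower()
    if key in COMPARTMENTS:
        return key
    if key in _COMPARTMENT_ALIASES:
        return _COMPARTMENT_ALIASES[key]
    raise ModelValidationError(f"cannot map compartment {raw!r} onto "
                               f"{sorted(COMPARTMENTS)}")


# ---------------------------------------------------------------------------
# SBML
# ---------------------------------------------------------------------------

def read_sbml(path: str | Path) -> MetabolicModel:
    """Read an SBML (Level 3 + fbc, or Level 2 with notes) model file."""
    import cobra.io

    path = Path(path)
    if not path.exists():
        raise IOError(f"SBML file not found: {path}")
    cmodel = cobra.io.read_sbml_model(str(path))
    return from_cobra(cmodel)


def write_sbml(model: MetabolicModel, path: str | Path) -> None:
    """Write the model as SBML Level 3 with the fbc package.

    Gene products are listed in sorted order so output is byte-stable
    across processes (cobra gathers genes via sets).
    """
    import cobra.io

    cmodel = to_cobra(model)
    cmodel.genes.sort(key=lambda g: g.id)
    cobra.io.write_sbml_model(cmodel, str(path))


# ---------------------------------------------------------------------------
# Reaction-equation strings
# ---------------------------------------------------------------------------

_ARROWS = ("<=>", "<->", "-->", "->")
_MET_TOKEN = re.compile(r"^(?P<name>.+)\[(?P<comp>[a-z])\]$")


def parse_reaction_equation(equation: str) -> tuple[dict[str, float], bool]:
    """Parse ``"2 a[c] + b[c] -> c[c]"`` into (stoichiometry, reversible).

    Metabolite tokens ``name[comp]`` map to internal ids ``name_comp``.
    """
    arrow = None
    for cand in _ARROWS:
        if cand in equation:
            arrow = cand
            break
    if arrow is None:
        raise TabularParseError(f"no reaction arrow in equation {equation!r}")
    reversible = arrow in ("<=>", "<->")
    left, right = equation.split(arrow, 1)
    stoich: dict[str, float] = {}

    def add_side(side: str, sign: float) -> None:
        side = side.strip()
        if not side:
            return
        for term in side.split("+"):
            term = term.strip()
            if not term:
                raise TabularParseError(f"empty term in equation {equation!r}")
            parts = term.split()
            if len(parts) == 1:
                coeff, token = 1.0, parts[0]
            elif len(parts) == 2:
                try:
                    coeff = float(parts[0])
                except ValueError:
                    raise TabularParseError(
                        f"bad coefficient {parts[0]!r} in {equation!r}") from None
                token = parts[1]
            else:
                raise TabularParseError(f"bad term {term!r} in {equation!r}")
            m = _MET_TOKEN.match(token)
            if not m:
                raise TabularParseError(
                    f"metabolite token {token!r} lacks a [compartment] suffix "
                    f"in {equation!r}")
            met_id = f"{m.group('name')}_{m.group('comp')}"
            stoich[met_id] = stoich.get(met_id, 0.0) + sign * coeff

    add_side(left, -1.0)
    add_side(right, +1.0)
    stoich = {m: c for m, c in stoich.items() if c != 0.0}
    if not stoich:
        raise TabularParseError(f"equation {equation!r} has empty stoichiometry")
    return stoich, reversible


def format_reaction_equation(rxn: Reaction, model: MetabolicModel) -> str:
    """Inverse of :func:`parse_reaction_equation` for a model's reaction."""

    def token(met_id: str) -> str:
        comp = model.metabolite(met_id).compartment
        base = met_id[:-len(comp) - 1] if met_id.endswith(f"_{comp}") else met_id
        return f"{base}[{comp}]"

    def side(items: dict[str, float]) -> str:
        parts = []
        for met_id, coeff in items.items():
            parts.append(token(met_id) if coeff == 1.0 else f"{coeff:g} {token(met_id)}")
        return " + ".join(parts)

    arrow = "<=>" if rxn.reversible else "->"
    return f"{side(rxn.reactants)} {arrow} {side(rxn.products)}".strip()


# ---------------------------------------------------------------------------
# Tabular model (CSV directory or XLSX workbook)
# ---------------------------------------------------------------------------

_TABLES = ("reactions", "metabolites", "genes")


def _load_tables(path: Path) -> dict[str, pd.DataFrame]:
    if path.is_dir():
        tables = {}
        for name in _TABLES:
            f = path / f"{name}.csv"
            if name != "genes" and not f.exists():
                raise IOError(f"missing table {f}")
            tables[name] = pd.read_csv(f) if f.exists() else pd.DataFrame(columns=["id"])
        return tables
    if path.suffix.lower() in (".xlsx", ".xls"):
        sheets = pd.read_excel(path, sheet_name=None)
        missing = [n for n in _TABLES[:2] if n not in sheets]
        if missing:
            raise IOError(f"workbook {path} lacks sheets: {missing}")
        sheets.setdefault("genes", pd.DataFrame(columns=["id"]))
        return {n: sheets[n] for n in _TABLES}
    raise IOError(f"tabular model path {path} is neither a directory nor a workbook")


def read_tabular_model(path: str | Path, model_id: str | None = None) -> MetabolicModel:
    """Read a model from ``reactions/metabolites/genes`` tables."""
    path = Path(path)
    tables = _load_tables(path)

    metabolites = []
    for _, row in tables["metabolites"].iterrows():
        formula = row.get("formula")
        if pd.isna(formula):
            formula = None
        charge = row.get("charge")
        charge = None if pd.isna(charge) else int(charge)
        metabolites.append(Metabolite(
            id=str(row["id"]), name=str(row.get("name", row["id"])),
            compartment=str(row["compartment"]), formula=formula, charge=charge))

    reactions = []
    objective = None
    for i, row in tables["reactions"].iterrows():
        rownum = i + 2  # header is row 1
        try:
            stoich, reversible = parse_reaction_equation(str(row["equation"]))
        except TabularParseError as exc:
            raise TabularParseError(f"reactions row {rownum}: {exc}") from None
        lb = float(row["lower_bound"]) if not pd.isna(row.get("lower_bound")) \
            else (-1000.0 if reversible else 0.0)
        ub = float(row["upper_bound"]) if not pd.isna(row.get("upper_bound")) else 1000.0
        gpr_text = row.get("gpr")
        gpr = None
        if isinstance(gpr_text, str) and gpr_text.strip():
            gpr = parse_gpr(gpr_text)
        subsystem = row.get("subsystem")
        subsystem = "" if pd.isna(subsystem) else str(subsystem)
        rxn = Reaction(id=str(row["id"]), name=str(row.get("name", row["id"])),
                       stoichiometry=stoich, lower_bound=lb, upper_bound=ub,
                       subsystem=subsystem, gpr=gpr)
        reactions.append(rxn)
        if bool(row.get("objective")) and str(row.get("objective")).lower() not in (
                "nan", "false", "0", ""):
            objective = rxn.id

    genes = {str(g) for g in tables["genes"].get("id", pd.Series(dtype=str)).dropna()}
    return MetabolicModel(id=model_id or path.stem or "model",
                          metabolites=metabolites, reactions=reactions,
                          genes=genes, objective=objective)


def write_tabular_model(model: MetabolicModel, path: str | Path) -> None:
    """Write the model as a directory of CSVs or a single XLSX workbook."""
    path = Path(path)
    rxn_df = pd.DataFrame([{
        "id": r.id, "name": r.name,
        "equation": format_reaction_equation(r, model),
        "lower_bound": r.lower_bound, "upper_bound": r.upper_bound,
        "subsystem": r.subsystem,
        "gpr": r.gpr.to_string() if r.gpr is not None else "",
        "objective": r.id == model.objective,
    } for r in model.reactions])
    met_df = pd.DataFrame([{
        "id": m.id, "name": m.name, "compartment": m.compartment,
        "formula": m.formula if m.formula is not None else "",
        "charge": m.charge,
    } for m in model.metabolites])
    gene_df = pd.DataFrame({"id": sorted(model.genes)})
    if path.suffix.lower() in (".xlsx", ".xls"):
        with pd.ExcelWriter(path) as writer:
            rxn_df.to_excel(writer, sheet_name="reactions", index=False)
            met_df.to_excel(writer, sheet_name="metabolites", index=False)
            gene_df.to_excel(writer, sheet_name="genes", index=False)
    else:
        path.mkdir(parents=True, exist_ok=True)
        rxn_df.to_csv(path / "reactions.csv", index=False)
        met_df.to_csv(path / "metabolites.csv", index=False)
        gene_df.to_csv(path / "genes.csv", index=False)
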