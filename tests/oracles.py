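"""Independent reference implementations used to cross-check the package.

Each oracle deliberately takes a different route from the code under test:
FBA via scipy's HiGHS simplex and via exhaustive vertex enumeration of the
flux polytope, GPR evaluation via Python ``eval`` of the boolean string,
dead-end pruning via remove-one-and-recheck.
"""

from __future__ import annotations

from itertools import combinations

import numpy as np
from scipy.linalg import null_space
from scipy.optimize import linprog


def scipy_fba(model, objective=None, direction="max"):
    """FBA optimum via scipy.optimize.linprog (HiGHS simplex)."""
    S = model.stoichiometric_matrix()
    n = len(model.reactions)
    lb = np.array([r.lower_bound for r in model.reactions])
    ub = np.array([r.upper_bound for r in model.reactions])
    c = np.zeros(n)
    obj = objective or model.objective
    c[model.reaction_ids.index(obj)] = -1.0 if direction == "max" else 1.0
    res = linprog(c, A_eq=S, b_eq=np.zeros(S.shape[0]),
                  bounds=list(zip(lb, ub)), method="highs")
    if res.status != 0:
        return None
    return -res.fun if direction == "max" else res.fun


def vertex_enumeration_fba(model, objective=None, tol=1e-9):
    """FBA optimum by exhaustively enumerating polytope vertices.

    Reduces S v = 0 to the null-space coordinates y (v = N y), then visits
    every choice of dim(y) active bound constraints. Only tractable for
    tiny networks.
    """
    S = model.stoichiometric_matrix()
    N = null_space(S)
    d = N.shape[1]
    lb = np.array([r.lower_bound for r in model.reactions])
    ub = np.array([r.upper_bound for r in model.reactions])
    # constraints: N y <= ub  and  -N y <= -lb
    A = np.vstack([N, -N])
    b = np.concatenate([ub, -lb])
    obj = objective or model.objective
    c = np.zeros(len(model.reactions))
    c[model.reaction_ids.index(obj)] = 1.0
    cN = c @ N
    best = None
    for rows in combinations(range(A.shape[0]), d):
        Asub = A[list(rows)]
        if abs(np.linalg.det(Asub)) < 1e-12:
            continue
        y = np.linalg.solve(Asub, b[list(rows)])
        if np.all(A @ y <= b + tol):
            value = float(cN @ y)
            if best is None or value > best:
                best = value
    return best


def eval_gpr_string(text: str, present: set[str], genes: set[str]) -> bool:
    """Evaluate a GPR string with Python's own boolean operators."""
    env = {g: (g in present) for g in genes}
    return bool(eval(text, {"__builtins__": {}}, env))  # noqa: S307


def simple_dead_ends(model) -> set[str]:
    """Set-based dead-end finder written independently of the package."""
    producers: dict[str, int] = {}
    consumers: dict[str, int] = {}
    for rxn in model.reactions:
        boundary = len(rxn.stoichiometry) == 1
        rev = rxn.lower_bound < 0 < rxn.upper_bound
        for met, coeff in rxn.stoichiometry.items():
            fwd_produces = coeff > 0
            if rxn.upper_bound <= 0 and rxn.lower_bound < 0:
                fwd_produces = not fwd_produces  # reverse-only
            roles = {True: "p", False: "c"}[fwd_produces]
            if boundary or rev:
                roles = "pc"
            for role in roles:
                (producers if role == "p" else consumers)[met] = 1
    counts: dict[str, int] = {}
    boundary_mets: set[str] = set()
    for rxn in model.reactions:
        for met in rxn.stoichiometry:
            counts[met] = counts.get(met, 0) + 1
            if len(rxn.stoichiometry) == 1:
                boundary_mets.add(met)
    dead = set()
    for rxn in model.reactions:
        for met in rxn.stoichiometry:
            if met not in producers or met not in consumers:
                dead.add(met)
            if counts[met] == 1 and met not in boundary_mets:
                dead.add(met)
    return dead


def prune_oracle(model, protected: set[str]) -> set[str]:
    """Remove-one-recheck pruning: returns the set of removed reaction ids."""
    m = model.copy()
    protected = set(protected) | {
        r.id for r in m.reactions if len(r.stoichiometry) == 1}
    if m.objective:
        protected.add(m.objective)
    removed: set[str] = set()
    while True:
        dead = simple_dead_ends(m)
        candidate = None
        for rxn in m.reactions:  # deterministic order
            if rxn.id in protected:
                continue
            if any(met in dead for met in rxn.stoichiometry):
                candidate = rxn.id
                break
        if candidate is None:
            return removed
        m.remove_reactions([candidate])
        m.remove_orphan_metabolites()
        removed.add(candidate)


def random_gpr_text(rng: np.random.Generator, max_leaves: int = 10) -> str:
    """A random parenthesised and/or expression over genes g0..g9."""
    n_leaves = int(rng.integers(1, max_leaves + 1))
    leaves = [f"g{int(rng.integers(0, 10))}" for _ in range(n_leaves)]

    def build(items: list[str]) -> str:
        if len(items) == 1:
            return items[0]
        split = int(rng.integers(1, len(items)))
        op = rng.choice([" and ", " or "])
        left, right = build(items[:split]), build(items[split:])
        if rng.random() < 0.5:
            left = f"({left})"
        if rng.random() < 0.5:
            right = f"({right})"
        return op.join([left, right])

    return build(leaves)
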