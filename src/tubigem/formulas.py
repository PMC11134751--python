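"""Elemental formula parsing and molar-mass arithmetic.

Formulas are plain Hill-style strings ("C6H12O6", "HO4P"). Generic
placeholders (R-groups, asterisks, X residues) are recognised so that
reactions touching under-specified metabolites can be flagged during
curation rather than silently mis-balanced.
"""

from __future__ import annotations

import re
from collections import Counter

# Standard atomic weights (IUPAC 2021, abridged), g/mol. Only elements
# plausibly found in metabolite formulas are listed.
ATOMIC_WEIGHTS: dict[str, float] = {
    "H": 1.008, "C": 12.011, "N": 14.007, "O": 15.999, "P": 30.974,
    "S": 32.06, "Na": 22.990, "K": 39.098, "Mg": 24.305, "Ca": 40.078,
    "Fe": 55.845, "Zn": 65.38, "Cu": 63.546, "Mn": 54.938, "Cl": 35.45,
    "Se": 78.971, "Co": 58.933, "Mo": 95.95, "I": 126.904, "B": 10.81,
    "F": 18.998, "Br": 79.904, "Si": 28.085, "W": 183.84, "Ni": 58.693,
}

_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*)")
_GENERIC = re.compile(r"(\*|R(?![a-z])|X(?![a-z]))")


class FormulaError(ValueError):
    """Raised when a formula string cannot be parsed into element counts."""


def is_generic_formula(formula: str | None) -> bool:
    """True if the formula is absent or contains a generic placeholder.

    Metabolites "without exact mass specified" — R-group fatty acids and
    the like — make every reaction they touch unusable for mass balance.
    """
    if formula is None or formula == "":
        return True
    return bool(_GENERIC.search(formula))


def parse_formula(formula: str) -> dict[str, int]:
    """Parse a formula string into an element -> count map.

    Raises FormulaError for empty, generic or otherwise unparseable input.
    """
    if formula is None or formula == "":
        raise FormulaError("empty formula")
    if is_generic_formula(formula):
        raise FormulaError(f"generic (R-group) formula: {formula!r}")
    counts: Counter[str] = Counter()
    pos = 0
    for match in _TOKEN.finditer(formula):
        if match.start() != pos:
            raise FormulaError(f"unparseable formula {formula!r} at position {pos}")
        element, digits = match.groups()
        if element not in ATOMIC_WEIGHTS:
            raise FormulaError(f"unknown element {element!r} in {formula!r}")
        counts[element] += int(digits) if digits else 1
        pos = match.end()
    if pos != len(formula):
        raise FormulaError(f"trailing garbage in formula {formula!r}")
    return dict(counts)


def molar_mass(formula: str) -> float:
    """Molar mass in g/mol of a parseable formula."""
    return sum(ATOMIC_WEIGHTS[el] * n for el, n in parse_formula(formula).items())


def element_count(formula: str, element: str) -> int:
    """Number of atoms of ``element`` in the formula (0 if absent)."""
    return parse_formula(formula).get(element, 0)
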