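"""Boolean gene-protein-reaction (GPR) rules.

A GPR is a Boolean tree over gene identifiers: AND nodes model enzyme
complexes (all subunits required), OR nodes model isozymes (any one
suffices). The textual grammar accepted by :func:`parse_gpr` is the usual
one — gene ids, ``and``/``or`` (case-insensitive) and parentheses, with
``and`` binding tighter than ``or``.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from itertools import product
from typing import FrozenSet, Iterator


class GprParseError(ValueError):
    """Raised for malformed GPR strings (unbalanced parens, empty operands)."""


class GprExpression:
    """Base class for GPR tree nodes."""

    def evaluate(self, present: set[str] | frozenset[str]) -> bool:
        raise NotImplementedError

    def genes(self) -> frozenset[str]:
        raise NotImplementedError

    def complexes(self) -> set[FrozenSet[str]]:
        """Distinct maximal all-of gene sets (DNF terms with >= 2 genes)."""
        return {term for term in self.dnf() if len(term) >= 2}

    def dnf(self) -> set[FrozenSet[str]]:
        """Disjunctive normal form as a set of gene sets."""
        raise NotImplementedError

    def to_string(self) -> str:
        raise NotImplementedError

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"{type(self).__name__}({self.to_string()!r})"

    def __eq__(self, other) -> bool:
        return (isinstance(other, GprExpression)
                and self.to_string() == other.to_string())

    def __hash__(self) -> int:
        return hash(self.to_string())


@dataclass(frozen=True, eq=False)
class GeneLeaf(GprExpression):
    gene: str

    def evaluate(self, present) -> bool:
        return self.gene in present

    def genes(self) -> frozenset[str]:
        return frozenset({self.gene})

    def dnf(self) -> set[FrozenSet[str]]:
        return {frozenset({self.gene})}

    def to_string(self) -> str:
        return self.gene


@dataclass(frozen=True, eq=False)
class AllOf(GprExpression):
    """Enzyme complex: every child must be satisfied."""

    children: tuple[GprExpression, ...]

    def evaluate(self, present) -> bool:
        return all(c.evaluate(present) for c in self.children)

    def genes(self) -> frozenset[str]:
        return frozenset().union(*(c.genes() for c in self.children))

    def dnf(self) -> set[FrozenSet[str]]:
        terms: set[FrozenSet[str]] = set()
        for combo in product(*(c.dnf() for c in self.children)):
            terms.add(frozenset().union(*combo))
        return terms

    def to_string(self) -> str:
        return " and ".join(
            f"({c.to_string()})" if isinstance(c, AnyOf) else c.to_string()
            for c in self.children)


@dataclass(frozen=True, eq=False)
class AnyOf(GprExpression):
    """Isozymes: any one child suffices."""

    children: tuple[GprExpression, ...]

    def evaluate(self, present) -> bool:
        return any(c.evaluate(present) for c in self.children)

    def genes(self) -> frozenset[str]:
        return frozenset().union(*(c.genes() for c in self.children))

    def dnf(self) -> set[FrozenSet[str]]:
        terms: set[FrozenSet[str]] = set()
        for c in self.children:
            terms |= c.dnf()
        return terms

    def to_string(self) -> str:
        return " or ".join(c.to_string() for c in self.children)


_GPR_TOKEN = re.compile(r"\(|\)|[^\s()]+")


def _tokenize(text: str) -> Iterator[str]:
    for match in _GPR_TOKEN.finditer(text):
        yield match.group(0)


def parse_gpr(text: str) -> GprExpression:
    """Parse a GPR string into a Boolean tree.

    ``and`` binds tighter than ``or``; parentheses override. The empty
    string is rejected — callers represent "no GPR" as ``None``.
    """
    tokens = list(_tokenize(text))
    if not tokens:
        raise GprParseError("empty GPR expression")
    pos = 0

    def peek() -> str | None:
        return tokens[pos] if pos < len(tokens) else None

    def advance() -> str:
        nonlocal pos
        tok = tokens[pos]
        pos += 1
        return tok

    def parse_or() -> GprExpression:
        children = [parse_and()]
        while peek() is not None and peek().lower() == "or":
            advance()
            children.append(parse_and())
        return children[0] if len(children) == 1 else AnyOf(tuple(children))

    def parse_and() -> GprExpression:
        children = [parse_atom()]
        while peek() is not None and peek().lower() == "and":
            advance()
            children.append(parse_atom())
        return children[0] if len(children) == 1 else AllOf(tuple(children))

    def parse_atom() -> GprExpression:
        tok = peek()
        if tok is None:
            raise GprParseError(f"unexpected end of GPR in {text!r}")
        if tok == "(":
            advance()
            node = parse_or()
            if peek() != ")":
                raise GprParseError(f"unbalanced parentheses in {text!r}")
            advance()
            return node
        if tok == ")" or tok.lower() in ("and", "or"):
            raise GprParseError(f"empty operand near {tok!r} in {text!r}")
        return GeneLeaf(advance())

    tree = parse_or()
    if pos != len(tokens):
        raise GprParseError(f"trailing tokens in GPR {text!r}")
    return tree


def evaluate_gpr(gpr: GprExpression, present: set[str]) -> bool:
    """Evaluate a GPR under a gene-presence assignment."""
    return gpr.evaluate(present)
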