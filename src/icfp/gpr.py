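"""Gene-protein-reaction (GPR) Boolean rules.

A GPR rule is a Boolean expression over gene identifiers with ``and``
(enzyme complexes: every subunit required) and ``or`` (isoenzymes: any
one suffices).  Besides ordinary Boolean evaluation, rules are evaluated
over the ternary expression-state coding up = +1, invariant = 0,
down = -1 with AND = min and OR = max, the standard way discrete
expression states are projected onto reactions.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Mapping

__all__ = ["GprNode", "GprError", "parse_gpr", "evaluate_ternary"]


class GprError(ValueError):
    """Raised when a GPR string cannot be parsed."""


@dataclass(frozen=True)
class GprNode:
    """Node of a parsed GPR tree.

    ``op`` is one of ``"gene"``, ``"and"``, ``"or"``.  Leaves carry the
    gene identifier in ``gene``; internal nodes carry >= 2 children.
    """

    op: str
    gene: str | None = None
    children: tuple["GprNode", ...] = field(default_factory=tuple)

    def genes(self) -> set[str]:
        if self.op == "gene":
            return {self.gene}
        out: set[str] = set()
        for ch in self.children:
            out |= ch.genes()
        return out

    def __str__(self) -> str:  # round-trip-able textual form
        if self.op == "gene":
            return self.gene
        sep = f" {self.op} "
        parts = []
        for ch in self.children:
            s = str(ch)
            if ch.op != "gene" and ch.op != self.op:
                s = f"({s})"
            parts.append(s)
        return sep.join(parts)


_TOKEN_RE = re.compile(r"\(|\)|[^\s()]+")


def _tokenize(text: str) -> list[str]:
    return _TOKEN_RE.findall(text)


def parse_gpr(text: str | None) -> GprNode | None:
    """Parse a GPR string like ``"(g1 and g2) or g3"`` into a tree.

    Empty or whitespace-only input yields ``None`` (no gene evidence).
    ``and``/``or`` are case-insensitive; ``&``/``|`` are accepted.
    OR binds weaker than AND, as in cobra-style rule strings.
    """
    if text is None or not text.strip():
        return None
    tokens = _tokenize(text)
    pos = 0

    def peek() -> str | None:
        return tokens[pos] if pos < len(tokens) else None

    def is_op(tok: str | None, name: str) -> bool:
        if tok is None:
            return False
        low = tok.lower()
        return low == name or (name == "and" and tok == "&") or (
            name == "or" and tok == "|"
        )

    def parse_or() -> GprNode:
        nonlocal pos
        terms = [parse_and()]
        while is_op(peek(), "or"):
            pos += 1
            terms.append(parse_and())
        if len(terms) == 1:
            return terms[0]
        return GprNode("or", children=tuple(terms))

    def parse_and() -> GprNode:
        nonlocal pos
        terms = [parse_atom()]
        while is_op(peek(), "and"):
            pos += 1
            terms.append(parse_atom())
        if len(terms) == 1:
            return terms[0]
        return GprNode("and", children=tuple(terms))

    def parse_atom() -> GprNode:
        nonlocal pos
        tok = peek()
        if tok is None:
            raise GprError(f"unexpected end of GPR expression: {text!r}")
        if tok == "(":
            pos += 1
            node = parse_or()
            if peek() != ")":
                raise GprError(f"unbalanced parentheses in GPR: {text!r}")
            pos += 1
            return node
        if tok == ")" or is_op(tok, "and") or is_op(tok, "or"):
            raise GprError(f"misplaced token {tok!r} in GPR: {text!r}")
        pos += 1
        return GprNode("gene", gene=tok)

    root = parse_or()
    if pos != len(tokens):
        raise GprError(f"trailing tokens in GPR: {text!r}")
    return root


def evaluate_ternary(node: GprNode | None, states: Mapping[str, int]) -> int:
    """Evaluate a GPR tree over ternary gene states.

    ``states`` maps gene id -> {+1, 0, -1}; genes absent from the map
    count as 0 (no evidence).  AND takes the min of its children, OR the
    max.  A ``None`` rule (empty GPR) evaluates to 0.
    """
    if node is None:
        return 0
    if node.op == "gene":
        return int(states.get(node.gene, 0))
    vals = [evaluate_ternary(ch, states) for ch in node.children]
    return min(vals) if node.op == "and" else max(vals)
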