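"""Gene-protein-reaction (GPR) rule parsing, classification and boolean evaluation.

A GPR rule is a boolean expression over gene identifiers ("G1 and G2",
"G1 or G2", "(G1 and G2) or G3") stating which gene products enable a
reaction.  Rules fall into five categories that drive how expression data
is mapped onto reaction bounds:

* ``one-gene`` — a single enzyme; its expression is used directly.
* ``or`` — isoenzymes; any suffices, expressions are summed.
* ``and`` — obligate subunits; the minimum subunit expression is taken.
* ``andor`` — mixed isoenzyme/subunit rules; excluded from integration.
* ``none`` — no gene annotation.

The grammar is case-insensitive ``and``/``or`` with parentheses; any other
token is a gene id.  Duplicate genes within a rule are collapsed before
the category is assigned, so ``"G1 or G1"`` classifies as ``one-gene``.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Mapping, Sequence, Union

__all__ = ["GPRRule", "GPRParseError", "parse_gpr"]

_TOKEN_RE = re.compile(r"\(|\)|[^\s()]+")

# Expression tree: a gene id (str) or an operator node.
Node = Union[str, "OpNode"]


@dataclass(frozen=True)
class OpNode:
    op: str  # "and" | "or"
    children: tuple[Node, ...]

    def render(self) -> str:
        parts = []
        for child in self.children:
            if isinstance(child, OpNode):
                parts.append(f"({child.render()})")
            else:
                parts.append(child)
        return f" {self.op} ".join(parts)


class GPRParseError(ValueError):
    """Raised for unbalanced parentheses or malformed boolean expressions."""


@dataclass(frozen=True)
class GPRRule:
    """A parsed GPR rule with its integration category."""

    category: str  # one-gene | or | and | andor | none
    genes: tuple[str, ...]  # deduplicated, order of first appearance
    structure: Node | None = field(default=None, compare=False)

    def evaluate(self, gene_states: Mapping[str, bool]) -> bool:
        """Evaluate the boolean expression; genes absent from the mapping
        default to True (present/functional).  Rules with no genes are
        vacuously true."""
        if self.structure is None:
            return True
        return _eval_node(self.structure, gene_states)

    def render(self) -> str:
        if self.structure is None:
            return ""
        if isinstance(self.structure, str):
            return self.structure
        return self.structure.render()


def _eval_node(node: Node, states: Mapping[str, bool]) -> bool:
    if isinstance(node, str):
        return bool(states.get(node, True))
    results = (_eval_node(c, states) for c in node.children)
    return any(results) if node.op == "or" else all(results)


class _Parser:
    def __init__(self, tokens: Sequence[str]):
        self.tokens = tokens
        self.pos = 0

    def peek(self) -> str | None:
        return self.tokens[self.pos] if self.pos < len(self.tokens) else None

    def next(self) -> str:
        tok = self.peek()
        if tok is None:
            raise GPRParseError("unexpected end of rule")
        self.pos += 1
        return tok

    # expr := term ("or" term)*
    def expr(self) -> Node:
        terms = [self.term()]
        while self.peek() is not None and self.peek().lower() == "or":
            self.next()
            terms.append(self.term())
        if len(terms) == 1:
            return terms[0]
        return OpNode("or", tuple(terms))

    # term := factor ("and" factor)*
    def term(self) -> Node:
        factors = [self.factor()]
        while self.peek() is not None and self.peek().lower() == "and":
            self.next()
            factors.append(self.factor())
        if len(factors) == 1:
            return factors[0]
        return OpNode("and", tuple(factors))

    # factor := gene | "(" expr ")"
    def factor(self) -> Node:
        tok = self.next()
        if tok == "(":
            inner = self.expr()
            closing = self.peek()
            if closing != ")":
                raise GPRParseError("unbalanced parentheses in GPR rule")
            self.next()
            return inner
        if tok == ")":
            raise GPRParseError("unbalanced parentheses in GPR rule")
        if tok.lower() in ("and", "or"):
            raise GPRParseError(f"misplaced operator {tok!r} in GPR rule")
        return tok


def _collapse(node: Node) -> Node:
    """Flatten nested same-op nodes and drop duplicate children so that
    duplicate genes never influence the category."""
    if isinstance(node, str):
        return node
    flat: list[Node] = []
    for child in node.children:
        child = _collapse(child)
        if isinstance(child, OpNode) and child.op == node.op:
            flat.extend(child.children)
        else:
            flat.append(child)
    seen: list[Node] = []
    for child in flat:
        if child not in seen:
            seen.append(child)
    if len(seen) == 1:
        return seen[0]
    return OpNode(node.op, tuple(seen))


def _genes_in(node: Node, acc: list[str]) -> None:
    if isinstance(node, str):
        if node not in acc:
            acc.append(node)
        return
    for child in node.children:
        _genes_in(child, acc)


def _operators_in(node: Node, acc: set[str]) -> None:
    if isinstance(node, str):
        return
    acc.add(node.op)
    for child in node.children:
        _operators_in(child, acc)


def parse_gpr(rule_text: str) -> GPRRule:
    """Parse a GPR string into a classified :class:`GPRRule`.

    Parameters
    ----------
    rule_text:
        Empty string (no annotation) or a boolean expression of gene ids
        joined by case-insensitive ``and``/``or`` with parentheses.

    Raises
    ------
    GPRParseError
        On unbalanced parentheses or misplaced operators.
    """
    text = (rule_text or "").strip()
    if not text:
        return GPRRule(category="none", genes=())
    tokens = _TOKEN_RE.findall(text)
    parser = _Parser(tokens)
    tree = parser.expr()
    if parser.peek() is not None:
        raise GPRParseError(f"unexpected token {parser.peek()!r} in GPR rule")
    tree = _collapse(tree)
    genes: list[str] = []
    _genes_in(tree, genes)
    ops: set[str] = set()
    _operators_in(tree, ops)
    if len(genes) == 1 and not ops:
        category = "one-gene"
    elif ops == {"or"}:
        category = "or"
    elif ops == {"and"}:
        category = "and"
    else:
        category = "andor"
    return GPRRule(category=category, genes=tuple(genes), structure=tree)
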