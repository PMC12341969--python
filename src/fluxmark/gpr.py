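"""Boolean gene-protein-reaction (GPR) rules.

A GPR is a boolean expression over gene identifiers with ``and`` / ``or``
(case-insensitive) and parentheses.  ``or`` joins isozymes, ``and`` joins
complex subunits; evaluation over {0,1} states uses max for ``or`` and min
for ``and``.  Genes missing from the state map default to 1 (expressed),
i.e. absence of evidence never closes a reaction; a warning is logged.
"""

from __future__ import annotations

import logging
import re
from typing import Iterable

from .errors import GprParseError

logger = logging.getLogger(__name__)

# Gene identifiers may contain dots, dashes and colons (Ensembl, mt- genes...)
_TOKEN_RE = re.compile(r"\s*(\(|\)|[A-Za-z0-9_.:\-]+)")

# AST node: ("gene", name) | ("and", [nodes]) | ("or", [nodes])


def tokenize(expr: str) -> list[tuple[str, int]]:
    tokens: list[tuple[str, int]] = []
    pos = 0
    while pos < len(expr):
        match = _TOKEN_RE.match(expr, pos)
        if match is None:
            stripped = expr[pos:].strip()
            if not stripped:
                break
            raise GprParseError(f"unexpected character {stripped[0]!r}", pos)
        tokens.append((match.group(1), match.start(1)))
        pos = match.end()
    return tokens


def parse_gpr(expr: str):
    """Parse a GPR string into an AST; empty/whitespace input returns None."""
    tokens = tokenize(expr)
    if not tokens:
        return None
    node, index = _parse_or(tokens, 0)
    if index != len(tokens):
        raise GprParseError(
            f"unexpected token {tokens[index][0]!r}", tokens[index][1]
        )
    return node


def _parse_or(tokens, index):
    node, index = _parse_and(tokens, index)
    terms = [node]
    while index < len(tokens) and tokens[index][0].lower() == "or":
        term, index = _parse_and(tokens, index + 1)
        terms.append(term)
    return (terms[0] if len(terms) == 1 else ("or", terms)), index


def _parse_and(tokens, index):
    node, index = _parse_atom(tokens, index)
    factors = [node]
    while index < len(tokens) and tokens[index][0].lower() == "and":
        factor, index = _parse_atom(tokens, index + 1)
        factors.append(factor)
    return (factors[0] if len(factors) == 1 else ("and", factors)), index


def _parse_atom(tokens, index):
    if index >= len(tokens):
        end = tokens[-1][1] + len(tokens[-1][0]) if tokens else 0
        raise GprParseError("unexpected end of expression", end)
    token, pos = tokens[index]
    if token == "(":
        node, index = _parse_or(tokens, index + 1)
        if index >= len(tokens) or tokens[index][0] != ")":
            raise GprParseError("unbalanced parenthesis", pos)
        return node, index + 1
    if token == ")" or token.lower() in ("and", "or"):
        raise GprParseError(f"unexpected token {token!r}", pos)
    return ("gene", token), index + 1


def gpr_genes(expr: str) -> set[str]:
    """The set of gene identifiers referenced by a GPR string."""
    node = parse_gpr(expr)
    genes: set[str] = set()

    def walk(n):
        if n is None:
            return
        if n[0] == "gene":
            genes.add(n[1])
        else:
            for child in n[1]:
                walk(child)

    walk(node)
    return genes


def eval_gpr(expr: str, gene_states: dict[str, int]) -> int:
    """Evaluate a GPR over binary gene states (or = max, and = min).

    An empty GPR evaluates to 1: reactions without gene evidence stay open.
    """
    node = parse_gpr(expr)
    if node is None:
        return 1
    missing: set[str] = set()

    def walk(n) -> int:
        if n[0] == "gene":
            if n[1] not in gene_states:
                missing.add(n[1])
                return 1
            return 1 if gene_states[n[1]] else 0
        values: Iterable[int] = (walk(child) for child in n[1])
        return max(values) if n[0] == "or" else min(values)

    value = walk(node)
    if missing:
        logger.warning(
            "GPR genes missing from state map treated as expressed: %s",
            ", ".join(sorted(missing)),
        )
    return value
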