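"""Gene-protein-reaction (GPR) rules.

A GPR is a boolean expression over gene identifiers: AND encodes enzyme
complexes (all subunits required), OR encodes isozymes (any suffices).
Identifiers are maximal runs of non-space, non-parenthesis characters, which
tolerates Ensembl, HGNC and arbitrary synthetic gene ids. ``and``/``or`` are
recognised case-insensitively; the symbolic connectives ``&``/``|`` (and
their doubled forms) are accepted for compatibility with COBRA exports.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, Mapping

from .errors import GprParseError, ValidationError

_AND_TOKENS = frozenset({"and", "&", "&&"})
_OR_TOKENS = frozenset({"or", "|", "||"})


@dataclass(frozen=True)
class GprExpression:
    """Immutable GPR expression tree.

    ``op`` is one of ``"true"`` (always-active sentinel for empty rules),
    ``"gene"`` (leaf), ``"and"`` or ``"or"``.
    """

    op: str
    gene: str | None = None
    children: tuple["GprExpression", ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        if self.op not in ("true", "gene", "and", "or"):
            raise ValidationError(f"invalid GPR node op {self.op!r}")
        if self.op == "gene" and not self.gene:
            raise ValidationError("gene node requires a gene id")
        if self.op in ("and", "or") and len(self.children) < 2:
            raise ValidationError(f"{self.op} node requires >= 2 children")

    @property
    def is_always_active(self) -> bool:
        return self.op == "true"

    def genes(self) -> set[str]:
        """Set of gene identifiers referenced by the expression."""
        if self.op == "gene":
            return {self.gene}  # type: ignore[arg-type]
        out: set[str] = set()
        for c in self.children:
            out |= c.genes()
        return out

    def evaluate(self, gene_states: Mapping[str, int],
                 missing: str = "strict") -> int:
        """Evaluate to 0/1 given per-gene activity states.

        AND is the minimum over children, OR the maximum; the sentinel is 1.
        ``missing`` controls genes absent from ``gene_states``: ``"strict"``
        raises, ``"zero"`` treats them as inactive.
        """
        if self.op == "true":
            return 1
        if self.op == "gene":
            if self.gene in gene_states:
                return 1 if gene_states[self.gene] else 0
            if missing == "zero":
                return 0
            raise ValidationError(
                f"gene {self.gene!r} missing from activity states")
        vals = (c.evaluate(gene_states, missing=missing) for c in self.children)
        return min(vals) if self.op == "and" else max(vals)

    def to_text(self) -> str:
        """Canonical text form (parenthesised, lowercase connectives)."""
        if self.op == "true":
            return ""
        if self.op == "gene":
            return self.gene  # type: ignore[return-value]
        sep = f" {self.op} "
        parts = []
        for c in self.children:
            t = c.to_text()
            if c.op in ("and", "or") and c.op != self.op:
                t = f"({t})"
            parts.append(t)
        return sep.join(parts)


ALWAYS_ACTIVE = GprExpression("true")


def _tokenize(text: str) -> Iterator[tuple[str, int]]:
    i, n = 0, len(text)
    while i < n:
        ch = text[i]
        if ch.isspace():
            i += 1
            continue
        if ch in "()":
            yield ch, i
            i += 1
            continue
        j = i
        while j < n and not text[j].isspace() and text[j] not in "()":
            j += 1
        yield text[i:j], i
        i = j


def parse_gpr(rule_text: str) -> GprExpression:
    """Parse a GPR rule into an expression tree.

    ``and`` binds tighter than ``or``. The empty (or all-whitespace) rule
    parses to the always-active sentinel. Raises :class:`GprParseError` with
    the offending position for unbalanced parentheses or dangling operators.
    """
    tokens = list(_tokenize(rule_text))
    if not tokens:
        return ALWAYS_ACTIVE
    pos = 0

    def peek() -> tuple[str, int] | None:
        return tokens[pos] if pos < len(tokens) else None

    def advance() -> tuple[str, int]:
        nonlocal pos
        tok = tokens[pos]
        pos += 1
        return tok

    def parse_or() -> GprExpression:
        terms = [parse_and()]
        while (t := peek()) is not None and t[0].lower() in _OR_TOKENS:
            advance()
            terms.append(parse_and())
        return terms[0] if len(terms) == 1 else GprExpression("or", children=tuple(terms))

    def parse_and() -> GprExpression:
        factors = [parse_atom()]
        while (t := peek()) is not None and t[0].lower() in _AND_TOKENS:
            advance()
            factors.append(parse_atom())
        return factors[0] if len(factors) == 1 else GprExpression("and", children=tuple(factors))

    def parse_atom() -> GprExpression:
        t = peek()
        if t is None:
            raise GprParseError("unexpected end of rule", len(rule_text))
        tok, at = advance()
        if tok == "(":
            inner = parse_or()
            nxt = peek()
            if nxt is None or nxt[0] != ")":
                raise GprParseError("unbalanced parenthesis", at)
            advance()
            return inner
        if tok == ")":
            raise GprParseError("unexpected ')'", at)
        if tok.lower() in _AND_TOKENS | _OR_TOKENS:
            raise GprParseError(f"unexpected operator {tok!r}", at)
        return GprExpression("gene", gene=tok)

    expr = parse_or()
    if pos < len(tokens):
        tok, at = tokens[pos]
        raise GprParseError(f"unexpected token {tok!r}", at)
    return expr


def evaluate_gpr(expr: GprExpression, gene_states: Mapping[str, int],
                 missing: str = "strict") -> int:
    """Functional wrapper around :meth:`GprExpression.evaluate`."""
    return expr.evaluate(gene_states, missing=missing)
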