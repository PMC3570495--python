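"""Three-valued (Kleene) logic and the phenotype-rule expression language.

Pathway assertion statuses map onto strong-Kleene truth values: an asserted
pathway is TRUE, a not-asserted pathway is FALSE, and a pathway whose missing
functional roles are covered only by candidate genes is UNKNOWN.  Phenotype
rules are boolean AND/OR/NOT expressions over pathway identifiers evaluated
under these semantics, so a rule resolves to a definite verdict only when the
available annotation evidence forces one.
"""

from __future__ import annotations

import enum
import re
from dataclasses import dataclass
from typing import Iterator, Mapping


class TriState(enum.Enum):
    """Strong-Kleene truth value: TRUE, FALSE, or UNKNOWN."""

    TRUE = "true"
    FALSE = "false"
    UNKNOWN = "unknown"

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"TriState.{self.name}"


TRUE = TriState.TRUE
FALSE = TriState.FALSE
UNKNOWN = TriState.UNKNOWN

#: Pathway assertion status <-> truth value. The manual status "absent" is a
#: curator's definite negative and therefore maps to FALSE.
STATUS_TO_TRISTATE: dict[str, TriState] = {
    "asserted": TRUE,
    "not_asserted": FALSE,
    "unknown": UNKNOWN,
    "absent": FALSE,
}


def tri_not(a: TriState) -> TriState:
    """Kleene negation: UNKNOWN is its own negation."""
    if a is TRUE:
        return FALSE
    if a is FALSE:
        return TRUE
    return UNKNOWN


def tri_or(a: TriState, b: TriState) -> TriState:
    """Kleene disjunction: TRUE absorbs; FALSE is the identity."""
    if a is TRUE or b is TRUE:
        return TRUE
    if a is FALSE and b is FALSE:
        return FALSE
    return UNKNOWN


def tri_and(a: TriState, b: TriState) -> TriState:
    """Kleene conjunction: FALSE absorbs; TRUE is the identity."""
    if a is FALSE or b is FALSE:
        return FALSE
    if a is TRUE and b is TRUE:
        return TRUE
    return UNKNOWN


def tri_all(values) -> TriState:
    """Fold tri_and over an iterable; empty input yields TRUE."""
    out = TRUE
    for v in values:
        out = tri_and(out, v)
    return out


def tri_any(values) -> TriState:
    """Fold tri_or over an iterable; empty input yields FALSE."""
    out = FALSE
    for v in values:
        out = tri_or(out, v)
    return out


# ---------------------------------------------------------------------------
# Rule expressions


class RuleExpr:
    """Base class for phenotype-rule AST nodes."""

    __slots__ = ()

    def variables(self) -> list[str]:
        """All pathway identifiers in the expression, in first-seen order."""
        seen: dict[str, None] = {}
        for v in self._iter_vars():
            seen.setdefault(v, None)
        return list(seen)

    def _iter_vars(self) -> Iterator[str]:
        raise NotImplementedError

    def unparse(self) -> str:
        raise NotImplementedError

    def __str__(self) -> str:
        return self.unparse()


@dataclass(frozen=True, slots=True)
class Var(RuleExpr):
    name: str

    def _iter_vars(self) -> Iterator[str]:
        yield self.name

    def unparse(self) -> str:
        return self.name


@dataclass(frozen=True, slots=True)
class Not(RuleExpr):
    child: RuleExpr

    def _iter_vars(self) -> Iterator[str]:
        yield from self.child._iter_vars()

    def unparse(self) -> str:
        if isinstance(self.child, (Var, Not)):
            return f"NOT {self.child.unparse()}"
        return f"NOT ({self.child.unparse()})"


@dataclass(frozen=True, slots=True)
class And(RuleExpr):
    left: RuleExpr
    right: RuleExpr

    def _iter_vars(self) -> Iterator[str]:
        yield from self.left._iter_vars()
        yield from self.right._iter_vars()

    def unparse(self) -> str:
        # parenthesize lower precedence, and same-precedence right operands,
        # so left-associative re-parsing reproduces the tree exactly
        left = f"({self.left.unparse()})" if isinstance(self.left, Or) else self.left.unparse()
        right = (
            f"({self.right.unparse()})"
            if isinstance(self.right, (Or, And))
            else self.right.unparse()
        )
        return f"{left} AND {right}"


@dataclass(frozen=True, slots=True)
class Or(RuleExpr):
    left: RuleExpr
    right: RuleExpr

    def _iter_vars(self) -> Iterator[str]:
        yield from self.left._iter_vars()
        yield from self.right._iter_vars()

    def unparse(self) -> str:
        right = (
            f"({self.right.unparse()})"
            if isinstance(self.right, Or)
            else self.right.unparse()
        )
        return f"{self.left.unparse()} OR {right}"


# ---------------------------------------------------------------------------
# Parser


class RuleSyntaxError(ValueError):
    """Malformed rule text; carries the character position of the problem."""

    def __init__(self, message: str, position: int):
        super().__init__(f"{message} (at position {position})")
        self.position = position


class MissingPathwayError(KeyError):
    """A rule references a pathway with no known assertion status."""

    def __init__(self, pathway_id: str):
        super().__init__(pathway_id)
        self.pathway_id = pathway_id

    def __str__(self) -> str:
        return f"no assertion status for pathway {self.pathway_id!r}"


_TOKEN_RE = re.compile(r"\s*(?:(?P<lpar>\()|(?P<rpar>\))|(?P<word>[A-Za-z_][A-Za-z0-9_.-]*))")
_KEYWORDS = {"and", "or", "not"}


def _tokenize(text: str) -> list[tuple[str, str, int]]:
    tokens: list[tuple[str, str, int]] = []
    pos = 0
    while pos < len(text):
        m = _TOKEN_RE.match(text, pos)
        if m is None:
            rest = text[pos:].lstrip()
            if not rest:
                break
            at = len(text) - len(rest)
            raise RuleSyntaxError(f"unexpected character {rest[0]!r}", at)
        if m.lastgroup == "word":
            word = m.group("word")
            kind = word.lower() if word.lower() in _KEYWORDS else "ident"
            tokens.append((kind, word, m.start("word")))
        else:
            tokens.append((m.lastgroup, m.group(0).strip(), m.end() - 1))
        pos = m.end()
    return tokens


class _Parser:
    """Recursive descent over the grammar  or := and (OR and)* ;
    and := not (AND not)* ;  not := NOT not | '(' or ')' | IDENT.

    Precedence NOT > AND > OR, left associative. Keywords are
    case-insensitive; identifiers are case-sensitive.
    """

    def __init__(self, text: str):
        self.text = text
        self.tokens = _tokenize(text)
        self.i = 0

    def peek(self) -> tuple[str, str, int] | None:
        return self.tokens[self.i] if self.i < len(self.tokens) else None

    def take(self) -> tuple[str, str, int]:
        tok = self.peek()
        if tok is None:
            raise RuleSyntaxError("unexpected end of expression", len(self.text))
        self.i += 1
        return tok

    def parse(self) -> RuleExpr:
        if not self.tokens:
            raise RuleSyntaxError("empty expression", 0)
        expr = self.or_expr()
        tok = self.peek()
        if tok is not None:
            raise RuleSyntaxError(f"unexpected token {tok[1]!r}", tok[2])
        return expr

    def or_expr(self) -> RuleExpr:
        left = self.and_expr()
        while (tok := self.peek()) is not None and tok[0] == "or":
            self.take()
            left = Or(left, self.and_expr())
        return left

    def and_expr(self) -> RuleExpr:
        left = self.not_expr()
        while (tok := self.peek()) is not None and tok[0] == "and":
            self.take()
            left = And(left, self.not_expr())
        return left

    def not_expr(self) -> RuleExpr:
        tok = self.peek()
        if tok is not None and tok[0] == "not":
            self.take()
            return Not(self.not_expr())
        return self.atom()

    def atom(self) -> RuleExpr:
        kind, value, pos = self.take()
        if kind == "ident":
            return Var(value)
        if kind == "lpar":
            expr = self.or_expr()
            kind2, value2, pos2 = self.take()
            if kind2 != "rpar":
                raise RuleSyntaxError(f"expected ')' but found {value2!r}", pos2)
            return expr
        raise RuleSyntaxError(f"unexpected token {value!r}", pos)


def parse_rule(text: str) -> RuleExpr:
    """Parse rule text such as ``(P_146 OR P_519) AND (P_272 OR P_147)``.

    Raises :class:`RuleSyntaxError` on malformed input.
    """
    return _Parser(text).parse()


def evaluate_rule(
    expr: RuleExpr,
    statuses: Mapping[str, TriState],
    *,
    strict: bool = True,
    missing: set[str] | None = None,
) -> TriState:
    """Evaluate an expression bottom-up under Kleene semantics.

    In strict mode (default) an unmapped pathway identifier raises
    :class:`MissingPathwayError`; in lenient mode it evaluates to UNKNOWN and
    its id is added to *missing* when a set is supplied.
    """
    if isinstance(expr, Var):
        if expr.name in statuses:
            return statuses[expr.name]
        if strict:
            raise MissingPathwayError(expr.name)
        if missing is not None:
            missing.add(expr.name)
        return UNKNOWN
    if isinstance(expr, Not):
        return tri_not(evaluate_rule(expr.child, statuses, strict=strict, missing=missing))
    if isinstance(expr, And):
        return tri_and(
            evaluate_rule(expr.left, statuses, strict=strict, missing=missing),
            evaluate_rule(expr.right, statuses, strict=strict, missing=missing),
        )
    if isinstance(expr, Or):
        return tri_or(
            evaluate_rule(expr.left, statuses, strict=strict, missing=missing),
            evaluate_rule(expr.right, statuses, strict=strict, missing=missing),
        )
    raise TypeError(f"not a RuleExpr node: {expr!r}")
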