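"""The coded pathophem expression language.

Disease prototypes may carry a Boolean rule over coded findings, e.g. the
refractory-anemia-with-excess-blasts rule::

    M3094|; (O812| & 10209|: 5..20%) | (10221 T| &10209 T|: 2..20%)

Grammar (whitespace-insensitive)::

    expr       := clause (';' clause)*          -- ';' is top-level AND (SEQ)
    clause     := term ('|' term)*              -- OR
    term       := factor ('&' factor)*          -- AND
    factor     := atom | '(' clause ')' [':' constraint]
    atom       := CODE [FLAG] '|' [':' constraint]
    constraint := NUMBER '..' NUMBER [UNIT] | WORD

The vertical bar is overloaded: immediately after a code token (plus an
optional single-letter flag such as ``T``) it terminates the atom; anywhere
else it is the OR operator. A constraint written after a closing parenthesis
binds to the nearest preceding atom. Evaluation is Kleene three-valued
(TRUE / FALSE / NA) over a fact set in which absent codes mean
not-available; a range constraint ``a..b`` is closed below and open above.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Optional, Union

__all__ = [
    "TRUE",
    "FALSE",
    "NA",
    "Atom",
    "And",
    "Or",
    "Seq",
    "Range",
    "ValueConstraint",
    "DslSyntaxError",
    "SerializeError",
    "EvaluationError",
    "parse",
    "evaluate",
    "serialize",
]

# tri-state values; NA is "not available"
TRUE = "TRUE"
FALSE = "FALSE"
NA = "NA"


@dataclass(frozen=True)
class Range:
    """Half-open numeric constraint [lo, hi), optionally with a unit."""

    lo: float
    hi: float
    unit: Optional[str] = None


@dataclass(frozen=True)
class ValueConstraint:
    value: str


Constraint = Union[Range, ValueConstraint]


@dataclass(frozen=True)
class Atom:
    code: str
    flag: Optional[str] = None
    constraint: Optional[Constraint] = None

    @property
    def key(self) -> str:
        """Fact-set key: the flag distinguishes e.g. '10209' from '10209 T'."""
        return f"{self.code} {self.flag}" if self.flag else self.code


@dataclass(frozen=True)
class And:
    children: tuple


@dataclass(frozen=True)
class Or:
    children: tuple


@dataclass(frozen=True)
class Seq:
    """Top-level ';' conjunction; semantically AND."""

    children: tuple


ExprNode = Union[Atom, And, Or, Seq]


class DslSyntaxError(ValueError):
    def __init__(self, message: str, pos: int, expected: tuple[str, ...] = ()):
        detail = f"{message} at position {pos}"
        if expected:
            detail += " (expected " + " or ".join(expected) + ")"
        super().__init__(detail)
        self.pos = pos
        self.expected = expected


class SerializeError(ValueError):
    pass


class EvaluationError(ValueError):
    pass


_CODE_RE = re.compile(r"[A-Z]?[0-9]+")
_NUM_RE = re.compile(r"[0-9]+(?:\.[0-9]+)?")
_WORD_RE = re.compile(r"[A-Za-z][A-Za-z0-9_-]*")


class _Lexer:
    """Token stream: ('atom', Atom-without-constraint) | single-char ops |
    ('range', Range) | ('value', str) | ('end', None)."""

    def __init__(self, text: str):
        self.text = text
        self.pos = 0
        self.tokens: list[tuple[str, object, int]] = []
        self._run()

    def _skip_ws(self) -> None:
        while self.pos < len(self.text) and self.text[self.pos].isspace():
            self.pos += 1

    def _run(self) -> None:
        text = self.text
        while True:
            self._skip_ws()
            if self.pos >= len(text):
                self.tokens.append(("end", None, self.pos))
                return
            start = self.pos
            ch = text[self.pos]
            m = _CODE_RE.match(text, self.pos)
            if m:
                self.pos = m.end()
                code = m.group()
                flag = self._maybe_flag()
                self._skip_ws()
                if self.pos < len(text) and text[self.pos] == "|":
                    self.pos += 1
                    self.tokens.append(("atom", Atom(code, flag), start))
                else:
                    raise DslSyntaxError(
                        f"code {code!r} not terminated", self.pos, ("'|'",)
                    )
                continue
            if ch in "&|;()":
                self.pos += 1
                self.tokens.append((ch, ch, start))
                continue
            if ch == ":":
                self.pos += 1
                self.tokens.append(("constraint", self._lex_constraint(), start))
                continue
            raise DslSyntaxError(f"unexpected character {ch!r}", self.pos)

    def _maybe_flag(self) -> Optional[str]:
        # single uppercase letter, immediately or space-separated, that is
        # itself followed by the atom terminator
        save = self.pos
        self._skip_ws()
        if self.pos < len(self.text) and self.text[self.pos].isupper():
            after = self.pos + 1
            while after < len(self.text) and self.text[after].isspace():
                after += 1
            if after < len(self.text) and self.text[after] == "|":
                flag = self.text[self.pos]
                self.pos += 1
                return flag
        self.pos = save
        return None

    def _lex_constraint(self) -> Constraint:
        self._skip_ws()
        text = self.text
        m = _NUM_RE.match(text, self.pos)
        if m:
            lo = float(m.group())
            self.pos = m.end()
            if not text.startswith("..", self.pos):
                raise DslSyntaxError("range needs '..'", self.pos, ("'..'",))
            self.pos += 2
            m2 = _NUM_RE.match(text, self.pos)
            if not m2:
                raise DslSyntaxError("range needs an upper bound", self.pos, ("number",))
            hi = float(m2.group())
            self.pos = m2.end()
            unit = None
            if self.pos < len(text) and text[self.pos] == "%":
                unit = "%"
                self.pos += 1
            else:
                mu = _WORD_RE.match(text, self.pos)
                if mu:
                    unit = mu.group()
                    self.pos = mu.end()
            if not lo < hi:
                raise DslSyntaxError(f"empty range {lo}..{hi}", self.pos)
            return Range(lo, hi, unit)
        mw = _WORD_RE.match(text, self.pos)
        if mw:
            self.pos = mw.end()
            return ValueConstraint(mw.group())
        raise DslSyntaxError("constraint expected after ':'", self.pos,
                             ("number", "word"))


class _Parser:
    def __init__(self, text: str):
        self.tokens = _Lexer(text).tokens
        self.i = 0

    def _peek(self):
        return self.tokens[self.i]

    def _next(self):
        tok = self.tokens[self.i]
        self.i += 1
        return tok

    def _expect(self, kind: str):
        tok = self._next()
        if tok[0] != kind:
            raise DslSyntaxError(f"unexpected {tok[0]!r}", tok[2], (repr(kind),))
        return tok

    def parse(self) -> ExprNode:
        clauses = [self._clause()]
        while self._peek()[0] == ";":
            self._next()
            clauses.append(self._clause())
        tok = self._peek()
        if tok[0] != "end":
            raise DslSyntaxError(f"trailing {tok[0]!r}", tok[2], ("';'", "end of input"))
        return Seq(tuple(clauses)) if len(clauses) > 1 else clauses[0]

    def _clause(self) -> ExprNode:
        terms = [self._term()]
        while self._peek()[0] == "|":
            self._next()
            terms.append(self._term())
        return Or(tuple(terms)) if len(terms) > 1 else terms[0]

    def _term(self) -> ExprNode:
        factors = [self._factor()]
        while self._peek()[0] == "&":
            self._next()
            factors.append(self._factor())
        return And(tuple(factors)) if len(factors) > 1 else factors[0]

    def _factor(self) -> ExprNode:
        kind, value, pos = self._peek()
        if kind == "atom":
            self._next()
            node: ExprNode = value
            if self._peek()[0] == "constraint":
                _, constraint, _ = self._next()
                node = Atom(node.code, node.flag, constraint)
            return node
        if kind == "(":
            self._next()
            inner = self._clause()
            self._expect(")")
            if self._peek()[0] == "constraint":
                _, constraint, cpos = self._next()
                inner = _attach_to_rightmost_atom(inner, constraint, cpos)
            return inner
        raise DslSyntaxError(f"unexpected {kind!r}", pos, ("atom", "'('"))


def _attach_to_rightmost_atom(node: ExprNode, constraint: Constraint, pos: int) -> ExprNode:
    """A constraint after ')' binds to the nearest preceding atom."""
    if isinstance(node, Atom):
        if node.constraint is not None:
            raise DslSyntaxError("atom already carries a constraint", pos)
        return Atom(node.code, node.flag, constraint)
    last = _attach_to_rightmost_atom(node.children[-1], constraint, pos)
    return type(node)(node.children[:-1] + (last,))


def parse(text: str) -> ExprNode:
    """Parse a coded expression; raises :class:`DslSyntaxError` with the
    offending position on malformed input."""
    if not text or not text.strip():
        raise DslSyntaxError("empty expression", 0)
    return _Parser(text).parse()


# ---------------------------------------------------------------------------
# evaluation

def _eval_atom(atom: Atom, facts: dict) -> str:
    if atom.key not in facts:
        return NA
    v = facts[atom.key]
    value, unit = None, None
    if isinstance(v, bool):
        pass
    elif isinstance(v, (int, float)):
        value = float(v)
    elif isinstance(v, tuple):
        value, unit = float(v[0]), v[1]
    elif isinstance(v, dict):
        value, unit = float(v["value"]), v.get("unit")
    elif isinstance(v, str):
        pass
    else:
        raise EvaluationError(f"unsupported fact value {v!r} for {atom.key}")

    c = atom.constraint
    if isinstance(c, Range):
        if value is None:
            # presence asserted (or denied) but the quantity is unknown
            return NA if v is True or isinstance(v, str) else FALSE
        if c.unit is not None and unit is not None and c.unit != unit:
            raise EvaluationError(
                f"unit mismatch for {atom.key}: fact in {unit!r}, "
                f"constraint in {c.unit!r}"
            )
        return TRUE if c.lo <= value < c.hi else FALSE
    if isinstance(c, ValueConstraint):
        if isinstance(v, str):
            return TRUE if v == c.value else FALSE
        if isinstance(v, bool):
            return TRUE if v else FALSE
        return NA
    # no constraint: a numeric measurement counts as presence
    if isinstance(v, bool):
        return TRUE if v else FALSE
    return TRUE


def evaluate(ast: ExprNode, facts: dict) -> str:
    """Kleene three-valued evaluation.

    AND (and the top-level ';' sequence): FALSE dominates, then NA, else
    TRUE. OR: TRUE dominates, then NA, else FALSE. Facts map atom keys to
    True/False, a bare number, ``(value, unit)`` or
    ``{"value": x, "unit": u}``; absent keys are not-available.
    """
    if isinstance(ast, Atom):
        return _eval_atom(ast, facts)
    results = [evaluate(c, facts) for c in ast.children]
    if isinstance(ast, (And, Seq)):
        if FALSE in results:
            return FALSE
        return NA if NA in results else TRUE
    if isinstance(ast, Or):
        if TRUE in results:
            return TRUE
        return NA if NA in results else FALSE
    raise TypeError(f"not an expression node: {ast!r}")


# ---------------------------------------------------------------------------
# serialization

def _fmt_num(x: float) -> str:
    return str(int(x)) if float(x).is_integer() else repr(x)


def _ser_constraint(c: Constraint) -> str:
    if isinstance(c, Range):
        unit = c.unit or ""
        return f": {_fmt_num(c.lo)}..{_fmt_num(c.hi)}{unit}"
    return f": {c.value}"


def _ser_atom(a: Atom) -> str:
    text = a.code + (f" {a.flag}" if a.flag else "") + "|"
    if a.constraint is not None:
        text += _ser_constraint(a.constraint)
    return text


def _check_arity(node) -> None:
    if len(node.children) < 2:
        raise SerializeError(f"{type(node).__name__} needs >= 2 children")


def _ser_clause(node: ExprNode) -> str:
    if isinstance(node, Or):
        _check_arity(node)
        return " | ".join(_ser_term(c) for c in node.children)
    return _ser_term(node)


def _ser_term(node: ExprNode) -> str:
    if isinstance(node, And):
        _check_arity(node)
        return " & ".join(_ser_factor(c) for c in node.children)
    return _ser_factor(node)


def _ser_factor(node: ExprNode) -> str:
    if isinstance(node, Atom):
        return _ser_atom(node)
    if isinstance(node, Seq):
        raise SerializeError("';' sequence only allowed at top level")
    # parenthesize, and keep a trailing-constraint atom unambiguous: a
    # constraint directly before ')' would re-bind on re-parse
    return "(" + _ser_clause(node) + ")"


def serialize(ast: ExprNode) -> str:
    """Canonical text for an AST; ``parse(serialize(ast))`` is structurally
    identical to ``ast`` for any grammar-conformant tree."""
    if isinstance(ast, Seq):
        _check_arity(ast)
        return "; ".join(_ser_clause(c) for c in ast.children)
    return _ser_clause(ast)
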