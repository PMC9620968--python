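"""A small deterministic atom-selection language.

Grammar (boolean precedence ``not`` > ``and`` > ``or``)::

    expr     := or_expr
    or_expr  := and_expr ( "or" and_expr )*
    and_expr := not_expr ( "and" not_expr )*
    not_expr := "not" not_expr | "(" expr ")" | predicate
    predicate := ("name" | "resname" | "element" | "role") value+
               | "resid" int_or_range+
               | "all"

Values accept ``fnmatch`` wildcards (``*``, ``?``); ``resid`` accepts single
ids or inclusive ``a:b`` ranges. Multiple values after a keyword are OR-ed,
mirroring the common selection idiom ``name C1 C2``.

Results are sorted :class:`~gpianchor.system.AtomSet` objects, so selection
is deterministic and order-independent.
"""

from __future__ import annotations

from fnmatch import fnmatchcase

import numpy as np

from .system import AtomSet, Topology

_KEYWORDS = {"name", "resname", "element", "role", "resid", "all",
             "and", "or", "not"}


class SelectionError(ValueError):
    """Selection syntax error; carries the character position."""

    def __init__(self, message: str, position: int):
        super().__init__(f"{message} (at position {position})")
        self.position = position


def _tokenize(expression: str) -> list[tuple[str, int]]:
    tokens = []
    i = 0
    n = len(expression)
    while i < n:
        c = expression[i]
        if c.isspace():
            i += 1
            continue
        if c in "()":
            tokens.append((c, i))
            i += 1
            continue
        j = i
        while j < n and not expression[j].isspace() and expression[j] not in "()":
            j += 1
        tokens.append((expression[i:j], i))
        i = j
    return tokens


class _Parser:
    def __init__(self, expression: str, topology: Topology):
        self.expr = expression
        self.tokens = _tokenize(expression)
        self.pos = 0
        self.top = topology

    def peek(self):
        return self.tokens[self.pos] if self.pos < len(self.tokens) else (None, len(self.expr))

    def advance(self):
        tok = self.peek()
        self.pos += 1
        return tok

    def parse(self) -> np.ndarray:
        if not self.tokens:
            raise SelectionError("empty selection", 0)
        mask = self.parse_or()
        tok, at = self.peek()
        if tok is not None:
            raise SelectionError(f"unexpected token {tok!r}", at)
        return mask

    def parse_or(self) -> np.ndarray:
        mask = self.parse_and()
        while self.peek()[0] == "or":
            self.advance()
            mask = mask | self.parse_and()
        return mask

    def parse_and(self) -> np.ndarray:
        mask = self.parse_not()
        while self.peek()[0] == "and":
            self.advance()
            mask = mask & self.parse_not()
        return mask

    def parse_not(self) -> np.ndarray:
        tok, at = self.peek()
        if tok == "not":
            self.advance()
            return ~self.parse_not()
        if tok == "(":
            self.advance()
            mask = self.parse_or()
            tok2, at2 = self.advance()
            if tok2 != ")":
                raise SelectionError("expected ')'", at2)
            return mask
        return self.parse_predicate()

    def _values(self) -> list[str]:
        vals = []
        while True:
            tok, _ = self.peek()
            if tok is None or tok in _KEYWORDS or tok in "()":
                break
            vals.append(self.advance()[0])
        return vals

    def parse_predicate(self) -> np.ndarray:
        tok, at = self.advance()
        if tok is None:
            raise SelectionError("unexpected end of selection", at)
        if tok == "all":
            return np.ones(self.top.n_atoms, dtype=bool)
        if tok == "resid":
            vals = self._values()
            if not vals:
                raise SelectionError("'resid' needs at least one id", at)
            mask = np.zeros(self.top.n_atoms, dtype=bool)
            ids = self.top.residue_ids
            for v in vals:
                try:
                    if ":" in v:
                        lo, hi = v.split(":")
                        mask |= (ids >= int(lo)) & (ids <= int(hi))
                    else:
                        mask |= ids == int(v)
                except ValueError:
                    raise SelectionError(f"bad resid value {v!r}", at) from None
            return mask
        if tok in ("name", "resname", "element", "role"):
            vals = self._values()
            if not vals:
                raise SelectionError(f"{tok!r} needs at least one value", at)
            attr = {"name": self.top.names,
                    "resname": self.top.residue_names,
                    "element": self.top.elements,
                    "role": self.top.roles}[tok]
            mask = np.zeros(self.top.n_atoms, dtype=bool)
            for v in vals:
                if "*" in v or "?" in v:
                    mask |= np.array([fnmatchcase(x, v) for x in attr])
                else:
                    mask |= attr == v
            return mask
        raise SelectionError(f"unknown keyword {tok!r}", at)


def select(topology: Topology, expression: str, label: str | None = None) -> AtomSet:
    """Evaluate a selection expression and return a sorted AtomSet.

    Empty results are allowed; syntax errors raise :class:`SelectionError`
    with the offending character position.
    """
    mask = _Parser(expression, topology).parse()
    return AtomSet(topology, np.nonzero(mask)[0],
                   label=label if label is not None else expression)


def select_one(topology: Topology, expression: str) -> int:
    """Selection that must resolve to exactly one atom; returns its index."""
    s = select(topology, expression)
    if len(s) != 1:
        raise SelectionError(
            f"expected exactly one atom for {expression!r}, got {len(s)}", 0)
    return int(s.indices[0])
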