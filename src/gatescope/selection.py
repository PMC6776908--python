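"""Atom-selection mini-language.

Grammar (case-insensitive keywords)::

    expr    := or_expr
    or_expr := and_expr ( "or" and_expr )*
    and_expr:= not_expr ( "and" not_expr )*
    not_expr:= "not" not_expr | "(" expr ")" | term
    term    := "chain" ID
             | "resid" INT [ "-" INT ]
             | "name" NAME ("," NAME)*
             | "backbone" | "calpha" | "heavy" | "all"

``backbone`` selects atoms named N, CA, C, O; ``calpha`` selects CA;
``heavy`` selects atoms whose element is not hydrogen.  Resolution is
deterministic: indices come back in structure order.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np

from .model import Structure

__all__ = ["Selection", "SelectionSyntaxError", "resolve_selection"]

BACKBONE_NAMES = ("N", "CA", "C", "O")


class SelectionSyntaxError(ValueError):
    """Malformed selection expression."""


@dataclass(frozen=True)
class Selection:
    """A resolved selection: the expression and matching atom indices."""

    expression: str
    indices: tuple[int, ...]

    def __post_init__(self) -> None:
        idx = self.indices
        if any(b <= a for a, b in zip(idx, idx[1:])):
            raise ValueError("selection indices must be strictly increasing")

    def __len__(self) -> int:
        return len(self.indices)

    @property
    def index_array(self) -> np.ndarray:
        return np.asarray(self.indices, dtype=int)


_TOKEN_RE = re.compile(r"\s*([()]|,|-|[A-Za-z0-9_'*]+)")


def _tokenize(expression: str) -> list[str]:
    tokens: list[str] = []
    pos = 0
    while pos < len(expression):
        m = _TOKEN_RE.match(expression, pos)
        if m is None:
            raise SelectionSyntaxError(
                f"unexpected character {expression[pos]!r} at position {pos}"
            )
        tokens.append(m.group(1))
        pos = m.end()
    return tokens


class _Parser:
    def __init__(self, tokens: list[str], structure: Structure):
        self.tokens = tokens
        self.pos = 0
        self.structure = structure

    def peek(self) -> str | None:
        return self.tokens[self.pos] if self.pos < len(self.tokens) else None

    def next(self) -> str:
        tok = self.peek()
        if tok is None:
            raise SelectionSyntaxError("unexpected end of expression")
        self.pos += 1
        return tok

    # -- grammar ---------------------------------------------------------
    def parse(self) -> np.ndarray:
        mask = self.or_expr()
        if self.peek() is not None:
            raise SelectionSyntaxError(f"unexpected token {self.peek()!r}")
        return mask

    def or_expr(self) -> np.ndarray:
        mask = self.and_expr()
        while self.peek() is not None and self.peek().lower() == "or":
            self.next()
            mask = mask | self.and_expr()
        return mask

    def and_expr(self) -> np.ndarray:
        mask = self.not_expr()
        while self.peek() is not None and self.peek().lower() == "and":
            self.next()
            mask = mask & self.not_expr()
        return mask

    def not_expr(self) -> np.ndarray:
        tok = self.peek()
        if tok is None:
            raise SelectionSyntaxError("unexpected end of expression")
        if tok.lower() == "not":
            self.next()
            return ~self.not_expr()
        if tok == "(":
            self.next()
            mask = self.or_expr()
            closing = self.next()
            if closing != ")":
                raise SelectionSyntaxError(f"expected ')', got {closing!r}")
            return mask
        return self.term()

    def term(self) -> np.ndarray:
        atoms = self.structure.atoms
        tok = self.next().lower()
        if tok == "chain":
            cid = self.next()
            return np.array([a.chain_id == cid for a in atoms])
        if tok == "resid":
            first = self._int(self.next())
            last = first
            if self.peek() == "-":
                self.next()
                last = self._int(self.next())
            return np.array([first <= a.residue_id <= last for a in atoms])
        if tok == "name":
            names = {self.next().upper()}
            while self.peek() == ",":
                self.next()
                names.add(self.next().upper())
            return np.array([a.name.upper() in names for a in atoms])
        if tok == "backbone":
            return np.array([a.name.upper() in BACKBONE_NAMES for a in atoms])
        if tok == "calpha":
            return np.array([a.name.upper() == "CA" for a in atoms])
        if tok == "heavy":
            return np.array([a.element.upper() not in ("H", "D") for a in atoms])
        if tok == "all":
            return np.ones(len(atoms), dtype=bool)
        raise SelectionSyntaxError(f"unknown selection keyword {tok!r}")

    @staticmethod
    def _int(tok: str) -> int:
        try:
            return int(tok)
        except ValueError:
            raise SelectionSyntaxError(f"expected integer, got {tok!r}") from None


def resolve_selection(structure: Structure, expression: str) -> Selection:
    """Resolve ``expression`` against ``structure``.

    An empty result is legal; callers decide whether that is an error.
    """
    tokens = _tokenize(expression)
    if not tokens:
        raise SelectionSyntaxError("empty selection expression")
    mask = _Parser(tokens, structure).parse()
    indices = tuple(int(i) for i in np.flatnonzero(mask))
    return Selection(expression=expression, indices=indices)
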