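"""A tiny boolean expression language for subgroup filters.

Filters select samples from an annotation table using expressions over its
columns, e.g. ``"idh1_mut & !codel_1p19q"`` or
``"true_subtype == mesenchymal & !idh1_mut"``.  Grammar (no host-language
eval; ``!`` binds tightest, then ``&``, then ``|``)::

    expr    := or
    or      := and ('|' and)*
    and     := unary ('&' unary)*
    unary   := '!' unary | '(' expr ')' | atom
    atom    := IDENT ('==' VALUE)?

A bare IDENT names a boolean column; ``IDENT == VALUE`` compares a column to
a literal (string or number).
"""

from __future__ import annotations

import re

import pandas as pd

__all__ = ["parse_filter"]

_TOKEN = re.compile(r"\s*(==|[()&|!]|[^\s()&|!=]+)")


def _tokenize(expr: str) -> list[str]:
    tokens, pos = [], 0
    while pos < len(expr):
        m = _TOKEN.match(expr, pos)
        if not m:
            raise ValueError(f"cannot tokenize filter at position {pos}: {expr!r}")
        tokens.append(m.group(1))
        pos = m.end()
    return tokens


class _Parser:
    def __init__(self, tokens: list[str], table: pd.DataFrame):
        self.tokens = tokens
        self.pos = 0
        self.table = table

    def peek(self):
        return self.tokens[self.pos] if self.pos < len(self.tokens) else None

    def take(self):
        tok = self.peek()
        self.pos += 1
        return tok

    def expr(self) -> pd.Series:
        left = self.and_()
        while self.peek() == "|":
            self.take()
            left = left | self.and_()
        return left

    def and_(self) -> pd.Series:
        left = self.unary()
        while self.peek() == "&":
            self.take()
            left = left & self.unary()
        return left

    def unary(self) -> pd.Series:
        tok = self.peek()
        if tok == "!":
            self.take()
            return ~self.unary()
        if tok == "(":
            self.take()
            inner = self.expr()
            if self.take() != ")":
                raise ValueError("unbalanced parentheses in filter")
            return inner
        return self.atom()

    def atom(self) -> pd.Series:
        name = self.take()
        if name is None or name in "()&|!" or name == "==":
            raise ValueError(f"unexpected token {name!r} in filter")
        if name not in self.table.columns:
            raise KeyError(f"unknown annotation column {name!r}")
        col = self.table[name]
        if self.peek() == "==":
            self.take()
            value = self.take()
            if value is None:
                raise ValueError("missing value after '=='")
            try:
                value = type(col.iloc[0])(value) if len(col) else value
            except (TypeError, ValueError):
                pass
            return col == value
        return col.astype(bool)


def parse_filter(expr: str, annotations: pd.DataFrame) -> pd.Series:
    """Evaluate a filter expression to a boolean Series over the samples."""
    tokens = _tokenize(expr)
    if not tokens:
        raise ValueError("empty filter expression")
    parser = _Parser(tokens, annotations)
    mask = parser.expr()
    if parser.peek() is not None:
        raise ValueError(f"trailing tokens in filter: {parser.tokens[parser.pos:]}")
    return mask.astype(bool)
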