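"""Molecular formulae as exact compositions, element combinations, and
arranged formulae.

A :class:`Formula` is a mapping ``element symbol -> coefficient`` with
positive rational coefficients (atoms per formula unit).  Coefficients are
kept as exact :class:`fractions.Fraction` so that formulae rescaled to a
historical atomic-weight system never lose precision; integers are the
normal case and are rendered without denominators.

Canonical text rendering lists element symbols in lexicographic order with
coefficient 1 omitted ("H2O", "BrCH3", "O7/3" for a rational coefficient).

An *arranged formula* is the canonical rendering after replacing one
element's symbol with the placeholder ``X`` and re-sorting; it is the unit
of the substitutability comparison between elements.  ``X`` sorts as the
literal letter X (between W and Y).  Arranged formulae are plain strings
compared only for equality.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from fractions import Fraction
from typing import Iterator, Mapping

from .periodic import PLACEHOLDER, is_element

__all__ = [
    "Formula",
    "FormulaError",
    "Substance",
    "parse_formula",
    "combination_of",
    "arrange",
    "substitute_placeholder",
]


class FormulaError(ValueError):
    """Raised for malformed or chemically unknown formula text."""


# symbol, then optional coefficient: integer or p/q rational
_TOKEN = re.compile(r"([A-Z][a-z]?)(\d+(?:/\d+)?)?")


def _render_coeff(c: Fraction) -> str:
    if c == 1:
        return ""
    if c.denominator == 1:
        return str(c.numerator)
    return f"{c.numerator}/{c.denominator}"


class Formula(Mapping[str, Fraction]):
    """Immutable composition mapping element symbol -> positive coefficient."""

    __slots__ = ("_comp", "_canonical", "_arranged_cache")

    def __init__(self, composition: Mapping[str, int | Fraction]):
        comp: dict[str, Fraction] = {}
        for sym, coeff in composition.items():
            if not is_element(sym):
                raise FormulaError(f"unknown element symbol: {sym!r}")
            c = Fraction(coeff)
            if c <= 0:
                raise FormulaError(f"non-positive coefficient for {sym}: {coeff}")
            comp[sym] = c
        if not comp:
            raise FormulaError("formula must contain at least one element")
        self._comp = dict(sorted(comp.items()))
        self._canonical = "".join(
            sym + _render_coeff(c) for sym, c in self._comp.items()
        )
        self._arranged_cache: dict[str, str] = {}

    # -- Mapping protocol -------------------------------------------------
    def __getitem__(self, sym: str) -> Fraction:
        return self._comp[sym]

    def __iter__(self) -> Iterator[str]:
        return iter(self._comp)

    def __len__(self) -> int:
        return len(self._comp)

    # -- identity ---------------------------------------------------------
    def __eq__(self, other: object) -> bool:
        if isinstance(other, Formula):
            return self._comp == other._comp
        return NotImplemented

    def __hash__(self) -> int:
        return hash(self._canonical)

    def __repr__(self) -> str:
        return f"Formula({self._canonical!r})"

    # -- domain operations -------------------------------------------------
    @property
    def elements(self) -> tuple[str, ...]:
        """Element symbols, lexicographically sorted."""
        return tuple(self._comp)

    def render(self) -> str:
        """Canonical text: lexicographic symbols, coefficient 1 omitted."""
        return self._canonical

    @property
    def combination(self) -> str:
        """Element combination: concatenated sorted symbols, coefficients ignored."""
        return "".join(self._comp)

    def arrange(self, element: str) -> str:
        """Arranged formula with *element* replaced by the placeholder X.

        Coefficients are preserved and all symbols (including X) are
        lexicographically re-sorted.  Raises :class:`FormulaError` when the
        element does not occur in the formula.
        """
        cached = self._arranged_cache.get(element)
        if cached is not None:
            return cached
        if element not in self._comp:
            raise FormulaError(
                f"element {element!r} does not occur in {self._canonical}"
            )
        parts = sorted(
            (PLACEHOLDER if sym == element else sym, c)
            for sym, c in self._comp.items()
        )
        text = "".join(sym + _render_coeff(c) for sym, c in parts)
        self._arranged_cache[element] = text
        return text


def parse_formula(text: str) -> Formula:
    """Parse a plain concatenated composition string into a :class:`Formula`.

    Accepts symbols with optional positive integer or ``p/q`` rational
    coefficients ("H2SO4", "Fe2O3", "O7/3"); duplicate symbols are merged
    ("OO" -> O2).  Parsing is case-sensitive; no Hill ordering is assumed.
    """
    if not text:
        raise FormulaError("empty formula string")
    comp: dict[str, Fraction] = {}
    pos = 0
    while pos < len(text):
        m = _TOKEN.match(text, pos)
        if m is None or not is_element(m.group(1)):
            raise FormulaError(
                f"unrecognised token at {text[pos:pos + 3]!r} in formula {text!r}"
            )
        sym = m.group(1)
        coeff = Fraction(m.group(2)) if m.group(2) else Fraction(1)
        comp[sym] = comp.get(sym, Fraction(0)) + coeff
        pos = m.end()
    return Formula(comp)


def combination_of(f: Formula) -> str:
    """Element combination of *f* (e.g. ``H2SO4`` -> ``"HOS"``)."""
    return f.combination


def arrange(f: Formula, element: str) -> str:
    """Arranged formula of *f* with *element* replaced by X (see Formula.arrange)."""
    return f.arrange(element)


def substitute_placeholder(arranged: str, element: str) -> Formula:
    """Invert :func:`arrange`: put *element* back in place of the X placeholder.

    Useful for round-trip checks and for the naive substitute-and-look-up
    reading of the similarity measure.
    """
    comp: dict[str, Fraction] = {}
    pos = 0
    while pos < len(arranged):
        m = _TOKEN.match(arranged, pos)
        if m is None:
            raise FormulaError(f"bad arranged formula {arranged!r}")
        sym = m.group(1)
        if sym == PLACEHOLDER:
            sym = element
        elif not is_element(sym):
            raise FormulaError(f"unknown symbol {sym!r} in {arranged!r}")
        coeff = Fraction(m.group(2)) if m.group(2) else Fraction(1)
        comp[sym] = comp.get(sym, Fraction(0)) + coeff
        pos = m.end()
    return Formula(comp)


@dataclass(frozen=True)
class Substance:
    """One substance record: opaque id, composition formula, first-report year.

    Distinct substances may share a formula (isomers, allotropes,
    polymorphs); they are kept as distinct records, which is what makes the
    arranged-formula profiles multisets.
    """

    id: str
    formula: Formula = field(compare=False)
    first_year: int = field(compare=False)
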