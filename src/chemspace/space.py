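"""Year-indexed cumulative chemical spaces and their growth/diversity statistics.

The *chemical space* is the cumulative set of substances known up to a
given year.  A :class:`ChemicalSpace` holds substance records over a study
window and supports cumulative snapshots; the free functions compute the
combinatorial statistics used to describe its growth: how many element
combinations are theoretically possible, which fraction is realized, and
how substances distribute over elements and combinations.
"""

from __future__ import annotations

import math
from collections import Counter
from fractions import Fraction
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

import pandas as pd

from .formula import Substance, parse_formula

__all__ = [
    "ChemicalSpace",
    "read_substances",
    "write_substances",
    "elements_known",
    "theo_combinations",
    "theo_total",
    "realized_fraction",
    "combination_coverage",
    "element_span",
    "combination_span",
    "year_stats",
    "combination_counts",
]


class ChemicalSpace:
    """Cumulative collection of substances over a [first_year, last_year] window."""

    def __init__(
        self,
        substances: Iterable[Substance],
        window: tuple[int, int] | None = None,
    ):
        subs = list(substances)
        if not subs:
            raise ValueError("a chemical space needs at least one substance")
        ids = [s.id for s in subs]
        if len(set(ids)) != len(ids):
            dup = next(i for i, c in Counter(ids).items() if c > 1)
            raise ValueError(f"duplicate substance id: {dup!r}")
        years = [s.first_year for s in subs]
        if window is None:
            window = (min(years), max(years))
        lo, hi = window
        if lo > hi:
            raise ValueError(f"invalid window {window}")
        outside = [s.id for s in subs if not lo <= s.first_year <= hi]
        if outside:
            raise ValueError(
                f"substances outside window {window}: {outside[:5]}"
            )
        self._substances = subs
        self.window = (lo, hi)

    # -- container protocol ----------------------------------------------
    def __len__(self) -> int:
        return len(self._substances)

    def __iter__(self) -> Iterator[Substance]:
        return iter(self._substances)

    @property
    def substances(self) -> list[Substance]:
        return list(self._substances)

    def __repr__(self) -> str:
        lo, hi = self.window
        return f"<ChemicalSpace {len(self)} substances, {lo}-{hi}>"

    # -- snapshots ---------------------------------------------------------
    def snapshot(self, year: int) -> "ChemicalSpace":
        """Substances first reported in or before *year* (cumulative)."""
        lo, hi = self.window
        if not lo <= year <= hi:
            raise ValueError(f"year {year} outside study window {self.window}")
        return ChemicalSpace(
            [s for s in self._substances if s.first_year <= year],
            window=(lo, year),
        )

    def years(self) -> list[int]:
        """Sorted distinct first-report years present in the space."""
        return sorted({s.first_year for s in self._substances})

    def elements(self) -> set[str]:
        """Elements occurring in at least one substance."""
        out: set[str] = set()
        for s in self._substances:
            out.update(s.formula.elements)
        return out

    def combinations(self) -> Counter:
        """Multiplicity of each distinct element combination (substance counts)."""
        return Counter(s.formula.combination for s in self._substances)

    # -- tabular I/O --------------------------------------------------------
    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "id": [s.id for s in self._substances],
                "formula": [s.formula.render() for s in self._substances],
                "year": [s.first_year for s in self._substances],
            }
        )

    @classmethod
    def from_frame(
        cls,
        frame: pd.DataFrame,
        window: tuple[int, int] | None = None,
        record_filter=None,
    ) -> "ChemicalSpace":
        """Build a space from an id/formula/year table.

        ``record_filter`` is an optional predicate ``(id, Formula, year) ->
        bool`` through which curation rules can be plugged in; records
        failing it are dropped.
        """
        subs = []
        for row in frame.itertuples(index=False):
            f = parse_formula(str(row.formula))
            year = int(row.year)
            if record_filter is not None and not record_filter(str(row.id), f, year):
                continue
            subs.append(Substance(str(row.id), f, year))
        return cls(subs, window=window)


def read_substances(
    path: str | Path,
    window: tuple[int, int] | None = None,
    record_filter=None,
) -> ChemicalSpace:
    """Load a delimited substance table (columns id, formula, year).

    Comma and tab delimiters are auto-detected.
    """
    frame = pd.read_csv(path, sep=None, engine="python")
    missing = {"id", "formula", "year"} - set(frame.columns)
    if missing:
        raise ValueError(f"substance table missing columns: {sorted(missing)}")
    return ChemicalSpace.from_frame(frame, window=window, record_filter=record_filter)


def write_substances(space: ChemicalSpace, path: str | Path) -> None:
    space.to_frame().to_csv(path, index=False)


def elements_known(
    space: ChemicalSpace,
    year: int,
    discovery_table: Mapping[str, int] | None = None,
) -> set[str]:
    """Elements known by *year*.

    With a ``discovery_table`` (element -> discovery year, external
    scholarship) the table wins: an element is known iff its discovery year
    is <= *year*.  Without one, occurrence in the cumulative snapshot is
    used — computable from the data alone.
    """
    if discovery_table is not None:
        return {e for e, y in discovery_table.items() if y <= year}
    return space.snapshot(year).elements()


def theo_combinations(n: int, s: int) -> int:
    """Number of element combinations of size *s* from *n* elements: C(n, s)."""
    if s < 0 or n < 0:
        raise ValueError("n and s must be non-negative")
    if s > n:
        raise ValueError(f"combination size {s} exceeds element count {n}")
    return math.comb(n, s)

def theo_total(n: int) -> int:
    """Total theoretical combinations of >=2 elements: sum_{s=2}^{n} C(n,s) = 2^n - n - 1.

    A rough upper bound on chemical diversity that disregards valency and
    compound stability.
    """
    if n < 2:
        raise ValueError("at least two elements are required")
    return 2**n - n - 1


def realized_fraction(
    space: ChemicalSpace,
    year: int,
    s: int,
    discovery_table: Mapping[str, int] | None = None,
    count: str = "combinations",
) -> Fraction:
    """Fraction of theoretically possible size-*s* combinations observed by *year*.

    The numerator counts distinct observed combinations of size *s*
    (``count="combinations"``, the default); ``count="substances"`` instead
    counts substances whose combination has size *s* — the alternative
    reading of the realized/theoretical ratio.
    """
    known = elements_known(space, year, discovery_table)
    n = len(known)
    if n < s:
        raise ValueError(f"only {n} elements known by {year}, need >= {s}")
    theo = theo_combinations(n, s)
    if theo == 0:
        raise ValueError("no theoretical combinations of this size")
    snap = space.snapshot(year)
    if count == "combinations":
        observed = len({c for c in snap.combinations() if _comb_size(c) == s})
    elif count == "substances":
        observed = sum(1 for sub in snap if len(sub.formula) == s)
    else:
        raise ValueError(f"unknown count mode {count!r}")
    return Fraction(observed, theo)


def _comb_size(combination: str) -> int:
    # combinations are concatenations of 1-2 letter symbols; count capitals
    return sum(1 for ch in combination if ch.isupper())


def combination_coverage(space: ChemicalSpace, year: int, p: float) -> Fraction:
    """Percent of combinations needed to cover at least *p* percent of substances.

    Combinations are accumulated in descending order of substance count
    (ties broken lexicographically by combination string); returns
    100 * k / (total distinct combinations) for the minimal such k.
    """
    if not 0 < p <= 100:
        raise ValueError("p must be in (0, 100]")
    snap = space.snapshot(year)
    counts = snap.combinations()
    total_subs = len(snap)
    need = Fraction(p) * total_subs / 100
    ordered = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
    covered = 0
    for k, (_, c) in enumerate(ordered, start=1):
        covered += c
        if covered >= need:
            return Fraction(100 * k, len(ordered))
    # p <= 100 guarantees the loop returns; guard nonetheless
    raise AssertionError("coverage accumulation failed")


def element_span(space: ChemicalSpace, year: int, element: str) -> Fraction:
    """Fraction of the snapshot's substances containing *element*.

    Spans are nonadditive over elements: one substance counts toward each
    of its elements.
    """
    snap = space.snapshot(year)
    hits = sum(1 for s in snap if element in s.formula)
    return Fraction(hits, len(snap))


def combination_span(space: ChemicalSpace, year: int, combination: str) -> Fraction:
    """Fraction of the snapshot's substances having exactly *combination*."""
    snap = space.snapshot(year)
    hits = sum(1 for s in snap if s.formula.combination == combination)
    return Fraction(hits, len(snap))


def year_stats(
    space: ChemicalSpace,
    discovery_table: Mapping[str, int] | None = None,
) -> pd.DataFrame:
    """Per-year growth table: new/cumulative substances, combinations, elements."""
    lo, hi = space.window
    seen_combs: set[str] = set()
    rows = []
    cum_subs = 0
    for year in range(lo, hi + 1):
        new = [s for s in space if s.first_year == year]
        new_combs = {s.formula.combination for s in new} - seen_combs
        seen_combs.update(new_combs)
        cum_subs += len(new)
        rows.append(
            {
                "year": year,
                "n_new_substances": len(new),
                "n_new_combinations": len(new_combs),
                "n_cum_substances": cum_subs,
                "n_cum_combinations": len(seen_combs),
                "n_elements_known": len(elements_known(space, year, discovery_table))
                if cum_subs
                else 0,
            }
        )
    return pd.DataFrame(rows)


def combination_counts(space: ChemicalSpace, years: Sequence[int] | None = None) -> pd.DataFrame:
    """Long-format cumulative substance counts per combination and year."""
    if years is None:
        years = space.years()
    rows = []
    for year in years:
        for comb, count in sorted(space.snapshot(year).combinations().items()):
            rows.append({"year": year, "combination": comb, "count": count})
    return pd.DataFrame(rows, columns=["year", "combination", "count"])
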