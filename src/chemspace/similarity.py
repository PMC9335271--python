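"""Element-substitutability similarity and yearly maximum-similarity networks.

Similarity between elements follows the idea that two elements are alike
when one can replace the other in known compounds.  Every substance
containing element x contributes one *arranged formula* (its canonical
formula with x replaced by the placeholder X) to x's profile FX, a multiset
because distinct substances (isomers) may yield the same arranged formula.

The similarity of x toward y is

    s(x -> y) = (number of FX entries, with multiplicity, whose arranged
                 formula also occurs in FY) / |FX|

i.e. the probability that a randomly chosen compound of x stays a known
compound when x is replaced by y.  The measure is asymmetric: the numerator
counts FX multiplicities against FY *support membership*, so s(x->y) and
s(y->x) generally differ in both numerator and denominator.

A *system of chemical elements* (SCE) for a year is the directed network
whose edges point from each element to its most similar element(s), with
nodes carrying substance counts and atomic-weight ranks.
"""

from __future__ import annotations

import json
import logging
from collections import Counter, defaultdict
from dataclasses import dataclass
from fractions import Fraction
from pathlib import Path
from typing import Iterable, Mapping

import networkx as nx
import pandas as pd

from .formula import Substance
from .periodic import ATOMIC_WEIGHTS
from .space import ChemicalSpace

__all__ = [
    "ArrangedFormulaMultiset",
    "SimilarityValue",
    "element_profile",
    "profile_similarity",
    "similarity",
    "similarity_matrix",
    "most_similar",
    "sce_network",
    "edge_set",
    "network_to_json",
    "write_graphml",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ArrangedFormulaMultiset:
    """Profile FX of one element: arranged formula -> multiplicity."""

    element: str
    entries: Mapping[str, int]

    @property
    def cardinality(self) -> int:
        """|FX| — the number of substances containing the element."""
        return sum(self.entries.values())

    @property
    def support(self) -> frozenset[str]:
        return frozenset(self.entries)


@dataclass(frozen=True)
class SimilarityValue:
    """Directed similarity s(source -> target) with its exact ratio."""

    source: str
    target: str
    numerator: int
    denominator: int

    @property
    def value(self) -> Fraction:
        return Fraction(self.numerator, self.denominator)

    def __float__(self) -> float:
        return self.numerator / self.denominator


def _profiles(substances: Iterable[Substance]) -> dict[str, Counter]:
    """Arranged-formula profile of every element in *substances*."""
    prof: dict[str, Counter] = {}
    for s in substances:
        for e in s.formula.elements:
            prof.setdefault(e, Counter())[s.formula.arrange(e)] += 1
    return prof


def element_profile(space: ChemicalSpace, year: int, element: str) -> ArrangedFormulaMultiset:
    """Profile FX of *element* in the snapshot at *year*."""
    prof = _profiles(space.snapshot(year))
    if element not in prof:
        raise ValueError(f"element {element!r} absent from the {year} snapshot")
    return ArrangedFormulaMultiset(element, dict(prof[element]))


def profile_similarity(fx: ArrangedFormulaMultiset, fy: ArrangedFormulaMultiset) -> SimilarityValue:
    """s(x -> y) from two profiles: FX multiplicity against FY support."""
    if fx.cardinality == 0:
        raise ValueError(f"empty profile for {fx.element}")
    support = set(fy.entries)
    num = sum(m for af, m in fx.entries.items() if af in support)
    return SimilarityValue(fx.element, fy.element, num, fx.cardinality)


def similarity(space: ChemicalSpace, year: int, x: str, y: str) -> SimilarityValue:
    """Substitutability similarity s(x -> y) in the snapshot at *year*."""
    if x == y:
        raise ValueError("similarity is defined between distinct elements")
    prof = _profiles(space.snapshot(year))
    if x not in prof:
        raise ValueError(f"element {x!r} absent from the {year} snapshot")
    fy = prof.get(y, Counter())
    return profile_similarity(
        ArrangedFormulaMultiset(x, dict(prof[x])),
        ArrangedFormulaMultiset(y, dict(fy)),
    )


def _numerators(prof: Mapping[str, Counter]) -> dict[str, Counter]:
    """All pairwise similarity numerators at once.

    Groups profiles by arranged formula: whenever elements x and y both
    contribute an arranged formula, x's multiplicity of it counts toward
    s(x -> y).  Equivalent to the naive substitute-and-look-up loop but a
    single pass over the arranged-formula groups.
    """
    groups: dict[str, dict[str, int]] = defaultdict(dict)
    for e, counter in prof.items():
        for af, m in counter.items():
            groups[af][e] = m
    num: dict[str, Counter] = defaultdict(Counter)
    for members in groups.values():
        if len(members) < 2:
            continue
        for x, mx in members.items():
            for y in members:
                if x != y:
                    num[x][y] += mx
    return num


def most_similar(space: ChemicalSpace, year: int, x: str) -> frozenset[str]:
    """Argmax set of s(x -> .) over the other elements of the snapshot.

    Empty when the maximum similarity is 0 (no edge is drawn); ties are all
    retained.
    """
    prof = _profiles(space.snapshot(year))
    if x not in prof:
        raise ValueError(f"element {x!r} absent from the {year} snapshot")
    row = _numerators(prof).get(x)
    if not row:
        return frozenset()
    best = max(row.values())
    return frozenset(y for y, n in row.items() if n == best)


def sce_network(
    space: ChemicalSpace,
    year: int,
    weights: Mapping[str, object] | None = None,
) -> nx.DiGraph:
    """Maximum-similarity network (the SCE) of the snapshot at *year*.

    Nodes are all elements with at least one substance, attributed with
    their substance count and their rank in ascending atomic-weight order
    (1-based).  Each element x has a directed edge to every element
    attaining max_y s(x -> y) > 0, weighted by that similarity.

    *weights* maps element -> atomic weight; the modern standard weights
    are the default.  Elements missing from the table keep their node but
    get no rank (logged).
    """
    snap = space.snapshot(year)
    prof = _profiles(snap)
    wtab: Mapping[str, object] = ATOMIC_WEIGHTS if weights is None else weights

    g = nx.DiGraph(year=year)
    counts = {e: sum(c.values()) for e, c in prof.items()}
    ranked = sorted((e for e in prof if e in wtab), key=lambda e: wtab[e])  # type: ignore[arg-type]
    rank = {e: i + 1 for i, e in enumerate(ranked)}
    for e in sorted(prof):
        if e not in wtab:
            logger.warning("element %s missing from weight table; no rank", e)
        g.add_node(
            e,
            substance_count=counts[e],
            weight_rank=rank.get(e, -1),
        )
    num = _numerators(prof)
    for x, row in num.items():
        if not row:
            continue
        best = max(row.values())
        if best == 0:
            continue
        for y, n in row.items():
            if n == best:
                g.add_edge(x, y, weight=n / counts[x], numerator=n, denominator=counts[x])
    return g


def edge_set(network: nx.DiGraph) -> frozenset[tuple[str, str]]:
    """The SCE's directed element pairs, with set semantics."""
    return frozenset(network.edges())


def similarity_matrix(space: ChemicalSpace, year: int) -> pd.DataFrame:
    """Dense s(x -> y) matrix (rows: source x, columns: target y) as floats."""
    prof = _profiles(space.snapshot(year))
    elements = sorted(prof)
    num = _numerators(prof)
    card = {e: sum(c.values()) for e, c in prof.items()}
    data = [
        [num.get(x, Counter()).get(y, 0) / card[x] if x != y else 1.0 for y in elements]
        for x in elements
    ]
    return pd.DataFrame(data, index=elements, columns=elements)


def _shared_arranged(prof: Mapping[str, Counter], x: str, y: str) -> list[str]:
    return sorted(set(prof[x]) & set(prof[y]))


def network_to_json(space: ChemicalSpace, year: int, path: str | Path | None = None) -> dict:
    """JSON edge list of the year's SCE with supporting arranged formulae."""
    snap = space.snapshot(year)
    prof = _profiles(snap)
    g = sce_network(space, year)
    edges = [
        {
            "source": u,
            "target": v,
            "value": d["numerator"] / d["denominator"],
            "numerator": d["numerator"],
            "denominator": d["denominator"],
            "arranged_formulae": _shared_arranged(prof, u, v),
        }
        for u, v, d in sorted(g.edges(data=True))
    ]
    doc = {
        "year": year,
        "nodes": [
            {"element": n, **{k: v for k, v in d.items()}}
            for n, d in sorted(g.nodes(data=True))
        ],
        "edges": edges,
    }
    if path is not None:
        Path(path).write_text(json.dumps(doc, indent=1))
    return doc


def write_graphml(network: nx.DiGraph, path: str | Path) -> None:
    """Export an SCE as GraphML."""
    nx.write_graphml(network, str(path))
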