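"""Cross-year comparison of SCEs: overlap, historical backbone, ubiquity.

Three questions about the yearly maximum-similarity networks are answered
here:

* how much of one year's network survives in another year's
  (:func:`network_overlap`, :func:`overlap_matrix`);
* which most-similar pairs recur in most of the yearly networks over the
  window in which both elements existed — the *backbone*
  (:func:`backbone`);
* how small a random fraction of the chemical space suffices to still
  detect a given most-similar relationship — its *ubiquity*, estimated by
  repeated subsampling (:func:`ubiquity`).
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass
from fractions import Fraction
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .similarity import _numerators, _profiles, edge_set
from .space import ChemicalSpace

__all__ = [
    "BackboneEdge",
    "network_overlap",
    "overlap_matrix",
    "backbone",
    "backbone_pairs",
    "ubiquity",
]

logger = logging.getLogger(__name__)

Edges = frozenset  # directed pairs (source, target)


def _as_edges(n: "nx.DiGraph | Iterable[tuple[str, str]]") -> frozenset[tuple[str, str]]:
    if isinstance(n, nx.DiGraph):
        return edge_set(n)
    return frozenset(n)


def network_overlap(nx_edges, ny_edges) -> Fraction:
    """Fraction of Nx's directed pairs also present in Ny: |Nx ∩ Ny| / |Nx|."""
    a = _as_edges(nx_edges)
    b = _as_edges(ny_edges)
    if not a:
        raise ValueError("overlap undefined for an empty source edge set")
    return Fraction(len(a & b), len(a))


def overlap_matrix(networks: Mapping[int, nx.DiGraph]) -> pd.DataFrame:
    """Year-by-year SCE overlap: entry (row r, col c) is the overlap from the
    column-year network toward the row-year network.

    Row y therefore shows how similar every year's SCE is to the SCE of
    year y.  The diagonal is 1 by convention.
    """
    years = sorted(networks)
    if len(years) < 2:
        raise ValueError("need at least two yearly networks")
    edges = {y: edge_set(networks[y]) for y in years}
    data = np.ones((len(years), len(years)))
    for i, r in enumerate(years):
        for j, c in enumerate(years):
            if i == j:
                continue
            if not edges[c]:
                data[i, j] = float("nan")
                continue
            data[i, j] = len(edges[c] & edges[r]) / len(edges[c])
    return pd.DataFrame(data, index=years, columns=years)


@dataclass(frozen=True)
class BackboneEdge:
    """A recurrent most-similar pair with its observation window."""

    source: str
    target: str
    first_year: int          # first year both elements appear in an SCE
    frequency: int           # number of SCEs containing the edge
    ubiquity_percent: float  # 100 * frequency / (end_year - first_year)


def backbone(
    networks: Mapping[int, nx.DiGraph],
    threshold: float = 60.0,
    end_year: int | None = None,
) -> list[BackboneEdge]:
    """Directed edges appearing in more than *threshold* percent of the SCEs
    over the window in which both endpoints existed.

    For an edge i->j first possible in year y (the first SCE containing
    both i and j) and present in f SCEs, the recurrence percentage is
    100 * f / (end_year - y).  Edges with y == end_year have a zero-width
    window and are excluded (logged).  The comparison is strict
    ("more than").
    """
    years = sorted(networks)
    if not years:
        raise ValueError("no networks supplied")
    if end_year is None:
        end_year = years[-1]
    if years != list(range(years[0], years[-1] + 1)) or years[-1] != end_year:
        raise ValueError(
            f"networks must cover a contiguous year range ending at {end_year}"
        )
    first_node_year: dict[str, int] = {}
    freq: Counter = Counter()
    first_pair_year: dict[tuple[str, str], int] = {}
    for y in years:
        g = networks[y]
        for n in g.nodes:
            first_node_year.setdefault(n, y)
        for e in g.edges():
            freq[e] += 1
    out = []
    for (i, j), f in sorted(freq.items()):
        y = max(first_node_year[i], first_node_year[j])
        first_pair_year[(i, j)] = y
        if y == end_year:
            logger.warning("edge %s->%s first possible in %s: zero-width window, excluded", i, j, y)
            continue
        pct = 100.0 * f / (end_year - y)
        if pct > threshold:
            out.append(BackboneEdge(i, j, y, f, pct))
    return out


def backbone_pairs(edges: Iterable[BackboneEdge]) -> set[frozenset[str]]:
    """Unordered backbone pairs: a pair qualifies when either direction does."""
    return {frozenset((e.source, e.target)) for e in edges}


def _max_sim_edges(substances) -> frozenset[tuple[str, str]]:
    """Most-similar edges of a (sub)space, without building a graph object."""
    prof = _profiles(substances)
    num = _numerators(prof)
    edges = set()
    for x, row in num.items():
        if not row:
            continue
        best = max(row.values())
        if best == 0:
            continue
        edges.update((x, y) for y, n in row.items() if n == best)
    return frozenset(edges)


def ubiquity(
    space: ChemicalSpace,
    year: int,
    sample_sizes: Sequence[int] = tuple(range(5, 100, 5)),
    reps: int = 100,
    seed: int = 0,
) -> pd.DataFrame:
    """How often each full-space most-similar edge survives random subsampling.

    For every sample size s (percent of the snapshot), *reps* uniform
    substance subsamples are drawn without replacement, the max-similarity
    relations are rebuilt on each, and the appearances of every full-space
    edge are counted.  Low required sample sizes mean the similarity is
    spread over the whole space (ubiquitous); similarities confined to a
    small region need large samples.

    Each (size, replicate) gets its own RNG stream derived from the master
    seed, so adding sample sizes or replicates never perturbs existing
    draws.  Returns a long-format table (source, target, sample_pct, count,
    reps, seed).
    """
    snap = space.snapshot(year)
    subs = snap.substances
    n = len(subs)
    full = sorted(_max_sim_edges(subs))
    rows = []
    for s in sample_sizes:
        k = int(round(n * s / 100))
        if k == 0:
            logger.warning("sample size %d%% of %d substances is empty; skipped", s, n)
            continue
        counts = Counter()
        for rep in range(reps):
            rng = np.random.default_rng([seed, int(s), rep])
            idx = rng.choice(n, size=k, replace=False)
            sample_edges = _max_sim_edges([subs[i] for i in idx])
            counts.update(e for e in full if e in sample_edges)
        for u, v in full:
            rows.append(
                {
                    "source": u,
                    "target": v,
                    "sample_pct": s,
                    "count": counts.get((u, v), 0),
                    "reps": reps,
                    "seed": seed,
                }
            )
    return pd.DataFrame(
        rows, columns=["source", "target", "sample_pct", "count", "reps", "seed"]
    )
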