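"""Chemical spaces as seen through historical atomic-weight systems.

Nineteenth-century chemists measured composition as mass fractions and
converted them to formulae through assumed atomic weights, so each weight
system spans its own chemical space.  Modern formulae can be rescaled to a
chemist's system: for element e with modern weight W(e) and the chemist's
weight A(e) (both taken relative to a reference element, hydrogen unless
stated), the coefficient of e is multiplied by the simplest fraction
approximating the ratio

    (W/A)(e) = (W(e)/W(H)) / (A(e)/A(H))

within a relative-error tolerance τ.  "Simplest" is resolved through the
Farey sequence: the approximant with the smallest denominator meeting the
tolerance, ties broken by smaller error.  Ratios above 1 are split as
α + β with integer α and β in (0, 1], and β is approximated.

The resulting rescaled snapshot yields an SCE that can be scored against a
reference-year SCE: the true-positive rate measures how much of the
reference structure the chemist's weights preserve, the false-positive
rate the share of transient similarities they introduce.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from fractions import Fraction
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

from .formula import Formula
from .periodic import ATOMIC_WEIGHTS
from .similarity import edge_set, sce_network
from .space import ChemicalSpace

__all__ = [
    "WeightTable",
    "RescaleCoefficient",
    "RetroSCEScore",
    "UntranslatableElement",
    "TAU_SWEEP",
    "farey_best",
    "rescale_coefficient",
    "rescale_formula",
    "retro_space",
    "retro_scores",
    "retro_score_sweep",
    "ordering_agreement",
    "read_weight_tables",
    "write_weight_table",
]

logger = logging.getLogger(__name__)

#: the 20 relative-error tolerances swept by default: 1% ... 20%
TAU_SWEEP: tuple[Fraction, ...] = tuple(Fraction(i, 100) for i in range(1, 21))


class UntranslatableElement(KeyError):
    """Element absent from a chemist's weight table."""


@dataclass(frozen=True)
class WeightTable:
    """One chemist's atomic-weight system.

    ``weights`` maps element symbol -> A(e) on the chemist's own scale;
    ratios are always taken relative to ``reference`` (hydrogen unless the
    table states otherwise), so the scale itself cancels.
    """

    chemist: str
    year: int
    weights: Mapping[str, Fraction]
    reference: str = "H"

    def __post_init__(self):
        if self.reference not in self.weights:
            raise ValueError(
                f"reference element {self.reference!r} missing from table "
                f"{self.chemist!r}"
            )
        bad = [e for e, w in self.weights.items() if Fraction(w) <= 0]
        if bad:
            raise ValueError(f"non-positive weights for {bad}")

    def __contains__(self, element: str) -> bool:
        return element in self.weights

    def relative(self, element: str) -> Fraction:
        """A(e)/A(reference)."""
        if element not in self.weights:
            raise UntranslatableElement(element)
        return Fraction(self.weights[element]) / Fraction(self.weights[self.reference])


def _modern_relative(element: str, modern: Mapping[str, Fraction], reference: str) -> Fraction:
    if element not in modern or reference not in modern:
        raise UntranslatableElement(element)
    return Fraction(modern[element]) / Fraction(modern[reference])


def farey_best(
    r: Fraction | float,
    tau: Fraction | float,
    mode: str = "simplest",
    max_order: int = 200,
) -> Fraction:
    """Best Farey-fraction approximation of r in (0, 1] within tolerance τ.

    ``mode="simplest"`` (default): the fraction p/q with the smallest
    denominator whose relative error |r - p/q| / r is <= τ; among
    equal-denominator candidates the one with minimal error.  The search
    ascends denominator by denominator and always terminates because the
    error of the best order-q approximant vanishes as q grows.

    ``mode="min_error"``: the globally smallest error over all denominators
    up to *max_order*, ties broken by smaller denominator — the alternative
    reading of "simplest fraction minimizing the error".
    """
    r = Fraction(r)
    tau = Fraction(tau)
    if not 0 < r <= 1:
        raise ValueError(f"r must be in (0, 1], got {r}")
    if tau <= 0:
        raise ValueError("tolerance must be positive")

    def best_at(q: int) -> tuple[Fraction, Fraction]:
        # best numerator for denominator q, clamped into (0, 1]
        p = min(max(round(r * q), 1), q)
        cands = {p, min(max(p - 1, 1), q), min(p + 1, q)}
        best_f = min((Fraction(c, q) for c in cands), key=lambda f: abs(r - f))
        return best_f, abs(r - best_f) / r

    if mode == "simplest":
        q = 1
        while True:
            f, err = best_at(q)
            if err <= tau:
                return f
            q += 1
    elif mode == "min_error":
        best: tuple[Fraction, Fraction] | None = None
        for q in range(1, max_order + 1):
            f, err = best_at(q)
            if best is None or err < best[1]:
                best = (f, err)
                if err == 0:
                    break
        assert best is not None
        if best[1] > tau:
            raise ValueError(
                f"no approximant within tolerance {tau} up to order {max_order}"
            )
        return best[0]
    raise ValueError(f"unknown mode {mode!r}")


@dataclass(frozen=True)
class RescaleCoefficient:
    """Multiplier f_A(e) applied to e's stoichiometric coefficients."""

    element: str
    multiplier: Fraction
    tolerance: Fraction
    achieved_error: Fraction
    ratio_wa: Fraction = field(repr=False)  # (W/A)(e)
    ratio_aw: Fraction = field(repr=False)  # (A/W)(e)


def rescale_coefficient(
    element: str,
    table: WeightTable,
    tau: Fraction | float,
    modern: Mapping[str, Fraction] | None = None,
    mode: str = "simplest",
) -> RescaleCoefficient:
    """Farey-approximated multiplier carrying *element* into *table*'s system.

    The multiplier approximates r = (W/A)(e): multiplying modern
    coefficients by it preserves the substance's elemental mass ratios when
    the formula is re-read under the chemist's weights.  For r <= 1 the
    multiplier is the Farey approximant of r; for r = α + β with integer
    α >= 1 it is α plus the approximant of β.  The complementary ratio
    (A/W)(e) is computed and recorded alongside.
    """
    modern = ATOMIC_WEIGHTS if modern is None else modern
    tau = Fraction(tau)
    w_rel = _modern_relative(element, modern, table.reference)
    a_rel = table.relative(element)
    r = w_rel / a_rel
    if r <= 1:
        mult = farey_best(r, tau, mode=mode)
    else:
        alpha = math.floor(r)
        beta = r - alpha
        if beta == 0:
            # integer ratio: exact, written as (α-1) + 1/1
            mult = Fraction(alpha)
        else:
            mult = alpha + farey_best(beta, tau, mode=mode)
    err = abs(r - mult) / r
    return RescaleCoefficient(
        element=element,
        multiplier=mult,
        tolerance=tau,
        achieved_error=err,
        ratio_wa=r,
        ratio_aw=1 / r,
    )


def rescale_formula(
    f: Formula,
    table: WeightTable,
    tau: Fraction | float,
    modern: Mapping[str, Fraction] | None = None,
    mode: str = "simplest",
) -> Formula:
    """Rescale each coefficient of *f* by its element's multiplier and
    normalize to the smallest positive-integer coefficient vector.

    Normalization multiplies by the LCM of the coefficient denominators and
    divides by the GCD of the resulting numerators, so the output is always
    an integer formula and is invariant under scaling of the input.
    Raises :class:`UntranslatableElement` when *table* lacks one of f's
    elements.
    """
    scaled = {
        e: c * rescale_coefficient(e, table, tau, modern=modern, mode=mode).multiplier
        for e, c in f.items()
    }
    lcm = math.lcm(*(c.denominator for c in scaled.values()))
    nums = [int(c * lcm) for c in scaled.values()]
    gcd = math.gcd(*nums)
    return Formula({e: Fraction(c * lcm, gcd) for e, c in scaled.items()})


def reduce_formula(f: Formula) -> Formula:
    """Smallest positive-integer coefficient vector proportional to *f*.

    The retrodictive comparison works on reduced empirical formulae
    throughout (H2O2 -> HO), so that rescaled and unrescaled spaces are
    compared through the same lens; elsewhere in the package formulae are
    used exactly as given.
    """
    lcm = math.lcm(*(c.denominator for c in f.values()))
    nums = [int(c * lcm) for c in f.values()]
    gcd = math.gcd(*nums)
    if lcm == gcd == 1:
        return f
    return Formula({e: Fraction(c * lcm, gcd) for e, c in f.items()})


def _reduced_snapshot(space: ChemicalSpace, year: int) -> ChemicalSpace:
    snap = space.snapshot(year)
    cache: dict[Formula, Formula] = {}
    subs = []
    for s in snap:
        r = cache.get(s.formula)
        if r is None:
            r = reduce_formula(s.formula)
            cache[s.formula] = r
        subs.append(type(s)(s.id, r, s.first_year))
    return ChemicalSpace(subs, window=snap.window)


def retro_space(
    space: ChemicalSpace,
    year: int,
    table: WeightTable,
    tau: Fraction | float,
    modern: Mapping[str, Fraction] | None = None,
) -> ChemicalSpace:
    """The snapshot at *year* - 1 with every formula rescaled to *table*.

    A table published in year y acts on the space known up to y - 1
    inclusive.  Substances containing elements absent from the table are
    dropped (the chemist's system is restricted to his elements); the drop
    count is logged.
    """
    snap = space.snapshot(year - 1)
    modern_tab = ATOMIC_WEIGHTS if modern is None else modern
    # one Farey search per element, not per substance
    mult: dict[str, Fraction] = {
        e: rescale_coefficient(e, table, tau, modern=modern).multiplier
        for e in table.weights
        if e in modern_tab
    }
    kept = []
    dropped = 0
    cache: dict[Formula, Formula] = {}
    for s in snap:
        if any(e not in mult for e in s.formula.elements):
            dropped += 1
            continue
        rescaled = cache.get(s.formula)
        if rescaled is None:
            scaled = {e: c * mult[e] for e, c in s.formula.items()}
            lcm = math.lcm(*(c.denominator for c in scaled.values()))
            nums = [int(c * lcm) for c in scaled.values()]
            gcd = math.gcd(*nums)
            rescaled = Formula({e: Fraction(c * lcm, gcd) for e, c in scaled.items()})
            cache[s.formula] = rescaled
        kept.append(type(s)(s.id, rescaled, s.first_year))
    if dropped:
        logger.info(
            "%s (%d): dropped %d of %d substances with untranslatable elements",
            table.chemist, table.year, dropped, len(snap),
        )
    if not kept:
        raise ValueError(
            f"no substances survive rescaling to {table.chemist!r}'s system"
        )
    return ChemicalSpace(kept, window=snap.window)


@dataclass(frozen=True)
class RetroSCEScore:
    """Agreement of a chemist's SCE with the reference SCE at one tolerance."""

    chemist: str
    tau: Fraction
    tp_rate: float | None  # None when the unperturbed SCE shares no edge with the reference
    fp_rate: float | None  # None when the rescaled SCE is empty
    n_edges: int           # edges of the rescaled (τ) SCE


def retro_scores(
    space: ChemicalSpace,
    year: int,
    table: WeightTable,
    tau: Fraction | float,
    reference_year: int | None = None,
    modern: Mapping[str, Fraction] | None = None,
) -> RetroSCEScore:
    """Score the SCE under *table*'s weights against the reference-year SCE.

    With P the SCE edge set of the plain year-(y-1) snapshot, P_τ that of
    the rescaled snapshot, and P_ref the reference SCE:

        tp_rate = |P_τ ∩ P_ref| / |P ∩ P_ref|
        fp_rate = |P_τ \\ P_ref| / |P_τ|

    A tp_rate of 1 means the chemist's weights are as effective as modern
    ones at recovering the reference structure; fp_rate is the share of
    transient similarities.  Undefined rates are flagged as None.

    All three edge sets are computed on reduced empirical formulae (see
    :func:`reduce_formula`), so that differences reflect the weight system
    and not the normalization step.
    """
    if reference_year is None:
        reference_year = space.window[1]
    p_ref = edge_set(
        sce_network(_reduced_snapshot(space, reference_year), reference_year, weights=modern)
    )
    p_plain = edge_set(
        sce_network(_reduced_snapshot(space, year - 1), year - 1, weights=modern)
    )
    rspace = retro_space(space, year, table, tau, modern=modern)
    p_tau = edge_set(sce_network(rspace, year - 1, weights=table.weights))

    denom_tp = len(p_plain & p_ref)
    if denom_tp == 0:
        logger.warning(
            "%s (%d): unperturbed SCE shares no edge with the %d reference; "
            "tp_rate undefined", table.chemist, table.year, reference_year,
        )
        tp = None
    else:
        tp = len(p_tau & p_ref) / denom_tp
    fp = len(p_tau - p_ref) / len(p_tau) if p_tau else None
    return RetroSCEScore(table.chemist, Fraction(tau), tp, fp, len(p_tau))


def retro_score_sweep(
    space: ChemicalSpace,
    year: int,
    table: WeightTable,
    taus: Sequence[Fraction] = TAU_SWEEP,
    reference_year: int | None = None,
    modern: Mapping[str, Fraction] | None = None,
) -> pd.DataFrame:
    """Tolerance sweep of :func:`retro_scores` as a tidy table."""
    rows = []
    for tau in taus:
        sc = retro_scores(space, year, table, tau, reference_year, modern=modern)
        rows.append(
            {
                "chemist": sc.chemist,
                "tau": float(sc.tau),
                "tp_rate": sc.tp_rate,
                "fp_rate": sc.fp_rate,
                "n_edges": sc.n_edges,
            }
        )
    return pd.DataFrame(rows)


def ordering_agreement(
    a: WeightTable | Mapping[str, Fraction],
    b: WeightTable | Mapping[str, Fraction],
) -> Fraction:
    """Pairwise concordance of the element orderings of two weight systems.

    Over all unordered pairs of shared elements, the fraction ranked in the
    same order by both tables.  Pairs tied in exactly one table count as
    discordant; pairs tied in both count as concordant.
    """
    wa = a.weights if isinstance(a, WeightTable) else a
    wb = b.weights if isinstance(b, WeightTable) else b
    shared = sorted(set(wa) & set(wb))
    if len(shared) < 2:
        raise ValueError("need at least two shared elements")
    concordant = 0
    total = 0
    for i, x in enumerate(shared):
        for y in shared[i + 1:]:
            da = Fraction(wa[x]) - Fraction(wa[y])
            db = Fraction(wb[x]) - Fraction(wb[y])
            sa = (da > 0) - (da < 0)
            sb = (db > 0) - (db < 0)
            concordant += sa == sb
            total += 1
    return Fraction(concordant, total)


def read_weight_tables(path: str | Path) -> list[WeightTable]:
    """Load weight tables from delimited text.

    Columns: chemist, year, element, weight, reference_element (the latter
    constant within a chemist).  Comma and tab delimiters are
    auto-detected; weights are parsed exactly from their decimal or p/q
    text.  Returns one table per (chemist, year) group.
    """
    frame = pd.read_csv(path, sep=None, engine="python", dtype=str)
    required = {"chemist", "year", "element", "weight"}
    missing = required - set(frame.columns)
    if missing:
        raise ValueError(f"weight table missing columns: {sorted(missing)}")
    tables = []
    for (chemist, year), grp in frame.groupby(["chemist", "year"], sort=True):
        refs = (
            set(grp["reference_element"].dropna())
            if "reference_element" in grp
            else set()
        )
        if len(refs) > 1:
            raise ValueError(f"conflicting reference elements for {chemist}: {refs}")
        ref = refs.pop() if refs else "H"
        weights = {
            str(r.element): Fraction(str(r.weight)) for r in grp.itertuples(index=False)
        }
        tables.append(WeightTable(str(chemist), int(year), weights, reference=ref))
    return tables


def write_weight_table(table: WeightTable, path: str | Path) -> None:
    pd.DataFrame(
        {
            "chemist": table.chemist,
            "year": table.year,
            "element": list(table.weights),
            "weight": [str(Fraction(w)) for w in table.weights.values()],
            "reference_element": table.reference,
        }
    ).to_csv(path, index=False)
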