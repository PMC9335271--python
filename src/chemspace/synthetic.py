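"""Synthetic chemical spaces with planted ground truth.

The historical corpus behind this kind of analysis is proprietary, so every
pipeline stage is exercised on generated spaces that emulate its gross
statistics: exponential growth of new substances per year, staged
introduction of elements, reuse of element combinations after a configured
turning year (decreasing diversity), an "organic" bias toward a designated
element subset, combination sizes of at most eight elements, and isomers
sharing one empirical formula.

Substances are built from *templates*: a combination of families, one
fixed member and coefficient per family, and one designated *slot* family.
A template event emits a cohort of substances, one per included slot-family
member, identical except for the slot element.  Replacing the slot element
with the placeholder therefore yields the same arranged formula for every
cohort member — substitutability, not abundance, is what plants the
within-family similarity structure.

Slot coefficients are even and globally unique per template while fixed
coefficients are odd, so an arranged formula can only ever match another
arranged formula from the same template, at the slot position.  (Arranging
away a fixed element leaves the slot member's unique even coefficient in
the rest; arranging away the slot gives the placeholder an even
coefficient that no fixed position can produce.)  This keeps the planted
signal exact: cross-family similarities are structurally zero and
equally-established siblings tie exactly at the maximum.  The price is
that slot coefficients act as template tags rather than chemistry; the
generator emulates the space's combinatorial structure, not stoichiometric
realism.

The planted truth records the max-similarity pairs this construction
implies: within a family, element x is expected to point at every sibling
y introduced no later than x (siblings introduced later co-occur with x in
strictly fewer cohorts and cannot attain the maximum).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from fractions import Fraction
from typing import Mapping, Sequence

import numpy as np

from .formula import Formula, Substance, parse_formula
from .periodic import ATOMIC_WEIGHTS
from .retrodiction import WeightTable
from .space import ChemicalSpace

__all__ = [
    "GeneratorConfig",
    "PlantedTruth",
    "generate",
    "toy_space",
    "TOY_EXPECTED_SIMILARITIES",
    "TOY_EXPECTED_EDGES",
    "perturb_weights",
    "recovered_fraction",
    "default_config",
]


@dataclass(frozen=True)
class GeneratorConfig:
    """Study conditions for one synthetic space.

    ``element_intro`` maps element -> introduction year; ``families``
    partitions the roster into groups whose members substitute for each
    other (every family needs at least two members, otherwise no
    substitution can be planted).  New-substance counts per year are
    Poisson with mean ``initial_rate * growth_base**(year - start_year)``.
    ``template_fill`` is the probability that each available slot-family
    member joins a cohort (1.0 = full template sharing); ``reuse_prob`` /
    ``reuse_after_prob`` control how often an existing template is reused
    instead of a new one being created, before/after ``reuse_year`` —
    raising reuse after the turning year is what bends combination
    diversity downward.  ``organic_elements`` get ``organic_weight``-fold
    sampling weight after ``organic_year``.
    """

    start_year: int = 1800
    end_year: int = 1868
    element_intro: Mapping[str, int] = field(default_factory=dict)
    families: Sequence[Sequence[str]] = ()
    initial_rate: float = 5.0
    growth_base: float = 1.078
    size_dist: Mapping[int, float] = field(
        default_factory=lambda: {1: 0.04, 2: 0.30, 3: 0.34, 4: 0.18,
                                 5: 0.08, 6: 0.03, 7: 0.02, 8: 0.01}
    )
    max_coeff: int = 9
    template_fill: float = 1.0
    isomer_rate: float = 0.05
    reuse_prob: float = 0.2
    reuse_after_prob: float = 0.6
    reuse_year: int = 1830
    organic_year: int | None = 1830
    organic_elements: frozenset[str] = frozenset()
    organic_weight: float = 4.0
    seed: int = 0

    def __post_init__(self):
        if self.start_year > self.end_year:
            raise ValueError("start_year must not exceed end_year")
        if self.growth_base <= 1:
            raise ValueError("growth_base must exceed 1 for an exponential regime")
        roster = set(self.element_intro)
        fam_members = [m for fam in self.families for m in fam]
        if len(fam_members) != len(set(fam_members)):
            raise ValueError("families overlap")
        if set(fam_members) != roster:
            raise ValueError("family partition must cover the element roster exactly")
        for fam in self.families:
            if len(fam) < 2:
                raise ValueError(
                    f"family {tuple(fam)} has fewer than two members and cannot "
                    "produce substitutions"
                )
        for p in (self.template_fill, self.isomer_rate, self.reuse_prob,
                  self.reuse_after_prob):
            if not 0 <= p <= 1:
                raise ValueError("probabilities must lie in [0, 1]")
        if not 0 < max(self.size_dist) <= 8:
            raise ValueError("combination sizes must stay within 1..8")
        unknown = roster - set(ATOMIC_WEIGHTS)
        if unknown:
            raise ValueError(f"unknown elements in roster: {sorted(unknown)}")


@dataclass(frozen=True)
class PlantedTruth:
    """Ground truth implied by the family partition and introduction years."""

    expected_pairs: frozenset[tuple[str, str]]
    expected_backbone_pairs: frozenset[frozenset[str]]


@dataclass
class _Template:
    families: tuple[int, ...]        # family indices, slot family first
    fixed: tuple[tuple[str, int], ...]  # (element, coefficient) for non-slot slots
    slot_coeff: int                  # even, globally unique: the template tag
    min_year: int                    # earliest year all fixed members exist


def _expected_truth(config: GeneratorConfig) -> PlantedTruth:
    pairs = set()
    backbone = set()
    for fam in config.families:
        present = [e for e in fam if config.element_intro[e] <= config.end_year]
        for x in present:
            for y in present:
                if x != y and config.element_intro[y] <= config.element_intro[x]:
                    pairs.add((x, y))
                    backbone.add(frozenset((x, y)))
    return PlantedTruth(frozenset(pairs), frozenset(backbone))


def generate(config: GeneratorConfig) -> tuple[ChemicalSpace, PlantedTruth]:
    """Generate a chemical space under *config*; deterministic under its seed.

    RNG streams are split hierarchically (one stream per year), so changing
    one year's volume never reshuffles the draws of other years.
    """
    if not config.families:
        raise ValueError("at least one element family is required")
    intro = dict(config.element_intro)
    fam_lists = [list(f) for f in config.families]
    templates: list[_Template] = []
    substances: list[Substance] = []
    counter = 0

    def fam_weight(idx: int, year: int) -> float:
        if (
            config.organic_year is not None
            and year >= config.organic_year
            and set(fam_lists[idx]) & config.organic_elements
        ):
            return config.organic_weight
        return 1.0

    for year in range(config.start_year, config.end_year + 1):
        rng = np.random.default_rng([config.seed, year])
        target = rng.poisson(
            config.initial_rate * config.growth_base ** (year - config.start_year)
        )
        avail_fams = [
            i for i, fam in enumerate(fam_lists)
            if sum(intro[e] <= year for e in fam) >= 1
        ]
        slot_fams = [
            i for i, fam in enumerate(fam_lists)
            if sum(intro[e] <= year for e in fam) >= 2
        ]
        if not slot_fams:
            raise ValueError(
                f"no family has two members introduced by {year}; "
                "substitution cannot be planted"
            )
        made = 0
        while made < target:
            # isomer: duplicate an existing formula under a fresh id
            if substances and rng.random() < config.isomer_rate:
                src = substances[int(rng.integers(len(substances)))]
                counter += 1
                substances.append(Substance(f"S{counter:06d}", src.formula, year))
                made += 1
                continue

            reuse_p = (
                config.reuse_after_prob if year >= config.reuse_year
                else config.reuse_prob
            )
            feasible = [t for t in templates if t.min_year <= year]
            if feasible and rng.random() < reuse_p:
                # reuse concentrates the space on existing element
                # combinations: same families and members, fresh
                # coefficients (a new template tag, so no duplicate
                # formulae — duplicates are the isomer channel's job)
                base = feasible[int(rng.integers(len(feasible)))]
                odd = [c for c in range(1, config.max_coeff + 1) if c % 2]
                tpl = _Template(
                    families=base.families,
                    fixed=tuple((e, int(rng.choice(odd))) for e, _ in base.fixed),
                    slot_coeff=2 * (len(templates) + 1),
                    min_year=base.min_year,
                )
            else:
                tpl = _new_template(
                    config, rng, year, fam_lists, intro, avail_fams, slot_fams,
                    fam_weight, slot_coeff=2 * (len(templates) + 1),
                )
            templates.append(tpl)

            members = [
                e for e in fam_lists[tpl.families[0]] if intro[e] <= year
            ]
            included = [m for m in members if rng.random() < config.template_fill]
            if len(included) < 2:
                included = members[:2]
            for m in included:
                comp: dict[str, int] = {m: tpl.slot_coeff}
                for e, c in tpl.fixed:
                    comp[e] = comp.get(e, 0) + c
                counter += 1
                substances.append(Substance(f"S{counter:06d}", Formula(comp), year))
                made += 1
    return ChemicalSpace(substances, (config.start_year, config.end_year)), _expected_truth(config)


def _new_template(config, rng, year, fam_lists, intro, avail_fams, slot_fams,
                  fam_weight, slot_coeff: int):
    sizes = sorted(config.size_dist)
    probs = np.array([config.size_dist[s] for s in sizes], dtype=float)
    probs /= probs.sum()
    size = int(rng.choice(sizes, p=probs))
    size = min(size, len(avail_fams))
    slot = int(rng.choice(slot_fams))
    others = [i for i in avail_fams if i != slot]
    n_fixed = min(size - 1, len(others))
    fixed_fams: list[int] = []
    if n_fixed > 0:
        w = np.array([fam_weight(i, year) for i in others], dtype=float)
        w /= w.sum()
        fixed_fams = [int(i) for i in rng.choice(others, size=n_fixed, replace=False, p=w)]
    fixed = []
    # template becomes feasible once the slot family has two members and
    # every fixed member exists
    min_year = sorted(intro[e] for e in fam_lists[slot])[1]
    odd_coeffs = [c for c in range(1, config.max_coeff + 1) if c % 2]
    for i in fixed_fams:
        members = [e for e in fam_lists[i] if intro[e] <= year]
        e = members[int(rng.integers(len(members)))]
        fixed.append((e, int(rng.choice(odd_coeffs))))
        min_year = max(min_year, intro[e])
    return _Template(
        families=(slot, *fixed_fams),
        fixed=tuple(fixed),
        slot_coeff=slot_coeff,
        min_year=min_year,
    )


def recovered_fraction(truth: PlantedTruth, network) -> float:
    """Fraction of planted max-similarity pairs present as SCE edges."""
    edges = set(network.edges()) if hasattr(network, "edges") else set(network)
    if not truth.expected_pairs:
        raise ValueError("planted truth holds no expected pairs")
    return len(truth.expected_pairs & edges) / len(truth.expected_pairs)


# ---------------------------------------------------------------------------
# Hand-auditable 13-substance toy space
# ---------------------------------------------------------------------------

_TOY_ROWS = [
    ("t01", "HCl", 1800),
    ("t02", "HBr", 1800),
    ("t03", "H2O", 1800),
    ("t04", "O2", 1800),
    ("t05", "NaCl", 1801),
    ("t06", "NaBr", 1801),
    ("t07", "CO2", 1801),
    ("t08", "KCl", 1802),
    ("t09", "Na2O", 1802),
    ("t10", "C2H2Cl2", 1803),
    ("t11", "K2O", 1803),
    ("t12", "C2H2Br2", 1803),
    ("t13", "C2H2Br2", 1804),  # isomer of t12: same formula, distinct record
]

#: hand-computed s(x -> y) of the full toy space (1804 snapshot), exact.
#: Every pair not listed has similarity 0.
TOY_EXPECTED_SIMILARITIES: dict[tuple[str, str], Fraction] = {
    ("Br", "Cl"): Fraction(4, 4),   # HX, NaX, C2H2X2 (x2) all in FCl
    ("Cl", "Br"): Fraction(3, 4),   # KX has no Br partner
    ("Na", "H"): Fraction(3, 3),    # ClX, BrX, OX2 all in FH
    ("H", "Na"): Fraction(3, 6),    # the C2-bearing arranged formulae are unmatched
    ("K", "Na"): Fraction(2, 2),    # ClX, OX2
    ("K", "H"): Fraction(2, 2),
    ("Na", "K"): Fraction(2, 3),    # BrX unmatched
    ("H", "K"): Fraction(2, 6),
}

#: max-similarity edges of the full toy space; C and O are isolated
#: (their arranged formulae are shared with no one).
TOY_EXPECTED_EDGES: frozenset[tuple[str, str]] = frozenset(
    {("Br", "Cl"), ("Cl", "Br"), ("Na", "H"), ("H", "Na"), ("K", "Na"), ("K", "H")}
)


def toy_space() -> ChemicalSpace:
    """Fixed 13-substance space whose similarities are documented above.

    The profiles of the full (1804) snapshot, for reference:
    FBr = {HX, NaX, C2H2X2 x2}, FCl = {HX, NaX, KX, C2H2X2},
    FH = {ClX, BrX, OX2, C2Cl2X2, Br2C2X2 x2}, FNa = {ClX, BrX, OX2},
    FK = {ClX, OX2}, FO = {H2X, X2, CX2, Na2X, K2X},
    FC = {O2X, Cl2H2X2, Br2H2X2 x2}.
    """
    return ChemicalSpace(
        [Substance(i, parse_formula(f), y) for i, f, y in _TOY_ROWS],
        window=(1800, 1804),
    )


def perturb_weights(
    factors: Mapping[str, Fraction | int | str],
    chemist: str = "synthetic",
    year: int = 1850,
    modern: Mapping[str, Fraction] | None = None,
    elements: Sequence[str] | None = None,
    reference: str = "H",
) -> WeightTable:
    """Historical-style weight table with A(e) = factor(e) * W(e) on the
    modern hydrogen scale.

    Exact rational factors guarantee exactly recoverable rescale
    multipliers: a factor of 2 on Fe makes (W/A)(Fe) = 1/2 at any
    tolerance.  Elements not named in *factors* keep factor 1; *elements*
    restricts the table to a subset (the reference is always kept).
    """
    modern = ATOMIC_WEIGHTS if modern is None else modern
    keep = set(modern if elements is None else elements) | {reference}
    weights: dict[str, Fraction] = {}
    for e in keep:
        if e not in modern:
            raise ValueError(f"element {e!r} has no modern weight")
        factor = Fraction(factors.get(e, 1))
        if factor <= 0:
            raise ValueError(f"non-positive factor for {e}: {factor}")
        weights[e] = Fraction(modern[e]) * factor
    return WeightTable(chemist, year, weights, reference=reference)


def dalton_style_table() -> WeightTable:
    """Illustrative synthetic stand-in for an early (Dalton-like) weight system.

    Built from the one published anchor — water read as HO gives oxygen a
    weight of seven on the hydrogen-1 scale — with a handful of further
    elements at weights roughly half their modern hydrogen-relative values,
    as early equivalent-based systems tended to be.  It is *not* a
    historical table (those live in supplementary sources not shipped
    here); it exists so the retrodiction machinery can be exercised
    end to end.
    """
    weights = {
        "H": "1", "O": "7", "C": "5.4", "N": "5", "S": "13",
        "P": "9", "Cl": "22", "Na": "21", "K": "35", "Ca": "17",
        "Fe": "25", "Cu": "28", "Pb": "95", "Zn": "29",
    }
    return WeightTable(
        "dalton-style", 1810,
        {e: Fraction(w) for e, w in weights.items()},
    )


def iron_doubled_table(modern: Mapping[str, Fraction] | None = None) -> WeightTable:
    """Illustrative table with iron's hydrogen-relative weight doubled.

    Doubling A(Fe) halves every iron coefficient on rescaling, carrying the
    modern Fe2O3 to FeO3 — the canonical sanity check for the rescaling
    direction.  All other elements keep their modern weights.
    """
    return perturb_weights({"Fe": 2}, chemist="iron-doubled", year=1819, modern=modern)


def default_config(seed: int = 0) -> GeneratorConfig:
    """Study-scale default conditions: 1800-1868, 9 elements growing to 60,
    ~11,000 substances by the end, organic turn and diversity decline after
    1830.

    The roster is a stylized discovery schedule over real symbols: 9
    elements available in 1800 growing to 60 by 1868, grouped into
    periodic-style families.
    """
    families: list[list[str]] = [
        ["H", "Na", "K", "Li", "Rb", "Cs"],
        ["C", "Si", "Ti", "Zr", "Sn"],
        ["N", "P", "As", "Sb", "Bi"],
        ["O", "S", "Se", "Te"],
        ["Cl", "F", "Br", "I"],
        ["Fe", "Co", "Ni", "Mn", "Cr"],
        ["Ca", "Mg", "Ba", "Sr", "Be"],
        ["Cu", "Ag", "Au"],
        ["Zn", "Cd", "Hg"],
        ["Pt", "Pd", "Ir", "Os", "Rh", "Ru"],
        ["Mo", "W", "Ta", "Nb", "V"],
        ["Al", "B", "In", "Tl"],
        ["Pb", "U", "Th"],
        ["La", "Ce"],
    ]
    intro: dict[str, int] = {
        # the 1800 core
        "H": 1800, "C": 1800, "N": 1800, "O": 1800, "S": 1800,
        "P": 1800, "Cl": 1800, "Fe": 1800, "Na": 1800,
        # staged introductions up to 1868
        "K": 1807, "Ca": 1808, "Ba": 1808, "Sr": 1808, "Mg": 1808,
        "B": 1809, "Cu": 1805, "Pb": 1803, "Zn": 1806, "Hg": 1804,
        "Ag": 1805, "Au": 1807, "Pt": 1810, "Pd": 1812, "Rh": 1812,
        "Ir": 1813, "Os": 1814, "I": 1811, "Li": 1817, "Cd": 1817,
        "Se": 1817, "Si": 1823, "Zr": 1824, "Ti": 1825, "Br": 1826,
        "Al": 1827, "Be": 1828, "Th": 1828, "V": 1830, "La": 1839,
        "Ce": 1839, "U": 1841, "Ru": 1844, "Cs": 1846, "Nb": 1844,
        "Ta": 1844, "W": 1816, "Mo": 1815, "Mn": 1808, "Cr": 1807,
        "Ni": 1804, "Co": 1802, "Sn": 1801, "Sb": 1801, "Bi": 1802,
        "As": 1801, "Te": 1802, "F": 1846, "Rb": 1861, "Tl": 1861,
        "In": 1863,
    }
    return GeneratorConfig(
        start_year=1800,
        end_year=1868,
        element_intro=intro,
        families=families,
        initial_rate=5.0,
        growth_base=1.078,
        organic_elements=frozenset({"C", "H", "O", "N"}),
        seed=seed,
    )
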