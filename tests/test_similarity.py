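"""Substitutability similarity and maximum-similarity networks.

The toy fixture's expected values are hand computations recorded next to
the fixture itself; the brute-force oracle re-derives similarity by the
naive substitute-and-look-up loop over substances.
"""

from fractions import Fraction

import pytest

from chemspace.formula import Formula, Substance
from chemspace.similarity import (
    element_profile,
    most_similar,
    sce_network,
    similarity,
    similarity_matrix,
)
from chemspace.space import ChemicalSpace
from chemspace.synthetic import TOY_EXPECTED_EDGES, TOY_EXPECTED_SIMILARITIES

from conftest import make_random_space


def brute_force_similarity(space, year, x, y) -> Fraction:
    """Naive oracle: for each substance of x, does replacing x by y give a
    formula (as an arranged string) some substance of y provides?"""
    subs = list(space.snapshot(year))
    y_strings = {
        s.formula.arrange(y) for s in subs if y in s.formula
    }
    x_subs = [s for s in subs if x in s.formula]
    hits = sum(1 for s in x_subs if s.formula.arrange(x) in y_strings)
    return Fraction(hits, len(x_subs))


def test_toy_similarities_match_hand_computation(toy):
    elements = sorted(toy.elements())
    for x in elements:
        for y in elements:
            if x == y:
                continue
            expected = TOY_EXPECTED_SIMILARITIES.get((x, y), Fraction(0))
            got = similarity(toy, 1804, x, y)
            assert got.value == expected, (x, y)
    # the exact counts behind two asymmetric ratios
    br_cl = similarity(toy, 1804, "Br", "Cl")
    cl_br = similarity(toy, 1804, "Cl", "Br")
    assert (br_cl.numerator, br_cl.denominator) == (4, 4)
    assert (cl_br.numerator, cl_br.denominator) == (3, 4)


def test_profile_multiplicity_and_cardinality(toy):
    fbr = element_profile(toy, 1804, "Br")
    assert fbr.entries["C2H2X2"] == 2  # two isomer records share the formula
    assert fbr.cardinality == 4
    fh = element_profile(toy, 1804, "H")
    assert fh.cardinality == 6
    single = element_profile(toy, 1800, "Cl")
    assert single.cardinality == 1


def test_profile_errors(toy):
    with pytest.raises(ValueError):
        element_profile(toy, 1800, "K")  # K enters in 1802
    with pytest.raises(ValueError):
        similarity(toy, 1804, "H", "H")


def test_removing_isomer_shifts_documented_ratios(toy):
    """Dropping the duplicate C2H2Br2 record changes exactly the
    H-denominator ratios and Br's numerator, nothing else."""
    smaller = ChemicalSpace(
        [s for s in toy if s.id != "t13"], window=(1800, 1804)
    )
    assert similarity(smaller, 1804, "Br", "Cl").value == 1
    assert similarity(smaller, 1804, "Br", "Cl").denominator == 3
    assert similarity(smaller, 1804, "H", "Na").value == Fraction(3, 5)
    assert similarity(smaller, 1804, "H", "K").value == Fraction(2, 5)
    # untouched pairs keep their values
    assert similarity(smaller, 1804, "Cl", "Br").value == Fraction(3, 4)
    assert similarity(smaller, 1804, "Na", "K").value == Fraction(2, 3)


def test_most_similar_ties_and_empty(toy):
    assert most_similar(toy, 1804, "K") == {"H", "Na"}
    assert most_similar(toy, 1804, "Br") == {"Cl"}
    # C and O share no arranged formula with anyone: no edge drawn
    assert most_similar(toy, 1804, "C") == frozenset()
    assert most_similar(toy, 1804, "O") == frozenset()


def test_sce_network_structure(toy):
    g = sce_network(toy, 1804)
    assert set(g.edges()) == set(TOY_EXPECTED_EDGES)
    assert set(g.nodes) == toy.elements()
    assert g.nodes["Br"]["substance_count"] == 4
    assert g.nodes["H"]["substance_count"] == 6
    # no self loops; weights in (0, 1]; out-edges of a node all share the max
    for x in g.nodes:
        ws = [d["weight"] for _, _, d in g.out_edges(x, data=True)]
        assert all(0 < w <= 1 for w in ws)
        assert len(set(ws)) <= 1
    # atomic-weight ranks ascend with modern weights (H < C < O < Na < Cl < K < Br)
    order = sorted(g.nodes, key=lambda e: g.nodes[e]["weight_rank"])
    assert order == ["H", "C", "O", "Na", "Cl", "K", "Br"]


def test_missing_weight_flagged(toy, caplog):
    partial = {e: i + 1 for i, e in enumerate(sorted(toy.elements() - {"Br"}))}
    with caplog.at_level("WARNING"):
        g = sce_network(toy, 1804, weights=partial)
    assert g.nodes["Br"]["weight_rank"] == -1
    assert any("Br" in r.message for r in caplog.records)


def test_similarity_locality(toy):
    """A substance containing neither x nor y leaves s(x->y) unchanged."""
    before = similarity(toy, 1804, "Br", "Cl")
    bigger = ChemicalSpace(
        list(toy) + [Substance("extra", Formula({"Fe": 2, "S": 3}), 1804)],
        window=(1800, 1804),
    )
    after = similarity(bigger, 1804, "Br", "Cl")
    assert (before.numerator, before.denominator) == (after.numerator, after.denominator)


def test_full_substitutability_gives_one():
    """When every x-formula's substitution exists, s(x->y) = 1."""
    rows = [
        Substance("a", Formula({"Br": 1, "H": 2}), 1800),
        Substance("b", Formula({"Cl": 1, "H": 2}), 1800),
        Substance("c", Formula({"Br": 2, "Na": 1}), 1800),
        Substance("d", Formula({"Cl": 2, "Na": 1}), 1800),
    ]
    sp = ChemicalSpace(rows)
    assert similarity(sp, 1800, "Br", "Cl").value == 1
    assert similarity(sp, 1800, "Cl", "Br").value == 1


@pytest.mark.parametrize("seed", range(8))
def test_similarity_equals_brute_force(seed):
    """Grouped-numerator implementation vs the naive loop, all pairs."""
    sp = make_random_space(seed=seed, n_substances=30)
    elements = sorted(sp.elements())
    for x in elements:
        for y in elements:
            if x == y:
                continue
            got = similarity(sp, 1804, x, y)
            assert got.value == brute_force_similarity(sp, 1804, x, y)
            # the numerator is a count: value * |FX| is integral
            assert got.numerator == int(got.value * got.denominator)


def test_similarity_matrix_consistent(random_space):
    m = similarity_matrix(random_space, 1804)
    for x in m.index[:4]:
        for y in m.columns[:4]:
            if x == y:
                continue
            assert m.loc[x, y] == pytest.approx(
                float(similarity(random_space, 1804, x, y).value)
            )
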