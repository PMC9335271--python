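"""Farey approximation, formula rescaling, retro-SCE scoring, orderings."""

from fractions import Fraction

import pytest
from hypothesis import given
from hypothesis import strategies as st

from chemspace.formula import parse_formula
from chemspace.retrodiction import (
    TAU_SWEEP,
    UntranslatableElement,
    WeightTable,
    farey_best,
    ordering_agreement,
    read_weight_tables,
    reduce_formula,
    rescale_coefficient,
    rescale_formula,
    retro_scores,
    retro_space,
    write_weight_table,
)
from chemspace.similarity import edge_set, sce_network
from chemspace.synthetic import iron_doubled_table, perturb_weights


def brute_force_farey(r: Fraction, tau: Fraction, qmax: int = 60):
    """Smallest denominator within tolerance by exhaustive enumeration."""
    for q in range(1, qmax + 1):
        best = min(
            (Fraction(p, q) for p in range(1, q + 1)),
            key=lambda f: abs(r - f),
        )
        if abs(r - best) / r <= tau:
            return best
    return None


@pytest.mark.parametrize(
    "r, tau, expected",
    [
        (Fraction(1, 2), Fraction(1, 100), Fraction(1, 2)),
        (Fraction(1), Fraction(1, 100), Fraction(1)),
        (Fraction(7, 16), Fraction(1, 100), Fraction(7, 16)),
        (Fraction(3, 10), Fraction(15, 100), Fraction(1, 3)),
    ],
)
def test_farey_examples(r, tau, expected):
    assert farey_best(r, tau) == expected


@given(
    st.fractions(min_value=Fraction(1, 20), max_value=1, max_denominator=500),
    st.integers(min_value=1, max_value=20),
)
def test_farey_bound_and_brute_force(r, tau_pct):
    tau = Fraction(tau_pct, 100)
    f = farey_best(r, tau)
    assert 0 < f <= 1
    assert abs(r - f) / r <= tau
    oracle = brute_force_farey(r, tau)
    if oracle is not None:
        assert f == oracle


@given(st.fractions(min_value=Fraction(1, 10), max_value=1, max_denominator=200))
def test_farey_error_monotone_in_tolerance(r):
    errs = [
        abs(r - farey_best(r, Fraction(t, 100))) / r for t in (20, 10, 5, 1)
    ]
    assert errs == sorted(errs, reverse=True)
    # exact rationals are recovered as the tolerance tightens
    assert farey_best(r, Fraction(1, 10**9)) == r


def test_farey_min_error_mode():
    # within 15%, smallest denominator is 1/3; global minimum up to order 10
    # is the exact 3/10
    r = Fraction(3, 10)
    assert farey_best(r, Fraction(15, 100), mode="simplest") == Fraction(1, 3)
    assert farey_best(r, Fraction(15, 100), mode="min_error", max_order=10) == r


def test_identity_table_all_multipliers_one():
    ident = perturb_weights({}, chemist="identity", year=1850)
    for e in ("H", "O", "Fe", "Cl", "W"):
        for tau in (TAU_SWEEP[0], TAU_SWEEP[-1]):
            rc = rescale_coefficient(e, ident, tau)
            assert rc.multiplier == 1
            assert rc.achieved_error == 0


def test_iron_doubled_rescales_fe2o3():
    table = iron_doubled_table()
    for tau in TAU_SWEEP:
        rc = rescale_coefficient("Fe", table, tau)
        assert rc.multiplier == Fraction(1, 2)
        assert rescale_coefficient("O", table, tau).multiplier == 1
        assert rescale_formula(parse_formula("Fe2O3"), table, tau).render() == "FeO3"


def test_exact_fraction_factor_recovered():
    # A(O) = 7/16 W(O) -> (W/A)(O) = 16/7 = 2 + 2/7, exact at any tolerance
    table = perturb_weights({"O": Fraction(7, 16)})
    rc = rescale_coefficient("O", table, Fraction(1, 100))
    assert rc.multiplier == Fraction(16, 7)
    assert rc.achieved_error == 0
    assert rc.ratio_wa == Fraction(16, 7)
    assert rc.ratio_aw == Fraction(7, 16)


def test_rescale_formula_normalizes_to_integers():
    # H2O with f(O) = 7/3: H2 O7/3 -> x3 -> H6O7
    table = perturb_weights({"O": Fraction(3, 7)})
    got = rescale_formula(parse_formula("H2O"), table, Fraction(1, 100))
    assert got.render() == "H6O7"
    # integerizing then reducing: H2 O14/3 -> x3 -> H6O14 -> /2 -> H3O7
    got = rescale_formula(parse_formula("H2O2"), table, Fraction(1, 100))
    assert got.render() == "H3O7"


def test_rescale_scale_invariant():
    table = perturb_weights({"Fe": 2, "O": Fraction(1, 2)})
    f = parse_formula("Fe2O3")
    f2 = parse_formula("Fe4O6")
    tau = Fraction(5, 100)
    assert rescale_formula(f, table, tau) == rescale_formula(f2, table, tau)


def test_rescale_round_trip_recovers_ratios():
    """Rescaling with A then with the inverse-factor table restores the
    original coefficient ratios exactly (factors are exact rationals)."""
    fwd = perturb_weights({"Fe": 2, "O": Fraction(2, 3)})
    back = perturb_weights({"Fe": Fraction(1, 2), "O": Fraction(3, 2)})
    f = parse_formula("Fe2O3")
    tau = Fraction(1, 100)
    there = rescale_formula(f, fwd, tau)
    home = rescale_formula(there, back, tau)
    ratio_orig = f["Fe"] / f["O"]
    assert home["Fe"] / home["O"] == ratio_orig


@given(
    st.sampled_from(["O", "Fe", "Cl", "Na", "W", "Pb"]),
    st.fractions(min_value=Fraction(1, 4), max_value=4, max_denominator=40),
    st.integers(min_value=1, max_value=20),
)
def test_rescale_coefficient_error_bound(element, factor, tau_pct):
    """Achieved relative error never exceeds the tolerance."""
    table = perturb_weights({element: factor})
    rc = rescale_coefficient(element, table, Fraction(tau_pct, 100))
    assert rc.achieved_error <= Fraction(tau_pct, 100)
    assert rc.multiplier > 0


def test_reduce_formula():
    assert reduce_formula(parse_formula("H2O2")).render() == "HO"
    assert reduce_formula(parse_formula("H2O")).render() == "H2O"
    assert reduce_formula(parse_formula("O7/3H2")).render() == "H6O7"


def test_retro_space_identity_and_missing_elements(toy):
    ident = perturb_weights({}, chemist="identity", year=1804)
    rs = retro_space(toy, 1804, ident, Fraction(1, 100))
    # identity rescaling reduces formulae but keeps every substance
    assert len(rs) == len(toy.snapshot(1803))
    # a table without Br drops every Br-containing substance
    no_br = perturb_weights({}, elements=sorted(toy.elements() - {"Br"}))
    rs = retro_space(toy, 1804, no_br, Fraction(1, 100))
    assert all("Br" not in s.formula for s in rs)
    assert len(rs) == len([s for s in toy.snapshot(1803) if "Br" not in s.formula])


def test_retro_space_empty_errors(toy):
    lonely = WeightTable("none", 1804, {"H": Fraction(1)})
    with pytest.raises(ValueError):
        retro_space(toy, 1801, lonely, Fraction(1, 100))


def test_untranslatable_element_raises():
    table = perturb_weights({}, elements=["H", "O"])
    with pytest.raises(UntranslatableElement):
        rescale_coefficient("Fe", table, Fraction(1, 100))


def test_retro_scores_identity(planted):
    """Identity weights: tp = 1, fp = share of early edges gone by the end."""
    space, _ = planted
    ident = perturb_weights({}, chemist="identity", year=1820)
    sc = retro_scores(space, 1820, ident, Fraction(5, 100))
    assert sc.tp_rate == 1.0
    # oracle: explicit set algebra on reduced-formula SCEs
    from chemspace.retrodiction import _reduced_snapshot

    p = edge_set(sce_network(_reduced_snapshot(space, 1819), 1819))
    ref = edge_set(sce_network(_reduced_snapshot(space, 1829), 1829))
    assert sc.fp_rate == pytest.approx(len(p - ref) / len(p))
    assert sc.n_edges == len(p)


def test_retro_scores_perturbed_matches_set_algebra(planted):
    space, _ = planted
    table = perturb_weights({"Cl": 2, "Na": Fraction(1, 2), "O": Fraction(2, 3)},
                            chemist="pert", year=1820)
    tau = Fraction(5, 100)
    sc = retro_scores(space, 1820, table, tau)
    from chemspace.retrodiction import _reduced_snapshot

    p = edge_set(sce_network(_reduced_snapshot(space, 1819), 1819))
    ref = edge_set(sce_network(_reduced_snapshot(space, 1829), 1829))
    rs = retro_space(space, 1820, table, tau)
    p_tau = edge_set(sce_network(rs, 1819, weights=table.weights))
    assert sc.tp_rate == pytest.approx(len(p_tau & ref) / len(p & ref))
    assert sc.fp_rate == pytest.approx(len(p_tau - ref) / len(p_tau))


def test_ordering_agreement_cases():
    a = {"H": Fraction(1), "O": Fraction(16), "S": Fraction(32), "Fe": Fraction(56)}
    assert ordering_agreement(a, a) == 1
    reversed_ = {"H": Fraction(56), "O": Fraction(32), "S": Fraction(16)}
    assert ordering_agreement(
        {k: a[k] for k in ("H", "O", "S")}, reversed_
    ) == 0
    # one adjacent swap among 4 elements: 5 of 6 pairs concordant
    swapped = dict(a)
    swapped["O"], swapped["S"] = swapped["S"], swapped["O"]
    assert ordering_agreement(a, swapped) == Fraction(5, 6)
    with pytest.raises(ValueError):
        ordering_agreement({"H": Fraction(1)}, a)


def test_ordering_agreement_tie_handling():
    a = {"H": Fraction(1), "O": Fraction(16), "S": Fraction(16)}
    b = {"H": Fraction(1), "O": Fraction(16), "S": Fraction(17)}
    # (O,S) tied in a only -> discordant; tied in both -> concordant
    assert ordering_agreement(a, b) == Fraction(2, 3)
    assert ordering_agreement(a, a) == 1


def test_weight_table_io_round_trip(tmp_path):
    table = perturb_weights({"Fe": 2}, chemist="demo", year=1819,
                            elements=["H", "O", "Fe", "Cl"])
    path = tmp_path / "weights.csv"
    write_weight_table(table, path)
    back = read_weight_tables(path)
    assert len(back) == 1
    assert back[0].chemist == "demo" and back[0].year == 1819
    assert back[0].weights == dict(table.weights)
    assert back[0].reference == "H"


def test_weight_table_validation():
    with pytest.raises(ValueError):
        WeightTable("x", 1800, {"O": Fraction(16)})  # reference H missing
    with pytest.raises(ValueError):
        WeightTable("x", 1800, {"H": Fraction(-1)}, reference="H")
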