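"""Shared fixtures: toy space, random-space factory, planted-family space."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import settings

from chemspace.formula import Formula, Substance
from chemspace.space import ChemicalSpace
from chemspace.synthetic import GeneratorConfig, generate, toy_space

settings.register_profile("ci", derandomize=True, max_examples=50)
settings.load_profile("ci")

#: element pool for random spaces; single and double letter symbols mixed
RANDOM_POOL = ["H", "C", "N", "O", "S", "Cl", "Br", "Na", "Fe", "K"]


@pytest.fixture
def toy() -> ChemicalSpace:
    return toy_space()


def make_random_space(seed: int, n_substances: int = 40, pool=None) -> ChemicalSpace:
    """Small random space with plenty of arranged-formula overlap.

    Coefficients and combination sizes are kept small so that substituted
    formulae frequently exist, exercising nonzero similarities.
    """
    rng = np.random.default_rng(seed)
    pool = list(pool or RANDOM_POOL)
    subs = []
    for i in range(n_substances):
        size = int(rng.integers(1, 4))
        elems = rng.choice(pool, size=size, replace=False)
        comp = {str(e): int(rng.integers(1, 4)) for e in elems}
        year = 1800 + int(rng.integers(0, 5))
        subs.append(Substance(f"r{i:03d}", Formula(comp), year))
    return ChemicalSpace(subs, window=(1800, 1804))


@pytest.fixture
def random_space() -> ChemicalSpace:
    return make_random_space(seed=11)


def planted_config(seed: int = 7) -> GeneratorConfig:
    """Two-epoch, 12-element, 4-family study conditions (~2,000 substances)."""
    fams = [["F", "Cl", "Br"], ["Li", "Na", "K"], ["O", "S", "Se"], ["Ni", "Pd", "Pt"]]
    intro = {
        "F": 1800, "Cl": 1800, "Br": 1815,
        "Li": 1800, "Na": 1800, "K": 1815,
        "O": 1800, "S": 1800, "Se": 1815,
        "Ni": 1800, "Pd": 1800, "Pt": 1815,
    }
    return GeneratorConfig(
        start_year=1800,
        end_year=1829,
        element_intro=intro,
        families=fams,
        initial_rate=8.0,
        growth_base=1.12,
        organic_elements=frozenset({"O", "S"}),
        seed=seed,
    )


@pytest.fixture(scope="session")
def planted():
    """Generated planted-family space with its ground truth (seeded)."""
    return generate(planted_config(seed=7))
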