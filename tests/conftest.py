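import numpy as np
import pytest

from mlrefine.fixtures import (
    FixtureRecipe,
    simulate_half_maps,
    simulate_reflections,
    toy_system,
)


@pytest.fixture(scope="session")
def small_recipe():
    return FixtureRecipe(n_residues=12, seed=11, d_min=2.5, cell_padding=8.0)


@pytest.fixture(scope="session")
def xtal_system(small_recipe):
    """State-A/state-B models, shared cell and reflections simulated from B."""
    a, b, cell = toy_system(small_recipe)
    refl, _, f_true = simulate_reflections(b, small_recipe, cell)
    return {"a": a, "b": b, "cell": cell, "refl": refl, "f_true": f_true,
            "recipe": small_recipe}


@pytest.fixture(scope="session")
def em_system():
    rec = FixtureRecipe(n_residues=12, seed=3, map_shape=(40, 40, 40),
                        cell_padding=8.0, d_min=2.0)
    a, b, cell = toy_system(rec)
    m1, m2, _, clean = simulate_half_maps(b, rec, cell)
    return {"a": a, "b": b, "cell": cell, "map1": m1, "map2": m2,
            "clean": clean, "recipe": rec}


@pytest.fixture(scope="session")
def degrade_system():
    """Large-box half-map pair for resolution-degradation tests: a wide
    cell gives enough low-resolution shells below 6-10 A cutoffs."""
    rec = FixtureRecipe(n_residues=16, seed=21, map_shape=(64, 64, 64),
                        cell_padding=55.0, map_noise_to_signal=0.002,
                        d_min=4.0)
    a, b, cell = toy_system(rec)
    m1, m2, _, clean = simulate_half_maps(b, rec, cell)
    return {"b": b, "cell": cell, "map1": m1, "map2": m2, "clean": clean,
            "recipe": rec}


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
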