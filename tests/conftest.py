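import dataclasses

import pytest

import ecocap as ec


@pytest.fixture(scope="session")
def toy_recipe():
    return ec.WebRecipe(preset="toy3", seed=0)


@pytest.fixture(scope="session")
def toy_config(toy_recipe):
    return ec.generate_toy_web(toy_recipe)


@pytest.fixture(scope="session")
def toy_forcings(toy_recipe):
    return ec.generate_forcings(toy_recipe)


@pytest.fixture(scope="session")
def goa_recipe():
    return ec.WebRecipe(preset="goa_like", seed=0)


@pytest.fixture(scope="session")
def goa_config(goa_recipe):
    return ec.generate_goa_like_web(goa_recipe)


@pytest.fixture(scope="session")
def goa_forcings(goa_recipe):
    return ec.generate_forcings(goa_recipe)


@pytest.fixture(scope="session")
def solo_spec():
    """A single decoupled stock with flat weight-at-age and h = 1.

    Cmax = 0 (no feeding in the model, so rations are full and weights
    stay at reference) and steepness 1 (recruitment fixed at R0 for any
    positive spawning biomass): the configuration whose equilibrium has
    an exact Baranov yield-per-recruit closed form.
    """
    return ec.GroupSpec(
        id="solo", kind="age_structured_fish", n_ages=8, M0=0.25, F_OFL=0.3,
        age_mature=3, age_select=3, W_ref=(1.0,) * 8, R0=1e6, h=1.0,
        Cmax=0.0, T_opt=8.0, T_max=17.0, Qc=2.5,
        spawn_window=(0.0, 12.0, 2.0), niche=(-5.0, 0.0, 20.0, 25.0),
        is_focal=True)


@pytest.fixture(scope="session")
def solo_config(solo_spec):
    return ec.FoodWebConfig(groups=[dataclasses.replace(solo_spec)],
                            diet=ec.DietMatrix())
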