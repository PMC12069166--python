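"""Synthetic food webs and forcings with the structure the analysis assumes.

Two presets are provided. ``toy3`` is a minimal three-group chain
(predator fish, prey fish, plankton pool) whose decoupled equilibria
have closed forms, used throughout the test-suite. ``goa_like`` is a
26-group Gulf-of-Alaska-flavoured web: 12 exploited groundfish focal
groups (including a lightly valued flatfish key predator and a
warm-sensitive-spawning gadid), five forage-fish groups, three plankton
pools plus benthos, and five endotherm top-predator groups. Overfishing
limit fishing mortalities (F_OFL) for the focal stocks follow published
Gulf of Alaska assessment values; all other life-history parameters are
deterministic, documented, plausible-range choices (with a small seeded
jitter on thermal/growth coefficients) rather than fitted quantities.

The diet structure deliberately encodes the study's mechanisms: the
arrowtooth-like predator has dominant availability on the pollock-like
and cod-like stocks (top-down control), forage fish feed on plankton
(bottom-up food limitation under a warm, low-productivity regime), and
endotherms rely on groundfish and forage fish (indirect effects of
groundfish removals).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ConfigurationError
from .foodweb import DietMatrix, FoodWebConfig, GroupSpec, unfished_equilibrium
from .forcing import (
    DAYS_PER_YEAR,
    ForcingSeries,
    build_daily_climatology,
    delta_correct,
    warm_regime,
)

__all__ = [
    "WebRecipe",
    "generate_toy_web",
    "generate_goa_like_web",
    "generate_forcings",
    "generate_web",
    "PLANKTON_IDS",
    "FORAGE_IDS",
    "ENDOTHERM_IDS",
]

PLANKTON_IDS = ("diatoms", "copepods", "euphausiids")
FORAGE_IDS = ("capelin", "sand_lance", "herring", "eulachon", "slope_forage")
ENDOTHERM_IDS = ("steller_sea_lion", "other_pinnipeds", "dolphins_porpoises",
                 "surface_seabirds", "diving_seabirds")

# Default thermal envelope: wide niche and spawn window that stay open
# under both regimes; the cod-like group overrides the spawn window.
WIDE_SPAWN = (0.0, 12.0, 2.0)
WIDE_NICHE = (-2.0, 2.0, 11.0, 16.0)
PHI_BASELINE = 10.0  # availability-weighted prey field / H at the unfished baseline
GFDL_BIAS = 0.6      # deg C synthetic mean bias of the free-running climate model


@dataclass(frozen=True)
class WebRecipe:
    """Recipe for a synthetic web + forcing pair.

    ``preset``: 'toy3' or 'goa_like'. ``warming_delta`` is the uniform
    warming (deg C) of the projected regime before bias correction.
    ``predator_strength`` scales the arrowtooth-like group's
    availability on its gadid prey (1.0 = default top-down control).
    """

    preset: str = "goa_like"
    seed: int = 0
    warming_delta: float = 2.5
    predator_strength: float = 1.0


def _vonb_weights(Winf: float, k: float, n_ages: int, ypa: int) -> tuple[float, ...]:
    ages = np.arange(1, n_ages + 1) * ypa
    w = Winf * (1.0 - np.exp(-k * (ages + 0.5))) ** 3
    w = np.maximum.accumulate(np.maximum(w, 1e-4 * Winf))
    return tuple(float(x) for x in w)


def _calibrate_R0(spec: GroupSpec, target: float, basis: str = "ssb") -> GroupSpec:
    """Set R0 so the decoupled unfished equilibrium hits a biomass target (t)."""
    from dataclasses import replace
    probe = replace(spec, R0=1.0, S0=0.0)
    N, W = unfished_equilibrium(probe)
    if basis == "ssb":
        m = probe.age_mature - 1
        per_recruit = float((N[m:] * np.asarray(W[:probe.n_ages])[m:]).sum()) / 1000.0
    else:
        per_recruit = float((N * np.asarray(W[:probe.n_ages])).sum()) / 1000.0
    if per_recruit <= 0:
        raise ConfigurationError(f"group {spec.id!r}: degenerate per-recruit biomass")
    return replace(spec, R0=target / per_recruit, S0=0.0)


def _ontogenetic(av_juv: float, av_adult: float, spec: GroupSpec) -> tuple:
    """Per-age availability: one value below age at maturity, another at/above."""
    out = [av_juv if a < spec.age_mature else av_adult
           for a in range(1, spec.n_ages + 1)]
    return tuple(out)


def _half_saturations(groups: list[GroupSpec], diet: DietMatrix) -> dict:
    """H per predator so the unfished-baseline prey field gives phi ~= PHI_BASELINE."""
    baseline = {}
    for g in groups:
        if g.age_structured:
            N, W = unfished_equilibrium(g)
            baseline[g.id] = float((N * np.asarray(W[:g.n_ages])).sum()) / 1000.0
        else:
            baseline[g.id] = g.K
    by_id = {g.id: g for g in groups}
    fields: dict[str, np.ndarray] = {}
    for (pred, prey), val in diet.availability.items():
        arr = np.atleast_1d(np.asarray(val, dtype=float))
        if arr.size == 1:
            arr = np.full(by_id[pred].n_ages, arr[0])
        fields.setdefault(pred, np.zeros(by_id[pred].n_ages))
        fields[pred] = fields[pred] + arr * baseline[prey]
    H = {}
    for pred, f in fields.items():
        pos = f[f > 0]
        if pos.size:
            H[pred] = float(pos.mean() / PHI_BASELINE)
    return H


# --------------------------------------------------------------------------
# toy web
# --------------------------------------------------------------------------

def generate_toy_web(recipe: WebRecipe | None = None) -> FoodWebConfig:
    """Three-group chain: predator fish <- prey fish <- plankton pool.

    Decoupling any link (zero availability) makes the affected fish
    group follow its single-species closed-form equilibrium exactly.
    """
    pred = GroupSpec(
        id="pred", kind="age_structured_fish", n_ages=5, M0=0.3, F_OFL=0.3,
        age_mature=2, age_select=2, W_ref=(0.8, 1.6, 2.4, 3.0, 3.4),
        h=0.8, Cmax=3.0, T_opt=8.0, T_max=17.0, Qc=2.5,
        spawn_window=WIDE_SPAWN, niche=WIDE_NICHE, is_focal=True)
    prey = GroupSpec(
        id="prey", kind="age_structured_fish", n_ages=3, M0=0.6, F_OFL=0.5,
        age_mature=2, age_select=2, W_ref=(0.05, 0.12, 0.18),
        h=0.8, Cmax=5.0, T_opt=8.0, T_max=17.0, Qc=2.5,
        spawn_window=WIDE_SPAWN, niche=WIDE_NICHE, is_focal=True)
    plankton = GroupSpec(id="plankton", kind="biomass_pool", r=6.0, K=2.0e6,
                         counts_toward_cap=False)
    pred = _calibrate_R0(pred, 150e3)
    prey = _calibrate_R0(prey, 600e3)
    diet = DietMatrix(
        availability={
            ("pred", "prey"): _ontogenetic(0.1, 0.4, pred),
            ("pred", "plankton"): _ontogenetic(0.4, 0.05, pred),
            ("prey", "plankton"): 0.5,
        })
    diet.half_saturation = _half_saturations([pred, prey, plankton], diet)
    return FoodWebConfig(groups=[pred, prey, plankton], diet=diet)


# --------------------------------------------------------------------------
# GOA-like web
# --------------------------------------------------------------------------

def _goa_fish_table() -> list[dict]:
    """Focal groundfish: published F_OFL values; the halibut-like group
    uses its natural mortality (0.2 yr^-1) as the base rate and does not
    count toward the cap."""
    return [
        # id, F_OFL, n_ages, ypa, M0, mat, sel, Winf, k, h, Cmax, Topt, ssb_target (t)
        dict(id="arrowtooth", F_OFL=0.23, n_ages=10, ypa=1, M0=0.20, mat=4, sel=4,
             Winf=3.0, k=0.25, h=0.80, Cmax=2.5, Topt=8.0, ssb=700e3),
        dict(id="deepwater_flatfish", F_OFL=0.11, n_ages=10, ypa=1, M0=0.12, mat=5,
             sel=5, Winf=1.5, k=0.20, h=0.75, Cmax=2.0, Topt=7.5, ssb=50e3),
        dict(id="flathead_sole", F_OFL=0.25, n_ages=9, ypa=1, M0=0.20, mat=4, sel=4,
             Winf=0.8, k=0.25, h=0.75, Cmax=2.5, Topt=8.0, ssb=120e3),
        dict(id="pacific_ocean_perch", F_OFL=0.12, n_ages=20, ypa=1, M0=0.07, mat=8,
             sel=8, Winf=0.9, k=0.15, h=0.70, Cmax=1.8, Topt=7.0, ssb=350e3),
        dict(id="pacific_cod", F_OFL=0.51, n_ages=9, ypa=1, M0=0.38, mat=4, sel=4,
             Winf=9.0, k=0.22, h=0.85, Cmax=3.0, Topt=8.5, ssb=350e3,
             spawn=(3.0, 8.5, 0.5)),
        dict(id="rex_sole", F_OFL=0.30, n_ages=9, ypa=1, M0=0.20, mat=4, sel=4,
             Winf=0.6, k=0.25, h=0.75, Cmax=2.5, Topt=8.0, ssb=60e3),
        dict(id="pelagic_rockfish", F_OFL=0.11, n_ages=15, ypa=1, M0=0.09, mat=6,
             sel=6, Winf=1.1, k=0.18, h=0.70, Cmax=2.0, Topt=8.0, ssb=50e3),
        dict(id="slope_rockfish", F_OFL=0.06, n_ages=20, ypa=1, M0=0.05, mat=9,
             sel=9, Winf=1.3, k=0.12, h=0.70, Cmax=1.6, Topt=7.0, ssb=80e3),
        dict(id="sablefish", F_OFL=0.09, n_ages=15, ypa=1, M0=0.10, mat=5, sel=5,
             Winf=4.0, k=0.30, h=0.75, Cmax=2.2, Topt=7.5, ssb=250e3),
        dict(id="shallow_flatfish", F_OFL=0.25, n_ages=9, ypa=1, M0=0.22, mat=4,
             sel=4, Winf=0.7, k=0.30, h=0.75, Cmax=2.5, Topt=8.5, ssb=150e3),
        dict(id="pollock", F_OFL=0.31, n_ages=10, ypa=1, M0=0.30, mat=4, sel=4,
             Winf=1.4, k=0.30, h=0.85, Cmax=3.0, Topt=9.0, ssb=900e3),
        dict(id="halibut", F_OFL=0.20, n_ages=20, ypa=1, M0=0.20, mat=9, sel=9,
             Winf=30.0, k=0.12, h=0.75, Cmax=2.0, Topt=8.0, ssb=250e3,
             countable=False),
    ]


def _forage_table() -> list[dict]:
    return [
        dict(id="capelin", n_ages=4, M0=0.90, mat=2, sel=2, Winf=0.025, k=0.8,
             h=0.70, Cmax=6.0, Topt=8.0, ssb=600e3),
        dict(id="sand_lance", n_ages=4, M0=0.85, mat=2, sel=2, Winf=0.020, k=0.8,
             h=0.70, Cmax=6.0, Topt=8.5, ssb=450e3),
        dict(id="herring", n_ages=6, M0=0.50, mat=3, sel=3, Winf=0.15, k=0.5,
             h=0.70, Cmax=5.0, Topt=8.5, ssb=300e3),
        dict(id="eulachon", n_ages=4, M0=0.80, mat=2, sel=2, Winf=0.04, k=0.7,
             h=0.70, Cmax=6.0, Topt=7.5, ssb=100e3),
        dict(id="slope_forage", n_ages=5, M0=0.60, mat=2, sel=2, Winf=0.03, k=0.6,
             h=0.70, Cmax=5.0, Topt=7.0, ssb=200e3),
    ]


def _endotherm_table() -> list[dict]:
    # biomass targets are whole-population (t); reproduction is
    # condition-scaled, so steepness/spawn parameters are inert here
    return [
        dict(id="steller_sea_lion", n_ages=8, ypa=2, M0=0.10, mat=3, Winf=300.0,
             k=0.25, Cmax=6.0, biomass=25e3),
        dict(id="other_pinnipeds", n_ages=8, ypa=2, M0=0.12, mat=3, Winf=80.0,
             k=0.30, Cmax=6.0, biomass=35e3),
        dict(id="dolphins_porpoises", n_ages=8, ypa=2, M0=0.10, mat=3, Winf=80.0,
             k=0.30, Cmax=7.0, biomass=20e3),
        dict(id="surface_seabirds", n_ages=6, ypa=2, M0=0.15, mat=2, Winf=1.5,
             k=0.60, Cmax=15.0, biomass=4e3),
        dict(id="diving_seabirds", n_ages=6, ypa=2, M0=0.15, mat=2, Winf=1.2,
             k=0.60, Cmax=15.0, biomass=3e3),
    ]


def generate_goa_like_web(recipe: WebRecipe | None = None) -> FoodWebConfig:
    """26-group Gulf-of-Alaska-like web (see module docstring)."""
    recipe = recipe or WebRecipe()
    rng = np.random.default_rng(recipe.seed)
    groups: list[GroupSpec] = []

    def jitter(scale=0.05):
        return 1.0 + scale * float(rng.uniform(-1, 1))

    for row in _goa_fish_table():
        spec = GroupSpec(
            id=row["id"], kind="age_structured_fish", n_ages=row["n_ages"],
            years_per_age=row["ypa"], M0=row["M0"], F_OFL=row["F_OFL"],
            age_mature=row["mat"], age_select=row["sel"],
            W_ref=_vonb_weights(row["Winf"], row["k"] * jitter(), row["n_ages"],
                                row["ypa"]),
            h=row["h"], Cmax=row["Cmax"],
            T_opt=row["Topt"] + 0.2 * float(rng.uniform(-1, 1)),
            T_max=row["Topt"] + 9.0, Qc=2.5 * jitter(),
            spawn_window=row.get("spawn", WIDE_SPAWN), niche=WIDE_NICHE,
            is_focal=True, counts_toward_cap=row.get("countable", True))
        groups.append(_calibrate_R0(spec, row["ssb"], basis="ssb"))

    for row in _forage_table():
        spec = GroupSpec(
            id=row["id"], kind="age_structured_fish", n_ages=row["n_ages"],
            years_per_age=1, M0=row["M0"], F_OFL=None, age_mature=row["mat"],
            age_select=row["sel"],
            W_ref=_vonb_weights(row["Winf"], row["k"] * jitter(), row["n_ages"], 1),
            h=row["h"], Cmax=row["Cmax"],
            T_opt=row["Topt"] + 0.2 * float(rng.uniform(-1, 1)),
            T_max=row["Topt"] + 9.0, Qc=2.5 * jitter(),
            spawn_window=WIDE_SPAWN, niche=(-2.0, 1.0, 12.0, 17.0),
            is_focal=False, counts_toward_cap=False)
        groups.append(_calibrate_R0(spec, row["ssb"], basis="ssb"))

    groups += [
        GroupSpec(id="diatoms", kind="biomass_pool", r=10.0, K=20e6,
                  counts_toward_cap=False),
        GroupSpec(id="copepods", kind="biomass_pool", r=6.0, K=15e6,
                  counts_toward_cap=False),
        GroupSpec(id="euphausiids", kind="biomass_pool", r=5.0, K=10e6,
                  counts_toward_cap=False),
        GroupSpec(id="benthos", kind="biomass_pool", r=3.0, K=12e6,
                  counts_toward_cap=False),
    ]

    for row in _endotherm_table():
        spec = GroupSpec(
            id=row["id"], kind="endotherm", n_ages=row["n_ages"],
            years_per_age=row["ypa"], M0=row["M0"], age_mature=row["mat"],
            age_select=row["mat"],
            W_ref=_vonb_weights(row["Winf"], row["k"], row["n_ages"], row["ypa"]),
            h=0.75, Cmax=row["Cmax"], T_opt=8.0, T_max=30.0, Qc=2.0,
            spawn_window=WIDE_SPAWN, niche=(-10.0, -5.0, 25.0, 30.0),
            is_focal=False, counts_toward_cap=False)
        groups.append(_calibrate_R0(spec, row["biomass"], basis="total"))

    by_id = {g.id: g for g in groups}
    ps = recipe.predator_strength

    def onto(pred, juv, adult):
        return _ontogenetic(juv, adult, by_id[pred])

    av = {
        # groundfish
        ("pollock", "copepods"): onto("pollock", 0.40, 0.10),
        ("pollock", "euphausiids"): onto("pollock", 0.50, 0.50),
        ("pollock", "diatoms"): onto("pollock", 0.10, 0.0),
        ("pollock", "capelin"): onto("pollock", 0.0, 0.03),
        ("pacific_cod", "euphausiids"): onto("pacific_cod", 0.30, 0.05),
        ("pacific_cod", "benthos"): onto("pacific_cod", 0.20, 0.40),
        ("pacific_cod", "pollock"): onto("pacific_cod", 0.0, 0.02),
        ("pacific_cod", "capelin"): onto("pacific_cod", 0.0, 0.10),
        ("pacific_cod", "sand_lance"): onto("pacific_cod", 0.0, 0.08),
        ("arrowtooth", "euphausiids"): onto("arrowtooth", 0.50, 0.12),
        ("arrowtooth", "capelin"): onto("arrowtooth", 0.10, 0.04),
        ("arrowtooth", "herring"): onto("arrowtooth", 0.0, 0.04),
        ("arrowtooth", "sand_lance"): onto("arrowtooth", 0.05, 0.04),
        ("arrowtooth", "pollock"): onto("arrowtooth", 0.0, min(1.0, 0.07 * ps)),
        ("arrowtooth", "pacific_cod"): onto("arrowtooth", 0.0, min(1.0, 0.05 * ps)),
        ("arrowtooth", "flathead_sole"): onto("arrowtooth", 0.0, 0.03),
        ("arrowtooth", "shallow_flatfish"): onto("arrowtooth", 0.0, 0.02),
        ("arrowtooth", "rex_sole"): onto("arrowtooth", 0.0, 0.02),
        ("halibut", "benthos"): onto("halibut", 0.30, 0.25),
        ("halibut", "euphausiids"): onto("halibut", 0.30, 0.0),
        ("halibut", "pollock"): onto("halibut", 0.0, 0.04),
        ("halibut", "pacific_cod"): onto("halibut", 0.0, 0.03),
        ("halibut", "arrowtooth"): onto("halibut", 0.0, 0.03),
        ("halibut", "flathead_sole"): onto("halibut", 0.0, 0.03),
        ("halibut", "shallow_flatfish"): onto("halibut", 0.0, 0.02),
        ("halibut", "herring"): onto("halibut", 0.0, 0.05),
        ("flathead_sole", "benthos"): onto("flathead_sole", 0.30, 0.50),
        ("flathead_sole", "euphausiids"): onto("flathead_sole", 0.30, 0.10),
        ("rex_sole", "benthos"): onto("rex_sole", 0.30, 0.50),
        ("rex_sole", "euphausiids"): onto("rex_sole", 0.30, 0.10),
        ("shallow_flatfish", "benthos"): onto("shallow_flatfish", 0.30, 0.50),
        ("shallow_flatfish", "euphausiids"): onto("shallow_flatfish", 0.30, 0.10),
        ("shallow_flatfish", "sand_lance"): onto("shallow_flatfish", 0.0, 0.03),
        ("deepwater_flatfish", "benthos"): onto("deepwater_flatfish", 0.30, 0.50),
        ("deepwater_flatfish", "euphausiids"): onto("deepwater_flatfish", 0.30, 0.10),
        ("pacific_ocean_perch", "euphausiids"): onto("pacific_ocean_perch", 0.60, 0.60),
        ("pacific_ocean_perch", "copepods"): onto("pacific_ocean_perch", 0.30, 0.20),
        ("pelagic_rockfish", "euphausiids"): onto("pelagic_rockfish", 0.50, 0.40),
        ("pelagic_rockfish", "capelin"): onto("pelagic_rockfish", 0.0, 0.05),
        ("pelagic_rockfish", "sand_lance"): onto("pelagic_rockfish", 0.0, 0.05),
        ("slope_rockfish", "euphausiids"): onto("slope_rockfish", 0.50, 0.40),
        ("slope_rockfish", "slope_forage"): onto("slope_rockfish", 0.0, 0.08),
        ("sablefish", "euphausiids"): onto("sablefish", 0.40, 0.20),
        ("sablefish", "pollock"): onto("sablefish", 0.0, 0.02),
        ("sablefish", "capelin"): onto("sablefish", 0.0, 0.06),
        ("sablefish", "benthos"): onto("sablefish", 0.10, 0.20),
        ("sablefish", "slope_forage"): onto("sablefish", 0.0, 0.05),
        # forage fish
        ("capelin", "copepods"): 0.60,
        ("capelin", "diatoms"): 0.30,
        ("capelin", "euphausiids"): 0.10,
        ("sand_lance", "copepods"): 0.60,
        ("sand_lance", "diatoms"): 0.30,
        ("sand_lance", "euphausiids"): 0.10,
        ("herring", "copepods"): 0.50,
        ("herring", "euphausiids"): 0.30,
        ("herring", "diatoms"): 0.20,
        ("eulachon", "copepods"): 0.60,
        ("eulachon", "euphausiids"): 0.20,
        ("slope_forage", "copepods"): 0.50,
        ("slope_forage", "euphausiids"): 0.30,
        # endotherm top predators
        ("steller_sea_lion", "pollock"): 0.03,
        ("steller_sea_lion", "pacific_cod"): 0.04,
        ("steller_sea_lion", "arrowtooth"): 0.06,
        ("steller_sea_lion", "sablefish"): 0.04,
        ("steller_sea_lion", "flathead_sole"): 0.02,
        ("steller_sea_lion", "capelin"): 0.08,
        ("steller_sea_lion", "herring"): 0.08,
        ("other_pinnipeds", "pollock"): 0.02,
        ("other_pinnipeds", "pacific_cod"): 0.03,
        ("other_pinnipeds", "flathead_sole"): 0.02,
        ("other_pinnipeds", "shallow_flatfish"): 0.03,
        ("other_pinnipeds", "capelin"): 0.12,
        ("other_pinnipeds", "sand_lance"): 0.10,
        ("other_pinnipeds", "herring"): 0.04,
        ("other_pinnipeds", "eulachon"): 0.05,
        ("dolphins_porpoises", "capelin"): 0.30,
        ("dolphins_porpoises", "sand_lance"): 0.20,
        ("dolphins_porpoises", "herring"): 0.10,
        ("dolphins_porpoises", "eulachon"): 0.08,
        ("dolphins_porpoises", "slope_forage"): 0.08,
        ("dolphins_porpoises", "pollock"): 0.02,
        ("surface_seabirds", "capelin"): 0.30,
        ("surface_seabirds", "sand_lance"): 0.25,
        ("surface_seabirds", "herring"): 0.10,
        ("surface_seabirds", "eulachon"): 0.10,
        ("surface_seabirds", "slope_forage"): 0.05,
        ("diving_seabirds", "capelin"): 0.25,
        ("diving_seabirds", "sand_lance"): 0.30,
        ("diving_seabirds", "herring"): 0.10,
        ("diving_seabirds", "pollock"): 0.01,
    }
    diet = DietMatrix(availability=av)
    diet.half_saturation = _half_saturations(groups, diet)
    return FoodWebConfig(groups=groups, diet=diet)


def generate_web(recipe: WebRecipe) -> FoodWebConfig:
    if recipe.preset == "toy3":
        return generate_toy_web(recipe)
    if recipe.preset == "goa_like":
        return generate_goa_like_web(recipe)
    raise ConfigurationError(f"unknown preset {recipe.preset!r}")


# --------------------------------------------------------------------------
# forcings
# --------------------------------------------------------------------------

def _base_sinusoid(mean: float = 7.0, amplitude: float = 4.0) -> np.ndarray:
    d = np.arange(DAYS_PER_YEAR)
    return mean + amplitude * np.sin(2.0 * np.pi * (d - 105.0) / DAYS_PER_YEAR)


def generate_forcings(recipe: WebRecipe | None = None
                      ) -> tuple[ForcingSeries, ForcingSeries]:
    """(historical, projected) regimes for a recipe.

    Historical: a sinusoidal daily climatology (mean 7 deg C, amplitude
    4 deg C), looped. Projected: an 11-year synthetic "climate model"
    series -- the same seasonality plus ``warming_delta``, a constant
    model bias, and mean-zero interannual offsets -- delta-corrected
    against the hindcast/historical-model means, collapsed to a daily
    climatology, and carrying halved productivity for the plankton
    pools. With these synthetic bias terms the corrected warming is
    exactly ``warming_delta`` on annual average.
    """
    recipe = recipe or WebRecipe()
    if recipe.warming_delta < 0:
        raise ConfigurationError("warming_delta must be non-negative")
    base = _base_sinusoid()
    historical = ForcingSeries(daily_T=base.copy(), label="historical")

    n_years = 11
    offsets = np.linspace(-0.5, 0.5, n_years)
    offsets = offsets - offsets.mean()
    proj_raw = base[None, :] + recipe.warming_delta + GFDL_BIAS + offsets[:, None]
    hindcast_mean = float(base.mean())
    historical_model_mean = hindcast_mean + GFDL_BIAS
    corrected = delta_correct(proj_raw, hindcast_mean, historical_model_mean)
    corrected_clim = build_daily_climatology(corrected)

    plankton = (("plankton",) if recipe.preset == "toy3" else PLANKTON_IDS)
    projected = warm_regime(historical, corrected_clim, plankton, label="projected")
    return historical, projected
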