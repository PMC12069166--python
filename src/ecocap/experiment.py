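"""Two-step fishing experiment: per-stock F_MSY profiling, then the
multispecies MF_MSY multiplier grid under climate x predator-exploitation
scenarios.

Step 1 profiles F for one focal group at a time over 13 evenly spaced
values between 0 and 4 x F_OFL (all other fished groups held at their
calibration F) and selects the F with the highest last-5-year mean catch
as that group's F_MSY. Step 2 multiplies the resulting MF_MSY vector by
the same 13 scalars under four scenarios combining climate regime
(historical vs projected-warm) and key-predator exploitation (scaling
with the multiplier vs held at the calibration quarter-F_OFL).
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np

from .errors import ConfigurationError
from .foodweb import FoodWebConfig
from .forcing import ForcingSeries
from .simulator import Engine, RunResult, RunSpec, summarize_equilibrium

__all__ = [
    "N_GRID",
    "MsyProfile",
    "ScenarioSpec",
    "Step1Result",
    "Step2Result",
    "f_grid",
    "multiplier_grid",
    "profile_fmsy",
    "run_step1",
    "run_step2",
    "SCENARIOS",
]

log = logging.getLogger(__name__)

N_GRID = 13          # F levels per profile and multipliers per scenario
MAX_MULTIPLIER = 4.0

SCENARIOS = (
    ("historical", "full"),
    ("historical", "underexploited"),
    ("projected", "full"),
    ("projected", "underexploited"),
)


def multiplier_grid() -> np.ndarray:
    """The 13 evenly spaced multipliers {0, 1/3, ..., 4}."""
    return np.linspace(0.0, MAX_MULTIPLIER, N_GRID)


def f_grid(F_base: float) -> np.ndarray:
    """13 evenly spaced F values from 0 to 4 x the base rate (F_OFL, or M
    for groups lacking an assessment F_OFL)."""
    if F_base <= 0:
        raise ConfigurationError(f"f_grid requires a positive base rate, got {F_base}")
    return multiplier_grid() * F_base


@dataclass
class MsyProfile:
    """Step-1 yield profile for one focal group.

    ``grid`` holds one row per F level: (F, equilibrium catch,
    equilibrium SSB, catch CV), all from last-5-year means.
    ``F_MSY`` is the grid F with the highest equilibrium catch (ties
    broken toward the smallest F); ``at_boundary`` flags an argmax at
    the upper grid edge. ``depletion_at_FMSY`` is SSB(F_MSY)/SSB(F=0).
    """

    group: str
    F_values: np.ndarray
    catch: np.ndarray
    ssb: np.ndarray
    catch_cv: np.ndarray
    F_MSY: float
    msy: float
    depletion_at_FMSY: float
    at_boundary: bool
    partial: bool = False

    @property
    def grid(self):
        return list(zip(self.F_values, self.catch, self.ssb, self.catch_cv))


@dataclass(frozen=True)
class ScenarioSpec:
    """One Step-2 cell: climate regime x predator policy x multiplier."""

    climate: str                  # 'historical' | 'projected'
    predator_policy: str          # 'full' | 'underexploited'
    multiplier: float
    predator_id: str = "arrowtooth"

    def __post_init__(self):
        if self.climate not in ("historical", "projected"):
            raise ConfigurationError(f"unknown climate {self.climate!r}")
        if self.predator_policy not in ("full", "underexploited"):
            raise ConfigurationError(f"unknown predator policy {self.predator_policy!r}")
        if not (0.0 <= self.multiplier <= MAX_MULTIPLIER):
            raise ConfigurationError("multiplier must lie in [0, 4]")

    @property
    def scenario_key(self) -> str:
        return f"{self.climate}-{self.predator_policy}"


@dataclass
class Step1Result:
    mf_msy: dict                       # group id -> F_MSY
    profiles: dict                     # group id -> MsyProfile
    run_count: int


@dataclass
class Step2Result:
    runs: dict                         # ScenarioSpec -> RunResult
    summaries: dict                    # ScenarioSpec -> EquilibriumSummary
    mf_msy: dict
    run_count: int
    predator_id: str = "arrowtooth"
    multipliers: np.ndarray = field(default_factory=multiplier_grid)


def _scenario_policy(config: FoodWebConfig, focal_F: dict) -> dict:
    """Scenario fishing: focal groups per ``focal_F``; all other fished
    groups stay at calibration quarter-M / quarter-F_OFL."""
    pol = config.calibration_policy()
    pol.update(focal_F)
    return pol


def profile_fmsy(config: FoodWebConfig, group: str, historical: ForcingSeries,
                 *, total_years: int = 80, burn_in_years: int = 30,
                 dt: float = 1.0 / 12.0, engine: Engine | None = None) -> MsyProfile:
    """Step-1 F profile for one focal group.

    Thirteen simulations with the target group's F at each grid value
    and every other fished group at its calibration F, under looped
    historical forcing. F_MSY is the argmax of last-5-year mean catch.
    """
    if group not in config.index:
        raise ConfigurationError(f"unknown group {group!r}")
    if not config.by_id[group].is_focal:
        raise ConfigurationError(f"group {group!r} is not focal")
    eng = engine if engine is not None else Engine(config)
    grid = f_grid(config.f_base(group))
    calib = config.calibration_policy()
    catch = np.full(N_GRID, np.nan)
    ssb = np.full(N_GRID, np.nan)
    cv = np.full(N_GRID, np.nan)
    partial = False
    for k, F in enumerate(grid):
        spec = RunSpec(historical=historical, burn_in_fishing=calib,
                       scenario_fishing=_scenario_policy(config, {group: float(F)}),
                       total_years=total_years, burn_in_years=burn_in_years,
                       dt=dt, record_flows=False)
        try:
            res = eng.run(spec)
        except Exception:
            log.exception("profile run diverged: group=%s F=%.4f", group, F)
            partial = True
            continue
        summ = summarize_equilibrium(res)
        catch[k] = summ.table.loc[group, "catch_mean"]
        ssb[k] = summ.table.loc[group, "ssb_mean"]
        cv[k] = summ.table.loc[group, "catch_cv"]
    if np.all(np.isnan(catch)):
        raise RuntimeError(f"all profile runs failed for group {group!r}")
    finite = np.nan_to_num(catch, nan=-np.inf)
    best = int(np.argmax(finite))      # first occurrence => smallest F on ties
    unfished_ssb = ssb[0]
    depl = float(ssb[best] / unfished_ssb) if unfished_ssb > 0 else float("nan")
    if best == N_GRID - 1:
        log.warning("F_MSY for %s at the upper grid boundary (4 x base)", group)
    return MsyProfile(group=group, F_values=grid, catch=catch, ssb=ssb,
                      catch_cv=cv, F_MSY=float(grid[best]), msy=float(catch[best]),
                      depletion_at_FMSY=depl, at_boundary=best == N_GRID - 1,
                      partial=partial)


def run_step1(config: FoodWebConfig, historical: ForcingSeries,
              focal_ids: list[str] | None = None, *, total_years: int = 80,
              burn_in_years: int = 30, dt: float = 1.0 / 12.0) -> Step1Result:
    """Profile every focal group; |focal| x 13 runs total."""
    ids = list(focal_ids) if focal_ids is not None else config.focal_ids
    unknown = [g for g in ids if g not in config.index]
    if unknown:
        raise ConfigurationError(f"unknown focal ids {unknown}")
    eng = Engine(config)
    profiles = {}
    for gid in ids:
        log.info("step 1: profiling %s", gid)
        profiles[gid] = profile_fmsy(config, gid, historical,
                                     total_years=total_years,
                                     burn_in_years=burn_in_years, dt=dt,
                                     engine=eng)
    mf_msy = {gid: p.F_MSY for gid, p in profiles.items()}
    return Step1Result(mf_msy=mf_msy, profiles=profiles,
                       run_count=len(ids) * N_GRID)


def step2_fishing_policy(config: FoodWebConfig, mf_msy: dict, scenario: ScenarioSpec
                         ) -> dict:
    """Realized scenario F per fished group for one Step-2 cell.

    Focal F = multiplier x F_MSY; under the underexploited policy the
    key predator's F is pinned at its calibration quarter-F_OFL
    regardless of the multiplier; non-focal fished groups stay at
    calibration quarter-M.
    """
    focal_F = {gid: scenario.multiplier * f for gid, f in mf_msy.items()}
    if scenario.predator_policy == "underexploited":
        if scenario.predator_id not in config.index:
            raise ConfigurationError(
                f"unknown predator group {scenario.predator_id!r}")
        focal_F[scenario.predator_id] = 0.25 * config.f_base(scenario.predator_id)
    return _scenario_policy(config, focal_F)


def run_step2(config: FoodWebConfig, mf_msy: dict, historical: ForcingSeries,
              warm: ForcingSeries, *, multipliers=None,
              predator_id: str = "arrowtooth", scenarios=SCENARIOS,
              total_years: int = 80, burn_in_years: int = 30,
              dt: float = 1.0 / 12.0, record_flows: bool = True) -> Step2Result:
    """The 4-scenario x 13-multiplier grid (52 runs at defaults).

    Burn-in always uses calibration fishing and historical forcing; at
    the scenario switch both the fishing policy and (for projected
    scenarios) the warm regime are applied abruptly.
    """
    mult = multiplier_grid() if multipliers is None else np.asarray(multipliers, float)
    eng = Engine(config)
    calib = config.calibration_policy()
    runs, summaries = {}, {}
    count = 0
    for (climate, policy), m in itertools.product(scenarios, mult):
        sc = ScenarioSpec(climate=climate, predator_policy=policy,
                          multiplier=float(m), predator_id=predator_id)
        regime = warm if climate == "projected" else historical
        spec = RunSpec(historical=historical, regime=regime,
                       burn_in_fishing=calib,
                       scenario_fishing=step2_fishing_policy(config, mf_msy, sc),
                       total_years=total_years, burn_in_years=burn_in_years,
                       dt=dt, record_flows=record_flows)
        log.info("step 2: %s multiplier %.3f", sc.scenario_key, m)
        res = eng.run(spec)
        runs[sc] = res
        summaries[sc] = summarize_equilibrium(res)
        count += 1
    return Step2Result(runs=runs, summaries=summaries, mf_msy=dict(mf_msy),
                       run_count=count, predator_id=predator_id, multipliers=mult)
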