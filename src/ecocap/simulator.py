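"""Time-stepping engine: burn-in + scenario phases and equilibrium summaries.

Runs are 80 years by default: a 30-year burn-in under calibration
fishing and the historical regime (letting the web cycle through initial
instabilities), then an abrupt switch to the scenario fishing policy and
climate regime. Outputs are recorded at year boundaries; "equilibrium"
is operationalized as the mean over the final five years.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ConfigurationError, SimulationDivergedError
from .foodweb import (
    GROWTH_KAPPA,
    KG_PER_T,
    MAX_REMOVAL_FRACTION,
    EcosystemState,
    FoodWebConfig,
    advance_year,
    habitat_suitability,
    temperature_scalar,
    unfished_equilibrium,
)
from .forcing import ForcingSeries

__all__ = [
    "RunSpec",
    "RunResult",
    "EquilibriumSummary",
    "Engine",
    "run_simulation",
    "summarize_equilibrium",
    "default_initial_state",
]

log = logging.getLogger(__name__)


@dataclass
class RunSpec:
    """Protocol for one simulation run.

    ``burn_in_fishing`` / ``scenario_fishing`` map fished group id to
    its time-invariant F (yr^-1); every group of kind
    ``age_structured_fish`` must be covered (endotherms are not fished).
    ``historical`` forces the burn-in; ``regime`` forces the scenario
    years (defaults to ``historical``).
    """

    historical: ForcingSeries
    regime: ForcingSeries | None = None
    burn_in_fishing: dict = field(default_factory=dict)
    scenario_fishing: dict = field(default_factory=dict)
    total_years: int = 80
    burn_in_years: int = 30
    dt: float = 1.0 / 12.0
    record_flows: bool = True
    init_jitter: float = 0.0   # fractional abundance jitter at t=0 (seeded), default off

    def __post_init__(self):
        if self.regime is None:
            self.regime = self.historical
        if not (0 <= self.burn_in_years < self.total_years):
            raise ConfigurationError(
                "RunSpec requires 0 <= burn_in_years < total_years"
            )
        if self.dt <= 0 or self.dt > 1:
            raise ConfigurationError("RunSpec requires 0 < dt <= 1")
        spy = round(1.0 / self.dt)
        if abs(spy * self.dt - 1.0) > 1e-9:
            raise ConfigurationError("dt must divide one year into integer steps")

    @property
    def steps_per_year(self) -> int:
        return round(1.0 / self.dt)

    def fishing_for(self, config: FoodWebConfig, phase: str) -> dict:
        pol = dict(self.burn_in_fishing if phase == "burn_in" else self.scenario_fishing)
        missing = [g.id for g in config.groups
                   if g.kind == "age_structured_fish" and g.id not in pol]
        if missing:
            raise ConfigurationError(
                f"{phase} fishing policy does not cover fished groups: {missing}"
            )
        return pol


@dataclass
class RunResult:
    """Annual outputs of one run: [year, group(, age)] arrays plus a spec echo."""

    group_ids: list[str]
    years: np.ndarray          # [T], 1-based simulation year
    catch: np.ndarray          # [T, G], t
    ssb: np.ndarray            # [T, G], t (0 for pools)
    biomass: np.ndarray        # [T, G], t
    naa: np.ndarray            # [T, G, A], individuals (post-aging census)
    flows: np.ndarray | None   # [T, G, G] pred->prey biomass consumed, t
    spec: RunSpec
    final_state: EcosystemState | None = None
    config: FoodWebConfig | None = None

    @property
    def index(self) -> dict:
        return {g: i for i, g in enumerate(self.group_ids)}

    def to_frame(self) -> pd.DataFrame:
        """Tidy (year, group, metric, value) table of the annual series."""
        frames = []
        for metric, arr in (("catch", self.catch), ("ssb", self.ssb),
                            ("biomass", self.biomass)):
            df = pd.DataFrame(arr, columns=self.group_ids)
            df["year"] = self.years
            df = df.melt(id_vars="year", var_name="group", value_name="value")
            df["metric"] = metric
            frames.append(df)
        return pd.concat(frames, ignore_index=True)[["year", "group", "metric", "value"]]


@dataclass
class EquilibriumSummary:
    """Last-5-year means and CVs of catch and SSB per group.

    ``table`` has one row per group with columns ``catch_mean``,
    ``catch_cv``, ``ssb_mean``, ``ssb_cv``, ``biomass_mean``,
    ``is_focal`` and ``counts_toward_cap``; ``aggregate_focal_catch`` is
    the summed mean catch over focal groups (t). CV = sd/mean, defined 0
    when the mean is 0.
    """

    table: pd.DataFrame
    aggregate_focal_catch: float
    window: int = 5


class Engine:
    """Precomputed, reusable simulation engine for one food-web configuration."""

    def __init__(self, config: FoodWebConfig):
        self.config = config
        G = len(config.groups)
        A = config.max_ages
        self.G, self.A = G, A
        self.av, self.H = config.diet.to_arrays(config)
        self.is_pool = np.array([g.kind == "biomass_pool" for g in config.groups])
        self.is_fish = np.array([g.kind == "age_structured_fish" for g in config.groups])
        self.is_endo = np.array([g.kind == "endotherm" for g in config.groups])
        self.age_struct = ~self.is_pool
        self.M0 = np.array([g.M0 for g in config.groups])
        self.Cmax = np.array([g.Cmax for g in config.groups])
        self.W_ref = np.zeros((G, A))
        self.valid = np.zeros((G, A), dtype=bool)
        self.select = np.zeros((G, A))
        for i, g in enumerate(config.groups):
            if g.age_structured:
                self.W_ref[i, :g.n_ages] = g.W_ref
                self.valid[i, :g.n_ages] = True
                self.select[i, g.age_select - 1:g.n_ages] = 1.0
        self.pool_r = np.array([g.r for g in config.groups])
        self.pool_K = np.array([max(g.K, 1.0) for g in config.groups])

    # -- thermal responses precomputed per regime ------------------------

    def _thermal(self, regime: ForcingSeries, steps_per_year: int):
        stepT = regime.step_means(steps_per_year)
        fT = np.ones((steps_per_year, self.G))
        sigma = np.ones((steps_per_year, self.G))
        for i, g in enumerate(self.config.groups):
            if not g.age_structured:
                continue
            sigma[:, i] = habitat_suitability(stepT, g.niche)
            if g.kind == "endotherm":
                fT[:, i] = 1.0
            else:
                fT[:, i] = temperature_scalar(stepT, g.T_opt, g.T_max, g.Qc)
        return stepT, fT, sigma

    # -- main loop -------------------------------------------------------

    def run(self, spec: RunSpec, seed: int | None = None,
            initial_state: EcosystemState | None = None) -> RunResult:
        cfg = self.config
        G, A = self.G, self.A
        spy = spec.steps_per_year
        dt = spec.dt

        state = (initial_state.copy() if initial_state is not None
                 else default_initial_state(cfg))
        if spec.init_jitter > 0:
            rng = np.random.default_rng(0 if seed is None else seed)
            state.N *= 1.0 + spec.init_jitter * rng.uniform(-1, 1, size=state.N.shape)
            state.B_pool *= 1.0 + spec.init_jitter * rng.uniform(-1, 1, size=G)

        phases = {}
        for phase, regime in (("burn_in", spec.historical), ("scenario", spec.regime)):
            pol = spec.fishing_for(cfg, phase)
            F = np.zeros(G)
            for gid, f in pol.items():
                if gid not in cfg.index:
                    raise ConfigurationError(f"fishing policy names unknown group {gid!r}")
                if f < 0:
                    raise ConfigurationError(f"negative F for group {gid!r}")
                F[cfg.index[gid]] = f
            stepT, fT, sigma = self._thermal(regime, spy)
            s_prod = np.array([regime.scalar_for(g.id) for g in cfg.groups])
            phases[phase] = (F, stepT, fT, sigma, s_prod, regime.annual_mean)

        T_years = spec.total_years
        catch = np.zeros((T_years, G))
        ssb = np.zeros((T_years, G))
        biomass = np.zeros((T_years, G))
        naa = np.zeros((T_years, G, A))
        flows = np.zeros((T_years, G, G)) if spec.record_flows else None

        log.info("run start: %d years (%d burn-in), dt=%.4f", T_years,
                 spec.burn_in_years, dt)
        for year in range(1, T_years + 1):
            phase = "burn_in" if year <= spec.burn_in_years else "scenario"
            if year == spec.burn_in_years + 1:
                log.info("switching to scenario fishing and regime at year %d", year)
            F, stepT, fT, sigma, s_prod, T_spawn = phases[phase]

            demand_year = np.zeros(G)
            realized_year = np.zeros(G)
            for k in range(spy):
                self._step(state, F, stepT[k], fT[k], sigma[k], s_prod, dt,
                           year, catch[year - 1],
                           flows[year - 1] if flows is not None else None,
                           demand_year, realized_year)
            state.t = float(year)

            # annual transition: aging, spawning, recruitment
            with np.errstate(invalid="ignore"):
                rho_year = np.where(demand_year > 0,
                                    realized_year / np.where(demand_year > 0,
                                                             demand_year, 1.0),
                                    1.0)
            for i, g in enumerate(cfg.groups):
                if not g.age_structured:
                    continue
                if g.kind == "endotherm":
                    # reproduction scales with realized body condition, not SSB
                    rec = g.R0 * float(np.clip(rho_year[i], 0.0, 1.0))
                    N, W, s = advance_year(state.N[i, :g.n_ages],
                                           state.W[i, :g.n_ages], g,
                                           recruits=rec, year=year)
                else:
                    N, W, s = advance_year(state.N[i, :g.n_ages],
                                           state.W[i, :g.n_ages], g,
                                           recruits=None, year=year,
                                           T_spawn=T_spawn)
                state.N[i, :g.n_ages] = N
                state.W[i, :g.n_ages] = W
                ssb[year - 1, i] = s

            if not (np.all(np.isfinite(state.N)) and np.all(np.isfinite(state.W))
                    and np.all(np.isfinite(state.B_pool))):
                bad = ~(np.all(np.isfinite(state.N), axis=1)
                        & np.all(np.isfinite(state.W), axis=1)
                        & np.isfinite(state.B_pool))
                raise SimulationDivergedError(year, cfg.groups[int(np.argmax(bad))].id)

            biomass[year - 1] = state.biomass(cfg)
            naa[year - 1] = state.N
            if year % 10 == 0:
                log.debug("completed year %d", year)

        log.info("run complete")
        return RunResult(group_ids=cfg.ids, years=np.arange(1, T_years + 1),
                         catch=catch, ssb=ssb, biomass=biomass, naa=naa,
                         flows=flows, spec=spec, final_state=state, config=cfg)

    def _step(self, state, F, T, fT, sigma, s_prod, dt, year,
              catch_acc, flow_acc, demand_year, realized_year):
        """One sub-annual step: consumption, mortality, growth, pool dynamics."""
        G, A = self.G, self.A
        B = state.biomass(self.config)

        # consumption (Holling II over availability-weighted prey field);
        # non-finite intermediates are tolerated here and trapped by the
        # per-year divergence check
        with np.errstate(invalid="ignore", divide="ignore"):
            demand = (self.Cmax * fT * sigma)[:, None] * state.N * state.W * dt \
                / KG_PER_T
            weighted = self.av * B[None, None, :]
            prey_field = weighted.sum(axis=2)
            phi = prey_field / self.H[:, None]
            realized = demand * phi / (1.0 + phi)
            denom = np.where(prey_field > 0, prey_field, 1.0)
            Q = realized[:, :, None] * (weighted / denom[:, :, None])
        removal = Q.sum(axis=(0, 1))
        limit = MAX_REMOVAL_FRACTION * B
        over = removal > limit
        if np.any(over):
            scale = np.where(over, limit / np.where(removal > 0, removal, 1.0), 1.0)
            Q *= scale[None, None, :]
            removal = Q.sum(axis=(0, 1))
        realized = Q.sum(axis=2)

        demand_year += demand.sum(axis=1)
        realized_year += realized.sum(axis=1)

        # predation mortality on age-structured prey: removal spread over
        # ages proportionally to biomass-at-age, i.e. a uniform rate
        with np.errstate(divide="ignore", invalid="ignore"):
            M2 = np.where(self.age_struct & (B > 0),
                          removal / (np.where(B > 0, B, 1.0) * dt), 0.0)

        # Baranov survival and catch
        Z = (self.M0 + M2)[:, None] + F[:, None] * self.select
        decay = np.exp(-Z * dt)
        deaths = state.N * (1.0 - decay)
        with np.errstate(divide="ignore", invalid="ignore"):
            frac_f = np.where(Z > 0, F[:, None] * self.select / np.where(Z > 0, Z, 1.0),
                              0.0)
        catch_n = frac_f * deaths
        catch_acc += (catch_n * state.W).sum(axis=1) / KG_PER_T
        state.N *= decay

        # growth toward ration-scaled reference weight
        with np.errstate(invalid="ignore"):
            rho = np.where(demand > 0, realized / np.where(demand > 0, demand, 1.0), 1.0)
        grow = state.W + GROWTH_KAPPA * (rho * self.W_ref - state.W) * dt
        state.W = np.where(self.valid, grow, state.W)

        # logistic pools with scenario productivity scalars
        pools = self.is_pool
        Bp = state.B_pool
        growth_inc = self.pool_r * s_prod * Bp * (1.0 - Bp / self.pool_K) * dt
        state.B_pool = np.where(pools, np.maximum(Bp + growth_inc - removal, 0.0), Bp)

        if flow_acc is not None:
            flow_acc += Q.sum(axis=1)


def default_initial_state(config: FoodWebConfig) -> EcosystemState:
    """Initial state: each group at its decoupled unfished equilibrium, pools at B0 (or K)."""
    G, A = len(config.groups), config.max_ages
    N = np.zeros((G, A))
    W = np.zeros((G, A))
    B_pool = np.zeros(G)
    for i, g in enumerate(config.groups):
        if g.age_structured:
            n, w = unfished_equilibrium(g)
            N[i, :g.n_ages] = n
            W[i, :g.n_ages] = w
        else:
            B_pool[i] = g.B0 if g.B0 > 0 else g.K
    return EcosystemState(N=N, W=W, B_pool=B_pool, t=0.0)


def run_simulation(config: FoodWebConfig, spec: RunSpec,
                   seed: int | None = None) -> RunResult:
    """Run one simulation. The model is deterministic; ``seed`` only
    controls optional initialization jitter (``spec.init_jitter``, default off)."""
    return Engine(config).run(spec, seed=seed)


def summarize_equilibrium(result: RunResult, window: int = 5) -> EquilibriumSummary:
    """Means and CVs of catch and SSB over exactly the final ``window`` years."""
    if result.catch.shape[0] < window:
        raise ValueError(
            f"run has {result.catch.shape[0]} years; need at least {window}"
        )
    cfg_ids = result.group_ids
    tail = slice(-window, None)

    def mean_cv(arr):
        m = arr[tail].mean(axis=0)
        sd = arr[tail].std(axis=0, ddof=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            cv = np.where(m != 0, sd / np.where(m != 0, m, 1.0), 0.0)
        return m, cv

    cm, ccv = mean_cv(result.catch)
    sm, scv = mean_cv(result.ssb)
    bm = result.biomass[tail].mean(axis=0)
    if result.config is not None:
        focal = np.array([g.is_focal for g in result.config.groups])
        countable = np.array([g.counts_toward_cap for g in result.config.groups])
    else:
        focal = np.zeros(len(cfg_ids), dtype=bool)
        countable = np.ones(len(cfg_ids), dtype=bool)
    table = pd.DataFrame({
        "group": cfg_ids, "catch_mean": cm, "catch_cv": ccv,
        "ssb_mean": sm, "ssb_cv": scv, "biomass_mean": bm,
        "is_focal": focal, "counts_toward_cap": countable,
    }).set_index("group")
    agg = float(cm[focal].sum())
    return EquilibriumSummary(table=table, aggregate_focal_catch=agg, window=window)
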