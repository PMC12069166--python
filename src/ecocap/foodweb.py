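"""Domain types and single-step dynamics of the age-structured food-web model.

The model is a zero-dimensional (single well-mixed box) multispecies
simulator. Vertebrates are age-structured populations with annual
recruitment, sub-annual Baranov mortality, and consumption-mediated
growth; invertebrates and plankton are logistic biomass pools. Three
temperature linkages are represented:

1. a trapezoidal thermal-habitat suitability that scales foraging
   exposure (the 0-D collapse of a spatial thermal niche),
2. a trapezoidal spawning-temperature gate on recruitment
   (stenothermic reproduction), and
3. a unimodal bioenergetic scaling of maximum consumption rate.

All biomasses are metric tons (t), body mass is kg, abundance is
individuals, rates are yr^-1 and temperatures are deg C. Age classes are
1-based; each class may span ``years_per_age`` calendar years for
long-lived species.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace

import numpy as np

from .errors import ConfigurationError, StateCorruptionError

__all__ = [
    "GroupSpec",
    "DietMatrix",
    "FoodWebConfig",
    "EcosystemState",
    "ConsumptionFlows",
    "temperature_scalar",
    "habitat_suitability",
    "spawning_gate",
    "beverton_holt",
    "recruit",
    "compute_consumption",
    "pool_update",
    "apply_mortality_and_catch",
    "update_growth",
    "advance_year",
    "unfished_equilibrium",
]

log = logging.getLogger(__name__)

KINDS = ("age_structured_fish", "biomass_pool", "endotherm")

# Fraction of prey standing stock that may be removed by predation in a
# single sub-annual step; flows onto a prey are rescaled proportionally
# when aggregate demand exceeds this. Keeps state positive without an
# implicit solver.
MAX_REMOVAL_FRACTION = 0.9

# Relaxation rate (yr^-1) of weight-at-age toward the ration-scaled
# reference weight.
GROWTH_KAPPA = 1.0

KG_PER_T = 1000.0


# --------------------------------------------------------------------------
# group specification
# --------------------------------------------------------------------------

@dataclass
class GroupSpec:
    """Life-history, thermal and exploitation parameters for one functional group.

    Age-structured fields (``n_ages`` ... ``h``) apply to kinds
    ``age_structured_fish`` and ``endotherm``; pool fields (``r``, ``K``,
    ``B0``) apply to ``biomass_pool``. ``S0`` is the unfished spawning
    biomass used to normalize the Beverton-Holt curve; if left at 0 it is
    derived from ``R0`` and the unfished per-recruit spawning biomass at
    validation time.
    """

    id: str
    kind: str = "age_structured_fish"
    # --- age-structured parameters ---
    n_ages: int = 1
    years_per_age: int = 1
    M0: float = 0.0                  # background natural mortality, yr^-1
    F_OFL: float | None = None       # overfishing-limit fishing mortality, yr^-1
    age_mature: int = 1              # first mature age class (1-based)
    age_select: int = 1              # first fished age class (knife edge)
    W_ref: tuple[float, ...] = ()    # reference weight-at-age, kg
    R0: float = 0.0                  # unfished recruitment, individuals/yr
    S0: float = 0.0                  # unfished spawning biomass, t (0 => derive)
    h: float = 0.75                  # Beverton-Holt steepness, (0.2, 1]
    Cmax: float = 0.0                # max per-mass consumption, yr^-1
    T_opt: float = 8.0               # bioenergetic optimum, deg C
    T_max: float = 16.0              # upper lethal temperature, deg C
    Qc: float = 2.0                  # Q10-like consumption coefficient, > 1
    spawn_window: tuple[float, float, float] = (-5.0, 25.0, 1.0)  # (T_lo, T_hi, taper)
    niche: tuple[float, float, float, float] = (-5.0, 0.0, 20.0, 25.0)
    is_focal: bool = False
    counts_toward_cap: bool = True
    # --- biomass-pool parameters ---
    r: float = 0.0                   # logistic growth rate, yr^-1
    K: float = 0.0                   # carrying capacity, t
    B0: float = 0.0                  # initial biomass, t (0 => K)

    @property
    def age_structured(self) -> bool:
        return self.kind in ("age_structured_fish", "endotherm")

    def validate(self) -> None:
        if self.kind not in KINDS:
            raise ConfigurationError(f"group {self.id!r}: unknown kind {self.kind!r}")
        if self.kind == "biomass_pool":
            if self.r <= 0 or self.K <= 0:
                raise ConfigurationError(
                    f"group {self.id!r}: biomass pool requires r > 0 and K > 0"
                )
            return
        if self.n_ages < 1:
            raise ConfigurationError(f"group {self.id!r}: n_ages must be >= 1")
        if self.years_per_age < 1:
            raise ConfigurationError(f"group {self.id!r}: years_per_age must be >= 1")
        if self.kind == "age_structured_fish" and self.M0 <= 0:
            raise ConfigurationError(f"group {self.id!r}: fish require M0 > 0")
        if self.M0 < 0:
            raise ConfigurationError(f"group {self.id!r}: M0 must be non-negative")
        if self.F_OFL is not None and self.F_OFL < 0:
            raise ConfigurationError(f"group {self.id!r}: F_OFL must be non-negative")
        if len(self.W_ref) != self.n_ages:
            raise ConfigurationError(
                f"group {self.id!r}: W_ref length {len(self.W_ref)} != n_ages {self.n_ages}"
            )
        w = np.asarray(self.W_ref, dtype=float)
        if np.any(w <= 0) or np.any(np.diff(w) < 0):
            raise ConfigurationError(
                f"group {self.id!r}: W_ref must be strictly positive and non-decreasing"
            )
        if not (1 <= self.age_mature <= self.n_ages):
            raise ConfigurationError(f"group {self.id!r}: age_mature out of range")
        if not (1 <= self.age_select <= self.n_ages):
            raise ConfigurationError(f"group {self.id!r}: age_select out of range")
        if self.age_select > self.age_mature:
            # at least one mature class must be fully selected (knife edge
            # aligned with the age at first maturity)
            raise ConfigurationError(
                f"group {self.id!r}: age_select ({self.age_select}) must not exceed "
                f"age_mature ({self.age_mature})"
            )
        if not (0.2 < self.h <= 1.0):
            raise ConfigurationError(f"group {self.id!r}: steepness h must be in (0.2, 1]")
        if self.R0 < 0:
            raise ConfigurationError(f"group {self.id!r}: R0 must be non-negative")
        if self.Cmax < 0:
            raise ConfigurationError(f"group {self.id!r}: Cmax must be non-negative")
        if not self.T_opt < self.T_max:
            raise ConfigurationError(
                f"group {self.id!r}: requires T_opt < T_max "
                f"(got T_opt={self.T_opt}, T_max={self.T_max})"
            )
        if self.Qc <= 1.0:
            raise ConfigurationError(f"group {self.id!r}: Qc must exceed 1")
        lo, hi, tau = self.spawn_window
        if lo > hi or tau < 0:
            raise ConfigurationError(
                f"group {self.id!r}: spawn_window requires T_lo <= T_hi and taper >= 0"
            )
        t0, t1, t2, t3 = self.niche
        if not (t0 <= t1 <= t2 <= t3):
            raise ConfigurationError(
                f"group {self.id!r}: niche breakpoints must be ordered T0<=T1<=T2<=T3"
            )


# --------------------------------------------------------------------------
# diet matrix
# --------------------------------------------------------------------------

@dataclass
class DietMatrix:
    """Availability of prey groups to predator age classes.

    ``availability`` maps ``(pred_id, prey_id)`` to either a scalar
    (applies to every predator age) or a sequence of per-age fractions.
    ``half_saturation`` maps predator id to the available-prey biomass
    (t) at which intake reaches half of demand (shared across the
    predator's prey, multispecies Holling type II).
    """

    availability: dict = field(default_factory=dict)
    half_saturation: dict = field(default_factory=dict)

    def validate(self, config: "FoodWebConfig") -> None:
        by_id = config.by_id
        for (pred, prey), val in self.availability.items():
            if pred not in by_id:
                raise ConfigurationError(f"diet: unknown predator {pred!r}")
            if prey not in by_id:
                raise ConfigurationError(f"diet: unknown prey {prey!r}")
            if pred == prey:
                raise ConfigurationError(
                    f"diet: self-predation entry for {pred!r} is not allowed"
                )
            if not by_id[pred].age_structured:
                raise ConfigurationError(
                    f"diet: biomass pool {pred!r} cannot be a predator"
                )
            arr = np.atleast_1d(np.asarray(val, dtype=float))
            if np.any(arr < 0) or np.any(arr > 1):
                raise ConfigurationError(
                    f"diet: availability for ({pred!r}, {prey!r}) must lie in [0, 1]"
                )
            if arr.size not in (1, by_id[pred].n_ages):
                raise ConfigurationError(
                    f"diet: availability for ({pred!r}, {prey!r}) must be scalar or "
                    f"length n_ages={by_id[pred].n_ages}"
                )
        for pred, H in self.half_saturation.items():
            if pred not in by_id:
                raise ConfigurationError(f"diet: half_saturation for unknown group {pred!r}")
            if H <= 0:
                raise ConfigurationError(f"diet: half_saturation for {pred!r} must be > 0")

    def predators_of(self, prey_id: str) -> list[str]:
        """Groups with non-zero availability onto ``prey_id``."""
        out = []
        for (pred, prey), val in self.availability.items():
            if prey == prey_id and np.any(np.asarray(val, dtype=float) > 0):
                out.append(pred)
        return sorted(set(out))

    def prey_of(self, pred_id: str) -> list[str]:
        """Groups with non-zero availability to predator ``pred_id``."""
        out = []
        for (pred, prey), val in self.availability.items():
            if pred == pred_id and np.any(np.asarray(val, dtype=float) > 0):
                out.append(prey)
        return sorted(set(out))

    def to_arrays(self, config: "FoodWebConfig") -> tuple[np.ndarray, np.ndarray]:
        """Dense ``(availability[G, A, G], H[G])`` arrays aligned with the config."""
        G = len(config.groups)
        A = config.max_ages
        av = np.zeros((G, A, G))
        idx = config.index
        for (pred, prey), val in self.availability.items():
            gi = idx[pred]
            na = config.groups[gi].n_ages
            arr = np.atleast_1d(np.asarray(val, dtype=float))
            if arr.size == 1:
                av[gi, :na, idx[prey]] = arr[0]
            else:
                av[gi, :na, idx[prey]] = arr
        H = np.ones(G)
        for pred, val in self.half_saturation.items():
            H[idx[pred]] = float(val)
        return av, H


# --------------------------------------------------------------------------
# configuration container
# --------------------------------------------------------------------------

@dataclass
class FoodWebConfig:
    """A fully parameterized food web: groups plus their trophic links."""

    groups: list[GroupSpec]
    diet: DietMatrix = field(default_factory=DietMatrix)

    def __post_init__(self):
        self.validate()

    @property
    def by_id(self) -> dict[str, GroupSpec]:
        return {g.id: g for g in self.groups}

    @property
    def index(self) -> dict[str, int]:
        return {g.id: i for i, g in enumerate(self.groups)}

    @property
    def ids(self) -> list[str]:
        return [g.id for g in self.groups]

    @property
    def focal_ids(self) -> list[str]:
        return [g.id for g in self.groups if g.is_focal]

    @property
    def max_ages(self) -> int:
        return max((g.n_ages for g in self.groups if g.age_structured), default=1)

    def validate(self) -> None:
        seen = set()
        for g in self.groups:
            if g.id in seen:
                raise ConfigurationError(f"duplicate group id {g.id!r}")
            seen.add(g.id)
            g.validate()
        self.diet.validate(self)
        # derive S0 where not provided
        for i, g in enumerate(self.groups):
            if g.age_structured and g.R0 > 0 and g.S0 == 0.0:
                N, W = unfished_equilibrium(g)
                s0 = spawning_biomass(g, N, W)
                self.groups[i] = replace(g, S0=s0)

    def calibration_policy(self) -> dict[str, float]:
        """Calibration fishing: quarter F_OFL where defined, else quarter M.

        Endotherm groups are not fished.
        """
        pol = {}
        for g in self.groups:
            if g.kind != "age_structured_fish":
                continue
            base = g.F_OFL if g.F_OFL is not None else g.M0
            pol[g.id] = 0.25 * base
        return pol

    def f_base(self, group_id: str) -> float:
        """Base rate for F grids: F_OFL where available, else M."""
        g = self.by_id[group_id]
        base = g.F_OFL if g.F_OFL is not None else g.M0
        if base is None or base <= 0:
            raise ConfigurationError(
                f"group {group_id!r}: no positive F_OFL or M to scale an F grid from"
            )
        return base


# --------------------------------------------------------------------------
# state containers
# --------------------------------------------------------------------------

@dataclass
class EcosystemState:
    """Numbers-, weight-at-age and pool biomasses at one instant.

    ``N`` and ``W`` are ``[G, A]`` arrays padded with zeros beyond each
    group's ``n_ages``; ``B_pool`` is ``[G]`` (zero for age-structured
    groups); ``t`` is fractional simulation time in years.
    """

    N: np.ndarray
    W: np.ndarray
    B_pool: np.ndarray
    t: float = 0.0

    def copy(self) -> "EcosystemState":
        return EcosystemState(self.N.copy(), self.W.copy(), self.B_pool.copy(), self.t)

    def check(self, config: FoodWebConfig) -> None:
        for arr, name in ((self.N, "N"), (self.W, "W"), (self.B_pool, "B_pool")):
            if np.any(arr < 0):
                g = int(np.argwhere(arr < 0)[0][0])
                raise StateCorruptionError(
                    f"negative {name} for group {config.groups[g].id!r}"
                )

    def biomass(self, config: FoodWebConfig) -> np.ndarray:
        """Total biomass per group (t): sum(N*W)/1000 for age-structured, pool value else."""
        b = (self.N * self.W).sum(axis=1) / KG_PER_T
        pool = np.array([g.kind == "biomass_pool" for g in config.groups])
        return np.where(pool, self.B_pool, b)


@dataclass
class ConsumptionFlows:
    """Realized predation flows for one step.

    ``Q[pred, pred_age, prey]`` is biomass (t) consumed during the step;
    ``demand`` and ``realized`` are the per-predator-age demanded and
    realized intake (t), with ``realized <= demand`` elementwise.
    """

    Q: np.ndarray
    demand: np.ndarray
    realized: np.ndarray
    group_ids: list[str] = field(default_factory=list)


# --------------------------------------------------------------------------
# temperature responses
# --------------------------------------------------------------------------

def temperature_scalar(T, T_opt: float, T_max: float, Qc: float):
    """Unimodal bioenergetic scaling of consumption rate, in [0, 1].

    The classic thermal-performance form f(T) = V^X * exp(X*(1-V)) with
    V = (T_max - T)/(T_max - T_opt). It equals 1 at T_opt, falls to 0 at
    T_max (and above), and declines smoothly toward cold temperatures at
    a rate set by the Q10-like coefficient ``Qc``.
    """
    if not T_opt < T_max:
        raise ConfigurationError(
            f"temperature_scalar requires T_opt < T_max (got {T_opt}, {T_max})"
        )
    if Qc <= 1.0:
        raise ConfigurationError(f"temperature_scalar requires Qc > 1 (got {Qc})")
    T = np.asarray(T, dtype=float)
    span = T_max - T_opt
    Z = math.log(Qc) * span
    Y = math.log(Qc) * (span + 2.0)
    X = Z * Z * (1.0 + math.sqrt(1.0 + 40.0 / Y)) ** 2 / 400.0
    V = (T_max - T) / span
    with np.errstate(divide="ignore", invalid="ignore"):
        f = np.where(V > 0, np.power(np.clip(V, 1e-300, None), X) * np.exp(X * (1.0 - V)), 0.0)
    out = np.clip(f, 0.0, 1.0)
    return float(out) if out.ndim == 0 else out


def habitat_suitability(T, niche):
    """Trapezoidal thermal-habitat suitability in [0, 1].

    0 outside [T0, T3], 1 on the plateau [T1, T2], linear on the
    shoulders. In this 0-D model it multiplies foraging demand,
    standing in for the fraction of a population's spatial habitat
    that remains thermally suitable.
    """
    t0, t1, t2, t3 = (float(v) for v in niche)
    if not (t0 <= t1 <= t2 <= t3):
        raise ConfigurationError("habitat niche breakpoints must be ordered")
    T = np.asarray(T, dtype=float)
    out = np.interp(T, [t0, t1, t2, t3], [0.0, 1.0, 1.0, 0.0], left=0.0, right=0.0)
    # np.interp handles degenerate (equal) breakpoints; force exact zeros
    # strictly outside the support
    out = np.where((T < t0) | (T > t3), 0.0, out)
    return float(out) if out.ndim == 0 else out


def spawning_gate(T, window):
    """Trapezoidal spawning-temperature gate in [0, 1].

    1 inside [T_lo, T_hi], linear taper to 0 over width tau on each
    side; tau = 0 gives a hard gate (closed strictly outside the
    window).
    """
    lo, hi, tau = (float(v) for v in window)
    if lo > hi or tau < 0:
        raise ConfigurationError("spawn window requires T_lo <= T_hi and taper >= 0")
    T = np.asarray(T, dtype=float)
    if tau == 0.0:
        out = np.where((T >= lo) & (T <= hi), 1.0, 0.0)
    else:
        out = np.interp(T, [lo - tau, lo, hi, hi + tau], [0.0, 1.0, 1.0, 0.0],
                        left=0.0, right=0.0)
    return float(out) if out.ndim == 0 else out


# --------------------------------------------------------------------------
# recruitment
# --------------------------------------------------------------------------

def beverton_holt(SSB: float, S0: float, R0: float, h: float) -> float:
    """Beverton-Holt recruitment in steepness form.

    R = 4 h R0 SSB / (S0 (1-h) + SSB (5h - 1)); returns R0 at SSB = S0
    and h*R0 at SSB = 0.2 S0.
    """
    if S0 <= 0:
        raise ConfigurationError("beverton_holt requires S0 > 0")
    if not (0.2 < h <= 1.0):
        raise ConfigurationError("beverton_holt requires h in (0.2, 1]")
    if SSB <= 0:
        return 0.0
    return 4.0 * h * R0 * SSB / (S0 * (1.0 - h) + SSB * (5.0 * h - 1.0))


def recruit(SSB: float, S0: float, R0: float, h: float,
            T_spawn_season: float, spawn_window) -> float:
    """Temperature-gated Beverton-Holt recruitment (individuals)."""
    return beverton_holt(SSB, S0, R0, h) * spawning_gate(T_spawn_season, spawn_window)


# --------------------------------------------------------------------------
# consumption
# --------------------------------------------------------------------------

def compute_consumption(state: EcosystemState, config: FoodWebConfig,
                        T: float, dt: float,
                        arrays: tuple[np.ndarray, np.ndarray] | None = None,
                        thermal: tuple[np.ndarray, np.ndarray] | None = None,
                        ) -> ConsumptionFlows:
    """Realized predation flows over one step of length ``dt`` years.

    Demand per predator age is Cmax * f(T) * sigma(T) * W * N * dt
    (converted to t); a shared-half-saturation Holling type II response
    converts the availability-weighted prey field into realized intake,
    allocated across prey proportionally to availability x biomass.
    Aggregate removal from any single prey is capped at
    ``MAX_REMOVAL_FRACTION`` of its standing biomass, with proportional
    rescaling of all flows onto that prey.

    ``arrays`` (dense diet arrays) and ``thermal`` (per-group f_T and
    sigma at this T) may be supplied by a caller that precomputes them.
    """
    if dt <= 0:
        raise ConfigurationError("compute_consumption requires dt > 0")
    state.check(config)
    av, H = arrays if arrays is not None else config.diet.to_arrays(config)
    G = len(config.groups)
    if thermal is None:
        fT = np.ones(G)
        sigma = np.ones(G)
        for i, g in enumerate(config.groups):
            if not g.age_structured:
                continue
            sigma[i] = habitat_suitability(T, g.niche)
            if g.kind == "endotherm":
                fT[i] = 1.0  # endotherm metabolism is not temperature-forced
            else:
                fT[i] = temperature_scalar(T, g.T_opt, g.T_max, g.Qc)
    else:
        fT, sigma = thermal

    B = state.biomass(config)                       # [G] prey biomass, t
    cmax = np.array([g.Cmax for g in config.groups])
    demand = (cmax * fT * sigma)[:, None] * state.N * state.W * dt / KG_PER_T  # t

    weighted = av * B[None, None, :]                # [G, A, G]
    prey_field = weighted.sum(axis=2)               # [G, A], t
    phi = prey_field / H[:, None]
    realized = demand * phi / (1.0 + phi)

    with np.errstate(invalid="ignore"):
        shares = np.where(prey_field[:, :, None] > 0,
                          weighted / np.where(prey_field[:, :, None] > 0,
                                              prey_field[:, :, None], 1.0),
                          0.0)
    Q = realized[:, :, None] * shares

    removal = Q.sum(axis=(0, 1))                    # [G] total onto each prey, t
    limit = MAX_REMOVAL_FRACTION * B
    with np.errstate(divide="ignore", invalid="ignore"):
        scale = np.where(removal > limit, limit / np.where(removal > 0, removal, 1.0), 1.0)
    Q = Q * scale[None, None, :]
    realized = Q.sum(axis=2)
    return ConsumptionFlows(Q=Q, demand=demand, realized=realized,
                            group_ids=config.ids)


# --------------------------------------------------------------------------
# pool dynamics, mortality, growth
# --------------------------------------------------------------------------

def pool_update(B: float, r: float, K: float, productivity_scalar: float,
                losses: float, dt: float):
    """Logistic biomass-pool step: B' = B + r*s*B*(1 - B/K)*dt - losses, floored at 0.

    ``productivity_scalar`` is the hook for scenario-driven productivity
    changes (e.g., halving plankton growth under a warm regime).
    """
    if r <= 0 or K <= 0:
        raise ConfigurationError("pool_update requires r > 0 and K > 0")
    if not (0.0 < productivity_scalar <= 1.0):
        raise ConfigurationError("productivity scalar must lie in (0, 1]")
    B = np.asarray(B, dtype=float)
    new = B + r * productivity_scalar * B * (1.0 - B / K) * dt - losses
    if np.any(new < 0):
        log.warning("biomass pool depleted below zero by losses; flooring at 0")
    out = np.maximum(new, 0.0)
    return float(out) if out.ndim == 0 else out


def apply_mortality_and_catch(N, W, M0: float, M2, F: float, age_select: int,
                              dt: float):
    """Baranov mortality over one step with knife-edge selectivity.

    Z = M0 + M2 + F*S with S(age) = 1 for age >= age_select (1-based)
    else 0. Returns ``(survivors, catch_biomass_t, catch_numbers)``;
    catch numbers are (F*S/Z) * N * (1 - exp(-Z*dt)) and catch biomass
    uses the current weight-at-age.
    """
    N = np.asarray(N, dtype=float)
    W = np.asarray(W, dtype=float)
    M2 = np.broadcast_to(np.asarray(M2, dtype=float), N.shape)
    if M0 < 0 or F < 0 or np.any(M2 < 0):
        raise ConfigurationError("mortality rates must be non-negative")
    ages = np.arange(1, N.shape[-1] + 1)
    S = (ages >= age_select).astype(float)
    Z = M0 + M2 + F * S
    decay = np.exp(-Z * dt)
    deaths = N * (1.0 - decay)
    with np.errstate(divide="ignore", invalid="ignore"):
        frac_f = np.where(Z > 0, F * S / np.where(Z > 0, Z, 1.0), 0.0)
    catch_n = frac_f * deaths
    survivors = N * decay
    catch_biomass = float((catch_n * W).sum() / KG_PER_T)
    return survivors, catch_biomass, catch_n


def update_growth(W, realized_intake, demand, W_ref, dt: float, kappa: float = 1.0):
    """Consumption-mediated growth: relaxation toward the condition-scaled reference.

    W' = W + kappa * (rho * W_ref - W) * dt with rho =
    realized_intake/demand (rho = 1 where demand = 0). Sustained full
    rations drive weight-at-age to W_ref; sustained rationing to
    rho * W_ref, the mechanism by which prey shortage translates into
    predator biomass loss.
    """
    W = np.asarray(W, dtype=float)
    W_ref = np.asarray(W_ref, dtype=float)
    demand = np.asarray(demand, dtype=float)
    realized = np.asarray(realized_intake, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        rho = np.where(demand > 0, realized / np.where(demand > 0, demand, 1.0), 1.0)
    out = W + kappa * (rho * W_ref - W) * dt
    return out


# --------------------------------------------------------------------------
# annual transition
# --------------------------------------------------------------------------

def spawning_biomass(spec: GroupSpec, N, W) -> float:
    """SSB (t): mature numbers x weight summed over classes >= age_mature."""
    m = spec.age_mature - 1
    return float((np.asarray(N)[m:spec.n_ages] * np.asarray(W)[m:spec.n_ages]).sum()
                 / KG_PER_T)


def advance_year(N, W, spec: GroupSpec, recruits: float | None,
                 year: int,
                 T_spawn: float | None = None) -> tuple[np.ndarray, np.ndarray, float]:
    """Annual aging + recruitment for one age-structured group.

    Aging (a shift with plus-group accumulation) happens on years that
    are multiples of ``years_per_age``; spawning biomass is evaluated on
    the post-aging structure and recruitment enters class 1 afterwards.
    If ``recruits`` is None, temperature-gated Beverton-Holt recruitment
    from the post-aging SSB is used (requires ``T_spawn``).

    Returns ``(N', W', SSB)``.
    """
    A = spec.n_ages
    N = np.asarray(N, dtype=float).copy()
    W = np.asarray(W, dtype=float).copy()
    if spec.years_per_age < 1:
        raise ConfigurationError(f"group {spec.id!r}: years_per_age must be >= 1")
    if year % spec.years_per_age == 0:
        newN = np.zeros_like(N)
        newW = np.asarray(spec.W_ref, dtype=float).copy()
        newN[1:A] = N[0:A - 1]
        newW[1:A] = W[0:A - 1]
        if A >= 2:
            tot = N[A - 1] + newN[A - 1]
            if tot > 0:
                newW[A - 1] = (N[A - 1] * W[A - 1] + newN[A - 1] * newW[A - 1]) / tot
            newN[A - 1] = tot
        else:
            newN[0] = N[0]
            newW[0] = W[0]
        N, W = newN, newW
    ssb = spawning_biomass(spec, N, W)
    if recruits is None:
        if T_spawn is None:
            raise ConfigurationError("advance_year needs T_spawn for gated recruitment")
        recruits = recruit(ssb, spec.S0, spec.R0, spec.h, T_spawn, spec.spawn_window)
    if recruits < 0:
        raise ConfigurationError("recruits must be non-negative")
    tot = N[0] + recruits
    if tot > 0:
        W[0] = (N[0] * W[0] + recruits * spec.W_ref[0]) / tot
    else:
        W[0] = spec.W_ref[0]
    N[0] = tot
    return N, W, ssb


def unfished_equilibrium(spec: GroupSpec, F: float = 0.0,
                         dt: float = 1.0 / 12.0, kappa: float = GROWTH_KAPPA,
                         max_cycles: int = 60) -> tuple[np.ndarray, np.ndarray]:
    """Equilibrium numbers/weights for a decoupled group at fixed recruitment R0
    and full rations (rho = 1).

    Iterates the annual survival + growth + aging recursion (exact for
    the time-stepping scheme, including multi-year age classes and the
    plus group) until the age structure stops changing. With F = 0 and
    years_per_age = 1 the numbers converge to N_a = R0 * exp(-M0 (a-1))
    with the plus group accumulating the geometric tail; a cohort's
    weight relaxes toward the reference weight of each class it passes
    through at rate ``kappa`` in ``1/dt`` sub-steps per year.
    """
    A = spec.n_ages
    N = np.zeros(A)
    W = np.asarray(spec.W_ref, dtype=float).copy()
    W_ref = np.asarray(spec.W_ref, dtype=float)
    ages = np.arange(1, A + 1)
    S = (ages >= spec.age_select).astype(float)
    surv = np.exp(-(spec.M0 + F * S))
    steps = round(1.0 / dt)
    lam = (1.0 - kappa * dt) ** steps   # within-year relaxation remainder
    for year in range(1, max_cycles * A * spec.years_per_age + 1):
        prev = N.copy()
        N = N * surv
        W = W_ref + (W - W_ref) * lam
        N, W, _ = advance_year(N, W, spec, recruits=spec.R0, year=year)
        if year > A * spec.years_per_age and np.allclose(N, prev, rtol=1e-13, atol=0):
            break
    return N, W
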