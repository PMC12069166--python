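"""Cap attainment, overfishing counts, depletion and indirect food-web metrics.

These are the quantities an ecosystem-cap evaluation reports: aggregate
cap-countable yield against the optimum-yield cap (800,000 t by
default), the number of focal stocks whose spawning biomass falls below
B35% (35% of unfished spawning biomass, the North Pacific overfishing
reference point), per-stock depletion, and percentage changes in the
total biomass of the predators/prey linked to forage fish and top
predators relative to the unfished run.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import CompletenessError
from .experiment import ScenarioSpec, Step2Result
from .foodweb import DietMatrix
from .simulator import EquilibriumSummary, RunResult

__all__ = [
    "DEFAULT_CAP",
    "B35_THRESHOLD",
    "CapEvaluation",
    "IndirectEffects",
    "evaluate_cap",
    "count_below_b35",
    "depletion",
    "indirect_effects",
    "realized_diet_composition",
]

log = logging.getLogger(__name__)

DEFAULT_CAP = 800_000.0   # t, Gulf of Alaska optimum-yield cap
B35_THRESHOLD = 0.35


@dataclass
class CapEvaluation:
    """Scenario x multiplier table of aggregate yield vs the cap.

    ``table`` has columns ``scenario``, ``multiplier``,
    ``aggregate_yield`` (t, cap-countable focal groups only),
    ``attained`` (aggregate >= cap), and ``n_below_b35``.
    ``depletion`` maps (scenario, multiplier) -> per-group SSB ratio
    against that scenario's multiplier-0 run.
    """

    table: pd.DataFrame
    depletion: dict
    cap: float = DEFAULT_CAP
    baseline: str = "same_scenario"


@dataclass
class IndirectEffects:
    """Per-group indirect-effect metrics vs the unfished run.

    One row per forage group (role='forage': % change in total biomass
    of its predators) and per top-predator group (role='predator':
    % change in total biomass of its prey), plus the group's own
    equilibrium biomass. ``pct_change`` is NaN where the link set is
    empty (reported not-applicable).
    """

    table: pd.DataFrame


def _aggregate_yield(summary: EquilibriumSummary, exclude_non_countable: bool = True
                     ) -> float:
    t = summary.table
    sel = t["is_focal"]
    if exclude_non_countable:
        sel = sel & t["counts_toward_cap"]
    return float(t.loc[sel, "catch_mean"].sum())


def count_below_b35(ssb: dict, ssb_unfished: dict,
                    threshold: float = B35_THRESHOLD) -> int:
    """Count groups with SSB below ``threshold`` x their unfished SSB.

    Groups with zero unfished SSB are excluded with a warning (their
    status is undefined against a collapsed baseline).
    """
    n = 0
    for gid, s in ssb.items():
        if gid not in ssb_unfished:
            raise CompletenessError(f"no unfished SSB for group {gid!r}")
        s0 = ssb_unfished[gid]
        if s0 <= 0:
            log.warning("group %s excluded from B35%% count: zero unfished SSB", gid)
            continue
        if s < threshold * s0:
            n += 1
    return n


def depletion(ssb_at_F: float, ssb_unfished: float) -> float:
    """SSB at a fishing level as a fraction of unfished SSB.

    May slightly exceed 1 when fishing elsewhere in the web releases the
    stock from predation.
    """
    if ssb_unfished <= 0:
        raise CompletenessError("depletion undefined for zero unfished SSB")
    return float(ssb_at_F / ssb_unfished)


def evaluate_cap(step2: Step2Result | dict, cap: float = DEFAULT_CAP,
                 exclude_non_countable: bool = True,
                 baseline: str = "same_scenario") -> CapEvaluation:
    """Aggregate cap-countable focal yield vs the cap, per scenario x multiplier.

    ``step2`` is a :class:`~ecocap.experiment.Step2Result` or a plain
    ``{ScenarioSpec: EquilibriumSummary}`` mapping (so a report can be
    recomputed from exported summaries alone). Attainment uses >= at
    the boundary. ``baseline`` selects the unfished reference for B35%
    counts: ``'same_scenario'`` (that scenario's multiplier-0 run,
    isolating fishing effects from climate effects) or ``'historical'``
    (the historical-climate multiplier-0 run of the same predator
    policy, measuring combined climate + fishing depletion).
    """
    summaries = step2.summaries if isinstance(step2, Step2Result) else dict(step2)
    if not summaries:
        raise CompletenessError("no scenario summaries to evaluate")
    if baseline not in ("same_scenario", "historical"):
        raise ValueError(f"unknown baseline policy {baseline!r}")

    by_key: dict = {}
    for sc, summ in summaries.items():
        by_key.setdefault(sc.scenario_key, {})[sc.multiplier] = (sc, summ)

    # unfished references
    refs = {}
    for key, cells in by_key.items():
        if 0.0 not in cells:
            raise CompletenessError(
                f"scenario {key!r} lacks the multiplier-0 (unfished baseline) run")
        refs[key] = cells[0.0][1]

    rows, depl = [], {}
    for key in sorted(by_key):
        for m in sorted(by_key[key]):
            sc, summ = by_key[key][m]
            ref_key = key if baseline == "same_scenario" else \
                f"historical-{sc.predator_policy}"
            if ref_key not in refs:
                raise CompletenessError(
                    f"baseline scenario {ref_key!r} missing for {key!r}")
            ref = refs[ref_key]
            focal = summ.table.index[summ.table["is_focal"]]
            missing = [g for g in focal if g not in ref.table.index]
            if missing:
                raise CompletenessError(f"baseline lacks groups {missing}")
            ssb = {g: float(summ.table.loc[g, "ssb_mean"]) for g in focal}
            ssb0 = {g: float(ref.table.loc[g, "ssb_mean"]) for g in focal}
            agg = _aggregate_yield(summ, exclude_non_countable)
            rows.append({
                "scenario": key, "multiplier": m, "aggregate_yield": agg,
                "attained": agg >= cap,
                "n_below_b35": count_below_b35(ssb, ssb0),
            })
            depl[(key, m)] = {g: (ssb[g] / ssb0[g] if ssb0[g] > 0 else np.nan)
                              for g in focal}
    return CapEvaluation(table=pd.DataFrame(rows), depletion=depl, cap=cap,
                         baseline=baseline)


def _equilibrium_biomass(result: RunResult, window: int = 5) -> np.ndarray:
    return result.biomass[-window:].mean(axis=0)


def indirect_effects(result: RunResult, unfished: RunResult, diet: DietMatrix,
                     forage_ids=(), predator_ids=(), window: int = 5
                     ) -> IndirectEffects:
    """Indirect food-web effects of fishing relative to the unfished run.

    For each forage group: its equilibrium biomass and the % change in
    total biomass of its predators (groups with availability > 0 onto
    it) vs the unfished run. For each top predator: its equilibrium
    biomass and the % change in total biomass of its prey. Link sets
    come from the diet availability structure.
    """
    if result.group_ids != unfished.group_ids:
        raise CompletenessError("result and unfished run cover different groups")
    idx = result.index
    b = _equilibrium_biomass(result, window)
    b0 = _equilibrium_biomass(unfished, window)

    def pct_change(linked: list[str]) -> float:
        if not linked:
            return float("nan")
        j = [idx[g] for g in linked]
        denom = b0[j].sum()
        if denom <= 0:
            return float("nan")
        return 100.0 * (b[j].sum() / denom - 1.0)

    rows = []
    for gid in forage_ids:
        linked = [g for g in diet.predators_of(gid) if g in idx]
        rows.append({"group": gid, "role": "forage",
                     "equilibrium_biomass": float(b[idx[gid]]),
                     "linked_groups": len(linked),
                     "linked_pct_change": pct_change(linked)})
    for gid in predator_ids:
        linked = [g for g in diet.prey_of(gid) if g in idx]
        rows.append({"group": gid, "role": "predator",
                     "equilibrium_biomass": float(b[idx[gid]]),
                     "linked_groups": len(linked),
                     "linked_pct_change": pct_change(linked)})
    return IndirectEffects(table=pd.DataFrame(rows))


def realized_diet_composition(result: RunResult, predator_id: str,
                              window: int = 5) -> dict:
    """Proportional realized diet of a predator over the final ``window`` years.

    Proportions over consumed prey sum to 1; an empty dict is returned
    if the predator consumed nothing in the window.
    """
    if result.flows is None:
        raise CompletenessError("run was executed without flow recording")
    idx = result.index
    if predator_id not in idx:
        raise CompletenessError(f"unknown predator {predator_id!r}")
    q = result.flows[-window:, idx[predator_id], :].sum(axis=0)
    total = q.sum()
    if total <= 0:
        return {}
    return {g: float(q[i] / total) for g, i in idx.items() if q[i] > 0}
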