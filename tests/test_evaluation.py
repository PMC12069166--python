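"""Metric-algebra tests: cap evaluation, B35% counts, depletion, indirect effects."""

import numpy as np
import pandas as pd
import pytest

import ecocap as ec
from ecocap.errors import CompletenessError
from ecocap.evaluation import _aggregate_yield


def make_summary(rows):
    """EquilibriumSummary from {group: (catch, ssb, biomass, focal, countable)}."""
    table = pd.DataFrame(
        [{"group": g, "catch_mean": c, "catch_cv": 0.0, "ssb_mean": s,
          "ssb_cv": 0.0, "biomass_mean": b, "is_focal": f, "counts_toward_cap": cc}
         for g, (c, s, b, f, cc) in rows.items()]).set_index("group")
    agg = float(table.loc[table["is_focal"], "catch_mean"].sum())
    return ec.EquilibriumSummary(table=table, aggregate_focal_catch=agg)


def scenario(climate, policy, m):
    return ec.ScenarioSpec(climate=climate, predator_policy=policy, multiplier=m)


class TestEvaluateCap:
    def _summaries(self, fished_catch, fished_ssb):
        base = make_summary({
            "a": (0.0, 100.0, 100.0, True, True),
            "b": (0.0, 100.0, 100.0, True, True),
            "hal": (0.0, 100.0, 100.0, True, False),
        })
        fished = make_summary({
            "a": (fished_catch, fished_ssb, 100.0, True, True),
            "b": (300_000.0, 50.0, 100.0, True, True),
            "hal": (500_000.0, 80.0, 100.0, True, False),
        })
        return {scenario("historical", "full", 0.0): base,
                scenario("historical", "full", 1.0): fished}

    def test_aggregate_below_cap_not_attained(self):
        ev = ec.evaluate_cap(self._summaries(400_000.0, 30.0), cap=800_000.0)
        row = ev.table[ev.table.multiplier == 1.0].iloc[0]
        assert row.aggregate_yield == 700_000.0
        assert not row.attained

    def test_boundary_counts_as_attained(self):
        ev = ec.evaluate_cap(self._summaries(500_000.0, 30.0), cap=800_000.0)
        row = ev.table[ev.table.multiplier == 1.0].iloc[0]
        assert row.aggregate_yield == 800_000.0
        assert row.attained

    def test_non_countable_catch_excluded(self):
        # the halibut-like group's 500 kt never enters the aggregate
        ev = ec.evaluate_cap(self._summaries(400_000.0, 30.0))
        assert ev.table[ev.table.multiplier == 1.0].iloc[0].aggregate_yield == 700_000.0
        summ = self._summaries(400_000.0, 30.0)[scenario("historical", "full", 1.0)]
        assert _aggregate_yield(summ, exclude_non_countable=False) == 1_200_000.0

    def test_b35_count_uses_multiplier_zero_baseline(self):
        ev = ec.evaluate_cap(self._summaries(400_000.0, 30.0))
        # a: 30/100 < 0.35; b: 50/100 >= 0.35; hal: 80/100 >= 0.35
        assert ev.table[ev.table.multiplier == 1.0].iloc[0].n_below_b35 == 1
        assert ev.table[ev.table.multiplier == 0.0].iloc[0].n_below_b35 == 0

    def test_missing_baseline_rejected(self):
        with pytest.raises(CompletenessError):
            ec.evaluate_cap({scenario("historical", "full", 1.0):
                             make_summary({"a": (1.0, 1.0, 1.0, True, True)})})

    def test_pure_function_of_exported_summaries(self, tmp_path):
        from ecocap.config_io import load_summary, save_summary
        summaries = self._summaries(400_000.0, 30.0)
        ev1 = ec.evaluate_cap(summaries)
        reloaded = {}
        for sc, summ in summaries.items():
            path = tmp_path / f"{sc.scenario_key}_{sc.multiplier}.tsv"
            save_summary(summ, path)
            reloaded[sc] = load_summary(path)
        ev2 = ec.evaluate_cap(reloaded)
        pd.testing.assert_frame_equal(ev1.table, ev2.table)


class TestCountBelowB35:
    def test_hand_example(self):
        ssb = {"a": 30.0, "b": 40.0, "c": 36.0}
        unfished = {"a": 100.0, "b": 100.0, "c": 100.0}
        assert ec.count_below_b35(ssb, unfished) == 1

    def test_all_collapsed(self):
        ssb = {"a": 0.0, "b": 0.0}
        assert ec.count_below_b35(ssb, {"a": 10.0, "b": 10.0}) == 2

    def test_zero_baseline_excluded_with_warning(self, caplog):
        import logging
        with caplog.at_level(logging.WARNING):
            n = ec.count_below_b35({"a": 1.0, "b": 0.0}, {"a": 10.0, "b": 0.0})
        assert n == 1
        assert "excluded" in caplog.text

    def test_missing_group_rejected(self):
        with pytest.raises(CompletenessError):
            ec.count_below_b35({"a": 1.0}, {})


class TestDepletion:
    def test_simple_ratio(self):
        assert ec.depletion(35.0, 100.0) == pytest.approx(0.35)

    def test_unfished_is_one(self):
        assert ec.depletion(100.0, 100.0) == 1.0

    def test_zero_baseline_rejected(self):
        with pytest.raises(CompletenessError):
            ec.depletion(10.0, 0.0)


def _synthetic_run(group_ids, biomass_by_group, years=6, flows=None):
    T, G = years, len(group_ids)
    biomass = np.tile(np.asarray([biomass_by_group[g] for g in group_ids],
                                 dtype=float), (T, 1))
    return ec.RunResult(group_ids=group_ids, years=np.arange(1, T + 1),
                        catch=np.zeros((T, G)), ssb=biomass.copy(),
                        biomass=biomass, naa=np.zeros((T, G, 1)),
                        flows=flows, spec=None)


class TestIndirectEffects:
    def _diet(self):
        return ec.DietMatrix(availability={("pred", "forage"): 0.5,
                                           ("pred", "other"): 0.2})

    def test_unfished_comparison_is_zero_change(self):
        ids = ["pred", "forage", "other"]
        run = _synthetic_run(ids, {"pred": 100.0, "forage": 50.0, "other": 20.0})
        eff = ec.indirect_effects(run, run, self._diet(), forage_ids=["forage"],
                                  predator_ids=["pred"])
        assert np.allclose(eff.table["linked_pct_change"], 0.0)

    def test_halved_predators_is_minus_fifty_percent(self):
        ids = ["pred", "forage", "other"]
        unfished = _synthetic_run(ids, {"pred": 100.0, "forage": 50.0, "other": 20.0})
        fished = _synthetic_run(ids, {"pred": 50.0, "forage": 60.0, "other": 20.0})
        eff = ec.indirect_effects(fished, unfished, self._diet(),
                                  forage_ids=["forage"])
        row = eff.table.iloc[0]
        assert row["linked_pct_change"] == pytest.approx(-50.0)
        assert row["equilibrium_biomass"] == pytest.approx(60.0)

    def test_prey_change_for_top_predator(self):
        ids = ["pred", "forage", "other"]
        unfished = _synthetic_run(ids, {"pred": 100.0, "forage": 50.0, "other": 50.0})
        fished = _synthetic_run(ids, {"pred": 100.0, "forage": 75.0, "other": 50.0})
        eff = ec.indirect_effects(fished, unfished, self._diet(),
                                  predator_ids=["pred"])
        # prey set = {forage, other}: (75+50)/(50+50) - 1 = +25%
        assert eff.table.iloc[0]["linked_pct_change"] == pytest.approx(25.0)

    def test_empty_link_set_is_not_applicable(self):
        ids = ["pred", "forage", "lonely"]
        run = _synthetic_run(ids, {"pred": 1.0, "forage": 1.0, "lonely": 1.0})
        eff = ec.indirect_effects(run, run, self._diet(), forage_ids=["lonely"])
        assert np.isnan(eff.table.iloc[0]["linked_pct_change"])


class TestRealizedDietComposition:
    def test_single_prey(self):
        flows = np.zeros((6, 2, 2))
        flows[:, 0, 1] = 3.0
        run = _synthetic_run(["pred", "prey"], {"pred": 1.0, "prey": 1.0},
                             flows=flows)
        assert ec.realized_diet_composition(run, "pred") == {"prey": 1.0}

    def test_equal_flows_split_evenly(self):
        flows = np.zeros((6, 3, 3))
        flows[:, 0, 1] = 2.0
        flows[:, 0, 2] = 2.0
        run = _synthetic_run(["pred", "a", "b"], {"pred": 1, "a": 1, "b": 1},
                             flows=flows)
        diet = ec.realized_diet_composition(run, "pred")
        assert diet["a"] == pytest.approx(0.5) and diet["b"] == pytest.approx(0.5)

    def test_no_consumption_is_empty(self):
        flows = np.zeros((6, 2, 2))
        run = _synthetic_run(["pred", "prey"], {"pred": 1.0, "prey": 1.0},
                             flows=flows)
        assert ec.realized_diet_composition(run, "pred") == {}

    def test_proportions_sum_to_one_on_real_run(self, toy_config, toy_forcings):
        hist, _ = toy_forcings
        calib = toy_config.calibration_policy()
        res = ec.run_simulation(toy_config, ec.RunSpec(
            historical=hist, burn_in_fishing=calib, scenario_fishing=calib,
            total_years=12, burn_in_years=4))
        diet = ec.realized_diet_composition(res, "pred")
        assert sum(diet.values()) == pytest.approx(1.0, abs=1e-12)

    def test_flows_required(self):
        run = _synthetic_run(["pred"], {"pred": 1.0}, flows=None)
        with pytest.raises(CompletenessError):
            ec.realized_diet_composition(run, "pred")
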