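"""Unit and property tests for the food-web building blocks."""

import dataclasses

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import ecocap as ec
from ecocap.errors import ConfigurationError, StateCorruptionError
from ecocap.foodweb import spawning_biomass


# ---------------------------------------------------------------- thermal

class TestTemperatureScalar:
    @pytest.mark.parametrize("T,expected", [
        (10.0, 1.0),                    # ration is maximal at the optimum
        (15.0, 0.0),                    # and zero at the upper lethal limit
        (12.0, 0.9238679159730779),     # frozen from a one-line evaluation of the closed form
    ])
    def test_known_values(self, T, expected):
        assert ec.temperature_scalar(T, 10.0, 15.0, 2.5) == pytest.approx(expected, abs=1e-12)

    def test_above_lethal_is_zero(self):
        assert ec.temperature_scalar(20.0, 10.0, 15.0, 2.5) == 0.0

    @settings(max_examples=200, derandomize=True)
    @given(T=st.floats(-50, 60), Topt=st.floats(-5, 20), span=st.floats(0.5, 25),
           Qc=st.floats(1.01, 5))
    def test_bounded_and_unimodal(self, T, Topt, span, Qc):
        Tmax = Topt + span
        f = ec.temperature_scalar(T, Topt, Tmax, Qc)
        assert 0.0 <= f <= 1.0
        # non-decreasing below the optimum, non-increasing above it
        eps = 0.01
        if T + eps <= Topt:
            assert ec.temperature_scalar(T + eps, Topt, Tmax, Qc) >= f - 1e-12
        if Topt <= T <= Tmax - eps:
            assert ec.temperature_scalar(T + eps, Topt, Tmax, Qc) <= f + 1e-12

    def test_invalid_parameters(self):
        with pytest.raises(ConfigurationError):
            ec.temperature_scalar(10, 15.0, 15.0, 2.5)
        with pytest.raises(ConfigurationError):
            ec.temperature_scalar(10, 5.0, 15.0, 1.0)


class TestHabitatSuitability:
    @pytest.mark.parametrize("T,expected", [
        (5.0, 1.0),     # plateau
        (0.0, 0.0),     # lower edge
        (1.0, 0.5),     # midpoint of the linear shoulder
        (-3.0, 0.0),    # outside support
        (20.0, 0.0),
        (12.0, 0.5),    # upper shoulder midpoint
    ])
    def test_trapezoid(self, T, expected):
        assert ec.habitat_suitability(T, (0.0, 2.0, 10.0, 14.0)) == pytest.approx(expected)

    @settings(max_examples=200, derandomize=True)
    @given(T=st.floats(-50, 60))
    def test_bounded(self, T):
        assert 0.0 <= ec.habitat_suitability(T, (0.0, 2.0, 10.0, 14.0)) <= 1.0

    def test_unordered_breakpoints_rejected(self):
        with pytest.raises(ConfigurationError):
            ec.habitat_suitability(5.0, (2.0, 0.0, 10.0, 14.0))


class TestSpawningGate:
    def test_open_inside_window(self):
        assert ec.spawning_gate(7.0, (3.0, 8.5, 0.5)) == 1.0

    def test_closed_beyond_taper(self):
        assert ec.spawning_gate(9.5, (3.0, 8.5, 0.5)) == 0.0

    def test_linear_taper(self):
        assert ec.spawning_gate(8.75, (3.0, 8.5, 0.5)) == pytest.approx(0.5)

    def test_hard_gate(self):
        assert ec.spawning_gate(8.5, (3.0, 8.5, 0.0)) == 1.0
        assert ec.spawning_gate(8.500001, (3.0, 8.5, 0.0)) == 0.0


# ------------------------------------------------------------ recruitment

class TestRecruitment:
    def test_steepness_normalization(self):
        # R(S0) = R0 and R(0.2 S0) = h R0 define the steepness form
        assert ec.beverton_holt(1000.0, 1000.0, 5e6, 0.7) == pytest.approx(5e6)
        assert ec.beverton_holt(200.0, 1000.0, 5e6, 0.7) == pytest.approx(0.7 * 5e6)

    def test_zero_ssb_zero_recruits(self):
        assert ec.beverton_holt(0.0, 1000.0, 5e6, 0.7) == 0.0

    def test_gate_closes_recruitment(self):
        full = ec.recruit(1000.0, 1000.0, 5e6, 0.7, 7.0, (3.0, 8.5, 0.5))
        assert full == pytest.approx(5e6)
        assert ec.recruit(1000.0, 1000.0, 5e6, 0.7, 9.5, (3.0, 8.5, 0.5)) == 0.0

    def test_parameter_validation(self):
        with pytest.raises(ConfigurationError):
            ec.beverton_holt(10.0, 0.0, 1e6, 0.7)
        with pytest.raises(ConfigurationError):
            ec.beverton_holt(10.0, 100.0, 1e6, 0.1)


# ------------------------------------------------------------ consumption

def _two_prey_config(a1=0.2, a2=0.4, H=1000.0):
    pred = ec.GroupSpec(id="p", n_ages=1, M0=0.2, age_mature=1, age_select=1,
                        W_ref=(1.0,), R0=1.0, Cmax=2.0, T_opt=8, T_max=17, Qc=2.5)
    prey1 = ec.GroupSpec(id="a", kind="biomass_pool", r=1.0, K=1e6)
    prey2 = ec.GroupSpec(id="b", kind="biomass_pool", r=1.0, K=1e6)
    diet = ec.DietMatrix(availability={("p", "a"): a1, ("p", "b"): a2},
                         half_saturation={"p": H})
    return ec.FoodWebConfig(groups=[pred, prey1, prey2], diet=diet)


class TestComputeConsumption:
    def test_no_links_no_flows(self):
        cfg = _two_prey_config(0.0, 0.0)
        state = ec.default_initial_state(cfg)
        state.N[0, 0] = 1e6
        flows = ec.compute_consumption(state, cfg, T=8.0, dt=1 / 12)
        assert np.all(flows.Q == 0)

    def test_saturation_reaches_demand(self):
        cfg = _two_prey_config(1.0, 1.0, H=1e-6)   # phi -> infinity
        state = ec.default_initial_state(cfg)
        state.N[0, 0] = 1e6
        flows = ec.compute_consumption(state, cfg, T=8.0, dt=1 / 12)
        assert flows.realized[0, 0] == pytest.approx(flows.demand[0, 0], rel=1e-6)

    def test_allocation_proportional_to_availability(self):
        cfg = _two_prey_config(0.2, 0.4)
        state = ec.default_initial_state(cfg)
        state.N[0, 0] = 1e6
        flows = ec.compute_consumption(state, cfg, T=8.0, dt=1 / 12)
        qa = flows.Q[0, 0, cfg.index["a"]]
        qb = flows.Q[0, 0, cfg.index["b"]]
        assert qb / qa == pytest.approx(2.0)

    def test_removal_capped_at_90_percent(self):
        cfg = _two_prey_config(1.0, 1.0, H=1.0)
        state = ec.default_initial_state(cfg)
        state.N[0, 0] = 1e12          # monstrous demand
        state.B_pool[1] = 10.0        # tiny prey pool
        state.B_pool[2] = 10.0
        flows = ec.compute_consumption(state, cfg, T=8.0, dt=1 / 12)
        removal = flows.Q.sum(axis=(0, 1))
        assert removal[1] <= 0.9 * 10.0 + 1e-9
        assert np.all(flows.realized <= flows.demand + 1e-9)

    def test_negative_state_rejected(self):
        cfg = _two_prey_config()
        state = ec.default_initial_state(cfg)
        state.B_pool[1] = -5.0
        with pytest.raises(StateCorruptionError, match="a"):
            ec.compute_consumption(state, cfg, T=8.0, dt=1 / 12)


# ---------------------------------------------------------------- pools

class TestPoolUpdate:
    def test_logistic_equilibrium(self):
        assert ec.pool_update(100.0, 1.0, 100.0, 1.0, 0.0, 0.1) == 100.0

    def test_hand_arithmetic(self):
        # 50 + 1*50*(1 - 0.5)*0.1 = 52.5
        assert ec.pool_update(50.0, 1.0, 100.0, 1.0, 0.0, 0.1) == pytest.approx(52.5)

    def test_productivity_scalar_halves_growth(self):
        full = ec.pool_update(50.0, 1.0, 100.0, 1.0, 0.0, 0.1) - 50.0
        half = ec.pool_update(50.0, 1.0, 100.0, 0.5, 0.0, 0.1) - 50.0
        assert half == pytest.approx(0.5 * full)

    def test_floor_at_zero_on_excess_losses(self):
        assert ec.pool_update(10.0, 1.0, 100.0, 1.0, 50.0, 0.1) == 0.0

    def test_invalid_scalar(self):
        with pytest.raises(ConfigurationError):
            ec.pool_update(10.0, 1.0, 100.0, 0.0, 0.0, 0.1)


# ------------------------------------------------------------- mortality

class TestBaranovMortality:
    def test_unfished_limit(self):
        N = np.array([1000.0, 500.0])
        surv, catch_b, catch_n = ec.apply_mortality_and_catch(
            N, np.ones(2), M0=0.2, M2=0.1, F=0.0, age_select=1, dt=1.0)
        assert np.allclose(surv, N * np.exp(-0.3))
        assert catch_b == 0.0 and np.all(catch_n == 0)

    def test_baranov_catch_equation(self):
        # (0.2/0.5) * 1000 * (1 - e^-0.5) = 157.38773611...
        _, _, catch_n = ec.apply_mortality_and_catch(
            np.array([1000.0]), np.array([1.0]), M0=0.3, M2=0.0, F=0.2,
            age_select=1, dt=1.0)
        assert catch_n[0] == pytest.approx(157.38773611494662, abs=1e-9)

    def test_knife_edge_protects_young(self):
        N = np.array([1000.0, 1000.0, 1000.0])
        _, _, catch_n = ec.apply_mortality_and_catch(
            N, np.ones(3), M0=0.2, M2=0.0, F=5.0, age_select=3, dt=1.0)
        assert catch_n[0] == 0.0 and catch_n[1] == 0.0 and catch_n[2] > 0

    def test_death_accounting_identity(self):
        # catch/deaths = F*S/Z to within 1e-10, and survivors + deaths = N
        N = np.array([1000.0, 800.0, 600.0])
        M0, M2, F = 0.3, 0.15, 0.4
        surv, _, catch_n = ec.apply_mortality_and_catch(
            N, np.ones(3), M0=M0, M2=M2, F=F, age_select=2, dt=1 / 12)
        deaths = N - surv
        S = np.array([0.0, 1.0, 1.0])
        Z = M0 + M2 + F * S
        assert np.all(np.abs(catch_n / deaths - F * S / Z) < 1e-10)

    def test_negative_rate_rejected(self):
        with pytest.raises(ConfigurationError):
            ec.apply_mortality_and_catch(np.ones(2), np.ones(2), M0=-0.1, M2=0.0,
                                         F=0.0, age_select=1, dt=1.0)


# ---------------------------------------------------------------- growth

class TestGrowth:
    def test_reference_weight_is_fixed_point(self):
        W = ec.update_growth(np.array([2.0]), 1.0, 1.0, np.array([2.0]), dt=0.1)
        assert W[0] == pytest.approx(2.0)

    def test_hand_arithmetic(self):
        W = ec.update_growth(np.array([1.0]), 1.0, 1.0, np.array([2.0]), dt=0.1)
        assert W[0] == pytest.approx(1.1)

    def test_sustained_half_ration_halves_weight(self):
        W = np.array([2.0])
        for _ in range(2000):
            W = ec.update_growth(W, 0.5, 1.0, np.array([2.0]), dt=0.1)
        assert W[0] == pytest.approx(1.0, rel=1e-6)

    def test_zero_demand_means_full_ration(self):
        W = ec.update_growth(np.array([1.0]), 0.0, 0.0, np.array([2.0]), dt=0.1)
        assert W[0] == pytest.approx(1.1)


# ----------------------------------------------------------- annual step

class TestAdvanceYear:
    def _spec(self, n_ages=4, ypa=1, mature=2):
        return ec.GroupSpec(id="g", n_ages=n_ages, years_per_age=ypa, M0=0.2,
                            age_mature=mature, age_select=mature,
                            W_ref=tuple(float(i) for i in range(1, n_ages + 1)),
                            R0=100.0, S0=1.0, h=0.8)

    def test_cohort_shift(self):
        spec = self._spec()
        N = np.array([100.0, 0.0, 0.0, 0.0])
        N2, _, _ = ec.advance_year(N, np.ones(4), spec, recruits=0.0, year=1)
        assert N2[1] == 100.0 and N2[0] == 0.0

    def test_plus_group_accumulates(self):
        spec = self._spec()
        N = np.array([0.0, 0.0, 40.0, 60.0])
        N2, _, _ = ec.advance_year(N, np.ones(4), spec, recruits=0.0, year=1)
        assert N2[3] == pytest.approx(100.0)

    def test_recruits_enter_first_class(self):
        spec = self._spec()
        N2, _, _ = ec.advance_year(np.zeros(4), np.ones(4), spec, recruits=50.0, year=1)
        assert N2[0] == 50.0

    def test_multi_year_classes_age_on_schedule(self):
        spec = self._spec(ypa=2)
        N = np.array([100.0, 0.0, 0.0, 0.0])
        # odd year: no aging, recruits accumulate in class 1
        N1, _, _ = ec.advance_year(N, np.ones(4), spec, recruits=10.0, year=1)
        assert N1[0] == 110.0 and N1[1] == 0.0
        # even year: the whole class moves up
        N2, _, _ = ec.advance_year(N1, np.ones(4), spec, recruits=10.0, year=2)
        assert N2[1] == 110.0 and N2[0] == 10.0

    def test_ssb_uses_post_aging_mature_classes(self):
        spec = self._spec(mature=2)
        N = np.array([0.0, 100.0, 0.0, 0.0])
        W = np.array([1.0, 2.0, 3.0, 4.0])
        _, _, ssb = ec.advance_year(N, W, spec, recruits=0.0, year=1)
        # the cohort of 100 moved to class 3 (weight carried = 2 kg)
        assert ssb == pytest.approx(100.0 * 2.0 / 1000.0)


class TestUnfishedEquilibrium:
    def test_matches_exponential_closed_form(self):
        spec = ec.GroupSpec(id="g", n_ages=6, M0=0.35, age_mature=2, age_select=2,
                            W_ref=(1.0,) * 6, R0=1000.0, h=0.8)
        N, W = ec.unfished_equilibrium(spec)
        a = np.arange(1, 6)
        expected = 1000.0 * np.exp(-0.35 * (a - 1))
        assert np.allclose(N[:5], expected, rtol=1e-10)
        plus = 1000.0 * np.exp(-0.35 * 5) / (1 - np.exp(-0.35))
        assert N[5] == pytest.approx(plus, rel=1e-10)

    def test_spawning_biomass_consistency(self, goa_config):
        # S0 recorded on each fish group equals the spawning biomass of
        # its own decoupled unfished equilibrium
        g = goa_config.by_id["pollock"]
        N, W = ec.unfished_equilibrium(g)
        assert spawning_biomass(g, N, W) == pytest.approx(g.S0, rel=1e-9)


# ------------------------------------------------------------ validation

class TestValidation:
    def test_bad_thermal_ordering_names_group(self):
        with pytest.raises(ConfigurationError, match="badfish"):
            ec.GroupSpec(id="badfish", n_ages=1, M0=0.2, W_ref=(1.0,),
                         T_opt=18.0, T_max=16.0).validate()

    def test_decreasing_weights_rejected(self):
        with pytest.raises(ConfigurationError, match="W_ref"):
            ec.GroupSpec(id="g", n_ages=3, M0=0.2, W_ref=(2.0, 1.0, 3.0)).validate()

    def test_selectivity_must_cover_a_mature_class(self):
        with pytest.raises(ConfigurationError, match="age_select"):
            ec.GroupSpec(id="g", n_ages=5, M0=0.2, W_ref=(1.0,) * 5,
                         age_mature=2, age_select=4).validate()

    def test_pool_cannot_be_predator(self):
        pool = ec.GroupSpec(id="pool", kind="biomass_pool", r=1.0, K=10.0)
        fish = ec.GroupSpec(id="fish", n_ages=1, M0=0.2, W_ref=(1.0,), R0=1.0)
        with pytest.raises(ConfigurationError, match="pool"):
            ec.FoodWebConfig(groups=[pool, fish],
                             diet=ec.DietMatrix(availability={("pool", "fish"): 0.5}))

    def test_self_predation_rejected(self):
        fish = ec.GroupSpec(id="fish", n_ages=2, M0=0.2, W_ref=(1.0, 2.0), R0=1.0)
        with pytest.raises(ConfigurationError, match="self-predation"):
            ec.FoodWebConfig(groups=[fish],
                             diet=ec.DietMatrix(availability={("fish", "fish"): 0.1}))

    def test_availability_range_enforced(self):
        a = ec.GroupSpec(id="a", n_ages=1, M0=0.2, W_ref=(1.0,), R0=1.0)
        b = ec.GroupSpec(id="b", kind="biomass_pool", r=1.0, K=10.0)
        with pytest.raises(ConfigurationError, match="\\[0, 1\\]"):
            ec.FoodWebConfig(groups=[a, b],
                             diet=ec.DietMatrix(availability={("a", "b"): 1.5}))
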