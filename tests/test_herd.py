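import math

import pytest

from flockvalue import (
    InfeasibleParameterError,
    advance_one_year,
    annual_births,
    cohort_flow,
    constant_growth_state,
    solve_stationary_offtake,
    stationary_state,
)
from flockvalue.params import DemographicParameters

TOL = 0.02  # published tables are printed to 1 decimal


def make_d(**kw):
    base = dict(
        n_breeding_females=100.0, male_breeder_ratio=0.1,
        parturition_rate=1.0, prolificacy=1.0, sex_ratio_at_birth=0.5,
        lamb_mortality=0.1, subadult_mortality_f=0.05,
        subadult_mortality_m=0.05, adult_mortality_f=0.05,
        adult_mortality_m=0.05, subadult_offtake_f=0.1,
        subadult_offtake_m=0.3)
    base.update(kw)
    return DemographicParameters(**base)


class TestAnnualBirths:
    def test_unit_rates(self):
        b = annual_births(make_d(parturition_rate=1.0, prolificacy=1.0))
        assert b == {"f": 50.0, "m": 50.0}

    def test_zero_parturition(self):
        b = annual_births(make_d(parturition_rate=0.0))
        assert b["f"] == 0.0 and b["m"] == 0.0

    def test_sex_ratio_split(self):
        b = annual_births(make_d(sex_ratio_at_birth=0.3))
        assert b["f"] == pytest.approx(30.0)
        assert b["m"] == pytest.approx(70.0)

    def test_continuous_product(self, demo):
        b = annual_births(demo)
        expected = (demo.n_breeding_females * demo.parturition_rate
                    * demo.prolificacy)
        assert sum(b.values()) == pytest.approx(expected, rel=1e-12)


class TestCohortFlow:
    def test_lossless_flow(self):
        d = make_d(lamb_mortality=0.0, subadult_mortality_f=0.0,
                   subadult_mortality_m=0.0, subadult_offtake_f=0.0,
                   subadult_offtake_m=0.0)
        flows = cohort_flow({"f": 40.0, "m": 60.0}, d)
        assert flows["promotions"][("subadult", "f")] == pytest.approx(40.0)
        assert flows["promotions"][("subadult", "m")] == pytest.approx(60.0)
        assert sum(flows["deaths"].values()) == 0.0

    def test_absorbing_lamb_mortality(self):
        flows = cohort_flow({"f": 50.0, "m": 50.0}, make_d(lamb_mortality=1.0))
        assert flows["deaths"][("lamb", "f")] == pytest.approx(50.0)
        assert flows["deaths"][("lamb", "m")] == pytest.approx(50.0)
        assert flows["promotions"][("subadult", "f")] == 0.0
        assert flows["offtake"][("subadult", "m")] == 0.0

    def test_linear_in_births(self):
        d = make_d()
        one = cohort_flow({"f": 10.0, "m": 10.0}, d)
        two = cohort_flow({"f": 20.0, "m": 20.0}, d)
        for key in one["deaths"]:
            assert two["deaths"][key] == pytest.approx(2 * one["deaths"][key])

    def test_risk_arithmetic(self):
        # independent hand computation: 100 births/sex, 20% lamb risk,
        # sub-adult risks f: 10% death + 20% offtake
        d = make_d(lamb_mortality=0.2, subadult_mortality_f=0.1,
                   subadult_offtake_f=0.2)
        flows = cohort_flow({"f": 100.0, "m": 100.0}, d)
        assert flows["deaths"][("lamb", "f")] == pytest.approx(20.0)
        assert flows["deaths"][("subadult", "f")] == pytest.approx(80 * 0.1)
        assert flows["offtake"][("subadult", "f")] == pytest.approx(80 * 0.2)
        assert flows["promotions"][("subadult", "f")] == pytest.approx(80 * 0.7)


class TestSolveStationaryOfftake:
    def test_closed_form_oracle(self):
        # independent closed form: per sex, adult offtake balances the
        # survivors of the birth cohort against adult deaths
        d = make_d()
        off = solve_stationary_offtake(d)
        for sex, a_stock in (("f", 100.0), ("m", 10.0)):
            births = 50.0
            weaned = births * (1 - d.lamb_mortality)
            mort = getattr(d, f"subadult_mortality_{sex}")
            o = getattr(d, f"subadult_offtake_{sex}")
            promoted = weaned * (1 - mort - o)
            expected = promoted - a_stock * getattr(d, f"adult_mortality_{sex}")
            assert off[sex] == pytest.approx(expected, rel=1e-12)

    def test_one_class_toy(self):
        # collapse young classes: offtake = births - stock * mortality
        d = make_d(lamb_mortality=0.0, subadult_mortality_f=0.0,
                   subadult_mortality_m=0.0, subadult_offtake_f=0.0,
                   subadult_offtake_m=0.0, adult_mortality_f=0.2,
                   adult_mortality_m=0.2)
        off = solve_stationary_offtake(d)
        assert off["f"] == pytest.approx(50.0 - 100.0 * 0.2, rel=1e-12)
        assert off["m"] == pytest.approx(50.0 - 10.0 * 0.2, rel=1e-12)

    def test_infeasible_no_recruits(self):
        d = make_d(parturition_rate=0.0, adult_mortality_f=0.1)
        with pytest.raises(InfeasibleParameterError) as err:
            solve_stationary_offtake(d)
        assert err.value.required_offtake < 0

    def test_feasibility_boundary_is_exact(self):
        # required female offtake = weaned*survival - A*d_af; the error must
        # trigger exactly when that closed form goes negative
        d = make_d()
        promoted = 50.0 * 0.9 * (1 - 0.05 - 0.1)
        boundary = promoted / 100.0
        solve_stationary_offtake(d.replace(adult_mortality_f=boundary))
        with pytest.raises(InfeasibleParameterError) as err:
            solve_stationary_offtake(
                d.replace(adult_mortality_f=boundary * (1 + 1e-9)))
        assert err.value.sex == "f"

    def test_baseline_adult_offtake(self, demo):
        off = solve_stationary_offtake(demo)
        assert off["f"] == pytest.approx(23.5, rel=TOL)
        assert off["m"] == pytest.approx(10.0, rel=TOL)


class TestStationaryState:
    def test_fixed_point(self, demo):
        state, flows = stationary_state(demo)
        advanced = advance_one_year(state, flows)
        for key, value in state.stock.items():
            assert advanced.stock[key] == pytest.approx(value, rel=1e-9)

    def test_adult_stocks_are_structural(self, demo):
        state, _ = stationary_state(demo)
        assert state.breeding_females == demo.n_breeding_females
        assert state.stock[("adult", "m")] == pytest.approx(
            demo.n_breeding_females * demo.male_breeder_ratio)

    def test_total_is_sum(self, demo):
        state, _ = stationary_state(demo)
        assert state.total == pytest.approx(sum(state.stock.values()))

    def test_zero_growth_conservation(self, demo):
        _, flows = stationary_state(demo)
        assert flows.total_births == pytest.approx(
            flows.total_deaths + flows.total_offtake, rel=1e-12)
        assert flows.growth_rate == 0.0

    def test_no_lamb_sales(self, baseline_sweep):
        for rec in baseline_sweep.records:
            assert rec.flows.offtake_by_class("lamb") == 0.0

    def test_baseline_headline_numbers(self, demo):
        state, flows = stationary_state(demo)
        assert state.total == pytest.approx(169.6, rel=TOL)
        assert flows.total_offtake == pytest.approx(50.9, rel=TOL)
        assert state.other_females == pytest.approx(31.6, rel=TOL)
        assert state.other_males == pytest.approx(27.5, rel=TOL)
        assert flows.offtake[("subadult", "f")] == pytest.approx(1.2, rel=TOL)
        assert flows.offtake[("subadult", "m")] == pytest.approx(16.2, rel=TOL)
        assert flows.deaths_by_class("subadult") == pytest.approx(3.6, rel=TOL)
        assert flows.deaths_by_class("adult") == pytest.approx(5.4, rel=TOL)

    def test_zero_ysm_numbers(self, demo):
        state, flows = stationary_state(demo.replace(lamb_mortality=0.0))
        assert flows.deaths_by_class("lamb") == 0.0
        assert flows.deaths_by_class("subadult") == pytest.approx(4.5, rel=TOL)
        assert state.total == pytest.approx(179.0, rel=TOL)
        assert flows.total_offtake == pytest.approx(65.0, rel=TOL)

    def test_high_fertility_numbers(self, demo):
        state, flows = stationary_state(demo.replace(parturition_rate=1.0))
        assert state.total == pytest.approx(210.6, rel=TOL)
        assert flows.total_offtake == pytest.approx(90.0, rel=TOL)

    def test_homogeneity_in_flock_scale(self, demo):
        s1, f1 = stationary_state(demo)
        s2, f2 = stationary_state(demo.replace(n_breeding_females=200.0))
        assert s2.total == pytest.approx(2 * s1.total, rel=1e-12)
        for key in f1.offtake:
            assert f2.offtake[key] == pytest.approx(
                2 * f1.offtake[key], rel=1e-12, abs=1e-12)

    def test_offtake_monotone_in_lamb_mortality(self, demo):
        offs = [stationary_state(demo.replace(lamb_mortality=m))[1].total_offtake
                for m in (0.0, 0.1, 0.2, 0.3)]
        assert offs == sorted(offs, reverse=True)

    def test_offtake_monotone_in_parturition(self, demo):
        offs = [stationary_state(demo.replace(parturition_rate=r))[1].total_offtake
                for r in (0.59, 0.8, 1.0, 1.2)]
        assert offs == sorted(offs)


class TestConstantGrowth:
    def test_g0_equals_stationary(self, demo):
        s0, f0 = stationary_state(demo)
        sg, fg, inc = constant_growth_state(demo, 0.0)
        for key in s0.stock:
            assert sg.stock[key] == pytest.approx(s0.stock[key], rel=1e-12)
            assert inc[key] == 0.0
        for key in f0.offtake:
            assert fg.offtake[key] == pytest.approx(
                f0.offtake[key], rel=1e-12, abs=1e-12)

    def test_increment_is_g_times_stock(self, demo):
        state, _, inc = constant_growth_state(demo, 0.102)
        for key, value in state.stock.items():
            assert inc[key] == pytest.approx(0.102 * value, rel=1e-12)

    def test_advance_grows_every_compartment(self, demo):
        state, flows, _ = constant_growth_state(demo, 0.102)
        nxt = advance_one_year(state, flows)
        for key, value in state.stock.items():
            assert nxt.stock[key] == pytest.approx(1.102 * value, rel=1e-9)

    def test_homogeneity_at_fixed_g(self, demo):
        s1, f1, _ = constant_growth_state(demo, 0.102)
        s2, f2, _ = constant_growth_state(
            demo.replace(n_breeding_females=200.0), 0.102)
        assert s2.total == pytest.approx(2 * s1.total, rel=1e-12)
        assert f2.total_offtake == pytest.approx(
            2 * f1.total_offtake, rel=1e-12)

    def test_growth_reduces_offtake(self, demo):
        _, f0 = stationary_state(demo)
        _, fg, _ = constant_growth_state(demo, 0.102)
        assert fg.total_offtake < f0.total_offtake

    def test_negative_growth_rejected(self, demo):
        with pytest.raises(ValueError):
            constant_growth_state(demo, -0.05)


class TestHazardConvention:
    def test_runs_and_differs_from_risk(self, demo):
        s_r, f_r = stationary_state(demo, convention="risk")
        s_h, f_h = stationary_state(demo, convention="hazard")
        assert s_h.total != pytest.approx(s_r.total, rel=1e-6)
        assert f_h.total_births == f_r.total_births

    def test_lamb_deaths_match_exponential_risk(self, demo):
        _, flows = stationary_state(demo, convention="hazard")
        expected = flows.total_births * -math.expm1(
            -demo.lamb_mortality * demo.lamb_class_duration)
        assert flows.deaths_by_class("lamb") == pytest.approx(
            expected, rel=1e-12)

    def test_fixed_point_holds(self, demo):
        state, flows = stationary_state(demo, convention="hazard")
        advanced = advance_one_year(state, flows)
        for key, value in state.stock.items():
            assert advanced.stock[key] == pytest.approx(value, rel=1e-9)

    def test_unknown_convention_rejected(self, demo):
        with pytest.raises(ValueError):
            stationary_state(demo, convention="bogus")
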