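"""Projection dynamics: component functions, oracle equivalence, properties."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from fleetreform import (
    DomainError,
    Fleet,
    ModelParams,
    compare_scenarios,
    fleet_harvest,
    fleet_profit,
    price_from_harvest,
    run_projection,
    surplus_production,
    surplus_production_step,
    total_harvest,
    update_effort,
)
from fleetreform.projection import fleet_cost


def toy_params(**kw):
    base = dict(
        phi=0.5,
        k=1000.0,
        b0=500.0,
        p0=10.0,
        epsilon=-1.2,
        beta=1.2,
        eta=1e-3,
        omega=1e-4,
        g=0.3,
        base_year=2018,
        horizon_year=2021,
    )
    base.update(kw)
    return ModelParams(**base)


def toy_fleet(label, e0, q, s0, s_reformed=None, alpha=None, h0=None, p0=10.0, beta=1.2, b0=500.0):
    h0 = h0 if h0 is not None else q * b0 * e0
    if alpha is None:
        alpha = (p0 * h0 + s0 * e0) / e0**beta
    return Fleet(
        label=label,
        vessel_ids=frozenset({f"{label}-v"}),
        h0=h0,
        e0=e0,
        s0=s0,
        revenue0=p0 * h0,
        q=q,
        alpha=alpha,
        s_reformed=s0 if s_reformed is None else s_reformed,
    )


class TestSurplusProduction:
    def test_no_growth_at_carrying_capacity(self):
        p = toy_params()
        assert surplus_production_step(p.k, p, 0.0) == pytest.approx(p.k)

    def test_msy_equilibrium_at_bmsy(self):
        p = toy_params(phi=0.188, k=2.5e9, b0=1.0e9, g=None, msy=9.0e7)
        b_star = p.bmsy
        b_next = surplus_production_step(b_star, p, p.msy)
        assert b_next == pytest.approx(b_star, rel=1e-9)

    def test_overharvest_floors_at_zero(self):
        p = toy_params()
        assert surplus_production_step(100.0, p, 1e9) == 0.0

    def test_surplus_peaks_at_the_analytic_maximiser(self):
        p = toy_params(phi=0.7, k=5e8, b0=1e8, g=None, msy=2e7)
        grid = np.linspace(1.0, p.k, 20001)
        values = [surplus_production(b, p) for b in grid]
        assert grid[int(np.argmax(values))] == pytest.approx(p.bmsy, rel=1e-3)
        assert max(values) == pytest.approx(p.msy, rel=1e-6)


class TestHarvestAndPrice:
    def test_harvest_products(self):
        assert fleet_harvest(1e-8, 10_000.0, 1_000_000.0) == pytest.approx(100.0)
        assert fleet_harvest(1e-8, 10_000.0, 0.0) == 0.0
        assert total_harvest([1.0, 2.0, 3.5]) == pytest.approx(6.5)

    def test_price_roundtrip_at_base_harvest(self):
        p = toy_params().with_demand_calibrated(100.0)
        assert price_from_harvest(100.0, p) == p.p0

    @pytest.mark.parametrize(
        "epsilon, h, expected",
        [(-1.0, 200.0, 5.0), (-2.0, 400.0, 5.0)],
    )
    def test_price_halves_on_the_stated_curves(self, epsilon, h, expected):
        p = toy_params(epsilon=epsilon).with_demand_calibrated(100.0)
        assert price_from_harvest(h, p) == pytest.approx(expected)

    def test_price_is_decreasing_in_harvest(self):
        p = toy_params().with_demand_calibrated(100.0)
        prices = [price_from_harvest(h, p) for h in (50.0, 100.0, 200.0, 400.0)]
        assert prices == sorted(prices, reverse=True)

    def test_vanishing_harvest_priced_at_floor_not_infinity(self):
        p = toy_params().with_demand_calibrated(100.0)
        assert np.isfinite(price_from_harvest(0.0, p))


class TestProfitAndEffort:
    def test_profit_hand_arithmetic(self):
        assert fleet_profit(p=2.0, h=50.0, c=80.0, s=0.01, e=1000.0) == pytest.approx(30.0)

    def test_zero_effort_costs_nothing(self):
        assert fleet_cost(0.5, 0.0, 1.3) == 0.0
        assert fleet_profit(2.0, 0.0, 0.0, 0.05, 0.0) == 0.0

    def test_effort_update_hand_arithmetic(self):
        assert update_effort(10_000.0, 0.0, 2.0) == 10_000.0
        assert update_effort(10_000.0, -1_000.0, 2.0) == pytest.approx(8_000.0)
        assert update_effort(100.0, -1e9, 2.0) == 0.0  # floored

    @settings(max_examples=50, deadline=None)
    @given(
        e=st.floats(0, 1e10),
        profit=st.floats(-1e9, 0),
        omega=st.floats(0, 0.1),
        eta_gap=st.floats(1e-6, 1.0),
    )
    def test_managed_contracts_no_more_than_open_access(self, e, profit, omega, eta_gap):
        eta = omega + eta_gap
        e_managed = update_effort(e, profit, omega)
        e_open = update_effort(e, profit, eta)
        assert e - e_managed <= e - e_open + 1e-9


class TestRunProjection:
    def test_null_reform_reproduces_bau_bitwise(self):
        params = toy_params(horizon_year=2050)  # 32 annual steps
        fleets = [
            toy_fleet("OA-A", 1000.0, 1e-4, 0.05),  # s_reformed defaults to s0
            toy_fleet("M-U", 800.0, 1.2e-4, 0.04),
        ]
        bau = run_projection(fleets, params, "BAU")
        reform = run_projection(fleets, params, "reform")
        assert np.array_equal(bau.biomass, reform.biomass)
        assert np.array_equal(bau.price, reform.price)
        assert np.array_equal(bau.harvest, reform.harvest)
        for label in ("OA-A", "M-U"):
            assert bau.fleet_states[label] == reform.fleet_states[label]

    def test_single_step_response_to_subsidy_removal(self):
        params = toy_params()
        affected = toy_fleet("OA-A", 1000.0, 1e-4, s0=0.05, s_reformed=0.0)
        bystander = toy_fleet("M-U", 800.0, 1.2e-4, s0=0.04)
        reform = run_projection([affected, bystander], params, "reform")
        # base-year profit of the stripped fleet is (s_ref - s0) * e0 < 0
        pi0 = reform.fleet_states["OA-A"][0].profit
        assert pi0 == pytest.approx(-0.05 * 1000.0, rel=1e-9)
        e1 = reform.fleet_states["OA-A"][1].effort
        assert e1 == pytest.approx(1000.0 + params.eta * pi0, rel=1e-12)
        assert e1 < 1000.0
        # the unaffected fleet starts at zero profit: unchanged at t=1
        assert reform.fleet_states["M-U"][0].profit == pytest.approx(0.0, abs=1e-9)
        assert reform.fleet_states["M-U"][1].effort == pytest.approx(800.0, rel=1e-12)

    def test_matches_independent_recurrence_oracle(self):
        """Two fleets, three annual steps, against a from-scratch transcription
        of the update rules in plain arithmetic."""
        params = toy_params(horizon_year=2021)
        oa = toy_fleet("OA-A", 1000.0, 1e-4, s0=0.05, s_reformed=0.01)
        mu = toy_fleet("M-U", 800.0, 1.2e-4, s0=0.04)
        traj = run_projection([oa, mu], params, "reform")

        # -- oracle: spreadsheet-style recurrence, no package calls --
        h0_total = oa.h0 + mu.h0
        b, e_oa, e_mu = 500.0, 1000.0, 800.0
        expect = []
        for _ in range(4):
            h_oa = 1e-4 * b * e_oa
            h_mu = 1.2e-4 * b * e_mu
            h = h_oa + h_mu
            p = 10.0 * (h / h0_total) ** (1.0 / -1.2)
            c_oa = oa.alpha * e_oa**1.2
            c_mu = mu.alpha * e_mu**1.2
            pi_oa = p * h_oa - c_oa + 0.01 * e_oa
            pi_mu = p * h_mu - c_mu + 0.04 * e_mu
            expect.append((b, p, h, e_oa, e_mu, pi_oa, pi_mu))
            growth = ((0.5 + 1) / 0.5) * 0.3 * b * (1 - (b / 1000.0) ** 0.5)
            b = max(0.0, b + growth - h)
            e_oa = max(0.0, e_oa + 1e-3 * pi_oa)
            e_mu = max(0.0, e_mu + 1e-4 * pi_mu)

        for i, (b_e, p_e, h_e, eoa_e, emu_e, pioa_e, pimu_e) in enumerate(expect):
            assert traj.biomass[i] == pytest.approx(b_e, rel=1e-9)
            assert traj.price[i] == pytest.approx(p_e, rel=1e-9)
            assert traj.harvest[i] == pytest.approx(h_e, rel=1e-9)
            assert traj.fleet_states["OA-A"][i].effort == pytest.approx(eoa_e, rel=1e-9)
            assert traj.fleet_states["M-U"][i].effort == pytest.approx(emu_e, rel=1e-9)
            assert traj.fleet_states["OA-A"][i].profit == pytest.approx(pioa_e, rel=1e-9)
            assert traj.fleet_states["M-U"][i].profit == pytest.approx(pimu_e, rel=1e-9)

    def test_bau_fixed_point_when_base_harvest_equals_growth(self):
        params = toy_params(horizon_year=2040)
        growth_b0 = surplus_production(params.b0, params)
        e0 = 1000.0
        q = growth_b0 / (params.b0 * e0)
        fleet = toy_fleet("OA-U", e0, q, s0=0.05, h0=growth_b0)
        traj = run_projection([fleet], params, "BAU")
        assert np.allclose(traj.biomass, params.b0, rtol=1e-9)
        assert np.allclose(traj.harvest, growth_b0, rtol=1e-9)
        assert np.allclose(traj.price, params.p0, rtol=1e-9)
        efforts = [s.effort for s in traj.fleet_states["OA-U"]]
        profits = [s.profit for s in traj.fleet_states["OA-U"]]
        assert np.allclose(efforts, e0, rtol=1e-9)
        assert np.allclose(profits, 0.0, atol=1e-6)

    @settings(max_examples=30, deadline=None)
    @given(
        q1=st.floats(1e-7, 1e-3),
        q2=st.floats(1e-7, 1e-3),
        e1=st.floats(1.0, 1e5),
        e2=st.floats(1.0, 1e5),
        s=st.floats(0.0, 1.0),
        eta=st.floats(1e-6, 1e-2),
    )
    def test_state_never_goes_negative(self, q1, q2, e1, e2, s, eta):
        params = toy_params(eta=eta, omega=eta / 10, horizon_year=2030)
        fleets = [
            toy_fleet("OA-A", e1, q1, s0=s, s_reformed=0.0),
            toy_fleet("M-U", e2, q2, s0=s),
        ]
        for scenario in ("BAU", "reform"):
            traj = run_projection(fleets, params, scenario)
            assert (traj.biomass >= 0).all()
            for states in traj.fleet_states.values():
                assert all(st_.effort >= 0 for st_ in states)
                assert all(st_.harvest >= 0 for st_ in states)

    def test_empty_fleet_is_inert(self):
        params = toy_params()
        empty = Fleet("M-A", frozenset(), 0.0, 0.0, 0.0, 0.0, s_reformed=0.0)
        live = toy_fleet("OA-U", 1000.0, 1e-4, s0=0.05)
        traj = run_projection([empty, live], params, "BAU")
        assert all(s.effort == 0 and s.harvest == 0 for s in traj.fleet_states["M-A"])


class TestCompareScenarios:
    def test_identical_trajectories_give_zero_changes(self):
        params = toy_params()
        fleets = [toy_fleet("OA-U", 1000.0, 1e-4, s0=0.05)]
        traj = run_projection(fleets, params, "BAU")
        result = compare_scenarios(traj, traj)
        assert result.as_dict() == {
            "biomass_pct": 0.0,
            "catch_pct": 0.0,
            "revenue_pct": 0.0,
            "fishing_mortality_pct": 0.0,
        }

    def test_ten_percent_biomass_gain_arithmetic(self):
        params = toy_params()
        fleets = [toy_fleet("OA-U", 1000.0, 1e-4, s0=0.05)]
        bau = run_projection(fleets, params, "BAU")
        boosted = np.array(bau.biomass) * 1.1
        reform = type(bau)(
            years=bau.years,
            biomass=boosted,
            price=bau.price,
            harvest=bau.harvest,
            fishing_mortality=bau.fishing_mortality,
            fleet_states=bau.fleet_states,
        )
        result = compare_scenarios(bau, reform)
        assert result.biomass_pct == pytest.approx(10.0)

    def test_mismatched_windows_rejected(self):
        params = toy_params()
        fleets = [toy_fleet("OA-U", 1000.0, 1e-4, s0=0.05)]
        a = run_projection(fleets, params, "BAU")
        b = run_projection(fleets, toy_params(horizon_year=2025), "BAU")
        with pytest.raises(DomainError):
            compare_scenarios(a, b)
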