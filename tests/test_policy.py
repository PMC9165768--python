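"""Discipline predicates, proposal evaluation, removals, cap rules."""

import dataclasses

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from fleetreform import (
    CapBasis,
    CapRule,
    ConfigurationError,
    CountryProfile,
    Discipline,
    DisciplineCategory,
    EffectiveSubsidyWeights,
    Predicate,
    PredicateKind,
    Proposal,
    RemovalScope,
    apply_cap_rule,
    compute_removal_amounts,
    evaluate_discipline,
    select_affected_vessels,
)
from fleetreform.policy import distribute_cap_removal

from .helpers import make_vessel

UNIT = EffectiveSubsidyWeights.unit()
CE = {"fuel": True, "vessel_construction": True, "management": False}


def iuu_discipline(**kw):
    return Discipline(
        category=DisciplineCategory.IUU,
        predicate=Predicate(PredicateKind.IUU_LISTED),
        **kw,
    )


class TestPredicates:
    def test_iuu_listed_vessel_triggers_iuu_discipline(self):
        assert evaluate_discipline(make_vessel(iuu_listed=True), iuu_discipline())
        assert not evaluate_discipline(make_vessel(iuu_listed=False), iuu_discipline())

    @pytest.mark.parametrize(
        "status, threshold, expected",
        [(0.9, 1.0, True), (0.9, 0.8, False), (0.79, 0.8, True), (0.8, 0.8, False)],
    )
    def test_overfished_threshold_is_strict_less_than(self, status, threshold, expected):
        d = Discipline(
            category=DisciplineCategory.OVERFISHED,
            predicate=Predicate(PredicateKind.STOCK_STATUS_BELOW, threshold=threshold),
        )
        assert evaluate_discipline(make_vessel(stock_status=status), d) is expected

    @pytest.mark.parametrize(
        "fraction, expected", [(0.96, True), (0.95, True), (0.94, False)]
    )
    def test_high_seas_threshold_is_at_least(self, fraction, expected):
        d = Discipline(
            category=DisciplineCategory.OFOC,
            predicate=Predicate(PredicateKind.HIGH_SEAS_FRACTION_AT_LEAST, threshold=0.95),
        )
        vessel = make_vessel(
            high_seas_fraction=fraction, distant_water_fraction=0.0, territorial_fraction=1 - fraction
        )
        assert evaluate_discipline(vessel, d) is expected

    def test_exempted_development_status_never_triggers(self):
        d = iuu_discipline(exemptions=frozenset({"LDC"}))
        vessel = make_vessel(iuu_listed=True, development_status="LDC")
        assert not evaluate_discipline(vessel, d)
        assert evaluate_discipline(
            make_vessel(iuu_listed=True, development_status="developed"), d
        )


class TestSelection:
    def test_non_triggering_proposal_leaves_all_unaffected(self):
        vessels = [make_vessel(f"V{i}") for i in range(5)]
        proposal = Proposal("nothing", (iuu_discipline(),))
        part = select_affected_vessels(vessels, proposal)
        assert part.affected == ()
        assert len(part.unaffected) == 5

    def test_worked_example_affects_three_of_ten(self, worked_example):
        vessels, proposal = worked_example
        part = select_affected_vessels(vessels, proposal)
        assert len(part.affected) == 3
        assert len(part.unaffected) == 7
        assert set(part.affected_ids) == {"WE05", "WE09", "WE10"}

    def test_overlapping_disciplines_union_their_scopes(self):
        vessel = make_vessel(iuu_listed=True, stock_status=0.5)
        proposal = Proposal(
            "both",
            (
                iuu_discipline(
                    removal_scope=RemovalScope(False, frozenset({"fuel"}))
                ),
                Discipline(
                    category=DisciplineCategory.OVERFISHED,
                    predicate=Predicate(PredicateKind.STOCK_STATUS_BELOW, threshold=1.0),
                    removal_scope=RemovalScope(False, frozenset({"vessel_construction"})),
                ),
            ),
        )
        part = select_affected_vessels([vessel], proposal)
        assert len(part.affected) == 1  # affected once, not twice
        scope = part.scopes[vessel.vessel_id]
        assert scope.listed_types == {"fuel", "vessel_construction"}

    def test_partition_is_exhaustive_and_disjoint(self, small_world):
        world, _ = small_world
        proposal = Proposal(
            "hs",
            (
                Discipline(
                    category=DisciplineCategory.OFOC,
                    predicate=Predicate(PredicateKind.HIGH_SEAS_FRACTION_AT_LEAST, threshold=0.05),
                ),
            ),
        )
        part = select_affected_vessels(world.vessels, proposal)
        ids_a = {v.vessel_id for v in part.affected}
        ids_u = {v.vessel_id for v in part.unaffected}
        assert ids_a | ids_u == {v.vessel_id for v in world.vessels}
        assert ids_a & ids_u == set()

    @settings(max_examples=50, deadline=None)
    @given(
        flags=st.lists(st.booleans(), min_size=1, max_size=8),
        statuses=st.lists(st.floats(0.1, 2.0), min_size=1, max_size=8),
    )
    def test_adding_a_discipline_never_shrinks_the_affected_set(self, flags, statuses):
        n = min(len(flags), len(statuses))
        vessels = [
            make_vessel(f"V{i}", iuu_listed=flags[i], stock_status=statuses[i])
            for i in range(n)
        ]
        base = Proposal("iuu", (iuu_discipline(),))
        extended = Proposal(
            "iuu+of",
            base.disciplines
            + (
                Discipline(
                    category=DisciplineCategory.OVERFISHED,
                    predicate=Predicate(PredicateKind.STOCK_STATUS_BELOW, threshold=1.0),
                ),
            ),
        )
        small = select_affected_vessels(vessels, base).affected_ids
        large = select_affected_vessels(vessels, extended).affected_ids
        assert small <= large


class TestRemoval:
    def test_vessel_without_capacity_enhancing_subsidies_loses_nothing(self):
        vessel = make_vessel(subsidies_by_type={"management": 40.0})
        removed, remaining = compute_removal_amounts(vessel, RemovalScope(True), UNIT, CE)
        assert removed == 0.0
        assert remaining == {"management": 40.0}

    def test_all_capacity_enhancing_scope_removes_only_ce_types(self):
        vessel = make_vessel(subsidies_by_type={"fuel": 60.0, "management": 40.0})
        removed, remaining = compute_removal_amounts(vessel, RemovalScope(True), UNIT, CE)
        assert removed == pytest.approx(60.0)
        assert remaining == {"management": 40.0}

    def test_listed_types_removed_regardless_of_ce_flag(self):
        vessel = make_vessel(subsidies_by_type={"fuel": 60.0, "management": 40.0})
        scope = RemovalScope(False, frozenset({"management"}))
        removed, remaining = compute_removal_amounts(vessel, scope, UNIT, CE)
        assert removed == pytest.approx(40.0)
        assert remaining == {"fuel": 60.0}

    def test_weights_convert_removal_to_effective_dollars(self):
        vessel = make_vessel(subsidies_by_type={"fuel": 100.0})
        weights = EffectiveSubsidyWeights({"fuel": 0.5})
        removed, _ = compute_removal_amounts(vessel, RemovalScope(True), weights, CE)
        assert removed == pytest.approx(50.0)

    @settings(max_examples=50, deadline=None)
    @given(
        fuel=st.floats(0, 1e6),
        mgmt=st.floats(0, 1e6),
        all_ce=st.booleans(),
    )
    def test_removal_never_exceeds_holdings_and_remainder_nonnegative(self, fuel, mgmt, all_ce):
        vessel = make_vessel(subsidies_by_type={"fuel": fuel, "management": mgmt})
        scope = RemovalScope(True) if all_ce else RemovalScope(False, frozenset({"fuel"}))
        removed, remaining = compute_removal_amounts(vessel, scope, UNIT, CE)
        assert 0 <= removed <= fuel + mgmt + 1e-9
        assert all(a >= 0 for a in remaining.values())


class TestCapRule:
    def _rule(self, basis=CapBasis.PERCENT_OF_CURRENT_SUBSIDIES, pct=3.0, green=()):
        return CapRule(
            tier_criterion={"developed": "t1", "developing": "t1", "LDC": "t1"},
            cap_basis=basis,
            cap_percent_by_tier={"t1": pct},
            green_box_types=frozenset(green),
        )

    def _country(self, subsidies, landed=200_000_000.0):
        return CountryProfile("AAA", "developed", subsidies, landed, 1_000_000.0)

    def test_three_percent_cap_on_current_subsidies(self):
        removed = apply_cap_rule(self._country({"fuel": 10_000_000.0}), self._rule())
        assert removed == pytest.approx(9_700_000.0)

    def test_landed_value_basis_can_leave_subsidies_untouched(self):
        rule = self._rule(basis=CapBasis.PERCENT_OF_LANDED_VALUE, pct=5.0)
        removed = apply_cap_rule(self._country({"fuel": 8_000_000.0}), rule)
        assert removed == 0.0  # cap of $10M exceeds $8M of subsidies

    def test_all_green_box_removes_nothing(self):
        rule = self._rule(green=("fuel", "management"))
        removed = apply_cap_rule(
            self._country({"fuel": 5e6, "management": 1e6}), rule
        )
        assert removed == 0.0

    @pytest.mark.parametrize("subs", [0.0, 1e3, 5e7, 1e10])
    def test_hundred_percent_cap_removes_exactly_zero(self, subs):
        rule = self._rule(pct=100.0)
        assert apply_cap_rule(self._country({"fuel": subs}), rule) == 0.0

    def test_unmapped_development_status_is_a_configuration_error(self):
        rule = CapRule(
            tier_criterion={"developed": "t1"},
            cap_basis=CapBasis.PERCENT_OF_CURRENT_SUBSIDIES,
            cap_percent_by_tier={"t1": 3.0},
        )
        country = CountryProfile("BBB", "LDC", {"fuel": 1e6}, 1e7, 1e4)
        with pytest.raises(ConfigurationError):
            apply_cap_rule(country, rule)

    def test_distribution_is_proportional_and_capped_at_holdings(self):
        vessels = [
            make_vessel("V1", subsidies_by_type={"fuel": 300.0}),
            make_vessel("V2", subsidies_by_type={"fuel": 100.0}),
        ]
        shares = distribute_cap_removal(vessels, 200.0)
        assert shares == {"V1": pytest.approx(150.0), "V2": pytest.approx(50.0)}
        over = distribute_cap_removal(vessels, 1e9)
        assert over == {"V1": pytest.approx(300.0), "V2": pytest.approx(100.0)}


class TestProposalValidation:
    def test_empty_proposal_rejected(self):
        with pytest.raises(ConfigurationError):
            Proposal("empty")

    def test_listed_scope_requires_types(self):
        with pytest.raises(ConfigurationError):
            RemovalScope(all_capacity_enhancing=False, listed_types=frozenset())
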