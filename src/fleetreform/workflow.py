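"""End-to-end scenario pipeline.

Chains the stages a reform analysis needs: allocate vessel economics,
assign management tiers, evaluate the proposal (disciplines and optional
cap rule), partition into the four fleets, calibrate, project business as
usual and reform, and compare.  Each stage is also usable on its own from
its home module; this is the orchestration layer used by the CLI, the
examples and the acceptance checks.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

from .errors import DomainError
from .fleets import (
    FLEET_LABELS,
    Fleet,
    aggregate_fleet,
    calibrate_fleet,
    partition_fleets,
)
from .policy import (
    AffectedPartition,
    CountryProfile,
    Proposal,
    apply_cap_rule,
    capacity_enhancing_map,
    compute_removal_amounts,
    distribute_cap_removal,
    select_affected_vessels,
)
from .projection import (
    ModelParams,
    ScenarioResult,
    Trajectory,
    compare_scenarios,
    run_projection,
)
from .vessels import (
    AllocationRates,
    EffectiveSubsidyWeights,
    SubsidyProgram,
    VesselRecord,
    allocate_vessel_economics,
    assign_management_tier,
)


@dataclass(frozen=True)
class ScenarioOutcome:
    """Everything a single proposal run produces."""

    proposal_name: str
    fleets: Mapping[str, Fleet]
    partition: AffectedPartition
    removed_effective_usd: float
    bau: Trajectory
    reform: Trajectory
    result: ScenarioResult

    @property
    def fleet_sizes(self) -> dict[str, int]:
        return {label: len(f.vessel_ids) for label, f in self.fleets.items()}


def build_country_profiles(
    vessels: Sequence[VesselRecord], programs: Sequence[SubsidyProgram]
) -> dict[str, CountryProfile]:
    """Country-level aggregates (for cap-and-tier rules) from allocated
    vessels and the subsidy table."""
    by_flag: dict[str, dict] = {}
    for v in vessels:
        d = by_flag.setdefault(
            v.flag_state,
            {"landed": 0.0, "catch": 0.0, "status": v.development_status},
        )
        d["landed"] += v.revenue_usd
        d["catch"] += v.catch_t
    subsidies: dict[str, dict[str, float]] = {}
    for p in programs:
        t = subsidies.setdefault(p.flag_state, {})
        t[p.subsidy_type] = t.get(p.subsidy_type, 0.0) + p.amount_usd
    return {
        flag: CountryProfile(
            flag_state=flag,
            development_status=d["status"],
            total_subsidies_by_type=subsidies.get(flag, {}),
            landed_value_usd=d["landed"],
            capture_production_t=d["catch"],
        )
        for flag, d in by_flag.items()
    }


def compute_vessel_removals(
    vessels: Sequence[VesselRecord],
    proposal: Proposal,
    programs: Sequence[SubsidyProgram],
    weights: EffectiveSubsidyWeights,
    removal_fraction: float = 1.0,
) -> tuple[AffectedPartition, dict[str, float]]:
    """Per-vessel effective subsidy removals under a proposal.

    Discipline removals come from each affected vessel's unioned removal
    scope; cap-rule removals are computed per country and spread over its
    vessels in proportion to their subsidy holdings.  A vessel touched by
    either route counts as affected.  ``removal_fraction`` scales every
    removal (1.0 = the proposal as written), supporting partial-ambition
    sweeps.

    Returns the affected/unaffected partition (including cap-affected
    vessels) and a map vessel_id -> effective USD removed.
    """
    if not 0 <= removal_fraction <= 1:
        raise DomainError("removal_fraction must be in [0, 1]")
    from .synthetic import DEFAULT_SUBSIDY_TYPES

    # subsidy table rows are authoritative on which types are
    # capacity-enhancing; the canonical registry fills any gaps
    ce_map = {**DEFAULT_SUBSIDY_TYPES, **capacity_enhancing_map(programs)}
    part = select_affected_vessels(vessels, proposal)

    removed: dict[str, float] = {}
    for v in part.affected:
        eff, _remaining = compute_removal_amounts(v, part.scopes[v.vessel_id], weights, ce_map)
        removed[v.vessel_id] = eff * removal_fraction

    cap_affected_ids: set[str] = set()
    if proposal.cap_rule is not None:
        rule = proposal.cap_rule
        profiles = build_country_profiles(vessels, programs)
        by_flag: dict[str, list[VesselRecord]] = {}
        for v in vessels:
            by_flag.setdefault(v.flag_state, []).append(v)
        for flag, country in profiles.items():
            removed_usd = apply_cap_rule(country, rule)
            if removed_usd <= 0:
                continue
            shares = distribute_cap_removal(
                by_flag[flag], removed_usd, rule.green_box_types
            )
            for v in by_flag[flag]:
                nominal = shares[v.vessel_id]
                if nominal <= 0:
                    continue
                holdings = sum(
                    a
                    for t, a in v.subsidies_by_type.items()
                    if t not in rule.green_box_types
                )
                if holdings <= 0:
                    continue
                # drawdown is spread across the vessel's non-green-box types
                # pro rata, then weighted into effective dollars
                frac = nominal / holdings
                eff = sum(
                    a * frac * weights.weight_for(t)
                    for t, a in v.subsidies_by_type.items()
                    if t not in rule.green_box_types
                )
                removed[v.vessel_id] = removed.get(v.vessel_id, 0.0) + eff * removal_fraction
                cap_affected_ids.add(v.vessel_id)

    if cap_affected_ids:
        affected_ids = set(part.affected_ids) | cap_affected_ids
        affected = tuple(v for v in vessels if v.vessel_id in affected_ids)
        unaffected = tuple(v for v in vessels if v.vessel_id not in affected_ids)
        part = AffectedPartition(affected, unaffected, dict(part.scopes))

    # an affected vessel never loses more effective dollars than it holds
    for v in part.affected:
        holding = sum(
            a * weights.weight_for(t) for t, a in v.subsidies_by_type.items()
        )
        if v.vessel_id in removed:
            removed[v.vessel_id] = min(removed[v.vessel_id], holding)
    return part, removed


def calibrate_scenario(
    vessels: Sequence[VesselRecord],
    partition: AffectedPartition,
    params: ModelParams,
    weights: EffectiveSubsidyWeights,
    removed_by_vessel: Mapping[str, float],
) -> dict[str, Fleet]:
    """Partition tier-labelled vessels into the four fleets and calibrate
    each fleet's catchability and cost coefficient."""
    groups = partition_fleets(vessels, partition.affected_ids)
    fleets = {
        label: aggregate_fleet(label, groups[label], weights, removed_by_vessel)
        for label in FLEET_LABELS
    }
    return {
        label: calibrate_fleet(f, params.b0, params.p0, params.beta)
        for label, f in fleets.items()
    }


def run_scenario(
    vessels: Sequence[VesselRecord],
    programs: Sequence[SubsidyProgram],
    proposal: Proposal,
    params: ModelParams,
    weights: EffectiveSubsidyWeights | None = None,
    rates: AllocationRates | None = None,
    quantile_threshold: float = 0.5,
    removal_fraction: float = 1.0,
) -> ScenarioOutcome:
    """Run one proposal end to end and compare against business as usual.

    ``vessels`` may come pre-allocated (catch/revenue/subsidies already
    filled, as in the worked example); otherwise pass ``rates`` to allocate
    here.  Tier labels are (re)assigned from management scores unless every
    vessel already carries one.
    """
    weights = weights or EffectiveSubsidyWeights.unit()
    if rates is not None:
        vessels = allocate_vessel_economics(vessels, rates, programs)
    if any(v.management_tier is None for v in vessels):
        vessels = assign_management_tier(vessels, quantile_threshold)

    partition, removed = compute_vessel_removals(
        vessels, proposal, programs, weights, removal_fraction
    )
    fleets = calibrate_scenario(vessels, partition, params, weights, removed)
    if params.h0_demand is None:
        params = params.with_demand_calibrated(sum(f.h0 for f in fleets.values()))

    bau = run_projection(fleets, params, "BAU")
    reform = run_projection(fleets, params, "reform")
    return ScenarioOutcome(
        proposal_name=proposal.name,
        fleets=fleets,
        partition=partition,
        removed_effective_usd=float(sum(removed.values())),
        bau=bau,
        reform=reform,
        result=compare_scenarios(bau, reform),
    )
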