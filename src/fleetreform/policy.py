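"""Subsidy-reform disciplines, proposals, and removal computation.

A *discipline* is a single proposed prohibition: a predicate over vessel
attributes (IUU listing, fishing on overfished stocks, high-seas activity,
...) plus a removal scope saying which subsidy types the triggered vessel
loses.  A *proposal* (reform package) is a set of disciplines, optionally
with a country-level cap-and-tier rule.  Development-status exemptions
implement special and differential treatment (S&DT).

Predicate thresholds follow the half-open conventions of the negotiating
text: "at least X% of time" is >=, "stock status below Y" is strict <.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Mapping, Sequence

from .errors import ConfigurationError
from .vessels import (
    EffectiveSubsidyWeights,
    SubsidyProgram,
    VesselRecord,
    apply_effective_subsidy_weights,
)


class DisciplineCategory(str, Enum):
    IUU = "IUU"
    OVERFISHED = "overfished"
    OFOC = "OFOC"  # overcapacity and overfishing


class PredicateKind(str, Enum):
    IUU_LISTED = "iuu_listed"
    STOCK_STATUS_BELOW = "stock_status_below"
    HIGH_SEAS_FRACTION_AT_LEAST = "high_seas_fraction_at_least"
    DISTANT_WATER_FRACTION_AT_LEAST = "distant_water_fraction_at_least"
    DISPUTED_AREA = "disputed_area"
    DEVELOPMENT_STATUS_IN = "development_status_in"


#: removal-scope sentinel: remove every capacity-enhancing subsidy type
ALL_CAPACITY_ENHANCING = "all_capacity_enhancing"


@dataclass(frozen=True)
class Predicate:
    """A single vessel-attribute test with an optional numeric threshold."""

    kind: PredicateKind
    threshold: float | None = None
    statuses: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        if self.kind is PredicateKind.STOCK_STATUS_BELOW:
            if self.threshold is None or self.threshold <= 0:
                raise ConfigurationError("threshold", "stock-status threshold must be > 0")
        elif self.kind in (
            PredicateKind.HIGH_SEAS_FRACTION_AT_LEAST,
            PredicateKind.DISTANT_WATER_FRACTION_AT_LEAST,
        ):
            if self.threshold is None or not 0 <= self.threshold <= 1:
                raise ConfigurationError("threshold", "fraction threshold must be in [0, 1]")
        elif self.kind is PredicateKind.DEVELOPMENT_STATUS_IN and not self.statuses:
            raise ConfigurationError("statuses", "development-status set must be non-empty")

    def holds(self, vessel: VesselRecord) -> bool:
        k = self.kind
        if k is PredicateKind.IUU_LISTED:
            return vessel.iuu_listed
        if k is PredicateKind.STOCK_STATUS_BELOW:
            return vessel.stock_status < self.threshold
        if k is PredicateKind.HIGH_SEAS_FRACTION_AT_LEAST:
            return vessel.high_seas_fraction >= self.threshold
        if k is PredicateKind.DISTANT_WATER_FRACTION_AT_LEAST:
            return vessel.distant_water_fraction >= self.threshold
        if k is PredicateKind.DISPUTED_AREA:
            return vessel.disputed_area
        if k is PredicateKind.DEVELOPMENT_STATUS_IN:
            return vessel.development_status in self.statuses
        raise AssertionError(f"unhandled predicate kind {k}")


@dataclass(frozen=True)
class RemovalScope:
    """Which subsidy types a triggered prohibition removes.

    Either every capacity-enhancing type (IUU / overfished disciplines) or
    an explicit list of types (OFOC list-based disciplines).  Listed types
    are removed whether or not they are flagged capacity-enhancing.
    """

    all_capacity_enhancing: bool = True
    listed_types: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        if not self.all_capacity_enhancing and not self.listed_types:
            raise ConfigurationError(
                "listed_types", "must be non-empty when not removing all capacity-enhancing types"
            )

    def removed_types(self, present_types: Iterable[str], capacity_enhancing: Mapping[str, bool]) -> set[str]:
        present = set(present_types)
        if self.all_capacity_enhancing:
            ce = {t for t in present if capacity_enhancing.get(t, False)}
            return ce | (self.listed_types & present)
        return self.listed_types & present

    def union(self, other: "RemovalScope") -> "RemovalScope":
        return RemovalScope(
            all_capacity_enhancing=self.all_capacity_enhancing or other.all_capacity_enhancing,
            listed_types=self.listed_types | other.listed_types,
        )


@dataclass(frozen=True)
class Discipline:
    category: DisciplineCategory
    predicate: Predicate
    removal_scope: RemovalScope = field(default_factory=RemovalScope)
    exemptions: frozenset[str] = frozenset()  # exempted development statuses (S&DT)
    name: str = ""

    def applies_to(self, vessel: VesselRecord) -> bool:
        """True iff the predicate holds and the vessel's flag is not exempt."""
        if vessel.development_status in self.exemptions:
            return False
        return self.predicate.holds(vessel)


class CapBasis(str, Enum):
    PERCENT_OF_CURRENT_SUBSIDIES = "percent_of_current_subsidies"
    PERCENT_OF_LANDED_VALUE = "percent_of_landed_value"


@dataclass(frozen=True)
class CapRule:
    """Country-level cap-and-tier rule.

    Members are tiered (here by development status) and each tier's
    permissible subsidies capped at a percentage of a basis — either the
    country's current non-green-box subsidies or its landed value.
    Green-box types are exempt from the cap base and are never removed.
    """

    tier_criterion: Mapping[str, str]  # development_status -> tier
    cap_basis: CapBasis
    cap_percent_by_tier: Mapping[str, float]  # tier -> percentage
    green_box_types: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        if any(p < 0 for p in self.cap_percent_by_tier.values()):
            raise ConfigurationError("cap_percent_by_tier", "percentages must be >= 0")
        for status, tier in self.tier_criterion.items():
            if tier not in self.cap_percent_by_tier:
                raise ConfigurationError(
                    "cap_percent_by_tier", f"no cap percentage for tier {tier!r} (status {status!r})"
                )


@dataclass(frozen=True)
class Proposal:
    """A reform package: a set of disciplines, optionally plus a cap rule."""

    name: str
    disciplines: tuple[Discipline, ...] = ()
    cap_rule: CapRule | None = None

    def __post_init__(self) -> None:
        if not self.disciplines and self.cap_rule is None:
            raise ConfigurationError("disciplines", "a proposal needs at least one discipline or a cap rule")


@dataclass(frozen=True)
class CountryProfile:
    """Country-level aggregates used by cap-and-tier rules."""

    flag_state: str
    development_status: str
    total_subsidies_by_type: Mapping[str, float]
    landed_value_usd: float
    capture_production_t: float
    subsidy_per_fisher_usd: float = 0.0

    def __post_init__(self) -> None:
        amounts = list(self.total_subsidies_by_type.values()) + [
            self.landed_value_usd,
            self.capture_production_t,
            self.subsidy_per_fisher_usd,
        ]
        if any(a < 0 for a in amounts):
            raise ConfigurationError("amounts", "country amounts must be >= 0")


# ---------------------------------------------------------------------------
# Evaluation
# ---------------------------------------------------------------------------

def evaluate_discipline(vessel: VesselRecord, discipline: Discipline) -> bool:
    """Does this vessel trigger this discipline's prohibition?"""
    return discipline.applies_to(vessel)


@dataclass(frozen=True)
class AffectedPartition:
    """Exhaustive, disjoint split of the vessel list under a proposal."""

    affected: tuple[VesselRecord, ...]
    unaffected: tuple[VesselRecord, ...]
    scopes: Mapping[str, RemovalScope]  # vessel_id -> unioned removal scope

    @property
    def affected_ids(self) -> frozenset[str]:
        return frozenset(v.vessel_id for v in self.affected)


def select_affected_vessels(
    vessels: Sequence[VesselRecord], proposal: Proposal
) -> AffectedPartition:
    """Partition vessels into affected / unaffected under a proposal.

    A vessel is affected iff at least one discipline triggers; when several
    trigger, their removal scopes union so no dollar is removed twice.
    """
    affected: list[VesselRecord] = []
    unaffected: list[VesselRecord] = []
    scopes: dict[str, RemovalScope] = {}
    for v in vessels:
        scope: RemovalScope | None = None
        for d in proposal.disciplines:
            if d.applies_to(v):
                scope = d.removal_scope if scope is None else scope.union(d.removal_scope)
        if scope is None:
            unaffected.append(v)
        else:
            affected.append(v)
            scopes[v.vessel_id] = scope
    return AffectedPartition(tuple(affected), tuple(unaffected), scopes)


def capacity_enhancing_map(programs: Iterable[SubsidyProgram]) -> dict[str, bool]:
    """Subsidy type -> capacity-enhancing flag (a type is CE if any program says so)."""
    out: dict[str, bool] = {}
    for p in programs:
        out[p.subsidy_type] = out.get(p.subsidy_type, False) or p.capacity_enhancing
    return out


def compute_removal_amounts(
    vessel: VesselRecord,
    scope: RemovalScope,
    weights: EffectiveSubsidyWeights,
    capacity_enhancing: Mapping[str, bool],
) -> tuple[float, dict[str, float]]:
    """Effective USD removed from one vessel and its post-removal subsidies.

    Returns ``(effective_removed_usd, remaining_subsidies_by_type)``.
    Removal zeroes the scoped types; the remaining map keeps the others
    unchanged, so remaining amounts are always >= 0.
    """
    removed_types = scope.removed_types(vessel.subsidies_by_type, capacity_enhancing)
    removed_nominal = {t: vessel.subsidies_by_type[t] for t in removed_types}
    remaining = {
        t: a for t, a in vessel.subsidies_by_type.items() if t not in removed_types
    }
    removed_effective = apply_effective_subsidy_weights(removed_nominal, weights)
    return removed_effective, remaining


def apply_cap_rule(
    country: CountryProfile, rule: CapRule
) -> float:
    """Nominal USD of subsidies a cap-and-tier rule removes from one country.

    cap = tier percentage x basis; removed = max(0, non-green-box subsidies
    - cap).  With a 100% cap on current subsidies the removal is exactly 0.
    """
    if country.development_status not in rule.tier_criterion:
        raise ConfigurationError(
            "tier_criterion", f"development status {country.development_status!r} has no tier"
        )
    tier = rule.tier_criterion[country.development_status]
    pct = rule.cap_percent_by_tier[tier] / 100.0
    non_green = sum(
        a for t, a in country.total_subsidies_by_type.items() if t not in rule.green_box_types
    )
    if rule.cap_basis is CapBasis.PERCENT_OF_CURRENT_SUBSIDIES:
        cap = pct * non_green
    else:
        cap = pct * country.landed_value_usd
    return max(0.0, non_green - cap)


def distribute_cap_removal(
    vessels: Sequence[VesselRecord],
    removed_usd: float,
    green_box_types: frozenset[str] = frozenset(),
) -> dict[str, float]:
    """Spread a country-level cap removal over its vessels, proportional to
    each vessel's current (non-green-box) subsidy allocation.

    Returns vessel_id -> nominal USD removed.  Vessel shares are capped at
    their holdings, so no vessel goes negative.
    """
    holdings = {
        v.vessel_id: sum(a for t, a in v.subsidies_by_type.items() if t not in green_box_types)
        for v in vessels
    }
    total = sum(holdings.values())
    if total <= 0 or removed_usd <= 0:
        return {v.vessel_id: 0.0 for v in vessels}
    frac = min(1.0, removed_usd / total)
    return {vid: h * frac for vid, h in holdings.items()}
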