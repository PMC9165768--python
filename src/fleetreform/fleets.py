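"""Four-fleet partition and bioeconomic calibration.

The simulator tracks four fleets formed by crossing the management tier
(managed *M* vs open-access *OA*) with reform exposure (affected *A* vs
unaffected *U*): M-A, M-U, OA-A, OA-U.  Base-year aggregates (harvest h0,
effort e0, effective subsidy rate s0, revenue) are sums over each fleet's
vessels.  Calibration then pins the model to the base year:

* growth rate       g  = (MSY / K) * (phi + 1)^(1/phi)
* catchability      q_j = h_{j,0} / (b_0 * e_{j,0})
* demand constant   delta = h_0 * p_0^epsilon
* cost coefficient  alpha_j = (p_0 h_{j,0} + s_{j,0} e_{j,0}) / e_{j,0}^beta

The cost coefficient is solved under the zero-profit (open-access
equilibrium) assumption, crediting subsidies as artificially lowered costs,
so every fleet's base-year profit is exactly zero by construction.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from .errors import DomainError
from .vessels import (
    MANAGED,
    EffectiveSubsidyWeights,
    VesselRecord,
    apply_effective_subsidy_weights,
)

FLEET_LABELS = ("M-A", "M-U", "OA-A", "OA-U")

#: labels of the two reform-affected fleets
AFFECTED_LABELS = ("M-A", "OA-A")

#: labels of the open-access fleets (fast effort response, speed eta)
OPEN_ACCESS_LABELS = ("OA-A", "OA-U")


@dataclass(frozen=True)
class Fleet:
    """One model fleet with base-year aggregates and calibrated coefficients.

    ``s0`` and ``s_reformed`` are effective subsidy rates in USD/kWh; under
    business as usual the fleet fishes at ``s0`` forever, under reform the
    affected fleets drop to ``s_reformed``.  An empty fleet (``e0 == 0``)
    is inert: it carries zero effort and is skipped by the projection.
    """

    label: str
    vessel_ids: frozenset[str]
    h0: float  # base-year harvest, tonnes
    e0: float  # base-year effort, kWh
    s0: float  # base-year effective subsidy rate, USD/kWh
    revenue0: float  # base-year landed value, USD
    q: float = 0.0  # catchability, 1/kWh (per unit biomass)
    alpha: float = 0.0  # cost coefficient, USD per kWh^beta
    s_reformed: float | None = None  # post-reform subsidy rate, USD/kWh

    def __post_init__(self) -> None:
        if self.label not in FLEET_LABELS:
            raise DomainError(f"unknown fleet label {self.label!r}")
        if self.e0 < 0 or self.h0 < 0 or self.q < 0 or self.alpha < 0:
            raise DomainError(f"fleet {self.label}: negative aggregate")
        if self.s_reformed is not None and not (
            -1e-12 <= self.s_reformed <= self.s0 + 1e-12
        ):
            raise DomainError(
                f"fleet {self.label}: s_reformed must lie in [0, s0]"
            )

    @property
    def is_empty(self) -> bool:
        return self.e0 == 0

    @property
    def is_open_access(self) -> bool:
        return self.label in OPEN_ACCESS_LABELS

    @property
    def is_affected(self) -> bool:
        return self.label in AFFECTED_LABELS


def partition_fleets(
    vessels: Sequence[VesselRecord], affected_ids: Iterable[str]
) -> dict[str, list[VesselRecord]]:
    """Split tier-labelled vessels into the four fleets.

    Every vessel must already carry a management tier; ``affected_ids``
    comes from the policy engine.  The four lists are disjoint and cover
    the input exactly.
    """
    affected = frozenset(affected_ids)
    out: dict[str, list[VesselRecord]] = {label: [] for label in FLEET_LABELS}
    for v in vessels:
        if v.management_tier is None:
            raise DomainError(f"vessel {v.vessel_id} has no management tier")
        tier = "M" if v.management_tier == MANAGED else "OA"
        exposure = "A" if v.vessel_id in affected else "U"
        out[f"{tier}-{exposure}"].append(v)
    return out


def aggregate_fleet(
    label: str,
    vessels: Sequence[VesselRecord],
    weights: EffectiveSubsidyWeights | None = None,
    removed_effective_by_vessel: Mapping[str, float] | None = None,
) -> Fleet:
    """Aggregate a fleet's base-year characteristics from its vessels.

    Harvest, effort and revenue are sums; the subsidy rate s0 is total
    *effective* (multiplier-weighted) subsidies over total effort.  When
    per-vessel removals are given (effective USD), ``s_reformed`` is the
    post-removal rate; otherwise it defaults to s0 (no reform).
    """
    weights = weights or EffectiveSubsidyWeights.unit()
    h0 = sum(v.catch_t for v in vessels)
    e0 = sum(v.total_effort_kwh for v in vessels)
    revenue0 = sum(v.revenue_usd for v in vessels)
    subs_eff = sum(
        apply_effective_subsidy_weights(v.subsidies_by_type, weights) for v in vessels
    )
    if e0 == 0:
        if subs_eff > 0:
            raise DomainError(f"fleet {label}: zero effort but nonzero subsidies")
        return Fleet(label, frozenset(), 0.0, 0.0, 0.0, 0.0, s_reformed=0.0)
    removed = 0.0
    if removed_effective_by_vessel:
        removed = sum(
            removed_effective_by_vessel.get(v.vessel_id, 0.0) for v in vessels
        )
    s0 = subs_eff / e0
    s_reformed = max(0.0, (subs_eff - removed)) / e0
    return Fleet(
        label=label,
        vessel_ids=frozenset(v.vessel_id for v in vessels),
        h0=h0,
        e0=e0,
        s0=s0,
        revenue0=revenue0,
        s_reformed=min(s_reformed, s0),
    )


# ---------------------------------------------------------------------------
# Calibration
# ---------------------------------------------------------------------------

def growth_rate_from_msy(msy: float, k: float, phi: float) -> float:
    """Intrinsic growth rate implied by MSY, carrying capacity and the
    production-curve asymmetry phi."""
    if msy < 0 or k <= 0 or phi <= 0:
        raise DomainError("growth_rate_from_msy requires msy >= 0, k > 0, phi > 0")
    return (msy / k) * (phi + 1.0) ** (1.0 / phi)


def calibrate_catchability(h0: float, b0: float, e0: float) -> float:
    """Fleet catchability from base-year harvest, global biomass and effort."""
    if b0 <= 0 or e0 <= 0:
        raise DomainError("calibrate_catchability requires b0 > 0 and e0 > 0")
    if h0 < 0:
        raise DomainError("h0 must be >= 0")
    return h0 / (b0 * e0)


def calibrate_demand_constant(h0: float, p0: float, epsilon: float) -> float:
    """Constant of the isoelastic demand curve, delta = h0 * p0^epsilon."""
    if h0 <= 0 or p0 <= 0:
        raise DomainError("calibrate_demand_constant requires h0 > 0 and p0 > 0")
    if epsilon == 0:
        raise DomainError("demand elasticity must be nonzero")
    return h0 * p0**epsilon


def calibrate_cost_coefficient(
    p0: float, h0: float, s0: float, e0: float, beta: float
) -> float:
    """Cost coefficient making base-year profit exactly zero.

    alpha = (p0*h0 + s0*e0) / e0^beta, i.e. base-year revenue plus subsidies
    fully dissipated by costs (rational fleets expand effort until marginal
    profits vanish).
    """
    if e0 <= 0:
        raise DomainError("calibrate_cost_coefficient requires e0 > 0")
    if beta <= 0:
        raise DomainError("beta must be > 0")
    return (p0 * h0 + s0 * e0) / e0**beta


def calibrate_fleet(fleet: Fleet, b0: float, p0: float, beta: float) -> Fleet:
    """Return the fleet with q and alpha calibrated; empty fleets unchanged."""
    if fleet.is_empty:
        return fleet
    q = calibrate_catchability(fleet.h0, b0, fleet.e0)
    alpha = calibrate_cost_coefficient(p0, fleet.h0, fleet.s0, fleet.e0, beta)
    return replace(fleet, q=q, alpha=alpha)


def calibration_summary(
    fleets: Mapping[str, Fleet], g: float, delta: float, path: str | Path | None = None
) -> dict:
    """Audit record of the calibration (per-fleet aggregates and coefficients,
    plus the global growth rate and demand constant); optionally written as JSON."""
    summary = {
        "global": {"g": g, "delta": delta},
        "fleets": {
            label: {
                "n_vessels": len(f.vessel_ids),
                "h0_t": f.h0,
                "e0_kwh": f.e0,
                "s0_usd_per_kwh": f.s0,
                "revenue0_usd": f.revenue0,
                "q": f.q,
                "alpha": f.alpha,
                "s_reformed_usd_per_kwh": f.s_reformed,
            }
            for label, f in fleets.items()
        },
    }
    if path is not None:
        Path(path).write_text(json.dumps(summary, indent=2, sort_keys=True))
    return summary
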