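"""Annual bioeconomic projection and scenario comparison.

State evolves on a yearly grid from the base year to the horizon.  A single
global stock follows Pella-Tomlinson surplus production

    b_{t+1} = b_t + ((phi+1)/phi) * g * b_t * (1 - (b_t/K)^phi) - h_t

with fleet harvests h_{j,t} = q_j * b_t * e_{j,t}, an isoelastic demand
curve p_t = p_0 (h_t / h_0)^(1/epsilon) linking price to total harvest, costs
c_{j,t} = alpha_j * e_{j,t}^beta, and profits pi = p*h - c + s*e where s is
the (effective) subsidy rate.  Effort follows profits with a regime-specific
speed: open-access fleets respond at eta kWh per dollar, managed fleets at
omega << eta, so identical losses shrink an open-access fleet's effort much
faster than a managed one's.

Within a year the order is: harvest -> price -> costs/profits -> biomass
-> effort; the biomass update uses the current year's harvest and the
effort update the current year's profit.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from typing import Literal, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import DomainError, SimulationError
from .fleets import Fleet, growth_rate_from_msy

logger = logging.getLogger(__name__)

#: relative harvest floor used when evaluating the demand curve near h = 0
PRICE_FLOOR_FRACTION = 1e-6

Scenario = Literal["BAU", "reform"]


@dataclass(frozen=True)
class ModelParams:
    """Global biological and economic parameters.

    Exactly one of ``msy`` (tonnes/yr) or ``g`` (1/yr) may be given; the
    other is derived through g = (MSY/K)(phi+1)^(1/phi).  ``delta`` is the
    demand constant, normally calibrated from base-year harvest and price
    via :meth:`with_demand_calibrated`.  ``epsilon`` must be negative
    (downward-sloping demand).  ``eta`` and ``omega`` are effort-adjustment
    speeds in kWh per USD of profit for open-access and managed fleets.
    """

    phi: float
    k: float
    b0: float
    p0: float
    epsilon: float
    beta: float
    eta: float
    omega: float
    msy: float | None = None
    g: float | None = None
    delta: float | None = None
    h0_demand: float | None = None  # base-year total harvest anchoring demand
    base_year: int = 2018
    horizon_year: int = 2050

    def __post_init__(self) -> None:
        if self.k <= 0:
            raise DomainError("carrying capacity K must be > 0")
        if not 0 < self.b0 <= self.k:
            raise DomainError("base-year biomass b0 must satisfy 0 < b0 <= K")
        if self.phi <= 0:
            raise DomainError("phi must be > 0")
        if self.beta < 1:
            raise DomainError("cost exponent beta must be >= 1")
        if not self.eta > self.omega >= 0:
            raise DomainError("effort speeds must satisfy eta > omega >= 0")
        if self.epsilon >= 0:
            raise DomainError("demand elasticity epsilon must be < 0")
        if self.p0 <= 0:
            raise DomainError("base-year price p0 must be > 0")
        if self.horizon_year <= self.base_year:
            raise DomainError("horizon_year must be after base_year")
        if self.msy is None and self.g is None:
            raise DomainError("give msy or g")
        if self.g is None:
            object.__setattr__(
                self, "g", growth_rate_from_msy(self.msy, self.k, self.phi)
            )
        else:
            if self.g <= 0:
                raise DomainError("growth rate g must be > 0")
            implied_msy = self.g * self.k * (self.phi + 1.0) ** (-1.0 / self.phi)
            if self.msy is None:
                object.__setattr__(self, "msy", implied_msy)
            elif abs(self.msy - implied_msy) > 1e-6 * max(1.0, abs(implied_msy)):
                raise DomainError("msy and g are inconsistent with K and phi")

    @property
    def n_years(self) -> int:
        return self.horizon_year - self.base_year + 1

    @property
    def bmsy(self) -> float:
        """Biomass maximising surplus production, K(phi+1)^(-1/phi)."""
        return self.k * (self.phi + 1.0) ** (-1.0 / self.phi)

    def with_demand_calibrated(self, h0: float) -> "ModelParams":
        """Pin the demand curve through the base point, so price(h0) = p0."""
        from .fleets import calibrate_demand_constant

        return replace(
            self,
            delta=calibrate_demand_constant(h0, self.p0, self.epsilon),
            h0_demand=h0,
        )

    @property
    def h_floor(self) -> float:
        """Harvest floor for the demand curve, a tiny fraction of h0."""
        if self.h0_demand is None:
            raise DomainError("demand curve not calibrated")
        return PRICE_FLOOR_FRACTION * self.h0_demand


# ---------------------------------------------------------------------------
# Component functions
# ---------------------------------------------------------------------------

def surplus_production(b: float, params: ModelParams) -> float:
    """Annual surplus production of the stock at biomass b (tonnes/yr)."""
    if b <= 0:
        return 0.0
    return (
        (params.phi + 1.0)
        / params.phi
        * params.g
        * b
        * (1.0 - (b / params.k) ** params.phi)
    )


def surplus_production_step(b_t: float, params: ModelParams, h_t: float) -> float:
    """One-year biomass update, floored at zero under overharvest."""
    if b_t < 0 or h_t < 0:
        raise DomainError("biomass and harvest must be >= 0")
    return max(0.0, b_t + surplus_production(b_t, params) - h_t)


def fleet_harvest(q: float, b: float, e: float) -> float:
    """Harvest of one fleet: catchability x biomass x effort."""
    return q * b * e


def total_harvest(harvests: Sequence[float]) -> float:
    return float(sum(harvests))


def price_from_harvest(h_t: float, params: ModelParams) -> float:
    """Price from total harvest on the isoelastic demand curve through the
    base point: p = p0 * (h / h0)^(1/epsilon), decreasing in h for
    epsilon < 0 and returning exactly p0 at the base-year harvest.

    Evaluated at a small harvest floor when h_t is at or below it, to avoid
    the singularity of h^(1/epsilon) at zero; the substitution is logged.
    """
    if params.h0_demand is None:
        raise DomainError("demand curve not calibrated")
    floor = params.h_floor
    if h_t <= floor:
        logger.warning(
            "total harvest %.3g at or below pricing floor %.3g; pricing at floor",
            h_t,
            floor,
        )
        h_t = floor
    return params.p0 * (h_t / params.h0_demand) ** (1.0 / params.epsilon)


def fleet_cost(alpha: float, e: float, beta: float) -> float:
    """Fishing cost of one fleet, alpha * e^beta."""
    return alpha * e**beta


def fleet_profit(p: float, h: float, c: float, s: float, e: float) -> float:
    """Profit: revenue (p*h) less costs plus subsidies (s*e)."""
    return p * h - c + s * e


def update_effort(e: float, profit: float, speed: float) -> float:
    """Next-year effort: e + speed * profit, floored at zero."""
    if e < 0:
        raise DomainError("effort must be >= 0")
    return max(0.0, speed * profit + e)


# ---------------------------------------------------------------------------
# Trajectories
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FleetState:
    """One fleet's state in one year."""

    effort: float
    harvest: float
    cost: float
    profit: float
    subsidy_rate: float

    def __post_init__(self) -> None:
        if self.effort < 0 or self.harvest < 0:
            raise DomainError("effort and harvest must be >= 0")


@dataclass(frozen=True)
class Trajectory:
    """Annual states of the stock, market and fleets over the projection."""

    years: np.ndarray  # (T,)
    biomass: np.ndarray  # tonnes
    price: np.ndarray  # USD/tonne
    harvest: np.ndarray  # total, tonnes
    fishing_mortality: np.ndarray  # h_t / b_t, 1/yr
    fleet_states: Mapping[str, tuple[FleetState, ...]]  # label -> per-year

    def at_horizon(self) -> dict[str, float]:
        """Headline metrics in the final projected year."""
        i = -1
        revenue = float(
            self.price[i] * sum(fs[i].harvest for fs in self.fleet_states.values())
        )
        return {
            "biomass": float(self.biomass[i]),
            "catch": float(self.harvest[i]),
            "revenue": revenue,
            "fishing_mortality": float(self.fishing_mortality[i]),
        }

    def to_frame(self) -> pd.DataFrame:
        """Tidy long-format table: one row per (year, fleet, variable)."""
        rows = []
        for i, year in enumerate(self.years):
            for var, series in (
                ("biomass_t", self.biomass),
                ("price_usd_per_t", self.price),
                ("harvest_t", self.harvest),
                ("fishing_mortality", self.fishing_mortality),
            ):
                rows.append((int(year), "global", var, float(series[i])))
            for label, states in self.fleet_states.items():
                st = states[i]
                rows.append((int(year), label, "effort_kwh", st.effort))
                rows.append((int(year), label, "harvest_t", st.harvest))
                rows.append((int(year), label, "cost_usd", st.cost))
                rows.append((int(year), label, "profit_usd", st.profit))
                rows.append((int(year), label, "subsidy_rate_usd_per_kwh", st.subsidy_rate))
        return pd.DataFrame(rows, columns=["year", "fleet", "variable", "value"])


@dataclass(frozen=True)
class ScenarioResult:
    """Percent changes of a reform run versus BAU at the horizon year.

    A metric whose BAU value is zero has no defined percent change and is
    reported as None.
    """

    biomass_pct: float | None
    catch_pct: float | None
    revenue_pct: float | None
    fishing_mortality_pct: float | None

    def as_dict(self) -> dict[str, float | None]:
        return {
            "biomass_pct": self.biomass_pct,
            "catch_pct": self.catch_pct,
            "revenue_pct": self.revenue_pct,
            "fishing_mortality_pct": self.fishing_mortality_pct,
        }


def run_projection(
    fleets: Mapping[str, Fleet] | Sequence[Fleet],
    params: ModelParams,
    scenario: Scenario = "BAU",
) -> Trajectory:
    """Project the four-fleet system from the base year to the horizon.

    All fleets start at their base-year efforts.  Under ``"reform"`` the
    affected fleets (M-A, OA-A) fish at their post-removal subsidy rate
    ``s_reformed`` for the whole projection while the unaffected fleets keep
    ``s0``; under ``"BAU"`` every fleet keeps ``s0``.  Empty fleets are
    carried with zero effort.

    When a year's total harvest would exceed the biomass available plus the
    year's surplus production, fleet harvests are scaled down proportionally
    to that bound before the biomass update (the floor at zero then never
    engages except at exact depletion).
    """
    if isinstance(fleets, Mapping):
        fleet_list = list(fleets.values())
    else:
        fleet_list = list(fleets)
    labels = [f.label for f in fleet_list]
    if len(set(labels)) != len(labels):
        raise DomainError("duplicate fleet labels")
    if scenario not in ("BAU", "reform"):
        raise DomainError(f"unknown scenario {scenario!r}")

    if params.h0_demand is None:
        h0 = sum(f.h0 for f in fleet_list)
        params = params.with_demand_calibrated(h0)

    n = params.n_years
    years = np.arange(params.base_year, params.horizon_year + 1)
    biomass = np.empty(n)
    price = np.empty(n)
    harvest_tot = np.empty(n)
    fmort = np.empty(n)
    states: dict[str, list[FleetState]] = {lab: [] for lab in labels}

    srate = {}
    for f in fleet_list:
        if scenario == "reform" and f.is_affected and f.s_reformed is not None:
            srate[f.label] = f.s_reformed
        else:
            srate[f.label] = f.s0

    b = params.b0
    effort = {f.label: f.e0 for f in fleet_list}

    for i in range(n):
        h_by_fleet = {
            f.label: fleet_harvest(f.q, b, effort[f.label]) for f in fleet_list
        }
        h_t = total_harvest(list(h_by_fleet.values()))
        available = b + surplus_production(b, params)
        if h_t > available > 0:
            scale = available / h_t
            h_by_fleet = {lab: h * scale for lab, h in h_by_fleet.items()}
            h_t = available
        elif available <= 0:
            h_by_fleet = {lab: 0.0 for lab in h_by_fleet}
            h_t = 0.0

        p_t = price_from_harvest(h_t, params)

        profits = {}
        for f in fleet_list:
            c = fleet_cost(f.alpha, effort[f.label], params.beta)
            pi = fleet_profit(p_t, h_by_fleet[f.label], c, srate[f.label], effort[f.label])
            profits[f.label] = pi
            states[f.label].append(
                FleetState(
                    effort=effort[f.label],
                    harvest=h_by_fleet[f.label],
                    cost=c,
                    profit=pi,
                    subsidy_rate=srate[f.label],
                )
            )

        biomass[i] = b
        price[i] = p_t
        harvest_tot[i] = h_t
        fmort[i] = h_t / b if b > 0 else 0.0

        if not (math.isfinite(b) and math.isfinite(p_t) and math.isfinite(h_t)):
            raise SimulationError(
                "non-finite state encountered",
                state={
                    "year": int(years[i]),
                    "biomass": b,
                    "price": p_t,
                    "harvest": h_t,
                    "effort": dict(effort),
                    "profit": profits,
                },
            )

        if i < n - 1:
            b = surplus_production_step(b, params, h_t)
            for f in fleet_list:
                speed = params.eta if f.is_open_access else params.omega
                if f.is_empty:
                    continue  # inert fleet: no vessels, no entry
                effort[f.label] = update_effort(effort[f.label], profits[f.label], speed)

    return Trajectory(
        years=years,
        biomass=biomass,
        price=price,
        harvest=harvest_tot,
        fishing_mortality=fmort,
        fleet_states={lab: tuple(sts) for lab, sts in states.items()},
    )


def compare_scenarios(bau: Trajectory, reform: Trajectory) -> ScenarioResult:
    """Percent change of reform vs BAU at the horizon year for the four
    headline metrics (biomass, catch, revenue, fishing mortality)."""
    if bau.years[-1] != reform.years[-1] or len(bau.years) != len(reform.years):
        raise DomainError("trajectories cover different projection windows")
    b = bau.at_horizon()
    r = reform.at_horizon()
    out: dict[str, float | None] = {}
    for key in ("biomass", "catch", "revenue", "fishing_mortality"):
        if b[key] == 0:
            logger.warning("BAU %s is zero at horizon; percent change undefined", key)
            out[key] = None
        else:
            out[key] = 100.0 * (r[key] - b[key]) / b[key]
    return ScenarioResult(
        biomass_pct=out["biomass"],
        catch_pct=out["catch"],
        revenue_pct=out["revenue"],
        fishing_mortality_pct=out["fishing_mortality"],
    )
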