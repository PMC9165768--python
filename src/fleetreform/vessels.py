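"""Vessel database: records, effort-weighted economics allocation, tiers.

The vessel database holds one row per industrial fishing vessel with the
behavioural attributes that subsidy-reform disciplines test (IUU listing,
high-seas / distant-water activity, stock status of fished areas,
management score, flag-state development status).

Catches and landed values are allocated to vessels from per-(flag state,
FAO region) rates; subsidies from per-flag-state rates.  All rates are in
"per fishing kilowatt-hour" units (tonnes/kWh or USD/kWh): effort in kWh is
the common currency that makes vessels of different sizes and gear types
comparable.  Monetary amounts are 2018 USD throughout and are never
converted.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

from .errors import (
    DomainError,
    MissingRateError,
    UnknownSubsidyTypeError,
)

#: tolerance used for "fractions sum to at most 1" checks
_FRACTION_TOL = 1e-9

#: vessel CSV header version, written as a comment-free magic first column set
CSV_SCHEMA_VERSION = "1"

EFFORT_COLUMN_PREFIX = "effort_kwh__"
SUBSIDY_COLUMN_PREFIX = "subsidy_usd__"

DEVELOPMENT_STATUSES = ("developed", "developing", "LDC")

MANAGED = "managed"
OPEN_ACCESS = "open-access"


@dataclass
class VesselRecord:
    """One industrial fishing vessel and its base-year attributes.

    ``effort_by_region`` maps FAO major-area codes to fishing effort in kWh
    (fishing hours weighted by engine power).  ``stock_status`` is the
    effort-weighted mean B/B_MSY of the areas the vessel fished; values
    below 1 indicate predominantly overfished grounds.  ``management_score``
    in [0, 1] summarises the management effectiveness of those areas and
    drives the managed / open-access split.
    """

    vessel_id: str
    flag_state: str
    vessel_class: str
    length_m: float
    gross_tonnage: float
    engine_power_kw: float
    effort_by_region: dict[str, float]
    high_seas_fraction: float
    distant_water_fraction: float
    territorial_fraction: float
    disputed_area: bool
    iuu_listed: bool
    stock_status: float
    management_score: float
    development_status: str
    catch_t: float = 0.0
    revenue_usd: float = 0.0
    subsidies_by_type: dict[str, float] = field(default_factory=dict)
    management_tier: str | None = None

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if self.engine_power_kw <= 0:
            raise DomainError(
                f"vessel {self.vessel_id}: engine_power_kw must be > 0"
            )
        if self.length_m <= 0 or self.gross_tonnage <= 0:
            raise DomainError(
                f"vessel {self.vessel_id}: length_m and gross_tonnage must be > 0"
            )
        if any(e < 0 for e in self.effort_by_region.values()):
            raise DomainError(f"vessel {self.vessel_id}: negative regional effort")
        if self.total_effort_kwh <= 0:
            raise DomainError(f"vessel {self.vessel_id}: total effort must be > 0")
        zone_sum = (
            self.high_seas_fraction
            + self.distant_water_fraction
            + self.territorial_fraction
        )
        fractions = (
            self.high_seas_fraction,
            self.distant_water_fraction,
            self.territorial_fraction,
        )
        if any(f < 0 for f in fractions) or zone_sum > 1 + _FRACTION_TOL:
            raise DomainError(
                f"vessel {self.vessel_id}: zone-time fractions must be "
                f"non-negative and sum to <= 1 (got {zone_sum})"
            )
        if not 0 <= self.management_score <= 1:
            raise DomainError(
                f"vessel {self.vessel_id}: management_score must be in [0, 1]"
            )
        if self.stock_status < 0:
            raise DomainError(f"vessel {self.vessel_id}: stock_status must be >= 0")
        if self.development_status not in DEVELOPMENT_STATUSES:
            raise DomainError(
                f"vessel {self.vessel_id}: unknown development_status "
                f"{self.development_status!r}"
            )
        if self.catch_t < 0 or self.revenue_usd < 0:
            raise DomainError(f"vessel {self.vessel_id}: negative catch or revenue")
        if any(v < 0 for v in self.subsidies_by_type.values()):
            raise DomainError(f"vessel {self.vessel_id}: negative subsidy amount")

    @property
    def total_effort_kwh(self) -> float:
        return float(sum(self.effort_by_region.values()))

    @property
    def total_subsidies_usd(self) -> float:
        return float(sum(self.subsidies_by_type.values()))


@dataclass(frozen=True)
class SubsidyProgram:
    """One (flag state, subsidy type) row of a country subsidy table."""

    flag_state: str
    subsidy_type: str
    amount_usd: float
    capacity_enhancing: bool

    def __post_init__(self) -> None:
        if self.amount_usd < 0:
            raise DomainError(
                f"subsidy amount for ({self.flag_state}, {self.subsidy_type}) "
                "must be >= 0"
            )


@dataclass(frozen=True)
class AllocationRates:
    """Per-flag subsidy rates and per-(flag, region) catch / revenue rates."""

    subsidy_rate: Mapping[str, float]  # flag -> USD/kWh
    catch_rate: Mapping[tuple[str, str], float]  # (flag, region) -> t/kWh
    revenue_rate: Mapping[tuple[str, str], float]  # (flag, region) -> USD/kWh

    def __post_init__(self) -> None:
        for name, mapping in (
            ("subsidy_rate", self.subsidy_rate),
            ("catch_rate", self.catch_rate),
            ("revenue_rate", self.revenue_rate),
        ):
            if any(v < 0 for v in mapping.values()):
                raise DomainError(f"{name} contains a negative rate")


@dataclass(frozen=True)
class EffectiveSubsidyWeights:
    """Type-specific multipliers normalising subsidy dollars by their effect
    on fishing effort.

    A dollar of fuel subsidy does not change fishing behaviour the same way
    a dollar of, say, a vessel buyback does; the multipliers convert nominal
    amounts into "effective" dollars before they enter the bioeconomic
    model.  The shipped default is 1.0 for every type (nominal = effective).
    """

    multiplier: Mapping[str, float]
    default: float | None = None

    def __post_init__(self) -> None:
        if any(m < 0 for m in self.multiplier.values()):
            raise DomainError("effective-subsidy multipliers must be >= 0")
        if self.default is not None and self.default < 0:
            raise DomainError("default multiplier must be >= 0")

    def weight_for(self, subsidy_type: str) -> float:
        if subsidy_type in self.multiplier:
            return self.multiplier[subsidy_type]
        if self.default is not None:
            return self.default
        raise UnknownSubsidyTypeError(subsidy_type)

    @classmethod
    def unit(cls) -> "EffectiveSubsidyWeights":
        """Identity weights: every type counts at face value."""
        return cls(multiplier={}, default=1.0)


# ---------------------------------------------------------------------------
# Rate computation
# ---------------------------------------------------------------------------

def compute_flag_subsidy_rate(subsidy_total_usd: float, effort_total_kwh: float) -> float:
    """Subsidy rate (USD/kWh) of a flag state: total subsidies over total effort.

    E.g. $2M of subsidies spread over 15M kWh of effort gives a rate of
    about $0.133/kWh.
    """
    if effort_total_kwh <= 0:
        raise DomainError("effort_total_kwh must be > 0")
    if subsidy_total_usd < 0:
        raise DomainError("subsidy_total_usd must be >= 0")
    return subsidy_total_usd / effort_total_kwh


def compute_region_rates(
    catch_t: float, revenue_usd: float, effort_kwh: float
) -> tuple[float, float]:
    """Catch (t/kWh) and revenue (USD/kWh) rates for one (flag, region) cell."""
    if effort_kwh <= 0:
        raise DomainError("effort_kwh must be > 0")
    if catch_t < 0 or revenue_usd < 0:
        raise DomainError("catch and revenue must be >= 0")
    return catch_t / effort_kwh, revenue_usd / effort_kwh


def rates_from_totals(
    vessels: Sequence[VesselRecord],
    region_catch: Mapping[tuple[str, str], float],
    region_revenue: Mapping[tuple[str, str], float],
    country_subsidies: Iterable[SubsidyProgram],
) -> AllocationRates:
    """Derive allocation rates from observed (flag, region) totals and the
    fleet's effort, the inverse of :func:`allocate_vessel_economics`."""
    flag_effort: dict[str, float] = {}
    cell_effort: dict[tuple[str, str], float] = {}
    for v in vessels:
        flag_effort[v.flag_state] = flag_effort.get(v.flag_state, 0.0) + v.total_effort_kwh
        for region, e in v.effort_by_region.items():
            key = (v.flag_state, region)
            cell_effort[key] = cell_effort.get(key, 0.0) + e

    flag_subsidy: dict[str, float] = {}
    for prog in country_subsidies:
        flag_subsidy[prog.flag_state] = flag_subsidy.get(prog.flag_state, 0.0) + prog.amount_usd

    subsidy_rate = {
        flag: compute_flag_subsidy_rate(flag_subsidy.get(flag, 0.0), eff)
        for flag, eff in flag_effort.items()
    }
    catch_rate: dict[tuple[str, str], float] = {}
    revenue_rate: dict[tuple[str, str], float] = {}
    for key, eff in cell_effort.items():
        if eff <= 0:
            continue
        cr, rr = compute_region_rates(
            region_catch.get(key, 0.0), region_revenue.get(key, 0.0), eff
        )
        catch_rate[key] = cr
        revenue_rate[key] = rr
    return AllocationRates(subsidy_rate, catch_rate, revenue_rate)


# ---------------------------------------------------------------------------
# Allocation
# ---------------------------------------------------------------------------

def allocate_vessel_economics(
    vessels: Sequence[VesselRecord],
    rates: AllocationRates,
    country_subsidies: Iterable[SubsidyProgram],
) -> list[VesselRecord]:
    """Fill ``catch_t``, ``revenue_usd`` and ``subsidies_by_type`` on every
    vessel by effort-weighted allocation.

    Catch and revenue are regional: for each FAO region the vessel fished,
    its regional effort times the (flag, region) rate.  Subsidies are
    allocated by flag state only: each vessel receives its flag's per-type
    subsidy mix scaled by its share of the flag's total effort, so flag-level
    sums are conserved exactly.

    Returns new records; the inputs are not mutated.
    """
    flag_effort: dict[str, float] = {}
    for v in vessels:
        flag_effort[v.flag_state] = flag_effort.get(v.flag_state, 0.0) + v.total_effort_kwh

    flag_type_amounts: dict[str, dict[str, float]] = {}
    for prog in country_subsidies:
        by_type = flag_type_amounts.setdefault(prog.flag_state, {})
        by_type[prog.subsidy_type] = by_type.get(prog.subsidy_type, 0.0) + prog.amount_usd

    out: list[VesselRecord] = []
    for v in vessels:
        if v.flag_state not in rates.subsidy_rate:
            raise MissingRateError(v.flag_state)
        catch = 0.0
        revenue = 0.0
        for region, effort in v.effort_by_region.items():
            if effort == 0:
                continue
            key = (v.flag_state, region)
            if key not in rates.catch_rate or key not in rates.revenue_rate:
                raise MissingRateError(key)
            catch += rates.catch_rate[key] * effort
            revenue += rates.revenue_rate[key] * effort
        share = v.total_effort_kwh / flag_effort[v.flag_state]
        subsidies = {
            stype: amount * share
            for stype, amount in flag_type_amounts.get(v.flag_state, {}).items()
        }
        out.append(
            replace(v, catch_t=catch, revenue_usd=revenue, subsidies_by_type=subsidies)
        )
    return out


def apply_effective_subsidy_weights(
    subsidies_by_type: Mapping[str, float], weights: EffectiveSubsidyWeights
) -> float:
    """Total effective subsidy dollars: sum of amount x type multiplier."""
    return float(
        sum(amount * weights.weight_for(stype) for stype, amount in subsidies_by_type.items())
    )


# ---------------------------------------------------------------------------
# Management tier
# ---------------------------------------------------------------------------

def management_score_cut(scores: Sequence[float], quantile_threshold: float = 0.5) -> float:
    """Empirical quantile of management scores used as the managed cut point.

    Uses the ``higher`` order-statistic convention so that at the default
    median threshold an even-sized fleet splits exactly in half, with the
    upper half managed.
    """
    if len(scores) == 0:
        raise DomainError("cannot compute a quantile of an empty vessel set")
    if not 0 < quantile_threshold < 1:
        raise DomainError("quantile_threshold must be in (0, 1)")
    return float(np.quantile(np.asarray(scores, dtype=float), quantile_threshold, method="higher"))


def assign_management_tier(
    vessels: Sequence[VesselRecord], quantile_threshold: float = 0.5
) -> list[VesselRecord]:
    """Label each vessel managed / open-access by its management score.

    Vessels scoring at or above the empirical quantile of all scores at
    ``quantile_threshold`` are managed; ties at the cut go to managed.
    """
    cut = management_score_cut([v.management_score for v in vessels], quantile_threshold)
    return [
        replace(v, management_tier=MANAGED if v.management_score >= cut else OPEN_ACCESS)
        for v in vessels
    ]


# ---------------------------------------------------------------------------
# CSV round trip
# ---------------------------------------------------------------------------

_FIXED_COLUMNS = [
    "schema_version",
    "vessel_id",
    "flag_state",
    "vessel_class",
    "length_m",
    "gross_tonnage",
    "engine_power_kw",
    "high_seas_fraction",
    "distant_water_fraction",
    "territorial_fraction",
    "disputed_area",
    "iuu_listed",
    "stock_status",
    "management_score",
    "development_status",
    "catch_t",
    "revenue_usd",
    "management_tier",
]


def write_vessel_csv(vessels: Sequence[VesselRecord], path: str | Path) -> None:
    """Write the vessel database as UTF-8 CSV, one row per vessel.

    Regional efforts become ``effort_kwh__<FAO-code>`` columns and allocated
    subsidies ``subsidy_usd__<type>`` columns; the column sets are the unions
    over all vessels, zero-filled.
    """
    regions = sorted({r for v in vessels for r in v.effort_by_region})
    stypes = sorted({s for v in vessels for s in v.subsidies_by_type})
    header = (
        _FIXED_COLUMNS
        + [EFFORT_COLUMN_PREFIX + r for r in regions]
        + [SUBSIDY_COLUMN_PREFIX + s for s in stypes]
    )
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(header)
        for v in vessels:
            row = [
                CSV_SCHEMA_VERSION,
                v.vessel_id,
                v.flag_state,
                v.vessel_class,
                repr(v.length_m),
                repr(v.gross_tonnage),
                repr(v.engine_power_kw),
                repr(v.high_seas_fraction),
                repr(v.distant_water_fraction),
                repr(v.territorial_fraction),
                int(v.disputed_area),
                int(v.iuu_listed),
                repr(v.stock_status),
                repr(v.management_score),
                v.development_status,
                repr(v.catch_t),
                repr(v.revenue_usd),
                v.management_tier or "",
            ]
            row += [repr(v.effort_by_region.get(r, 0.0)) for r in regions]
            row += [repr(v.subsidies_by_type.get(s, 0.0)) for s in stypes]
            writer.writerow(row)


def read_vessel_csv(path: str | Path) -> list[VesselRecord]:
    """Read a vessel database written by :func:`write_vessel_csv`."""
    vessels: list[VesselRecord] = []
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None:
            return vessels
        effort_cols = [c for c in reader.fieldnames if c.startswith(EFFORT_COLUMN_PREFIX)]
        subsidy_cols = [c for c in reader.fieldnames if c.startswith(SUBSIDY_COLUMN_PREFIX)]
        for row in reader:
            if row["schema_version"] != CSV_SCHEMA_VERSION:
                raise DomainError(
                    f"unsupported vessel CSV schema version {row['schema_version']!r}"
                )
            effort = {
                c[len(EFFORT_COLUMN_PREFIX):]: float(row[c])
                for c in effort_cols
                if float(row[c]) > 0
            }
            subsidies = {
                c[len(SUBSIDY_COLUMN_PREFIX):]: float(row[c])
                for c in subsidy_cols
                if float(row[c]) != 0
            }
            vessels.append(
                VesselRecord(
                    vessel_id=row["vessel_id"],
                    flag_state=row["flag_state"],
                    vessel_class=row["vessel_class"],
                    length_m=float(row["length_m"]),
                    gross_tonnage=float(row["gross_tonnage"]),
                    engine_power_kw=float(row["engine_power_kw"]),
                    effort_by_region=effort,
                    high_seas_fraction=float(row["high_seas_fraction"]),
                    distant_water_fraction=float(row["distant_water_fraction"]),
                    territorial_fraction=float(row["territorial_fraction"]),
                    disputed_area=bool(int(row["disputed_area"])),
                    iuu_listed=bool(int(row["iuu_listed"])),
                    stock_status=float(row["stock_status"]),
                    management_score=float(row["management_score"]),
                    development_status=row["development_status"],
                    catch_t=float(row["catch_t"]),
                    revenue_usd=float(row["revenue_usd"]),
                    subsidies_by_type=subsidies,
                    management_tier=row["management_tier"] or None,
                )
            )
    return vessels


def write_subsidy_csv(programs: Sequence[SubsidyProgram], path: str | Path) -> None:
    """Write a country subsidy table as CSV."""
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(["flag_state", "subsidy_type", "amount_usd", "capacity_enhancing"])
        for p in programs:
            writer.writerow([p.flag_state, p.subsidy_type, repr(p.amount_usd), int(p.capacity_enhancing)])


def read_subsidy_csv(path: str | Path) -> list[SubsidyProgram]:
    """Read a country subsidy table written by :func:`write_subsidy_csv`."""
    out: list[SubsidyProgram] = []
    with open(path, newline="", encoding="utf-8") as fh:
        for row in csv.DictReader(fh):
            out.append(
                SubsidyProgram(
                    flag_state=row["flag_state"],
                    subsidy_type=row["subsidy_type"],
                    amount_usd=float(row["amount_usd"]),
                    capacity_enhancing=bool(int(row["capacity_enhancing"])),
                )
            )
    return out
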