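"""Synthetic vessel databases, subsidy tables, and worked fixtures.

Real analyses of subsidy reform start from a satellite-derived (AIS)
database of tens of thousands of industrial vessels plus national landings,
price and subsidy datasets.  None of those ship with this package; instead
this module generates inputs with the same *structure* — one row per vessel
with effort by FAO region, zone-time fractions, IUU flags, stock status,
management scores and development status, plus a country-by-type subsidy
table — at a scale of a few hundred "vessels", each standing for a slice of
a real fleet.  Distributions are chosen for structural realism only; no
attempt is made to match the real datasets statistically.

Categorical attributes (IUU listing, designated high-seas vessels,
disputed-area activity) are assigned by deterministic quota — shuffle, then
flag the first round(n * fraction) vessels — rather than independent draws,
so fixture counts are exact and tests can assert them.  All randomness
flows from one ``numpy`` Generator seeded from the config; equal configs
give byte-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .errors import ConfigurationError
from .policy import (
    Discipline,
    DisciplineCategory,
    Predicate,
    PredicateKind,
    Proposal,
    RemovalScope,
)
from .vessels import (
    DEVELOPMENT_STATUSES,
    MANAGED,
    OPEN_ACCESS,
    SubsidyProgram,
    VesselRecord,
)

#: subsidy types of the default synthetic world and whether each is
#: capacity-enhancing (artificially lowers costs / raises revenues)
DEFAULT_SUBSIDY_TYPES: dict[str, bool] = {
    "fuel": True,
    "vessel_construction": True,
    "access": True,
    "buyback": True,
    "management": False,
}

#: default shares of national subsidy budgets by type (sums to 1)
DEFAULT_SUBSIDY_TYPE_SHARES: dict[str, float] = {
    "fuel": 0.35,
    "vessel_construction": 0.20,
    "access": 0.10,
    "buyback": 0.05,
    "management": 0.30,
}

_VESSEL_CLASSES = ("trawler", "purse_seine", "longliner", "squid_jigger")


@dataclass(frozen=True)
class HighSeasMixture:
    """Mixture for the fraction of time a vessel fishes on the high seas:
    a point mass at 0 (coastal vessels), a mass near 1 (dedicated high-seas
    vessels, forced to >= 0.95), and a uniform body in between."""

    mass_at_zero: float = 0.85
    mass_near_one: float = 0.03
    body_low: float = 0.0
    body_high: float = 0.30

    def __post_init__(self) -> None:
        if not 0 <= self.mass_at_zero <= 1 or not 0 <= self.mass_near_one <= 1:
            raise ConfigurationError("high_seas_fraction_dist", "masses must be in [0, 1]")
        if self.mass_at_zero + self.mass_near_one > 1 + 1e-9:
            raise ConfigurationError("high_seas_fraction_dist", "masses sum to > 1")
        if not 0 <= self.body_low <= self.body_high <= 1:
            raise ConfigurationError("high_seas_fraction_dist", "invalid uniform body bounds")


@dataclass(frozen=True)
class SyntheticConfig:
    """Parameters of the synthetic world.

    Defaults sketch a downscaled global industrial fishery: ~200 aggregated
    vessels, ~8e10 kWh of effort, catch rates around 1e-3 t/kWh so total
    catch is of order 1e8 tonnes, ex-vessel prices near $1,400/t, and
    subsidy intensities of $0.3-0.6 per kWh (roughly a quarter of landed
    value, with ~70% of subsidy dollars in capacity-enhancing types).
    """

    n_vessels: int = 200
    n_flag_states: int = 8
    n_fao_regions: int = 5
    iuu_fraction: float = 0.02
    disputed_fraction: float = 0.05
    high_seas_fraction_dist: HighSeasMixture = field(default_factory=HighSeasMixture)
    management_score_alpha: float = 2.0  # Beta(alpha, beta) on [0, 1]
    management_score_beta: float = 2.0
    stock_status_sigma: float = 0.3  # lognormal around B/B_MSY = 1
    subsidy_type_shares: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_SUBSIDY_TYPE_SHARES)
    )
    effort_median_kwh: float = 2.5e8  # lognormal median per vessel
    effort_sigma: float = 1.0
    catch_rate_range: tuple[float, float] = (0.8e-3, 1.6e-3)  # t/kWh
    price_usd_per_t: float = 1400.0
    subsidy_rate_range: tuple[float, float] = (0.3, 0.6)  # USD/kWh by flag
    development_status_shares: Mapping[str, float] = field(
        default_factory=lambda: {"developed": 0.4, "developing": 0.4, "LDC": 0.2}
    )
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_vessels < 0:
            raise ConfigurationError("n_vessels", "must be >= 0")
        if self.n_flag_states <= 0:
            raise ConfigurationError("n_flag_states", "must be > 0")
        if self.n_fao_regions <= 0:
            raise ConfigurationError("n_fao_regions", "must be > 0")
        for name in ("iuu_fraction", "disputed_fraction"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ConfigurationError(name, "must be in [0, 1]")
        if abs(sum(self.subsidy_type_shares.values()) - 1.0) > 1e-9:
            raise ConfigurationError("subsidy_type_shares", "must sum to 1")
        if any(s < 0 for s in self.subsidy_type_shares.values()):
            raise ConfigurationError("subsidy_type_shares", "shares must be >= 0")
        if self.effort_median_kwh <= 0:
            raise ConfigurationError("effort_median_kwh", "must be > 0")
        if not 0 < self.catch_rate_range[0] <= self.catch_rate_range[1]:
            raise ConfigurationError("catch_rate_range", "must be a positive interval")
        if self.price_usd_per_t <= 0:
            raise ConfigurationError("price_usd_per_t", "must be > 0")
        if set(self.development_status_shares) - set(DEVELOPMENT_STATUSES):
            raise ConfigurationError("development_status_shares", "unknown status")
        if abs(sum(self.development_status_shares.values()) - 1.0) > 1e-9:
            raise ConfigurationError("development_status_shares", "must sum to 1")
        if self.management_score_alpha <= 0 or self.management_score_beta <= 0:
            raise ConfigurationError("management_score_alpha", "Beta parameters must be > 0")

    @property
    def flag_states(self) -> tuple[str, ...]:
        return tuple(f"C{i:02d}" for i in range(self.n_flag_states))

    @property
    def fao_regions(self) -> tuple[str, ...]:
        # numbered like FAO major fishing areas (two-digit codes)
        return tuple(f"{21 + 6 * i}" for i in range(self.n_fao_regions))


def _quota_flags(rng: np.random.Generator, n: int, fraction: float) -> np.ndarray:
    """Boolean mask with exactly round(n * fraction) True entries, placed at
    uniformly random positions (deterministic given the generator state)."""
    k = int(round(n * fraction))
    mask = np.zeros(n, dtype=bool)
    if k > 0:
        mask[rng.permutation(n)[:k]] = True
    return mask


def generate_vessel_database(cfg: SyntheticConfig) -> list[VesselRecord]:
    """Generate ``cfg.n_vessels`` vessel records.

    Economic fields (catch, revenue, subsidies) are left unallocated; run
    the allocator with the rates from :func:`generate_world` to fill them.
    """
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_vessels
    if n == 0:
        return []

    flags = np.array(cfg.flag_states)[rng.integers(0, cfg.n_flag_states, size=n)]
    classes = np.array(_VESSEL_CLASSES)[rng.integers(0, len(_VESSEL_CLASSES), size=n)]
    power = rng.lognormal(mean=np.log(1500.0), sigma=0.6, size=n)  # kW
    length = 15.0 + power**0.5  # crude allometry, m
    tonnage = 0.15 * length**2.2  # gt

    iuu = _quota_flags(rng, n, cfg.iuu_fraction)
    disputed = _quota_flags(rng, n, cfg.disputed_fraction)

    hs_dist = cfg.high_seas_fraction_dist
    dedicated_hs = _quota_flags(rng, n, hs_dist.mass_near_one)
    at_zero = _quota_flags(rng, n, hs_dist.mass_at_zero / max(1e-12, 1 - hs_dist.mass_near_one))
    hs = rng.uniform(hs_dist.body_low, hs_dist.body_high, size=n)
    hs[at_zero & ~dedicated_hs] = 0.0
    hs[dedicated_hs] = rng.uniform(0.95, 1.0, size=int(dedicated_hs.sum()))
    # split the remainder of each vessel's year between distant water and
    # territorial fishing
    dw_share = rng.uniform(0.0, 1.0, size=n)
    dw = (1.0 - hs) * dw_share
    terr = (1.0 - hs) * (1.0 - dw_share)

    scores = rng.beta(cfg.management_score_alpha, cfg.management_score_beta, size=n)
    status = np.exp(rng.normal(0.0, cfg.stock_status_sigma, size=n))

    dev_by_flag: dict[str, str] = {}
    statuses, shares = zip(*sorted(cfg.development_status_shares.items()))
    cum = np.cumsum(shares)
    for i, flag in enumerate(cfg.flag_states):
        u = (i + 0.5) / cfg.n_flag_states  # deterministic stratified assignment
        dev_by_flag[flag] = statuses[int(np.searchsorted(cum, u))]

    efforts = rng.lognormal(np.log(cfg.effort_median_kwh), cfg.effort_sigma, size=n)
    regions = cfg.fao_regions
    vessels: list[VesselRecord] = []
    for i in range(n):
        n_regions = int(rng.integers(1, min(3, len(regions)) + 1))
        picked = rng.choice(len(regions), size=n_regions, replace=False)
        region_shares = rng.dirichlet(np.ones(n_regions))
        effort_by_region = {
            regions[int(r)]: float(efforts[i] * s)
            for r, s in zip(picked, region_shares)
        }
        vessels.append(
            VesselRecord(
                vessel_id=f"V{i:05d}",
                flag_state=str(flags[i]),
                vessel_class=str(classes[i]),
                length_m=float(length[i]),
                gross_tonnage=float(tonnage[i]),
                engine_power_kw=float(power[i]),
                effort_by_region=effort_by_region,
                high_seas_fraction=float(hs[i]),
                distant_water_fraction=float(dw[i]),
                territorial_fraction=float(terr[i]),
                disputed_area=bool(disputed[i]),
                iuu_listed=bool(iuu[i]),
                stock_status=float(status[i]),
                management_score=float(scores[i]),
                development_status=dev_by_flag[str(flags[i])],
            )
        )
    return vessels


def generate_country_subsidy_table(
    cfg: SyntheticConfig, vessels: Sequence[VesselRecord] | None = None
) -> list[SubsidyProgram]:
    """One subsidy program per (flag state, subsidy type).

    National budgets scale with each flag's fishing effort (at a per-kWh
    intensity drawn from ``cfg.subsidy_rate_range``) when vessels are
    given, and are split across types by ``cfg.subsidy_type_shares`` with
    Dirichlet jitter.  Flags with no vessels get effort-free budgets from
    the median effort so every flag state is present.
    """
    rng = np.random.default_rng(cfg.seed + 1)  # separate stream from vessels
    flag_effort = {flag: 0.0 for flag in cfg.flag_states}
    if vessels:
        for v in vessels:
            flag_effort[v.flag_state] = flag_effort.get(v.flag_state, 0.0) + v.total_effort_kwh
    fallback = cfg.effort_median_kwh * max(1, cfg.n_vessels) / max(1, cfg.n_flag_states)

    types, shares = zip(*sorted(cfg.subsidy_type_shares.items()))
    programs: list[SubsidyProgram] = []
    for flag in cfg.flag_states:
        effort = flag_effort.get(flag, 0.0) or fallback
        intensity = rng.uniform(*cfg.subsidy_rate_range)
        total = effort * intensity
        jitter = rng.dirichlet(np.asarray(shares) * 50.0 + 1e-9)
        for t, share in zip(types, jitter):
            programs.append(
                SubsidyProgram(
                    flag_state=flag,
                    subsidy_type=t,
                    amount_usd=float(total * share),
                    capacity_enhancing=DEFAULT_SUBSIDY_TYPES.get(t, True),
                )
            )
    return programs


@dataclass(frozen=True)
class SyntheticWorld:
    """A complete, self-consistent synthetic input set."""

    vessels: list[VesselRecord]
    subsidy_programs: list[SubsidyProgram]
    region_catch_t: dict[tuple[str, str], float]  # (flag, region) -> tonnes
    region_revenue_usd: dict[tuple[str, str], float]


def generate_world(cfg: SyntheticConfig) -> SyntheticWorld:
    """Vessels, subsidy table and per-(flag, region) catch/revenue totals.

    Regional totals are built from per-cell catch rates drawn in
    ``cfg.catch_rate_range`` and regional price levels within +/-20% of
    ``cfg.price_usd_per_t``, so that the allocator's derived rates land in
    a realistic band by construction.
    """
    vessels = generate_vessel_database(cfg)
    programs = generate_country_subsidy_table(cfg, vessels)
    rng = np.random.default_rng(cfg.seed + 2)

    cell_effort: dict[tuple[str, str], float] = {}
    for v in vessels:
        for region, e in v.effort_by_region.items():
            key = (v.flag_state, region)
            cell_effort[key] = cell_effort.get(key, 0.0) + e

    region_catch: dict[tuple[str, str], float] = {}
    region_revenue: dict[tuple[str, str], float] = {}
    for key in sorted(cell_effort):
        rate = rng.uniform(*cfg.catch_rate_range)
        price = cfg.price_usd_per_t * rng.uniform(0.8, 1.2)
        catch = cell_effort[key] * rate
        region_catch[key] = catch
        region_revenue[key] = catch * price
    return SyntheticWorld(vessels, programs, region_catch, region_revenue)


# ---------------------------------------------------------------------------
# The ten-vessel worked example
# ---------------------------------------------------------------------------

def worked_example_fixture() -> tuple[list[VesselRecord], Proposal]:
    """The ten-vessel illustrative fleet and its IUU discipline.

    Ten vessels: five managed, five open-access, with equal total subsidies
    in the two groups ($1.0M each).  One managed and two open-access
    vessels are IUU-listed, so the IUU discipline partitions the fleet into
    M-U = 4, M-A = 1, OA-U = 3 and OA-A = 2 vessels.  (The count of two
    OA-A vessels follows from the stated criteria; see the methods note for
    the discrepancy in the original narration of this example.)

    Vessels come pre-allocated (catch, revenue, subsidies filled) so the
    fixture can be fed straight to the fleet partition and projection.
    """
    # (id, tier, score, iuu, effort kWh, catch t, fuel USD, management USD)
    rows = [
        ("WE01", MANAGED, 0.90, False, 3.0e6, 300.0, 240_000.0, 60_000.0),
        ("WE02", MANAGED, 0.85, False, 2.5e6, 250.0, 200_000.0, 50_000.0),
        ("WE03", MANAGED, 0.80, False, 2.0e6, 200.0, 160_000.0, 40_000.0),
        ("WE04", MANAGED, 0.75, False, 1.5e6, 150.0, 120_000.0, 30_000.0),
        ("WE05", MANAGED, 0.70, True, 1.0e6, 100.0, 80_000.0, 20_000.0),
        ("WE06", OPEN_ACCESS, 0.40, False, 3.5e6, 350.0, 280_000.0, 70_000.0),
        ("WE07", OPEN_ACCESS, 0.35, False, 2.5e6, 250.0, 200_000.0, 50_000.0),
        ("WE08", OPEN_ACCESS, 0.30, False, 2.0e6, 200.0, 160_000.0, 40_000.0),
        ("WE09", OPEN_ACCESS, 0.25, True, 1.2e6, 120.0, 96_000.0, 24_000.0),
        ("WE10", OPEN_ACCESS, 0.20, True, 0.8e6, 80.0, 64_000.0, 16_000.0),
    ]
    price_per_t = 1000.0  # flat ex-vessel price for the example
    vessels = [
        VesselRecord(
            vessel_id=vid,
            flag_state="EX",
            vessel_class="trawler",
            length_m=40.0,
            gross_tonnage=400.0,
            engine_power_kw=1000.0,
            effort_by_region={"21": effort},
            high_seas_fraction=0.0,
            distant_water_fraction=0.0,
            territorial_fraction=1.0,
            disputed_area=False,
            iuu_listed=iuu,
            stock_status=1.0,
            management_score=score,
            development_status="developed",
            catch_t=catch,
            revenue_usd=catch * price_per_t,
            subsidies_by_type={"fuel": fuel, "management": mgmt},
            management_tier=tier,
        )
        for vid, tier, score, iuu, effort, catch, fuel, mgmt in rows
    ]
    proposal = Proposal(
        name="IUU prohibition (worked example)",
        disciplines=(
            Discipline(
                category=DisciplineCategory.IUU,
                predicate=Predicate(PredicateKind.IUU_LISTED),
                removal_scope=RemovalScope(all_capacity_enhancing=True),
                name="IUU-listed vessels lose all capacity-enhancing subsidies",
            ),
        ),
    )
    return vessels, proposal
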