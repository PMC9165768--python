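# Methods

## Scope and model structure

`fleetreform` models all global marine fisheries as one aggregate stock
exploited by four fleets, formed by crossing management regime (managed
*M* vs open-access *OA*) with exposure to a subsidy-reform proposal
(affected *A* vs unaffected *U*). This deliberately coarse structure is
what makes reform comparisons transparent: a proposal changes only *which
vessels* fall into the affected fleets and *how much* subsidy those fleets
lose, while the biology and market are held fixed across scenarios. The
model is not suitable for analysing individual fisheries or predicting
market outcomes; its purpose is the *difference* between a reform
trajectory and business as usual, not the levels.

### Biomass

The stock follows discrete-time Pella–Tomlinson surplus production:

    b_{t+1} = b_t + ((φ+1)/φ) · g · b_t · (1 − (b_t/K)^φ) − h_t

`φ` controls the asymmetry of the production curve: surplus peaks at
b\* = K(φ+1)^{−1/φ}, which is K/2 for φ = 1 (logistic) and ≈ 0.4 K for the
default φ = 0.188. The growth rate is tied to maximum sustainable yield by
g = (MSY/K)(φ+1)^{1/φ}, so the surplus maximum equals MSY exactly (this
identity is verified numerically in the tests against a grid-plus-refinement
maximiser). Biomass is floored at zero; in addition, if a year's aggregate
harvest would exceed the biomass available plus that year's surplus, fleet
harvests are scaled down proportionally to that bound first, so the floor
only engages at exact depletion and fleet shares are preserved. Whether the
within-year harvest should be capped this way or only floored is not
determined by the model statement; we cap, because it keeps fleet
composition meaningful under extreme parameterisations.

### Harvest, demand, costs, profit

Fleet harvest is h_{j,t} = q_j b_t e_{j,t} with time-invariant catchability
q_j = h_{j,0}/(b_0 e_{j,0}); all fleets share the global b_t, so fleets
differ only through their base-year harvest and effort. Price responds to
total harvest through a constant-elasticity demand curve anchored at the
base year:

    p_t = p_0 · (h_t / h_0)^{1/ε},   ε < 0

Note on the demand constant: the conventional parameterisation writes
demand as h = δ p^ε and prices as p = (h/δ)^{1/ε} with δ = h_0 p_0^{−ε}.
The package exposes `calibrate_demand_constant` returning δ = h_0 p_0^{ε}
(the form some presentations print); combining *that* constant with the
(1/δ)^{1/ε} h^{1/ε} price expression would return 1/p_0 at the base
harvest, which contradicts the defining property of a demand curve
calibrated through the base point. We therefore evaluate prices through the
base-point form above, which is algebraically identical to the conventional
pair and satisfies p(h_0) = p_0 exactly; δ is carried as an audit value in
the calibration summary. Because 1/ε < 0, price rises as harvest falls —
this is one of the two channels (with biomass recovery) that lets
unaffected fleets profit from a reform they are not subject to.

Prices are evaluated at max(h_t, 10⁻⁶ h_0) to avoid the singularity at
zero harvest; the substitution is a numerical guard only and is logged.

Costs are c_{j,t} = α_j e_{j,t}^β with β ≥ 1 (convex effort costs), and
profit is π_{j,t} = p_t h_{j,t} − c_{j,t} + s_{j,t} e_{j,t}, where s_{j,t}
is the fleet's effective subsidy rate in USD/kWh. The cost coefficient is
calibrated under the open-access equilibrium assumption that base-year
profits are zero *inclusive of subsidies*:

    α_j = (p_0 h_{j,0} + s_{j,0} e_{j,0}) / e_{j,0}^β

so subsidies enter as artificially lowered costs. Base-year profit is then
zero by construction for every fleet (verified to 1e-9 relative in tests).

### Effort dynamics and scenarios

Effort follows profit: e_{j,t+1} = max(0, e_{j,t} + speed · π_{j,t}), with
speed η for open-access fleets and ω for managed fleets, ω ≪ η. Managed
fleets are sticky by assumption — quota systems, licensing and capital
commitments damp their response — so equal losses shrink an open-access
fleet's effort faster.

All four fleets start at base-year efforts. Under BAU every fleet keeps
its base-year subsidy rate forever; under reform the affected fleets fish
at their post-removal rate s_reformed (time-invariant) for the whole
projection while unaffected fleets keep s_0. The within-year update order
is: harvest → price → costs/profits → biomass → effort; the biomass update
uses the current year's harvest and the effort update the current year's
profit. Scenario results are percent changes vs BAU at the horizon for
biomass, catch, revenue (p_t Σ_j h_{j,t}) and fishing mortality, with
F_t ≡ h_t/b_t (equivalently Σ_j q_j e_{j,t}); the model statement reports
fishing mortality without defining it, and this is the natural definition
under the harvest equation. Empty fleets carry zero effort and are inert.

## Policy engine

A discipline is a predicate over vessel attributes plus a removal scope.
Threshold conventions follow the negotiating language: "at least X% of
time" is ≥, "stock status below Y" is strict <. Scopes are either *all
capacity-enhancing types* (used for IUU and overfished-stock disciplines)
or a *listed set of types* (used for overcapacity/overfishing list-based
disciplines). Listed types are removed regardless of their
capacity-enhancing flag — the rule names the types, not their
classification. When several disciplines trigger on one vessel the scopes
union and dollars are removed once (idempotence). A vessel whose flag's
development status is exempted (S&DT) never triggers, whatever the
predicate; flag state and subsidising Member are identical in this model,
so vessel-level and Member-level exemption coincide.

Cap-and-tier rules operate at country level: each development-status tier
is capped at a percentage of a basis (current non-green-box subsidies, or
landed value), the excess is removed, and the removal is spread over the
country's vessels in proportion to their current subsidy holdings — the
symmetric inverse of the effort-proportional allocation. Green-box types
are excluded from both the cap base and the removal. Vessels receiving a
cap removal count as affected for fleet-partition purposes.

Removals are computed in effective dollars (after type weighting) and
never exceed a vessel's holdings. A `removal_fraction` knob scales all
removals, supporting partial-ambition sweeps; the biomass response is
monotone in this fraction on the default world.

## Vessel economics and tiers

Subsidies are allocated by flag state only (rate = flag total / flag
effort); catch and revenue by (flag state, FAO region). Within a flag,
each vessel receives the flag's subsidy-type mix scaled by its effort
share — the minimal assumption given no per-type vessel rule. Effective-
subsidy multipliers default to 1.0 for every type; empirically derived
multipliers (e.g. OECD-based effort-effect estimates) belong in a user
config, and the fleet subsidy rate s_0 is computed from effective dollars,
since the weighting exists precisely to normalise effort effects before
the bioeconomics. Monetary amounts are 2018 USD throughout and never
converted.

The managed / open-access cut is the empirical quantile of management
scores at a configurable threshold (default 0.5), using the `higher`
order-statistic convention with ties classified managed: on an even-sized
fleet with distinct scores the default threshold splits it exactly in
half, with the upper half managed, and at extreme thresholds exactly the
top vessels qualify.

## Synthetic data

The generator emulates the *structure* of an AIS-derived industrial vessel
database, not its statistics: effort is lognormal, management scores Beta,
stock status lognormal around B/B_MSY = 1, high-seas time a mixture of a
coastal point mass at 0, a small dedicated-high-seas mass forced ≥ 0.95,
and a uniform body. Categorical attributes (IUU listing, dedicated
high-seas status, disputed-area activity) are assigned by deterministic
quota — shuffle, then flag the first round(n·fraction) — so fixture counts
are exact and tests can assert them. All randomness flows from one seeded
generator per call; equal configs give byte-identical CSVs.

The shipped default world is a downscaled global fishery chosen once as a
coherent set of magnitudes: 200 aggregated vessels across 8 flag states
and 5 FAO-style regions, ~8×10¹⁰ kWh of effort, catch rates of
0.8–1.6×10⁻³ t/kWh (total catch ≈ 10⁸ t), ex-vessel prices near
\$1,400/t, and subsidy intensities of \$0.3–0.6/kWh (≈ 25% of landed
value, ~70% of it in capacity-enhancing types). With the default
parameters (φ = 0.188, K = 2.5×10⁹ t, MSY = 9×10⁷ t/yr, b_0 = 1.2×10⁹ t ≈
1.2 B_MSY) the base-year harvest sits near surplus production at b_0, so
the BAU trajectory is nearly stationary and scenario differences are
attributable to the reform rather than to transient drift. η = 0.3 and
ω = 0.03 kWh per USD of profit were set from a linear-stability estimate
of the effort map at this world's scale (the profit slope near equilibrium
is about −1.4 USD/kWh per kWh, so η must stay well below ≈ 1.4) and the
qualitative requirement ω ≪ η. These parameter values are illustrative
magnitudes, not estimates of the real global fishery: passing tests on
this world demonstrate the pipeline's internal consistency and the model's
qualitative mechanisms (contraction of affected fleets, rebound of
unaffected ones, monotone biomass response), not empirical predictions.

What the generator does *not* emulate: spatial autocorrelation of effort,
gear-specific catchability, vessel-size/effort dependence, price
heterogeneity beyond ±20% regional jitter, or any statistical match to
real landings/subsidy datasets.

## The ten-vessel worked example

The fixture used throughout the tests has ten vessels — five managed, five
open-access, each group holding \$1.0M of subsidies — facing a discipline
that strips all capacity-enhancing subsidies from IUU-listed vessels. One
managed and two open-access vessels are listed, so the four fleets have
4 (M-U), 1 (M-A), 3 (OA-U) and 2 (OA-A) vessels. The narration this
example is modelled on is internally inconsistent about the last count
(its stated criteria put two vessels in OA-A, its fleet list one; three
open-access vessels then go missing from a five-vessel group). The fixture
follows the criteria — OA-A has 2 vessels — rather than silently adopting
the printed count.

## Numerical choices and degenerate inputs

- Quantile of management scores: `numpy.quantile(..., method="higher")`;
  ties at the cut are managed.
- Demand singularity: harvest floored at 10⁻⁶ h_0 for pricing only.
- Overharvest: proportional scaling to b_t + surplus, then a floor at 0.
- Zero-effort fleets: inert (skipped by effort updates, zero harvest);
  aggregating a zero-effort fleet with nonzero subsidies is an error.
- Conservation tolerances: allocations re-sum to totals within 1e-9
  relative (they are exact up to float associativity).
- Non-finite projection states abort with a diagnostic dump of the year,
  biomass, price, efforts and profits.
- Seeds: one `numpy` Generator per generator call, derived from the config
  seed; the subsidy table and region totals use fixed offsets (+1, +2) of
  the same seed so the three outputs are independently reproducible.

## Problem sizes used in the checks

The shipped checks run on the 200-vessel default world (33 projected
years, four removal fractions), a 10,000-vessel database for conservation
at scale, 100–200 random parameter draws for the calibration identities,
and a two-fleet, three-step toy projection compared against an
independently coded recurrence oracle at 1e-9 relative tolerance.

## Known limitations

- Single global stock: no spatial structure, no regional parameterisation,
  no stock-specific rebuilding dynamics.
- Deterministic dynamics: no recruitment variability or observation error,
  so "percent change vs BAU" carries no uncertainty interval.
- Constant post-reform subsidy rates: disciplines bind immediately and
  forever; phase-ins and sunset clauses are not modelled.
- The effort response is linear in profit with fixed speeds; capital
  dynamics, exit frictions and fleet heterogeneity within the four
  aggregates are ignored.
- Effective-subsidy multipliers and the bioeconomic parameters shipped as
  defaults are illustrative; conclusions about the real global fishery
  require user-supplied, empirically calibrated values.
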