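# fleetreform

A four-fleet global bioeconomic simulator for analysing fisheries
subsidy-reform proposals of the kind negotiated at the WTO. It is aimed at
fisheries economists and policy analysts who want to ask: *if a given class
of subsidies were prohibited for a given class of vessels, what would happen
to global fish biomass, catch, revenue, and fishing mortality by some
horizon year, relative to business as usual?*

## What it does

Starting from a vessel database (one row per industrial vessel, with effort
in fishing kilowatt-hours by FAO region, IUU listing, high-seas / distant-
water activity, stock status of fished grounds, management score, and flag
development status) and a country-by-type subsidy table, the package:

1. **Allocates economics to vessels.** Catch, landed value and subsidies
   are converted to per-kWh rates — subsidies by flag state, catch and
   revenue by (flag state, FAO region) — and credited to each vessel in
   proportion to its effort, so country and regional totals are conserved
   exactly. Subsidy dollars can be re-weighted by type into "effective"
   dollars reflecting their relative effect on fishing effort.
2. **Evaluates a reform proposal.** A proposal is a set of *disciplines* —
   predicates over vessel attributes (IUU-listed; fishing on stocks with
   B/B_MSY below a threshold; at least X% of time on the high seas; ...)
   plus a removal scope (all capacity-enhancing subsidy types, or a listed
   set) and optional development-status exemptions (S&DT) — and/or a
   country-level cap-and-tier rule.
3. **Partitions the fleet.** Vessels are split managed / open-access at a
   quantile of management scores, and affected / unaffected by the
   proposal, giving four fleets: M-A, M-U, OA-A, OA-U.
4. **Calibrates and projects.** A single global stock follows
   Pella–Tomlinson surplus production

   b_{t+1} = b_t + ((φ+1)/φ) g b_t (1 − (b_t/K)^φ) − h_t,  g = (MSY/K)(φ+1)^{1/φ}

   with fleet harvest h_{j,t} = q_j b_t e_{j,t}, isoelastic demand
   p_t = p_0 (h_t/h_0)^{1/ε} (ε < 0), costs c_{j,t} = α_j e_{j,t}^β, and
   profit π_{j,t} = p_t h_{j,t} − c_{j,t} + s_{j,t} e_{j,t}. Catchability
   q_j = h_{j,0}/(b_0 e_{j,0}) and cost coefficients
   α_j = (p_0 h_{j,0} + s_{j,0} e_{j,0})/e_{j,0}^β are calibrated so every
   fleet starts at zero profit. Effort then follows profit,
   e_{j,t+1} = max(0, e_{j,t} + speed·π_{j,t}), at speed η for open-access
   fleets and ω ≪ η for managed ones. Reform sets the affected fleets'
   subsidy rate to its post-removal value; the unaffected fleets keep
   theirs — and may expand as biomass and price recover (the rebound
   effect).
5. **Compares scenarios** as percent changes vs BAU at the horizon year.

No proprietary data ship with the package: a synthetic generator produces
vessel databases and subsidy tables with the right structure (including a
ten-vessel worked example), and every input is a plain CSV/YAML file you
can replace with real data.

## A worked example

```bash
$ python examples/01_allocation_rates.py
flag subsidy rate : 0.133 USD/kWh
regional catch rate : 0.100 t/kWh
regional revenue rate: 0.200 USD/kWh
...
```

A flag state that paid \$2M in subsidies over 15M kWh of effort subsidises
at \$0.133/kWh; a (flag, region) cell with 0.5M t caught and \$1M landed
over 5M kWh yields 0.1 t/kWh and \$0.2/kWh. Each vessel receives rate ×
its own effort.

```bash
$ python examples/03_reform_projection.py
proposal: High seas (5% threshold, S&DT for LDCs)
fleet sizes: {'M-A': 15, 'M-U': 85, 'OA-A': 10, 'OA-U': 90}
effective subsidies removed: $2.61B
percent change vs BAU at 2050:
               biomass_pct: +0.75%
                 catch_pct: -0.27%
               revenue_pct: -0.02%
     fishing_mortality_pct: -1.02%
```

On the default synthetic world, stripping fuel, construction and access
subsidies from vessels that spend ≥ 5% of their time on the high seas
removes \$2.6B of effective support from 25 of 200 vessels; by 2050 the
stock is 0.75% larger and fishing mortality 1.0% lower than under business
as usual, while catch dips slightly as the affected fleets contract. The
other example scripts cover the ten-vessel fleet partition, cap-and-tier
rules, and the (monotone) biomass response to partial removals.

The same pipeline is available from the shell:

```bash
fleetreform generate --n 200 --seed 1 --out world/
fleetreform run --vessels world/vessels.csv --subsidies world/subsidies.csv \
    --region-totals world/region_totals.csv --proposal high_seas_5pct --out run/
fleetreform compare run/ other_run/
```

## Layout

- `src/fleetreform/` — the library (`synthetic`, `vessels`, `policy`,
  `fleets`, `projection`, `workflow`, `config`, `cli`)
- `src/fleetreform/data/` — illustrative default parameters, identity
  effective-subsidy weights, and example proposal configs
- `examples/` — one narrative script per capability
- `docs/methods.md` — model description, parameter choices, limitations
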