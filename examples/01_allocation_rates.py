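"""Effort-weighted allocation rates, on the numbers from the two textbook cases.

A flag state that paid $2M in subsidies while its vessels expended 15M kWh
of fishing effort has a subsidy rate of $0.133/kWh; a (flag, FAO region)
cell with 0.5M tonnes caught and $1M landed over 5M kWh has catch and
revenue rates of 0.1 t/kWh and $0.2/kWh.  Every vessel is then credited
with rate x its own effort, so totals are conserved by construction.
"""

from fleetreform import compute_flag_subsidy_rate, compute_region_rates

subsidy_rate = compute_flag_subsidy_rate(subsidy_total_usd=2_000_000, effort_total_kwh=15_000_000)
catch_rate, revenue_rate = compute_region_rates(
    catch_t=500_000, revenue_usd=1_000_000, effort_kwh=5_000_000
)

print(f"flag subsidy rate : {subsidy_rate:.3f} USD/kWh")
print(f"regional catch rate : {catch_rate:.3f} t/kWh")
print(f"regional revenue rate: {revenue_rate:.3f} USD/kWh")
print()
print("A vessel contributing 1M kWh under this flag in this region would be")
print(f"allocated {catch_rate * 1e6:,.0f} t of catch, ${revenue_rate * 1e6:,.0f} of revenue")
print(f"and ${subsidy_rate * 1e6:,.0f} of subsidies.")
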