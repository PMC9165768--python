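"""A cap-and-tier rule applied to country subsidy profiles.

Members are tiered by development status; developed countries may keep only
3% of their current non-green-box subsidies, developing countries 5%, and
LDCs are effectively uncapped.  Management subsidies are green-box (exempt
from the cap base and never removed).
"""

from fleetreform import CapBasis, CapRule, CountryProfile, apply_cap_rule

rule = CapRule(
    tier_criterion={"developed": "tier1", "developing": "tier2", "LDC": "tier3"},
    cap_basis=CapBasis.PERCENT_OF_CURRENT_SUBSIDIES,
    cap_percent_by_tier={"tier1": 3.0, "tier2": 5.0, "tier3": 100.0},
    green_box_types=frozenset({"management"}),
)

countries = [
    CountryProfile("AAA", "developed",
                   {"fuel": 8_000_000, "management": 2_000_000}, 150_000_000, 90_000),
    CountryProfile("BBB", "developing",
                   {"fuel": 4_000_000, "vessel_construction": 1_000_000}, 60_000_000, 45_000),
    CountryProfile("CCC", "LDC", {"fuel": 500_000}, 9_000_000, 8_000),
]

for c in countries:
    removed = apply_cap_rule(c, rule)
    non_green = sum(a for t, a in c.total_subsidies_by_type.items() if t != "management")
    print(
        f"{c.flag_state} ({c.development_status:>10s}): "
        f"${non_green:,.0f} cappable -> ${removed:,.0f} removed"
    )
print()
print("A 100% cap (tier3) removes nothing; a 3% cap removes 97% of the")
print("cappable subsidies. Removals are then spread over each country's")
print("vessels in proportion to their allocated subsidies.")
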