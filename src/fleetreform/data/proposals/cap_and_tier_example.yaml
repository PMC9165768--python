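# Cap-and-tier example: developed Members capped at 3% of their current
# non-green-box subsidies, developing at 5%, LDCs at 100% (effectively
# uncapped); management subsidies are green-box and exempt.
name: Cap and tier (3% / 5% by development status)
disciplines: []
cap_rule:
  cap_basis: percent_of_current_subsidies
  tier_criterion: {developed: tier1, developing: tier2, LDC: tier3}
  cap_percent_by_tier: {tier1: 3.0, tier2: 5.0, tier3: 100.0}
  green_box_types: [management]
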