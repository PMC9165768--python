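# Overcapacity/overfishing discipline targeting high-seas fishing: vessels
# spending at least 5% of their fishing time beyond national jurisdiction
# lose fuel, vessel-construction and access subsidies.  LDC-flagged vessels
# are exempt (S&DT).
name: High seas (5% threshold, S&DT for LDCs)
disciplines:
  - name: high-seas vessels lose fuel, construction and access subsidies
    category: OFOC
    predicate: {kind: high_seas_fraction_at_least, threshold: 0.05}
    removal_scope: {listed_types: [fuel, vessel_construction, access]}
    exemptions: [LDC]
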