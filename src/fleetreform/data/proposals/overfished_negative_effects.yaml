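# "Negative effects" variant: the prohibition only bites under a more
# conservative overfished definition (B/B_MSY below 0.8), standing in for
# the requirement to demonstrate a causal subsidy-stock link.
name: Overfished (negative effects, conservative definition)
disciplines:
  - name: vessels on severely overfished stocks lose all capacity-enhancing subsidies
    category: overfished
    predicate: {kind: stock_status_below, threshold: 0.8}
    removal_scope: all_capacity_enhancing
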