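# Prohibit subsidies to fishing on overfished stocks, with "overfished"
# read as B/B_MSY below 1.
name: Overfished (standard definition)
disciplines:
  - name: vessels on overfished stocks lose all capacity-enhancing subsidies
    category: overfished
    predicate: {kind: stock_status_below, threshold: 1.0}
    removal_scope: all_capacity_enhancing
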