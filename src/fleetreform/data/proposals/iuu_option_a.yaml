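# Prohibit subsidies to vessels on RFMO IUU lists: every capacity-enhancing
# subsidy is removed from a listed vessel, no development-status exemption.
name: IUU (Option A)
disciplines:
  - name: RFMO IUU-listed vessels lose all capacity-enhancing subsidies
    category: IUU
    predicate: {kind: iuu_listed}
    removal_scope: all_capacity_enhancing
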