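# Upper-bound scenario: complete removal of all subsidies with the
# potential to be capacity-enhancing, from every vessel.  The predicate is
# a tautology over development statuses, so every vessel triggers.
name: Ambitious Reform
disciplines:
  - name: all vessels lose all capacity-enhancing subsidies
    category: OFOC
    predicate: {kind: development_status_in, statuses: [developed, developing, LDC]}
    removal_scope: all_capacity_enhancing
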