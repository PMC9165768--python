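# Effective-subsidy weights: multipliers converting nominal subsidy dollars
# into effort-effect-normalised ("effective") dollars.  The default treats
# every type at face value; replace with empirically derived multipliers
# (e.g. from OECD subsidy-effect estimates) for a calibrated analysis.
description: identity weights (effective = nominal)
multiplier: {}
default: 1.0
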