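# Illustrative global parameterisation for the default synthetic world.
# These are NOT estimates of the real global fishery; they are plausible
# magnitudes chosen so the default synthetic fleet starts near bioeconomic
# equilibrium.  Supply your own file for a calibrated analysis.
description: illustrative single-stock global parameterisation (2018 USD)
phi: 0.188          # Pella-Tomlinson asymmetry; production peaks at ~0.4 K
k: 2.5e9            # carrying capacity, tonnes
msy: 9.0e7          # maximum sustainable yield, tonnes/yr
b0: 1.2e9           # base-year biomass, tonnes (~1.2 x B_MSY)
p0: 1400.0          # base-year ex-vessel price, USD/tonne
epsilon: -1.1       # demand elasticity (< 0: downward-sloping)
beta: 1.3           # cost-curve exponent (convex costs)
eta: 0.3            # open-access effort response, kWh per USD of profit
omega: 0.03         # managed effort response, kWh per USD (omega << eta)
base_year: 2018
horizon_year: 2050
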