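# Bounded exponential integrate-and-fire point membrane
model: beif
Cm: 1.0        # uF/cm^2
GL: 0.1        # mS/cm^2
EL: -65.3      # mV
VT: -60.2      # mV (soft threshold)
KT: 3.5        # mV (slope factor)
AT: 520        # ceiling factor (dimensionless)
Vrep: 10.0     # mV (repolarization trigger)
tau_rep: 0.60  # ms
Arep: 90       # repolarizing-conductance amplitude factor (dimensionless)
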