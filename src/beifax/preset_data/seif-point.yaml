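# Standard exponential integrate-and-fire point membrane
model: seif
Cm: 1.0        # uF/cm^2
GL: 0.1        # mS/cm^2
EL: -65.3      # mV
VT: -60.2      # mV (soft threshold)
KT: 3.5        # mV (slope factor)
Vspike: 15.0   # mV (spike-detection threshold)
Vreset: -65.3  # mV (same as EL)
tau_ref: 2.8   # ms
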