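# Wang-Buzsaki point membrane (reference conductance model)
model: wb
Cm: 1.0        # uF/cm^2
GL: 0.1        # mS/cm^2
GK: 15.0       # mS/cm^2
GNa: 35.0      # mS/cm^2
EL: -65.0      # mV
EK: -90.0      # mV
ENa: 55.0      # mV
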