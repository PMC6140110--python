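# Default unmyelinated cable: 301 bEIF compartments of 20 um, 10 nA x 1 ms at #50
membrane:
  model: beif
  Cm: 1.0
  GL: 0.1
  EL: -65.3
  VT: -60.2
  KT: 3.5
  AT: 520
  Vrep: 10.0
  tau_rep: 0.60
  Arep: 90
geometry:
  kind: unmyelinated
  D_um: 10.0
  dx_um: 20.0
  n_comp: 301
Rax_ohm_cm: 100.0
stimulus:
  site: 50
  amplitude_pA: 10000.0
  onset_ms: 0.0
  duration_ms: 1.0
velocity_nodes: [100, 200]
solver:
  dt_us: 4.0
  scheme: euler-cn
  duration_ms: 12.0
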