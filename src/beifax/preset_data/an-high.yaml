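# High-frequency (basal) auditory-nerve fiber: 40 bEIF nodes, 60 pA x 1 ms at node #1
membrane:
  model: beif
  Cm: 1.0
  GL: 0.4
  EL: -65.3
  VT: -50.0
  KT: 3.5
  AT: 520
  Vrep: 10.0
  tau_rep: 0.60
  Arep: 90
geometry:
  kind: myelinated
  D_um: 2.5
  Ln_um: 2.0
  Li_um: 450.0
  n_nodes: 40
Rax_ohm_cm: 100.0
stimulus:
  site: 1
  amplitude_pA: 60.0
  onset_ms: 0.0
  duration_ms: 1.0
velocity_nodes: [10, 30]
solver:
  dt_us: 4.0
  scheme: euler-cn
  duration_ms: 6.0
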