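# Extracellular point-source stimulation of the default myelinated bEIF axon:
# -1 mA x 0.1 ms from an electrode 1 mm above node #20
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
  kind: myelinated
  D_um: 2.0
  Ln_um: 2.0
  Li_um: 200.0
  n_nodes: 141
Rax_ohm_cm: 100.0
extracellular:
  I_ex_mA: -1.0
  onset_ms: 0.1
  pulse_ms: 0.1
  rho_ex_ohm_m: 3.0
  electrode_node: 20
  electrode_distance_mm: 1.0
velocity_nodes: [40, 90]
solver:
  dt_us: 4.0
  scheme: euler-cn
  duration_ms: 8.0
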