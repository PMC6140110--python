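# beifax

Spike conduction along axons with a **bounded exponential
integrate-and-fire (bEIF)** membrane — a nine-parameter alternative to
Hodgkin–Huxley-type models for simulating action-potential propagation,
intracellular and extracellular electrical stimulation, and auditory-nerve
(AN) fiber conduction.

## Why

Simulating conducted spikes (for example in models of cochlear implants and
other neuroprostheses) has traditionally required conductance-based models:
simple integrate-and-fire neurons reset the potential instantaneously, which
is incompatible with a spatially extended, multi-compartment membrane, and
the standard exponential IF (sEIF) potential diverges to infinity at every
spike. The bEIF model fixes both problems with two changes to the sEIF spike
current

$$I_{\mathrm{dep}} = \frac{G_L K_T A_T}{1 + A_T\, e^{-(V-V_T)/K_T}},$$

which caps the depolarizing current at $G_L K_T A_T$ (ceiling factor $A_T$),
and an alpha-function repolarizing conductance

$$G_{\mathrm{rep}}(t) = G_L A_{\mathrm{rep}} \frac{t-T_{\mathrm{rep}}}{\tau_{\mathrm{rep}}}\,
e^{1-(t-T_{\mathrm{rep}})/\tau_{\mathrm{rep}}},$$

launched when $V$ crosses $V_{\mathrm{rep}}$, which replaces the hard reset
with a smooth spike-shaped outward current. Every membrane obeys
$C_m \dot V = G_L(E_L - V) + \psi(V) + I_{\mathrm{inj}}$; the package ships
the bEIF, the sEIF, and the Wang–Buzsáki (WB) conductance model as the
biophysical reference.

Axons are chains of compartments coupled by axial conductances
$g_{\mathrm{axon}} = \pi D^2/(4 L_i R_{\mathrm{ax}})$ (myelinated nodes of
Ranvier with perfectly insulating internodes) or the discretized cable
$g_{\mathrm{axon}} = \pi D^2/(4 R_{\mathrm{ax}}\,\mathrm{d}x)$
(unmyelinated). Time stepping is the standard hybrid scheme: forward Euler
for the membrane currents, Crank–Nicolson (one tridiagonal solve per step)
for the axial coupling, dt = 4 µs by default. Extracellular point-source
stimulation enters through $U_{\mathrm{ex}} = \rho_{\mathrm{ex}} I_{\mathrm{ex}}/(4\pi r)$
with axial currents driven by gradients of $U_{\mathrm{in}} = V + U_{\mathrm{ex}}$.

## Worked example

```python
import beifax as bx

chain = bx.build_myelinated(bx.MyelinatedGeometry(), bx.BEIFModel())
stim = bx.IntracellularStep(site=20, amplitude_nA=0.1, duration=1.0)
trace = bx.simulate_chain(chain, stim, bx.SolverConfig(duration=8.0))
est = bx.conduction_velocity(trace, 40, 90, chain)
print(f"u = {est.velocity:.2f} m/s")
```

prints `u = 5.76 m/s`: a 100 pA, 1 ms step at node #20 of the default
141-node axon (D = 2 µm, nodal length 2 µm, internodal length 200 µm,
R_ax = 100 Ω·cm) launches a spike whose peak travels the 10.1 mm from node
#40 to node #90 in about 1.75 ms. The same axon with WB nodes conducts at
5.71 m/s — the ten-fold simpler bEIF membrane reproduces the conductance
model's velocity to within 1%. The `examples/` scripts walk through the
other capabilities (f-I curves, √-scaling sweeps, extracellular stimulation,
AN presets), each printing the numbers it computes.

Shipped presets (`beifax.available_presets()`) cover the three point
membranes and six axon experiments, including the low/high-frequency AN
fibers (40 bEIF nodes; leak density 0.2 vs 0.4 mS/cm², internode 350 vs
450 µm) which conduct at 9.1 and 14.4 m/s — bracketing measured cat AN
velocities and predicting faster conduction for high-frequency fibers.

A thin CLI mirrors the library:

```bash
beifax velocity --preset an-high
beifax simulate-axon --preset myelinated-default --outdir results/
beifax sweep-diameter
```

## Layout

- `src/beifax/membrane.py` — WB / sEIF / bEIF point-membrane models
- `src/beifax/axon.py` — myelinated and unmyelinated chain builders
- `src/beifax/integrate.py` — hybrid Euler / Crank–Nicolson stepper
- `src/beifax/stimulation.py` — current steps and point-source stimulation
- `src/beifax/analysis.py` — peaks, velocities, f-I curves, √-fits, sweeps
- `src/beifax/presets.py`, `preset_data/` — parameter tables as YAML presets
- `docs/methods.md` — model equations, numerical choices, and limitations
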