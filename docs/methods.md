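# Methods

## Membrane models

All three point membranes share the current-balance equation

    Cm dV/dt = GL (EL - V) + psi(V) + I_inj

in density units (Cm in µF/cm², GL in mS/cm², V in mV, t in ms, currents in
µA/cm² — a mutually consistent set), and differ only in the spike-generating
term psi.

**Wang–Buzsáki (WB).** psi = G_Na m³h (E_Na − V) + G_K n⁴ (E_K − V), with
first-order kinetics dy/dt = α_y(V)(1−y) − β_y(V) y for y ∈ {m, h, n}.
Sodium activation m is integrated like the other gates (voltage-dependent
time constant), not treated as instantaneous. The rate functions come in
three shapes — a·x/(1−e^(−x/k)) with x = V − V_ref (evaluated as its
analytic limit a·k within 10⁻⁹ mV of the removable singularity),
a·e^(−x/k), and a/(1+e^(−x/k)) — with the usual temperature factor folded
into the amplitudes. Counting the seven membrane parameters plus three
coefficients for each of six rate functions, the model has 25 parameters.

**Standard EIF (sEIF).** psi = G_L K_T exp((V−V_T)/K_T): the soft threshold
V_T and slope factor K_T summarize spike initiation. Once V exceeds the
detection threshold V_spike the potential is reset to and held at V_reset
for the refractory period τ_ref. The exponential makes V diverge to
infinity in finite time by design; numerically the exponent is capped at
700 (near the float64 limit) so the divergence saturates instead of
overflowing while V_spike still does the detection.

**Bounded EIF (bEIF).** The exponential is replaced by the saturating form
psi_dep = G_L K_T A_T / (1 + A_T e^(−(V−V_T)/K_T)), bounded above by
G_L K_T A_T and agreeing with the sEIF current to relative order
e^((V−V_T)/K_T)/A_T below threshold. The reset is replaced by a
repolarizing current I_rep = G_rep(t)(E_L − V) with the alpha-function
conductance G_rep(s) = G_L A_rep (s/τ_rep) e^(1−s/τ_rep), s = t − T_rep,
evaluated in closed form at every step (never via auxiliary ODEs). An
episode starts when V crosses V_rep from below. Nine parameters total:
three passive (Cm, GL, EL), three for spiking (V_T, K_T, A_T), three for
repolarization (V_rep, τ_rep, A_rep). A `hard-reset` variant replaces the
conductance with an instantaneous reset to EL; it exists to demonstrate
why conducted spikes need the smooth current (see Limitations).

Default parameter values ship as YAML presets (`preset_data/`); the bEIF
defaults are V_T = −60.2 mV, K_T = 3.5 mV, A_T = 520, V_rep = +10 mV,
τ_rep = 0.6 ms, A_rep = 90 on Cm = 1 µF/cm², GL = 0.1 mS/cm²,
EL = −65.3 mV.

### Event handling details

- The repolarization onset T_rep is the linearly interpolated crossing time
  of V_rep within the step, not the grid time. With grid-snapped onsets the
  crossing phase feeds back into the traveling wave along a chain and
  perturbs its spatial uniformity by ~dt × dV/dt (a few mV at dt = 4 µs);
  interpolation removes that coupling while keeping the closed-form
  conductance exact. Conduction velocities are unaffected at the printed
  precision.
- At most one episode is active per compartment. A new episode may start
  only after the running one has decayed below 10⁻⁶ of its peak (s ≈
  17.8 τ_rep) *and* V has fallen back below V_rep. Consequence: sustained
  firing cannot exceed ≈ 1/(17.8 τ_rep) ≈ 94 spikes/s at the default
  τ_rep; far above rheobase the model locks in a depolarized state instead
  of firing faster. All conduction experiments involve a single wave per
  compartment and are unaffected.
- Ties (V exactly at threshold) count as crossings. Spike events are logged
  at the end of the step in which the crossing occurred.
- Initialization: sEIF/bEIF compartments start at their numerically solved
  resting fixed point (GL(EL−V) + I_dep(V) = 0; ≈ −64.2 mV for the bEIF
  defaults), so traces begin flat. WB compartments start at V = EL with
  gates at steady state — not the exact fixed point of the full system, but
  within a fraction of a millivolt, and the residual transient cancels in
  two-point velocity measurements.

## Axon chains

**Myelinated.** Nodes of Ranvier are the only excitable membrane: per node
c_m = πD·L_n·Cm and g_L = πD·L_n·GL (absolute values in nF and µS; the
internal unit system is mV, ms, nF, µS, nA so that µS·mV = nA and
nF·mV/ms = nA). Internodes are perfect insulators contributing only the
axial conductance g_axon = πD²/(4 L_i R_ax). Node centers are spaced
L_n + L_i apart (the alternative reading, spacing L_i, changes velocities
by ≤ 1%). Defaults: D = 2 µm, L_n = 2 µm, L_i = 200 µm, R_ax = 100 Ω·cm,
141 nodes. Compartments are numbered 1-based throughout the interface to
match conventional node numbering (#20, #40, #90).

**Unmyelinated.** A uniform cable split into compartments of length dx with
membrane area πD·dx and coupling g_axon = πD²/(4 R_ax dx); the discrete
axial operator reproduces the cable term (D/(4R_ax)) ∂²V/∂x² exactly on
quadratic profiles and in the dx → 0 limit generally. Defaults: D = 10 µm,
dx = 20 µm, 301 compartments. The builder warns when dx exceeds λ/10 with
λ = sqrt(D/(4 GL R_ax)). For the defaults this formula gives λ² = 2.5 mm²
(λ ≈ 1.58 mm); a commonly quoted value of 1.25 mm² for the same parameters
differs by a factor of two from the formula's direct evaluation — we report
the formula's value, and nothing downstream depends on λ.

**Boundaries.** Sealed ends (no axial current past the terminal
compartments). Measurement nodes sit far from the ends; the sealed end
makes the last few nodes fire nearly simultaneously (reflected charge), a
boundary effect visible only within ~λ of the terminals.

## Time stepping

One step of the hybrid (`euler-cn`) scheme: membrane currents (leak,
spike-generating, repolarizing, injected) are evaluated explicitly at the
old state and accumulated into the right-hand side; the linear axial
operator L (tridiagonal, off-diagonals g_axon) is advanced by the
trapezoidal rule, giving the banded system

    (C/dt − L/2) V_new = (C/dt + L/2) V_old + I_mem(V_old) + I_inj
                         + L (U_ex_old + U_ex_new)/2

solved with a tridiagonal banded solve (the matrix is strictly diagonally
dominant for positive conductances and is factored implicitly each step).
Gating variables advance by forward Euler from the old state; event logic
runs after the voltage update. dt = 4 µs by default; the sEIF conduction
demo uses 0.2 µs to resolve the divergent upstroke.

A pure forward-Euler scheme (`euler`) exists for cross-checks. For the
default myelinated geometry its axial stability limit is
dt < c_m/(2 g_axon) = 4 µs — exactly the default step — so the pure
scheme diverges at dt = 4 µs and matches the hybrid scheme to within one
step at dt ≤ 2 µs. This is precisely why the axial term is treated
implicitly. The hybrid scheme remains bounded at 10× the default step on a
passive chain; the explicit membrane part then sets the practical limit.
Halving dt changes the node #40→#90 travel time by < 1%.

There is no randomness anywhere: every simulation is bit-reproducible.

## Stimulation

Intracellular: rectangular current steps at a named compartment (100 pA ×
1 ms at node #20 for the default myelinated axon; 10 nA × 1 ms at
compartment #50 unmyelinated; 60 pA × 1 ms at node #1 for the AN presets).
In diameter sweeps the amplitude scales linearly with D ((D/2)×100 pA
myelinated, (D/10)×10 nA unmyelinated) to keep initiation secure.

Extracellular: a point source at perpendicular distance d (default 1 mm)
from a reference node imposes U_ex,j = ρ_ex I_ex/(4π r_j) with
r_j = sqrt(d² + axial offset²), ρ_ex = 3.0 Ω·m, applied at nodes only
(consistent with insulating internodes). Membrane currents depend on V
alone; axial currents on U_in = V + U_ex. Pulses are monophasic rectangular
with instantaneous edges. With I_ex = 0 the extracellular stepper follows
bit-identical trajectories to the intracellular one.

## Analysis

Velocity is the center-to-center distance between two compartments divided
by the difference of their voltage-peak times. No sub-sample interpolation
is used by default (at dt = 4 µs over a ≥ 1.7 ms travel time the
quantization error is < 0.3%); parabolic refinement is available. A
compartment "spiked" when its voltage exceeds −20 mV. Geometry sweeps are
summarized by the closed-form least-squares fit u = c√x,
c = Σ(u√x)/Σx. Sweep grids: D ∈ {1,2,3,4,5,6,8} µm, L_i ∈
{50,100,150,200,300,400,500} µm, unmyelinated D ∈ {2,5,10,15,20} µm.
f-I curves count spikes during a 1000-ms step; the rheobase is reported as
the smallest grid amplitude with ≥ 1 spike (no bisection).

The A_T sweep reproduces the ceiling-factor dependence of velocity: for
each A_T the trigger voltage V_rep starts at +15 mV and is lowered in 5 mV
steps (to −20 mV) until the stimulated node returns to within 2 mV of rest
by trace end; failures are flagged rather than silently skipped. Both
extremes genuinely fail with the default repolarization parameters: for
small A_T (≲ 130) the propagating peak grazes V_rep and some nodes never
trigger; for large A_T (≳ 1000) the ceiling current exceeds what the
repolarizing conductance can counter and the membrane cannot return to
rest for any allowed V_rep.

## What the simulations do and do not show

The chain experiments are self-contained: all inputs are parameter tables
and printed protocols, so "data" here means simulated traces, and passing
tests shows internal consistency with cable theory (√-scaling, charge
antisymmetry, scheme convergence) and agreement with the WB reference —
not agreement with any recording. The AN presets inherit somatic membrane
properties for the axon (leak density from spiral-ganglion input
resistance), a deliberate simplification; measured cat conduction
velocities are only bracketed, not fitted.

Known limitations, intentional in scope: perfectly insulating internodes
(no myelin capacitance or paranodal detail), uniform channel properties
along the fiber, no channel noise or stochastic thresholds, no adaptation
currents, no branching, monophasic extracellular pulses only. The bEIF
spike does not undershoot (its repolarizing current reverses at EL, not
E_K). The hard-reset variant conducts but with wildly non-uniform per-node
waveforms — the discontinuous reset injects an effectively unbounded
current within one step — which is the reason the alpha-function current
exists.

One subtle conduction property: with the default V_rep = +10 mV the
propagating bEIF spike peaks only ~0.1 mV above the trigger, and the
discrete chain settles into a slightly mode-locked traveling wave
(per-node delays cycle with period ~3 nodes around their 35 µs mean; at
fine dt some nodes peak just below V_rep and repolarize through axial
coupling alone). The spike waveform itself is translation-invariant to
< 0.1 mV across distant nodes once aligned by upstroke time; differences
up to ~1 mV appear only in the late repolarization tail, where the slowly
decaying stimulus pedestal (membrane τ = Cm/GL = 10 ms) differs with
distance from the stimulated node. Velocity measurements average over 50
internodes and are insensitive to both effects.
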