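"""Point-membrane models: Wang-Buzsaki (WB), standard EIF (sEIF), bounded EIF (bEIF).

All three models share the membrane equation

    Cm dV/dt = GL*(EL - V) + psi(V) + I_inj

where ``psi`` is the spike-generating nonlinearity: Na/K conductances for WB,
an exponential depolarizing current for sEIF, and a bounded (sigmoidal)
depolarizing current plus an alpha-function repolarizing conductance for bEIF.

Units are current *densities* throughout this module: uF/cm^2, mS/cm^2, mV, ms,
uA/cm^2 (a mutually consistent set).  Conversion to absolute per-compartment
quantities happens in :mod:`beifax.axon` using compartment areas.

All state arrays are vectorized: a "state" holds one entry per compartment (or
per batch member for point-neuron parameter sweeps), so the same model code
drives single neurons, amplitude sweeps, and axon chains.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

import numpy as np
from scipy.optimize import brentq

__all__ = [
    "PassiveParams",
    "RateFunctionCoeffs",
    "WBParams",
    "SEIFParams",
    "BEIFParams",
    "WBModel",
    "SEIFModel",
    "BEIFModel",
    "eval_rate",
    "seif_dep_current",
    "beif_dep_current",
    "beif_rep_conductance",
    "simulate_point",
]

# Cap on exp() arguments: exp(700) is near the float64 overflow limit.  The
# sEIF potential diverges to infinity in finite time by design; this cap keeps
# the divergence finite in floating point while leaving the V_spike test to do
# the actual spike detection.
_EXP_CAP = 700.0

# Relative level below which an alpha-function repolarization episode is
# considered over (re-arming one of the two retrigger conditions).
_REP_DECAY_LEVEL = 1e-6


@dataclass(frozen=True)
class PassiveParams:
    """Passive membrane properties shared by all three models."""

    Cm: float = 1.0  # uF/cm^2
    GL: float = 0.1  # mS/cm^2
    EL: float = -65.0  # mV

    def __post_init__(self) -> None:
        if self.Cm <= 0 or self.GL <= 0:
            raise ValueError("Cm and GL must be positive")


@dataclass(frozen=True)
class RateFunctionCoeffs:
    """One gating rate function alpha_y(V) or beta_y(V).

    Three functional shapes occur in the WB kinetics:

    - ``linear-over-expm1``: a*(V - Vref) / (1 - exp(-(V - Vref)/k))
    - ``pure-exponential``:  a * exp(-(V - Vref)/k)
    - ``sigmoid``:           a / (1 + exp(-(V - Vref)/k))

    ``amplitude`` is in ms^-1 (ms^-1 mV^-1 for the linear-over-expm1 form).
    """

    amplitude: float
    Vref: float
    slope: float
    form: Literal["linear-over-expm1", "pure-exponential", "sigmoid"]

    def __post_init__(self) -> None:
        if self.slope == 0:
            raise ValueError("slope factor must be nonzero")


def eval_rate(coeffs: RateFunctionCoeffs, V):
    """Evaluate a gating rate function at membrane potential ``V`` (mV).

    Returns the rate in ms^-1.  The linear-over-expm1 form has a removable
    singularity at ``V == Vref``; within 1e-9 mV of it the analytic limit
    ``amplitude * slope`` is returned.
    """
    V = np.asarray(V, dtype=float)
    if not np.all(np.isfinite(V)):
        raise ValueError("membrane potential must be finite")
    x = V - coeffs.Vref
    a, k = coeffs.amplitude, coeffs.slope
    if coeffs.form == "linear-over-expm1":
        with np.errstate(divide="ignore", invalid="ignore"):
            r = a * x / (-np.expm1(-x / k))
        return np.where(np.abs(x) < 1e-9, a * k, r)
    if coeffs.form == "pure-exponential":
        return a * np.exp(-x / k)
    if coeffs.form == "sigmoid":
        return a / (1.0 + np.exp(-x / k))
    raise ValueError(f"unknown rate-function form {coeffs.form!r}")


def _wb_default_rates() -> dict[str, RateFunctionCoeffs]:
    # Rate constants with the factor-of-5 temperature scaling folded into the
    # amplitudes; sodium activation m is integrated (not instantaneous).
    return {
        "alpha_m": RateFunctionCoeffs(0.50, -35.0, 10.0, "linear-over-expm1"),
        "beta_m": RateFunctionCoeffs(20.0, -60.0, 18.0, "pure-exponential"),
        "alpha_h": RateFunctionCoeffs(0.35, -58.0, 20.0, "pure-exponential"),
        "beta_h": RateFunctionCoeffs(5.0, -28.0, 10.0, "sigmoid"),
        "alpha_n": RateFunctionCoeffs(0.05, -34.0, 10.0, "linear-over-expm1"),
        "beta_n": RateFunctionCoeffs(0.625, -44.0, 80.0, "pure-exponential"),
    }


@dataclass(frozen=True)
class WBParams:
    """Wang-Buzsaki conductance model: transient Na + delayed-rectifier K."""

    passive: PassiveParams = field(default_factory=lambda: PassiveParams(EL=-65.0))
    GK: float = 15.0  # mS/cm^2
    GNa: float = 35.0  # mS/cm^2
    EK: float = -90.0  # mV
    ENa: float = 55.0  # mV
    rates: dict[str, RateFunctionCoeffs] = field(default_factory=_wb_default_rates)

    def __post_init__(self) -> None:
        if not (self.EK < self.passive.EL < self.ENa):
            raise ValueError("require EK < EL < ENa")
        missing = {"alpha_m", "beta_m", "alpha_h", "beta_h", "alpha_n", "beta_n"} - set(self.rates)
        if missing:
            raise ValueError(f"missing rate functions: {sorted(missing)}")


@dataclass(frozen=True)
class SEIFParams:
    """Standard EIF: exponential spike current with hard reset + refractoriness."""

    passive: PassiveParams = field(default_factory=lambda: PassiveParams(EL=-65.3))
    VT: float = -60.2  # mV, soft threshold
    KT: float = 3.5  # mV, slope factor
    Vspike: float = 15.0  # mV, spike-detection threshold
    Vreset: float = -65.3  # mV
    tau_ref: float = 2.8  # ms

    def __post_init__(self) -> None:
        if self.KT <= 0:
            raise ValueError("KT must be positive")
        if not (self.Vreset <= self.VT < self.Vspike):
            raise ValueError("require Vreset <= VT < Vspike")


@dataclass(frozen=True)
class BEIFParams:
    """Bounded EIF: sigmoidally saturating spike current (ceiling GL*KT*AT)
    plus an alpha-function repolarizing conductance replacing the hard reset.

    ``mode='hard-reset'`` swaps the repolarizing conductance for an
    instantaneous reset to EL when V reaches Vrep (an intentionally unstable
    variant used to demonstrate why the conductance is needed for conduction).
    """

    passive: PassiveParams = field(default_factory=lambda: PassiveParams(EL=-65.3))
    VT: float = -60.2  # mV
    KT: float = 3.5  # mV
    AT: float = 520.0  # dimensionless ceiling factor
    Vrep: float = 10.0  # mV, repolarization trigger voltage
    tau_rep: float = 0.60  # ms
    Arep: float = 90.0  # dimensionless conductance amplitude factor
    mode: Literal["alpha-repolarization", "hard-reset"] = "alpha-repolarization"

    def __post_init__(self) -> None:
        if self.KT <= 0 or self.AT <= 0 or self.tau_rep <= 0 or self.Arep <= 0:
            raise ValueError("KT, AT, tau_rep, Arep must be positive")


def seif_dep_current(V, p: SEIFParams):
    """sEIF depolarizing current density GL*KT*exp((V-VT)/KT) (uA/cm^2).

    The exponent is capped at 700 so that the model's finite-time divergence
    saturates instead of overflowing; spike detection relies on Vspike.
    """
    V = np.asarray(V, dtype=float)
    arg = np.minimum((V - p.VT) / p.KT, _EXP_CAP)
    return p.passive.GL * p.KT * np.exp(arg)


def beif_dep_current(V, p: BEIFParams):
    """bEIF depolarizing current density GL*KT*AT / (1 + AT*exp(-(V-VT)/KT)).

    Globally bounded above by GL*KT*AT and strictly increasing in V; for
    V well below VT it coincides with the sEIF exponential to relative
    order exp((V-VT)/KT)/AT.
    """
    V = np.asarray(V, dtype=float)
    if not np.all(np.isfinite(V)):
        raise ValueError("membrane potential must be finite")
    arg = np.minimum(-(V - p.VT) / p.KT, _EXP_CAP)
    return p.passive.GL * p.KT * p.AT / (1.0 + p.AT * np.exp(arg))


def beif_rep_conductance(t_since_onset, p: BEIFParams):
    """Alpha-function repolarizing conductance density (mS/cm^2).

    G_rep(s) = GL * Arep * (s/tau_rep) * exp(1 - s/tau_rep), peaking at
    GL*Arep when s = tau_rep.  Evaluated in closed form, never by an ODE.
    """
    s = np.asarray(t_since_onset, dtype=float)
    if np.any(s < 0):
        raise ValueError("time since onset must be nonnegative")
    x = s / p.tau_rep
    # guard exp underflow for long-dead episodes
    x = np.minimum(x, _EXP_CAP)
    return p.passive.GL * p.Arep * x * np.exp(1.0 - x)


def _alpha_decay_point() -> float:
    """x such that x*exp(1-x) has decayed to _REP_DECAY_LEVEL (x > 1)."""
    return brentq(lambda x: x * np.exp(1.0 - x) - _REP_DECAY_LEVEL, 1.0, 60.0)


class WBModel:
    """Wang-Buzsaki point membrane, vectorized over compartments.

    State dict: ``V`` (mV), gating variables ``m``, ``h``, ``n``; spike events
    are upward crossings of ``spike_detect`` (used only for event bookkeeping,
    peak times come from the voltage trace).
    """

    def __init__(self, params: WBParams | None = None, spike_detect: float = -20.0):
        self.p = params or WBParams()
        self.spike_detect = spike_detect

    # -- currents ---------------------------------------------------------
    def active_current(self, state) -> np.ndarray:
        """psi(V) = INa + IK current density (uA/cm^2)."""
        p = self.p
        V, m, h, n = state["V"], state["m"], state["h"], state["n"]
        INa = p.GNa * m**3 * h * (p.ENa - V)
        IK = p.GK * n**4 * (p.EK - V)
        return INa + IK

    def gating_derivatives(self, state):
        """(dm/dt, dh/dt, dn/dt) from first-order kinetics (ms^-1)."""
        V = state["V"]
        out = []
        for y in ("m", "h", "n"):
            a = eval_rate(self.p.rates[f"alpha_{y}"], V)
            b = eval_rate(self.p.rates[f"beta_{y}"], V)
            out.append(a * (1.0 - state[y]) - b * state[y])
        return tuple(out)

    def steady_gates(self, V):
        """Steady-state gating values y_inf = alpha/(alpha+beta) at fixed V."""
        V = np.asarray(V, dtype=float)
        vals = {}
        for y in ("m", "h", "n"):
            a = eval_rate(self.p.rates[f"alpha_{y}"], V)
            b = eval_rate(self.p.rates[f"beta_{y}"], V)
            vals[y] = a / (a + b)
        return vals

    def init_state(self, n: int) -> dict:
        V = np.full(n, self.p.passive.EL, dtype=float)
        gates = self.steady_gates(V)
        return {"V": V, "m": gates["m"], "h": gates["h"], "n": gates["n"]}

    def resting_potential(self) -> float:
        return self.p.passive.EL

    def psi(self, state, t: float) -> np.ndarray:
        return self.active_current(state)

    def post_update(self, state, V_new, t_new: float, dt: float) -> np.ndarray:
        """Advance gates by forward Euler (from the pre-update state) and
        apply event logic on the updated voltage.  Returns the spike mask."""
        dm, dh, dn = self.gating_derivatives(state)
        spikes = (V_new >= self.spike_detect) & (state["V"] < self.spike_detect)
        state["m"] = np.clip(state["m"] + dt * dm, 0.0, 1.0)
        state["h"] = np.clip(state["h"] + dt * dh, 0.0, 1.0)
        state["n"] = np.clip(state["n"] + dt * dn, 0.0, 1.0)
        state["V"] = V_new
        return spikes


class SEIFModel:
    """Standard EIF point membrane with reset-and-hold refractoriness.

    State dict: ``V`` and ``refrac`` (remaining refractory time, ms).  While
    refractory the voltage is pinned to Vreset regardless of input.
    """

    def __init__(self, params: SEIFParams | None = None):
        self.p = params or SEIFParams()

    def init_state(self, n: int) -> dict:
        return {
            "V": np.full(n, self.resting_potential(), dtype=float),
            "refrac": np.zeros(n, dtype=float),
        }

    def resting_potential(self) -> float:
        p = self.p
        f = lambda V: p.passive.GL * (p.passive.EL - V) + seif_dep_current(V, p)
        return brentq(f, p.passive.EL - 5.0, p.VT - 1e-9)

    def psi(self, state, t: float) -> np.ndarray:
        return seif_dep_current(state["V"], self.p)

    def post_update(self, state, V_new, t_new: float, dt: float) -> np.ndarray:
        p = self.p
        held = state["refrac"] > 0.0
        V_new = np.where(held, p.Vreset, V_new)
        state["refrac"] = np.where(held, state["refrac"] - dt, 0.0)
        spikes = (~held) & (V_new >= p.Vspike)
        V_new = np.where(spikes, p.Vreset, V_new)
        state["refrac"] = np.where(spikes, p.tau_ref, state["refrac"])
        state["V"] = V_new
        return spikes


class BEIFModel:
    """Bounded EIF point membrane with alpha-function repolarization.

    State dict: ``V``, ``Trep`` (onset time of the current repolarization
    episode; large negative when none has occurred) and ``armed`` (True when a
    new episode may be triggered).  At most one episode is active at a time: a
    new one may start only once the previous episode's conductance has decayed
    below 1e-6 of its peak *and* V has fallen back below Vrep.
    """

    _NEVER = -1.0e9  # sentinel onset time: "no episode yet"

    def __init__(self, params: BEIFParams | None = None):
        self.p = params or BEIFParams()
        self._s_off = _alpha_decay_point() * self.p.tau_rep

    def init_state(self, n: int) -> dict:
        return {
            "V": np.full(n, self.resting_potential(), dtype=float),
            "Trep": np.full(n, self._NEVER, dtype=float),
            "armed": np.ones(n, dtype=bool),
        }

    def resting_potential(self) -> float:
        p = self.p
        f = lambda V: p.passive.GL * (p.passive.EL - V) + beif_dep_current(V, p)
        # rest sits between EL and VT (the bounded spike current lifts it
        # slightly above EL)
        return brentq(f, p.passive.EL - 5.0, p.VT - 1e-9)

    def rep_conductance_at(self, state, t: float) -> np.ndarray:
        """Repolarizing conductance density of each compartment at time t."""
        s = t - state["Trep"]
        g = np.zeros_like(state["V"])
        active = (s >= 0.0) & (s < self._s_off)
        if np.any(active):
            g[active] = beif_rep_conductance(s[active], self.p)
        return g

    def psi(self, state, t: float) -> np.ndarray:
        p = self.p
        I = beif_dep_current(state["V"], p)
        if p.mode == "alpha-repolarization":
            g = self.rep_conductance_at(state, t)
            I = I + g * (p.passive.EL - state["V"])
        return I

    def post_update(self, state, V_new, t_new: float, dt: float) -> np.ndarray:
        p = self.p
        # ties with Vrep count as crossings
        spikes = state["armed"] & (V_new >= p.Vrep)
        if p.mode == "hard-reset":
            V_new = np.where(spikes, p.passive.EL, V_new)
            state["armed"] = np.where(spikes, False, state["armed"])
            # re-arm once the potential has fallen back below Vrep
            state["armed"] = state["armed"] | (V_new < p.Vrep)
        else:
            # episode onset at the interpolated crossing time within the
            # step: keeps the alpha-function phase independent of how the
            # crossing falls on the time grid (otherwise the grid snapping
            # feeds back into the traveling wave and breaks its spatial
            # uniformity)
            with np.errstate(divide="ignore", invalid="ignore"):
                frac = (p.Vrep - state["V"]) / (V_new - state["V"])
            frac = np.clip(np.where(np.isfinite(frac), frac, 1.0), 0.0, 1.0)
            t_cross = t_new - dt + frac * dt
            state["Trep"] = np.where(spikes, t_cross, state["Trep"])
            state["armed"] = np.where(spikes, False, state["armed"])
            decayed = (t_new - state["Trep"]) >= self._s_off
            state["armed"] = state["armed"] | (decayed & (V_new < p.Vrep))
        state["V"] = V_new
        return spikes


def step_point(model, state, dt: float, I_inj: float | np.ndarray = 0.0, t: float = 0.0):
    """One forward-Euler step of a point membrane.

    ``I_inj`` is a current density (uA/cm^2).  Returns the spike mask; the
    state is updated in place.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    p = model.p.passive
    V = state["V"]
    dVdt = (p.GL * (p.EL - V) + model.psi(state, t) + I_inj) / p.Cm
    V_new = V + dt * dVdt
    return model.post_update(state, V_new, t + dt, dt)


def simulate_point(model, amplitudes, duration: float, dt: float = 0.004,
                   onset: float = 0.0, stim_duration: float | None = None,
                   record: bool = False, record_stride: int = 1):
    """Simulate point neurons driven by step currents, batched over amplitudes.

    Parameters
    ----------
    amplitudes : array-like
        Step-current densities (uA/cm^2), one batch member each.
    duration : float
        Total simulated time (ms).
    dt : float
        Time step (ms); default 4 us.
    onset, stim_duration : float
        Step onset and length (ms); ``stim_duration=None`` means on until the
        end of the simulation.
    record : bool
        If True, also return the voltage traces (time x batch).

    Returns
    -------
    spike_times : list of ndarray, one per amplitude
    trace : (times, V) tuple if ``record`` else None
    """
    amplitudes = np.atleast_1d(np.asarray(amplitudes, dtype=float))
    n = amplitudes.size
    state = model.init_state(n)
    n_steps = int(round(duration / dt))
    stim_end = duration if stim_duration is None else onset + stim_duration
    spike_times: list[list[float]] = [[] for _ in range(n)]
    rec_t, rec_v = [], []
    for k in range(n_steps):
        t = k * dt
        if record and k % record_stride == 0:
            rec_t.append(t)
            rec_v.append(state["V"].copy())
        I = amplitudes if (onset <= t < stim_end) else 0.0
        spikes = step_point(model, state, dt, I_inj=I, t=t)
        if np.any(spikes):
            t_new = t + dt
            for i in np.nonzero(spikes)[0]:
                spike_times[i].append(t_new)
    out = [np.asarray(s) for s in spike_times]
    if record:
        return out, (np.asarray(rec_t), np.asarray(rec_v))
    return out, None
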