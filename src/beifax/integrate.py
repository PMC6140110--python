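"""Time stepping for compartment chains.

The hybrid scheme treats membrane currents (leak, spike-generating,
repolarizing, injected) with the explicit forward Euler method and the linear
axial-coupling operator with the Crank-Nicolson (trapezoidal) rule, which
requires one tridiagonal solve per step:

    (C/dt - L/2) V_new = (C/dt + L/2) V_old + L*(U_ex_old + U_ex_new)/2
                         + I_membrane(V_old) + I_inj

where C = diag(cm) and L is the tridiagonal axial operator with off-diagonal
entries g_axon.  Event logic (sEIF reset/hold, bEIF repolarization trigger)
runs after the voltage update; ties with the threshold count as crossings.
A pure forward-Euler scheme is also available for cross-checks.

Everything is deterministic; there is no randomness anywhere in the system.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.linalg import solve_banded

from .stimulation import ExtracellularSource, IntracellularStep

__all__ = ["SolverConfig", "SimulationTrace", "simulate_chain", "step_chain"]


@dataclass(frozen=True)
class SolverConfig:
    """Solver settings: time step dt (ms; default 4 us), scheme
    ('euler-cn' or 'euler'), total duration (ms), and trace stride."""

    dt: float = 0.004
    scheme: str = "euler-cn"
    duration: float = 10.0
    record_stride: int = 1

    def __post_init__(self) -> None:
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if self.scheme not in ("euler", "euler-cn"):
            raise ValueError("scheme must be 'euler' or 'euler-cn'")
        if self.record_stride < 1:
            raise ValueError("record_stride must be >= 1")


@dataclass
class SimulationTrace:
    """Recorded voltages and spike events of a chain simulation.

    ``V`` has shape (n_times, n_compartments); ``events`` is a list with one
    array of spike times (ms, full dt resolution) per compartment.
    """

    times: np.ndarray
    V: np.ndarray
    events: list
    dt: float
    stride: int = 1

    @property
    def n_comp(self) -> int:
        return self.V.shape[1]

    def voltage(self, comp: int) -> np.ndarray:
        """Voltage series of a 1-based compartment index."""
        return self.V[:, comp - 1]

    def events_table(self) -> np.ndarray:
        """All spike events as a (k, 2) array of (1-based compartment, time)."""
        rows = [
            (j + 1, t) for j, ts in enumerate(self.events) for t in ts
        ]
        return np.asarray(rows, dtype=float).reshape(-1, 2)

    def to_delimited(self, path, stride: int = 1) -> None:
        """Write time + per-compartment voltage columns as tab-separated text."""
        data = np.column_stack([self.times[::stride], self.V[::stride]])
        header = "time_ms\t" + "\t".join(f"V{j + 1}" for j in range(self.n_comp))
        np.savetxt(path, data, delimiter="\t", header=header, comments="")


class _AxialOperator:
    """Tridiagonal axial operator L and the banded Crank-Nicolson system."""

    def __init__(self, chain, dt: float):
        g = chain.g_axon
        n = chain.n
        self.n = n
        # L: off-diagonals g, diagonal -(g_left + g_right); sealed ends
        diag = np.zeros(n)
        diag[:-1] -= g
        diag[1:] -= g
        self.diag = diag
        self.off = g
        # banded form of A = C/dt - L/2 (positive definite for g, cm > 0)
        c_over_dt = chain.cm / dt
        ab = np.zeros((3, n))
        ab[0, 1:] = -0.5 * g  # superdiagonal
        ab[1] = c_over_dt - 0.5 * diag
        ab[2, :-1] = -0.5 * g  # subdiagonal
        self.ab = ab
        self.c_over_dt = c_over_dt

    def apply(self, u: np.ndarray) -> np.ndarray:
        """L @ u (nA when u is in mV)."""
        out = self.diag * u
        out[:-1] += self.off * u[1:]
        out[1:] += self.off * u[:-1]
        return out

    def solve(self, rhs: np.ndarray) -> np.ndarray:
        return solve_banded((1, 1), self.ab, rhs)


def _membrane_current(chain, state, t: float) -> np.ndarray:
    """Absolute membrane current (nA): leak + active/repolarizing currents."""
    passive = chain.membrane.p.passive
    leak = chain.gl * (passive.EL - state["V"])
    # density uA/cm^2 * cm^2 = uA -> nA
    active = chain.membrane.psi(state, t) * chain.area_cm2 * 1e3
    return leak + active


def step_chain(chain, state, t: float, dt: float, injected=None,
               u_ex_old=None, u_ex_new=None, scheme: str = "euler-cn",
               _op: _AxialOperator | None = None) -> np.ndarray:
    """Advance the chain state by one step of length dt; returns spike mask.

    ``injected`` is the per-compartment injected current (nA); ``u_ex_old`` /
    ``u_ex_new`` the extracellular potentials (mV) at the step's start and
    end (None means intracellular stimulation only).
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    op = _op if _op is not None else _AxialOperator(chain, dt)
    V = state["V"]
    I_mem = _membrane_current(chain, state, t)
    if injected is not None:
        I_mem = I_mem + injected
    if scheme == "euler-cn":
        u_old = V if u_ex_old is None else V + u_ex_old
        rhs = op.c_over_dt * V + 0.5 * op.apply(u_old) + I_mem
        if u_ex_new is not None:
            rhs = rhs + 0.5 * op.apply(u_ex_new)
        elif u_ex_old is not None:
            pass  # pulse off at the new time: no extracellular contribution
        V_new = op.solve(rhs)
    elif scheme == "euler":
        u_old = V if u_ex_old is None else V + u_ex_old
        V_new = V + dt * (I_mem + op.apply(u_old)) / chain.cm
    else:
        raise ValueError("scheme must be 'euler' or 'euler-cn'")
    return chain.membrane.post_update(state, V_new, t + dt, dt)


def simulate_chain(chain, stimulus=None, solver: SolverConfig | None = None,
                   extracellular: ExtracellularSource | None = None) -> SimulationTrace:
    """Run a chain simulation and record the voltage trace and spike events.

    ``stimulus`` is an :class:`IntracellularStep` (or a list of them);
    ``extracellular`` an optional :class:`ExtracellularSource`.  Initial state
    is the membrane model's resting state for every compartment.
    """
    solver = solver or SolverConfig()
    dt = solver.dt
    n_steps = int(round(solver.duration / dt))
    n = chain.n
    steps = []
    if stimulus is not None:
        steps = [stimulus] if isinstance(stimulus, IntracellularStep) else list(stimulus)
    for s in steps:
        if not (1 <= s.site <= n):
            raise ValueError(f"stimulus site {s.site} outside chain of {n} compartments")

    state = chain.membrane.init_state(n)
    op = _AxialOperator(chain, dt)

    n_rec = n_steps // solver.record_stride + 1
    times = np.empty(n_rec)
    V_rec = np.empty((n_rec, n))
    events: list[list[float]] = [[] for _ in range(n)]

    # the point-source pulse is a fixed spatial profile gated by a time window
    if extracellular is not None:
        from .stimulation import extracellular_potential

        _profile = extracellular_potential(
            extracellular.I_mA,
            extracellular.node_distances(chain),
            extracellular.rho_ex,
        )
        _on, _off = extracellular.onset, extracellular.onset + extracellular.duration

    def u_ex(k: int):
        if extracellular is None:
            return None
        t = k * dt
        return _profile if (_on <= t < _off) else None

    i_rec = 0
    for k in range(n_steps):
        t = k * dt
        if k % solver.record_stride == 0:
            times[i_rec] = t
            V_rec[i_rec] = state["V"]
            i_rec += 1
        injected = None
        if steps:
            injected = np.zeros(n)
            for s in steps:
                injected += s.current_vector(n, t)
            if not injected.any():
                injected = None
        spikes = step_chain(
            chain, state, t, dt, injected=injected,
            u_ex_old=u_ex(k), u_ex_new=u_ex(k + 1),
            scheme=solver.scheme, _op=op,
        )
        if spikes.any():
            t_new = t + dt
            for j in np.nonzero(spikes)[0]:
                events[j].append(t_new)
    times[i_rec] = n_steps * dt
    V_rec[i_rec] = state["V"]

    return SimulationTrace(
        times=times[: i_rec + 1],
        V=V_rec[: i_rec + 1],
        events=[np.asarray(e) for e in events],
        dt=dt,
        stride=solver.record_stride,
    )
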