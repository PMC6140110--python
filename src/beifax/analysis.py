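"""Trace analysis: spike peak times, conduction velocity, f-I curves,
square-root scaling fits, and parameter sweeps.

Conduction velocity is measured the standard way for compartmental axon
models: the center-to-center distance between two recording compartments
divided by the difference of the times at which the membrane potential peaks
there.  Velocity-versus-geometry sweeps are summarized by a one-parameter
least-squares fit u = c*sqrt(x) (classical scaling for both myelinated
internode/diameter dependence and unmyelinated diameter dependence).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .axon import (
    MyelinatedGeometry,
    UnmyelinatedGeometry,
    build_myelinated,
    build_unmyelinated,
)
from .integrate import SimulationTrace, SolverConfig, simulate_chain
from .membrane import BEIFModel, simulate_point
from .stimulation import IntracellularStep, diameter_scaled_amplitude

__all__ = [
    "NoSpikeError",
    "VelocityEstimate",
    "SqrtFit",
    "spike_peak_time",
    "conduction_velocity",
    "f_i_curve",
    "fit_sqrt",
    "sweep_diameter_myelinated",
    "sweep_internode",
    "sweep_diameter_unmyelinated",
    "at_sweep",
]

# a compartment is considered to have spiked when its voltage exceeds this
SPIKE_LEVEL = -20.0  # mV


class NoSpikeError(RuntimeError):
    """Raised when a trace segment contains no suprathreshold excursion."""


@dataclass(frozen=True)
class VelocityEstimate:
    """Conduction speed derived from a pair of spike-peak times."""

    node_a: int
    node_b: int
    t_peak_a: float  # ms
    t_peak_b: float  # ms
    distance_um: float

    @property
    def velocity(self) -> float:
        """Conduction speed in m/s (um/ms * 1e-3)."""
        dt = self.t_peak_b - self.t_peak_a
        if dt == 0:
            raise ZeroDivisionError("equal peak times: velocity undefined")
        return self.distance_um / dt * 1e-3


@dataclass(frozen=True)
class SqrtFit:
    """Least-squares coefficient of u = c*sqrt(x)."""

    coefficient: float
    predictor: str
    residual_norm: float

    def __post_init__(self) -> None:
        if self.coefficient <= 0:
            raise ValueError("fit coefficient must be positive")


def spike_peak_time(trace: SimulationTrace, comp: int, window=None,
                    interpolate: bool = False) -> float:
    """Time (ms) of the voltage maximum of a 1-based compartment.

    ``window=(t0, t1)`` restricts the search.  Raises :class:`NoSpikeError`
    when the maximum stays below the suprathreshold level (-20 mV).  Ties are
    broken by the earliest sample.  With ``interpolate=True`` a parabola
    through the peak sample and its neighbors refines the estimate.
    """
    v = trace.voltage(comp)
    t = trace.times
    if window is not None:
        mask = (t >= window[0]) & (t <= window[1])
        if not mask.any():
            raise ValueError("empty search window")
        v, t = v[mask], t[mask]
    i = int(np.argmax(v))
    if v[i] <= SPIKE_LEVEL:
        raise NoSpikeError(
            f"compartment {comp}: max V = {v[i]:.1f} mV stays below {SPIKE_LEVEL} mV"
        )
    if interpolate and 0 < i < len(v) - 1:
        y0, y1, y2 = v[i - 1], v[i], v[i + 1]
        denom = y0 - 2 * y1 + y2
        if denom < 0:
            shift = 0.5 * (y0 - y2) / denom
            return float(t[i] + shift * (t[1] - t[0]))
    return float(t[i])


def conduction_velocity(trace: SimulationTrace, node_a: int, node_b: int,
                        chain, interpolate: bool = False) -> VelocityEstimate:
    """Velocity estimate between two 1-based compartments of ``chain``."""
    ta = spike_peak_time(trace, node_a, interpolate=interpolate)
    tb = spike_peak_time(trace, node_b, interpolate=interpolate)
    if tb == ta:
        raise ZeroDivisionError("equal peak times: velocity undefined")
    return VelocityEstimate(
        node_a=node_a,
        node_b=node_b,
        t_peak_a=ta,
        t_peak_b=tb,
        distance_um=chain.distance_um(node_a, node_b),
    )


def f_i_curve(model, amplitudes, duration: float = 1000.0, dt: float = 0.004):
    """Firing rate (spikes/s) of a point neuron per step-current amplitude.

    ``amplitudes`` are current densities (uA/cm^2); the step lasts the whole
    ``duration`` (ms).  All amplitudes are integrated in one vectorized run.
    """
    if duration <= 0:
        raise ValueError("duration must be positive")
    spikes, _ = simulate_point(model, amplitudes, duration=duration, dt=dt)
    return np.array([len(s) for s in spikes]) / (duration * 1e-3)


def fit_sqrt(x_values, u_values, predictor: str = "x") -> SqrtFit:
    """Closed-form least-squares fit of u = c*sqrt(x):
    c = sum(u*sqrt(x)) / sum(x)."""
    x = np.asarray(x_values, dtype=float)
    u = np.asarray(u_values, dtype=float)
    if x.size < 3:
        raise ValueError("need at least three points")
    if np.any(x <= 0) or np.any(u <= 0):
        raise ValueError("x and u must be positive")
    c = float(np.sum(u * np.sqrt(x)) / np.sum(x))
    resid = float(np.linalg.norm(u - c * np.sqrt(x)))
    return SqrtFit(coefficient=c, predictor=predictor, residual_norm=resid)


# ---------------------------------------------------------------------------
# velocity sweeps

# default sweep grids (geometry ranges over which the sqrt scaling holds)
DIAMETER_GRID_UM = (1.0, 2.0, 3.0, 4.0, 5.0, 6.0, 8.0)
INTERNODE_GRID_UM = (50.0, 100.0, 150.0, 200.0, 300.0, 400.0, 500.0)
UNMYEL_DIAMETER_GRID_UM = (2.0, 5.0, 10.0, 15.0, 20.0)


def _myelinated_velocity(model, geometry: MyelinatedGeometry, amplitude_nA: float,
                         solver: SolverConfig, site: int = 20,
                         node_a: int = 40, node_b: int = 90) -> float:
    chain = build_myelinated(geometry, model)
    stim = IntracellularStep(site=site, amplitude_nA=amplitude_nA, duration=1.0)
    trace = simulate_chain(chain, stim, solver)
    return conduction_velocity(trace, node_a, node_b, chain).velocity


def sweep_diameter_myelinated(model_factory=BEIFModel, diameters=DIAMETER_GRID_UM,
                              dt: float = 0.004, duration: float = 8.0):
    """Myelinated velocity vs diameter with diameter-scaled stimulus
    ((D/2) x 100 pA).  Returns (diameters, velocities)."""
    solver = SolverConfig(dt=dt, duration=duration)
    vels = []
    for D in diameters:
        geom = MyelinatedGeometry(D=D)
        amp = diameter_scaled_amplitude(D, base=0.1, D_ref=2.0)  # nA
        vels.append(_myelinated_velocity(model_factory(), geom, amp, solver))
    return np.asarray(diameters, dtype=float), np.asarray(vels)


def sweep_internode(model_factory=BEIFModel, internode_lengths=INTERNODE_GRID_UM,
                    dt: float = 0.004, duration: float = 8.0):
    """Myelinated velocity vs internodal length at D = 2 um, 100 pA x 1 ms."""
    solver = SolverConfig(dt=dt, duration=duration)
    vels = []
    for Li in internode_lengths:
        geom = MyelinatedGeometry(Li=Li)
        vels.append(_myelinated_velocity(model_factory(), geom, 0.1, solver))
    return np.asarray(internode_lengths, dtype=float), np.asarray(vels)


def sweep_diameter_unmyelinated(model_factory=BEIFModel,
                                diameters=UNMYEL_DIAMETER_GRID_UM,
                                dt: float = 0.004, duration: float = 14.0):
    """Unmyelinated velocity vs diameter (301 compartments, dx = 20 um),
    stimulus (D/10) x 10 nA x 1 ms at compartment #50, velocity between
    compartments #100 and #200."""
    solver = SolverConfig(dt=dt, duration=duration)
    vels = []
    for D in diameters:
        geom = UnmyelinatedGeometry(D=D)
        chain = build_unmyelinated(geom, model_factory())
        amp = diameter_scaled_amplitude(D, base=10.0, D_ref=10.0)  # nA
        stim = IntracellularStep(site=50, amplitude_nA=amp, duration=1.0)
        trace = simulate_chain(chain, stim, solver)
        vels.append(conduction_velocity(trace, 100, 200, chain).velocity)
    return np.asarray(diameters, dtype=float), np.asarray(vels)


def at_sweep(AT_values, model_params=None, geometry: MyelinatedGeometry | None = None,
             Vrep_start: float = 15.0, Vrep_min: float = -20.0, Vrep_step: float = 5.0,
             dt: float = 0.004, duration: float = 8.0, rest_tol: float = 2.0):
    """Velocity vs ceiling factor A_T with automatic Vrep readjustment.

    For each A_T the repolarization trigger Vrep starts at ``Vrep_start``
    (+15 mV, the sweep protocol's starting point) and is lowered in 5 mV steps
    down to -20 mV until the stimulated node's potential has returned to
    within ``rest_tol`` mV of rest by the end of the trace.  Returns a list of
    dicts with keys AT, Vrep, velocity (velocity None when conduction failed,
    Vrep None when no setting restored rest).
    """
    from .membrane import BEIFModel, BEIFParams
    from dataclasses import replace as _replace

    base = model_params or BEIFParams()
    geometry = geometry or MyelinatedGeometry()
    solver = SolverConfig(dt=dt, duration=duration)
    results = []
    for AT in AT_values:
        if AT <= 0:
            raise ValueError("AT must be positive")
        entry = {"AT": float(AT), "Vrep": None, "velocity": None}
        vrep = Vrep_start
        while vrep >= Vrep_min - 1e-9:
            params = _replace(base, AT=float(AT), Vrep=vrep)
            model = BEIFModel(params)
            chain = build_myelinated(geometry, model)
            stim = IntracellularStep(site=20, amplitude_nA=0.1, duration=1.0)
            trace = simulate_chain(chain, stim, solver)
            rest = model.resting_potential()
            if abs(trace.voltage(20)[-1] - rest) <= rest_tol:
                entry["Vrep"] = vrep
                try:
                    entry["velocity"] = conduction_velocity(trace, 40, 90, chain).velocity
                except NoSpikeError:
                    entry["velocity"] = None
                break
            vrep -= Vrep_step
        results.append(entry)
    return results
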