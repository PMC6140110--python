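"""Stimulus protocols: intracellular current steps and extracellular
point-source stimulation.

An extracellular point electrode at distance r from a node imposes the
potential U_ex = rho_ex * I_ex / (4*pi*r).  Axial currents are then driven by
gradients of the intracellular potential U_in = V + U_ex, while the
transmembrane currents still depend on V alone.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "IntracellularStep",
    "ExtracellularSource",
    "diameter_scaled_amplitude",
    "extracellular_potential",
]


@dataclass(frozen=True)
class IntracellularStep:
    """Rectangular current step injected into one compartment.

    ``site`` is 1-based; ``amplitude_nA`` in nA (100 pA = 0.1 nA);
    times in ms.
    """

    site: int
    amplitude_nA: float
    onset: float = 0.0
    duration: float = 1.0

    def __post_init__(self) -> None:
        if self.duration <= 0:
            raise ValueError("duration must be positive")
        if self.site < 1:
            raise ValueError("site is a 1-based compartment index")

    def current_vector(self, n: int, t: float) -> np.ndarray:
        """Injected current (nA) for each of n compartments at time t."""
        I = np.zeros(n)
        if self.onset <= t < self.onset + self.duration:
            I[self.site - 1] = self.amplitude_nA
        return I


def diameter_scaled_amplitude(D: float, base: float, D_ref: float) -> float:
    """Scale a stimulus amplitude linearly with axon diameter: base * D/D_ref.

    Used to keep spike initiation secure across diameter sweeps (e.g.
    (D/2) x 100 pA for the myelinated axon, (D/10) x 10 nA unmyelinated).
    """
    if D <= 0 or D_ref <= 0:
        raise ValueError("diameters must be positive")
    return base * D / D_ref


@dataclass(frozen=True)
class ExtracellularSource:
    """Monophasic rectangular pulse from a point electrode near a straight axon.

    Default geometry is an electrode at perpendicular distance
    ``electrode_distance_mm`` from compartment ``electrode_node`` (1-based);
    per-node distances are then r_j = sqrt(d_perp^2 + axial_offset_j^2).
    Explicit per-node ``distances_mm`` override the geometric construction.
    """

    I_mA: float = -1.0
    onset: float = 0.0
    duration: float = 0.1
    rho_ex: float = 3.0  # Ohm*m
    electrode_node: int = 20
    electrode_distance_mm: float = 1.0
    distances_mm: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.duration <= 0:
            raise ValueError("duration must be positive")
        if self.distances_mm is not None and np.any(np.asarray(self.distances_mm) <= 0):
            raise ValueError("electrode-to-node distances must be positive")
        if self.distances_mm is None and self.electrode_distance_mm <= 0:
            raise ValueError("electrode must be off the axon (distance > 0)")

    def node_distances(self, chain) -> np.ndarray:
        """Electrode-to-compartment distances r_j (mm)."""
        if self.distances_mm is not None:
            r = np.asarray(self.distances_mm, dtype=float)
            if len(r) != chain.n:
                raise ValueError("distances_mm length must match the chain")
            return r
        x0 = chain.positions[self.electrode_node - 1]
        offset_mm = (chain.positions - x0) * 1e-3
        return np.sqrt(self.electrode_distance_mm**2 + offset_mm**2)

    def potential(self, chain, t: float) -> np.ndarray:
        """Extracellular potential U_ex at each compartment (mV) at time t."""
        if not (self.onset <= t < self.onset + self.duration):
            return np.zeros(chain.n)
        return extracellular_potential(self.I_mA, self.node_distances(chain), self.rho_ex)


def extracellular_potential(I_mA: float, r_mm, rho_ex: float = 3.0) -> np.ndarray:
    """Point-source potential U_ex = rho_ex * I / (4*pi*r), returned in mV.

    ``rho_ex`` in Ohm*m, ``I_mA`` in mA, ``r_mm`` in mm.  With these units
    rho*I/(4*pi*r) is in volts, hence the factor 1000.
    """
    r = np.asarray(r_mm, dtype=float)
    if np.any(r <= 0):
        raise ValueError("r must be positive (electrode cannot sit on the axon)")
    return 1000.0 * rho_ex * I_mA / (4.0 * np.pi * r)
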