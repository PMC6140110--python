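"""Compartment-chain construction for myelinated and unmyelinated axons.

Density parameters from the membrane models (uF/cm^2, mS/cm^2) are converted
to absolute per-compartment values (nF, uS) using each compartment's membrane
area; the internal unit system is mV, ms, nF, uS, nA, which is mutually
consistent (uS*mV = nA, nF*mV/ms = nA).

Myelinated axons are chains of nodes of Ranvier: only the nodal membrane
(area pi*D*Ln) carries capacitance and transmembrane current, while the
internodes are perfectly insulating and contribute only the axial conductance
g_axon = pi*D^2 / (4*Li*Rax).  Unmyelinated axons are a uniform cable split
into compartments of length dx with g_axon = pi*D^2 / (4*Rax*dx).

Compartments are numbered 1-based in the external interface (node #1 is the
first node), matching the conventional numbering of stimulation and recording
sites; internal arrays are 0-based.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "MyelinatedGeometry",
    "UnmyelinatedGeometry",
    "CompartmentChain",
    "build_myelinated",
    "build_unmyelinated",
    "length_constant",
]

# unit conversion factors
_UM2_TO_CM2 = 1e-8
_UF_TO_NF = 1e3  # (uF/cm^2 * cm^2) -> nF
_MS_TO_US = 1e3  # (mS/cm^2 * cm^2) -> uS
_S_TO_US = 1e6


@dataclass(frozen=True)
class MyelinatedGeometry:
    """Geometry of a myelinated axon: D, nodal length Ln, internodal length Li
    (all um) and the number of nodes."""

    D: float = 2.0
    Ln: float = 2.0
    Li: float = 200.0
    n_nodes: int = 141

    def __post_init__(self) -> None:
        if min(self.D, self.Ln, self.Li) <= 0:
            raise ValueError("D, Ln, Li must be positive")
        if self.n_nodes < 2:
            raise ValueError("need at least two nodes")


@dataclass(frozen=True)
class UnmyelinatedGeometry:
    """Geometry of an unmyelinated cable: diameter D, compartment length dx
    (both um), and the compartment count."""

    D: float = 10.0
    dx: float = 20.0
    n_comp: int = 301

    def __post_init__(self) -> None:
        if self.D <= 0 or self.dx <= 0:
            raise ValueError("D and dx must be positive")
        if self.n_comp < 2:
            raise ValueError("need at least two compartments")


@dataclass
class CompartmentChain:
    """A 1-D chain of membrane compartments coupled by axial conductances.

    Attributes
    ----------
    cm : ndarray (n,)
        Absolute capacitance per compartment (nF).
    gl : ndarray (n,)
        Absolute leak conductance per compartment (uS).
    area_cm2 : ndarray (n,)
        Membrane area per compartment (cm^2); converts model current
        densities to absolute currents.
    g_axon : ndarray (n-1,)
        Axial coupling conductance between adjacent compartments (uS).
    positions : ndarray (n,)
        Compartment-center coordinates along the axon (um), strictly
        increasing.
    membrane : object
        Attached membrane model (WBModel | SEIFModel | BEIFModel).
    Rax : float
        Axial resistivity (Ohm*cm), kept for provenance.
    """

    cm: np.ndarray
    gl: np.ndarray
    area_cm2: np.ndarray
    g_axon: np.ndarray
    positions: np.ndarray
    membrane: object
    Rax: float
    geometry: object = None

    def __post_init__(self) -> None:
        n = len(self.cm)
        if not (len(self.gl) == len(self.area_cm2) == len(self.positions) == n):
            raise ValueError("inconsistent per-compartment array lengths")
        if len(self.g_axon) != n - 1:
            raise ValueError("g_axon must have length n-1")
        if np.any(self.cm <= 0) or np.any(self.gl <= 0) or np.any(self.g_axon <= 0):
            raise ValueError("capacitances and conductances must be positive")
        if np.any(np.diff(self.positions) <= 0):
            raise ValueError("positions must be strictly increasing")

    @property
    def n(self) -> int:
        return len(self.cm)

    def distance_um(self, a: int, b: int) -> float:
        """Center-to-center distance between 1-based compartments a and b."""
        return abs(float(self.positions[b - 1] - self.positions[a - 1]))

    def axial_currents(self, V: np.ndarray) -> np.ndarray:
        """Per-link axial current g_axon*(V[j] - V[j+1]) in nA, positive when
        flowing from j toward j+1.  Sealed ends: no current beyond the chain."""
        return self.g_axon * (V[:-1] - V[1:])

    def axial_current_into(self, V: np.ndarray) -> np.ndarray:
        """Net axial current into each compartment (nA): the discrete
        divergence of the link currents."""
        link = self.axial_currents(V)
        out = np.zeros_like(V)
        out[1:] += link
        out[:-1] -= link
        return out


def _passive_of(membrane):
    return membrane.p.passive


def build_myelinated(geometry: MyelinatedGeometry, membrane, Rax: float = 100.0) -> CompartmentChain:
    """Build a myelinated node chain.

    Per node: cm = pi*D*Ln*Cm, gl = pi*D*Ln*GL (nodal membrane only);
    between nodes: g_axon = pi*D^2/(4*Li*Rax).  Node centers are spaced
    Ln + Li apart.  ``Rax`` in Ohm*cm.
    """
    g = geometry
    passive = _passive_of(membrane)
    area = np.pi * g.D * g.Ln * _UM2_TO_CM2  # cm^2 per node
    cm = passive.Cm * area * _UF_TO_NF
    gl = passive.GL * area * _MS_TO_US
    D_cm = g.D * 1e-4
    Li_cm = g.Li * 1e-4
    gax = np.pi * D_cm**2 / (4.0 * Li_cm * Rax) * _S_TO_US
    n = g.n_nodes
    return CompartmentChain(
        cm=np.full(n, cm),
        gl=np.full(n, gl),
        area_cm2=np.full(n, area),
        g_axon=np.full(n - 1, gax),
        positions=np.arange(n, dtype=float) * (g.Ln + g.Li),
        membrane=membrane,
        Rax=Rax,
        geometry=g,
    )


def build_unmyelinated(geometry: UnmyelinatedGeometry, membrane, Rax: float = 100.0) -> CompartmentChain:
    """Discretize a uniform unmyelinated cable into compartments.

    Per compartment: membrane area pi*D*dx; coupling g_axon =
    pi*D^2/(4*Rax*dx), which reproduces the cable term (D/(4*Rax)) d2V/dx2
    as dx -> 0.  Warns when dx exceeds lambda/10.
    """
    g = geometry
    passive = _passive_of(membrane)
    lam_mm = length_constant(g, passive.GL, Rax)
    if g.dx > lam_mm * 1000.0 / 10.0:
        warnings.warn(
            f"compartment length dx={g.dx} um exceeds lambda/10 "
            f"({lam_mm * 100.0:.1f} um); discretization may be too coarse",
            stacklevel=2,
        )
    area = np.pi * g.D * g.dx * _UM2_TO_CM2
    cm = passive.Cm * area * _UF_TO_NF
    gl = passive.GL * area * _MS_TO_US
    D_cm = g.D * 1e-4
    dx_cm = g.dx * 1e-4
    gax = np.pi * D_cm**2 / (4.0 * Rax * dx_cm) * _S_TO_US
    n = g.n_comp
    return CompartmentChain(
        cm=np.full(n, cm),
        gl=np.full(n, gl),
        area_cm2=np.full(n, area),
        g_axon=np.full(n - 1, gax),
        positions=np.arange(n, dtype=float) * g.dx,
        membrane=membrane,
        Rax=Rax,
        geometry=g,
    )


def length_constant(geometry: UnmyelinatedGeometry, GL_density: float, Rax: float) -> float:
    """Passive length constant lambda = sqrt(D / (4*GL*Rax)) in mm.

    ``GL_density`` in mS/cm^2, ``Rax`` in Ohm*cm, diameter from the geometry
    in um.
    """
    if GL_density <= 0 or Rax <= 0:
        raise ValueError("GL and Rax must be positive")
    D_cm = geometry.D * 1e-4
    GL_S = GL_density * 1e-3  # S/cm^2
    lam_cm = np.sqrt(D_cm / (4.0 * GL_S * Rax))
    return float(lam_cm * 10.0)  # cm -> mm
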