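"""Shared fixtures: default axon chains and their simulated traces.

The default myelinated axon (141 nodes, D = 2 um, Ln = 2 um, Li = 200 um,
Rax = 100 Ohm*cm) with a 100 pA x 1 ms step at node #20 and dt = 4 us is used
by many tests; its traces are simulated once per session.
"""

import numpy as np
import pytest

import beifax as bx


@pytest.fixture(scope="session")
def default_stim():
    return bx.IntracellularStep(site=20, amplitude_nA=0.1, duration=1.0)


@pytest.fixture(scope="session")
def beif_chain():
    return bx.build_myelinated(bx.MyelinatedGeometry(), bx.BEIFModel())


@pytest.fixture(scope="session")
def wb_chain():
    return bx.build_myelinated(bx.MyelinatedGeometry(), bx.WBModel())


@pytest.fixture(scope="session")
def beif_trace(beif_chain, default_stim):
    return bx.simulate_chain(beif_chain, default_stim, bx.SolverConfig(duration=8.0))


@pytest.fixture(scope="session")
def wb_trace(wb_chain, default_stim):
    return bx.simulate_chain(wb_chain, default_stim, bx.SolverConfig(duration=8.0))


def upstroke_crossing(trace, comp, level=-30.0):
    """Sub-sample time of the first upward crossing of ``level`` (steep part
    of the upstroke, so timing is precise)."""
    v = trace.voltage(comp)
    t = trace.times
    i = int(np.argmax(v > level))
    assert i > 0, f"compartment {comp} never crosses {level} mV"
    f = (level - v[i - 1]) / (v[i] - v[i - 1])
    return t[i - 1] + f * (t[i] - t[i - 1])


def aligned_waveform_diff(trace, comp_a, comp_b, pre=0.5, post=0.5):
    """Max abs difference between the spike waveforms of two compartments
    after aligning them by their upstroke-crossing times.  The window covers
    ``pre`` ms before to ``post`` ms after the crossing (foot, upstroke, peak
    and main downstroke of the action potential)."""
    t = trace.times
    ta = upstroke_crossing(trace, comp_a)
    tb = upstroke_crossing(trace, comp_b)
    va, vb = trace.voltage(comp_a), trace.voltage(comp_b)
    mask = (t >= ta - pre) & (t <= ta + post)
    vb_shifted = np.interp(t[mask] + (tb - ta), t, vb)
    return float(np.max(np.abs(va[mask] - vb_shifted)))
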