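"""Integrator tests: passive-spread oracle, fixed points, scheme agreement,
stability, and trace plumbing."""

import numpy as np
import pytest
from scipy.linalg import expm

import beifax as bx
from beifax.integrate import _AxialOperator, step_chain


def passive_chain(n=5, EL=0.0):
    """A chain whose membrane is purely passive (WB with zeroed Na/K
    conductances), used as a linear-system oracle."""
    params = bx.WBParams(
        passive=bx.PassiveParams(Cm=1.0, GL=0.1, EL=EL), GNa=0.0, GK=0.0,
        EK=EL - 25.0, ENa=EL + 120.0,
    )
    geom = bx.MyelinatedGeometry(n_nodes=n)
    return bx.build_myelinated(geom, bx.WBModel(params))


class TestPassiveSpread:
    def test_matches_matrix_exponential(self):
        # dV/dt = C^-1 (L - diag(gl)) V for EL = 0; compare the hybrid
        # stepper against the exact dense solution on 5 compartments
        chain = passive_chain(5)
        op = _AxialOperator(chain, dt=1e-4)
        L = np.diag(op.diag) + np.diag(op.off, 1) + np.diag(op.off, -1)
        A = (L - np.diag(chain.gl)) / chain.cm[:, None]

        state = chain.membrane.init_state(5)
        state["V"] = np.array([0.0, 0.0, 1.0, 0.0, 0.0])
        V0 = state["V"].copy()
        dt, n_steps = 1e-4, 200  # 0.02 ms total
        axop = _AxialOperator(chain, dt)
        for k in range(n_steps):
            step_chain(chain, state, k * dt, dt, _op=axop)
        exact = expm(A * dt * n_steps) @ V0
        assert np.allclose(state["V"], exact, atol=1e-6)

    def test_spread_is_symmetric(self):
        chain = passive_chain(5)
        state = chain.membrane.init_state(5)
        state["V"] = np.array([0.0, 0.0, 1.0, 0.0, 0.0])
        axop = _AxialOperator(chain, 0.001)
        for k in range(50):
            step_chain(chain, state, k * 0.001, 0.001, _op=axop)
        V = state["V"]
        assert V[1] == pytest.approx(V[3], rel=1e-12)
        assert V[0] == pytest.approx(V[4], rel=1e-12)
        assert V[2] > V[1] > V[0] > 0

    def test_charge_conserved_up_to_leak(self):
        # with EL = 0 the total charge sum(cm*V) decays exactly at the
        # uniform leak rate gl/cm; axial coupling only redistributes it
        chain = passive_chain(5)
        state = chain.membrane.init_state(5)
        state["V"] = np.array([0.0, 0.0, 1.0, 0.0, 0.0])
        q0 = np.sum(chain.cm * state["V"])
        dt, n_steps = 1e-4, 100
        axop = _AxialOperator(chain, dt)
        for k in range(n_steps):
            step_chain(chain, state, k * dt, dt, _op=axop)
        q = np.sum(chain.cm * state["V"])
        decay = np.exp(-(chain.gl[0] / chain.cm[0]) * dt * n_steps)
        assert q == pytest.approx(q0 * decay, rel=1e-4)

    def test_crank_nicolson_stable_beyond_explicit_limit(self):
        # the explicit axial limit for this geometry is dt = 4 us; euler-cn
        # must remain bounded at 10x the default step
        chain = passive_chain(9)
        state = chain.membrane.init_state(9)
        state["V"] = np.zeros(9)
        state["V"][4] = 10.0
        dt = 0.04  # 40 us
        axop = _AxialOperator(chain, dt)
        for k in range(500):
            step_chain(chain, state, k * dt, dt, _op=axop)
        assert np.all(np.abs(state["V"]) <= 10.0)


class TestRestingChain:
    def test_beif_chain_stays_at_rest(self, beif_chain):
        trace = bx.simulate_chain(beif_chain, None, bx.SolverConfig(duration=2.0))
        rest = beif_chain.membrane.resting_potential()
        assert np.max(np.abs(trace.V - rest)) < 1e-6
        assert all(len(e) == 0 for e in trace.events)


class TestSchemes:
    def test_euler_and_hybrid_agree_when_both_stable(self, beif_chain, default_stim):
        # at dt = 2 us (inside the explicit axial stability region) the two
        # schemes' spike-peak times must agree to within 2 dt
        dt = 0.002
        cfg = lambda s: bx.SolverConfig(dt=dt, duration=6.0, scheme=s)
        tr_cn = bx.simulate_chain(beif_chain, default_stim, cfg("euler-cn"))
        tr_eu = bx.simulate_chain(beif_chain, default_stim, cfg("euler"))
        for node in (40, 90):
            d = abs(bx.spike_peak_time(tr_cn, node) - bx.spike_peak_time(tr_eu, node))
            assert d < 2 * dt

    def test_invalid_solver_settings(self):
        with pytest.raises(ValueError):
            bx.SolverConfig(dt=0.0)
        with pytest.raises(ValueError):
            bx.SolverConfig(scheme="rk4")


class TestPropagation:
    def test_wb_one_spike_per_node_with_ordered_peaks(self, wb_trace):
        # stable orthodromic conduction: every node past the stimulated one
        # spikes exactly once, with strictly increasing peak times
        peaks = []
        for node in range(21, 142):
            assert len(wb_trace.events[node - 1]) == 1
            peaks.append(bx.spike_peak_time(wb_trace, node))
        # strictly ordered away from the sealed far end; the last few nodes
        # fire nearly simultaneously (terminal boundary effect) so ties at
        # the 4-us sampling are allowed there
        assert np.all(np.diff(peaks) >= 0)
        assert np.all(np.diff(peaks[: 135 - 21]) > 0)

    def test_beif_conducts_with_wider_spike_than_wb(self, beif_trace, wb_trace):
        # width at half height of the propagating spike, node #60
        def half_width(trace):
            v = trace.voltage(60)
            rest = v[0]
            half = rest + (v.max() - rest) / 2
            above = v > half
            return np.count_nonzero(above) * trace.dt * trace.stride

        assert len(beif_trace.events[59]) == 1
        assert half_width(beif_trace) > half_width(wb_trace)

    def test_stimulus_site_validation(self, beif_chain):
        bad = bx.IntracellularStep(site=500, amplitude_nA=0.1)
        with pytest.raises(ValueError, match="site"):
            bx.simulate_chain(beif_chain, bad, bx.SolverConfig(duration=0.1))


class TestTracePlumbing:
    def test_stride_and_export(self, beif_chain, default_stim, tmp_path):
        cfg = bx.SolverConfig(duration=1.0, record_stride=10)
        trace = bx.simulate_chain(beif_chain, default_stim, cfg)
        assert np.allclose(np.diff(trace.times), 0.04)  # dt * stride
        path = tmp_path / "trace.tsv"
        trace.to_delimited(path)
        data = np.loadtxt(path, skiprows=1)
        assert data.shape[1] == beif_chain.n + 1

    def test_events_table_format(self, beif_trace):
        tab = beif_trace.events_table()
        assert tab.shape[1] == 2
        assert tab[:, 0].min() >= 1 and tab[:, 0].max() <= 141
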