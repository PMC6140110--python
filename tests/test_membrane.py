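"""Unit tests for the three point-membrane models."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import beifax as bx
from beifax.membrane import _wb_default_rates, step_point


RATES = _wb_default_rates()


class TestRateFunctions:
    @pytest.mark.parametrize(
        "name, V, expected",
        [
            # removable singularity of the linear-over-expm1 form: limit a*k
            ("alpha_n", -34.0, 0.5),
            # pure-exponential forms at their reference voltage: exp(0) = 1
            ("beta_n", -44.0, 0.625),
            ("alpha_h", -58.0, 0.35),
            ("beta_m", -60.0, 20.0),
            # sigmoid at its reference voltage: amplitude / 2
            ("beta_h", -28.0, 2.5),
            ("alpha_m", -35.0, 5.0),
        ],
    )
    def test_printed_values(self, name, V, expected):
        assert bx.eval_rate(RATES[name], V) == pytest.approx(expected, rel=1e-12)

    @pytest.mark.parametrize("name", ["alpha_n", "alpha_m"])
    def test_continuity_across_singularity(self, name):
        c = RATES[name]
        lo = bx.eval_rate(c, c.Vref - 1e-6)
        hi = bx.eval_rate(c, c.Vref + 1e-6)
        at = bx.eval_rate(c, c.Vref)
        assert lo == pytest.approx(at, rel=1e-6)
        assert hi == pytest.approx(at, rel=1e-6)

    def test_nonfinite_voltage_rejected(self):
        with pytest.raises(ValueError):
            bx.eval_rate(RATES["alpha_n"], np.nan)

    def test_zero_slope_rejected(self):
        with pytest.raises(ValueError):
            bx.RateFunctionCoeffs(1.0, -30.0, 0.0, "sigmoid")


class TestWBCurrents:
    def setup_method(self):
        self.model = bx.WBModel()

    def _state(self, V, m, h, n):
        arr = lambda x: np.atleast_1d(np.asarray(x, dtype=float))
        return {"V": arr(V), "m": arr(m), "h": arr(h), "n": arr(n)}

    def test_closed_gates_carry_no_current(self):
        assert self.model.active_current(self._state(-50.0, 0, 0, 0)) == 0.0

    def test_zero_driving_force(self):
        s = self._state(self.model.p.ENa, 1, 1, 0)
        assert self.model.active_current(s) == 0.0

    def test_half_open_gates(self):
        # direct evaluation: GNa*0.5^3*0.5*(55-(-65)) + GK*0.5^4*(-90-(-65))
        s = self._state(-65.0, 0.5, 0.5, 0.5)
        expected = 35.0 * 0.0625 * 120.0 + 15.0 * 0.0625 * (-25.0)
        assert self.model.active_current(s) == pytest.approx(expected, rel=1e-12)

    def test_steady_state_gates_have_zero_derivative(self):
        V = -55.0
        g = self.model.steady_gates(V)
        s = self._state(V, g["m"], g["h"], g["n"])
        for d in self.model.gating_derivatives(s):
            assert abs(d) < 1e-12

    def test_derivative_nonnegative_from_zero(self):
        s = self._state(-55.0, 0, 0, 0)
        for d in self.model.gating_derivatives(s):
            assert d >= 0

    def test_resting_step_is_within_euler_truncation(self):
        # V = EL with steady-state gates is not an exact fixed point of the
        # full system, but one 4-us Euler step must move V by far less than
        # the typical spike-upstroke step
        state = self.model.init_state(1)
        V0 = state["V"].copy()
        step_point(self.model, state, dt=0.004)
        assert abs(state["V"][0] - V0[0]) < 1e-3


class TestSpikeCurrents:
    def setup_method(self):
        self.seif = bx.SEIFParams()
        self.beif = bx.BEIFParams()

    def test_seif_at_threshold(self):
        # exp(0) = 1
        assert bx.seif_dep_current(self.seif.VT, self.seif) == pytest.approx(
            0.1 * 3.5, rel=1e-12
        )

    def test_seif_one_slope_above_threshold(self):
        v = self.seif.VT + self.seif.KT
        assert bx.seif_dep_current(v, self.seif) == pytest.approx(
            0.1 * 3.5 * np.e, rel=1e-12
        )

    def test_seif_at_rest(self):
        assert bx.seif_dep_current(-65.3, self.seif) == pytest.approx(
            0.35 * np.exp(-5.1 / 3.5), rel=1e-9
        )

    def test_seif_overflow_guard(self):
        assert np.isfinite(bx.seif_dep_current(1e6, self.seif))

    def test_beif_at_threshold(self):
        p = self.beif
        assert bx.beif_dep_current(p.VT, p) == pytest.approx(
            0.1 * 3.5 * 520 / 521, rel=1e-12
        )

    def test_beif_ceiling(self):
        p = self.beif
        ceiling = p.passive.GL * p.KT * p.AT
        assert bx.beif_dep_current(1e4, p) == pytest.approx(ceiling, rel=1e-6)
        V = np.linspace(-100.0, 60.0, 801)
        I = bx.beif_dep_current(V, p)
        assert np.all(I > 0)
        assert np.all(I < ceiling)
        assert np.all(np.diff(I) > 0)  # strictly increasing
        # far above threshold the bound saturates to the ceiling within
        # float resolution but is never exceeded
        assert np.all(bx.beif_dep_current(np.array([100.0, 1e4]), p) <= ceiling)

    def test_subthreshold_agreement_bound(self):
        # relative deviation from the sEIF exponential is (e^x/AT)/(1+e^x/AT)
        # <= e^x/AT for x = (V-VT)/KT <= 0
        p = self.beif
        V = np.linspace(-90.0, p.VT, 200)
        rel = np.abs(
            bx.beif_dep_current(V, p) - bx.seif_dep_current(V, self.seif)
        ) / bx.seif_dep_current(V, self.seif)
        bound = np.exp((V - p.VT) / p.KT) / p.AT
        assert np.all(rel <= bound + 1e-12)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.floats(min_value=-120.0, max_value=60.0))
    def test_beif_bounded_everywhere(self, V):
        p = self.beif
        I = float(bx.beif_dep_current(V, p))
        assert 0 < I < p.passive.GL * p.KT * p.AT


class TestRepolarizingConductance:
    def setup_method(self):
        self.p = bx.BEIFParams()

    def test_vanishes_at_onset(self):
        assert bx.beif_rep_conductance(0.0, self.p) == 0.0

    def test_peak_at_tau(self):
        # max of s*exp(1-s) is 1 at s = 1, so the peak is GL*Arep = 9 mS/cm^2
        g = bx.beif_rep_conductance(self.p.tau_rep, self.p)
        assert g == pytest.approx(0.1 * 90.0, rel=1e-12)
        eps = 1e-4
        assert g > bx.beif_rep_conductance(self.p.tau_rep - eps, self.p)
        assert g > bx.beif_rep_conductance(self.p.tau_rep + eps, self.p)

    def test_late_decay(self):
        g = bx.beif_rep_conductance(5 * self.p.tau_rep, self.p)
        assert g == pytest.approx(5 * np.exp(-4.0) * 9.0, rel=1e-12)

    def test_negative_time_rejected(self):
        with pytest.raises(ValueError):
            bx.beif_rep_conductance(-0.1, self.p)


class TestPointDynamics:
    def test_beif_resting_fixed_point(self):
        # root of GL*(EL-V) + I_dep(V): about -64.2 mV with default params
        model = bx.BEIFModel()
        rest = model.resting_potential()
        assert rest == pytest.approx(-64.18, abs=0.05)
        state = model.init_state(1)
        step_point(model, state, dt=0.004)
        assert abs(state["V"][0] - rest) < 1e-9

    def test_seif_held_at_reset_during_refractory(self):
        model = bx.SEIFModel()
        state = model.init_state(1)
        state["refrac"][0] = model.p.tau_ref
        state["V"][0] = model.p.Vreset
        for _ in range(100):  # 0.4 ms of strong input, all within tau_ref
            step_point(model, state, dt=0.004, I_inj=100.0)
            assert state["V"][0] == model.p.Vreset

    def test_zero_stimulus_no_spikes(self):
        for model in (bx.WBModel(), bx.SEIFModel(), bx.BEIFModel()):
            spikes, _ = bx.simulate_point(model, [0.0], duration=50.0)
            assert len(spikes[0]) == 0

    def test_beif_periodic_spiking_with_dead_time(self):
        # strongly driven bEIF spikes periodically; the repolarizing episode
        # enforces a minimum inter-spike interval of order tau_rep
        model = bx.BEIFModel()
        spikes, _ = bx.simulate_point(model, [1.0], duration=200.0)
        s = spikes[0]
        assert len(s) > 3
        isi = np.diff(s)
        assert np.all(isi > model.p.tau_rep)
        assert np.std(isi[1:]) < 0.01 * np.mean(isi[1:])  # periodic

    def test_invalid_dt_rejected(self):
        model = bx.BEIFModel()
        with pytest.raises(ValueError):
            step_point(model, model.init_state(1), dt=0.0)


class TestParameterValidation:
    def test_wb_reversal_ordering(self):
        with pytest.raises(ValueError):
            bx.WBParams(EK=-60.0)  # EK > EL

    def test_seif_threshold_ordering(self):
        with pytest.raises(ValueError):
            bx.SEIFParams(Vreset=-50.0)  # Vreset > VT

    def test_beif_positivity(self):
        with pytest.raises(ValueError):
            bx.BEIFParams(AT=-1.0)
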