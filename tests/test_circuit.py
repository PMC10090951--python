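"""Normalized-Hill algebra, right-hand sides, solvers and model variants."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import gtpase_circuit as gc
from gtpase_circuit.circuit import (DegenerateHillError, NonFiniteStateError,
                                    _HillTable, _rhs)
from gtpase_circuit.params import STATE_NAMES


def valid_hill():
    """Strategy over HillParams with real normalisation constants."""
    return st.tuples(
        st.floats(0.05, 0.9), st.floats(0.3, 6.0),
    ).filter(lambda t: t[0] ** t[1] < 0.499).map(lambda t: gc.HillParams(*t))


class TestHillConstants:
    def test_printed_formula_example(self):
        B, K = gc.hill_constants(gc.HillParams(0.5, 2.0))
        assert B == pytest.approx(1.5)
        assert K == pytest.approx(0.70711, abs=1e-5)

    def test_zero_denominator_is_degenerate(self):
        # ec50**n == 0.5 zeroes B's denominator; rejected at construction
        with pytest.raises(ValueError):
            gc.HillParams(0.5, 1.0)

    def test_k_not_real_is_degenerate(self):
        # ec50**n > 0.5 makes B < 1 and K complex
        with pytest.raises(DegenerateHillError):
            gc.hill_constants(gc.HillParams(0.8, 1.0))

    @settings(max_examples=200, deadline=None)
    @given(valid_hill())
    def test_defining_identity(self, h):
        B, K = gc.hill_constants(h)
        assert B * h.ec50 ** h.n / (K ** h.n + h.ec50 ** h.n) == \
            pytest.approx(0.5, abs=1e-12)


class TestNormalizedHill:
    @settings(max_examples=100, deadline=None)
    @given(valid_hill())
    def test_anchor_points(self, h):
        assert gc.normalized_hill(0.0, h) == 0.0
        assert gc.normalized_hill(h.ec50, h) == pytest.approx(0.5, abs=1e-12)
        assert gc.normalized_hill(1.0, h) == pytest.approx(1.0)

    def test_derived_value(self):
        # B = 1.5, K^2 = 0.5: 1.5*0.0625/0.5625
        assert gc.normalized_hill(0.25, gc.HillParams(0.5, 2.0)) == \
            pytest.approx(0.16667, abs=1e-5)

    def test_saturation_and_negative_clamp(self):
        h = gc.HillParams(0.5, 2.0)
        assert gc.normalized_hill(1.7, h) == 1.0
        assert gc.normalized_hill(-0.3, h) == 0.0

    @settings(max_examples=50, deadline=None)
    @given(valid_hill())
    def test_monotone_nondecreasing(self, h):
        x = np.linspace(-0.2, 1.3, 400)
        y = gc.normalized_hill(x, h)
        assert np.all(np.diff(y) >= -1e-12)


class TestMgapDrive:
    def test_and_gate_zero_inputs(self, params):
        assert gc.mgap_drive(0.0, 0.0, params, "AND") == 0.0

    def test_and_gate_half_times_one(self, params):
        ec50_2 = params.hill[1].ec50
        assert gc.mgap_drive(ec50_2, 1.0, params, "AND") == \
            pytest.approx(0.5)

    def test_or_gate_printed_constants(self, params):
        # 0.24*0.5 + 0.0017*0.5 with both facts at their half-max point
        ec50_2 = params.hill[1].ec50
        ec50_3 = params.hill[2].ec50
        assert gc.mgap_drive(ec50_2, ec50_3, params, "OR") == \
            pytest.approx(0.12085, abs=1e-5)


class TestCircuitRhs:
    def test_fixed_point_has_zero_derivatives(self, params, coupled, basal):
        rhs = gc.circuit_rhs(basal, 0.0, params, coupled)
        assert np.max(np.abs(rhs)) < 1e-8

    def test_no_secretion_means_pure_death(self, params, coupled, basal):
        state = gc.CircuitState(*basal.as_array()[:5], S=0.0, X=3.0)
        rhs = gc.circuit_rhs(state, 0.0, params, coupled)
        assert rhs[6] == pytest.approx(-params.mu * 3.0)

    def test_carrying_capacity_caps_growth(self, params, coupled, basal):
        state = gc.CircuitState(*basal.as_array()[:5], S=1.0,
                                X=params.K_capacity)
        rhs = gc.circuit_rhs(state, 0.0, params, coupled)
        assert rhs[6] == pytest.approx(-params.mu * params.K_capacity)

    def test_nonfinite_state_rejected(self, params, coupled):
        with pytest.raises(NonFiniteStateError):
            gc.circuit_rhs(np.array([np.nan] + [0.1] * 6), 0.0, params,
                           coupled)


class TestPreEquilibrate:
    def test_basal_mgef_follows_basal_rate(self, params, coupled):
        # with stimulus 0, fact1(0) = 0 so mGEF* = k_mGEF * Y_mGEF_max
        ss = gc.pre_equilibrate(params, coupled, 0.0)
        assert ss.mGEF == pytest.approx(
            params.k_mGEF * params.Y_mGEF_max, rel=1e-6)
        zero_k = params.replace(k_mGEF=0.0)
        ss0 = gc.pre_equilibrate(zero_k, coupled, 0.0)
        assert ss0.mGEF == pytest.approx(0.0, abs=1e-9)

    def test_start_independence(self, params, coupled, basal):
        alt = gc.pre_equilibrate(params, coupled,
                                 init=gc.CircuitState.uniform(0.05))
        assert np.max(np.abs(alt.as_array() - basal.as_array())) < 1e-6

    @pytest.mark.parametrize("kind", gc.ModelVariant.KINDS)
    @pytest.mark.parametrize("gate", gc.ModelVariant.GATES)
    def test_fixed_point_residual_all_variants(self, params, kind, gate):
        v = gc.ModelVariant(kind, gate)
        ss = gc.pre_equilibrate(params, v)
        assert np.max(np.abs(gc.circuit_rhs(ss, 0.0, params, v))) < 1e-6


class TestSimulateDeterministic:
    def test_fixed_point_stays_constant(self, params, coupled, basal):
        tc = gc.simulate_deterministic(params, coupled, 0.0, (0, 200),
                                       init=basal)
        assert np.max(np.abs(tc.y - basal.as_array())) < 1e-6

    def test_transient_overshoot_of_active_arf1(self, params, coupled, basal):
        tc = gc.simulate_deterministic(params, coupled, gc.STIMULUS_50NM,
                                       (0, 1440), init=basal)
        mg = tc.variable("mGstar")
        assert mg.max() > 1.05 * mg[-1]        # rises then falls below peak

    def test_giv_depletion_equals_uncoupling_for_arf1_block(self, params):
        t = np.linspace(0, 1440, 500)
        traces = {}
        for v in (gc.ModelVariant.giv_depleted(), gc.ModelVariant.uncoupled()):
            init = gc.pre_equilibrate(params, v)
            traces[v.kind] = gc.simulate_deterministic(
                params, v, gc.STIMULUS_50NM, (0, 1440), init=init, t_eval=t)
        for var in ("mGEF", "mGAP", "mGstar"):
            dev = np.abs(traces["giv_depleted"].variable(var)
                         - traces["uncoupled_single_switch"].variable(var))
            assert dev.max() < 1e-6, var
        # the trimeric switch is where the two topologies differ
        dev_tGEF = np.abs(traces["giv_depleted"].variable("tGEF")
                          - traces["uncoupled_single_switch"].variable("tGEF"))
        assert dev_tGEF.max() > 0.05

    def test_fractional_activations_bounded_without_basal_rates(self, params,
                                                                coupled):
        p0 = params.replace(k_mGEF=0.0, k_mGAP=0.0, k_mGstar=0.0,
                            k_tGEF=0.0, k_tGstar=0.0)
        init = gc.pre_equilibrate(p0, coupled)
        tc = gc.simulate_deterministic(p0, coupled, 0.46, (0, 1440),
                                       init=init)
        frac = tc.y[:, :5]
        assert frac.min() >= -1e-9
        assert frac.max() <= 1.0 + 1e-9

    def test_rk4_brute_force_oracle(self, params, coupled, basal):
        """Fixed-step RK4 agrees with the adaptive solver on a 60-min window."""
        ht = _HillTable(params.hill)
        dt = 0.002
        n = int(60 / dt)
        y = basal.as_array()
        keep = {}
        for i in range(n + 1):
            t = i * dt
            if abs(t - round(t)) < dt / 2 and round(t) % 10 == 0:
                keep[round(t)] = y.copy()
            k1 = _rhs(y, 0.23, params, coupled, ht)
            k2 = _rhs(y + dt / 2 * k1, 0.23, params, coupled, ht)
            k3 = _rhs(y + dt / 2 * k2, 0.23, params, coupled, ht)
            k4 = _rhs(y + dt * k3, 0.23, params, coupled, ht)
            y = y + dt / 6 * (k1 + 2 * k2 + 2 * k3 + k4)
        t_eval = np.array(sorted(keep))
        tc = gc.simulate_deterministic(params, coupled, 0.23, (0, 60),
                                       init=basal, t_eval=t_eval)
        rk4 = np.array([keep[t] for t in sorted(keep)])
        rel = np.abs(tc.y - rk4) / np.maximum(np.abs(rk4), 1e-6)
        assert rel.max() < 1e-4

    def test_timecourse_csv_roundtrip(self, params, coupled, basal, tmp_path):
        tc = gc.simulate_deterministic(params, coupled, 0.23, (0, 30),
                                       init=basal)
        path = tmp_path / "tc.csv"
        tc.to_csv(path)
        back = gc.TimeCourse.from_csv(path)
        assert np.allclose(back.y, tc.y)
        assert back.stimulus == tc.stimulus


class TestParamsIO:
    def test_yaml_roundtrip(self, params, tmp_path):
        path = tmp_path / "p.yaml"
        gc.save_parameters(params, path)
        again = gc.load_parameters(path)
        assert again == params

    def test_with_value_hill_key(self, params):
        p2 = params.with_value("hill4_ec50", 0.42)
        assert p2.hill[3].ec50 == 0.42
        with pytest.raises(KeyError):
            params.with_value("no_such_param", 1.0)

    def test_invariants_enforced(self, params):
        with pytest.raises(ValueError):
            params.replace(tau_mGEF=-1.0)
        with pytest.raises(ValueError):
            gc.HillParams(1.2, 2.0)
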