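"""Unit and property tests of the BCPNN learning-rule kernel."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from ebcpnn.kernel import (
    FloatArithmetic, OutOfOrderError, PreTraceState, ProbabilityEstimate,
    SpikeTrain, SynapseTraceState, TraceCorruptionError, compute_bias,
    compute_weight, decay_trace, event_driven_trajectory,
    rate_based_reference, reconstruct, time_driven_oracle,
    update_pre_on_spike, update_post_on_spike, update_synapse_on_pre,
    update_synapse_on_post,
)
from ebcpnn.params import BCPNNParams, DerivedCoefficients

from conftest import poisson_pair


class TestDecayTrace:
    @pytest.mark.parametrize("value,dt,tau,expected", [
        (1.0, 0.0, 10.0, 1.0),
        (0.0, 37.2, 10.0, 0.0),
        (1.0, 10.0, 10.0, math.exp(-1.0)),
    ])
    def test_examples(self, value, dt, tau, expected):
        assert decay_trace(value, dt, tau) == pytest.approx(expected,
                                                            abs=1e-9)

    def test_negative_dt_is_out_of_order(self):
        with pytest.raises(OutOfOrderError):
            decay_trace(1.0, -0.5, 10.0)

    @given(v=st.floats(0, 50), a=st.floats(0, 100), b=st.floats(0, 100),
           tau=st.floats(1, 2000))
    @settings(max_examples=200, deadline=None, derandomize=True)
    def test_semigroup(self, v, a, b, tau):
        """Decaying over a then b equals decaying over a+b."""
        two_step = decay_trace(decay_trace(v, a, tau), b, tau)
        one_step = decay_trace(v, a + b, tau)
        assert two_step == pytest.approx(one_step, rel=1e-12, abs=1e-300)


class TestPrimaryTraceUpdates:
    def test_fresh_state_unit_increment(self, val_params):
        out = update_pre_on_spike(PreTraceState(), 0.0, val_params)
        assert (out.z_star, out.p_star, out.t_last) == (1.0, 1.0, 0.0)

    def test_decay_then_increment(self, val_params):
        state = PreTraceState(z_star=1.0, p_star=1.0, t_last=0.0)
        out = update_pre_on_spike(state, 10.0, val_params)
        assert out.z_star == pytest.approx(math.exp(-1.0) + 1.0, rel=1e-12)
        assert out.p_star == pytest.approx(math.exp(-0.01) + 1.0, rel=1e-12)

    def test_complete_decay(self, val_params):
        state = PreTraceState(z_star=5.0, p_star=5.0, t_last=0.0)
        out = update_pre_on_spike(state, 1e9, val_params)
        assert out.z_star == pytest.approx(1.0)
        assert out.p_star == pytest.approx(1.0)

    def test_out_of_order_rejected(self, val_params):
        state = PreTraceState(t_last=10.0)
        with pytest.raises(OutOfOrderError):
            update_pre_on_spike(state, 5.0, val_params)


class TestSynapseTraceUpdates:
    def test_zero_trace_zero_increment(self, val_params):
        out = update_synapse_on_pre(SynapseTraceState(), 123.0, 0.0,
                                    val_params)
        assert out.pij_star == 0.0

    def test_no_decay_unit_post_trace(self, val_params):
        out = update_synapse_on_pre(SynapseTraceState(t_last=5.0), 5.0, 1.0,
                                    val_params)
        assert out.pij_star == pytest.approx(1.0)

    def test_pre_update_decays_with_tau_p(self, val_params):
        out = update_synapse_on_pre(
            SynapseTraceState(pij_star=2.0, t_last=0.0),
            val_params.tau_p, 0.5, val_params)
        assert out.pij_star == pytest.approx(2 * math.exp(-1) + 0.5,
                                             rel=1e-12)

    def test_post_update_symmetric(self, val_params):
        out = update_synapse_on_post(
            SynapseTraceState(pij_star=1.0, t_last=0.0),
            val_params.tau_p, 1.0, val_params)
        assert out.pij_star == pytest.approx(math.exp(-1) + 1.0, rel=1e-12)

    def test_pre_post_role_symmetry(self):
        """Swapping pre/post roles with mirrored parameters yields the
        same coactivation trajectory."""
        p = BCPNNParams(f_max=50, tau_zi=10, tau_zj=40, tau_p=1000)
        pm = BCPNNParams(f_max=50, tau_zi=40, tau_zj=10, tau_p=1000)
        si = SpikeTrain(np.array([5.0, 40.0, 90.0]))
        sj = SpikeTrain(np.array([20.0, 60.0]))
        ev = event_driven_trajectory(si, sj, p, eval_times=[100.0])
        ev_m = event_driven_trajectory(sj, si, pm, eval_times=[100.0])
        assert ev["p_ij"][0] == pytest.approx(ev_m["p_ij"][0], rel=1e-12)


class TestReconstructionAndMapping:
    def test_zero_states_zero_probabilities(self, val_params, val_coeffs):
        est = reconstruct(PreTraceState(), PreTraceState(),
                          SynapseTraceState(), 50.0, val_params, val_coeffs)
        assert (est.p_i, est.p_j, est.p_ij) == (0.0, 0.0, -0.0)

    def test_reconstruction_coefficient_example(self):
        """a_i = 1/(f_max (tau_zi - tau_p)) gives P_i = a_i (Z* - P*)."""
        p = BCPNNParams(f_max=50, tau_zi=10, tau_zj=10, tau_p=1000)
        co = DerivedCoefficients.from_params(p)
        assert co.a_i == pytest.approx(-0.020202020, rel=1e-6)
        est = reconstruct(PreTraceState(1.0, 5.0, 10.0), PreTraceState(),
                          SynapseTraceState(), 10.0, p, co)
        assert est.p_i == pytest.approx(0.080808, abs=1e-6)

    @pytest.mark.parametrize("pi,pj,pij,expected", [
        (0.0, 0.0, 0.0, 0.0),
        (0.5, 0.5, 0.25, math.log(0.2504 / 0.2704)),
        (0.5, 0.5, 0.5, math.log(0.5004 / 0.2704)),
    ])
    def test_weight_examples(self, val_params, pi, pj, pij, expected):
        est = ProbabilityEstimate(pi, pj, pij)
        assert compute_weight(est, val_params) == pytest.approx(expected,
                                                                abs=1e-9)

    def test_weight_rejects_corrupt_traces(self, val_params):
        with pytest.raises(TraceCorruptionError):
            compute_weight(ProbabilityEstimate(0.5, 0.5, -1.0), val_params)

    @pytest.mark.parametrize("pj,expected", [
        (0.98, 0.0),                       # 1 - eps with eps = 0.02
        (0.0, math.log(0.02)),
        (1.0, math.log(1.02)),
    ])
    def test_bias_examples(self, val_params, pj, expected):
        assert compute_bias(pj, val_params) == pytest.approx(expected,
                                                             abs=1e-9)

    @given(z_i=st.floats(0, 30), p_i=st.floats(0, 60),
           z_j=st.floats(0, 30), p_j=st.floats(0, 60),
           pij=st.floats(0, 60), t=st.floats(0, 100))
    @settings(max_examples=200, deadline=None, derandomize=True)
    def test_continuity_at_spikes(self, val_params, val_coeffs,
                                  z_i, p_i, z_j, p_j, pij, t):
        """The reconstructed probabilities do not jump at spike events:
        the unit increments of Z* and P* cancel, and the Z_j*-sized jumps
        of Z_i* Z_j* and P_ij* cancel."""
        pre = PreTraceState(z_i, p_i, t)
        post = PreTraceState(z_j, p_j, t)
        syn = SynapseTraceState(pij, t)
        before = reconstruct(pre, post, syn, t, val_params, val_coeffs)
        # presynaptic spike at t
        syn2 = update_synapse_on_pre(syn, t, post.z_star, val_params)
        pre2 = update_pre_on_spike(pre, t, val_params)
        after = reconstruct(pre2, post, syn2, t, val_params, val_coeffs)
        for a, b in ((before.p_i, after.p_i), (before.p_j, after.p_j),
                     (before.p_ij, after.p_ij)):
            assert abs(a - b) <= 1e-12 * max(1.0, abs(a))
        # postsynaptic spike at t
        syn3 = update_synapse_on_post(syn, t, pre.z_star, val_params)
        post3 = update_post_on_spike(post, t, val_params)
        after3 = reconstruct(pre, post3, syn3, t, val_params, val_coeffs)
        for a, b in ((before.p_i, after3.p_i), (before.p_j, after3.p_j),
                     (before.p_ij, after3.p_ij)):
            assert abs(a - b) <= 1e-12 * max(1.0, abs(a))


class TestOracleEquivalence:
    @pytest.mark.parametrize("seed", [11, 12, 13])
    def test_event_driven_matches_fine_step_integration(self, val_params,
                                                        seed):
        """Closed-form event-driven updates reproduce explicit fine-step
        integration of the trace ODEs at every presynaptic spike time to
        better than 1e-3 relative."""
        si, sj = poisson_pair(seed, 20.0, 20.0, 2000.0)
        orc = time_driven_oracle(si, sj, val_params, dt=0.01, t_end=2000.0)
        ev = event_driven_trajectory(si, sj, val_params)
        idx = np.round(ev["t"] / 0.01).astype(int)
        for key in ("p_i", "p_j", "p_ij", "w", "i_beta"):
            scale = max(1.0, np.max(np.abs(orc[key])))
            err = np.max(np.abs(orc[key][idx] - ev[key])) / scale
            assert err <= 1e-3, f"{key}: {err}"

    def test_error_shrinks_with_oracle_step(self, val_params):
        si, sj = poisson_pair(21, 30.0, 30.0, 500.0, grid=0.002)
        ev = event_driven_trajectory(si, sj, val_params)
        errs = []
        for dt in (0.02, 0.002):
            orc = time_driven_oracle(si, sj, val_params, dt=dt, t_end=500.0)
            idx = np.round(ev["t"] / dt).astype(int)
            errs.append(np.max(np.abs(orc["w"][idx] - ev["w"])))
        assert errs[1] < errs[0] / 5

    def test_empty_trains(self, val_params):
        orc = time_driven_oracle(SpikeTrain(np.array([])),
                                 SpikeTrain(np.array([])), val_params,
                                 dt=0.1, t_end=100.0)
        assert np.all(orc["w"] == 0.0)
        assert np.allclose(orc["i_beta"],
                           val_params.beta_gain * math.log(val_params.eps))

    def test_single_spike_impulse_response(self, val_params):
        orc = time_driven_oracle(SpikeTrain(np.array([10.0])),
                                 SpikeTrain(np.array([])), val_params,
                                 dt=0.01, t_end=60.0)
        jump = 1.0 / (val_params.f_max_ms * val_params.spike_duration
                      * val_params.tau_zi)
        peak = np.max(orc["z_i"])
        assert peak == pytest.approx(jump, rel=1e-3)
        # decays with tau_zi afterwards
        i10 = int(round(10.0 / 0.01))
        i30 = int(round(30.0 / 0.01))
        assert orc["z_i"][i30] / orc["z_i"][i10] == pytest.approx(
            math.exp(-20.0 / val_params.tau_zi), rel=5e-3)


class TestStatisticalProperties:
    def test_stationary_poisson_probability(self, val_params):
        """Time-averaged P_i under stationary Poisson at rate r equals
        r / f_max within three standard errors over 20 seeds."""
        r = 20.0
        vals = []
        for seed in range(30):
            rng = np.random.default_rng(100 + seed)
            n = rng.poisson(r * 1e-3 * 45000)
            st_ = SpikeTrain(np.sort(rng.uniform(0, 45000.0, n)))
            traj = event_driven_trajectory(
                st_, st_, val_params,
                eval_times=np.arange(5000.0, 45000.0, 200.0))
            vals.append(traj["p_i"].mean())
        vals = np.asarray(vals)
        se = vals.std(ddof=1) / math.sqrt(len(vals))
        assert abs(vals.mean() - r / val_params.f_max) <= 3 * se

    def test_weight_sign_structure(self, val_params):
        """Independent spike trains give weights consistent with zero;
        common trains positive; alternating exclusive firing negative."""
        finals = {"independent": [], "common": [], "exclusive": []}
        for seed in range(12):
            rng = np.random.default_rng(300 + seed)
            t_end = 10000.0
            a = np.sort(rng.uniform(0, t_end, rng.poisson(0.02 * t_end)))
            b = np.sort(rng.uniform(0, t_end, rng.poisson(0.02 * t_end)))
            eval_t = [t_end]
            finals["independent"].append(event_driven_trajectory(
                SpikeTrain(a), SpikeTrain(b), val_params,
                eval_times=eval_t)["w"][0])
            finals["common"].append(event_driven_trajectory(
                SpikeTrain(a), SpikeTrain(a), val_params,
                eval_times=eval_t)["w"][0])
            half = 500.0  # alternating 500 ms blocks of exclusive firing
            a_ex = a[(a // half) % 2 == 0]
            b_ex = b[(b // half) % 2 == 1]
            finals["exclusive"].append(event_driven_trajectory(
                SpikeTrain(a_ex), SpikeTrain(b_ex), val_params,
                eval_times=eval_t)["w"][0])
        ind = np.asarray(finals["independent"])
        se = ind.std(ddof=1) / math.sqrt(len(ind))
        assert abs(ind.mean()) <= 3 * se
        assert np.mean(finals["common"]) > 0
        assert np.mean(finals["exclusive"]) < 0


class TestRateBasedReference:
    def test_saturating_rates_drive_probabilities_to_one(self, val_params):
        n = 20001
        r = np.full(n, val_params.f_max)
        ref = rate_based_reference(r, r, val_params, dt=1.0)
        assert ref["p_i"][-1] == pytest.approx(1.0, abs=2e-3)
        assert ref["p_ij"][-1] == pytest.approx(1.0, abs=5e-3)

    def test_constant_rates_reach_stationary_weight(self, val_params):
        kap_i, kap_j = 0.6, 0.3
        n = 30001
        ref = rate_based_reference(
            np.full(n, kap_i * val_params.f_max),
            np.full(n, kap_j * val_params.f_max), val_params, dt=1.0)
        eps = val_params.eps
        expected = math.log((kap_i * kap_j + eps ** 2)
                            / ((kap_i + eps) * (kap_j + eps)))
        assert ref["w"][-1] == pytest.approx(expected, abs=2e-3)

    def test_zero_duration_initial_conditions(self, val_params):
        ref = rate_based_reference(np.zeros(1), np.zeros(1), val_params)
        assert ref["w"][0] == pytest.approx(0.0)
        assert ref["i_beta"][0] == pytest.approx(
            val_params.beta_gain * math.log(val_params.eps))


class TestParameterValidation:
    def test_eps_formula(self):
        p = BCPNNParams(f_max=50, tau_zi=10, tau_zj=10, tau_p=1000)
        assert p.eps == pytest.approx(0.02)
        p2 = BCPNNParams(f_max=20, tau_zi=5, tau_zj=150, tau_p=2000)
        assert p2.eps == pytest.approx(0.025)

    @pytest.mark.parametrize("kwargs", [
        dict(f_max=0, tau_zi=10, tau_zj=10, tau_p=1000),
        dict(f_max=50, tau_zi=1000, tau_zj=10, tau_p=1000),
        dict(f_max=50, tau_zi=10, tau_zj=10, tau_p=10),  # eps >= 1
    ])
    def test_invalid_parameters_rejected(self, kwargs):
        with pytest.raises(ValueError):
            BCPNNParams(**kwargs)

    def test_spike_train_validation(self):
        with pytest.raises(ValueError):
            SpikeTrain(np.array([1.0, 1.0]))
        with pytest.raises(ValueError):
            SpikeTrain(np.array([-1.0, 2.0]))


class TestParameterLoading:
    def test_presets_and_overrides(self, tmp_path):
        import json
        from ebcpnn.params import PRESETS, load_bcpnn_params
        assert load_bcpnn_params("validation_ampa") is PRESETS[
            "validation_ampa"]
        p = load_bcpnn_params({"preset": "attractor_ampa", "w_gain": 0.1})
        assert p.w_gain == 0.1 and p.f_max == 20.0
        path = tmp_path / "params.json"
        path.write_text(json.dumps({"f_max": 50, "tau_zi": 10,
                                    "tau_zj": 10, "tau_p": 1000}))
        assert load_bcpnn_params(path).eps == pytest.approx(0.02)
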