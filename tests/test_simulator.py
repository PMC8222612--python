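"""Numerical integration, outcome classification and cycle extraction."""

import math

import numpy as np
import pytest

from memspike import (
    EMPTY_STIMULUS,
    Pulse,
    StimulusProgram,
    Trajectory,
    build_stimulus,
    classify_outcome,
    compare_plc,
    design_spike,
    extract_cycle,
    integrate,
    plc_waveform,
    predicted_response,
    solve_plc,
)


class TestIntegrate:
    def test_equilibrium_initial_state_stays_put(self, ref):
        traj = integrate("qcoords", (-1.7, -1.7, 0.0), EMPTY_STIMULUS, (0.0, 20.0), ref)
        np.testing.assert_allclose(traj.qM, -1.7, atol=1e-9)
        np.testing.assert_allclose(traj.iL, 0.0, atol=1e-9)

    def test_manifold_form_rejects_stimulus(self, ref):
        stim = StimulusProgram((Pulse(1.0, 1.0, 0.5),))
        with pytest.raises(ValueError):
            integrate("manifold", (0.0, 0.5, 0.0), stim, (0.0, 5.0), ref)

    def test_unknown_form_rejected(self, ref):
        with pytest.raises(ValueError):
            integrate("planar", (0.0, 0.0, 0.0), EMPTY_STIMULUS, (0.0, 1.0), ref)

    def test_pulse_edges_are_exact_samples_and_area_is_booked(self, ref):
        stim = StimulusProgram((Pulse(10.0, 0.5, 1.0),))
        traj = integrate("qcoords", (-2.0, -2.0, 0.0), stim, (0.0, 20.0), ref)
        assert 10.0 in traj.t and 11.0 in traj.t
        before = traj.Q[traj.t == 10.0][0]
        after = traj.Q[traj.t == 11.0][0]
        assert after - before == pytest.approx(0.5, abs=100 * 1e-12)

    def test_index_conserved_on_source_free_segments(self, ref):
        stim = StimulusProgram((Pulse(5.0, 2.5, 1.0),))
        traj = integrate("qcoords", (-2.0, -2.0, 0.0), stim, (0.0, 40.0), ref)
        pre = traj.Q[traj.t <= 5.0]
        post = traj.Q[traj.t >= 6.0]
        assert np.max(np.abs(pre - pre[0])) <= 100 * 1e-12
        assert np.max(np.abs(post - post[0])) <= 100 * 1e-12

    def test_small_area_pulse_lands_on_a_stable_equilibrium(self, ref):
        """Area 0.5 from rest at -2: converges to the equilibrium at -1.5."""
        stim = StimulusProgram((Pulse(10.0, 0.5, 1.0),))
        traj = integrate("qcoords", (-2.0, -2.0, 0.0), stim, (0.0, 160.0), ref)
        outcome = classify_outcome(traj, window=30.0, eps=1e-4)
        assert outcome.kind == "equilibrium"
        assert outcome.value == pytest.approx(-1.5, abs=1e-3)

    def test_large_area_pulse_lands_on_an_oscillatory_manifold(self, ref):
        """Area 2.5 moves the index to 0.5 where a limit cycle attracts."""
        stim = StimulusProgram((Pulse(10.0, 2.5, 1.0),))
        traj = integrate("qcoords", (-2.0, -2.0, 0.0), stim, (0.0, 120.0), ref)
        assert traj.Q[-1] == pytest.approx(0.5, abs=1e-6)
        assert classify_outcome(traj, window=30.0, eps=1e-4).kind == "oscillation"


class TestClassifyOutcome:
    def test_all_zero_trajectory_is_the_origin_equilibrium(self, ref):
        t = np.linspace(0.0, 10.0, 101)
        traj = Trajectory(t, np.zeros_like(t), np.zeros_like(t), np.zeros_like(t), ref, EMPTY_STIMULUS)
        out = classify_outcome(traj, window=5.0, eps=1e-9)
        assert out.kind == "equilibrium" and out.value == 0.0

    def test_window_longer_than_post_stimulus_coverage_errors(self, ref):
        traj = integrate("qcoords", (0.0, 0.1, 0.0), EMPTY_STIMULUS, (0.0, 5.0), ref)
        with pytest.raises(ValueError):
            classify_outcome(traj, window=10.0)


class TestExtractCycle:
    def test_synthetic_plc_trajectory_recovers_its_own_parameters(self, ref):
        plc = solve_plc(ref, 0.3)
        t = np.arange(0.0, 20.0 * plc.period, 0.005)
        qM, iL = plc_waveform(plc, t)
        traj = Trajectory(t, np.full_like(t, 0.3), qM, iL, ref, EMPTY_STIMULUS)
        est = extract_cycle(traj, discard_fraction=0.1)
        assert est.period == pytest.approx(plc.period, rel=1e-6)
        assert est.qM_min == pytest.approx(plc.Q0 - plc.B_hat, abs=1e-4)
        assert est.qM_max == pytest.approx(plc.Q0 + plc.B_hat, abs=1e-4)

    def test_origin_manifold_cycle_close_to_prediction(self, ref):
        traj = integrate("manifold", (0.0, 0.9, 0.0), EMPTY_STIMULUS, (0.0, 80.0), ref)
        est = extract_cycle(traj, discard_fraction=0.5)
        assert est.period == pytest.approx(2.0 * math.pi * math.sqrt(0.15), rel=0.05)
        assert est.qM_max == pytest.approx(2.0, rel=0.1)
        assert est.qM_min == pytest.approx(-2.0, rel=0.1)
        # odd symmetry of the origin manifold
        assert est.qM_min == pytest.approx(-est.qM_max, abs=0.01)

    def test_too_few_crossings_error(self, ref):
        traj = integrate("qcoords", (-1.7, -1.7, 0.0), EMPTY_STIMULUS, (0.0, 10.0), ref)
        with pytest.raises(ValueError):
            extract_cycle(traj)


class TestComparePLC:
    def test_origin_manifold_agreement(self, ref):
        rep = compare_plc(ref, 0.0)
        assert rep.period_rel_err < 0.1
        assert rep.qM_min_err < 0.1 and rep.qM_max_err < 0.1

    def test_sweep_reports_finite_errors(self, ref):
        for q0 in (-0.9, -0.45, 0.45, 0.9):
            rep = compare_plc(ref, q0)
            assert math.isfinite(rep.period_rel_err)
            assert math.isfinite(rep.qM_min_err) and math.isfinite(rep.qM_max_err)

    def test_near_threshold_comparison_still_defined(self, ref):
        rep = compare_plc(ref, 0.99)
        assert rep.plc.B_hat < 0.3
        assert rep.cycle.qM_max - rep.cycle.qM_min < 0.8

    def test_no_cycle_beyond_threshold(self, ref):
        with pytest.raises(ValueError):
            compare_plc(ref, 1.2)


class TestPulseAsymptotics:
    def test_small_width_scaling_of_post_pulse_state(self, ref):
        """Halving the pulse width at fixed area at least roughly halves
        both the charge displacement and the residual inductor current."""
        d = design_spike(ref)
        dqs, dis = [], []
        for frac in (0.1, 0.05, 0.025):
            delta = frac * d.T
            stim = StimulusProgram((Pulse(1.0, d.Lambda, delta),))
            traj = integrate(
                "qcoords", (d.Q0_init, d.Q0_init, 0.0), stim, (0.0, 1.0 + delta), ref
            )
            dqs.append(abs(traj.qM[-1] - d.Q0_init))
            dis.append(abs(traj.iL[-1]))
        for seq in (dqs, dis):
            for wide, narrow in zip(seq, seq[1:]):
                assert narrow < 0.7 * wide


class TestEndToEndSpike:
    def test_designed_spike_returns_to_rest_and_tracks_prediction(self, ref):
        d = design_spike(ref, sigma=0.02)
        stim = build_stimulus(d, t_i=2.0)
        traj = integrate("qcoords", (d.Q0_init, d.Q0_init, 0.0), stim, (0.0, 20.0), ref)
        pred = predicted_response(d, t_i=2.0)
        # back to rest within 1% after the reset pulse
        assert abs(traj.qM[-1] - d.Q0_init) < 0.01 * abs(d.Q0_init)
        # oscillation-window extrema bracket the prediction within 15%
        win = (traj.t > pred.t_on) & (traj.t < pred.t_off)
        sim_min, sim_max = traj.qM[win].min(), traj.qM[win].max()
        pred_min, pred_max = d.Q0_init, d.Q0_target + pred.B_target
        assert sim_min == pytest.approx(pred_min, rel=0.15)
        assert sim_max == pytest.approx(pred_max, rel=0.15)

    def test_burst_produces_n_charge_peaks(self, ref):
        d = design_spike(ref)
        n = 8
        stim = build_stimulus(d, t_i=10.0, n_spikes=n)
        traj = integrate(
            "qcoords", (d.Q0_init, d.Q0_init, 0.0), stim, (0.0, 40.0), ref
        )
        win = (traj.t > 10.0 + d.Delta) & (traj.t < 10.0 + d.Delta + n * d.T)
        qM = traj.qM[win]
        peaks = np.nonzero((qM[1:-1] > qM[:-2]) & (qM[1:-1] > qM[2:]) & (qM[1:-1] > 0))[0]
        assert len(peaks) == n
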