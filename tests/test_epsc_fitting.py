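import numpy as np
import pytest

from ubcphase import epsc_fitting as ef
from ubcphase import synthetic_data as sd
from ubcphase.phase_metrics import decompose_train_epsc
from ubcphase.receptor_kinetics import GlutamatePulse, default_rate_constants
from ubcphase.stimulus_protocols import (EMFDrive, emf_rate, rate_to_times,
                                         train_stim_times)
from dataclasses import replace


def calibrated_pools(g_close=1.0, g_int=2.0, g_far=1.2):
    return {
        "close": ef.PoolModel("close", g_close, GlutamatePulse(400.0, 0.0, 1.2)),
        "intermediate": ef.PoolModel("intermediate", g_int,
                                     GlutamatePulse(60.0, 20.0, 10.0)),
        "far": ef.PoolModel("far", g_far, GlutamatePulse(8.0, 40.0, 150.0)),
    }


class TestSimulateEPSC:
    def test_no_stimulation_is_silent(self):
        m = ef.CompositeEPSCModel(pools=calibrated_pools())
        tr = ef.simulate_epsc(m, [], 500.0)
        assert np.allclose(tr.current, 0.0)

    def test_inward_sign_convention(self):
        m = ef.CompositeEPSCModel(pools=calibrated_pools())
        tr = ef.simulate_epsc(m, train_stim_times() + 50.0, 2050.0)
        assert np.all(tr.current <= 1e-12)
        assert tr.current.min() < -5.0

    def test_single_close_pool_fast_decay(self):
        pools = calibrated_pools(g_int=0.0, g_far=0.0)
        m = ef.CompositeEPSCModel(pools=pools)
        tr = ef.simulate_epsc(m, [10.0], 60.0, dt=0.02)
        i = -tr.current
        pk = np.argmax(i)
        below = np.where(i[pk:] < i[pk] * np.exp(-1))[0][0] * 0.02
        # decay within a factor 2 of the 1.2 ms glutamate clearance
        assert 0.6 < below < 4.0

    def test_offset_rebound_present(self):
        # a slowly clearing intermediate pool produces a current that rises
        # above its offset value after the train ends
        pools = calibrated_pools()
        pools["intermediate"] = ef.PoolModel(
            "intermediate", 3.0, GlutamatePulse(40.0, 40.0, 60.0))
        m = ef.CompositeEPSCModel(pools=pools)
        tr = ef.simulate_epsc(m, train_stim_times() + 50.0, 2050.0)
        t = tr.times
        i = -tr.current
        post = (t > 580.0) & (t < 1600.0)
        assert i[post].max() > i[int(575.0 / tr.dt)] + 1.0

    def test_disabling_desensitization_removes_rebound(self):
        m = ef.CompositeEPSCModel(pools=calibrated_pools())
        m0 = ef.CompositeEPSCModel(
            pools=m.pools, rates=replace(m.rates, alphaD=1e-9))
        stim = train_stim_times() + 50.0
        tr = ef.simulate_epsc(m, stim, 2050.0)
        tr0 = ef.simulate_epsc(m0, stim, 2050.0)
        t = tr.times
        post = t >= 575.0
        i0 = -tr0.current[post]
        # no-desensitization trace decays monotonically after offset
        assert np.all(np.diff(i0) < 1e-3)
        # and carries more charge during the train
        on = (t >= 50.0) & (t < 570.0)
        assert np.trapezoid(-tr0.current[on]) > np.trapezoid(-tr.current[on])

    def test_desensitization_removal_advances_phase(self):
        drive = EMFDrive(f_mod=1.0)
        stim = rate_to_times(lambda t: emf_rate(t, drive), 12000.0)
        pools = {
            "close": ef.PoolModel("close", 0.05, GlutamatePulse(400.0, 0.0, 1.2)),
            "intermediate": ef.PoolModel("intermediate", 2.0,
                                         GlutamatePulse(130.0, 30.0, 60.0)),
            "far": ef.PoolModel("far", 0.0, GlutamatePulse(8.0, 40.0, 150.0)),
        }
        m = ef.CompositeEPSCModel(pools=pools)
        fit = ef.FitResult(m, 0.5, True, 0)
        _, _, shift = ef.predict_modulated_epsc(fit, stim, 12000.0)
        m0 = ef.CompositeEPSCModel(pools=pools,
                                   rates=replace(m.rates, alphaD=1e-9))
        _, _, shift0 = ef.predict_modulated_epsc(
            ef.FitResult(m0, 0.5, True, 0), stim, 12000.0)
        # rebound-dominated cell fires late; removing desensitization
        # moves the response toward the stimulation peak
        assert abs(shift0) < abs(shift)


class TestFitEPSC:
    def test_noiseless_self_consistency(self):
        truth = ef.CompositeEPSCModel(pools=calibrated_pools())
        stim = train_stim_times() + 50.0
        clean = ef.simulate_epsc(truth, stim, 2050.0, dt=0.1)
        res = ef.fit_epsc(clean, ef.FitOptions(n_restarts=1, seed=0),
                          init=truth)
        assert res.converged
        assert res.residual_sd < 0.1

    def test_requires_train(self):
        t = np.arange(0, 2000.0, 0.1)
        tr = ef.CurrentTrace(t, np.zeros_like(t), np.array([100.0]))
        with pytest.raises(ValueError):
            ef.fit_epsc(tr)


class TestPhasePrediction:
    @pytest.fixture(scope="class")
    def stim_1hz(self):
        drive = EMFDrive(f_mod=1.0)
        return rate_to_times(lambda t: emf_rate(t, drive), 12000.0)

    def test_fast_tracking_cell_follows_stimulation(self, stim_1hz):
        pools = calibrated_pools(g_int=0.0, g_far=0.0)
        pools["close"] = ef.PoolModel("close", 1.0,
                                      GlutamatePulse(30.0, 0.0, 1.2))
        m = ef.CompositeEPSCModel(pools=pools)
        _, curve, shift = ef.predict_modulated_epsc(
            ef.FitResult(m, 0.5, True, 0), stim_1hz, 12000.0)
        assert abs(shift) < 45.0

    def test_rebound_dominated_cell_shifted(self, stim_1hz):
        pools = {
            "close": ef.PoolModel("close", 0.05, GlutamatePulse(400.0, 0.0, 1.2)),
            "intermediate": ef.PoolModel("intermediate", 2.0,
                                         GlutamatePulse(130.0, 30.0, 60.0)),
            "far": ef.PoolModel("far", 0.0, GlutamatePulse(8.0, 40.0, 150.0)),
        }
        m = ef.CompositeEPSCModel(pools=pools)
        _, curve, shift = ef.predict_modulated_epsc(
            ef.FitResult(m, 0.5, True, 0), stim_1hz, 12000.0)
        assert abs(shift) > 90.0

    def test_flat_response_flagged(self, stim_1hz):
        pools = calibrated_pools(g_close=0.0, g_int=0.0, g_far=0.0)
        m = ef.CompositeEPSCModel(pools=pools)
        _, curve, shift = ef.predict_modulated_epsc(
            ef.FitResult(m, 0.5, True, 0), stim_1hz, 12000.0)
        assert np.isnan(shift)

    def test_unconverged_fit_rejected(self, stim_1hz):
        m = ef.CompositeEPSCModel(pools=calibrated_pools())
        with pytest.raises(ValueError):
            ef.predict_modulated_epsc(ef.FitResult(m, np.nan, False, 1),
                                      stim_1hz, 12000.0)


class TestIFReadout:
    def test_silent_on_zero_current(self):
        t = np.arange(0, 5000.0, 0.1)
        tr = ef.CurrentTrace(t, np.zeros_like(t), np.empty(0))
        spikes = ef.if_readout(tr, seed=0)
        assert len(spikes) == 0

    def test_constant_inward_current_fires_regularly(self):
        from ubcphase.phase_metrics import cv2
        t = np.arange(0, 5000.0, 0.1)
        tr = ef.CurrentTrace(t, np.full_like(t, -30.0), np.empty(0))
        spikes = ef.if_readout(tr, seed=0)
        assert len(spikes) > 50
        assert cv2(np.diff(spikes)) < 0.05

    def test_spike_phase_matches_current_phase(self):
        drive = EMFDrive(f_mod=1.0)
        stim = rate_to_times(lambda t: emf_rate(t, drive), 12000.0)
        m = ef.CompositeEPSCModel(pools=calibrated_pools())
        trace = ef.simulate_epsc(m, stim, 12000.0, dt=0.1)
        _, curve, _ = ef.predict_modulated_epsc(
            ef.FitResult(m, 0.5, True, 0), stim, 12000.0, dt=0.1)
        from ubcphase.phase_metrics import fit_tuning
        spikes = ef.if_readout(trace, seed=3, g_control=4.0)
        spike_fit = fit_tuning(spikes, 1.0, 12000.0)
        dphi = abs((spike_fit.phi - curve.phi + 180.0) % 360.0 - 180.0)
        assert dphi < 45.0


class TestPhaseHistogramCorrelation:
    def test_identical_histograms(self):
        h = np.sin(np.linspace(0, 2 * np.pi, 20)) + 2.0
        r, p = ef.phase_histogram_correlation(h, h)
        assert r == pytest.approx(1.0)

    def test_reversed_unimodal_histogram_anticorrelates(self):
        h = np.exp(np.cos(np.linspace(0, 2 * np.pi, 20, endpoint=False)))
        r, _ = ef.phase_histogram_correlation(h, np.roll(h, 10))
        assert r < 0

    def test_matched_noisy_pairs_significant(self):
        rng = np.random.default_rng(0)
        base = np.exp(np.cos(np.linspace(0, 2 * np.pi, 20, endpoint=False)))
        n_sig = 0
        for _ in range(20):
            a = base + rng.normal(0, 0.2, 20)
            b = base + rng.normal(0, 0.2, 20)
            _, p = ef.phase_histogram_correlation(a, b)
            n_sig += p < 0.05
        assert n_sig >= 18

    def test_flat_histogram_flagged(self):
        r, p = ef.phase_histogram_correlation(np.ones(10), np.arange(10.0))
        assert np.isnan(r) and np.isnan(p)
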