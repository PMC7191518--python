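"""Intracellular analysis: access compensation, spikes, conductance, power law."""

import numpy as np
import pytest

from cgc import patch, synth
from cgc.patch import (
    compensate_access,
    detect_spikes,
    detect_up_states,
    estimate_conductance,
    fit_access_model,
    fit_power_law,
    mean_pulse_cycle,
    psp_metrics,
    spike_threshold,
    validate_compensation,
)
from cgc.synth import PatchSimParams, simulate_whole_cell

FS = 20_000.0


class TestUpStates:
    def test_flat_trace_not_flagged(self):
        assert not detect_up_states(np.full(20_000, -60.0), -55.0, FS)

    def test_inserted_plateau_flagged(self):
        v = np.full(20_000, -60.0)
        v[5000:9000] += 12.0  # 200-ms plateau
        assert detect_up_states(v, v.mean(), FS)

    def test_short_excursion_ignored(self):
        v = np.full(20_000, -60.0)
        v[5000:5200] += 12.0  # 10 ms < 50-ms dwell
        assert not detect_up_states(v, -58.0, FS)

    def test_simulator_plateau_flagged(self):
        p = PatchSimParams(up_state_rate=1.5, R_access=0.0, trial_noise_sd=0.2,
                           seed=7)
        sw = simulate_whole_cell(p, I_levels=[0.0, 0.0], n_trials=8,
                                 g_syn=np.zeros(40_000), fs=FS)
        thr = float(sw.sweeps.mean())
        assert any(detect_up_states(s, thr, FS) for s in sw.sweeps)

    def test_false_positive_rate_under_null(self):
        flags, n = 0, 0
        for seed in range(25):
            p = PatchSimParams(up_state_rate=0.0, R_access=0.0,
                               trial_noise_sd=0.3, seed=seed)
            sw = simulate_whole_cell(p, I_levels=[0.0, 0.0], n_trials=4,
                                     g_syn=np.zeros(20_000), fs=FS)
            thr = float(sw.sweeps.mean())
            flags += sum(detect_up_states(s, thr, FS) for s in sw.sweeps)
            n += sw.n_trials
        assert flags / n < 0.05

    def test_bimodality_precondition(self):
        rng = np.random.default_rng(1)
        unimodal = rng.normal(-60, 2, 50_000)
        assert not detect_up_states(unimodal, -60.0, FS, require_bimodal=True)


class TestAccessModel:
    def test_noiseless_parameter_recovery_within_5pct(self, passive_cell_sweeps):
        params, sweeps = passive_cell_sweeps
        fit = fit_access_model(mean_pulse_cycle(sweeps), I_inj=40.0, fs=FS)
        assert fit.R_access == pytest.approx(params.R_access, rel=0.05)
        assert fit.tau_access == pytest.approx(params.tau_access, rel=0.05)
        assert fit.R_input == pytest.approx(params.R_input, rel=0.05)
        assert fit.tau_input == pytest.approx(params.tau_input, rel=0.05)

    def test_absent_electrode_component(self):
        p = PatchSimParams(R_input=100.0, tau_input=20.0, R_access=0.0,
                           trial_noise_sd=0.0, seed=2)
        sw = simulate_whole_cell(p, I_levels=[-40.0, 40.0], n_trials=1,
                                 g_syn=np.zeros(2000), fs=FS)
        fit = fit_access_model(mean_pulse_cycle(sw), I_inj=40.0, fs=FS)
        assert fit.R_access < 1.0

    def test_mse_surface_retained(self, passive_cell_sweeps):
        _, sweeps = passive_cell_sweeps
        fit = fit_access_model(mean_pulse_cycle(sweeps), I_inj=40.0, fs=FS)
        assert np.isfinite(fit.mse_surface["mse"]).any()
        assert np.nanmin(fit.mse_surface["mse"][np.isfinite(fit.mse_surface["mse"])]) >= 0


class TestCompensation:
    def test_matches_electrode_free_ground_truth(self, passive_cell_sweeps):
        params, sweeps = passive_cell_sweeps
        fit = fit_access_model(mean_pulse_cycle(sweeps), I_inj=40.0, fs=FS)
        comp = compensate_access(sweeps, fit)
        rmse = np.sqrt(np.mean((comp.sweeps - sweeps.meta["v_true"]) ** 2))
        assert rmse < 0.2

    def test_zero_current_trials_unchanged(self):
        p = PatchSimParams(R_access=20.0, trial_noise_sd=0.0, seed=1)
        sw = simulate_whole_cell(p, I_levels=[0.0, 40.0], n_trials=1,
                                 g_syn=np.zeros(1000), fs=FS,
                                 pulse_amp=0.0)  # no pulse either
        fit = patch.AccessFit(R_access=20.0, tau_access=0.5, R_input=100.0,
                              tau_input=20.0)
        comp = compensate_access(sw, fit)
        zero = np.isclose(sw.I_inj, 0.0)
        assert np.allclose(comp.sweeps[zero], sw.sweeps[zero])

    def test_subtracted_component_linear_in_r_access(self, passive_cell_sweeps):
        _, sweeps = passive_cell_sweeps
        f1 = patch.AccessFit(R_access=10.0, tau_access=0.5, R_input=100.0,
                             tau_input=20.0)
        f2 = patch.AccessFit(R_access=20.0, tau_access=0.5, R_input=100.0,
                             tau_input=20.0)
        d1 = sweeps.sweeps - compensate_access(sweeps, f1).sweeps
        d2 = sweeps.sweeps - compensate_access(sweeps, f2).sweeps
        assert np.allclose(d2, 2.0 * d1, atol=1e-12)


def insert_spike(v, i, fs, height=45.0):
    """Piecewise-linear spike with an onset kink at sample i."""
    n_rise = int(round(0.4e-3 * fs))
    n_fall = int(round(1.0e-3 * fs))
    v[i : i + n_rise] += np.linspace(0, height, n_rise, endpoint=False)
    v[i + n_rise : i + n_rise + n_fall] += np.linspace(height, 0, n_fall,
                                                       endpoint=False)
    return v


class TestSpikes:
    def test_flat_trace_no_spikes(self):
        assert detect_spikes(np.full(20_000, -60.0), FS).size == 0

    def test_three_inserted_spikes_detected(self):
        rng = np.random.default_rng(4)
        v = rng.normal(-60.0, 0.5, 20_000)
        for i in (3000, 9000, 15_000):
            insert_spike(v, i, FS)
        times = detect_spikes(v, FS)
        assert times.size == 3
        assert np.allclose(times * FS, [3000, 9000, 15_000], atol=12)

    def test_threshold_definition(self):
        # a plateau just below mean + 7 SD of the despiked trace is silent;
        # just above, it is detected
        rng = np.random.default_rng(5)
        v = rng.normal(0.0, 1.0, 40_000)
        mu, sd = patch._despiked_stats(v, FS)
        for margin, expected in ((-0.5, 0), (+1.0, 1)):
            w = v.copy()
            w[20_000:20_030] = mu + 7.0 * sd + margin
            assert detect_spikes(w, FS).size == expected

    def test_spike_threshold_at_constructed_kink(self):
        v = np.full(20_000, -60.0)
        kink = 9000
        insert_spike(v, kink, FS)
        t = detect_spikes(v, FS)
        assert t.size == 1
        th = spike_threshold(v, t[0], FS)
        # inflection at the onset kink, within a sample or two of -60 mV
        assert th == pytest.approx(-60.0, abs=1.5)

    def test_baseline_shift_shifts_threshold(self):
        a = insert_spike(np.full(20_000, -60.0), 9000, FS)
        b = insert_spike(np.full(20_000, -50.0), 9000, FS)
        ta, tb = detect_spikes(a, FS)[0], detect_spikes(b, FS)[0]
        assert spike_threshold(b, tb, FS) - spike_threshold(a, ta, FS) == \
            pytest.approx(10.0, abs=0.5)

    def test_truncated_window_rejected(self):
        v = insert_spike(np.full(1000, -60.0), 2, FS)
        with pytest.raises(ValueError, match="1 ms"):
            spike_threshold(v, 3 / FS, FS)


@pytest.fixture(scope="module")
def spiking_cell():
    rng = np.random.default_rng(0)
    env = np.clip(rng.normal(0.6, 0.4, 100), 0, None)
    g = np.repeat(env, 200) * 2.0
    p = PatchSimParams(R_input=100.0, tau_input=20.0, R_access=20.0,
                       tau_access=0.5, spike_threshold=-50.0,
                       trial_noise_sd=0.2, seed=4)
    sw = simulate_whole_cell(p, I_levels=[-40.0, 0.0, 40.0, 80.0],
                             n_trials=4, g_syn=g, fs=FS)
    fit = fit_access_model(mean_pulse_cycle(sw), I_inj=40.0, fs=FS)
    return p, sw, compensate_access(sw, fit)


class TestCompensationValidation:
    @staticmethod
    def _threshold_table(sweeps):
        ths, Is = [], []
        for s in range(sweeps.n_trials):
            tr = sweeps.sweeps[s]
            for t in detect_spikes(tr, sweeps.fs):
                try:
                    ths.append(spike_threshold(tr, t, sweeps.fs))
                    Is.append(sweeps.I_inj[s])
                except ValueError:
                    continue
        return np.array(ths), np.array(Is)

    def test_uncompensated_slope_reflects_r_access(self, spiking_cell):
        p, sw, _ = spiking_cell
        ths, Is = self._threshold_table(sw)
        out = validate_compensation(ths, Is)
        assert out["residual_R_access"] == pytest.approx(p.R_access, rel=0.1)

    def test_compensation_removes_current_dependence(self, spiking_cell):
        p, sw, comp = spiking_cell
        ths_u, Is_u = self._threshold_table(sw)
        ths_c, Is_c = self._threshold_table(comp)
        slope_u = validate_compensation(ths_u, Is_u)["residual_R_access"]
        slope_c = validate_compensation(ths_c, Is_c)["residual_R_access"]
        assert abs(slope_c) < 2.0
        assert abs(slope_c) < 0.1 * abs(slope_u)

    def test_constant_thresholds_zero_slope(self):
        out = validate_compensation(np.full(10, -48.0), np.r_[np.zeros(5), np.ones(5)])
        assert out["residual_R_access"] == pytest.approx(0.0, abs=1e-9)

    def test_single_level_rejected(self):
        with pytest.raises(ValueError, match="2 current levels"):
            validate_compensation(np.ones(5), np.full(5, 40.0))


class TestConductance:
    def test_static_membrane_gives_constant_g(self):
        p = PatchSimParams(R_input=100.0, tau_input=20.0, R_access=0.0,
                           trial_noise_sd=0.0, seed=1)
        sw = simulate_whole_cell(p, I_levels=[-40.0, 0.0, 40.0], n_trials=2,
                                 g_syn=np.zeros(20_000), fs=FS)
        g = estimate_conductance(sw)
        sl = slice(int(0.2 * FS), None)  # after charging transient
        assert np.allclose(g.G[sl], 10.0, rtol=0.01)
        assert g.r2_reconstruction == pytest.approx(1.0, abs=1e-9)

    def test_synaptic_step_recovered_within_10pct(self):
        gstep = np.zeros(20_000)
        gstep[8000:16_000] = 5.0
        p = PatchSimParams(R_input=100.0, tau_input=20.0, R_access=0.0,
                           trial_noise_sd=0.0, seed=2)
        sw = simulate_whole_cell(p, I_levels=[-80.0, -40.0, 0.0, 40.0],
                                 n_trials=2, g_syn=gstep, fs=FS)
        g = estimate_conductance(sw)
        base = g.G[2000:7500].mean()
        plateau = g.G[10_000:15_500].mean()
        assert plateau - base == pytest.approx(5.0, rel=0.1)

    def test_single_current_level_rejected(self):
        p = PatchSimParams(trial_noise_sd=0.0, seed=1)
        sw = simulate_whole_cell(p, I_levels=[40.0, 40.0], n_trials=1,
                                 g_syn=np.zeros(1000), fs=FS)
        with pytest.raises(ValueError, match="current levels"):
            estimate_conductance(sw)

    def test_end_to_end_g_recovery_with_electrode(self):
        # full chain: simulate with R_access -> fit -> compensate -> G(t);
        # plateaus long relative to the membrane time constant, since the
        # per-timepoint Ohmic estimate relaxes to the true G with tau_eff
        rng = np.random.default_rng(6)
        n_step = 4000  # 200-ms plateaus
        g_true = np.repeat(rng.uniform(0.0, 6.0, 10), n_step)
        p = PatchSimParams(R_input=100.0, tau_input=20.0, R_access=20.0,
                           tau_access=0.5, trial_noise_sd=0.3, seed=6)
        sw = simulate_whole_cell(p, I_levels=[-80.0, -40.0, 0.0, 40.0],
                                 n_trials=6, g_syn=g_true, fs=FS)
        fit = fit_access_model(mean_pulse_cycle(sw), I_inj=40.0, fs=FS)
        comp = compensate_access(sw, fit)
        g = estimate_conductance(comp)
        g_syn_est = g.G - 1000.0 / p.R_input
        # compare quasi-steady plateau averages (last 50 ms of each step);
        # single-timepoint estimates carry ~0.25 nS of trial-noise jitter
        est = np.array([
            g_syn_est[k * n_step + 3000 : (k + 1) * n_step].mean() for k in range(10)
        ])
        true = g_true[::n_step]
        nrmse = np.sqrt(np.mean((est - true) ** 2)) / true.std()
        assert nrmse < 0.10


class TestPspMetrics:
    def _sweeps(self, n_trials=10, amp=5.0, base=-60.0, jitter=0.0, seed=0):
        rng = np.random.default_rng(seed)
        fs = 10_000.0
        t = np.arange(int(fs)) / fs
        out = np.empty((n_trials, t.size))
        for i in range(n_trials):
            a = amp * (1 + jitter * rng.standard_normal())
            psp = a * np.exp(-(t - 0.505).clip(0) / 0.02) * (t >= 0.505)
            out[i] = base + psp
        return out, fs

    def test_amplitude_and_zero_sd_for_identical_trials(self):
        V, fs = self._sweeps()
        m = psp_metrics(V, fs, noise_onset=0.5)
        assert m["amplitude"] == pytest.approx(5.0, rel=0.05)
        assert m["amplitude_sd"] == pytest.approx(0.0, abs=1e-9)

    def test_baseline_shift_invariance(self):
        V, fs = self._sweeps()
        a = psp_metrics(V, fs, noise_onset=0.5)["amplitude"]
        b = psp_metrics(V + 7.5, fs, noise_onset=0.5)["amplitude"]
        assert a == pytest.approx(b, abs=1e-9)

    def test_contrast_scaling_recovered(self):
        lo, fs = self._sweeps(amp=5.0, jitter=0.05, seed=1)
        hi, _ = self._sweeps(amp=4.0, jitter=0.05, seed=2)
        r = psp_metrics(hi, fs, 0.5)["amplitude"] / psp_metrics(lo, fs, 0.5)["amplitude"]
        assert r == pytest.approx(0.8, abs=0.05)

    def test_missing_baseline_rejected(self):
        V, fs = self._sweeps()
        with pytest.raises(ValueError, match="pre-onset"):
            psp_metrics(V, fs, noise_onset=0.002)


class TestPowerLaw:
    def test_linear_case_exact(self):
        rng = np.random.default_rng(1)
        vm = rng.uniform(-65, -40, 100)
        cond = np.where(rng.random(100) < 0.5, "low", "high")
        rate = np.clip(vm - (-60.0), 0, None)
        fit = fit_power_law(vm, rate, cond, v_rest=-60.0)
        assert fit.k_low == pytest.approx(1.0, rel=0.01)
        assert fit.k_high == pytest.approx(1.0, rel=0.01)
        assert fit.p == pytest.approx(1.0, rel=0.01)

    def test_recovery_at_5pct_noise(self):
        rng = np.random.default_rng(2)
        vm = rng.uniform(-65, -45, 400)
        cond = np.where(rng.random(400) < 0.5, "low", "high")
        k = np.where(cond == "low", 2.0, 1.0)
        rate = k * np.clip(vm + 60.0, 0, None) ** 2
        rate *= 1 + 0.05 * rng.standard_normal(400)
        fit = fit_power_law(vm, rate, cond, v_rest=-60.0)
        assert fit.k_low == pytest.approx(2.0, rel=0.1)
        assert fit.k_high == pytest.approx(1.0, rel=0.1)
        assert fit.p == pytest.approx(2.0, rel=0.1)
        assert fit.gain_change == pytest.approx(0.5, rel=0.1)

    def test_all_subthreshold_rejected(self):
        vm = np.full(50, -70.0)
        with pytest.raises(ValueError, match="rest"):
            fit_power_law(vm, np.zeros(50), np.full(50, "low"), v_rest=-60.0)
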