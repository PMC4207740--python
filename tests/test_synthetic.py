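"""Generator behavior: Markov fidelity, state-conditional spectra,
sleep deprivation, wheel activity and planted expression effects."""

import numpy as np
import pytest
from scipy import stats as sst

from chronosleep import ConfigurationError, GroupParams, SimulationConfig
from chronosleep.core import NREM, REM, WAKE
from chronosleep.synthetic import (
    apply_sleep_deprivation,
    homeostat_trajectory,
    simulate_expression,
    simulate_hypnogram,
    simulate_wheel_activity,
    synthesize_signals,
)
from conftest import make_hypnogram
from oracles import direct_dft_welch, tally_transitions


def _flat_config(**kw):
    groups = {"G": GroupParams(modulation_depth=0.0, **kw.pop("group_kw", {}))}
    return SimulationConfig(groups=groups, **kw)


class TestSimulateHypnogram:
    def test_absorbing_wake_state(self):
        P = np.array([[1.0, 0.0, 0.0], [0.03, 0.95, 0.02], [0.06, 0.01, 0.93]])
        cfg = _flat_config(base_transition_matrix=P)
        hyp = simulate_hypnogram(cfg, "G", seed=3, n_epochs=500)
        assert np.all(hyp.states == WAKE)

    def test_seeded_determinism(self, config):
        a = simulate_hypnogram(config, "WT", seed=11, n_epochs=2000)
        b = simulate_hypnogram(config, "WT", seed=11, n_epochs=2000)
        assert np.array_equal(a.states, b.states)
        assert np.array_equal(a.artifact_flags, b.artifact_flags)
        c = simulate_hypnogram(config, "WT", seed=12, n_epochs=2000)
        assert not np.array_equal(a.states, c.states)

    def test_markov_fidelity_without_modulation(self):
        """With zero modulation depth the empirical transition frequencies
        match the base matrix (3-SE bands and chi-square GOF at alpha=0.01)."""
        cfg = _flat_config()
        hyp = simulate_hypnogram(cfg, "G", seed=5, n_epochs=21600)
        counts = tally_transitions(hyp.states)
        P = cfg.base_transition_matrix
        for i in range(3):
            row_n = counts[i].sum()
            for j in range(3):
                p = P[i, j]
                se = np.sqrt(p * (1 - p) / row_n)
                assert abs(counts[i, j] / row_n - p) <= max(3 * se, 1e-12)
            expected = row_n * P[i]
            mask = expected > 0
            chi2 = ((counts[i][mask] - expected[mask]) ** 2 / expected[mask]).sum()
            assert sst.chi2.sf(chi2, mask.sum() - 1) > 0.01

    def test_excessive_modulation_depth_is_an_error(self):
        cfg = SimulationConfig(groups={"G": GroupParams(modulation_depth=1.2)})
        with pytest.raises(ConfigurationError, match="epoch"):
            simulate_hypnogram(cfg, "G", seed=0, n_epochs=21600)

    def test_unknown_group_gets_no_modulation(self, config):
        hyp = simulate_hypnogram(config, "nogroup", seed=0, n_epochs=100)
        assert hyp.n_epochs == 100


class TestSynthesizeSignals:
    def test_nrem_epochs_are_delta_dominated(self, config):
        """Without the homeostat, >=95% of all-NREM epochs have more 0.5-4 Hz
        than 5-10 Hz power (checked with the FFT-free oracle periodogram)."""
        hyp = make_hypnogram(np.full(150, NREM))
        rec = synthesize_signals(hyp, config, seed=21, homeostat=False)
        epochs = rec.epochs_2d("EEG")
        wins = 0
        for i in range(epochs.shape[0]):
            psd = direct_dft_welch(epochs[i])
            freqs = np.arange(psd.size) * 0.5
            delta = psd[(freqs >= 0.5) & (freqs <= 4.0)].mean()
            theta = psd[(freqs >= 5.0) & (freqs <= 10.0)].mean()
            wins += delta > theta
        assert wins >= 0.95 * epochs.shape[0]

    def test_rem_grand_mean_peaks_at_theta_center(self):
        cfg = SimulationConfig(groups={"G": GroupParams(theta_center_frequency=7.5)})
        hyp = make_hypnogram(np.full(150, REM))
        rec = synthesize_signals(hyp, cfg, seed=22, group="G")
        psd = np.mean([direct_dft_welch(e) for e in rec.epochs_2d("EEG")], axis=0)
        freqs = np.arange(psd.size) * 0.5
        band = (freqs >= 5.0) & (freqs <= 10.0)
        peak = freqs[band][np.argmax(psd[band])]
        assert abs(peak - 7.5) <= 0.5

    def test_emg_tone_orders_wake_above_nrem_above_rem(self, config):
        states = np.r_[np.full(50, WAKE), np.full(50, NREM), np.full(50, REM)]
        rec = synthesize_signals(make_hypnogram(states), config, seed=23)
        emg = rec.epochs_2d("EMG")
        rms = np.sqrt((emg**2).mean(axis=1))
        assert rms[:50].mean() > rms[50:100].mean() > rms[100:].mean()

    def test_zero_length_hypnogram_gives_empty_recording(self, config):
        rec = synthesize_signals(make_hypnogram([]), config, seed=1)
        assert rec.n_epochs == 0
        assert rec.sampling_rate == config.sampling_rate

    def test_theta_center_outside_analysis_band_rejected(self):
        cfg = SimulationConfig(groups={"G": GroupParams(theta_center_frequency=25.0)})
        with pytest.raises(ValueError, match="analysis band"):
            synthesize_signals(make_hypnogram([REM]), cfg, seed=1, group="G")

    def test_determinism(self, config):
        hyp = make_hypnogram(np.full(20, NREM))
        a = synthesize_signals(hyp, config, seed=9)
        b = synthesize_signals(hyp, config, seed=9)
        assert np.array_equal(a.channels["EEG"], b.channels["EEG"])
        assert np.array_equal(a.channels["EMG"], b.channels["EMG"])


class TestHomeostat:
    def test_rises_in_wake_decays_in_nrem(self, config):
        s_wake = homeostat_trajectory(make_hypnogram(np.full(100, WAKE)), config)
        assert np.all(np.diff(s_wake) >= 0)
        s_nrem = homeostat_trajectory(make_hypnogram(np.full(100, NREM)), config)
        assert np.all(np.diff(s_nrem) < 0)

    def test_sleep_deprivation_raises_process_s(self, config):
        """Enforced wakefulness ZT0-6 of day 2 leaves S higher at ZT6 than
        the undisturbed baseline day, for the same seed."""
        base = simulate_hypnogram(config, "WT", seed=31)
        sd = apply_sleep_deprivation(base, (24.0, 30.0), 0.97, seed=131)
        idx = int(30.0 * 3600 / config.epoch_seconds) - 1  # end of the SD window
        s_base = homeostat_trajectory(base, config)
        s_sd = homeostat_trajectory(sd, config)
        assert s_sd[idx] > s_base[idx]


class TestSleepDeprivation:
    def test_full_efficiency_forces_all_wake(self, config):
        hyp = simulate_hypnogram(config, "WT", seed=41, n_epochs=10800)
        sd = apply_sleep_deprivation(hyp, (0.0, 6.0), 1.0, seed=1)
        assert np.all(sd.states[sd.window_mask(0.0, 6.0)] == WAKE)
        outside = ~sd.window_mask(0.0, 6.0)
        assert np.array_equal(sd.states[outside], hyp.states[outside])

    def test_zero_efficiency_changes_nothing(self, config):
        hyp = simulate_hypnogram(config, "WT", seed=42, n_epochs=10800)
        sd = apply_sleep_deprivation(hyp, (0.0, 6.0), 0.0, seed=1)
        assert np.array_equal(sd.states, hyp.states)

    def test_partial_efficiency_matches_binomial_rate(self):
        """97% efficiency on 5400 sleeping epochs leaves a WAKE fraction
        within 3 binomial SE of 0.97."""
        hyp = make_hypnogram(np.full(5400, NREM))
        sd = apply_sleep_deprivation(hyp, (0.0, 6.0), 0.97, seed=7)
        frac = np.mean(sd.states == WAKE)
        se = np.sqrt(0.97 * 0.03 / 5400)
        assert abs(frac - 0.97) <= 3 * se

    def test_invalid_inputs(self, config):
        hyp = simulate_hypnogram(config, "WT", seed=43, n_epochs=100)
        with pytest.raises(ValueError):
            apply_sleep_deprivation(hyp, (0.0, 1.0), 1.5, seed=1)
        with pytest.raises(ValueError, match="outside"):
            apply_sleep_deprivation(hyp, (30.0, 36.0), 0.9, seed=1)


class TestWheelActivity:
    def test_zero_rates_give_zero_counts(self):
        cfg = _flat_config(group_kw=dict(wheel_rate_light=0.0, wheel_rate_dark=0.0))
        assert simulate_wheel_activity(cfg, "G", seed=1).counts.sum() == 0

    def test_light_phase_silent_when_light_rate_zero(self):
        cfg = _flat_config(group_kw=dict(wheel_rate_light=0.0, wheel_rate_dark=10.0))
        series = simulate_wheel_activity(cfg, "G", seed=2)
        light = series.schedule.is_light(series.minute_zt())
        assert series.counts[light].sum() == 0
        assert series.counts[~light].sum() > 0

    def test_flat_dark_rate_mean(self):
        """With the nocturnal taper disabled, the dark-phase mean matches the
        Poisson rate to 3 SE."""
        cfg = _flat_config(
            group_kw=dict(wheel_rate_light=0.0, wheel_rate_dark=10.0, wheel_halfmax_zt=None)
        )
        series = simulate_wheel_activity(cfg, "G", seed=3)
        dark = ~series.schedule.is_light(series.minute_zt())
        n = dark.sum()
        se = np.sqrt(10.0 / n)
        assert abs(series.counts[dark].mean() - 10.0) <= 3 * se


class TestSimulateExpression:
    def test_zero_noise_gives_exact_planted_difference(self):
        cfg = SimulationConfig(expression_noise_sd=0.0, expression_n_genes=200,
                               expression_n_planted=10, expression_n_robust=2)
        mat, truth = simulate_expression(cfg, seed=4)
        for gene in truth["planted_genes"]:
            night = mat.values.loc[gene, mat.samples_for("WT", "ZT16")].mean()
            day = mat.values.loc[gene, mat.samples_for("WT", "ZT4")].mean()
            assert night - day == pytest.approx(cfg.expression_effect_log2fc, abs=1e-12)

    def test_null_unadjusted_positive_count(self):
        """With no planted genes the p<0.05 count is binomial(n_genes, 0.05)."""
        cfg = SimulationConfig(expression_n_planted=0, expression_n_robust=0,
                               expression_n_genes=1000)
        mat, _ = simulate_expression(cfg, seed=5)
        from chronosleep.screen import day_night_screen

        res = day_night_screen(mat, "WT")
        count = int((res.table["p_value"] < 0.05).sum())
        lo, hi = sst.binom.interval(0.999, 1000, 0.05)
        assert lo <= count <= hi

    def test_determinism_and_replicate_guard(self, config):
        a, _ = simulate_expression(config, seed=6)
        b, _ = simulate_expression(config, seed=6)
        assert a.values.equals(b.values)
        with pytest.raises(ValueError, match="replicates"):
            simulate_expression(config.with_updates(expression_replicates=1), seed=6)
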