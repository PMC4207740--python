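"""Spectral estimation: epoch periodograms, SWA normalization, TPF."""

import numpy as np
import pytest

from chronosleep import GroupParams, SimulationConfig
from chronosleep.core import NREM, REM, WAKE, EpochedRecording
from chronosleep.spectral import (
    FREQ_GRID,
    PowerSpectrum,
    band_power,
    epoch_spectra,
    epoch_spectrum,
    mean_state_spectrum,
    swa_per_epoch,
    swa_reference,
    swa_timecourse,
    theta_peak_frequency,
)
from chronosleep.synthetic import synthesize_signals
from conftest import make_hypnogram
from oracles import direct_dft_welch

FS = 256.0
T = np.arange(1024) / FS


def _recording(eeg_epochs, start_zt=0.0):
    eeg = np.concatenate(eeg_epochs) if len(eeg_epochs) else np.zeros(0)
    return EpochedRecording(channels={"EEG": eeg}, sampling_rate=FS, start_zt=start_zt)


class TestEpochSpectrum:
    def test_pure_tone_peaks_in_its_bin(self):
        spec = epoch_spectrum(np.sin(2 * np.pi * 8.0 * T))
        assert spec.frequencies[np.argmax(spec.power)] == 8.0

    def test_zero_signal_gives_zero_power(self):
        assert np.all(epoch_spectrum(np.zeros(1024)).power == 0.0)

    def test_two_tones_give_two_local_maxima(self):
        x = np.sin(2 * np.pi * 2.0 * T) + np.sin(2 * np.pi * 7.5 * T)
        p = epoch_spectrum(x).power
        for f in (2.0, 7.5):
            i = int(np.where(FREQ_GRID == f)[0][0])
            assert p[i] > p[i - 1] and p[i] > p[i + 1]

    def test_matches_direct_dft_oracle(self, rng):
        """Implementation agrees with an FFT-free direct-DFT Welch
        periodogram to 1e-9 relative error on random epochs."""
        grid_idx = np.round(FREQ_GRID / 0.5).astype(int)
        for _ in range(50):
            x = rng.standard_normal(1024)
            expected = direct_dft_welch(x)[grid_idx]
            got = epoch_spectrum(x).power
            assert np.max(np.abs(got - expected) / expected) < 1e-9

    def test_input_validation(self):
        with pytest.raises(ValueError):
            epoch_spectrum(np.zeros(1000))
        bad = np.zeros(1024)
        bad[3] = np.nan
        with pytest.raises(ValueError):
            epoch_spectrum(bad)

    def test_scale_equivariance(self, rng):
        x = rng.standard_normal(1024)
        p1 = epoch_spectrum(x).power
        p2 = epoch_spectrum(3.0 * x).power
        assert np.allclose(p2, 9.0 * p1, rtol=1e-12)

    def test_parseval_with_window_power_correction(self, rng):
        """The integrated full-band density equals the windowed signal's
        mean square with the Hann power correction, to 1e-6."""
        x = rng.standard_normal(1024)
        spec = epoch_spectrum(x, full_band=True)
        df = spec.frequencies[1] - spec.frequencies[0]
        integral = spec.power.sum() * df
        seg = 512
        w = 0.5 - 0.5 * np.cos(2 * np.pi * np.arange(seg) / seg)
        expected = np.mean(
            [np.sum((x[s * seg : (s + 1) * seg] * w) ** 2) / np.sum(w**2) for s in range(2)]
        )
        assert integral == pytest.approx(expected, rel=1e-6)


class TestBandPower:
    def test_flat_spectrum(self):
        spec = PowerSpectrum(frequencies=FREQ_GRID, power=np.full(40, 3.7))
        assert band_power(spec, 0.5, 4.0) == pytest.approx(3.7)

    def test_single_bin_mean(self):
        p = np.zeros(40)
        p[FREQ_GRID == 2.0] = 1.0
        spec = PowerSpectrum(frequencies=FREQ_GRID, power=p)
        assert band_power(spec, 0.5, 4.0) == pytest.approx(1.0 / 8.0)

    def test_matches_independent_mean(self, rng):
        p = rng.random(40)
        spec = PowerSpectrum(frequencies=FREQ_GRID, power=p)
        sel = [i for i, f in enumerate(FREQ_GRID) if 5.0 <= f <= 10.0]
        assert band_power(spec, 5.0, 10.0) == pytest.approx(np.mean(p[sel]), abs=1e-12)

    def test_band_outside_grid_rejected(self):
        spec = PowerSpectrum(frequencies=FREQ_GRID, power=np.ones(40))
        with pytest.raises(ValueError):
            band_power(spec, 0.5, 30.0)


def _constant_epoch(rng):
    """One fixed epoch waveform reused everywhere, so SWA is constant."""
    return rng.standard_normal(1024)


class TestSwaReference:
    def test_constant_swa_recovered(self, rng):
        epoch = _constant_epoch(rng)
        hyp = make_hypnogram(np.full(900, NREM))
        rec = _recording([epoch] * 900)
        c = band_power(epoch_spectrum(epoch), 0.5, 4.0)
        assert swa_reference(rec, hyp) == pytest.approx(c, rel=1e-12)

    def test_too_few_epochs_rejected(self, rng):
        epoch = _constant_epoch(rng)
        hyp = make_hypnogram(np.full(899, NREM))
        with pytest.raises(ValueError, match="899"):
            swa_reference(_recording([epoch] * 899), hyp)

    def test_min_epochs_override(self, rng):
        epoch = _constant_epoch(rng)
        hyp = make_hypnogram(np.full(100, NREM))
        ref = swa_reference(_recording([epoch] * 100), hyp, min_epochs=50)
        assert ref > 0

    def test_matches_sort_and_average_oracle(self, config, rng):
        """Last-900 selection agrees with a brute-force rescan of the
        hypnogram (artifact-free NREM epochs in the light period)."""
        states = rng.integers(0, 3, size=3600)
        artifacts = rng.random(3600) < 0.05
        states[:1500] = NREM  # guarantee enough qualifying epochs
        hyp = make_hypnogram(states, artifacts)
        rec = synthesize_signals(hyp, config, seed=61, homeostat=False)
        swa = swa_per_epoch(rec)
        qualifying = [
            i
            for i in range(3600)
            if states[i] == NREM and not artifacts[i] and hyp.epoch_zt()[i] < 12.0
        ]
        expected = np.mean([swa[i] for i in qualifying[-900:]])
        assert swa_reference(rec, hyp) == pytest.approx(expected, rel=1e-12)


class TestSwaTimecourse:
    def test_constant_power_normalizes_to_100(self, rng):
        epoch = _constant_epoch(rng)
        hyp = make_hypnogram(np.full(1800, NREM))
        rec = _recording([epoch] * 1800)
        ref = swa_reference(rec, hyp)
        tc = swa_timecourse(rec, hyp, ref, bin_hours=1.0)
        assert np.allclose(tc.table["swa_percent"], 100.0, atol=1e-9)

    def test_bin_without_nrem_is_missing_not_zero(self, rng):
        epoch = _constant_epoch(rng)
        states = np.r_[np.full(900, NREM), np.full(900, WAKE)]
        rec = _recording([epoch] * 1800)
        hyp = make_hypnogram(states)
        ref = swa_reference(rec, hyp)
        tc = swa_timecourse(rec, hyp, ref, bin_hours=1.0)
        assert bool(tc.table.iloc[1]["missing"])
        assert np.isnan(tc.table.iloc[1]["swa_percent"])

    def test_invalid_reference(self, rng):
        epoch = _constant_epoch(rng)
        hyp = make_hypnogram(np.full(900, NREM))
        with pytest.raises(ValueError):
            swa_timecourse(_recording([epoch] * 900), hyp, 0.0)


class TestMeanStateSpectrum:
    def test_single_epoch_identity(self, rng):
        x = rng.standard_normal(1024)
        rec = _recording([x])
        spec = mean_state_spectrum(rec, make_hypnogram([REM]), "REM")
        assert np.allclose(spec.power, epoch_spectrum(x).power, rtol=1e-12)
        assert spec.n_epochs_averaged == 1

    def test_two_epoch_average(self, rng):
        x, y = rng.standard_normal(1024), rng.standard_normal(1024)
        rec = _recording([x, y])
        spec = mean_state_spectrum(rec, make_hypnogram([REM, REM]), "REM")
        expected = (epoch_spectrum(x).power + epoch_spectrum(y).power) / 2
        assert np.allclose(spec.power, expected, rtol=1e-12)

    def test_artifact_epochs_excluded(self, rng):
        x, y = rng.standard_normal(1024), rng.standard_normal(1024)
        rec = _recording([x, y])
        hyp = make_hypnogram([REM, REM], artifacts=[False, True])
        spec = mean_state_spectrum(rec, hyp, "REM")
        assert spec.n_epochs_averaged == 1
        assert np.allclose(spec.power, epoch_spectrum(x).power, rtol=1e-12)

    def test_no_qualifying_epochs_error_names_state(self, rng):
        rec = _recording([rng.standard_normal(1024)])
        with pytest.raises(ValueError, match="REM"):
            mean_state_spectrum(rec, make_hypnogram([WAKE]), "REM")


class TestThetaPeakFrequency:
    @staticmethod
    def _spec(power):
        return PowerSpectrum(frequencies=FREQ_GRID, power=np.asarray(power, dtype=float))

    def test_peak_bin(self):
        p = np.ones(40)
        p[FREQ_GRID == 7.5] = 5.0
        assert theta_peak_frequency(self._spec(p)).tpf == 7.5

    def test_tie_breaks_low(self):
        p = np.ones(40)
        p[FREQ_GRID == 7.0] = 5.0
        p[FREQ_GRID == 7.5] = 5.0
        assert theta_peak_frequency(self._spec(p)).tpf == 7.0

    def test_all_zero_band_rejected(self):
        p = np.ones(40)
        p[(FREQ_GRID >= 5.0) & (FREQ_GRID <= 10.0)] = 0.0
        with pytest.raises(ValueError):
            theta_peak_frequency(self._spec(p))

    def test_grid_closure(self, rng):
        for _ in range(50):
            tpf = theta_peak_frequency(self._spec(rng.random(40) + 0.01)).tpf
            assert 5.0 <= tpf <= 10.0 and (tpf * 2) == int(tpf * 2)

    def test_synthetic_rem_recovery(self):
        """Two hours of synthetic REM at a 7.6 Hz center estimate a TPF
        within 0.25 Hz of the nearest grid frequency."""
        cfg = SimulationConfig(groups={"G": GroupParams(theta_center_frequency=7.6)})
        hyp = make_hypnogram(np.full(1800, REM))
        rec = synthesize_signals(hyp, cfg, seed=62, group="G")
        tpf = theta_peak_frequency(mean_state_spectrum(rec, hyp, "REM")).tpf
        assert abs(tpf - 7.5) <= 0.25


class TestNormalizationInvariance:
    def test_gain_change_leaves_normalized_swa_and_tpf_unchanged(self, config, rng):
        states = np.r_[np.full(950, NREM), np.full(250, REM), np.full(600, WAKE)]
        hyp = make_hypnogram(states)
        rec = synthesize_signals(hyp, config, seed=63, homeostat=False)
        scaled = EpochedRecording(
            channels={"EEG": rec.channels["EEG"] * 4.0, "EMG": rec.channels["EMG"]},
            sampling_rate=rec.sampling_rate,
        )
        ref1 = swa_reference(rec, hyp, min_epochs=100)
        ref2 = swa_reference(scaled, hyp, min_epochs=100)
        assert ref2 == pytest.approx(16.0 * ref1, rel=1e-6)
        tc1 = swa_timecourse(rec, hyp, ref1, bin_hours=1.0)
        tc2 = swa_timecourse(scaled, hyp, ref2, bin_hours=1.0)
        a, b = tc1.table["swa_percent"], tc2.table["swa_percent"]
        assert np.allclose(a.dropna(), b.dropna(), rtol=1e-6)
        t1 = theta_peak_frequency(mean_state_spectrum(rec, hyp, "REM")).tpf
        t2 = theta_peak_frequency(mean_state_spectrum(scaled, hyp, "REM")).tpf
        assert t1 == t2
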