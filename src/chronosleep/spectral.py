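"""Epoch-based EEG spectra, slow-wave activity and theta peak frequency.

Each 4-s epoch (1024 samples at 256 Hz) is split into two non-overlapping
2-s segments; each segment is Hann-windowed and periodogram-transformed at
its native 0.5 Hz spacing and the two periodograms are averaged (a Welch
estimate).  Only the 0.5-20 Hz bins are retained, giving the 40-bin grid
0.5, 1.0, ..., 20.0 Hz.  SWA is the mean power over 0.5-4.0 Hz (8 bins,
both edges inclusive) during NREM sleep, expressed per animal as a
percentage of the mean SWA over the chronologically last 900 artifact-free
NREM epochs of the baseline light period.  Theta peak frequency (TPF) is
the frequency of maximal power between 5 and 10 Hz (11 bins, inclusive) of
interval-averaged REM spectra.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import NREM, STATE_CODES, EpochedRecording, Hypnogram

GRID_STEP = 0.5
GRID_LO, GRID_HI = 0.5, 20.0
FREQ_GRID = np.round(np.arange(1, 41) * GRID_STEP, 10)  # 0.5 ... 20.0 Hz
SWA_BAND = (0.5, 4.0)
THETA_BAND = (5.0, 10.0)


@dataclass
class PowerSpectrum:
    """Power on the analysis grid, (signal units)^2 / Hz."""

    frequencies: np.ndarray
    power: np.ndarray
    n_epochs_averaged: int = 1
    state: str | None = None

    def __post_init__(self) -> None:
        self.frequencies = np.asarray(self.frequencies, dtype=float)
        self.power = np.asarray(self.power, dtype=float)
        if self.frequencies.shape != self.power.shape:
            raise ValueError("frequency and power grids differ in length")
        if self.power.size and np.any(self.power < 0):
            raise ValueError("power must be non-negative")


@dataclass
class SWATimecourse:
    """Normalized SWA per time bin; under-sampled bins are missing, not zero."""

    table: pd.DataFrame  # bin_start, bin_end, swa_percent, n_nrem_epochs, missing
    reference: float
    condition: str = "baseline"


@dataclass
class TPFEstimate:
    """Theta peak frequency for one interval's mean REM spectrum."""

    tpf: float
    interval: tuple | None = None
    n_epochs: int = 0


def _segment_periodograms(epochs: np.ndarray, sampling_rate: float) -> np.ndarray:
    """Welch estimate per epoch row: two Hann 2-s segments, averaged.

    Returns one-sided power spectral density rows on the full native grid
    (0 ... Nyquist at 0.5 Hz spacing).
    """
    n_samples = epochs.shape[-1]
    seg = n_samples // 2
    x = epochs.reshape(epochs.shape[0], 2, seg).astype(np.float64)
    window = 0.5 - 0.5 * np.cos(2 * np.pi * np.arange(seg) / seg)  # periodic Hann
    X = np.fft.rfft(x * window, axis=-1)
    psd = (np.abs(X) ** 2) / (sampling_rate * np.sum(window**2))
    psd[..., 1:-1] *= 2.0  # one-sided doubling, DC and Nyquist excluded
    return psd.mean(axis=1)


def epoch_spectra(
    epochs: np.ndarray, sampling_rate: float = 256.0, full_band: bool = False
) -> np.ndarray:
    """Per-epoch power spectra for a (n_epochs, samples) array.

    Returns (n_epochs, 40) power on the 0.5-20 Hz grid, or the full
    one-sided grid (0 ... Nyquist) when ``full_band`` is set.
    """
    epochs = np.asarray(epochs)
    if epochs.ndim != 2:
        raise ValueError("expected a 2-D (n_epochs, samples) array")
    if epochs.shape[-1] % 2:
        raise ValueError("epoch length must be even")
    if epochs.size and not np.all(np.isfinite(epochs)):
        raise ValueError("non-finite samples in input")
    psd = _segment_periodograms(epochs, sampling_rate)
    if full_band:
        return psd
    seg = epochs.shape[-1] // 2
    df = sampling_rate / seg
    idx = np.round(FREQ_GRID / df).astype(int)
    if np.any(np.abs(idx * df - FREQ_GRID) > 1e-9) or idx[-1] >= psd.shape[-1]:
        raise ValueError(
            "epoch length and sampling rate do not produce the 0.5 Hz analysis grid"
        )
    return psd[:, idx]


def epoch_spectrum(
    epoch_signal: np.ndarray, sampling_rate: float = 256.0, full_band: bool = False
) -> PowerSpectrum:
    """Welch power spectrum of a single epoch (1024 samples at 256 Hz).

    The native grid of the 2-s segments is 0.5 Hz, matching the analysis
    resolution directly; only the 0.5-20 Hz bins are retained unless
    ``full_band`` is requested.
    """
    x = np.asarray(epoch_signal, dtype=np.float64)
    if x.ndim != 1:
        raise ValueError("epoch signal must be one-dimensional")
    expected = int(round(4.0 * sampling_rate))
    if x.size != expected:
        raise ValueError(f"expected {expected} samples, got {x.size}")
    psd = epoch_spectra(x[None, :], sampling_rate, full_band=full_band)[0]
    if full_band:
        freqs = np.fft.rfftfreq(x.size // 2, d=1.0 / sampling_rate)
        return PowerSpectrum(frequencies=freqs, power=psd)
    return PowerSpectrum(frequencies=FREQ_GRID.copy(), power=psd)


def band_power(spectrum: PowerSpectrum, lo: float, hi: float) -> float:
    """Arithmetic mean power over grid bins with ``lo <= f <= hi`` (inclusive)."""
    if lo >= hi:
        raise ValueError("lo must be below hi")
    if lo < GRID_LO - 1e-9 or hi > GRID_HI + 1e-9:
        raise ValueError(f"band [{lo}, {hi}] outside the {GRID_LO}-{GRID_HI} Hz grid")
    mask = (spectrum.frequencies >= lo - 1e-9) & (spectrum.frequencies <= hi + 1e-9)
    if not mask.any():
        raise ValueError("band contains no grid bins")
    return float(spectrum.power[mask].mean())


def swa_per_epoch(recording: EpochedRecording, channel: str = "EEG") -> np.ndarray:
    """SWA (mean 0.5-4.0 Hz power) for every epoch of a recording."""
    spectra = epoch_spectra(recording.epochs_2d(channel), recording.sampling_rate)
    mask = (FREQ_GRID >= SWA_BAND[0]) & (FREQ_GRID <= SWA_BAND[1])
    return spectra[:, mask].mean(axis=1)


def _check_alignment(recording: EpochedRecording, hypnogram: Hypnogram) -> None:
    if recording.n_epochs != hypnogram.n_epochs:
        raise ValueError(
            f"recording has {recording.n_epochs} epochs but hypnogram has "
            f"{hypnogram.n_epochs}"
        )


def swa_reference(
    recording: EpochedRecording,
    hypnogram: Hypnogram,
    baseline_day: int = 0,
    n_reference: int = 900,
    min_epochs: int | None = None,
    _swa: np.ndarray | None = None,
) -> float:
    """Mean SWA over the last ``n_reference`` artifact-free NREM epochs of
    the baseline light period.

    ``baseline_day`` selects which recorded day counts as baseline (its
    light period spans hours ``[24*day, 24*day + light_hours)``).  Fewer
    than ``min_epochs`` (default ``n_reference``) qualifying epochs is an
    error; passing a smaller ``min_epochs`` overrides the requirement for
    short recordings, in which case all qualifying epochs are used.
    """
    _check_alignment(recording, hypnogram)
    if min_epochs is None:
        min_epochs = n_reference
    lo = baseline_day * hypnogram.schedule.cycle_hours
    window = hypnogram.window_mask(lo, lo + hypnogram.schedule.light_hours)
    qualify = window & (hypnogram.states == NREM) & ~hypnogram.artifact_flags
    idx = np.where(qualify)[0]
    if idx.size < min_epochs:
        raise ValueError(
            f"only {idx.size} artifact-free NREM epochs in the baseline light period "
            f"(need {min_epochs})"
        )
    idx = idx[-n_reference:]
    swa = swa_per_epoch(recording) if _swa is None else _swa
    return float(swa[idx].mean())


def swa_timecourse(
    recording: EpochedRecording,
    hypnogram: Hypnogram,
    reference: float,
    bin_hours: float = 2.0,
    min_nrem_epochs: int = 10,
    condition: str = "baseline",
    _swa: np.ndarray | None = None,
) -> SWATimecourse:
    """Normalized SWA time course: per-bin mean over artifact-free NREM
    epochs, as percentage of ``reference``.

    Bins with fewer than ``min_nrem_epochs`` qualifying epochs are flagged
    missing (NaN), never reported as zero.
    """
    if reference <= 0:
        raise ValueError("reference SWA must be positive")
    _check_alignment(recording, hypnogram)
    epochs_per_bin_f = bin_hours * 3600.0 / hypnogram.epoch_seconds
    if abs(epochs_per_bin_f - round(epochs_per_bin_f)) > 1e-9:
        raise ValueError("bin is not an integer number of epochs")
    epochs_per_bin = int(round(epochs_per_bin_f))
    if hypnogram.n_epochs % epochs_per_bin:
        raise ValueError("bin_hours does not divide the recording span")
    swa = swa_per_epoch(recording) if _swa is None else _swa
    qualify = (hypnogram.states == NREM) & ~hypnogram.artifact_flags
    rows = []
    for b in range(hypnogram.n_epochs // epochs_per_bin):
        sel = slice(b * epochs_per_bin, (b + 1) * epochs_per_bin)
        q = qualify[sel]
        n = int(q.sum())
        missing = n < min_nrem_epochs
        rows.append(
            {
                "bin_start": hypnogram.start_zt + b * bin_hours,
                "bin_end": hypnogram.start_zt + (b + 1) * bin_hours,
                "swa_percent": np.nan if missing else 100.0 * swa[sel][q].mean() / reference,
                "n_nrem_epochs": n,
                "missing": missing,
            }
        )
    return SWATimecourse(table=pd.DataFrame(rows), reference=reference, condition=condition)


def mean_state_spectrum(
    recording: EpochedRecording,
    hypnogram: Hypnogram,
    state: str,
    interval: tuple | None = None,
) -> PowerSpectrum:
    """Bin-wise mean of per-epoch spectra over artifact-free epochs of one
    state inside a time interval (hours; whole recording when omitted)."""
    _check_alignment(recording, hypnogram)
    code = STATE_CODES[state] if isinstance(state, str) else int(state)
    mask = (hypnogram.states == code) & ~hypnogram.artifact_flags
    if interval is not None:
        mask &= hypnogram.window_mask(*interval)
    idx = np.where(mask)[0]
    if idx.size == 0:
        where = f"in interval {interval}" if interval else "in the recording"
        raise ValueError(f"no artifact-free {state} epochs {where}")
    spectra = epoch_spectra(recording.epochs_2d("EEG")[idx], recording.sampling_rate)
    name = state if isinstance(state, str) else None
    return PowerSpectrum(
        frequencies=FREQ_GRID.copy(),
        power=spectra.mean(axis=0),
        n_epochs_averaged=int(idx.size),
        state=name,
    )


def theta_peak_frequency(
    mean_spectrum: PowerSpectrum, interval: tuple | None = None
) -> TPFEstimate:
    """Grid frequency of maximal power in 5-10 Hz; ties break low."""
    mask = (mean_spectrum.frequencies >= THETA_BAND[0] - 1e-9) & (
        mean_spectrum.frequencies <= THETA_BAND[1] + 1e-9
    )
    if not mask.any():
        raise ValueError("spectrum does not cover the 5-10 Hz band")
    band = mean_spectrum.power[mask]
    if np.all(band == 0):
        raise ValueError("all-zero power in the 5-10 Hz band")
    freqs = mean_spectrum.frequencies[mask]
    return TPFEstimate(
        tpf=float(freqs[int(np.argmax(band))]),
        interval=interval,
        n_epochs=mean_spectrum.n_epochs_averaged,
    )
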