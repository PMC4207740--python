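"""Vigilance-state time budgets, L-D amplitudes, rasters and activity profiles.

All percentages are of recording time; artifact-flagged epochs count toward
their state's budget (artifacts are excluded only from spectral averaging).
Bins are half-open ``[start, end)`` intervals on the recording-hour axis.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import N_STATES, STATE_NAMES, WAKE, ActivitySeries, Hypnogram


@dataclass
class VigilanceSummary:
    """Per-bin state percentages plus 12-h L/D and 24-h aggregates.

    ``table`` has one row per bin with columns ``bin_start``, ``bin_end``
    (hours), one percentage column per state and ``n_epochs``.  ``light``,
    ``dark`` and ``total`` are dicts mapping state name to percentage, with
    an extra ``n_epochs`` entry.
    """

    table: pd.DataFrame
    light: dict
    dark: dict
    total: dict
    animal_id: str | None = None
    group: str | None = None


@dataclass
class LDAmplitude:
    """Signed light-dark difference per state, in percentage points."""

    amplitudes: dict
    normalized: bool = False
    animal_id: str | None = None
    group: str | None = None

    def __getitem__(self, state: str) -> float:
        return self.amplitudes[state]


@dataclass
class ActivityProfile:
    """Wheel counts accumulated across days, folded onto one 24-h cycle."""

    counts: np.ndarray
    bin_minutes: int = 18
    n_days: float = 0.0
    group: str | None = None

    @property
    def n_bins(self) -> int:
        return int(self.counts.size)

    def bin_centers_zt(self) -> np.ndarray:
        return (np.arange(self.n_bins) + 0.5) * self.bin_minutes / 60.0


def _percentages(states: np.ndarray) -> dict:
    n = states.size
    out = {}
    for code, name in enumerate(STATE_NAMES):
        out[name] = 100.0 * np.count_nonzero(states == code) / n if n else np.nan
    out["n_epochs"] = int(n)
    return out


def state_fractions(
    hypnogram: Hypnogram,
    bin_hours: float = 2.0,
    animal_id: str | None = None,
    group: str | None = None,
) -> VigilanceSummary:
    """Percentage of recording time per vigilance state, in time bins.

    ``bin_hours`` must divide the recording span.  The L/D aggregates pool
    every light-phase (resp. dark-phase) epoch across days; the 24-h total
    pools everything.
    """
    if hypnogram.n_epochs == 0:
        raise ValueError("empty hypnogram")
    span = hypnogram.span_hours
    n_bins_f = span / bin_hours
    if abs(n_bins_f - round(n_bins_f)) > 1e-9:
        raise ValueError(f"bin_hours={bin_hours} does not divide the {span} h span")
    epochs_per_bin_f = bin_hours * 3600.0 / hypnogram.epoch_seconds
    if abs(epochs_per_bin_f - round(epochs_per_bin_f)) > 1e-9:
        raise ValueError("bin is not an integer number of epochs")
    epochs_per_bin = int(round(epochs_per_bin_f))
    n_bins = int(round(n_bins_f))

    rows = []
    for b in range(n_bins):
        seg = hypnogram.states[b * epochs_per_bin : (b + 1) * epochs_per_bin]
        if seg.size == 0:
            raise ValueError(f"bin {b} is empty")
        row = {
            "bin_start": hypnogram.start_zt + b * bin_hours,
            "bin_end": hypnogram.start_zt + (b + 1) * bin_hours,
        }
        row.update(_percentages(seg))
        rows.append(row)
    table = pd.DataFrame(rows)

    light_mask = hypnogram.schedule.is_light(hypnogram.epoch_zt())
    light = _percentages(hypnogram.states[light_mask])
    dark = _percentages(hypnogram.states[~light_mask])
    total = _percentages(hypnogram.states)
    return VigilanceSummary(
        table=table, light=light, dark=dark, total=total, animal_id=animal_id, group=group
    )


def ld_amplitude(summary: VigilanceSummary, normalized: bool = False) -> LDAmplitude:
    """Light-dark amplitude per state: ``state%(L) - state%(D)``.

    With ``normalized=True`` the difference is divided by the L/D mean,
    ``(L - D) / ((L + D) / 2)`` — the study quantified "relative L-D
    differences" without giving the formula, so both variants are exposed
    and the signed difference in percentage points is the default.
    """
    for phase, name in ((summary.light, "light"), (summary.dark, "dark")):
        if not phase or phase["n_epochs"] == 0:
            raise ValueError(f"summary lacks a {name}-phase aggregate")
    amps = {}
    for state in STATE_NAMES:
        l, d = summary.light[state], summary.dark[state]
        if normalized:
            mean = (l + d) / 2.0
            amps[state] = (l - d) / mean if mean > 0 else 0.0
        else:
            amps[state] = l - d
    return LDAmplitude(
        amplitudes=amps,
        normalized=normalized,
        animal_id=summary.animal_id,
        group=summary.group,
    )


def wake_raster(hypnogram: Hypnogram, bin_minutes: float = 5.0) -> np.ndarray:
    """Fraction of WAKE epochs per ``bin_minutes`` bin, in [0, 1]."""
    if hypnogram.n_epochs == 0:
        raise ValueError("empty hypnogram")
    epochs_per_bin_f = bin_minutes * 60.0 / hypnogram.epoch_seconds
    if abs(epochs_per_bin_f - round(epochs_per_bin_f)) > 1e-9:
        raise ValueError("bin is not an integer number of epochs")
    epochs_per_bin = int(round(epochs_per_bin_f))
    if hypnogram.n_epochs % epochs_per_bin:
        raise ValueError("bin_minutes does not divide the recording span")
    wake = (hypnogram.states == WAKE).reshape(-1, epochs_per_bin)
    return wake.mean(axis=1)


def sd_efficiency(hypnogram: Hypnogram, window: tuple) -> float:
    """Percentage of in-window epochs scored WAKE (the deprivation efficiency)."""
    lo, hi = window
    if hi <= lo:
        raise ValueError("empty window")
    mask = hypnogram.window_mask(lo, hi)
    n = int(mask.sum())
    if n == 0:
        raise ValueError(f"window [{lo}, {hi}) lies outside the recording")
    return 100.0 * np.count_nonzero(hypnogram.states[mask] == WAKE) / n


def bin_activity(
    series: ActivitySeries, bin_minutes: int = 18, group: str | None = None
) -> ActivityProfile:
    """Accumulate wheel counts across days into a folded 24-h profile.

    Counts are summed within each ``bin_minutes`` bin of the cycle and
    accumulated over all complete days; trailing partial days are rejected.
    """
    if 1440 % bin_minutes:
        raise ValueError(f"bin_minutes={bin_minutes} does not divide 1440")
    if series.n_minutes < 1440:
        raise ValueError("activity series shorter than one full day")
    if series.n_minutes % 1440:
        raise ValueError("activity series must cover whole days")
    days = series.counts.reshape(-1, 1440)
    folded = days.sum(axis=0)
    profile = folded.reshape(-1, bin_minutes).sum(axis=1)
    return ActivityProfile(
        counts=profile, bin_minutes=bin_minutes, n_days=series.n_days, group=group
    )


def half_max_activity_time(profile: ActivityProfile, smoothing_bins: int = 3) -> float:
    """ZT at which nocturnal activity first falls below half its peak.

    The profile is smoothed with a centered ``smoothing_bins``-wide moving
    average (circular), the nocturnal (dark-phase) peak located, and the
    first crossing below 50% of that peak after it is linearly
    interpolated between bin centers.  Raises if the profile never falls
    below half-maximum before lights-on.
    """
    if smoothing_bins < 1 or smoothing_bins % 2 == 0:
        raise ValueError("smoothing_bins must be a positive odd count")
    counts = profile.counts.astype(float)
    if smoothing_bins > 1:
        kernel = np.ones(smoothing_bins) / smoothing_bins
        padded = np.concatenate([counts[-(smoothing_bins // 2):], counts, counts[: smoothing_bins // 2]])
        smoothed = np.convolve(padded, kernel, mode="valid")
    else:
        smoothed = counts
    centers = profile.bin_centers_zt()
    dark = centers >= 12.0  # standard 12:12 convention: D spans ZT 12-24
    if not dark.any():
        raise ValueError("profile does not cover the dark phase")
    dark_idx = np.where(dark)[0]
    peak_rel = int(np.argmax(smoothed[dark_idx]))
    peak_idx = int(dark_idx[peak_rel])
    peak = smoothed[peak_idx]
    if peak <= 0:
        raise ValueError("nocturnal maximum is not positive")
    half = peak / 2.0
    for i in range(peak_idx, dark_idx[-1]):
        a, b = smoothed[i], smoothed[i + 1]
        if a >= half > b:
            frac = (a - half) / (a - b)
            return float(centers[i] + frac * (centers[i + 1] - centers[i]))
    raise ValueError("no crossing: activity never falls below half-maximum before lights-on")
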