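"""Seeded synthetic cohorts: hypnograms, EEG/EMG signals, wheel counts, expression.

The generators emulate the statistical structure the analysis pipeline
assumes, so every downstream stage is testable without any recording:

* hypnograms follow a first-order Markov chain over WAKE/NREM/REM whose
  sleep-entry probabilities are modulated diurnally, with the modulation
  depth differing between cohort groups;
* EEG is a pink-noise floor plus state-conditional components — 0.5-4 Hz
  band-limited noise in NREM whose gain follows a two-process homeostat,
  a narrowband theta oscillation in REM, broadband noise in wake;
* wheel counts are Poisson with a nocturnal plateau that declines in the
  second half of the night;
* expression matrices carry planted day-night (ZT16 vs ZT4) inductions
  whose amplitude is attenuated in the mutant-like group.

Every generator is bit-reproducible given (config, seed).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import signal as sps

from .config import ConfigurationError, SimulationConfig
from .core import (
    NREM,
    REM,
    WAKE,
    ActivitySeries,
    EpochedRecording,
    ExpressionMatrix,
    Hypnogram,
)

# EMG root-mean-square per vigilance state (arbitrary units): muscle tone is
# high in wake, reduced in NREM and nearly absent in REM atonia.
EMG_RMS = {WAKE: 3.0, NREM: 1.0, REM: 0.3}

_SLEEP_ENTRY = [(WAKE, NREM), (WAKE, REM), (NREM, REM), (REM, NREM)]


def _as_rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def modulated_transition_matrices(
    config: SimulationConfig, depth: float, epoch_zt: np.ndarray
) -> np.ndarray:
    """Per-epoch transition matrices with diurnally modulated sleep entry.

    Off-diagonal probabilities into a sleep state are multiplied by
    ``m(t) = 1 + depth * cos(2*pi*(zt - phase)/24)`` and each row is then
    renormalized.  Raises :class:`ConfigurationError` naming the first
    offending epoch if any modulated probability leaves [0, 1].
    """
    m = 1.0 + depth * np.cos(2 * np.pi * (epoch_zt - config.modulation_phase) / 24.0)
    P = np.broadcast_to(
        config.base_transition_matrix, (epoch_zt.size, 3, 3)
    ).copy()
    for i, j in _SLEEP_ENTRY:
        P[:, i, j] *= m
    bad = np.where((P < 0).any(axis=(1, 2)) | (P > 1).any(axis=(1, 2)))[0]
    if bad.size:
        raise ConfigurationError(
            f"modulated transition probability outside [0, 1] at epoch {int(bad[0])} "
            f"(zt={epoch_zt[bad[0]]:.3f} h, depth={depth})"
        )
    P /= P.sum(axis=2, keepdims=True)
    return P


def simulate_hypnogram(
    config: SimulationConfig,
    group: str,
    seed=None,
    n_epochs: int | None = None,
    start_zt: float = 0.0,
    initial_state: int = WAKE,
) -> Hypnogram:
    """Simulate a per-epoch vigilance-state sequence for one animal.

    The chain starts in ``initial_state`` at ``start_zt``; artifact flags
    are drawn independently at ``config.artifact_probability``.
    """
    rng = _as_rng(config.random_seed if seed is None else seed)
    if n_epochs is None:
        n_epochs = config.recording_days * config.epochs_per_day
    depth = config.groups[group].modulation_depth if group in config.groups else 0.0
    dt_h = config.epoch_seconds / 3600.0
    epoch_zt = start_zt + np.arange(n_epochs) * dt_h
    P = modulated_transition_matrices(config, depth, epoch_zt)
    # cumulative rows for inverse-CDF sampling
    cum = np.cumsum(P, axis=2)
    u = rng.random(n_epochs)
    states = np.empty(n_epochs, dtype=np.int8)
    s = int(initial_state)
    for t in range(n_epochs):
        row = cum[t, s]
        ut = u[t]
        s = 0 if ut < row[0] else (1 if ut < row[1] else 2)
        states[t] = s
    artifacts = rng.random(n_epochs) < config.artifact_probability
    return Hypnogram(
        states=states,
        artifact_flags=artifacts,
        epoch_seconds=config.epoch_seconds,
        start_zt=start_zt,
        schedule=config.schedule,
    )


def homeostat_trajectory(
    hypnogram: Hypnogram, config: SimulationConfig, s0: float | None = None
) -> np.ndarray:
    """Process-S trajectory over the hypnogram (value at each epoch's end).

    S builds up during WAKE and REM (``S <- min(1, S + dt/tau_rise)``) and
    discharges exponentially during NREM (``S <- S * exp(-dt/tau_decay)``).
    """
    dt = hypnogram.epoch_seconds / 3600.0
    rise = dt / config.homeostat_rise_tau
    decay = np.exp(-dt / config.homeostat_decay_tau)
    s = config.homeostat_initial if s0 is None else float(s0)
    out = np.empty(hypnogram.n_epochs)
    states = hypnogram.states
    for t in range(hypnogram.n_epochs):
        if states[t] == NREM:
            s *= decay
        else:
            s = min(1.0, s + rise)
        out[t] = s
    return out


def _pink_noise(rng: np.random.Generator, n: int, fs: float, knee_hz: float = 0.5) -> np.ndarray:
    """Unit-RMS 1/f noise, flattened below ``knee_hz`` to keep power finite."""
    white = rng.standard_normal(n)
    X = np.fft.rfft(white)
    f = np.fft.rfftfreq(n, d=1.0 / fs)
    scale = 1.0 / np.sqrt(np.maximum(f, knee_hz))
    x = np.fft.irfft(X * scale, n)
    sd = x.std()
    return (x / sd if sd > 0 else x).astype(np.float32)


def _band_noise(rng: np.random.Generator, n: int, fs: float, lo: float, hi: float) -> np.ndarray:
    """Unit-RMS noise band-pass filtered to [lo, hi] Hz (4th-order Butterworth)."""
    sos = sps.butter(4, [lo, hi], btype="bandpass", fs=fs, output="sos")
    x = sps.sosfilt(sos, rng.standard_normal(n))
    sd = x.std()
    return (x / sd if sd > 0 else x).astype(np.float32)


def synthesize_signals(
    hypnogram: Hypnogram,
    config: SimulationConfig,
    seed=None,
    group: str = "WT",
    s_trajectory: np.ndarray | None = None,
    homeostat: bool = True,
) -> EpochedRecording:
    """Synthesize EEG and EMG channels consistent with a hypnogram.

    EEG per epoch = pink-noise floor + state component: NREM adds delta-band
    (0.5-4 Hz) noise with gain ``delta_gain * (0.5 + S)`` (S from the
    homeostat, or a fixed gain when ``homeostat=False``); REM adds a
    narrowband oscillation at the group's theta center; WAKE adds broadband
    noise.  Artifact-flagged epochs receive a high-amplitude transient.
    EMG RMS follows WAKE > NREM > REM.

    ``s_trajectory`` lets the caller supply a Process-S trajectory computed
    over a longer recording when synthesizing only a slice of it.
    """
    fs = config.sampling_rate
    theta_c = config.groups[group].theta_center_frequency if group in config.groups else 7.5
    bw = config.theta_bandwidth
    if not (0.5 < theta_c < 20.0):
        raise ValueError(
            f"theta_center_frequency {theta_c} Hz lies outside the analysis band (0.5, 20)"
        )
    if theta_c - bw / 2 <= 0:
        raise ValueError("theta band extends below 0 Hz")
    if hypnogram.epoch_seconds != config.epoch_seconds:
        raise ValueError("hypnogram epoch length inconsistent with config")
    n_epochs = hypnogram.n_epochs
    spe = config.samples_per_epoch
    n = n_epochs * spe
    meta = dict(
        sampling_rate=fs,
        epoch_seconds=config.epoch_seconds,
        start_zt=hypnogram.start_zt,
        schedule=hypnogram.schedule,
    )
    if n == 0:
        empty = np.zeros(0, dtype=np.float32)
        return EpochedRecording(channels={"EEG": empty, "EMG": empty.copy()}, **meta)

    rng = _as_rng(config.random_seed if seed is None else seed)
    states = hypnogram.states
    if homeostat:
        s = homeostat_trajectory(hypnogram, config) if s_trajectory is None else s_trajectory
        delta_per_epoch = config.delta_gain * (0.5 + np.asarray(s))
    else:
        delta_per_epoch = np.full(n_epochs, config.delta_gain)

    gain_delta = np.where(states == NREM, delta_per_epoch, 0.0).astype(np.float32)
    gain_theta = np.where(states == REM, config.theta_gain, 0.0).astype(np.float32)
    gain_wake = np.where(states == WAKE, config.wake_gain, 0.0).astype(np.float32)

    eeg = _pink_noise(rng, n, fs)
    eeg += _band_noise(rng, n, fs, 0.5, 4.0) * np.repeat(gain_delta, spe)
    eeg += _band_noise(rng, n, fs, theta_c - bw / 2, theta_c + bw / 2) * np.repeat(gain_theta, spe)
    eeg += rng.standard_normal(n).astype(np.float32) * np.repeat(gain_wake, spe)

    emg_rms = np.array([EMG_RMS[WAKE], EMG_RMS[NREM], EMG_RMS[REM]], dtype=np.float32)[states]
    emg = rng.standard_normal(n).astype(np.float32) * np.repeat(emg_rms, spe)

    art_idx = np.where(hypnogram.artifact_flags)[0]
    if art_idx.size:
        burst_len = max(1, int(0.5 * fs))
        burst = (25.0 * np.sin(np.pi * np.arange(burst_len) / burst_len)).astype(np.float32)
        for i in art_idx:
            eeg[i * spe : i * spe + burst_len] += burst
    return EpochedRecording(channels={"EEG": eeg, "EMG": emg}, **meta)


def apply_sleep_deprivation(
    hypnogram: Hypnogram, window: tuple, efficiency: float, seed=None
) -> Hypnogram:
    """Force in-window epochs to WAKE, each independently with P = efficiency.

    ``window`` is an (start, end) interval in absolute recording hours
    (hour 24 = ZT 0 of day two), matching gentle-handling deprivation whose
    per-epoch success rate is the protocol's efficiency.
    """
    if not 0.0 <= efficiency <= 1.0:
        raise ValueError("efficiency must lie in [0, 1]")
    lo, hi = window
    if hi <= lo:
        raise ValueError("empty sleep-deprivation window")
    mask = hypnogram.window_mask(lo, hi)
    if not mask.any():
        raise ValueError(
            f"sleep-deprivation window [{lo}, {hi}) lies outside the recording span"
        )
    rng = _as_rng(seed)
    states = hypnogram.states.copy()
    forced = mask & (rng.random(hypnogram.n_epochs) < efficiency)
    states[forced] = WAKE
    return Hypnogram(
        states=states,
        artifact_flags=hypnogram.artifact_flags.copy(),
        epoch_seconds=hypnogram.epoch_seconds,
        start_zt=hypnogram.start_zt,
        schedule=hypnogram.schedule,
    )


def simulate_wheel_activity(config: SimulationConfig, group: str, seed=None) -> ActivitySeries:
    """Poisson per-minute wheel counts over ``config.wheel_days`` days.

    The dark-phase rate starts at the group's nocturnal plateau and, if the
    group defines ``wheel_halfmax_zt``, declines logistically through the
    night with its half-maximum at that ZT — emulating the tapering of
    voluntary running toward the end of the active phase.
    """
    grp = config.groups[group]
    if grp.wheel_rate_light < 0 or grp.wheel_rate_dark < 0:
        raise ValueError("wheel rates must be non-negative")
    rng = _as_rng(config.random_seed if seed is None else seed)
    n_min = int(config.wheel_days * 24 * 60)
    zt = np.arange(n_min) / 60.0
    zt_mod = np.mod(zt, config.schedule.cycle_hours)
    light = config.schedule.is_light(zt)
    rate = np.where(light, grp.wheel_rate_light, grp.wheel_rate_dark).astype(float)
    if grp.wheel_halfmax_zt is not None:
        taper = 1.0 / (1.0 + np.exp((zt_mod - grp.wheel_halfmax_zt) / 0.6))
        rate = np.where(light, rate, rate * taper)
    counts = rng.poisson(rate)
    return ActivitySeries(counts=counts, start_zt=0.0, schedule=config.schedule)


def simulate_expression(config: SimulationConfig, seed=None):
    """Simulate a log2 expression matrix with planted day-night inductions.

    Planted genes gain ``expression_effect_log2fc`` at ZT16 relative to ZT4
    in the group with attenuation 1.0 (WT-like); other groups see the effect
    scaled by their ``expression_attenuation``, except for a small "robust"
    subset (the clock-gene analogue) that keeps
    ``expression_robust_attenuation`` of the effect everywhere.  Returns
    ``(ExpressionMatrix, truth)`` where ``truth`` records the planted and
    robust gene sets and the per-group effect scales.
    """
    if config.expression_replicates < 2:
        raise ValueError("at least 2 replicates per timepoint and genotype are required")
    rng = _as_rng(config.random_seed if seed is None else seed)
    n_genes = config.expression_n_genes
    gene_ids = [f"gene{i + 1:05d}" for i in range(n_genes)]
    planted = sorted(
        rng.choice(n_genes, size=config.expression_n_planted, replace=False).tolist()
    )
    robust = set(planted[: config.expression_n_robust])
    baseline = rng.normal(8.0, 1.0, size=n_genes)

    effect_scale = {}
    for label, grp in config.groups.items():
        scale = np.zeros(n_genes)
        for g in planted:
            att = grp.expression_attenuation
            if g in robust:
                att = max(att, config.expression_robust_attenuation)
            scale[g] = att
        effect_scale[label] = scale

    columns, data = [], []
    for label in sorted(config.groups):
        for tp in ("ZT4", "ZT16"):
            for rep in range(1, config.expression_replicates + 1):
                mu = baseline.copy()
                if tp == "ZT16":
                    mu = mu + config.expression_effect_log2fc * effect_scale[label]
                vals = mu + rng.normal(0.0, config.expression_noise_sd, size=n_genes)
                columns.append(f"{label}_{tp}_r{rep}")
                data.append(vals)
    values = pd.DataFrame(np.column_stack(data), index=gene_ids, columns=columns)
    ann = pd.DataFrame(
        [
            {
                "sample": c,
                "genotype": c.split("_")[0],
                "timepoint": c.split("_")[1],
                "replicate": int(c.split("_r")[-1]),
            }
            for c in columns
        ]
    ).set_index("sample")
    truth = {
        "planted_genes": [gene_ids[g] for g in planted],
        "robust_genes": [gene_ids[g] for g in sorted(robust)],
        "effect_log2fc": config.expression_effect_log2fc,
        "attenuation": {
            label: grp.expression_attenuation for label, grp in config.groups.items()
        },
        "robust_attenuation": config.expression_robust_attenuation,
    }
    return ExpressionMatrix(values=values, sample_annotations=ann), truth


def simulate_interaction_graph(
    seed=None, n_genes: int = 400, extra_hub_genes=(), attachment: int = 3
) -> pd.DataFrame:
    """Synthetic scale-free interaction edge list for end-to-end demos.

    This is a stand-in for a curated molecular-interaction database, which
    is proprietary; it only provides a graph with realistic degree
    heterogeneity over the synthetic gene universe.  ``extra_hub_genes``
    are appended as well-connected nodes so that expression hits can be
    wired into the network.
    """
    rng = _as_rng(seed)
    import networkx as nx

    names = [f"gene{i + 1:05d}" for i in range(n_genes)]
    for g in extra_hub_genes:
        if g not in names:
            names.append(g)
    g = nx.barabasi_albert_graph(len(names), attachment, seed=int(rng.integers(2**31)))
    mapping = dict(enumerate(names))
    rows = [
        {"source": mapping[a], "target": mapping[b]} for a, b in sorted(g.edges())
    ]
    return pd.DataFrame(rows)
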