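"""Simulation configuration for synthetic sleep-phenotyping cohorts.

The defaults describe a two-group cohort — a wild-type-like group ("WT")
with a deep diurnal modulation of sleep propensity, and a mutant-like group
("MUT") with an attenuated modulation — recorded under a 12:12 LD schedule
at 256 Hz with 4-s scoring epochs.  Group sizes follow the EEG cohort of
the phenotyping study this pipeline models (7 vs 8 animals); per-group
physiology (modulation depth, REM theta center, nocturnal wheel output,
day-night expression attenuation) is held in :class:`GroupParams`.
"""

from __future__ import annotations

import tomllib
from dataclasses import dataclass, field, replace

import numpy as np

from .core import N_STATES, NREM, REM, WAKE
from .schedule import LightSchedule


class ConfigurationError(ValueError):
    """Raised when a simulation configuration violates its invariants."""


def default_transition_matrix() -> np.ndarray:
    """Baseline per-epoch transition probabilities over (WAKE, NREM, REM).

    Chosen for plausible murine sleep at 4-s resolution: time budgets near
    47% wake / 42% NREM / 11% REM, mean bout lengths around 1.5 min (wake),
    1.3 min (NREM) and 1 min (REM), REM entered only from NREM
    (WAKE->REM is physiologically forbidden).
    """
    return np.array(
        [
            [0.955, 0.045, 0.000],  # from WAKE
            [0.032, 0.950, 0.018],  # from NREM
            [0.060, 0.010, 0.930],  # from REM
        ]
    )


@dataclass(frozen=True)
class GroupParams:
    """Per-group generator parameters."""

    n_animals: int = 7
    modulation_depth: float = 0.4  # amplitude A of diurnal sleep-propensity modulation
    theta_center_frequency: float = 7.2  # Hz, REM narrowband oscillation center
    wheel_rate_light: float = 1.0  # counts / min during L
    wheel_rate_dark: float = 20.0  # counts / min at the nocturnal plateau
    wheel_halfmax_zt: float = 18.3  # ZT at which nocturnal wheel output halves
    expression_attenuation: float = 1.0  # scale on planted day-night log2 effects


@dataclass(frozen=True)
class SimulationConfig:
    """Shared generator parameters plus the per-group table.

    All random draws are derived from ``random_seed``; each animal owns an
    independent stream spawned from (seed, group, animal index) so that
    changing the cohort size never perturbs existing animals.
    """

    epoch_seconds: float = 4.0
    sampling_rate: float = 256.0
    recording_days: int = 2  # day 1 baseline, day 2 optional SD day
    base_transition_matrix: np.ndarray = field(default_factory=default_transition_matrix)
    modulation_phase: float = 6.0  # hours; sleep propensity peaks mid-light
    theta_bandwidth: float = 1.0  # Hz, full width of the REM theta band
    delta_gain: float = 3.0  # NREM delta RMS relative to the pink-noise floor
    theta_gain: float = 3.0  # REM theta RMS relative to the pink-noise floor
    wake_gain: float = 1.0  # broadband wake RMS relative to the floor
    homeostat_rise_tau: float = 18.0  # hours, Process-S build-up in WAKE/REM
    homeostat_decay_tau: float = 4.0  # hours, Process-S discharge in NREM
    homeostat_initial: float = 0.6  # S at ZT0 (end of the active phase)
    artifact_probability: float = 0.01
    sd_window: tuple = (0.0, 6.0)  # ZT interval of enforced wakefulness
    sd_efficiency: float = 0.97
    wheel_days: int = 5
    expression_n_genes: int = 2000
    expression_n_planted: int = 22  # transcripts induced at ZT16 in the WT-like group
    expression_n_robust: int = 5  # planted subset keeping near-full induction in MUT
    expression_robust_attenuation: float = 0.85
    expression_effect_log2fc: float = 1.5
    expression_noise_sd: float = 0.25
    expression_replicates: int = 4
    swa_reference_epochs: int = 900  # reference-window size (and minimum, overridable)
    swa_min_bin_epochs: int = 10  # NREM epochs below which a SWA bin is missing
    random_seed: int = 0
    schedule: LightSchedule = field(default_factory=LightSchedule)
    groups: dict = field(
        default_factory=lambda: {
            "WT": GroupParams(),
            "MUT": GroupParams(
                n_animals=8,
                modulation_depth=0.15,
                theta_center_frequency=7.6,
                wheel_rate_dark=12.0,
                wheel_halfmax_zt=17.1,
                expression_attenuation=0.25,
            ),
        }
    )

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "base_transition_matrix", np.asarray(self.base_transition_matrix, dtype=float)
        )
        self.validate()

    def validate(self) -> None:
        P = self.base_transition_matrix
        if P.shape != (N_STATES, N_STATES):
            raise ConfigurationError("base_transition_matrix must be 3x3")
        if np.any(P < 0) or np.any(P > 1):
            raise ConfigurationError("transition probabilities must lie in [0, 1]")
        if not np.allclose(P.sum(axis=1), 1.0, atol=1e-9):
            raise ConfigurationError("each transition-matrix row must sum to 1")
        if P[WAKE, REM] != 0:
            raise ConfigurationError("WAKE->REM transitions are forbidden")
        if not 0.0 <= self.sd_efficiency <= 1.0:
            raise ConfigurationError("sd_efficiency must lie in [0, 1]")
        if not 0.0 <= self.artifact_probability <= 1.0:
            raise ConfigurationError("artifact_probability must lie in [0, 1]")
        for name in (
            "homeostat_rise_tau",
            "homeostat_decay_tau",
            "delta_gain",
            "theta_gain",
            "wake_gain",
            "theta_bandwidth",
            "expression_noise_sd",
        ):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name} must be non-negative")
        for label, grp in self.groups.items():
            if grp.modulation_depth < 0:
                raise ConfigurationError(f"group {label}: modulation depth must be >= 0")
            if grp.wheel_rate_light < 0 or grp.wheel_rate_dark < 0:
                raise ConfigurationError(f"group {label}: wheel rates must be >= 0")

    @property
    def samples_per_epoch(self) -> int:
        return int(round(self.epoch_seconds * self.sampling_rate))

    @property
    def epochs_per_day(self) -> int:
        return int(round(24 * 3600 / self.epoch_seconds))

    def with_updates(self, **kwargs) -> "SimulationConfig":
        return replace(self, **kwargs)

    def animal_rng(self, group: str, animal_index: int, stream: str = "") -> np.random.Generator:
        """Independent stream for one animal (and optional sub-stream tag)."""
        group_id = sorted(self.groups).index(group) if group in self.groups else hash(group) % 2**16
        tag = sum(ord(c) for c in stream)
        return np.random.default_rng(
            np.random.SeedSequence(
                entropy=int(self.random_seed) % 2**31,
                spawn_key=(group_id, int(animal_index), tag),
            )
        )


def load_config(path) -> SimulationConfig:
    """Build a :class:`SimulationConfig` from a TOML file.

    Recognized tables: ``[simulation]`` for the shared scalars (any field
    of :class:`SimulationConfig` except ``groups``/``schedule``),
    ``[schedule]`` and one ``[groups.<label>]`` table per cohort group.
    Unknown keys raise, so typos never pass silently.
    """
    with open(path, "rb") as fh:
        raw = tomllib.load(fh)
    sim = dict(raw.get("simulation", {}))
    if "base_transition_matrix" in sim:
        sim["base_transition_matrix"] = np.asarray(sim["base_transition_matrix"], dtype=float)
    if "sd_window" in sim:
        sim["sd_window"] = tuple(sim["sd_window"])
    allowed = set(SimulationConfig.__dataclass_fields__) - {"groups", "schedule"}
    unknown = set(sim) - allowed
    if unknown:
        raise ConfigurationError(f"unknown [simulation] keys: {sorted(unknown)}")
    kwargs = dict(sim)
    if "schedule" in raw:
        kwargs["schedule"] = LightSchedule(**raw["schedule"])
    if "groups" in raw:
        groups = {}
        for label, fields in raw["groups"].items():
            unknown = set(fields) - set(GroupParams.__dataclass_fields__)
            if unknown:
                raise ConfigurationError(f"unknown keys for group {label}: {sorted(unknown)}")
            groups[label] = GroupParams(**fields)
        kwargs["groups"] = groups
    return SimulationConfig(**kwargs)
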