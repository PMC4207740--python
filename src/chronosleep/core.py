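"""Core containers: hypnograms, epoched recordings, activity and expression data.

Vigilance states are encoded as small integers (0 = WAKE, 1 = NREM,
2 = REM); :data:`STATE_NAMES` maps codes to labels.  All containers carry a
:class:`~chronosleep.schedule.LightSchedule` and a ``start_zt`` so that any
epoch or sample can be placed on the zeitgeber axis.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .schedule import LightSchedule

WAKE, NREM, REM = 0, 1, 2
STATE_NAMES = ("WAKE", "NREM", "REM")
STATE_CODES = {name: code for code, name in enumerate(STATE_NAMES)}
N_STATES = 3


@dataclass
class Hypnogram:
    """Per-epoch vigilance-state labels with artifact flags.

    Each epoch carries exactly one state label (epochs containing more than
    one state are assumed to have been scored as the prevailing one by the
    upstream scorer).  Artifact-flagged epochs keep their state label; the
    flag only excludes them from spectral averaging.
    """

    states: np.ndarray
    artifact_flags: np.ndarray
    epoch_seconds: float = 4.0
    start_zt: float = 0.0
    schedule: LightSchedule = field(default_factory=LightSchedule)

    def __post_init__(self) -> None:
        self.states = np.asarray(self.states, dtype=np.int8)
        self.artifact_flags = np.asarray(self.artifact_flags, dtype=bool)
        if self.states.shape != self.artifact_flags.shape:
            raise ValueError("states and artifact_flags must have equal length")
        if self.states.ndim != 1:
            raise ValueError("states must be one-dimensional")
        if self.states.size and not np.all((self.states >= 0) & (self.states < N_STATES)):
            raise ValueError("state codes must be 0 (WAKE), 1 (NREM) or 2 (REM)")
        if self.epoch_seconds <= 0:
            raise ValueError("epoch_seconds must be positive")

    @property
    def n_epochs(self) -> int:
        return int(self.states.size)

    @property
    def span_hours(self) -> float:
        return self.n_epochs * self.epoch_seconds / 3600.0

    def epoch_zt(self) -> np.ndarray:
        """Hours since ZT 0 of day one, at each epoch start."""
        return self.start_zt + np.arange(self.n_epochs) * (self.epoch_seconds / 3600.0)

    def labels(self) -> np.ndarray:
        return np.asarray(STATE_NAMES, dtype=object)[self.states]

    def window_mask(self, start_hour: float, end_hour: float) -> np.ndarray:
        """Boolean mask of epochs whose start lies in ``[start_hour, end_hour)``.

        Hours are absolute recording time (hour 24 = ZT 0 of day 2).
        """
        zt = self.epoch_zt()
        return (zt >= start_hour) & (zt < end_hour)

    def slice(self, start_epoch: int, end_epoch: int) -> "Hypnogram":
        """Contiguous sub-hypnogram with ``start_zt`` shifted accordingly."""
        return replace(
            self,
            states=self.states[start_epoch:end_epoch].copy(),
            artifact_flags=self.artifact_flags[start_epoch:end_epoch].copy(),
            start_zt=self.start_zt + start_epoch * self.epoch_seconds / 3600.0,
        )


@dataclass
class EpochedRecording:
    """Multichannel signal sampled at a fixed rate, sliceable into epochs."""

    channels: dict
    sampling_rate: float = 256.0
    epoch_seconds: float = 4.0
    start_zt: float = 0.0
    schedule: LightSchedule = field(default_factory=LightSchedule)

    def __post_init__(self) -> None:
        lengths = {name: len(sig) for name, sig in self.channels.items()}
        if len(set(lengths.values())) > 1:
            raise ValueError(f"channels differ in length: {lengths}")
        spe = self.samples_per_epoch
        n = next(iter(lengths.values())) if lengths else 0
        if n % spe:
            raise ValueError(
                f"channel length {n} is not a multiple of {spe} samples per epoch"
            )

    @property
    def samples_per_epoch(self) -> int:
        spe = self.epoch_seconds * self.sampling_rate
        if abs(spe - round(spe)) > 1e-9:
            raise ValueError("epoch_seconds * sampling_rate must be integral")
        return int(round(spe))

    @property
    def n_epochs(self) -> int:
        if not self.channels:
            return 0
        n = len(next(iter(self.channels.values())))
        return n // self.samples_per_epoch

    def epochs_2d(self, channel: str = "EEG") -> np.ndarray:
        """View of one channel reshaped to (n_epochs, samples_per_epoch)."""
        sig = np.asarray(self.channels[channel])
        return sig.reshape(self.n_epochs, self.samples_per_epoch)


@dataclass
class ActivitySeries:
    """Running-wheel revolution counts in one-minute bins."""

    counts: np.ndarray
    start_zt: float = 0.0
    schedule: LightSchedule = field(default_factory=LightSchedule)

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.size and (
            np.any(self.counts < 0) or not np.issubdtype(self.counts.dtype, np.integer)
        ):
            raise ValueError("counts must be non-negative integers")

    @property
    def n_minutes(self) -> int:
        return int(self.counts.size)

    @property
    def n_days(self) -> float:
        return self.n_minutes / 1440.0

    def minute_zt(self) -> np.ndarray:
        return self.start_zt + np.arange(self.n_minutes) / 60.0


@dataclass
class ExpressionMatrix:
    """Log2 expression values (genes x samples) with factorial annotations.

    ``values`` is a DataFrame indexed by gene id; ``sample_annotations`` is
    indexed by sample id with columns ``timepoint`` (ZT4/ZT16 or CT4/CT16),
    ``genotype`` and ``replicate``.
    """

    values: pd.DataFrame
    sample_annotations: pd.DataFrame

    def __post_init__(self) -> None:
        if self.values.index.has_duplicates or self.values.index.isna().any():
            raise ValueError("gene ids must be unique and non-missing")
        missing = set(self.values.columns) - set(self.sample_annotations.index)
        if missing:
            raise ValueError(f"samples without annotation: {sorted(missing)}")
        for col in ("timepoint", "genotype"):
            if col not in self.sample_annotations.columns:
                raise ValueError(f"sample_annotations lacks required column {col!r}")
            if self.sample_annotations[col].isna().any():
                raise ValueError(f"missing {col} annotation")

    @property
    def gene_ids(self):
        return self.values.index

    def samples_for(self, genotype: str, timepoint: str | None = None):
        ann = self.sample_annotations
        sel = ann["genotype"] == genotype
        if timepoint is not None:
            sel &= ann["timepoint"] == timepoint
        return list(ann.index[sel])
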