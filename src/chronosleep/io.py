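"""Plain-text I/O for every pipeline intermediate, plus a raw signal container.

Hypnograms travel as TSV (epoch_index, zt_start_s, state, artifact) with
``#key=value`` metadata header lines; wheel counts and expression matrices
as CSV; interaction graphs as two-column TSV edge lists; term collections
as GMT.  Signals use a documented container: little-endian float32 raw
samples (channels concatenated) next to a JSON header — written only at
run time, since recordings are bulky.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .core import STATE_CODES, ActivitySeries, EpochedRecording, ExpressionMatrix, Hypnogram
from .network import TermCollection
from .schedule import LightSchedule

_FLOAT_FMT = "%.10g"  # fixed formatting so re-runs are byte-identical


def _schedule_meta(schedule: LightSchedule) -> dict:
    return {
        "lights_on_zt": schedule.lights_on_zt,
        "light_hours": schedule.light_hours,
        "dark_hours": schedule.dark_hours,
    }


def _read_meta(path) -> dict:
    meta = {}
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            key, _, value = line[1:].strip().partition("=")
            meta[key] = value
    return meta


def write_hypnogram_tsv(hypnogram: Hypnogram, path) -> None:
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(f"#epoch_seconds={hypnogram.epoch_seconds:g}\n")
        fh.write(f"#start_zt={hypnogram.start_zt:g}\n")
        for k, v in _schedule_meta(hypnogram.schedule).items():
            fh.write(f"#{k}={v:g}\n")
        fh.write("epoch_index\tzt_start_s\tstate\tartifact\n")
        labels = hypnogram.labels()
        zt0 = hypnogram.start_zt * 3600.0
        for i in range(hypnogram.n_epochs):
            fh.write(
                f"{i}\t{zt0 + i * hypnogram.epoch_seconds:g}\t{labels[i]}\t"
                f"{int(hypnogram.artifact_flags[i])}\n"
            )


def read_hypnogram_tsv(path) -> Hypnogram:
    meta = _read_meta(path)
    df = pd.read_csv(path, sep="\t", comment="#")
    schedule = LightSchedule(
        lights_on_zt=float(meta.get("lights_on_zt", 0)),
        light_hours=float(meta.get("light_hours", 12)),
        dark_hours=float(meta.get("dark_hours", 12)),
    )
    states = df["state"].map(STATE_CODES)
    if states.isna().any():
        bad = df.loc[states.isna(), "state"].iloc[0]
        raise ValueError(f"unknown vigilance state label {bad!r}")
    return Hypnogram(
        states=states.to_numpy(dtype=np.int8),
        artifact_flags=df["artifact"].to_numpy(dtype=bool),
        epoch_seconds=float(meta.get("epoch_seconds", 4)),
        start_zt=float(meta.get("start_zt", 0)),
        schedule=schedule,
    )


def write_activity_csv(series: ActivitySeries, path) -> None:
    with open(path, "w") as fh:
        fh.write(f"#start_zt={series.start_zt:g}\n")
        for k, v in _schedule_meta(series.schedule).items():
            fh.write(f"#{k}={v:g}\n")
        fh.write("minute_index,counts\n")
        for i, c in enumerate(series.counts):
            fh.write(f"{i},{int(c)}\n")


def read_activity_csv(path) -> ActivitySeries:
    meta = _read_meta(path)
    df = pd.read_csv(path, comment="#")
    schedule = LightSchedule(
        lights_on_zt=float(meta.get("lights_on_zt", 0)),
        light_hours=float(meta.get("light_hours", 12)),
        dark_hours=float(meta.get("dark_hours", 12)),
    )
    return ActivitySeries(
        counts=df["counts"].to_numpy(dtype=np.int64),
        start_zt=float(meta.get("start_zt", 0)),
        schedule=schedule,
    )


def write_expression(matrix: ExpressionMatrix, values_path, annotations_path) -> None:
    matrix.values.to_csv(values_path, index_label="gene_id", float_format=_FLOAT_FMT)
    matrix.sample_annotations.to_csv(annotations_path, index_label="sample")


def read_expression(values_path, annotations_path) -> ExpressionMatrix:
    values = pd.read_csv(values_path, index_col="gene_id")
    ann = pd.read_csv(annotations_path, index_col="sample")
    return ExpressionMatrix(values=values, sample_annotations=ann)


def write_edge_list(edges: pd.DataFrame, path) -> None:
    edges.to_csv(path, sep="\t", index=False)


def read_edge_list(path) -> list:
    df = pd.read_csv(path, sep="\t")
    cols = list(df.columns[:2])
    return [tuple(row) for row in df[cols].itertuples(index=False)]


def read_gene_list(path) -> list:
    with open(path) as fh:
        return [line.strip() for line in fh if line.strip() and not line.startswith("#")]


def write_gene_list(genes, path) -> None:
    with open(path, "w") as fh:
        for g in genes:
            fh.write(f"{g}\n")


def read_gmt(path) -> TermCollection:
    terms, descriptions = {}, {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3 or not parts[0]:
                continue
            terms[parts[0]] = set(parts[2:]) - {""}
            descriptions[parts[0]] = parts[1]
    return TermCollection(terms=terms, descriptions=descriptions)


def write_gmt(terms: TermCollection, path) -> None:
    with open(path, "w") as fh:
        for name in sorted(terms.terms):
            desc = terms.descriptions.get(name, "na")
            members = "\t".join(sorted(terms.terms[name]))
            fh.write(f"{name}\t{desc}\t{members}\n")


def save_recording(recording: EpochedRecording, base_path) -> None:
    """Write the raw float32 container: ``<base>.f32`` + ``<base>.json``."""
    base = Path(base_path)
    names = sorted(recording.channels)
    data = np.concatenate(
        [np.asarray(recording.channels[n], dtype="<f4") for n in names]
    )
    data.tofile(base.with_suffix(".f32"))
    n = len(recording.channels[names[0]]) if names else 0
    header = {
        "channels": names,
        "samples_per_channel": int(n),
        "sampling_rate": recording.sampling_rate,
        "epoch_seconds": recording.epoch_seconds,
        "start_zt": recording.start_zt,
        "schedule": _schedule_meta(recording.schedule),
        "dtype": "<f4",
    }
    base.with_suffix(".json").write_text(json.dumps(header, indent=1, sort_keys=True))


def load_recording(base_path) -> EpochedRecording:
    base = Path(base_path)
    header = json.loads(base.with_suffix(".json").read_text())
    raw = np.fromfile(base.with_suffix(".f32"), dtype=header["dtype"])
    n = header["samples_per_channel"]
    channels = {
        name: raw[i * n : (i + 1) * n] for i, name in enumerate(header["channels"])
    }
    return EpochedRecording(
        channels=channels,
        sampling_rate=header["sampling_rate"],
        epoch_seconds=header["epoch_seconds"],
        start_zt=header["start_zt"],
        schedule=LightSchedule(**header["schedule"]),
    )
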