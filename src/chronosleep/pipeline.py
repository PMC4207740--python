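"""End-to-end orchestration: simulate -> architecture -> spectral -> stats ->
screen -> network, with a reproducibility manifest.

Every stage reads plain-text intermediates from (and writes them back to)
a run directory, so any stage can be re-run in isolation or fed real data
in place of the synthetic files.  All randomness flows from the config's
master seed through per-animal streams; re-running an identical config
reproduces byte-identical outputs (floating-point formatting is fixed).
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__, architecture, io, screen as screen_mod, spectral, stats
from .config import ConfigurationError, SimulationConfig, load_config
from .core import STATE_NAMES
from .network import InteractionGraph, TermCollection, shortest_path_network, hypergeometric_enrichment
from .synthetic import (
    apply_sleep_deprivation,
    homeostat_trajectory,
    simulate_expression,
    simulate_hypnogram,
    simulate_interaction_graph,
    simulate_wheel_activity,
    synthesize_signals,
)

logger = logging.getLogger(__name__)

STAGES = ("simulate", "architecture", "spectral", "stats", "screen", "network")
_FLOAT_FMT = "%.10g"


class StageError(RuntimeError):
    pass


class MissingInputError(StageError):
    pass


@dataclass
class RunManifest:
    config_hash: str
    seed: int
    version: str
    stages: list
    files: dict = field(default_factory=dict)
    timestamps: dict = field(default_factory=dict)

    def to_json(self) -> str:
        return json.dumps(
            {
                "config_hash": self.config_hash,
                "seed": self.seed,
                "version": self.version,
                "stages": self.stages,
                "files": self.files,
                "timestamps": self.timestamps,
            },
            indent=1,
            sort_keys=True,
        )


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _animals(config: SimulationConfig):
    for group in sorted(config.groups):
        for idx in range(config.groups[group].n_animals):
            yield group, idx


def _hypnogram_path(out: Path, group: str, idx: int) -> Path:
    return out / f"hypnogram_{group}_{idx:02d}.tsv"


def _require(path: Path, stage: str) -> Path:
    if not path.exists():
        raise MissingInputError(f"stage {stage!r} requires missing input {path}")
    return path


def stage_simulate(config: SimulationConfig, out: Path) -> list:
    """Write hypnograms (baseline day + SD day), wheel series and the
    expression matrix for the whole cohort."""
    written = []
    sd_lo = 24.0 + config.sd_window[0]
    sd_hi = 24.0 + config.sd_window[1]
    for group, idx in _animals(config):
        rng = config.animal_rng(group, idx, "hypnogram")
        hyp = simulate_hypnogram(config, group, seed=rng)
        if config.recording_days >= 2:
            hyp = apply_sleep_deprivation(
                hyp, (sd_lo, sd_hi), config.sd_efficiency,
                seed=config.animal_rng(group, idx, "sd"),
            )
        path = _hypnogram_path(out, group, idx)
        io.write_hypnogram_tsv(hyp, path)
        written.append(path)
        wheel = simulate_wheel_activity(config, group, seed=config.animal_rng(group, idx, "wheel"))
        wpath = out / f"wheel_{group}_{idx:02d}.csv"
        io.write_activity_csv(wheel, wpath)
        written.append(wpath)
    matrix, truth = simulate_expression(config, seed=config.animal_rng("WT", 0, "expression"))
    io.write_expression(matrix, out / "expression.csv", out / "expression_annotations.csv")
    (out / "expression_truth.json").write_text(json.dumps(truth, indent=1, sort_keys=True))
    written += [out / "expression.csv", out / "expression_annotations.csv", out / "expression_truth.json"]
    return written


def stage_architecture(config: SimulationConfig, out: Path) -> list:
    """State time budgets, L-D amplitudes and wheel-activity profiles."""
    frac_rows, amp_rows, half_rows = [], [], []
    profiles = {}
    for group, idx in _animals(config):
        hyp = io.read_hypnogram_tsv(_require(_hypnogram_path(out, group, idx), "architecture"))
        baseline = hyp.slice(0, min(hyp.n_epochs, config.epochs_per_day))
        summary = architecture.state_fractions(
            baseline, bin_hours=2.0, animal_id=f"{group}_{idx:02d}", group=group
        )
        for _, row in summary.table.iterrows():
            for state in STATE_NAMES:
                frac_rows.append(
                    {
                        "animal_id": summary.animal_id,
                        "group": group,
                        "bin_start": row["bin_start"],
                        "bin_end": row["bin_end"],
                        "state": state,
                        "percent": row[state],
                    }
                )
        amp = architecture.ld_amplitude(summary)
        for state in STATE_NAMES:
            amp_rows.append(
                {
                    "animal_id": summary.animal_id,
                    "group": group,
                    "state": state,
                    "amplitude": amp[state],
                }
            )
        wheel = io.read_activity_csv(out / f"wheel_{group}_{idx:02d}.csv")
        prof = architecture.bin_activity(wheel, bin_minutes=18, group=group)
        profiles.setdefault(group, np.zeros(prof.n_bins))
        profiles[group] += prof.counts
    for group, counts in sorted(profiles.items()):
        prof = architecture.ActivityProfile(
            counts=counts, bin_minutes=18, group=group,
            n_days=config.wheel_days * config.groups[group].n_animals,
        )
        half_rows.append(
            {"group": group, "half_max_zt": architecture.half_max_activity_time(prof)}
        )
    pd.DataFrame(frac_rows).to_csv(out / "state_fractions.csv", index=False, float_format=_FLOAT_FMT)
    pd.DataFrame(amp_rows).to_csv(out / "ld_amplitude.csv", index=False, float_format=_FLOAT_FMT)
    prof_df = pd.DataFrame(
        {f"counts_{g}": profiles[g] for g in sorted(profiles)}
    )
    prof_df.insert(0, "bin_start_zt", np.arange(len(prof_df)) * 18 / 60.0)
    prof_df.to_csv(out / "activity_profile.csv", index=False, float_format=_FLOAT_FMT)
    pd.DataFrame(half_rows).to_csv(out / "half_max_activity.csv", index=False, float_format=_FLOAT_FMT)
    return [out / f for f in ("state_fractions.csv", "ld_amplitude.csv", "activity_profile.csv", "half_max_activity.csv")]


def stage_spectral(config: SimulationConfig, out: Path, animals_per_group: int = 1) -> list:
    """SWA time courses (baseline vs SD day) and TPF per 6-h block.

    Signals are resynthesized deterministically from the stored hypnograms
    and the config's per-animal streams, so this stage needs no bulky
    signal files on disk.
    """
    swa_rows, tpf_rows = [], []
    for group in sorted(config.groups):
        for idx in range(min(animals_per_group, config.groups[group].n_animals)):
            hyp = io.read_hypnogram_tsv(_require(_hypnogram_path(out, group, idx), "spectral"))
            s = homeostat_trajectory(hyp, config)
            rec = synthesize_signals(
                hyp, config, seed=config.animal_rng(group, idx, "signals"),
                group=group, s_trajectory=s,
            )
            swa = spectral.swa_per_epoch(rec)
            ref = spectral.swa_reference(
                rec, hyp, baseline_day=0,
                n_reference=config.swa_reference_epochs,
                min_epochs=min(config.swa_reference_epochs, 100),
                _swa=swa,
            )
            tc = spectral.swa_timecourse(
                rec, hyp, ref, bin_hours=2.0,
                min_nrem_epochs=config.swa_min_bin_epochs, _swa=swa,
            )
            for _, row in tc.table.iterrows():
                day = int(row["bin_start"] // 24)
                swa_rows.append(
                    {
                        "animal_id": f"{group}_{idx:02d}",
                        "group": group,
                        "condition": "SD" if (day >= 1 and config.recording_days >= 2) else "baseline",
                        "bin_start": row["bin_start"],
                        "swa_percent": row["swa_percent"],
                        "n_nrem_epochs": row["n_nrem_epochs"],
                    }
                )
            for block in range(int(hyp.span_hours // 6)):
                interval = (block * 6.0, (block + 1) * 6.0)
                try:
                    spec = spectral.mean_state_spectrum(rec, hyp, "REM", interval)
                except ValueError:
                    continue
                est = spectral.theta_peak_frequency(spec, interval)
                tpf_rows.append(
                    {
                        "animal_id": f"{group}_{idx:02d}",
                        "group": group,
                        "block_start": interval[0],
                        "tpf_hz": est.tpf,
                        "n_rem_epochs": est.n_epochs,
                    }
                )
    pd.DataFrame(swa_rows).to_csv(out / "swa_timecourse.csv", index=False, float_format=_FLOAT_FMT)
    pd.DataFrame(tpf_rows).to_csv(out / "tpf.csv", index=False, float_format=_FLOAT_FMT)
    return [out / "swa_timecourse.csv", out / "tpf.csv"]


def stage_stats(config: SimulationConfig, out: Path) -> list:
    """Genotype x vigilance-state ANOVA on L-D amplitudes + per-state MW tests."""
    amps = pd.read_csv(_require(out / "ld_amplitude.csv", "stats"))
    aov = stats.two_way_anova(
        amps["amplitude"], amps["group"], amps["state"],
        a_name="genotype", b_name="state",
    )
    aov.table.to_csv(out / "anova_ld_amplitude.csv", index_label="effect", float_format=_FLOAT_FMT)
    groups = sorted(amps["group"].unique())
    rows = []
    if len(groups) == 2:
        for state in STATE_NAMES:
            sub = amps[amps["state"] == state]
            x = sub.loc[sub["group"] == groups[0], "amplitude"].to_numpy()
            y = sub.loc[sub["group"] == groups[1], "amplitude"].to_numpy()
            res = stats.mann_whitney_u(x, y)
            rows.append(
                {"state": state, "u": res.u, "p": res.p, "method": res.method,
                 "group_x": groups[0], "group_y": groups[1]}
            )
    pd.DataFrame(rows).to_csv(out / "mann_whitney_ld_amplitude.csv", index=False, float_format=_FLOAT_FMT)
    return [out / "anova_ld_amplitude.csv", out / "mann_whitney_ld_amplitude.csv"]


def stage_screen(config: SimulationConfig, out: Path) -> list:
    """Day-night screens per genotype and the attenuation comparison."""
    matrix = io.read_expression(
        _require(out / "expression.csv", "screen"), out / "expression_annotations.csv"
    )
    results = {}
    written = []
    for genotype in sorted(config.groups):
        res = screen_mod.day_night_screen(matrix, genotype)
        results[genotype] = res
        path = out / f"screen_{genotype}.csv"
        res.table.to_csv(path, index_label="gene_id", float_format=_FLOAT_FMT)
        written.append(path)
    if {"WT", "MUT"} <= set(results):
        att = screen_mod.amplitude_attenuation(results["WT"], results["MUT"])
        att.table.to_csv(out / "attenuation.csv", index_label="gene_id", float_format=_FLOAT_FMT)
        (out / "pass_sets.json").write_text(
            json.dumps(
                {
                    "wt_only": sorted(att.wt_only),
                    "shared": sorted(att.shared),
                    "mut_only": sorted(att.mut_only),
                },
                indent=1,
            )
        )
        written += [out / "attenuation.csv", out / "pass_sets.json"]
    return written


def stage_network(
    config: SimulationConfig, out: Path, graph_path=None, terms_path=None
) -> list:
    """Seed-gene subnetwork + enrichment.

    Seeds are the WT screen hits; with no user-supplied edge list a
    synthetic interaction graph over the expression universe is generated
    (and clearly labeled as such).
    """
    wt_screen = pd.read_csv(_require(out / "screen_WT.csv", "network"), index_col="gene_id")
    seeds = sorted(wt_screen.index[wt_screen["passed"]])
    if not seeds:
        raise StageError("no screen hits to seed the network")
    if graph_path is not None:
        edges = io.read_edge_list(_require(Path(graph_path), "network"))
        graph_source = str(graph_path)
    else:
        edge_df = simulate_interaction_graph(
            seed=config.animal_rng("WT", 0, "graph"), extra_hub_genes=seeds
        )
        io.write_edge_list(edge_df, out / "synthetic_interaction_graph.tsv")
        edges = [tuple(r) for r in edge_df.itertuples(index=False)]
        graph_source = "synthetic"
    graph = InteractionGraph.from_edges(edges)
    model = shortest_path_network(graph, seeds, max_intermediates=1)
    pd.DataFrame(
        sorted(tuple(sorted(e)) for e in model.edges), columns=["source", "target"]
    ).to_csv(out / "network_edges.tsv", sep="\t", index=False)
    nodes = pd.DataFrame(
        [{"node": n, "role": "seed"} for n in sorted(model.seed_nodes)]
        + [{"node": n, "role": "connector"} for n in sorted(model.connector_nodes)]
    )
    nodes.to_csv(out / "network_nodes.csv", index=False)
    if terms_path is not None:
        terms = io.read_gmt(_require(Path(terms_path), "network"))
    else:
        truth_path = out / "expression_truth.json"
        planted = (
            json.loads(truth_path.read_text())["planted_genes"] if truth_path.exists() else seeds
        )
        terms = TermCollection.from_dict(
            {"planted_day_night_genes": set(planted)}
        )
    enrich = hypergeometric_enrichment(model.nodes, terms, graph.nodes)
    enrich.to_csv(out / "enrichment.csv", float_format=_FLOAT_FMT)
    (out / "network_meta.json").write_text(
        json.dumps(
            {
                "graph_source": graph_source,
                "n_seeds": len(model.seed_nodes),
                "n_connectors": len(model.connector_nodes),
                "n_edges": len(model.edges),
                "missing_seeds": sorted(model.missing_seeds),
            },
            indent=1,
            sort_keys=True,
        )
    )
    out_files = [out / "network_edges.tsv", out / "network_nodes.csv", out / "enrichment.csv", out / "network_meta.json"]
    if graph_path is None:
        out_files.append(out / "synthetic_interaction_graph.tsv")
    return out_files


_STAGE_FUNCS = {
    "simulate": stage_simulate,
    "architecture": stage_architecture,
    "spectral": stage_spectral,
    "stats": stage_stats,
    "screen": stage_screen,
    "network": stage_network,
}


def run_pipeline(
    config_path, stages=None, out_dir="chronosleep_run", **stage_kwargs
) -> RunManifest:
    """Execute pipeline stages in dependency order and write a manifest.

    ``stages`` defaults to all of :data:`STAGES`.  Raises
    :class:`ConfigurationError` on invalid config, ``ValueError`` on an
    unknown stage name and :class:`MissingInputError` when a stage's
    inputs are neither on disk nor produced by an earlier stage.
    """
    config = load_config(config_path) if not isinstance(config_path, SimulationConfig) else config_path
    stages = list(STAGES) if stages is None else list(stages)
    unknown = [s for s in stages if s not in _STAGE_FUNCS]
    if unknown:
        raise ValueError(f"unknown stage name(s): {unknown}; valid stages: {list(STAGES)}")
    stages = [s for s in STAGES if s in stages]  # dependency order
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    if isinstance(config_path, SimulationConfig):
        config_hash = hashlib.sha256(repr(config_path).encode()).hexdigest()
    else:
        config_hash = hashlib.sha256(Path(config_path).read_bytes()).hexdigest()
    manifest = RunManifest(
        config_hash=config_hash,
        seed=int(config.random_seed),
        version=__version__,
        stages=stages,
    )
    for stage in stages:
        t0 = time.time()
        logger.info("stage %s starting", stage)
        kwargs = {
            k[len(stage) + 1 :]: v
            for k, v in stage_kwargs.items()
            if k.startswith(stage + "_")
        }
        files = _STAGE_FUNCS[stage](config, out, **kwargs)
        for path in files:
            manifest.files[str(Path(path).relative_to(out))] = _sha256(Path(path))
        manifest.timestamps[stage] = time.time()
        logger.info("stage %s done in %.1f s", stage, time.time() - t0)
    (out / "manifest.json").write_text(manifest.to_json())
    return manifest
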