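"""End-to-end orchestration: ingest or simulate, subset every scenario,
compute all statistics, write all outputs from one declarative config.

The config is a nested key/value mapping (YAML on disk); every analysis
default is overridable there. Logging goes to standard error; results
are only ever written as delimited-text tables plus a manifest, so the
outputs stay machine-readable and byte-stable under a fixed seed.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time as _time
from itertools import combinations
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import pandas as pd
import yaml

from . import diversity, ordination, scheduler
from .io import read_annotations, read_point_counts, write_outputs
from .model import DetectionRecord, Scenario
from .simulate import SimulationConfig, default_community, simulate_detections

log = logging.getLogger("chorus_effort")

DEFAULT_CONFIG: dict[str, Any] = {
    "mode": "simulate",  # "simulate" | "files"
    "seed": 0,
    "output_dir": "chorus_effort_out",
    "inputs": {
        "annotations": None,
        "point_counts": None,
        "column_map": {},
    },
    "simulation": {
        "n_plots": 17,
        "n_days": 4,
        "n_species": 50,
    },
    "scenarios": {
        "intensities": [3, 6, 15, 30, 60],
        "phases": ["dawn", "morning", "both"],
        "durations": [1, 2, 3, 4],
    },
    "rarefaction": {
        "bootstrap": 200,
        "endpoint_factor": 2,
    },
    "nmds": {
        "enabled": True,
        "intensity": 15,
        "duration": 2,
        "k": 2,
        "restarts": 20,
        "metric": "euclidean",
    },
    "reference_minutes": 20,
}


def _deep_merge(base: Mapping[str, Any], override: Mapping[str, Any]) -> dict[str, Any]:
    out = dict(base)
    for key, value in override.items():
        if isinstance(value, Mapping) and isinstance(out.get(key), Mapping):
            out[key] = _deep_merge(out[key], value)
        else:
            out[key] = value
    return out


def load_config(source: str | Path | Mapping[str, Any] | None) -> dict[str, Any]:
    """Merge a YAML file or mapping over the package defaults."""
    if source is None:
        override: Mapping[str, Any] = {}
    elif isinstance(source, Mapping):
        override = source
    else:
        with open(source, "r", encoding="utf-8") as fh:
            override = yaml.safe_load(fh) or {}
    return _deep_merge(DEFAULT_CONFIG, override)


def _config_hash(config: Mapping[str, Any]) -> str:
    return hashlib.sha256(json.dumps(config, sort_keys=True, default=str).encode()).hexdigest()


def _stage_seeds(seed: int, n: int) -> list[int]:
    """Independent per-stage seeds (< 2^31) derived from the master seed."""
    return [int(child.generate_state(1)[0] % (2**31)) for child in np.random.SeedSequence(seed).spawn(n)]


def _ingest(config: Mapping[str, Any]) -> tuple[list[DetectionRecord], list[str], int, Any]:
    """Returns (records, plots, n_days, reference matrix or None)."""
    if config["mode"] == "simulate":
        sim = config["simulation"]
        sim_seed = _stage_seeds(int(config["seed"]), 1)[0]
        profiles = default_community(int(sim["n_species"]), seed=sim_seed)
        sconf = SimulationConfig(n_plots=int(sim["n_plots"]), n_days=int(sim["n_days"]), seed=sim_seed)
        records, _truth = simulate_detections(profiles, sconf)
        log.info("simulated %d detection records (%d plots, %d days, %d species)", len(records), sconf.n_plots, sconf.n_days, len(profiles))
        return records, list(sconf.plot_ids), sconf.n_days, None
    if config["mode"] != "files":
        raise ValueError(f"unknown mode {config['mode']!r}; expected 'simulate' or 'files'")
    inputs = config["inputs"]
    if not inputs.get("annotations"):
        raise ValueError("files mode requires inputs.annotations")
    records, report = read_annotations(inputs["annotations"], column_map=inputs.get("column_map") or None)
    log.info("ingest: %d rows read, %d retained, %d excluded", report.rows_read, report.rows_retained, report.rows_excluded)
    plots = sorted({r.plot_id for r in records})
    n_days = max((r.day_index for r in records), default=1)
    reference = None
    if inputs.get("point_counts"):
        reference = read_point_counts(inputs["point_counts"], unit_ids=plots)
        log.info("point-count reference: %d plots, %d species", reference.T, reference.S_obs)
    return records, plots, n_days, reference


def run_pipeline(config: str | Path | Mapping[str, Any] | None = None, *, out_dir: str | Path | None = None) -> dict[str, str]:
    """Run the full analysis; returns the output manifest.

    Stages: ingest/simulate -> scenario subsetting -> two-scale summary
    table -> rarefaction curves with bootstrap CI -> the three
    gradient-wise pairwise beta families -> gradient t-tests ->
    occurrence-by-time matrix -> optional NMDS -> delimited outputs plus
    manifest (config hash + seed). Deterministic under a fixed seed.
    """
    config = load_config(config)
    out = Path(out_dir if out_dir is not None else config["output_dir"])
    seed = int(config["seed"])
    t0 = _time.perf_counter()

    def stage(name: str) -> None:
        log.info("[%6.2fs] stage: %s", _time.perf_counter() - t0, name)

    stage("ingest")
    records, plots, n_days, reference = _ingest(config)

    stage("scenario subsetting")
    grid = config["scenarios"]
    scenarios = scheduler.enumerate_scenarios(
        grid["intensities"], grid["phases"], [d for d in grid["durations"] if d <= n_days]
    )
    matrices = {s: diversity.community_matrix(scheduler.subset_records(records, s), plots) for s in scenarios}
    log.info("%d scenarios over %d plots", len(scenarios), len(plots))

    stage("summary table")
    rows = diversity.build_summary_table(matrices, reference, reference_minutes=int(config["reference_minutes"]))
    summary = diversity.summary_frame(rows)

    stage("rarefaction curves")
    boot_seeds = _stage_seeds(seed, 2 + len(scenarios))
    B = int(config["rarefaction"]["bootstrap"])
    endpoint_factor = int(config["rarefaction"]["endpoint_factor"])
    curve_frames = []
    for i, s in enumerate(scenarios):
        m = matrices[s]
        curve = diversity.bootstrap_ci(m, B=B, seed=boot_seeds[2 + i], endpoint=endpoint_factor * m.T)
        frame = curve.to_frame()
        frame.insert(0, "scenario", s.label)
        curve_frames.append(frame)
    curves = pd.concat(curve_frames, ignore_index=True)

    stage("pairwise beta (three gradient families)")
    pools = {s: matrices[s].species_set for s in scenarios}
    intensities = sorted({s.intensity_min for s in scenarios})
    phases = [p for p in ("dawn", "morning", "both") if p in {s.day_phase for s in scenarios}]
    durations = sorted({s.duration_days for s in scenarios})
    beta_frames = []

    def beta_family(name: str, pairs: list[tuple[Scenario, Scenario]], cells: list[str]) -> None:
        frame = diversity.pairwise_beta_table(pools, pairs, family=name)
        frame.insert(1, "cell", cells)
        beta_frames.append(frame)

    pairs, cells = [], []
    for p in phases:
        for d in durations:
            for i1, i2 in combinations(intensities, 2):
                pairs.append((Scenario(i1, p, d), Scenario(i2, p, d)))
                cells.append(f"{p}_d{d}")
    beta_family("intensity", pairs, cells)

    pairs, cells = [], []
    for i in intensities:
        for d in durations:
            for p1, p2 in combinations(phases, 2):
                pairs.append((Scenario(i, p1, d), Scenario(i, p2, d)))
                cells.append(f"i{i:02d}_d{d}")
    beta_family("day_phase", pairs, cells)

    pairs, cells = [], []
    for i in intensities:
        for p in phases:
            for d1, d2 in combinations(durations, 2):
                pairs.append((Scenario(i, p, d1), Scenario(i, p, d2)))
                cells.append(f"i{i:02d}_{p}")
    beta_family("duration", pairs, cells)
    beta_long = pd.concat(beta_frames, ignore_index=True)

    stage("gradient t-tests")
    pooled = {s: matrices[s].S_obs for s in scenarios}
    ttest_frames = []
    for gradient, level_of in (
        ("intensity", lambda s: s.intensity_min),
        ("day_phase", lambda s: s.day_phase),
        ("duration", lambda s: s.duration_days),
    ):
        groups: dict[Any, list[float]] = {}
        for s in scenarios:
            groups.setdefault(level_of(s), []).append(float(pooled[s]))
        if all(len(v) >= 2 for v in groups.values()) and len(groups) >= 2:
            frame = diversity.gradient_ttest(groups)
            frame.insert(0, "gradient", gradient)
            ttest_frames.append(frame)
    ttests = pd.concat(ttest_frames, ignore_index=True) if ttest_frames else pd.DataFrame()

    stage("occurrence-by-time matrix")
    occ = diversity.occurrence_by_time(records)
    occ_out = occ.reset_index(names="species")
    occ_out.columns = ["species"] + [f"t{int(c):+04d}" for c in occ.columns]

    results: dict[str, pd.DataFrame] = {
        "summary_table": summary,
        "rarefaction_curves": curves,
        "beta_pairs_long": beta_long,
        "ttests": ttests,
        "occurrence_by_time": occ_out,
    }
    extra: dict[str, Any] = {"config_hash": _config_hash(config), "seed": seed, "n_plots": len(plots), "n_scenarios": len(scenarios)}

    nconf = config["nmds"]
    if nconf.get("enabled") and "dawn" in phases and "morning" in phases and 2 * len(plots) > int(nconf["k"]):
        stage("nmds")
        d_nmds = min(int(nconf["duration"]), n_days)
        points, labels = [], []
        for phase in ("dawn", "morning"):
            sub = scheduler.subset_records(records, Scenario(int(nconf["intensity"]), phase, d_nmds))
            mat = diversity.community_matrix(sub, plots)
            for row, plot in enumerate(mat.unit_ids):
                labels.append((plot, phase))
            points.append(mat.to_frame())
        stacked = pd.concat(points).fillna(0).astype(int)
        species = sorted(set(stacked.columns))
        cells = stacked.reindex(columns=species, fill_value=0).to_numpy(dtype=bool)
        from .model import IncidenceMatrix

        joint = IncidenceMatrix([f"{p}|{ph}" for p, ph in labels], species, cells)
        diss = ordination.assemblage_dissimilarity(joint, metric=nconf.get("metric", "euclidean"))
        res = ordination.nmds(diss, k=int(nconf["k"]), seed=boot_seeds[1], restarts=int(nconf["restarts"]))
        coords = pd.DataFrame(res.coordinates, columns=[f"axis{j + 1}" for j in range(res.coordinates.shape[1])])
        coords.insert(0, "phase", [ph for _, ph in labels])
        coords.insert(0, "plot", [p for p, _ in labels])
        results["nmds_coordinates"] = coords
        extra["nmds_stress"] = f"{res.stress:.6f}"
        extra["nmds_converged"] = res.converged

    stage("write outputs")
    manifest = write_outputs(results, out, manifest_extra=extra)
    log.info("wrote %d files to %s", len(results) + 1, out)
    return manifest
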