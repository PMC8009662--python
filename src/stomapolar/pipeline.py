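"""End-to-end pipeline: synthesize -> measure -> persistence -> lineage ->
simulator comparison, with a run manifest recording seeds, parameters and
input hashes so any run can be reproduced byte-for-byte.
"""

from __future__ import annotations

import hashlib
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from . import io, lineage as L, simulator, synth
from .persistence import PersistenceTrace, measure_persistence
from .polarity import measure_polarity, sample_profile, select_brightest_cells, trace_outline


@dataclass
class PipelineConfig:
    out_dir: str = "results/pipeline"
    seed: int = 0
    n_cells: int = 15
    n_portions: int = 63
    band_width: float = 3.0
    top_k: int = 10
    reporter_channel: int = 0
    membrane_channel: int = 1
    detect_contrast: float = 0.2
    detect_snr: float = 2.0
    frame_interval: float = 40.0
    n_frames: int = 13
    lineage_founders: int = 500
    sim_founders: int = 20000
    p_entry: float = 0.9
    p_amp: float = 0.5
    p_spacing: float = 0.1
    max_rounds: int = 5
    extra: dict = field(default_factory=dict)


def _file_hash(path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()[:16]


def _stage_seed(seed: int, stage: int, item: int = 0) -> int:
    return int(np.random.SeedSequence([seed, stage, item]).generate_state(1)[0] % (2 ** 31))


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every stage on synthetic inputs; returns the manifest dict.

    Stages: (1) render a population of synthetic cells and measure the POME
    table on the brightest ones, (2) render a post-division time series and
    measure persistence, (3) generate and summarize a lineage record,
    (4) run the simulator and compare against the analytic SI oracle.
    Any stage failure raises with the stage name attached.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"seed": config.seed, "config": asdict(config), "stages": {}}

    stage = "synth+measure"
    try:
        rng = np.random.default_rng(_stage_seed(config.seed, 1))
        records = []
        image_hashes = []
        for i in range(config.n_cells):
            params = synth.SynthCellParams(
                ellipse_axes=(float(rng.uniform(22, 32)), float(rng.uniform(16, 24))),
                baseline_intensity=float(rng.uniform(10, 30)),
                crescent_amplitude=float(rng.uniform(0, 90)),
                crescent_center=float(rng.uniform(0, 2 * np.pi)),
                crescent_width_sigma=float(rng.uniform(0.2, 0.8)),
                noise_sd=2.0,
                seed=_stage_seed(config.seed, 1, i + 1),
                cell_id=i + 1,
            )
            image, mask, truth = synth.render_cell_image(params)
            img_path = out / f"cell_{i + 1:02d}.tif"
            io.write_image(img_path, image)
            io.write_mask(out / f"cell_{i + 1:02d}_mask.tif", mask)
            io.write_json(out / f"cell_{i + 1:02d}_truth.json", truth)
            image_hashes.append(_file_hash(img_path))
            outline = trace_outline(mask, params.cell_id)
            profile = sample_profile(
                image, outline, config.n_portions, config.band_width,
                config.reporter_channel, config.membrane_channel)
            records.append((profile, measure_polarity(profile)))
        selected = select_brightest_cells([p for p, _ in records], k=config.top_k)
        table = [rec for p, rec in records if p.cell_id in selected]
        io.write_pome_table(out / "pome_table.csv", table)
        manifest["stages"][stage] = {
            "n_cells": config.n_cells, "selected": selected,
            "image_hashes": image_hashes, "pome_table": "pome_table.csv",
        }
    except Exception as exc:  # noqa: BLE001 - re-raise with stage context
        raise RuntimeError(f"pipeline stage '{stage}' failed: {exc}") from exc

    stage = "persistence"
    try:
        ts = synth.SynthTimeSeriesParams(
            frame_interval=config.frame_interval, n_frames=config.n_frames,
            half_life=160.0, disappearance_time=320.0,
            seed=_stage_seed(config.seed, 2))
        times, profiles, truth = synth.synthesize_decay_profiles(ts, noise_sd=2.0)
        trace = PersistenceTrace(cell_id=1, frame_times=times,
                                 records=[measure_polarity(p) for p in profiles])
        result = measure_persistence(trace, config.detect_contrast, config.detect_snr)
        io.write_persistence_table(out / "persistence.csv", [result])
        manifest["stages"][stage] = {
            "persistence_minutes": result.persistence_minutes,
            "censored": result.censored,
            "true_disappearance_frame": truth["disappearance_frame"],
        }
    except Exception as exc:  # noqa: BLE001
        raise RuntimeError(f"pipeline stage '{stage}' failed: {exc}") from exc

    stage = "lineage"
    try:
        record = synth.generate_lineage(synth.SynthLineageParams(
            n_founders=config.lineage_founders, p_entry=config.p_entry,
            p_amp=config.p_amp, p_spacing=config.p_spacing,
            max_steps=config.max_rounds, seed=_stage_seed(config.seed, 3)))
        issues = L.validate_lineage(record)
        if issues:
            raise ValueError(f"generated lineage invalid: {issues[:3]}")
        summary = L.summarize_divisions(record)
        io.write_lineage(out / "lineage.csv", record)
        io.write_json(out / "lineage_summary.json", {
            "counts": summary.counts, "fractions": summary.fractions,
            "total_divisions": summary.total_divisions,
            "meristemoid_histogram": summary.meristemoid_histogram,
            "stomatal_index": summary.stomatal_index,
            "cell_counts": summary.cell_counts,
        })
        manifest["stages"][stage] = {"stomatal_index": summary.stomatal_index,
                                     "total_divisions": summary.total_divisions}
    except Exception as exc:  # noqa: BLE001
        raise RuntimeError(f"pipeline stage '{stage}' failed: {exc}") from exc

    stage = "simulate"
    try:
        grid = simulator.sweep(
            p_amp_values=[0.0, 0.25, 0.5, 0.75],
            n_founders=config.sim_founders, max_rounds=config.max_rounds,
            seed=_stage_seed(config.seed, 4))
        grid.to_csv(out / "simulator_sweep.csv", index=False,
                    float_format=io.FLOAT_FORMAT)
        manifest["stages"][stage] = {
            "si": grid["stomatal_index"].tolist(),
            "expected_si": grid["expected_si_no_spacing"].tolist(),
        }
    except Exception as exc:  # noqa: BLE001
        raise RuntimeError(f"pipeline stage '{stage}' failed: {exc}") from exc

    io.write_json(out / "manifest.json", manifest)
    return manifest
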