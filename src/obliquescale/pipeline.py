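"""End-to-end pipeline orchestration.

A single YAML config drives the stages simulate → preprocess → register →
segment → fc → predict → geometry; each stage can be toggled.  A run
produces a JSON manifest recording the package version, per-stage seeds and
parameters, output paths and SHA-256 checksums of the numeric outputs, so a
rerun with the same config and seed is verifiably identical.

The single global seed is expanded deterministically into per-stage seeds
with ``numpy.random.SeedSequence``.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .core import CellTable, VolumeSeries
from .preprocess import ShearGeometry, unshear_volume
from .registration import detect_failed_frames, register_series
from .segmentation import segment_movie
from .synthetic import (
    GroundTruth,
    MovieNoiseModel,
    PopulationConfig,
    generate_cell_positions,
    generate_population_activity,
    generate_volume_movie,
)

__all__ = ["RunConfig", "run_pipeline"]

logger = logging.getLogger("obliquescale")

STAGES = ("simulate", "preprocess", "register", "segment", "fc", "predict", "geometry")


@dataclass
class RunConfig:
    """Pipeline run configuration (see package docs for the YAML schema)."""

    outdir: str = "run"
    seed: int = 0
    stages: dict = field(default_factory=lambda: {s: True for s in STAGES})
    population: dict = field(default_factory=dict)
    movie: dict = field(default_factory=dict)
    fc: dict = field(default_factory=dict)
    predict: dict = field(default_factory=dict)
    geometry: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        merged = {s: True for s in STAGES}
        merged.update(self.stages or {})
        unknown = set(merged) - set(STAGES)
        if unknown:
            raise ValueError(f"unknown stages: {sorted(unknown)}")
        self.stages = merged

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        d = yaml.safe_load(Path(path).read_text()) or {}
        unknown = set(d) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)


def _checksum(*arrays: np.ndarray) -> str:
    h = hashlib.sha256()
    for a in arrays:
        h.update(np.ascontiguousarray(a).tobytes())
    return h.hexdigest()[:16]


def _stage_seeds(seed: int) -> dict[str, int]:
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(len(STAGES))
    return {
        s: int(c.generate_state(1, dtype=np.uint32)[0]) % (2**31)
        for s, c in zip(STAGES, children)
    }


def run_pipeline(config: RunConfig) -> dict:
    """Execute the enabled stages and return (and write) the run manifest."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    seeds = _stage_seeds(config.seed)
    manifest: dict = {
        "version": __version__,
        "seed": config.seed,
        "stage_seeds": seeds,
        "stages": [],
    }

    def record(stage: str, params: dict, outputs: dict, checksum: str) -> None:
        manifest["stages"].append(
            {
                "stage": stage,
                "seed": seeds[stage],
                "params": params,
                "outputs": {k: str(v) for k, v in outputs.items()},
                "checksum": checksum,
            }
        )

    truth: GroundTruth | None = None
    movie: VolumeSeries | None = None
    table: CellTable | None = None
    valid = None

    t0 = time.time()
    current_stage = "init"
    try:
        current_stage = "simulate"
        if config.stages.get("simulate"):
            pop_kwargs = dict(config.population)
            pop_kwargs.setdefault("n_cells", 60)
            pop_kwargs.setdefault("duration", 360.0)
            pop_kwargs.setdefault("n_latent", 20)
            pop_kwargs.setdefault("brain_extent", (120.0, 90.0, 60.0))
            pop_kwargs["seed"] = seeds["simulate"]
            if "brain_extent" in pop_kwargs:
                pop_kwargs["brain_extent"] = tuple(pop_kwargs["brain_extent"])
            pop = PopulationConfig(**pop_kwargs)
            positions = generate_cell_positions(pop)
            truth = generate_population_activity(positions, pop)
            mv = dict(config.movie)
            geom = ShearGeometry(
                slope_s=float(mv.pop("slope_s", 1.0)),
                native_pitch=tuple(mv.pop("native_pitch", (2.0, 2.0, 4.0))),
                out_pitch=tuple(mv.pop("out_pitch", (2.0, 2.0, 4.0))),
            )
            shape = tuple(mv.pop("shape", (16, 48, 64)))
            movie = generate_volume_movie(
                truth, geom, MovieNoiseModel(), shape=shape, seed=seeds["simulate"], **mv
            )
            truth_path = outdir / "truth.h5"
            truth.to_hdf5(truth_path)
            movie_path = outdir / "movie.h5"
            movie.to_hdf5(movie_path)
            record(
                "simulate",
                {"population": pop_kwargs, "shape": list(shape)},
                {"truth": truth_path, "movie": movie_path},
                _checksum(truth.noisy_traces, movie.data),
            )

        current_stage = "preprocess"
        if config.stages.get("preprocess"):
            if movie is None:
                raise RuntimeError("preprocess stage requires the simulate stage output")
            if movie.sheared and movie.geometry is not None:
                vols = np.stack(
                    [unshear_volume(movie.data[t], movie.geometry) for t in range(movie.n_timepoints)]
                )
                pitch = movie.geometry.out_pitch
            else:
                vols = movie.data.astype(float)
                pitch = movie.pitch
            movie = VolumeSeries(data=vols, pitch=pitch, sheared=False, rate=movie.rate,
                                 motion=movie.motion)
            pre_path = outdir / "preprocessed.h5"
            movie.to_hdf5(pre_path)
            record("preprocess", {"pitch": list(pitch)}, {"volumes": pre_path}, _checksum(vols))

        current_stage = "register"
        if config.stages.get("register"):
            if movie is None:
                raise RuntimeError("register stage requires volumes")
            corrected, fields, metrics = register_series(
                movie.data, coarse_block_xyz=movie.data.shape[1:][::-1], fine_block_xyz=(16, 16, 8)
            )
            excluded = detect_failed_frames(metrics)
            valid = ~excluded
            movie = VolumeSeries(data=corrected, pitch=movie.pitch, sheared=False, rate=movie.rate)
            np.savetxt(outdir / "excluded_frames.csv", np.flatnonzero(excluded), fmt="%d")
            record(
                "register",
                {"n_excluded": int(excluded.sum())},
                {"excluded": outdir / "excluded_frames.csv"},
                _checksum(corrected, metrics),
            )

        current_stage = "segment"
        if config.stages.get("segment"):
            if movie is None:
                raise RuntimeError("segment stage requires volumes")
            table = segment_movie(movie, valid_timepoints=valid)
            seg_path = outdir / "cells.h5"
            table.to_hdf5(seg_path)
            table.summary_csv(outdir / "cells.csv")
            record(
                "segment",
                {"n_cells": table.n_cells},
                {"cells": seg_path},
                _checksum(table.positions, np.nan_to_num(table.dff) if table.dff is not None else np.zeros(1)),
            )

        current_stage = "fc"
        if config.stages.get("fc"):
            from .fcscale import correlation_vs_distance

            tab = table if table is not None and table.passing().n_cells >= 2 else (
                truth.to_cell_table() if truth is not None else None
            )
            if tab is None:
                raise RuntimeError("fc stage requires a cell table")
            prof = correlation_vs_distance(
                tab,
                bin_range_um=tuple(config.fc.get("bin_range_um", (5.0, 2000.0))),
                fit_range_um=tuple(config.fc.get("fit_range_um", (20.0, 1000.0))),
            )
            fc_path = outdir / "fc_profile.csv"
            prof.to_frame().to_csv(fc_path, index=False)
            record("fc", {"exponent": prof.exponent}, {"profile": fc_path}, _checksum(prof.mean_corr))

        current_stage = "predict"
        if config.stages.get("predict"):
            from .prediction import RegressionConfig, predict_brainwide

            tab = truth.to_cell_table() if truth is not None else table
            if tab is None or tab.n_timepoints < 300:
                raise RuntimeError("predict stage requires >= 300 timepoints of traces")
            pr = dict(config.predict)
            rc = RegressionConfig(n_seeds=int(pr.get("n_seeds", 2)))
            report = predict_brainwide(
                tab,
                predictor_type=pr.get("predictor", "cells"),
                count=pr.get("count", min(30, tab.n_cells // 2)),
                voxel_size_um=pr.get("voxel_size_um"),
                config=rc,
                base_seed=seeds["predict"],
                n_folds=pr.get("n_folds", 2),
            )
            pred_path = outdir / "prediction.csv"
            report.to_csv(pred_path, index=False)
            record(
                "predict",
                {"mean_r2": float(report.r2_weighted.mean())},
                {"report": pred_path},
                _checksum(report.r2_weighted.to_numpy()),
            )

        current_stage = "geometry"
        if config.stages.get("geometry"):
            from .geometry import geometry_scale_protocol

            tab = truth.to_cell_table() if truth is not None else table
            if tab is None:
                raise RuntimeError("geometry stage requires a cell table")
            geo = dict(config.geometry)
            report = geometry_scale_protocol(
                tab,
                counts=list(geo.get("counts", [10, 20])),
                voxel_sizes_um=list(geo.get("sizes", [30.0])),
                seed=seeds["geometry"],
                n_seeds=int(geo.get("n_seeds", 1)),
            )
            geo_path = outdir / "geometry.csv"
            report.to_csv(geo_path, index=False)
            record(
                "geometry",
                {"n_rows": len(report)},
                {"report": geo_path},
                _checksum(report.distortion.to_numpy()),
            )
    except Exception as err:
        raise RuntimeError(f"pipeline failed in stage '{current_stage}': {err}") from err

    manifest["runtime_s"] = time.time() - t0
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    logger.info("pipeline finished in %.1f s (%d stages)", manifest["runtime_s"], len(manifest["stages"]))
    return manifest
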