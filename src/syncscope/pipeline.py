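"""End-to-end driver: simulate/read -> preprocess -> coordination -> wave
-> network -> architecture, with a reproducibility manifest.

Every run is deterministic in its configuration (which embeds the
seed); results and the manifest are written with sorted keys and no
timestamps, so identical configurations produce byte-identical output.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Optional

import numpy as np

from . import __version__
from .architecture import contact_probabilities
from .config import RunConfig
from .coordination import active_fraction, analyze_coordination, largest_coordinated_fraction
from .errors import InputError
from .io import read_architecture, read_movie, write_architecture, write_movie
from .movie import IsletMovie
from .network import CellTraceSet, build_adjacency
from .preprocess import assess_motion, detrend_movie, mask_islet, smooth_movie
from .simulate import (
    ArchitectureMap,
    GroundTruth,
    generate_architecture,
    generate_calcium_movie,
)
from .wave import analyze_wave


@dataclass
class PipelineResult:
    """Everything a run produced, plus the numbers-only results dict."""

    results: dict[str, Any]
    manifest: dict[str, Any]
    movie: IsletMovie
    arch: Optional[ArchitectureMap] = None
    truth: Optional[GroundTruth] = None


def cell_traces_from_labels(
    movie: IsletMovie, label_image: np.ndarray, keep_mask: Optional[np.ndarray] = None
) -> CellTraceSet:
    """Per-cell mean traces from a label image, at the best-coverage z-plane.

    The plane with the most labelled (and kept) pixels is chosen, as a
    network analysis uses a single plane with the greatest coverage.
    """
    labels = np.asarray(label_image)
    n_z = movie.n_planes
    if keep_mask is None:
        keep_mask = np.ones((n_z, *labels.shape), dtype=bool)
    coverage = [int((keep_mask[z] & (labels >= 0)).sum()) for z in range(n_z)]
    z = int(np.argmax(coverage))
    traces, cents, ids = [], [], []
    for cid in np.unique(labels[labels >= 0]):
        sel = (labels == cid) & keep_mask[z]
        if sel.sum() < 3:
            continue
        ys, xs = np.nonzero(sel)
        traces.append(movie.data[:, z, ys, xs].mean(axis=1))
        cents.append((ys.mean(), xs.mean()))
        ids.append(int(cid))
    if len(traces) < 3:
        raise InputError("fewer than 3 usable cells for network analysis")
    return CellTraceSet(
        traces=np.asarray(traces),
        centroids=np.asarray(cents),
        cell_ids=np.asarray(ids),
    )


def run_pipeline(config: RunConfig) -> PipelineResult:
    """Execute the full analysis described by ``config``.

    Stages run in order; a stage failure raises with the stage name so
    partial output directories remain inspectable.
    """
    results: dict[str, Any] = {}
    stages: list[str] = []
    arch = truth = None

    # --- inputs ---------------------------------------------------------
    if config.simulation is not None:
        stages.append("simulate")
        arch = generate_architecture(config.simulation)
        movie, truth = generate_calcium_movie(arch, config.simulation)
        results["simulation"] = {
            "n_cells": arch.n_cells,
            "n_domains": int(config.simulation.n_domains),
            "true_wave_speed_um_s": config.simulation.wave_speed_um_s,
        }
    else:
        stages.append("read")
        in_dir = Path(config.input_dir)
        movie = read_movie(in_dir / "movie.tif")
        cells_csv = in_dir / "cells.csv"
        if cells_csv.exists():
            arch = read_architecture(cells_csv)

    # --- preprocess -----------------------------------------------------
    stages.append("preprocess")
    smoothed = smooth_movie(movie)
    motion = assess_motion(smoothed, cell_width_um=config.cell_width_um)
    if motion.status == "reject":
        raise InputError("movie rejected: motion leaves too few usable frames")
    if motion.status == "trim":
        smoothed = smoothed.trimmed(motion.t_end)
    mask = mask_islet(smoothed, config.min_mean_intensity)
    detrended = detrend_movie(smoothed) if config.detrend_per_pixel else smoothed
    results["preprocess"] = {"motion": motion.status, **mask.summary()}

    # --- coordination ---------------------------------------------------
    stages.append("coordination")
    cmap, blocks = analyze_coordination(
        detrended,
        mask,
        r_min=config.coordination_r_min,
        require_contiguity=config.require_contiguity,
    )
    results["coordination"] = {
        "active_fraction": active_fraction(cmap),
        "largest_coordinated_fraction": largest_coordinated_fraction(cmap),
        "n_regions": cmap.n_regions,
        "n_regions_ge_10pct": cmap.regions_holding_at_least(0.10),
    }

    # --- wave -----------------------------------------------------------
    stages.append("wave")
    pmap = analyze_wave(
        blocks,
        cmap,
        frame_interval_s=detrended.frame_interval_s,
        pixel_size_um=detrended.pixel_size_um,
        z_spacing_um=detrended.z_spacing_um,
        mode=config.lag_mode,
        coordination_gate=config.coordination_gate,
        phase_fit_r2_min=config.phase_fit_r2_min,
    )
    results["wave"] = {
        "f_peak_hz": pmap.f_peak_hz,
        "eligibility": pmap.eligibility,
        "phase_fit_r2": pmap.phase_fit_r2,
        "dt_as_printed_s": pmap.dt_as_printed_s,
        "dt_standard_s": pmap.dt_standard_s,
        "speed_um_s": pmap.speed_um_s,
        "speed_as_printed_um_s": pmap.speed_as_printed_um_s,
    }

    # --- network --------------------------------------------------------
    if truth is not None:
        stages.append("network")
        cells = cell_traces_from_labels(
            detrended, truth.cell_label_image, keep_mask=mask.included
        )
        net = build_adjacency(cells, r_th=config.network_r_th)
        results["network"] = net.metrics(hub_cut=config.hub_cut)

    # --- architecture ---------------------------------------------------
    if arch is not None and len(arch.contacts):
        stages.append("architecture")
        results["architecture"] = contact_probabilities(arch).as_dict()

    manifest = {
        "package": "syncscope",
        "version": __version__,
        "seed": config.seed,
        "config_sha256": hashlib.sha256(config.canonical_json().encode()).hexdigest(),
        "stages": stages,
    }

    if config.out_dir is not None:
        out = Path(config.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        (out / "results.json").write_text(json.dumps(results, sort_keys=True, indent=1))
        (out / "manifest.json").write_text(json.dumps(manifest, sort_keys=True, indent=1))
        (out / "config.json").write_text(config.canonical_json())
        write_movie(movie, out / "movie.tif")
        if arch is not None:
            write_architecture(arch, out / "cells.csv")

    return PipelineResult(
        results=results, manifest=manifest, movie=movie, arch=arch, truth=truth
    )
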