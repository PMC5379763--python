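"""End-to-end orchestration: frames in, database out.

Stages run in order — preprocess, colony, cellseg, lineage, analytics,
persistence — with per-stage logging of record counts and timings; any subset
can be selected.  Colonies are analyzed independently (divide and conquer),
and the random seed is recorded so a rerun reproduces the same tables.
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .colony import (Colony, build_colony_mask, colony_growth_curves,
                     estimate_background, extract_colonies,
                     track_movie_colonies)
from .config import PipelineConfig, min_fragment_area
from .preprocess import FrameStack, preprocess_frame
from .cellseg import segment_frame
from .lineage import OverlapTracker, export_cell_table, track_cells
from .analytics import life_attribute_table
from .persistence import ExperimentRecord, export_database

__all__ = ["PipelineResult", "run_pipeline", "STAGES"]

log = logging.getLogger(__name__)

STAGES = ("preprocess", "colony", "cellseg", "lineage", "analytics", "persist")


@dataclass
class PipelineResult:
    config: PipelineConfig
    preprocessed: list[np.ndarray] = field(default_factory=list)
    colonies_by_frame: list[list[Colony]] = field(default_factory=list)
    colony_tracks: list = field(default_factory=list)
    cells_by_frame: list[list] = field(default_factory=list)
    forest: object | None = None
    frame_df: pd.DataFrame | None = None
    colony_df: pd.DataFrame | None = None
    cell_instant_df: pd.DataFrame | None = None
    cell_df: pd.DataFrame | None = None
    timings: dict[str, float] = field(default_factory=dict)
    db_path: Path | None = None


def _instant_frame(cells, forest) -> pd.DataFrame:
    instant_to_cell = {}
    if forest is not None:
        for node in forest.nodes.values():
            for f, iid in node.instants:
                instant_to_cell[(f, iid)] = node.cell_id
    rows = []
    for frame_cells in cells:
        for c in frame_cells:
            rows.append({
                "cell_instant_id": c.cell_instant_id,
                "cell_id": instant_to_cell.get((c.frame, c.cell_instant_id)),
                "frame": c.frame + 1,  # 1-based in reports
                "colony_track_id": c.colony_id,
                "centroid_row": c.centroid[0], "centroid_col": c.centroid[1],
                "area_px": c.area_px, "area_um2": c.area_um2,
                "length_um": c.length_um, "width_um": c.width_um,
                "orientation": c.orientation,
                "dist_to_colony_centroid_um": c.dist_to_colony_centroid_um,
                "fluor_total": c.fluor_total, "fluor_mean": c.fluor_mean,
                "on_colony_boundary": int(c.on_colony_boundary),
            })
    return pd.DataFrame(rows)


def run_pipeline(stack: FrameStack, config: PipelineConfig | None = None,
                 stages: tuple[str, ...] = STAGES,
                 out_dir: str | Path | None = None,
                 experiment: ExperimentRecord | None = None) -> PipelineResult:
    """Run the selected stages over a calibrated frame stack."""
    config = config or PipelineConfig()
    res = PipelineResult(config=config)
    species = config.species
    seg = config.segmentation
    rng = np.random.default_rng(seg.rng_seed)
    a_min = min_fragment_area(species)

    def timed(name):
        t0 = time.perf_counter()

        def done(count):
            res.timings[name] = time.perf_counter() - t0
            log.info("stage %-10s %6.2fs  (%s records)", name,
                     res.timings[name], count)
        return done

    frames = stack.frames
    if "preprocess" in stages:
        done = timed("preprocess")
        res.preprocessed = [
            preprocess_frame(f, method=config.denoise_method,
                             clip_limit=config.clahe_clip_limit,
                             tiles=config.clahe_tiles) for f in frames]
        done(len(res.preprocessed))
    else:
        res.preprocessed = [np.asarray(f, dtype=float) for f in frames]

    if "colony" in stages:
        done = timed("colony")
        radius = config.resolved_ball_radius()
        dark = species.modality != "fluorescence"
        for f, pp in enumerate(res.preprocessed):
            bg = estimate_background(pp, radius, dark_cells=dark)
            corr = np.clip(pp - bg + float(np.median(pp)), 0.0, 1.0)
            mask = build_colony_mask(corr, min_area_px=a_min, dark_cells=dark)
            res.colonies_by_frame.append(
                extract_colonies(mask, f, species.cal_factor, a_min))
        res.colony_tracks = track_movie_colonies(res.colonies_by_frame)
        done(sum(len(c) for c in res.colonies_by_frame))

    if "cellseg" in stages and res.colonies_by_frame:
        done = timed("cellseg")
        for f, pp in enumerate(res.preprocessed):
            track_of = {}
            for t in res.colony_tracks:
                if f in t.members:
                    track_of[t.members[f]] = t.track_id
            fluor = (stack.fluorescence_frames[f]
                     if stack.fluorescence_frames else None)
            cells = segment_frame(pp, res.colonies_by_frame[f], species, seg,
                                  frame_index=f, fluor_frame=fluor, rng=rng,
                                  colony_track_ids=track_of)
            res.cells_by_frame.append(cells)
            # colony cell counts
            for colony in res.colonies_by_frame[f]:
                tid = track_of.get(colony.colony_id, colony.colony_id)
                colony.cell_count = sum(1 for c in cells if c.colony_id == tid)
        done(sum(len(c) for c in res.cells_by_frame))

    if "lineage" in stages and res.cells_by_frame:
        done = timed("lineage")
        res.forest = track_cells(res.cells_by_frame, OverlapTracker())
        done(len(res.forest.nodes))

    # ---- tables ----------------------------------------------------------
    res.frame_df = pd.DataFrame([{
        "frame": f + 1,
        "time_min": f * stack.sampling_period,
        "height_px": frames[f].shape[0], "width_px": frames[f].shape[1],
        "n_colonies": (len(res.colonies_by_frame[f])
                       if f < len(res.colonies_by_frame) else None),
        "n_cells": (len(res.cells_by_frame[f])
                    if f < len(res.cells_by_frame) else None),
    } for f in range(len(frames))])

    if res.colony_tracks:
        rows = []
        for t in res.colony_tracks:
            events = {f: ev for f, ev, _ in t.events}
            for f, cid in sorted(t.members.items()):
                colony = next(c for c in res.colonies_by_frame[f]
                              if c.colony_id == cid)
                rows.append({
                    "frame": f + 1, "colony_track_id": t.track_id,
                    "area_px": colony.area_px, "area_um2": colony.area_um2,
                    "centroid_row": colony.centroid[0],
                    "centroid_col": colony.centroid[1],
                    "cell_count": colony.cell_count,
                    "event": events.get(f, ""),
                })
        res.colony_df = pd.DataFrame(rows).sort_values(
            ["frame", "colony_track_id"]).reset_index(drop=True)

    if res.cells_by_frame:
        res.cell_instant_df = _instant_frame(res.cells_by_frame, res.forest)

    if "analytics" in stages and res.forest is not None:
        done = timed("analytics")
        inst = res.cell_instant_df.copy()
        inst["frame"] = inst["frame"] - 1  # analytics wants 0-based
        life = life_attribute_table(res.forest, inst, stack.sampling_period)
        cell_tab = export_cell_table(res.forest, stack.sampling_period)
        res.cell_df = cell_tab.merge(
            life.drop(columns=["colony_track_id", "generation"]),
            on="cell_id", how="left")
        done(len(res.cell_df))

    # partial runs persist partial tables; unreached stages are simply absent
    if out_dir is not None:
        done = timed("persist")
        experiment = experiment or ExperimentRecord(
            modality=species.modality, cell_length_um=species.cell_length,
            cell_width_um=species.cell_width, cal_factor=species.cal_factor,
            sampling_period_min=stack.sampling_period, rng_seed=seg.rng_seed)
        res.db_path = export_database(
            out_dir, experiment, res.frame_df, res.colony_df,
            res.cell_instant_df, res.cell_df)
        config.save(Path(out_dir) / "pipeline.cfg")
        done(1)
    return res


def growth_curves(res: PipelineResult, sampling_period: float) -> dict[int, pd.DataFrame]:
    """Per-track colony growth curves (area and cell count vs time)."""
    return {t.track_id: colony_growth_curves(t, res.colonies_by_frame,
                                             sampling_period)
            for t in res.colony_tracks}
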