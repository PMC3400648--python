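"""Readers and writers binding the pipeline stages together.

All intermediate artifacts are plain CSV/JSON so any stage can be
diffed or re-run in isolation.  TIFF input supports two layouts:
``zstack_per_time`` (one multi-page file per timepoint, pages = focal
planes) and ``single_plane_series`` (one single-plane file per
timepoint).
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Iterator

import numpy as np
import pandas as pd

from .clustering import Centroid, ClusterState
from .config import PipelineConfig
from .imaging import BinaryElementMap, FrameStack

log = logging.getLogger(__name__)


def read_frame_stacks(path: str | Path, config: PipelineConfig
                      ) -> Iterator[FrameStack]:
    """Stream FrameStacks from a directory of TIFF files (sorted by name)."""
    import tifffile

    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"input path does not exist: {path}")
    files = sorted(p for p in path.iterdir()
                   if p.suffix.lower() in (".tif", ".tiff"))
    if not files:
        raise FileNotFoundError(f"no TIFF files under {path}")
    shape = None
    for idx, f in enumerate(files):
        data = tifffile.imread(f)
        if data.ndim == 2:
            data = data[None]
        if config.tiff_layout == "single_plane_series" and data.shape[0] != 1:
            raise ValueError(f"{f}: expected a single plane, got {data.shape[0]}")
        if shape is None:
            shape = data.shape[1:]
        elif data.shape[1:] != shape:
            raise ValueError(f"{f}: plane shape {data.shape[1:]} does not match "
                             f"first frame {shape}")
        yield FrameStack(data, idx, idx * config.frame_interval_min,
                         config.pixel_size_um)


def read_seed_file(path: str | Path) -> list[Centroid]:
    """Manual first-frame seeds: CSV with columns x_px, y_px."""
    df = pd.read_csv(path)
    for col in ("x_px", "y_px"):
        if col not in df.columns:
            raise ValueError(f"seed file {path} lacks required column {col!r}")
    return [Centroid(i, float(r.x_px), float(r.y_px), 0)
            for i, r in enumerate(df.itertuples())]


def write_elements_csv(maps: list[BinaryElementMap], path: str | Path) -> None:
    rows = [dict(frame_index=m.frame_index, x_px=x, y_px=y,
                 threshold=m.threshold_used)
            for m in maps for x, y in m.elements]
    pd.DataFrame(rows, columns=["frame_index", "x_px", "y_px", "threshold"]
                 ).to_csv(path, index=False)


def read_elements_csv(path: str | Path) -> list[BinaryElementMap]:
    df = pd.read_csv(path)
    maps = []
    for frame, grp in df.groupby("frame_index", sort=True):
        maps.append(BinaryElementMap(
            int(frame), grp[["x_px", "y_px"]].to_numpy(float),
            float(grp["threshold"].iloc[0])))
    return maps


def write_clusters_csv(states: list[ClusterState], path: str | Path) -> None:
    rows = []
    for s in states:
        for c in sorted(s.centroids, key=lambda c: c.id):
            rows.append(dict(frame=s.frame_index, centroid_id=c.id,
                             x=c.x, y=c.y,
                             n_elements=s.n_elements[c.id],
                             mean_separation_um=s.mean_separation_um[c.id],
                             silhouette_mean=s.silhouette_mean))
    pd.DataFrame(rows, columns=["frame", "centroid_id", "x", "y", "n_elements",
                                "mean_separation_um", "silhouette_mean"]
                 ).to_csv(path, index=False)


def write_tracks_csv(track_graph, path: str | Path) -> None:
    g = track_graph.graph
    rows = []
    for tid, nodes in sorted(track_graph.tracks().items()):
        parent = track_graph.parent_track(tid)
        for frame, cid in nodes:
            d = g.nodes[(frame, cid)]
            rows.append(dict(track_id=tid, frame=frame, centroid_id=cid,
                             x=d["x"], y=d["y"],
                             parent_track_id=-1 if parent is None else parent))
    pd.DataFrame(rows, columns=["track_id", "frame", "centroid_id", "x", "y",
                                "parent_track_id"]).to_csv(path, index=False)


def write_divisions_csv(events, path: str | Path) -> None:
    rows = [dict(parent_track=e.parent_track_id,
                 daughter_a=e.daughter_track_ids[0],
                 daughter_b=e.daughter_track_ids[1],
                 frame_min=e.frame_of_minimum,
                 frame_confirmed=e.frame_confirmed,
                 baseline_um=e.baseline_um, minimum_um=e.minimum_um)
            for e in events]
    pd.DataFrame(rows, columns=["parent_track", "daughter_a", "daughter_b",
                                "frame_min", "frame_confirmed", "baseline_um",
                                "minimum_um"]).to_csv(path, index=False)


def write_curves_csv(curves, path: str | Path) -> None:
    rows = []
    for curve in curves:
        for frame, sep, cd, n in curve.series:
            rows.append(dict(track_id=curve.track_id, frame=frame,
                             mean_separation_um=sep,
                             mean_centroid_distance_um=cd, n_elements=n))
    pd.DataFrame(rows, columns=["track_id", "frame", "mean_separation_um",
                                "mean_centroid_distance_um", "n_elements"]
                 ).to_csv(path, index=False)


def write_sweep_csv(sweep, path: str | Path) -> None:
    sweep.to_dataframe().to_csv(path, index=False)
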