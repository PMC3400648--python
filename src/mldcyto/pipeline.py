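"""End-to-end pipeline: imaging -> clustering -> tracking -> mitosis -> lineage.

Frames are processed sequentially.  Each frame is reduced to binary
elements, clustered with seeds carried over from the previous frame
(spawn/removal/split rules applied), and linked to the previous frame's
centroids.  Every unbranched track carries an online contraction-
expansion detector over its mean-separation series; when a track's
curve completes the mitotic signature the cluster is force-split into
two daughters at that frame and a division event is recorded.
"""

from __future__ import annotations

import itertools
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import numpy as np

from . import io as mio
from .clustering import (Centroid, ClusterState, auto_seed, kmeans_assign,
                         run_split_tests, split_cluster, update_seeds)
from .config import PipelineConfig
from .imaging import BinaryElementMap, FrameStack, detect_elements
from .lineage import (LineageTree, PopulationStats, build_lineage,
                      motility_vectors, population_stats, to_json, to_newick)
from .mitosis import (ContractionExpansionDetector, DivisionEvent,
                      MitoticCurve, mitotic_curve)
from .tracking import LinkRecord, TrackGraph, build_track_graph, link_frames

log = logging.getLogger(__name__)


@dataclass
class RawDivision:
    """Division bookkeeping before track ids exist."""

    frame_confirmed: int
    frame_of_minimum: int
    baseline_um: float
    minimum_um: float
    parent_centroid: int      # centroid id in frame_confirmed - 1
    daughter_centroids: tuple[int, int]  # centroid ids in frame_confirmed


@dataclass
class PipelineResult:
    """Everything the pipeline computes for one movie."""

    config: PipelineConfig
    element_maps: list[BinaryElementMap]
    states: list[ClusterState]
    links: list[LinkRecord]
    track_graph: TrackGraph
    divisions: list[DivisionEvent]
    lineage: LineageTree
    curves: list[MitoticCurve]
    stats: PopulationStats | None
    manifest: dict

    def write_outputs(self, out_dir: str | Path) -> dict[str, Path]:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        paths = {
            "elements": out / "elements.csv",
            "clusters": out / "clusters.csv",
            "tracks": out / "tracks.csv",
            "divisions": out / "divisions.csv",
            "curves": out / "mitotic_curves.csv",
            "lineage_json": out / "lineage.json",
            "lineage_newick": out / "lineage.nwk",
            "stats": out / "population_stats.csv",
            "manifest": out / "manifest.json",
        }
        mio.write_elements_csv(self.element_maps, paths["elements"])
        mio.write_clusters_csv(self.states, paths["clusters"])
        mio.write_tracks_csv(self.track_graph, paths["tracks"])
        mio.write_divisions_csv(self.divisions, paths["divisions"])
        mio.write_curves_csv(self.curves, paths["curves"])
        paths["lineage_json"].write_text(
            to_json(self.lineage, self.config.frame_interval_min))
        paths["lineage_newick"].write_text(
            to_newick(self.lineage, self.config.frame_interval_min))
        if self.stats is not None:
            self.stats.per_frame.to_csv(paths["stats"], index=False)
        paths["manifest"].write_text(json.dumps(self.manifest, indent=2,
                                                sort_keys=True))
        return paths


def _empty_state(frame: int, pixel_size_um: float) -> ClusterState:
    return ClusterState(frame, np.zeros((0, 2)), [], np.zeros(0, dtype=int),
                        pixel_size_um)


class MLDPipeline:
    """Sequential movie processor; feed frames with :meth:`process_frame`."""

    def __init__(self, config: PipelineConfig,
                 manual_seeds: list[Centroid] | None = None) -> None:
        config.validate()
        self.config = config
        self.manual_seeds = manual_seeds
        if config.first_frame_seed_mode == "manual" and manual_seeds is None:
            raise ValueError("first_frame_seed_mode is 'manual' but no seed "
                             "file was provided")
        self.ids = itertools.count(0)
        self.element_maps: list[BinaryElementMap] = []
        self.states: list[ClusterState] = []
        self.links: list[LinkRecord] = []
        self.raw_divisions: list[RawDivision] = []
        self._detectors: dict[int, ContractionExpansionDetector] = {}
        self._started = False

    # ------------------------------------------------------------------
    def process_frame(self, stack: FrameStack) -> ClusterState:
        cfg = self.config
        _, emap = detect_elements(
            stack, cfg.fusion_region_px, cfg.peak_window_px,
            cfg.threshold_sigma, cfg.threshold_population_sigma)
        self.element_maps.append(emap)
        frame = stack.frame_index

        if not self._started:
            state = self._first_frame(frame, emap.elements)
        else:
            state = self._next_frame(frame, emap.elements)
        self.states.append(state)
        return state

    def _fresh_detector(self, frame: int, sep: float, n: int
                        ) -> ContractionExpansionDetector:
        det = ContractionExpansionDetector(
            self.config.baseline_window_frames,
            self.config.contraction_fraction,
            self.config.min_mitotic_baseline_um,
            self.config.split_separation_um)
        det.update(frame, sep, n)
        return det

    def _first_frame(self, frame: int, elements: np.ndarray) -> ClusterState:
        cfg = self.config
        if len(elements) == 0:
            return _empty_state(frame, cfg.pixel_size_um)
        if cfg.first_frame_seed_mode == "manual":
            seeds = [Centroid(next(self.ids), s.x, s.y, frame)
                     for s in self.manual_seeds]
        else:
            seeds = auto_seed(elements, cfg.um_to_px(cfg.auto_seed_radius_um),
                              self.ids)
        state = kmeans_assign(elements, seeds, cfg.kmeans_max_iter,
                              cfg.kmeans_tol_px, frame, cfg.pixel_size_um)
        state, _ = run_split_tests(state, cfg, self.ids)
        for c in state.centroids:
            self._detectors[c.id] = self._fresh_detector(
                frame, state.mean_separation_um[c.id], state.n_elements[c.id])
        self._started = True
        return state

    def _next_frame(self, frame: int, elements: np.ndarray) -> ClusterState:
        cfg = self.config
        prev = self.states[-1]
        if len(elements) == 0:
            self.links.append(link_frames(prev, _empty_state(
                frame, cfg.pixel_size_um), cfg.link_radius_um))
            self._detectors = {}
            return _empty_state(frame, cfg.pixel_size_um)

        seeds = update_seeds(prev, elements, cfg.um_to_px(cfg.seed_spawn_um),
                             cfg.um_to_px(cfg.seed_removal_um), self.ids)
        if not seeds:
            seeds = auto_seed(elements, cfg.um_to_px(cfg.auto_seed_radius_um),
                              self.ids)
        state = kmeans_assign(elements, seeds, cfg.kmeans_max_iter,
                              cfg.kmeans_tol_px, frame, cfg.pixel_size_um)
        state, _splits = run_split_tests(state, cfg, self.ids)

        link = link_frames(prev, state, cfg.link_radius_um)

        # advance the mitotic detectors along unbranched continuations
        new_detectors: dict[int, ContractionExpansionDetector] = {}
        forced: list[tuple[int, tuple[int, int, float, float]]] = []
        children = link.children_of()
        linked_children: set[int] = set()
        for pid, kids in children.items():
            linked_children.update(kids)
            if len(kids) == 1:
                cid = kids[0]
                det = self._detectors.get(pid)
                if det is None:
                    det = ContractionExpansionDetector(
                        cfg.baseline_window_frames, cfg.contraction_fraction,
                        cfg.min_mitotic_baseline_um, cfg.split_separation_um)
                hit = det.update(frame, state.mean_separation_um[cid],
                                 state.n_elements[cid])
                if hit is not None:
                    forced.append((cid, hit))
                else:
                    new_detectors[cid] = det
            else:
                # bifurcation from the 15 um split rule: fresh detectors
                for cid in kids:
                    new_detectors[cid] = self._fresh_detector(
                        frame, state.mean_separation_um[cid],
                        state.n_elements[cid])
        for cid in link.new_progenitors:
            new_detectors[cid] = self._fresh_detector(
                frame, state.mean_separation_um[cid], state.n_elements[cid])

        if forced:
            parent_of = link.parent_of()
            for cid, (f_min, f_conf, baseline, minimum) in forced:
                state, ok, new_ids = split_cluster(state, cid, cfg, self.ids,
                                                   force=True)
                if ok and new_ids is not None:
                    a, b = new_ids
                    self.raw_divisions.append(RawDivision(
                        frame, f_min, baseline, minimum,
                        parent_of[cid], (a, b)))
                    for d in (a, b):
                        new_detectors[d] = self._fresh_detector(
                            frame, state.mean_separation_um[d],
                            state.n_elements[d])
                else:
                    log.warning("frame %d: confirmed contraction-expansion on "
                                "centroid %d but the forced split failed", frame, cid)
                    new_detectors[cid] = self._fresh_detector(
                        frame, state.mean_separation_um[cid],
                        state.n_elements[cid])
            link = link_frames(prev, state, cfg.link_radius_um)

        self.links.append(link)
        self._detectors = new_detectors
        return state

    # ------------------------------------------------------------------
    def finalize(self, seed_mode: str | None = None) -> PipelineResult:
        cfg = self.config
        tg = build_track_graph(self.links, self.states) if self.links else \
            build_track_graph([], self.states)
        events: list[DivisionEvent] = []
        for raw in self.raw_divisions:
            try:
                parent_t = tg.track_of((raw.frame_confirmed - 1,
                                        raw.parent_centroid))
                da = tg.track_of((raw.frame_confirmed, raw.daughter_centroids[0]))
                db = tg.track_of((raw.frame_confirmed, raw.daughter_centroids[1]))
            except KeyError:  # pragma: no cover - defensive
                log.warning("division at frame %d references missing nodes",
                            raw.frame_confirmed)
                continue
            if len({parent_t, da, db}) != 3:
                # the split products did not both re-link as children of the
                # mother (contorted geometry); not a usable division
                log.warning("division at frame %d discarded: daughters did "
                            "not form a clean bifurcation", raw.frame_confirmed)
                continue
            events.append(DivisionEvent(parent_t, (da, db),
                                        raw.frame_of_minimum,
                                        raw.frame_confirmed,
                                        raw.baseline_um, raw.minimum_um))
        last = self.states[-1].frame_index if self.states else 0
        lineage = build_lineage(tg, events, last_frame=last)
        states_by_frame = {s.frame_index: s for s in self.states}
        curves = [mitotic_curve(tid, nodes, states_by_frame)
                  for tid, nodes in sorted(tg.tracks().items())
                  if len(nodes) >= 2]
        stats = None
        frames_with = [s.frame_index for s in self.states if s.centroids]
        if len(frames_with) >= 2:
            stats = population_stats(self.states, frames_with[0],
                                     frames_with[-1], cfg.frame_interval_min)
        from . import __version__
        manifest = {
            "package": "mldcyto",
            "version": __version__,
            "config": cfg.to_dict(),
            "seed_mode": seed_mode or cfg.first_frame_seed_mode,
            "n_frames": len(self.states),
            "n_tracks": len(tg.tracks()),
            "n_divisions": len(events),
        }
        return PipelineResult(cfg, self.element_maps, self.states, self.links,
                              tg, events, lineage, curves, stats, manifest)


def run_pipeline(config: PipelineConfig,
                 frames: Iterable[FrameStack] | str | Path,
                 manual_seeds: list[Centroid] | None = None) -> PipelineResult:
    """Run the full pipeline over TIFFs on disk or in-memory FrameStacks."""
    if isinstance(frames, (str, Path)):
        frames = mio.read_frame_stacks(frames, config)
    pipe = MLDPipeline(config, manual_seeds)
    t0 = time.perf_counter()
    n = 0
    for stack in frames:
        pipe.process_frame(stack)
        n += 1
    log.info("processed %d frames in %.1f s", n, time.perf_counter() - t0)
    if n == 0:
        raise ValueError("no input frames")
    return pipe.finalize()
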