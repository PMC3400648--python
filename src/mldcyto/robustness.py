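"""Operational-range analysis: threshold sweeps on a single frame.

Sweeping the noise-filter cut-off maps the accuracy of cell
identification against the number of binary elements available: too
high a threshold starves clusters of points, too low a threshold lets
background noise shift centroid positions.  The usable span between
those regimes is the system's operational range.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .clustering import Centroid, ClusterState, kmeans_assign, update_seeds
from .config import PipelineConfig
from .imaging import BinaryElementMap, FrameStack, apply_threshold, \
    compute_threshold, detect_peaks, fuse_focal_planes

log = logging.getLogger(__name__)


@dataclass
class SweepResult:
    """Per-threshold outcome of the operational-range sweep.

    ``displacement_um[i]`` maps reference centroid id -> displacement
    (um) from that centroid's position at the highest (cleanest)
    threshold of the sweep.  ``snr`` is spot peak / threshold.
    """

    thresholds: list[float]
    n_elements: list[int]
    n_centroids: list[int]
    displacement_um: list[dict[int, float]]
    snr: list[float]
    element_maps: list[BinaryElementMap] = field(default_factory=list)
    states: list[ClusterState] = field(default_factory=list)

    def to_dataframe(self) -> pd.DataFrame:
        rows = []
        for i, th in enumerate(self.thresholds):
            disp = self.displacement_um[i]
            rows.append(dict(
                threshold=th, n_elements=self.n_elements[i],
                n_centroids=self.n_centroids[i],
                mean_displacement_um=(float(np.mean(list(disp.values())))
                                      if disp else np.nan),
                max_displacement_um=(float(np.max(list(disp.values())))
                                     if disp else np.nan),
                snr=self.snr[i]))
        return pd.DataFrame(rows)


def threshold_sweep(frame: FrameStack, thresholds: list[float],
                    reference_seeds: list[Centroid],
                    config: PipelineConfig | None = None,
                    spot_peak: float | None = None) -> SweepResult:
    """Re-run detection and clustering at each threshold of a sweep.

    Thresholds must be ascending.  For every threshold the peak finder
    and the seeded clustering (spawn/removal rules included) are re-run
    from the same reference seeds; element count, validated centroid
    count, and the displacement of each surviving reference centroid
    from its position at the *highest* threshold are recorded.  ``snr``
    is ``spot_peak / threshold`` (reference spot peak over cut-off);
    when ``spot_peak`` is omitted the image maximum is used.
    """
    if list(thresholds) != sorted(thresholds):
        raise ValueError("thresholds must be sorted ascending")
    config = config or PipelineConfig(pixel_size_um=frame.pixel_size_um)
    composite = fuse_focal_planes(frame, config.fusion_region_px)
    img_min = float(composite.intensity.min())
    if thresholds and thresholds[0] < img_min:
        log.warning("lowest threshold %.1f is below the image minimum %.1f; "
                    "the whole image passes the filter", thresholds[0], img_min)
    if spot_peak is None:
        spot_peak = float(composite.intensity.max())

    spawn_px = config.um_to_px(config.seed_spawn_um)
    removal_px = config.um_to_px(config.seed_removal_um)

    per_threshold: list[tuple[BinaryElementMap, ClusterState | None]] = []
    for th in thresholds:
        mask = apply_threshold(composite, th)
        emap = detect_peaks(composite, mask, config.peak_window_px,
                            frame_index=frame.frame_index)
        emap.threshold_used = float(th)
        state = None
        if len(emap):
            ids = itertools.count(max((s.id for s in reference_seeds),
                                      default=-1) + 1)
            prev = ClusterState(frame.frame_index - 1, np.zeros((0, 2)),
                                [Centroid(s.id, s.x, s.y, frame.frame_index - 1)
                                 for s in reference_seeds],
                                np.zeros(0, dtype=int), config.pixel_size_um)
            seeds = update_seeds(prev, emap.elements, spawn_px, removal_px, ids)
            if seeds:
                state = kmeans_assign(emap.elements, seeds,
                                      config.kmeans_max_iter,
                                      config.kmeans_tol_px,
                                      frame.frame_index, config.pixel_size_um)
        per_threshold.append((emap, state))

    # reference positions from the highest (cleanest) threshold
    ref_state = per_threshold[-1][1]
    ref_pos: dict[int, np.ndarray] = {}
    if ref_state is not None:
        for c in ref_state.centroids:
            if any(c.id == s.id for s in reference_seeds):
                ref_pos[c.id] = c.xy

    result = SweepResult([], [], [], [], [])
    for th, (emap, state) in zip(thresholds, per_threshold):
        disp: dict[int, float] = {}
        n_cent = 0
        if state is not None:
            n_cent = len(state.centroids)
            for c in state.centroids:
                if c.id in ref_pos:
                    disp[c.id] = float(np.linalg.norm(c.xy - ref_pos[c.id])
                                       ) * config.pixel_size_um
        result.thresholds.append(float(th))
        result.n_elements.append(len(emap))
        result.n_centroids.append(n_cent)
        result.displacement_um.append(disp)
        result.snr.append(spot_peak / th if th > 0 else np.inf)
        result.element_maps.append(emap)
        result.states.append(state)
    return result


def minimum_elements_analysis(sweep: SweepResult,
                              true_centroids_px: np.ndarray,
                              min_elements: int = 1,
                              cover_radius_um: float = 12.5,
                              pixel_size_um: float = 0.25) -> dict:
    """Smallest element budget that still covers every true cell.

    For each threshold, elements are attributed to their nearest true
    centroid within ``cover_radius_um``; the analysis reports the
    smallest total element count at which *all* true centroids own at
    least one element, and the smallest at which all own at least
    ``min_elements``.  Unattainable conditions are reported as None.
    """
    true_centroids_px = np.asarray(true_centroids_px, dtype=float).reshape(-1, 2)
    n_true = len(true_centroids_px)
    radius_px = cover_radius_um / pixel_size_um

    best_all: tuple[int, float] | None = None
    best_m: tuple[int, float] | None = None
    rows = []
    for th, emap in zip(sweep.thresholds, sweep.element_maps):
        counts = np.zeros(n_true, dtype=int)
        if len(emap) and n_true:
            from scipy.spatial.distance import cdist
            d = cdist(emap.elements, true_centroids_px)
            nearest = np.argmin(d, axis=1)
            within = d[np.arange(len(emap)), nearest] <= radius_px
            for t in nearest[within]:
                counts[t] += 1
        covered = int((counts >= 1).sum())
        covered_m = int((counts >= min_elements).sum())
        rows.append(dict(threshold=th, n_elements=len(emap),
                         centroids_covered=covered,
                         centroids_with_min=covered_m))
        if n_true and covered == n_true:
            if best_all is None or len(emap) < best_all[0]:
                best_all = (len(emap), th)
        if n_true and covered_m == n_true:
            if best_m is None or len(emap) < best_m[0]:
                best_m = (len(emap), th)
    return {
        "n_true_centroids": n_true,
        "min_elements_all_covered": None if best_all is None else best_all[0],
        "threshold_all_covered": None if best_all is None else best_all[1],
        "min_elements_all_with_m": None if best_m is None else best_m[0],
        "threshold_all_with_m": None if best_m is None else best_m[1],
        "per_threshold": pd.DataFrame(rows),
    }


def plot_sweep(sweep: SweepResult, ax_pair=None):
    """Two-panel operational-range figure: element count vs threshold,
    and centroid count plus displacements vs element count."""
    import matplotlib
    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    if ax_pair is None:
        fig, (ax1, ax2) = plt.subplots(1, 2, figsize=(10, 4))
    else:
        ax1, ax2 = ax_pair
        fig = ax1.figure
    ax1.plot(sweep.thresholds, sweep.n_elements, "k.-")
    ax1.set_xlabel("threshold (intensity units)")
    ax1.set_ylabel("binary elements")
    ax2.plot(sweep.n_elements, sweep.n_centroids, "k.-", label="centroids")
    ax2.set_xlabel("binary elements")
    ax2.set_ylabel("centroids identified")
    ids = sorted({cid for d in sweep.displacement_um for cid in d})[:8]
    ax2b = ax2.twinx()
    for cid in ids:
        xs = [n for n, d in zip(sweep.n_elements, sweep.displacement_um)
              if cid in d]
        ys = [d[cid] for d in sweep.displacement_um if cid in d]
        ax2b.plot(xs, ys, alpha=0.5)
    ax2b.set_ylabel("centroid displacement (um)")
    fig.tight_layout()
    return fig
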