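"""Mitotic-curve analysis and division detection.

A dividing cell rounds up, which condenses its vesicle cloud: the mean
separation of its binary elements drops well below its stable baseline,
reaches a minimum around cytokinesis, and then climbs past the baseline
as the daughter clusters move apart.  A division is confirmed at the
first post-minimum frame whose separation exceeds the pre-contraction
baseline; at that frame the cluster is re-split into two daughters.
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass, field

import numpy as np


@dataclass
class MitoticCurve:
    """Per-track time series of cluster dispersion.

    ``series`` rows are (frame_index, mean_separation_um,
    mean_centroid_dist_um, n_elements); frames are contiguous along the
    track.  Single-element frames record 0 separation and are flagged.
    """

    track_id: int
    series: list[tuple[int, float, float, int]] = field(default_factory=list)
    flagged_frames: list[int] = field(default_factory=list)

    def frames(self) -> list[int]:
        return [row[0] for row in self.series]

    def separations(self) -> list[float]:
        return [row[1] for row in self.series]


@dataclass
class DivisionEvent:
    """A confirmed cell division."""

    parent_track_id: int
    daughter_track_ids: tuple[int, int]
    frame_of_minimum: int
    frame_confirmed: int
    baseline_um: float
    minimum_um: float

    def __post_init__(self) -> None:
        if self.frame_of_minimum >= self.frame_confirmed:
            raise ValueError("frame_of_minimum must precede frame_confirmed")
        if self.minimum_um >= self.baseline_um:
            raise ValueError("minimum_um must be below baseline_um")


class ContractionExpansionDetector:
    """Online state machine for the mitotic signature of one track.

    Feed (frame, separation) samples in order.  While *stable*, a
    rolling window of recent separations defines the baseline (median).
    A sample below ``contraction_fraction x baseline`` starts the
    *contracting/expanding* phase with the baseline frozen; the running
    minimum is tracked, and the first subsequent sample above the
    baseline confirms a division, after which the machine resets.
    """

    def __init__(self, baseline_window: int = 12,
                 contraction_fraction: float = 0.6,
                 min_baseline_um: float = 2.5,
                 max_baseline_um: float = 15.0,
                 min_cluster_elements: int = 4) -> None:
        self.baseline_window = int(baseline_window)
        self.contraction_fraction = float(contraction_fraction)
        # a mitotic baseline is the stable dispersion of a *single*,
        # well-sampled cell: well above pixel scale, below the 15 um
        # single-cell limit, and measured on a cluster of at least a
        # handful of elements (a 2-3 point cluster carries no usable
        # dispersion statistic)
        self.min_baseline_um = float(min_baseline_um)
        self.max_baseline_um = float(max_baseline_um)
        self.min_cluster_elements = int(min_cluster_elements)
        self._window: deque[float] = deque(maxlen=self.baseline_window)
        self._n_window: deque[int] = deque(maxlen=self.baseline_window)
        self._phase = "stable"
        self._baseline = np.nan
        self._min_value = np.inf
        self._min_frame = -1

    def reset(self) -> None:
        self._window.clear()
        self._n_window.clear()
        self._phase = "stable"
        self._baseline = np.nan
        self._min_value = np.inf
        self._min_frame = -1

    def update(self, frame: int, separation_um: float,
               n_elements: int | None = None
               ) -> tuple[int, int, float, float] | None:
        """Returns (frame_of_minimum, frame_confirmed, baseline, minimum)
        when this sample confirms a division, else None.

        Frames with fewer than two elements carry no separation
        measurement.  While no baseline is established they are skipped
        (their 0 is a flag, not data); once a valid baseline exists, a
        multi-element cluster collapsing to a single peak is the
        strongest contraction observable and is scored as separation 0.
        """
        if n_elements is not None and n_elements < 2:
            if self._phase == "stable":
                if not self._baseline_valid():
                    return None
                self._phase = "contracted"
                self._baseline = self._stable_baseline()
            self._min_value = 0.0
            self._min_frame = frame
            return None
        if self._phase == "stable":
            if (self._baseline_valid()
                    and separation_um
                    < self.contraction_fraction * self._stable_baseline()):
                self._phase = "contracted"
                self._baseline = self._stable_baseline()
                self._min_value = separation_um
                self._min_frame = frame
            else:
                self._window.append(separation_um)
                self._n_window.append(n_elements if n_elements is not None
                                      else self.min_cluster_elements)
            return None
        # contracted / expanding
        if separation_um < self._min_value:
            self._min_value = separation_um
            self._min_frame = frame
        if separation_um > self._baseline and frame > self._min_frame:
            event = (self._min_frame, frame, self._baseline, self._min_value)
            self.reset()
            return event
        return None

    def _stable_baseline(self) -> float:
        return float(np.median(self._window))

    def _baseline_valid(self) -> bool:
        """A usable pre-contraction baseline: at least half the window
        filled, a single-cell-scale median separation, and a cluster
        populated well enough to carry a dispersion statistic.  Tracks
        that start shortly before a division still qualify."""
        if len(self._window) < max(self.baseline_window // 2, 2):
            return False
        if not (self.min_baseline_um <= self._stable_baseline()
                < self.max_baseline_um):
            return False
        return float(np.median(self._n_window)) >= self.min_cluster_elements


def mitotic_curve(track_id: int, track_nodes: list[tuple[int, int]],
                  states_by_frame: dict[int, "ClusterState"]) -> MitoticCurve:
    """Assemble the dispersion time series of one track.

    ``track_nodes`` are the (frame, centroid_id) nodes of the track in
    time order; both the mean pairwise element separation and the mean
    element-to-centroid distance are recorded for every frame.
    """
    if len(track_nodes) < 2:
        raise ValueError("mitotic_curve requires a track spanning >= 2 frames")
    curve = MitoticCurve(track_id)
    for frame, cid in track_nodes:
        state = states_by_frame[frame]
        sep = state.mean_separation_um.get(cid, 0.0)
        cdist_um = state.mean_centroid_dist_um.get(cid, 0.0)
        n = state.n_elements.get(cid, 0)
        if n < 2:
            curve.flagged_frames.append(frame)
        curve.series.append((frame, sep, cdist_um, n))
    return curve


def detect_division(curve: MitoticCurve, baseline_window_frames: int = 12,
                    contraction_fraction: float = 0.6) -> DivisionEvent | None:
    """Scan a complete mitotic curve for the first contraction–expansion
    signature.  Daughter ids are unknown at this level and set to (-1, -1);
    the pipeline fills them in when it performs the split.
    """
    if len(curve.series) <= baseline_window_frames:
        return None
    det = ContractionExpansionDetector(baseline_window_frames, contraction_fraction)
    for frame, sep, _cd, n in curve.series:
        hit = det.update(frame, sep, n)
        if hit is not None:
            f_min, f_conf, baseline, minimum = hit
            return DivisionEvent(curve.track_id, (-1, -1), f_min, f_conf,
                                 baseline, minimum)
    return None


def match_events(detected: list[tuple[int, float, float]],
                 truth: list[tuple[int, float, float]],
                 frame_tolerance: int = 3,
                 radius_um: float = 20.0) -> tuple[int, int, int]:
    """Greedy one-to-one matching of detected vs ground-truth divisions.

    Events are (frame, x_um, y_um).  A pair matches when the frames
    differ by at most ``frame_tolerance`` and the positions by at most
    ``radius_um``.  Returns (n_matched, n_detected, n_truth), from which
    precision = matched/detected and recall = matched/truth.
    """
    pairs = []
    for i, (fd, xd, yd) in enumerate(detected):
        for j, (ft, xt, yt) in enumerate(truth):
            if abs(fd - ft) <= frame_tolerance:
                dist = float(np.hypot(xd - xt, yd - yt))
                if dist <= radius_um:
                    pairs.append((abs(fd - ft), dist, i, j))
    pairs.sort()
    used_d: set[int] = set()
    used_t: set[int] = set()
    for _, _, i, j in pairs:
        if i not in used_d and j not in used_t:
            used_d.add(i)
            used_t.add(j)
    return len(used_d), len(detected), len(truth)
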