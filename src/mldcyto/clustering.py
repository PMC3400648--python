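"""Cell identification by seeded k-means on binary element maps.

Each cell appears as a cluster of light points.  Frames are clustered
with k-means seeded from the previous frame's centroids, with three
rules that handle cells entering or leaving the field and cell division:

* an element farther than ``seed_spawn_um`` (default 30 um) from every
  seed spawns a new seed at its own position;
* a seed with no element within ``seed_removal_um`` (default 12.5 um)
  is removed;
* a cluster whose mean pairwise element separation exceeds
  ``split_separation_um`` (default 15 um, ~1.5 cell diameters) is
  re-clustered with one extra seed and the split kept only if the mean
  silhouette score improves.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import cdist, pdist

from .config import PipelineConfig

log = logging.getLogger(__name__)


@dataclass
class Centroid:
    """A cluster centre: the tracked coordinate of one cell."""

    id: int
    x: float
    y: float
    frame_index: int = 0

    @property
    def xy(self) -> np.ndarray:
        return np.array([self.x, self.y])


@dataclass
class ClusterState:
    """Converged clustering of one frame's binary elements.

    ``assignment[i]`` is the id of the centroid owning element ``i``.
    Per-centroid dispersion metrics are in micrometres: the mean over
    all unordered element pairs (``mean_separation_um``, which drives
    the 15 um split rule) and the mean element-to-centroid distance
    (``mean_centroid_dist_um``, the mitotic-curve parameter).
    """

    frame_index: int
    elements: np.ndarray
    centroids: list[Centroid]
    assignment: np.ndarray
    pixel_size_um: float
    mean_separation_um: dict[int, float] = field(default_factory=dict)
    mean_centroid_dist_um: dict[int, float] = field(default_factory=dict)
    n_elements: dict[int, int] = field(default_factory=dict)
    silhouette_mean: float = 0.0
    n_iterations: int = 0

    @property
    def centroid_ids(self) -> list[int]:
        return [c.id for c in self.centroids]

    def centroid_by_id(self, cid: int) -> Centroid:
        for c in self.centroids:
            if c.id == cid:
                return c
        raise KeyError(cid)

    def members(self, cid: int) -> np.ndarray:
        return self.elements[self.assignment == cid]


def mean_pairwise_separation(points: np.ndarray) -> float:
    """Mean distance over all unordered point pairs (0 for < 2 points)."""
    if len(points) < 2:
        return 0.0
    return float(pdist(points).mean())


def _compute_metrics(state: ClusterState) -> None:
    px = state.pixel_size_um
    for c in state.centroids:
        m = state.members(c.id)
        state.n_elements[c.id] = len(m)
        state.mean_separation_um[c.id] = mean_pairwise_separation(m) * px
        if len(m):
            state.mean_centroid_dist_um[c.id] = float(
                np.linalg.norm(m - c.xy, axis=1).mean()) * px
        else:
            state.mean_centroid_dist_um[c.id] = 0.0


def kmeans_assign(elements: np.ndarray, seeds: list[Centroid],
                  max_iter: int = 100, tol_px: float = 0.5,
                  frame_index: int = 0, pixel_size_um: float = 0.25) -> ClusterState:
    """Lloyd iteration from fixed seeds.

    Alternates assignment-to-nearest-centroid with centroid
    recomputation until no centroid moves more than ``tol_px`` or
    ``max_iter`` is reached.  Nearest-seed ties break to the lowest
    centroid id; clusters that lose all elements are dropped with a
    warning.  Seed ids are preserved on the surviving centroids.
    """
    elements = np.asarray(elements, dtype=float).reshape(-1, 2)
    if len(elements) == 0:
        raise ValueError("kmeans_assign requires at least one element")
    if not seeds:
        raise ValueError("kmeans_assign requires at least one seed")

    order = np.argsort([s.id for s in seeds], kind="stable")
    ids = np.array([seeds[i].id for i in order])
    centres = np.array([[seeds[i].x, seeds[i].y] for i in order], dtype=float)

    n_iter = 0
    labels = np.zeros(len(elements), dtype=int)
    for n_iter in range(1, max_iter + 1):
        d = cdist(elements, centres)
        labels = np.argmin(d, axis=1)  # ties -> lowest index = lowest id
        new_centres = centres.copy()
        for k in range(len(centres)):
            pts = elements[labels == k]
            if len(pts):
                new_centres[k] = pts.mean(axis=0)
        shift = np.linalg.norm(new_centres - centres, axis=1).max()
        centres = new_centres
        if shift <= tol_px:
            break

    # final assignment against converged centres
    labels = np.argmin(cdist(elements, centres), axis=1)
    occupied = np.unique(labels)
    if len(occupied) < len(centres):
        dropped = [int(ids[k]) for k in range(len(centres)) if k not in occupied]
        log.warning("frame %d: dropping empty clusters %s", frame_index, dropped)
    keep = {int(k): i for i, k in enumerate(occupied)}
    centroids = [Centroid(int(ids[k]), float(centres[k, 0]), float(centres[k, 1]),
                          frame_index) for k in occupied]
    assignment = np.array([int(ids[k]) for k in labels])

    state = ClusterState(frame_index, elements, centroids, assignment,
                         pixel_size_um, n_iterations=n_iter)
    _compute_metrics(state)
    state.silhouette_mean = silhouette(elements, assignment)[1]
    return state


def wcss(elements: np.ndarray, centroids: list[Centroid],
         assignment: np.ndarray) -> float:
    """Within-cluster sum of squared distances (the k-means objective)."""
    total = 0.0
    for c in centroids:
        pts = elements[assignment == c.id]
        if len(pts):
            total += float(((pts - c.xy) ** 2).sum())
    return total


def silhouette(elements: np.ndarray, assignment: np.ndarray
               ) -> tuple[np.ndarray, float]:
    """Per-element silhouette scores s = (b - a) / max(a, b).

    ``a`` is the mean distance to the other members of the element's own
    cluster; ``b`` the smallest mean distance to the members of any
    other cluster.  Values near 1 mean the element sits well inside its
    cluster.  Conventions: a singleton member scores 0; with a single
    cluster the mean is defined as 0 (with a warning).
    """
    elements = np.asarray(elements, dtype=float).reshape(-1, 2)
    assignment = np.asarray(assignment)
    labels = np.unique(assignment)
    n = len(elements)
    if len(labels) < 2:
        log.warning("silhouette undefined for a single cluster; returning 0")
        return np.zeros(n), 0.0

    d = cdist(elements, elements)
    # distance sums from every element to every cluster, vectorised
    k = len(labels)
    onehot = np.stack([assignment == lab for lab in labels], axis=1)  # (n, k)
    sums = d @ onehot                                                 # (n, k)
    sizes = onehot.sum(axis=0)                                        # (k,)
    own_col = np.argmax(onehot, axis=1)
    own_size = sizes[own_col]
    idx = np.arange(n)
    with np.errstate(invalid="ignore", divide="ignore"):
        a = sums[idx, own_col] / np.maximum(own_size - 1, 1)
        means = sums / sizes[None, :]
        means[idx, own_col] = np.inf  # exclude the own cluster from b
        b = means.min(axis=1)
        denom = np.maximum(a, b)
        scores = np.where(denom > 0, (b - a) / denom, 0.0)
    scores = np.where(own_size == 1, 0.0, scores)  # singleton convention
    return scores, float(scores.mean())


def update_seeds(prev: ClusterState, elements: np.ndarray,
                 spawn_px: float, removal_px: float,
                 id_counter: itertools.count) -> list[Centroid]:
    """Derive the seed set for frame t from the centroids of frame t-1.

    Seeds start as the previous centroids.  Scanning elements in order,
    any element farther than ``spawn_px`` from every current seed
    (including freshly spawned ones) becomes a new seed at its own
    position — this absorbs both cells entering the field and sporadic
    noise points, which are indistinguishable at this stage.  Finally
    any seed with no element within ``removal_px`` is removed (clusters
    that left the field, or stale noise seeds).
    """
    elements = np.asarray(elements, dtype=float).reshape(-1, 2)
    seeds: list[Centroid] = [Centroid(c.id, c.x, c.y, prev.frame_index + 1)
                             for c in prev.centroids]
    positions = [s.xy for s in seeds]
    for e in elements:
        if positions:
            dmin = np.min(np.linalg.norm(np.asarray(positions) - e, axis=1))
        else:
            dmin = np.inf
        if dmin > spawn_px:
            s = Centroid(next(id_counter), float(e[0]), float(e[1]),
                         prev.frame_index + 1)
            seeds.append(s)
            positions.append(s.xy)
    if not len(elements):
        return []
    kept = []
    for s in seeds:
        dmin = np.min(np.linalg.norm(elements - s.xy, axis=1))
        if dmin <= removal_px:
            kept.append(s)
    return kept


def auto_seed(elements: np.ndarray, radius_px: float,
              id_counter: itertools.count) -> list[Centroid]:
    """First-frame seeding: one seed per connected component of elements
    linked at ``radius_px`` (automatic alternative to a manual seed file).
    """
    elements = np.asarray(elements, dtype=float).reshape(-1, 2)
    n = len(elements)
    if n == 0:
        return []
    from scipy.spatial import cKDTree

    tree = cKDTree(elements)
    pairs = tree.query_pairs(radius_px)
    parent = list(range(n))

    def find(a: int) -> int:
        while parent[a] != a:
            parent[a] = parent[parent[a]]
            a = parent[a]
        return a

    for i, j in pairs:
        ri, rj = find(i), find(j)
        if ri != rj:
            parent[rj] = ri
    groups: dict[int, list[int]] = {}
    for i in range(n):
        groups.setdefault(find(i), []).append(i)
    seeds = []
    for members in sorted(groups.values(), key=lambda m: m[0]):
        centre = elements[members].mean(axis=0)
        seeds.append(Centroid(next(id_counter), float(centre[0]), float(centre[1]), 0))
    return seeds


def _split_seed_position(state: ClusterState, cid: int,
                         offset_px: float) -> np.ndarray:
    """Extra-seed position: ``offset_px`` from the centroid toward the
    cluster's farthest member (fastest separation of bimodal clusters).

    The offset is capped at the farthest-member distance so the probe
    seed always lands inside the cluster's support; otherwise a compact
    cluster could place the probe beyond every element and the trial
    split would collapse immediately.
    """
    c = state.centroid_by_id(cid)
    members = state.members(cid)
    d = np.linalg.norm(members - c.xy, axis=1)
    far = members[int(np.argmax(d))]
    direction = far - c.xy
    norm = np.linalg.norm(direction)
    if norm == 0:
        direction, norm = np.array([1.0, 0.0]), 1.0
    return c.xy + direction / norm * min(offset_px, norm)


def split_cluster(state: ClusterState, cid: int, config: PipelineConfig,
                  id_counter: itertools.count, force: bool = False
                  ) -> tuple[ClusterState, bool, tuple[int, int] | None]:
    """Re-run k-means with one extra seed next to cluster ``cid``.

    The extra seed is placed ``split_seed_offset_px`` from the centroid,
    toward the cluster's farthest member.  Unless ``force`` is given the
    split is accepted only if the frame's mean silhouette improves.  On
    acceptance both products receive fresh ids (daughters are treated
    symmetrically) and their ids are returned.
    """
    if state.n_elements.get(cid, 0) < 2:
        return state, False, None
    extra_xy = _split_seed_position(state, cid, config.split_seed_offset_px)
    probe_id = max(state.centroid_ids) + 1_000_000  # placeholder, replaced below
    seeds = [Centroid(c.id, c.x, c.y, state.frame_index) for c in state.centroids]
    seeds.append(Centroid(probe_id, float(extra_xy[0]), float(extra_xy[1]),
                          state.frame_index))
    trial = kmeans_assign(state.elements, seeds, config.kmeans_max_iter,
                          config.kmeans_tol_px, state.frame_index,
                          state.pixel_size_um)
    if probe_id not in trial.centroid_ids or cid not in trial.centroid_ids:
        return state, False, None
    if not force and trial.silhouette_mean <= state.silhouette_mean:
        return state, False, None
    # accept: relabel both products with fresh ids
    id_a, id_b = next(id_counter), next(id_counter)
    remap = {cid: id_a, probe_id: id_b}
    for c in trial.centroids:
        if c.id in remap:
            c.id = remap[c.id]
    trial.assignment = np.array([remap.get(int(a), int(a)) for a in trial.assignment])
    trial.centroids.sort(key=lambda c: c.id)
    for d in (trial.mean_separation_um, trial.mean_centroid_dist_um, trial.n_elements):
        for old, new in remap.items():
            if old in d:
                d[new] = d.pop(old)
    return trial, True, (id_a, id_b)


def run_split_tests(state: ClusterState, config: PipelineConfig,
                    id_counter: itertools.count
                    ) -> tuple[ClusterState, list[tuple[int, int, int]]]:
    """Apply the 15 um split rule until every cluster validates.

    Returns the final state and a list of accepted splits as
    ``(old_id, new_id_a, new_id_b)``.
    """
    accepted: list[tuple[int, int, int]] = []
    refused: set[int] = set()
    guard = 0
    while guard < 100:
        guard += 1
        trigger = None
        for c in sorted(state.centroids, key=lambda c: c.id):
            if (c.id not in refused and state.n_elements[c.id] >= 2
                    and state.mean_separation_um[c.id] > config.split_separation_um):
                trigger = c.id
                break
        if trigger is None:
            break
        state, ok, new_ids = split_cluster(state, trigger, config, id_counter)
        if ok and new_ids is not None:
            accepted.append((trigger, *new_ids))
        else:
            refused.add(trigger)
    return state, accepted
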