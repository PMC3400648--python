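"""Lineage trees, motility vectors and population statistics.

A *cell* of the lineage is a maximal chain of track segments between
divisions.  Bifurcations confirmed by the mitotic curve become
mother->daughter edges; unconfirmed bifurcations (cluster corrections,
e.g. two touching cells separating again) continue the cell through the
nearest child while the other child starts a new progenitor.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .mitosis import DivisionEvent
from .tracking import TrackGraph


@dataclass
class LineageCell:
    """One cell of the lineage: birth to division/loss/movie end."""

    cell_id: int
    parent_id: int | None
    birth_frame: int
    end_frame: int
    end_reason: str  # "division" | "lost" | "movie_end"
    daughter_ids: list[int] = field(default_factory=list)
    track_ids: list[int] = field(default_factory=list)
    nodes: list[tuple[int, int]] = field(default_factory=list)
    positions_px: list[tuple[float, float]] = field(default_factory=list)


@dataclass
class LineageTree:
    """Forest of lineage cells, one tree per progenitor."""

    cells: dict[int, LineageCell] = field(default_factory=dict)
    roots: list[int] = field(default_factory=list)

    def n_divisions(self) -> int:
        return sum(1 for c in self.cells.values() if c.end_reason == "division")

    def subtree_shape(self, cell_id: int) -> str:
        """Canonical (order-independent) topology string of a subtree."""
        cell = self.cells[cell_id]
        if not cell.daughter_ids:
            return "*"
        kids = sorted(self.subtree_shape(d) for d in cell.daughter_ids)
        return "(" + ",".join(kids) + ")"


@dataclass
class PopulationStats:
    """Whole-field counts and derived proliferation rates."""

    per_frame: pd.DataFrame  # frame, n_centroids, mean_elements_per_cluster
    doubling_time_h: float | None
    element_halving_time_h: float | None


def doubling_time(n0: float, n1: float, delta_hours: float) -> float | None:
    """Two-point exponential-growth estimate T = dt / log2(N1/N0).

    Returns None (undefined) when the count does not increase.
    """
    if n1 <= n0 or n0 <= 0:
        return None
    return delta_hours / math.log2(n1 / n0)


def build_lineage(tracks: TrackGraph, divisions: list[DivisionEvent],
                  last_frame: int | None = None) -> LineageTree:
    """Assemble the lineage forest from the track graph and the
    curve-confirmed division events.
    """
    g = tracks.graph
    track_nodes = tracks.tracks()
    known = set(track_nodes)
    div_by_parent: dict[int, DivisionEvent] = {}
    for ev in divisions:
        if ev.parent_track_id not in known:
            raise ValueError(f"division references unknown track {ev.parent_track_id}")
        for d in ev.daughter_track_ids:
            if d not in known:
                raise ValueError(f"division references unknown daughter track {d}")
        div_by_parent[ev.parent_track_id] = ev

    if last_frame is None:
        last_frame = max((n[0] for n in g.nodes), default=0)

    tree = LineageTree()
    next_cell = iter(range(1, 10 ** 9)).__next__

    def successors_of_track(tid: int) -> list[int]:
        """Track ids of the children reached at the end of track tid."""
        tail = track_nodes[tid][-1]
        return [g.nodes[s]["track_id"] for s in sorted(g.successors(tail))]

    # jobs: (start_track, parent_cell_id or None, birth_frame, is_root)
    from collections import deque

    jobs: deque[tuple[int, int | None, int, bool]] = deque()
    queued: set[int] = set()
    for root in sorted(tracks.roots, key=lambda n: (n[0], n[1])):
        tid = tracks.track_of(root)
        if tid not in queued:
            queued.add(tid)
            jobs.append((tid, None, root[0], True))

    while jobs:
        start_track, parent_cell, birth_frame, is_root = jobs.popleft()
        cid = next_cell()
        cell = LineageCell(cid, parent_cell, birth_frame, birth_frame,
                           "movie_end")
        tree.cells[cid] = cell
        if is_root:
            tree.roots.append(cid)
        if parent_cell is not None:
            tree.cells[parent_cell].daughter_ids.append(cid)
        tid = start_track
        while True:
            cell.track_ids.append(tid)
            for node in track_nodes[tid]:
                cell.nodes.append(node)
                cell.positions_px.append((g.nodes[node]["x"],
                                          g.nodes[node]["y"]))
            succ = successors_of_track(tid)
            ev = div_by_parent.get(tid) if len(succ) == 2 else None
            if ev is not None and set(ev.daughter_track_ids) == set(succ):
                cell.end_frame = track_nodes[tid][-1][0]
                cell.end_reason = "division"
                for d in sorted(ev.daughter_track_ids):
                    if d not in queued:
                        queued.add(d)
                        jobs.append((d, cid, ev.frame_confirmed, False))
                break
            if len(succ) == 2:
                # unconfirmed bifurcation (cluster correction): continue
                # through the nearest child; the other starts a new root
                tail = track_nodes[tid][-1]
                tx, ty = g.nodes[tail]["x"], g.nodes[tail]["y"]

                def dist(t: int) -> float:
                    n0 = track_nodes[t][0]
                    return float(np.hypot(g.nodes[n0]["x"] - tx,
                                          g.nodes[n0]["y"] - ty))

                near, far = sorted(succ, key=dist)
                if far not in queued:
                    queued.add(far)
                    jobs.append((far, None, track_nodes[far][0][0], True))
                if near in queued:
                    break  # defensive: never walk a track twice
                queued.add(near)
                tid = near
            elif len(succ) == 1:
                if succ[0] in queued:
                    break
                queued.add(succ[0])
                tid = succ[0]
            else:
                end = track_nodes[tid][-1][0]
                cell.end_frame = end
                cell.end_reason = "movie_end" if end >= last_frame else "lost"
                break

    tree.roots = sorted(set(tree.roots),
                        key=lambda c: (tree.cells[c].birth_frame, c))
    return tree


def _descendants(tree: LineageTree, cell_id: int) -> list[int]:
    out = [cell_id]
    for d in tree.cells[cell_id].daughter_ids:
        out.extend(_descendants(tree, d))
    return out


def motility_vectors(tree: LineageTree, pixel_size_um: float,
                     frame_interval_min: float) -> pd.DataFrame:
    """Per-cell mean velocity between birth and end, in um/h.

    The vector is net displacement over elapsed time (matching the
    lineage-portrait arrows); total path length is also reported.
    Single-frame cells get a zero vector and are flagged.
    """
    rows = []
    dt_h = frame_interval_min / 60.0
    for cell in tree.cells.values():
        pos = np.asarray(cell.positions_px, dtype=float) * pixel_size_um
        frames = [n[0] for n in cell.nodes]
        if len(pos) < 2 or frames[-1] == frames[0]:
            rows.append(dict(cell_id=cell.cell_id, vx_um_h=0.0, vy_um_h=0.0,
                             speed_um_h=0.0, path_length_um=0.0,
                             flagged=True))
            continue
        elapsed_h = (frames[-1] - frames[0]) * dt_h
        net = pos[-1] - pos[0]
        v = net / elapsed_h
        path = float(np.linalg.norm(np.diff(pos, axis=0), axis=1).sum())
        rows.append(dict(cell_id=cell.cell_id, vx_um_h=float(v[0]),
                         vy_um_h=float(v[1]),
                         speed_um_h=float(np.linalg.norm(v)),
                         path_length_um=path, flagged=False))
    return pd.DataFrame(rows)


def population_stats(states: list["ClusterState"], t0_frame: int, t1_frame: int,
                     frame_interval_min: float = 5.0) -> PopulationStats:
    """Per-frame centroid counts, mean cluster sizes, and the two-point
    doubling / element-halving times between ``t0_frame`` and ``t1_frame``.
    """
    if t0_frame >= t1_frame:
        raise ValueError("t0_frame must precede t1_frame")
    rows = []
    for s in states:
        n = len(s.centroids)
        mean_el = (float(np.mean([s.n_elements[c.id] for c in s.centroids]))
                   if n else 0.0)
        rows.append(dict(frame=s.frame_index, n_centroids=n,
                         mean_elements_per_cluster=mean_el))
    df = pd.DataFrame(rows).set_index("frame", drop=False)
    dt_h = (t1_frame - t0_frame) * frame_interval_min / 60.0
    n0 = float(df.loc[t0_frame, "n_centroids"])
    n1 = float(df.loc[t1_frame, "n_centroids"])
    e0 = float(df.loc[t0_frame, "mean_elements_per_cluster"])
    e1 = float(df.loc[t1_frame, "mean_elements_per_cluster"])
    T = doubling_time(n0, n1, dt_h)
    # elements per cluster *halve* as cells double: same formula on the inverse
    H = doubling_time(e1, e0, dt_h)
    return PopulationStats(df.reset_index(drop=True), T, H)


def to_json(tree: LineageTree, frame_interval_min: float = 5.0) -> str:
    """Nested-dict JSON rendering of the lineage forest."""

    def node(cell_id: int) -> dict:
        c = tree.cells[cell_id]
        return {
            "cell_id": c.cell_id,
            "birth_frame": c.birth_frame,
            "end_frame": c.end_frame,
            "end_reason": c.end_reason,
            "lifetime_h": (c.end_frame - c.birth_frame) * frame_interval_min / 60.0,
            "children": [node(d) for d in c.daughter_ids],
        }

    return json.dumps({"roots": [node(r) for r in tree.roots]}, indent=2)


def to_newick(tree: LineageTree, frame_interval_min: float = 5.0) -> str:
    """Newick forest (one tree per line); branch lengths in hours."""

    def render(cell_id: int) -> str:
        c = tree.cells[cell_id]
        length = (c.end_frame - c.birth_frame) * frame_interval_min / 60.0
        label = f"c{c.cell_id}"
        if not c.daughter_ids:
            return f"{label}:{length:.4g}"
        kids = ",".join(render(d) for d in c.daughter_ids)
        return f"({kids}){label}:{length:.4g}"

    return "\n".join(render(r) + ";" for r in tree.roots)
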