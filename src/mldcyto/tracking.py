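"""Frame-to-frame centroid linkage and track graph assembly.

Centroids of successive frames are linked by a greedy nearest-neighbour
pass over the ascending list of cross-frame distances, restricted to the
average single-cell diameter (10 um).  A centroid claiming two children
is flagged as a division candidate; a next-frame centroid that no parent
reaches within the radius starts a new progenitor track.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
from scipy.spatial.distance import cdist

from .clustering import ClusterState


@dataclass
class LinkRecord:
    """Parent/child centroid pairing between two consecutive frames."""

    frame_from: int
    frame_to: int
    pairs: list[tuple[int, int]]
    new_progenitors: list[int]
    division_candidates: list[int]

    def parent_of(self) -> dict[int, int]:
        return {child: parent for parent, child in self.pairs}

    def children_of(self) -> dict[int, list[int]]:
        out: dict[int, list[int]] = {}
        for parent, child in self.pairs:
            out.setdefault(parent, []).append(child)
        return out


def link_frames(c_i: ClusterState, c_next: ClusterState,
                link_radius_um: float = 10.0) -> LinkRecord:
    """Greedy ascending nearest-neighbour linkage of two frames.

    All cross-frame pairs within ``link_radius_um`` are visited in order
    of increasing distance (ties broken by (parent id, child id)); a
    pair links when the child is still parentless and the parent has
    fewer than two children.  A third nearest neighbour is never linked:
    only two-way splits occur at division.
    """
    if c_next.frame_index != c_i.frame_index + 1:
        raise ValueError("link_frames expects consecutive frames")
    radius_px = link_radius_um / c_i.pixel_size_um

    parents = sorted(c_i.centroids, key=lambda c: c.id)
    children = sorted(c_next.centroids, key=lambda c: c.id)
    if not parents:
        return LinkRecord(c_i.frame_index, c_next.frame_index, [],
                          [c.id for c in children], [])
    if not children:
        return LinkRecord(c_i.frame_index, c_next.frame_index, [], [], [])

    pxy = np.array([[p.x, p.y] for p in parents])
    cxy = np.array([[c.x, c.y] for c in children])
    d = cdist(pxy, cxy)
    cand = [(d[i, j], parents[i].id, children[j].id)
            for i in range(len(parents)) for j in range(len(children))
            if d[i, j] <= radius_px]
    cand.sort()

    child_parent: dict[int, int] = {}
    n_children: dict[int, int] = {p.id: 0 for p in parents}
    for dist, pid, cid in cand:
        if cid in child_parent or n_children[pid] >= 2:
            continue
        child_parent[cid] = pid
        n_children[pid] += 1

    pairs = sorted((p, c) for c, p in child_parent.items())
    progenitors = sorted(c.id for c in children if c.id not in child_parent)
    candidates = sorted(pid for pid, n in n_children.items() if n == 2)
    return LinkRecord(c_i.frame_index, c_next.frame_index, pairs,
                      progenitors, candidates)


@dataclass
class TrackGraph:
    """Temporal graph of centroids: nodes are (frame, centroid_id).

    Node attributes: ``x``, ``y`` (px), ``track_id``.  Edges run parent
    to child, frame strictly increasing; out-degree 2 marks a division
    bifurcation and starts two new track ids.
    """

    graph: nx.DiGraph = field(default_factory=nx.DiGraph)
    roots: list[tuple[int, int]] = field(default_factory=list)

    def tracks(self) -> dict[int, list[tuple[int, int]]]:
        """Track id -> time-ordered list of (frame, centroid_id) nodes."""
        out: dict[int, list[tuple[int, int]]] = {}
        for node, data in self.graph.nodes(data=True):
            out.setdefault(data["track_id"], []).append(node)
        for nodes in out.values():
            nodes.sort()
        return out

    def track_of(self, node: tuple[int, int]) -> int:
        return self.graph.nodes[node]["track_id"]

    def parent_track(self, track_id: int) -> int | None:
        first = self.tracks()[track_id][0]
        preds = list(self.graph.predecessors(first))
        if not preds:
            return None
        return self.graph.nodes[preds[0]]["track_id"]

    def validate(self) -> None:
        g = self.graph
        if not nx.is_directed_acyclic_graph(g):
            raise ValueError("track graph has a cycle")
        for u, v in g.edges:
            if v[0] != u[0] + 1:
                raise ValueError(f"edge {u}->{v} does not advance one frame")
        for n in g.nodes:
            if g.out_degree(n) > 2:
                raise ValueError(f"node {n} has out-degree > 2")
            if g.in_degree(n) > 1:
                raise ValueError(f"node {n} has more than one parent")


def build_track_graph(links: list[LinkRecord],
                      states: list[ClusterState] | None = None) -> TrackGraph:
    """Concatenate consecutive LinkRecords into a TrackGraph.

    Track ids are stable along unbranched chains; both children of a
    division bifurcation start fresh track ids (daughters are treated
    symmetrically).  ``states`` supplies node coordinates when given.
    """
    for a, b in zip(links, links[1:]):
        if b.frame_from != a.frame_to:
            raise ValueError("link records must cover consecutive frame pairs")

    tg = TrackGraph()
    g = tg.graph
    pos: dict[tuple[int, int], tuple[float, float]] = {}
    by_frame: dict[int, ClusterState] = {}
    if states:
        for s in states:
            by_frame[s.frame_index] = s
            for c in s.centroids:
                pos[(s.frame_index, c.id)] = (c.x, c.y)

    def ensure(node: tuple[int, int]) -> None:
        if node not in g:
            xy = pos.get(node, (np.nan, np.nan))
            g.add_node(node, x=xy[0], y=xy[1], track_id=-1)

    next_track = iter(range(10 ** 9)).__next__
    # frame of the first link's parents is the root frame
    if links:
        f0 = links[0].frame_from
        first_ids = ({c.id for c in by_frame[f0].centroids} if f0 in by_frame
                     else {p for p, _ in links[0].pairs})
        for cid in sorted(first_ids):
            node = (f0, cid)
            ensure(node)
            g.nodes[node]["track_id"] = next_track()
            tg.roots.append(node)
    elif states:
        for c in by_frame[min(by_frame)].centroids:
            node = (min(by_frame), c.id)
            ensure(node)
            g.nodes[node]["track_id"] = next_track()
            tg.roots.append(node)

    for link in links:
        children = link.children_of()
        for pid, kids in children.items():
            pnode = (link.frame_from, pid)
            ensure(pnode)
            if g.nodes[pnode]["track_id"] < 0:
                g.nodes[pnode]["track_id"] = next_track()
                tg.roots.append(pnode)
            for cid in kids:
                cnode = (link.frame_to, cid)
                ensure(cnode)
                g.add_edge(pnode, cnode)
                if len(kids) == 2:
                    g.nodes[cnode]["track_id"] = next_track()
                else:
                    g.nodes[cnode]["track_id"] = g.nodes[pnode]["track_id"]
        for cid in link.new_progenitors:
            cnode = (link.frame_to, cid)
            ensure(cnode)
            g.nodes[cnode]["track_id"] = next_track()
            tg.roots.append(cnode)

    tg.validate()
    return tg
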