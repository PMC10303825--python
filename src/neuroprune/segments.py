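"""Segment-based tree representation of a neuron reconstruction.

A *segment* is a maximal unbranched polyline between branch points (the
soma, bifurcations, and tips), oriented in the direction of reconstruction
outwards from the soma.  Adjacent segments share exactly their junction
node: a segment's first (proximal) node is its parent segment's last
(distal) node.  Leaf segments have level 0; an internal segment's level is
the height of the segment subtree below it (max over descendant leaves).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .swc import NeuronTree

__all__ = [
    "Segment",
    "SegmentTree",
    "PruneReport",
    "PruneEntry",
    "StructuralError",
    "build_segment_tree",
    "path_between",
    "prune_segments",
]


class StructuralError(ValueError):
    """Tree is not a single rooted component (cycle / forest)."""


@dataclass
class Segment:
    seg_id: int
    node_ids: list[int]          # proximal (soma side) -> distal
    parent_seg: int | None
    child_segs: list[int] = field(default_factory=list)
    level: int = 0
    length: float = 0.0          # micrometers, cached

    @property
    def proximal(self) -> int:
        return self.node_ids[0]

    @property
    def distal(self) -> int:
        return self.node_ids[-1]

    @property
    def is_leaf(self) -> bool:
        return not self.child_segs


@dataclass
class PruneEntry:
    seg_id: int
    reason: str                  # C1 / C2 / C3 / C4
    model: str                   # none / Y / T / X / H / pseudoX / separation
    length: float
    iteration: int = 0
    n_nodes: int = 0


@dataclass
class PruneReport:
    entries: list[PruneEntry] = field(default_factory=list)

    def extend(self, other: "PruneReport") -> None:
        self.entries.extend(other.entries)

    def by_reason(self, reason: str) -> list[PruneEntry]:
        return [e for e in self.entries if e.reason == reason]

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("seg_id\treason\tmodel\tlength_um\titeration\tn_nodes\n")
            for e in self.entries:
                fh.write(f"{e.seg_id}\t{e.reason}\t{e.model}\t{e.length:.4f}\t"
                         f"{e.iteration}\t{e.n_nodes}\n")


class SegmentTree:
    """Rooted tree of oriented segments over a :class:`NeuronTree`."""

    def __init__(self, segments: dict[int, Segment], soma_seg: int,
                 source: NeuronTree):
        self.segments = segments
        self.soma_seg = soma_seg
        self.source = source
        self.coords = source.coords_um()
        # each node maps to the unique segment where it is non-proximal
        # (the segment arriving from its parent); the root maps to soma_seg
        self.node_seg: dict[int, int] = {}
        for s in segments.values():
            for nid in s.node_ids[1:]:
                self.node_seg[nid] = s.seg_id
        root = segments[soma_seg].proximal
        self.node_seg.setdefault(root, soma_seg)

    # -- queries -----------------------------------------------------------

    def n_nodes(self) -> int:
        return len(self.source.nodes)

    def leaf_segments(self) -> list[int]:
        return [s.seg_id for s in self.segments.values() if s.is_leaf]

    def segment_level(self, seg_id: int) -> int:
        if seg_id not in self.segments:
            raise KeyError(f"unknown segment id {seg_id}")
        return self.segments[seg_id].level

    def seg_coords(self, seg_id: int) -> np.ndarray:
        """(n, 3) micrometer coordinates, proximal -> distal."""
        return np.array([self.coords[n] for n in self.segments[seg_id].node_ids])

    def bifurcation_segments(self) -> list[int]:
        """Segments whose distal node is a branch point (>= 2 children)."""
        return [s.seg_id for s in self.segments.values() if len(s.child_segs) >= 2]

    def descendants(self, seg_id: int) -> set[int]:
        out = set()
        stack = [seg_id]
        while stack:
            sid = stack.pop()
            out.add(sid)
            stack.extend(self.segments[sid].child_segs)
        return out

    def incident_segments(self, node_id: int) -> list[int]:
        """All segments having ``node_id`` as an endpoint."""
        out = []
        for s in self.segments.values():
            if s.proximal == node_id or s.distal == node_id:
                out.append(s.seg_id)
        return out


def _segment_length(coords: np.ndarray) -> float:
    if len(coords) < 2:
        return 0.0
    return float(np.linalg.norm(np.diff(coords, axis=0), axis=1).sum())


def build_segment_tree(tree: NeuronTree) -> SegmentTree:
    """Convert a single-rooted node tree into its segment tree.

    Branch points are the root, tips, and any node with >= 2 children
    (multifurcations yield one segment per child).  If the root itself is a
    branch point the soma segment is degenerate (a single node).
    """
    tree.validate()
    roots = tree.roots()
    if len(tree.nodes) == 0:
        raise StructuralError("empty tree")
    if len(roots) != 1:
        raise StructuralError(f"expected a single rooted component, found {len(roots)} roots")
    root = roots[0]
    ch = tree.children_map()
    coords = tree.coords_um()

    segments: dict[int, Segment] = {}
    next_id = [0]

    def new_segment(nodes: list[int], parent: int | None) -> int:
        sid = next_id[0]
        next_id[0] += 1
        pts = np.array([coords[n] for n in nodes])
        segments[sid] = Segment(sid, nodes, parent, [], 0, _segment_length(pts))
        if parent is not None:
            segments[parent].child_segs.append(sid)
        return sid

    def walk(start: int, first: int, parent: int | None) -> int:
        """Collect [start, first, ...] until the next branch point."""
        nodes = [start, first]
        cur = first
        while len(ch[cur]) == 1:
            cur = ch[cur][0]
            nodes.append(cur)
        return new_segment(nodes, parent)

    root_children = ch[root]
    if len(root_children) == 1:
        soma_seg = walk(root, root_children[0], None)
    else:
        # root is itself a branch point (or isolated): degenerate soma segment
        soma_seg = new_segment([root], None)

    # every walked segment ends at a tip (0 children) or a branch point
    # (>= 2 children); each child of a distal branch node starts a segment
    stack = [soma_seg]
    while stack:
        sid = stack.pop()
        distal = segments[sid].distal
        for c in ch[distal]:
            stack.append(walk(distal, c, sid))

    _recompute_levels(segments, soma_seg)
    return SegmentTree(segments, soma_seg, tree)


def _recompute_levels(segments: dict[int, Segment], soma_seg: int) -> None:
    order: list[int] = []
    stack = [soma_seg]
    while stack:
        sid = stack.pop()
        order.append(sid)
        stack.extend(segments[sid].child_segs)
    for sid in reversed(order):
        s = segments[sid]
        s.level = 0 if not s.child_segs else 1 + max(segments[c].level for c in s.child_segs)


def _node_path(tree: NeuronTree, a: int, b: int) -> list[int]:
    """Unique tree path a -> b via the lowest common ancestor."""
    anc_a = []
    nid = a
    while nid in tree.nodes:
        anc_a.append(nid)
        nid = tree.nodes[nid].parent_id
    pos = {n: i for i, n in enumerate(anc_a)}
    chain_b = []
    nid = b
    while nid not in pos:
        chain_b.append(nid)
        nid = tree.nodes[nid].parent_id
        if nid not in tree.nodes and nid not in pos:
            raise ValueError("nodes are not in the same component")
    lca = nid
    return anc_a[: pos[lca] + 1] + list(reversed(chain_b))


def path_between(stree: SegmentTree, a: int, b: int):
    """Tree path between two nodes.

    Returns ``(segment_ids, bifurcation_node_ids, off_path_children)`` where
    ``segment_ids`` lists main-path segments in order a -> b,
    ``bifurcation_node_ids`` are the branch nodes strictly between a and b,
    and ``off_path_children`` maps each such node to the incident segments
    hanging off the path there.
    """
    if a == b:
        return [], [], {}
    nodes = _node_path(stree.source, a, b)
    node_set = set(nodes)
    # segments along the path, in order
    seg_order: list[int] = []
    for prev, cur in zip(nodes, nodes[1:]):
        # the edge (prev, cur) lies in the segment where the child-side node
        # is non-proximal
        child = cur if stree.source.nodes[cur].parent_id == prev else prev
        sid = stree.node_seg[child]
        if not seg_order or seg_order[-1] != sid:
            seg_order.append(sid)
    path_segs = set(seg_order)
    bifs: list[int] = []
    off: dict[int, list[int]] = {}
    for nid in nodes[1:-1]:
        inc = [s for s in stree.incident_segments(nid) if s not in path_segs]
        if inc:
            bifs.append(nid)
            off[nid] = inc
    return seg_order, bifs, off


def prune_segments(stree: SegmentTree, to_remove, reason: str,
                   model: str = "none", iteration: int = 0):
    """Remove segments (and, by orientation, their whole descendant
    subtrees), then rebuild the canonical segment tree.

    Junction nodes shared with kept segments are retained.  If a junction
    is left with exactly one child the two incident segments merge in the
    rebuild, so later steps see true bifurcations only.  Removing the soma
    segment is refused.
    """
    to_remove = set(to_remove)
    if not to_remove:
        return stree, PruneReport()
    unknown = to_remove - set(stree.segments)
    if unknown:
        raise KeyError(f"unknown segment ids {sorted(unknown)}")
    if stree.soma_seg in to_remove:
        raise ValueError("refusing to remove the soma segment")
    closed: set[int] = set()
    for sid in to_remove:
        closed |= stree.descendants(sid)
    if stree.soma_seg in closed:
        raise ValueError("refusing to remove the soma segment")
    report = PruneReport([
        PruneEntry(sid, reason, model, stree.segments[sid].length, iteration,
                   len(stree.segments[sid].node_ids) - 1)
        for sid in sorted(closed)
    ])
    drop_nodes: set[int] = set()
    for sid in closed:
        drop_nodes.update(stree.segments[sid].node_ids[1:])
    keep = set(stree.source.nodes) - drop_nodes
    new_source = stree.source.subset(keep)
    return build_segment_tree(new_source), report
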