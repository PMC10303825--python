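"""Step 2: separation of entangled multi-neuron reconstructions (C2).

When dendrites of nearby neurons are entangled, the automated tracer can
merge several neurons into one connected reconstruction.  Given the soma
locations, each inter-soma path is examined: every bifurcation on the path
is a candidate separation site, scored by a weight reflecting how likely
it belongs to each soma's neuron (smooth continuation of the main path and
forward-branching children favor ownership; the weight decays with
distance from the soma).  The split maximizes the summed weights

    W_s = sum_{i<=s} W_A(B_i) + sum_{j>=s} W_A'(B_j)

over the split index s (the index sums overlap at s, matching the printed
form of the criterion).  Abnormally long root-to-tip paths are handled by
treating their endpoints as "fake" somata so entanglements with neurons
outside the image can still be cut off.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np

from .features import Thresholds, angle_between
from .segments import (PruneEntry, PruneReport, SegmentTree,
                       build_segment_tree, path_between, _node_path)
from .swc import NeuronTree

log = logging.getLogger(__name__)

__all__ = [
    "SomaPath",
    "SeparationResult",
    "map_soma",
    "soma_path",
    "bifurcation_weight",
    "best_separation_point",
    "separate_pair",
    "separate_all",
    "fake_soma_patch",
]

#: default bound on soma-to-reconstruction mapping distance (micrometers)
SOMA_MAP_MAX_DIST = 50.0


@dataclass
class SomaPath:
    """The main path between two somata and its candidate split sites."""

    node_a: int
    node_b: int
    nodes: list[int]                       # full node path a -> b
    main_segments: list[int]
    bifurcations: list[int]                # branch node ids strictly between
    off_path_children: dict[int, list[int]]
    stree: SegmentTree

    @property
    def n_bif(self) -> int:
        return len(self.bifurcations)


@dataclass
class SeparationResult:
    split_index: int                       # s in [0, N_B]; 0 = mid-edge cut
    split_node: int | None
    cut_edge: tuple[int, int]              # (parent-side node, child-side node)
    tree_a: SegmentTree | None
    tree_b: SegmentTree | None
    w_a: list[float] = field(default_factory=list)
    w_b: list[float] = field(default_factory=list)


def map_soma(tree: NeuronTree, xyz, max_dist: float = SOMA_MAP_MAX_DIST) -> int:
    """Nearest node to a soma location (micrometer distance, ties to the
    smallest id); errors if the soma lies farther than ``max_dist`` from
    the reconstruction."""
    soma = np.asarray(xyz, dtype=float)
    best, best_d = None, math.inf
    for nid in sorted(tree.nodes):
        d = float(np.linalg.norm(tree.xyz_um(nid) - soma))
        if d < best_d - 1e-12:
            best, best_d = nid, d
    if best is None:
        raise ValueError("empty tree")
    if best_d > max_dist:
        raise ValueError(
            f"soma at {tuple(soma)} maps {best_d:.1f} um from the reconstruction "
            f"(bound {max_dist} um)")
    return best


def soma_path(stree: SegmentTree, soma_a, soma_b,
              max_dist: float = SOMA_MAP_MAX_DIST) -> SomaPath:
    na = map_soma(stree.source, soma_a, max_dist)
    nb = map_soma(stree.source, soma_b, max_dist)
    if na == nb:
        raise ValueError("somata not distinct in reconstruction")
    segs, bifs, off = path_between(stree, na, nb)
    nodes = _node_path(stree.source, na, nb)
    return SomaPath(na, nb, nodes, segs, bifs, off, stree)


def _chord(coords: list[np.ndarray], start: int, step: int, local_len: float):
    """Unit chord from coords[start] along the list in direction ``step``
    until ``local_len`` of arclength is covered (clamped)."""
    acc = 0.0
    i = start
    target = None
    while 0 <= i + step < len(coords):
        nxt = i + step
        acc += float(np.linalg.norm(coords[nxt] - coords[i]))
        i = nxt
        target = coords[i]
        if acc >= local_len:
            break
    if target is None:
        return None
    v = target - coords[start]
    n = float(np.linalg.norm(v))
    return v / n if n > 0 else None


def bifurcation_weight(path: SomaPath, i: int, toward: str,
                       thr: Thresholds) -> float:
    """Weight W_X(B_i): likelihood that bifurcation i belongs to the neuron
    whose soma is on side ``toward`` ("A" or "B").

    ``W = alpha * f_angle + (1 - alpha) * exp(-d / lambda_d)`` where
    ``f_angle`` averages the cosine of the main-path turning angle at B_i
    (traversed from soma X) with the cosine of each child branch's
    deviation from a typical forward branching angle, and ``d`` is the
    Euclidean distance from B_i to soma X.  A smooth continuation with
    forward-branching children scores high; the weight decays with
    distance from the soma.
    """
    if toward not in ("A", "B"):
        raise ValueError("toward must be 'A' or 'B'")
    stree = path.stree
    bnode = path.bifurcations[i]
    coords = [stree.coords[n] for n in path.nodes]
    k = path.nodes.index(bnode)
    u_back = _chord(coords, k, -1, thr.local_len)   # toward soma A
    u_fwd = _chord(coords, k, +1, thr.local_len)    # toward soma B
    if u_back is None or u_fwd is None:
        log.warning("degenerate path direction at bifurcation node %d", bnode)
        return 0.0
    travel_out = u_fwd if toward == "A" else u_back  # direction leaving soma X
    travel_in = -u_back if toward == "A" else -u_fwd
    cos_turn = float(np.dot(travel_in, travel_out))

    child_terms = []
    for sid in path.off_path_children.get(bnode, []):
        s = stree.segments[sid]
        pts = stree.seg_coords(sid)
        if s.distal == bnode:
            pts = pts[::-1]
        elif s.proximal != bnode:
            continue
        cd = _chord(list(pts), 0, +1, thr.local_len)
        if cd is None:
            continue
        phi = angle_between(travel_out, cd)
        child_terms.append(math.cos(math.radians(phi - thr.typical_branch_angle)))
    f_angle = cos_turn if not child_terms else 0.5 * (cos_turn + float(np.mean(child_terms)))

    soma_xyz = stree.coords[path.node_a if toward == "A" else path.node_b]
    d = float(np.linalg.norm(stree.coords[bnode] - soma_xyz))
    return thr.alpha * f_angle + (1.0 - thr.alpha) * math.exp(-d / thr.lambda_d)


def path_weights(path: SomaPath, thr: Thresholds):
    w_a = [bifurcation_weight(path, i, "A", thr) for i in range(path.n_bif)]
    w_b = [bifurcation_weight(path, i, "B", thr) for i in range(path.n_bif)]
    return w_a, w_b


def best_separation_point(w_a, w_b) -> int:
    """Split index s in 1..N_B maximizing
    ``W_s = sum_{i=1}^{s} w_a[i] + sum_{j=s}^{N_B} w_b[j]`` (the sums
    overlap at s, as printed).  Exhaustive over all s; ties break toward
    the index closest to ceil(N_B/2), then the smaller s."""
    n = len(w_a)
    if n == 0 or n != len(w_b):
        raise ValueError("need equal, non-empty weight lists")
    mid = math.ceil(n / 2)
    best_s, best_w, best_key = None, -math.inf, None
    for s in range(1, n + 1):
        w = sum(w_a[:s]) + sum(w_b[s - 1:])
        key = (abs(s - mid), s)
        if w > best_w + 1e-12 or (abs(w - best_w) <= 1e-12 and key < best_key):
            best_s, best_w, best_key = s, w, key
        elif best_key is None:
            best_s, best_w, best_key = s, w, key
    return best_s


def _choose_cut_edge(path: SomaPath, thr: Thresholds):
    """Pick the cut edge on the main path.

    Cuts on the far side of B_s relative to A when W_A(B_s) >= W_B(B_s)
    (B_s and its children stay with A), else on the near side.  With no
    bifurcation on the path the single mid-edge is cut with a warning.
    """
    nodes = path.nodes
    if path.n_bif == 0:
        log.warning("no bifurcation between somata; cutting path mid-edge")
        k = len(nodes) // 2
        return 0, None, (nodes[k - 1], nodes[k]), [], []
    w_a, w_b = path_weights(path, thr)
    s = best_separation_point(w_a, w_b)
    bnode = path.bifurcations[s - 1]
    k = nodes.index(bnode)
    if w_a[s - 1] >= w_b[s - 1]:
        edge = (nodes[k], nodes[k + 1])
    else:
        edge = (nodes[k - 1], nodes[k])
    return s, bnode, edge, w_a, w_b


def _cut(tree: NeuronTree, edge: tuple[int, int]) -> NeuronTree:
    u, v = edge
    child = v if tree.nodes[v].parent_id == u else u
    other = u if child == v else v
    if tree.nodes[child].parent_id != other:
        raise ValueError(f"({u}, {v}) is not a tree edge")
    import dataclasses
    nodes = dict(tree.nodes)
    nodes[child] = dataclasses.replace(nodes[child], parent_id=-1)
    return NeuronTree(nodes, tree.unit, tree.voxel_size)


def separate_pair(stree: SegmentTree, soma_a, soma_b, thr: Thresholds,
                  max_dist: float = SOMA_MAP_MAX_DIST) -> SeparationResult:
    """Separate one entangled neuron pair at the best bifurcation.

    The tree is cut on the main path at the chosen split; each fragment is
    re-rooted at the node nearest its soma.  Off-path children at B_i for
    i <= s go with soma A, i > s with soma A'; B_s's own children follow
    the side with the larger weight at B_s.
    """
    path = soma_path(stree, soma_a, soma_b, max_dist)
    s, bnode, edge, w_a, w_b = _choose_cut_edge(path, thr)
    cut_tree = _cut(stree.source, edge)
    comps = cut_tree.components()
    comp_a = next(c for c in comps if path.node_a in c)
    comp_b = next(c for c in comps if path.node_b in c)
    tree_a = cut_tree.subset(comp_a).reroot(path.node_a)
    tree_b = cut_tree.subset(comp_b).reroot(path.node_b)
    return SeparationResult(s, bnode, edge,
                            build_segment_tree(tree_a),
                            build_segment_tree(tree_b), w_a, w_b)


def _path_length_um(tree: NeuronTree, a: int, b: int) -> float:
    nodes = _node_path(tree, a, b)
    return float(sum(np.linalg.norm(tree.xyz_um(u) - tree.xyz_um(v))
                     for u, v in zip(nodes, nodes[1:])))


def separate_all(stree: SegmentTree, somata, target_index: int,
                 thr: Thresholds, max_dist: float = SOMA_MAP_MAX_DIST):
    """Apply pairwise separation over all soma pairs sharing a path.

    Pairs are processed in order of increasing inter-soma path length
    (shortest, most entangled bridges first), re-deriving paths after each
    cut.  Returns one segment tree per soma (rooted at that soma) and a
    report listing the target neuron's C2 prunes (segments assigned to
    other somata).
    """
    if not somata:
        raise ValueError("need at least one soma location")
    if not 0 <= target_index < len(somata):
        raise ValueError("target index out of range")
    tree = stree.source
    soma_nodes = [map_soma(tree, xyz, max_dist) for xyz in somata]
    if len(set(soma_nodes)) != len(soma_nodes):
        raise ValueError("somata not distinct in reconstruction")

    work = tree
    while True:
        comps = work.components()
        comp_of = {}
        for idx, nid in enumerate(soma_nodes):
            for ci, c in enumerate(comps):
                if nid in c:
                    comp_of[idx] = ci
                    break
        pairs = [(i, j) for i in range(len(somata)) for j in range(i + 1, len(somata))
                 if comp_of.get(i) is not None and comp_of.get(i) == comp_of.get(j)]
        if not pairs:
            break
        pairs.sort(key=lambda p: _path_length_um(work, soma_nodes[p[0]],
                                                 soma_nodes[p[1]]))
        i, j = pairs[0]
        comp = comps[comp_of[i]]
        sub = work.subset(comp).reroot(soma_nodes[i])
        sub_stree = build_segment_tree(sub)
        path = soma_path(sub_stree, somata[i], somata[j], max_dist)
        _, _, edge, _, _ = _choose_cut_edge(path, thr)
        work = _cut(work, edge)

    comps = work.components()
    out: list[SegmentTree] = []
    for idx, nid in enumerate(soma_nodes):
        comp = next(c for c in comps if nid in c)
        out.append(build_segment_tree(work.subset(comp).reroot(nid)))

    target_nodes = set(out[target_index].source.nodes)
    report = PruneReport()
    for s in stree.segments.values():
        body = s.node_ids[1:] if len(s.node_ids) > 1 else s.node_ids
        if body and not any(n in target_nodes for n in body):
            report.entries.append(PruneEntry(s.seg_id, "C2", "separation",
                                             s.length, 0, len(body)))
    return out, report


def fake_soma_patch(stree: SegmentTree, thr: Thresholds) -> list[np.ndarray]:
    """Endpoints of abnormally long root-to-tip paths, to be used as
    pseudo-somata in separation (their fragments are then discarded)."""
    depth: dict[int, float] = {stree.soma_seg: stree.segments[stree.soma_seg].length}
    stack = [stree.soma_seg]
    tips = []
    while stack:
        sid = stack.pop()
        s = stree.segments[sid]
        if s.is_leaf and depth[sid] > thr.long_path_len:
            tips.append(stree.coords[s.distal].copy())
        for c in s.child_segs:
            depth[c] = depth[sid] + stree.segments[c].length
            stack.append(c)
    return tips
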