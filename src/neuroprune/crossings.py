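"""Step 3: pruning of crossing artifacts (categories C3 and C4).

Entanglement of the traced neuron with passing fibers of other neurons
(C3) or with its own fibers (C4) produces characteristic local structures
around bifurcations:

* **Y** — one isolated bifurcation.  The two best-aligned incident
  segments are labeled S1 and S2 (S2 being the one at the smaller angle to
  the remaining segment S3).  A genuine bifurcation has the parent in the
  S1 role; a parent in the S3 role means the tracer entered through the
  stub of a crossing and S1/S2 are foreign; a parent in the S2 role makes
  S3 suspicious (a possible missing-segment crossing), resolved by local
  re-tracing against the image or, image-free, by a geometric fallback.
* **T** — a Y whose two S3 angles are both near 90 degrees; handled as Y.
* **X / H** — two bifurcations joined by a short linking segment S5.  In
  an H the link itself is spurious: if the leaf child pair beyond the link
  continues almost straight through (child-child angle beta > t_beta) the
  pair and the link are removed, recursively.  In an X the link is
  genuine: the child/brother pair across the link with the largest mutual
  angle, if above t_beta, is the foreign straight-through fiber and is
  removed.
* **pseudo-X** — a crossing traced as a single segment with no surviving
  bifurcation shows up as a pair of sharp inflection points; the jumped
  foreign portion between them is excised and the distal remainder is
  re-attached at the proximal cut when the enter/exit directions continue
  collinearly.

H structures are prioritized over X; the whole step is prune-only on the
node set and idempotent.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace as dc_replace

import numpy as np

from .features import Thresholds, angle_between, direction_from, segment_angle
from .segments import (PruneEntry, PruneReport, SegmentTree,
                       build_segment_tree, prune_segments)
from .swc import NeuronTree

log = logging.getLogger(__name__)

__all__ = [
    "CrossingStructure",
    "RetraceQuery",
    "find_crossing_structures",
    "assign_Y_roles",
    "prune_Y_T",
    "prune_H",
    "prune_X",
    "resolve_degenerate",
    "prune_single_segment_inflections",
    "run_step3",
]


@dataclass
class CrossingStructure:
    model: str                       # "Y", "T", "X", "H" ("XH" until resolved)
    bifurcations: list[int]          # 1 (Y/T) or 2 (X/H) junction node ids
    parent_seg: int                  # segment whose distal node is the 1st junction
    link_seg: int | None = None      # S5 for X/H
    roles: dict[str, int] = field(default_factory=dict)   # S1..S5 -> seg_id
    angles: dict[tuple[int, int], float] = field(default_factory=dict)
    parent_label: str | None = None  # which of S1/S2/S3 is the tree parent


@dataclass
class RetraceQuery:
    suspicious_seg: int
    junction_node: int
    structure: CrossingStructure


def _outward_dir(stree: SegmentTree, seg_id: int, node_id: int,
                 local_len: float) -> np.ndarray | None:
    s = stree.segments[seg_id]
    pts = stree.seg_coords(seg_id)
    if s.distal == node_id:
        pts = pts[::-1]
    elif s.proximal != node_id:
        raise ValueError(f"node {node_id} not an endpoint of segment {seg_id}")
    try:
        return direction_from(pts, local_len)
    except ValueError:
        return None


def find_crossing_structures(stree: SegmentTree,
                             thr: Thresholds) -> list[CrossingStructure]:
    """Classify every bifurcation as a Y/T candidate or pair it into an
    X/H candidate.

    Two bifurcations whose junctions are joined by a single segment of
    length <= ``near_dist`` form an X/H candidate (nearest link first,
    each bifurcation in at most one pair); the rest become Y/T candidates.
    Multifurcations (> 2 children) are left unclassified.
    """
    bif_segs = stree.bifurcation_segments()
    bif_set = set(bif_segs)
    # candidate links: a bifurcation segment whose parent is also a
    # bifurcation segment, with a short linking segment (the child segment)
    links = []
    for sid in bif_segs:
        p = stree.segments[sid].parent_seg
        if p is not None and p in bif_set and stree.segments[sid].length <= thr.near_dist:
            links.append((stree.segments[sid].length, p, sid))
    links.sort()
    paired: set[int] = set()
    out: list[CrossingStructure] = []
    for _, p, sid in links:
        if p in paired or sid in paired:
            continue
        paired.update((p, sid))
        out.append(CrossingStructure(
            model="XH",
            bifurcations=[stree.segments[p].distal, stree.segments[sid].distal],
            parent_seg=p, link_seg=sid))
    for sid in bif_segs:
        if sid in paired:
            continue
        if len(stree.segments[sid].child_segs) != 2:
            continue  # multifurcation: no 3-segment Y/T model applies
        c = CrossingStructure(model="Y",
                              bifurcations=[stree.segments[sid].distal],
                              parent_seg=sid)
        try:
            assign_Y_roles(stree, c, thr)
        except ValueError:
            continue
        out.append(c)
    return out


def assign_Y_roles(stree: SegmentTree, c: CrossingStructure,
                   thr: Thresholds) -> dict[str, int]:
    """Label the three incident segments of a Y/T: the pair with angle
    closest to 180 degrees is {S1, S2}; of those, the one at the smaller
    angle to the remaining segment S3 is S2.  Exact ties assign S2 to the
    smaller segment id.  Declares the T model when both S3 angles are
    within ``delta_t`` of 90 degrees."""
    jnode = c.bifurcations[0]
    p = c.parent_seg
    kids = stree.segments[p].child_segs
    if len(kids) != 2:
        raise ValueError("Y/T requires exactly 3 incident segments")
    incident = [p, kids[0], kids[1]]
    ang = {}
    for i in range(3):
        for j in range(i + 1, 3):
            a = segment_angle(stree, incident[i], incident[j], jnode, thr.local_len)
            ang[(incident[i], incident[j])] = a
            ang[(incident[j], incident[i])] = a
    # pair closest to 180
    pairs = [(incident[0], incident[1]), (incident[0], incident[2]),
             (incident[1], incident[2])]
    s1s2 = min(pairs, key=lambda pr: (180.0 - ang[pr], min(pr)))
    s3 = next(s for s in incident if s not in s1s2)
    a, b = s1s2
    if ang[(a, s3)] < ang[(b, s3)] - 1e-9:
        s2, s1 = a, b
    elif ang[(b, s3)] < ang[(a, s3)] - 1e-9:
        s2, s1 = b, a
    else:
        s2, s1 = min(a, b), max(a, b)
    c.roles = {"S1": s1, "S2": s2, "S3": s3}
    c.angles = ang
    if (abs(ang[(s1, s3)] - 90.0) <= thr.delta_t
            and abs(ang[(s2, s3)] - 90.0) <= thr.delta_t):
        c.model = "T"
    c.parent_label = next(lbl for lbl, sid in c.roles.items() if sid == p)
    return c.roles


def prune_Y_T(stree: SegmentTree, c: CrossingStructure, thr: Thresholds):
    """Decision for a Y/T structure.

    Returns ``("keep", None)``, ``("remove", [seg_ids])`` (parent in the
    S3 role: both aligned segments are a foreign straight-through pair),
    or ``("suspicious", RetraceQuery)`` (parent in the S2 role: S3 may be
    the stub of a crossing with missing segments)."""
    if c.parent_label == "S1":
        return ("keep", None)
    if c.parent_label == "S3":
        return ("remove", [c.roles["S1"], c.roles["S2"]])
    return ("suspicious", RetraceQuery(c.roles["S3"], c.bifurcations[0], c))


def prune_H(stree: SegmentTree, c: CrossingStructure, thr: Thresholds):
    """H rule: if the link's two children are both leaves and their mutual
    angle beta exceeds ``t_beta`` (an implausibly straight-through child
    pair), remove both leaves and their parent link segment."""
    link = c.link_seg
    kids = stree.segments[link].child_segs
    leaves = [k for k in kids if stree.segments[k].is_leaf]
    if len(kids) != 2 or len(leaves) != 2:
        return ("not_h", None)
    beta = segment_angle(stree, kids[0], kids[1], stree.segments[link].distal,
                         thr.local_len)
    if beta > thr.t_beta:
        return ("remove", [kids[0], kids[1], link])
    return ("keep", None)


def prune_X(stree: SegmentTree, c: CrossingStructure, thr: Thresholds):
    """X rule: across the link S5, compute the angles between every child
    of S5 and every brother of S5 (the other children at the near
    bifurcation); the maximum pair, if above ``t_beta``, is a foreign
    fiber traced straight through the crossing and is removed (ties break
    toward the pair with the smaller segment id)."""
    link = c.link_seg
    p = c.parent_seg
    near_j = stree.segments[p].distal
    far_j = stree.segments[link].distal
    brothers = [k for k in stree.segments[p].child_segs if k != link]
    children = stree.segments[link].child_segs
    best = None
    for ch in children:
        dch = _outward_dir(stree, ch, far_j, thr.local_len)
        if dch is None:
            continue
        for br in brothers:
            dbr = _outward_dir(stree, br, near_j, thr.local_len)
            if dbr is None:
                continue
            a = angle_between(dch, dbr)
            key = (-a, min(ch, br), max(ch, br))
            if best is None or key < best[0]:
                best = (key, a, ch, br)
    if best is not None and best[1] > thr.t_beta:
        return ("remove", [best[2], best[3]])
    return ("keep", None)


# ---------------------------------------------------------------------------
# degenerate-Y resolution (local re-tracing)

def _to_voxel(p_um: np.ndarray, voxel_size) -> np.ndarray:
    return p_um / np.asarray(voxel_size, dtype=float)


def _tube_voxels(shape, pts_vox, radius_vox):
    """Voxel indices (z, y, x) within ``radius_vox`` of any point (points
    given as x, y, z voxel coordinates)."""
    mask = np.zeros(shape, dtype=bool)
    r = int(np.ceil(radius_vox))
    for p in pts_vox:
        x, y, z = (int(round(v)) for v in p)
        zlo, zhi = max(z - r, 0), min(z + r + 1, shape[0])
        ylo, yhi = max(y - r, 0), min(y + r + 1, shape[1])
        xlo, xhi = max(x - r, 0), min(x + r + 1, shape[2])
        if zlo >= zhi or ylo >= yhi or xlo >= xhi:
            continue
        zz, yy, xx = np.mgrid[zlo:zhi, ylo:yhi, xlo:xhi]
        d2 = (zz - z) ** 2 + (yy - y) ** 2 + (xx - x) ** 2
        mask[zlo:zhi, ylo:yhi, xlo:xhi] |= d2 <= radius_vox ** 2
    return mask


def _densify(pts: np.ndarray, step: float = 0.5) -> np.ndarray:
    out = [pts[0]]
    for a, b in zip(pts, pts[1:]):
        d = float(np.linalg.norm(b - a))
        n = max(1, int(np.ceil(d / step)))
        for t in range(1, n + 1):
            out.append(a + (b - a) * (t / n))
    return np.array(out)


def resolve_degenerate(stree: SegmentTree, query: RetraceQuery,
                       image: np.ndarray | None, thr: Thresholds):
    """Keep-or-prune decision for a suspicious segment.

    With an image volume (z, y, x): the node at arclength ``len_r`` from
    the bifurcation seeds a geodesic front over an intensity-derived speed
    map; the rest of the suspicious segment's tube is masked out.  The
    segment is kept iff the front reaches the tubes of both other incident
    segments within a geodesic budget (a genuinely connected branch is
    cheap to reach; a disjoint passing fiber is blocked by the dark gap).
    Without an image: geometric fallback — keep iff the suspicious
    segment's angle to its parent is in [``t_beta_low``, 180] (a plausible
    continuation), else prune.
    """
    c = query.structure
    sus = query.suspicious_seg
    jnode = query.junction_node
    if image is None:
        # geometric fallback: prune only the unambiguous crossing signature
        # -- the through-pair continues almost straight while the suspicious
        # segment doubles back against the path it came from
        parent = c.parent_seg
        a_sus = segment_angle(stree, sus, parent, jnode, thr.local_len)
        a_through = c.angles[(c.roles["S1"], c.roles["S2"])]
        if a_sus < thr.t_beta_low and a_through > thr.t_beta:
            return "prune"
        return "keep"

    from skimage.graph import MCP_Geometric

    vs = np.asarray(stree.source.voxel_size, dtype=float)
    sus_pts = stree.seg_coords(sus)
    if stree.segments[sus].distal == jnode:
        sus_pts = sus_pts[::-1]
    sus_pts = _densify(sus_pts)
    # seed at arclength len_r from the junction
    arcs = np.concatenate([[0.0], np.cumsum(np.linalg.norm(np.diff(sus_pts, axis=0), axis=1))])
    seed_idx = int(np.searchsorted(arcs, thr.len_r))
    seed_idx = min(seed_idx, len(sus_pts) - 1)
    seed_um = sus_pts[seed_idx]

    others = [s for s in (c.roles.get("S1"), c.roles.get("S2"), c.roles.get("S3"))
              if s is not None and s != sus]
    target_pts_um = []
    for sid in others:
        pts = stree.seg_coords(sid)
        if stree.segments[sid].distal == jnode:
            pts = pts[::-1]
        target_pts_um.append(_densify(pts))

    all_pts = np.vstack([sus_pts] + target_pts_um)
    all_vox = all_pts / vs
    shape = image.shape  # (z, y, x)
    xyz_max = np.array([shape[2], shape[1], shape[0]], dtype=float)
    if (all_vox < -0.5).any() or (all_vox >= xyz_max - 0.5).any():
        raise ValueError("reconstruction nodes fall outside the image volume")

    radius = max(2.0, float(np.median([stree.source.nodes[n].radius
                                       for n in stree.segments[sus].node_ids])))
    img = image.astype(float)
    lo = float(np.percentile(img, 60))
    hi = float(np.percentile(img, 99.5))
    if hi <= lo:
        hi = lo + 1.0
    speed = np.clip((img - lo) / (hi - lo), 0.01, 1.0)
    # mask the suspicious segment's own tube beyond the seed, leaving a
    # clearance so the tube does not swallow the seed voxel itself
    mask_from = int(np.searchsorted(arcs, thr.len_r + 3.0))
    masked = _tube_voxels(shape, sus_pts[mask_from:] / vs, radius)
    speed[masked] = 0.01
    cost = 1.0 / speed

    mcp = MCP_Geometric(cost, sampling=(vs[2], vs[1], vs[0]))
    sx, sy, sz = (int(round(v)) for v in seed_um / vs)
    cum, _ = mcp.find_costs([(sz, sy, sx)])

    for tpts in target_pts_um:
        tube = _tube_voxels(shape, tpts / vs, radius)
        tube &= ~masked
        if not tube.any():
            return "prune"
        reach = float(np.nanmin(np.where(tube, cum, np.inf)))
        budget = 4.0 * max(float(np.linalg.norm(seed_um - tpts[-1])), 10.0)
        if not np.isfinite(reach) or reach > budget:
            return "prune"
    return "keep"


# ---------------------------------------------------------------------------
# single-segment pseudo-X (inflection pairs)

def _tangent_turns(pts: np.ndarray, window_um: float):
    """Turn angle of the local tangent at each node (degrees), measured
    between the backward and forward chords of ``window_um`` arclength."""
    arcs = np.concatenate([[0.0], np.cumsum(np.linalg.norm(np.diff(pts, axis=0), axis=1))])
    turns = np.zeros(len(pts))
    for i in range(1, len(pts) - 1):
        jb = int(np.searchsorted(arcs, arcs[i] - window_um))
        jf = int(np.searchsorted(arcs, arcs[i] + window_um))
        jf = min(jf, len(pts) - 1)
        if jb >= i or jf <= i:
            continue
        vb = pts[i] - pts[jb]
        vf = pts[jf] - pts[i]
        nb, nf = np.linalg.norm(vb), np.linalg.norm(vf)
        if nb == 0 or nf == 0:
            continue
        turns[i] = angle_between(vb / nb, vf / nf)
    return turns, arcs


def prune_single_segment_inflections(stree: SegmentTree, thr: Thresholds,
                                     max_pair_sep: float = 30.0):
    """Excise pseudo-X traversals hidden inside single segments.

    Nodes where the tangent turns by more than ``inflect_angle`` within
    ``inflect_window`` of arclength are inflection candidates.  A nearby
    pair whose enter/exit directions continue nearly collinearly marks a
    jump across a crossing: the intervening foreign portion is removed and
    the distal remainder re-parented to the proximal cut node.  Segments
    without a qualifying inflection pair are unchanged.
    """
    report = PruneReport()
    changed = True
    while changed:
        changed = False
        for sid in sorted(stree.segments):
            s = stree.segments[sid]
            if len(s.node_ids) < 5:
                continue
            pts = stree.seg_coords(sid)
            turns, arcs = _tangent_turns(pts, thr.inflect_window)
            cand = [i for i in range(1, len(pts) - 1)
                    if turns[i] > thr.inflect_angle]
            # suppress runs of adjacent candidates to their sharpest node
            groups: list[int] = []
            for i in cand:
                if groups and arcs[i] - arcs[groups[-1]] < thr.inflect_window:
                    if turns[i] > turns[groups[-1]]:
                        groups[-1] = i
                else:
                    groups.append(i)
            if len(groups) < 2:
                continue
            hit = None
            for a_i in range(len(groups) - 1):
                i1, i2 = groups[a_i], groups[a_i + 1]
                if arcs[i2] - arcs[i1] > max_pair_sep:
                    continue
                jb = max(0, int(np.searchsorted(arcs, arcs[i1] - thr.inflect_window)))
                jf = min(len(pts) - 1, int(np.searchsorted(arcs, arcs[i2] + thr.inflect_window)))
                enter = pts[i1] - pts[jb]
                exit_ = pts[jf] - pts[i2]
                ne, nx = np.linalg.norm(enter), np.linalg.norm(exit_)
                if ne == 0 or nx == 0:
                    continue
                if angle_between(enter / ne, exit_ / nx) < 45.0:
                    hit = (i1, i2)
                    break
            if hit is None:
                continue
            i1, i2 = hit
            node_ids = s.node_ids
            drop = set(node_ids[i1 + 1:i2])
            if not drop:
                continue
            keep = set(stree.source.nodes) - drop
            new_src = stree.source.subset(keep)
            # re-parent the exit node to the entry node (splice)
            nodes = dict(new_src.nodes)
            nodes[node_ids[i2]] = dc_replace(nodes[node_ids[i2]],
                                             parent_id=node_ids[i1])
            removed_len = float(arcs[i2] - arcs[i1])
            report.entries.append(PruneEntry(sid, "C3", "pseudoX",
                                             removed_len, 0, len(drop)))
            stree = build_segment_tree(
                NeuronTree(nodes, stree.source.unit, stree.source.voxel_size))
            changed = True
            break
    return stree, report


# ---------------------------------------------------------------------------

def run_step3(stree: SegmentTree, image: np.ndarray | None,
              thr: Thresholds):
    """Full step 3: H structures first (recursively), then X, then Y/T
    with degenerate-case resolution, then single-segment pseudo-X.

    The phase sequence repeats until a global fixed point, since a removal
    in a later phase (and the segment merges it triggers) can expose a new
    qualifying H or X; this makes the whole step idempotent.
    """
    report = PruneReport()

    while True:
        changed_any = False

        # H recursively, then X (H re-checked whenever the tree changes)
        changed = True
        while changed:
            changed = False
            structs = [c for c in find_crossing_structures(stree, thr)
                       if c.model == "XH"]
            for c in structs:
                decision, segs = prune_H(stree, c, thr)
                if decision == "remove":
                    stree, rep = prune_segments(stree, segs, "C4", "H")
                    report.extend(rep)
                    changed = changed_any = True
                    break
            if changed:
                continue
            for c in structs:
                decision, segs = prune_X(stree, c, thr)
                if decision == "remove":
                    stree, rep = prune_segments(stree, segs, "C3", "X")
                    report.extend(rep)
                    changed = changed_any = True
                    break

        # Y/T with degenerate resolution
        changed = True
        while changed:
            changed = False
            for c in find_crossing_structures(stree, thr):
                if c.model not in ("Y", "T"):
                    continue
                decision, payload = prune_Y_T(stree, c, thr)
                if decision == "remove":
                    stree, rep = prune_segments(stree, payload, "C3", c.model)
                    report.extend(rep)
                    changed = changed_any = True
                    break
                if decision == "suspicious":
                    verdict = resolve_degenerate(stree, payload, image, thr)
                    if verdict == "prune":
                        stree, rep = prune_segments(
                            stree, [payload.suspicious_seg], "C4", c.model)
                        report.extend(rep)
                        changed = changed_any = True
                        break

        # single-segment pseudo-X
        stree, rep = prune_single_segment_inflections(stree, thr)
        if rep.entries:
            report.extend(rep)
            changed_any = True

        if not changed_any:
            return stree, report
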