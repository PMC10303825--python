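"""Ground-truth-labeled synthetic inputs for every pipeline step.

The generator emulates the dendritic arbor of a single neuron inside a
fixed imaging block (default 512 x 512 x 256 voxels at 0.6 x 0.6 x 1.0
micrometers): a soma-rooted binary tree of polyline segments grown by a
correlated random walk with Gaussian branching angles.  Valid segments are
drawn well above the length and linearity thresholds (the "valid regime"),
so every threshold violation in a corrupted tree is an injected error.

Four error categories can be injected, each with exact per-node truth
labels:

* **C1** — short, highly tortuous leaf chains (background noise).
* **C2** — a second arbor grafted through a smooth bridge at a recorded
  merge node (entangled neighboring dendrite).
* **C3** — a straight foreign fiber threaded through a segment, attached
  at two close-by new bifurcations (a passing axon traced as an X).
* **C4** — a spurious short link to an almost-straight leaf pair
  (self-entanglement traced as an H).

Volumes for the re-tracing check are rendered by rasterizing tubes at the
node radii, blurring with a Gaussian PSF and adding Poisson-Gaussian
noise.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
from numpy.random import default_rng

from .segments import SegmentTree, build_segment_tree
from .swc import NeuronTree, NodeRecord

log = logging.getLogger(__name__)

__all__ = [
    "ArborSpec",
    "ErrorSpec",
    "InjectionTruth",
    "generate_arbor",
    "inject_errors",
    "render_volume",
]

_STEP = 1.5          # node spacing along valid fibers (um)
_MIN_SEG_LEN = 15.0  # valid segments stay well above t_len = 6.6 um


@dataclass(frozen=True)
class ArborSpec:
    """Parameters of one synthetic dendritic arbor."""

    seed: int = 0
    n_tips: int = 10
    branch_angle_mean: float = 40.0   # per-child deviation from parent dir (deg)
    branch_angle_sd: float = 8.0
    segment_len_mean: float = 40.0    # um
    segment_len_sd: float = 10.0
    tortuosity: float = 0.06          # per-step direction jitter (rad scale)
    bbox: tuple[int, int, int] = (512, 512, 256)        # voxels, x/y/z
    voxel_size: tuple[float, float, float] = (0.6, 0.6, 1.0)
    soma: tuple[float, float, float] | None = None      # um; default center

    def bbox_um(self) -> np.ndarray:
        return np.asarray(self.bbox, dtype=float) * np.asarray(self.voxel_size)


@dataclass(frozen=True)
class ErrorSpec:
    """How many errors of each category to inject."""

    c1_count: int = 0
    c1_len_range: tuple[float, float] = (1.5, 5.0)      # < t_len
    c2_partner: ArborSpec | None = None
    c2_offset: tuple[float, float, float] = (130.0, 40.0, 0.0)  # partner soma shift
    c3_count: int = 0
    c3_fiber_len: float = 35.0
    c4_count: int = 0
    seed: int = 0


@dataclass
class InjectionTruth:
    """Per-node labels and recorded ground truth of an injection."""

    labels: dict[int, str] = field(default_factory=dict)   # node -> valid/C1..C4
    merge_nodes: list[tuple[int, int]] = field(default_factory=list)  # (u, v) per C2
    foreign_nodes: dict[str, set[int]] = field(default_factory=dict)  # per category

    def nodes_of(self, category: str) -> set[int]:
        return {n for n, lbl in self.labels.items() if lbl == category}


def _unit(v: np.ndarray) -> np.ndarray:
    n = float(np.linalg.norm(v))
    return v / n if n > 0 else np.array([1.0, 0.0, 0.0])


def _perp(d: np.ndarray, rng) -> np.ndarray:
    while True:
        r = rng.normal(size=3)
        p = r - np.dot(r, d) * d
        if np.linalg.norm(p) > 1e-6:
            return _unit(p)


def _rotate_towards(d: np.ndarray, u: np.ndarray, angle_deg: float) -> np.ndarray:
    a = np.radians(angle_deg)
    return _unit(np.cos(a) * d + np.sin(a) * u)


def generate_arbor(spec: ArborSpec) -> tuple[NeuronTree, SegmentTree, InjectionTruth]:
    """Grow a seed-deterministic binary arbor inside the bounding box.

    Exactly ``n_tips`` tip nodes and ``2 * n_tips - 1`` segments are
    produced.  Fiber directions follow a correlated random walk (jitter set
    by ``tortuosity``) and reflect off the box walls.
    """
    if spec.n_tips < 1:
        raise ValueError("n_tips must be >= 1")
    bbox = spec.bbox_um()
    est_extent = (np.log2(spec.n_tips) + 2) * (spec.segment_len_mean + 2 * spec.segment_len_sd)
    if spec.n_tips > 512 or est_extent > 8 * float(bbox.min()):
        raise ValueError("infeasible spec: too many tips for the bounding box")
    rng = default_rng(spec.seed)
    soma = np.asarray(spec.soma, float) if spec.soma is not None else bbox / 2.0

    nodes: dict[int, NodeRecord] = {
        1: NodeRecord(1, 1, *soma, 5.0, -1)
    }
    next_id = [2]
    margin = 4.0

    def grow_segment(attach: int, direction: np.ndarray) -> tuple[int, np.ndarray]:
        length = max(rng.normal(spec.segment_len_mean, spec.segment_len_sd),
                     _MIN_SEG_LEN)
        n_steps = max(3, int(round(length / _STEP)))
        pos = nodes[attach].xyz.copy()
        d = direction.copy()
        prev = attach
        soft = 20.0  # steer smoothly back inside within this distance of a wall
        for _ in range(n_steps):
            d = _unit(d + spec.tortuosity * rng.normal(size=3))
            pull = np.zeros(3)
            for ax in range(3):
                if pos[ax] < soft:
                    pull[ax] = (soft - pos[ax]) / soft
                elif pos[ax] > bbox[ax] - soft:
                    pull[ax] = -(pos[ax] - (bbox[ax] - soft)) / soft
            if pull.any():
                d = _unit(d + 0.35 * pull)
            pos = np.clip(pos + d * _STEP, margin, bbox - margin)
            nid = next_id[0]
            next_id[0] += 1
            nodes[nid] = NodeRecord(nid, 3, *pos, 1.0, prev)
            prev = nid
        return prev, d

    active: list[tuple[int, np.ndarray]] = []
    tip_end, tip_dir = grow_segment(1, _unit(rng.normal(size=3)))
    active.append((tip_end, tip_dir))
    bif_budget = spec.n_tips - 1
    tips: list[tuple[int, np.ndarray]] = []
    while active:
        idx = int(rng.integers(len(active)))
        end, d = active.pop(idx)
        if bif_budget > 0:
            bif_budget -= 1
            u = _perp(d, rng)
            for sgn in (+1.0, -1.0):
                ang = sgn * max(rng.normal(spec.branch_angle_mean,
                                           spec.branch_angle_sd), 5.0)
                cd = _rotate_towards(d, u, ang)
                active.append(grow_segment(end, cd))
        else:
            tips.append((end, d))

    tree = NeuronTree(nodes, unit="um", voxel_size=spec.voxel_size)
    stree = build_segment_tree(tree)
    truth = InjectionTruth(labels={nid: "valid" for nid in nodes})
    return tree, stree, truth


def _interior_nodes(tree: NeuronTree) -> list[int]:
    """Non-root nodes with exactly one child (safe attachment points)."""
    ch = tree.children_map()
    return [nid for nid in sorted(tree.nodes)
            if tree.nodes[nid].parent_id != -1 and len(ch[nid]) == 1]


def _append_chain(nodes: dict[int, NodeRecord], next_id, attach: int,
                  pts: list[np.ndarray], radius: float = 1.0) -> list[int]:
    out = []
    prev = attach
    for p in pts:
        nid = next_id[0]
        next_id[0] += 1
        nodes[nid] = NodeRecord(nid, 3, *p, radius, prev)
        out.append(nid)
        prev = nid
    return out


def inject_errors(tree: NeuronTree, err: ErrorSpec
                  ) -> tuple[NeuronTree, SegmentTree, InjectionTruth]:
    """Corrupt a valid arbor with labeled C1-C4 errors.

    Returns the corrupted tree, its segment tree, and the truth record
    (per-node labels, the C2 merge node pair, per-category foreign node
    sets).  When a requested injection cannot be placed, fewer are
    injected with a warning (labels stay exact).
    """
    rng = default_rng(err.seed)
    nodes = dict(tree.nodes)
    next_id = [max(nodes) + 1]
    truth = InjectionTruth(labels={nid: "valid" for nid in nodes})
    work = NeuronTree(nodes, tree.unit, tree.voxel_size)
    used: set[int] = set()

    def clear_of_branches(nid: int, clearance: float = 12.0) -> bool:
        """No branch point within ``clearance`` um up or down the fiber
        (keeps injected crossings from overlapping real bifurcations)."""
        ch = work.children_map()
        acc, cur = 0.0, nid
        while acc < clearance:
            kids = ch[cur]
            if len(kids) != 1:
                return False  # branch point or tip too close
            nxt = kids[0]
            acc += float(np.linalg.norm(work.xyz_um(nxt) - work.xyz_um(cur)))
            cur = nxt
        acc, cur = 0.0, nid
        while acc < clearance:
            pid = work.nodes[cur].parent_id
            if pid not in work.nodes:
                break
            if len(ch[pid]) != 1:
                return False
            acc += float(np.linalg.norm(work.xyz_um(pid) - work.xyz_um(cur)))
            cur = pid
        return True

    def pick_interior(clearance: float = 0.0) -> int | None:
        cands = [n for n in _interior_nodes(work)
                 if n not in used and truth.labels.get(n) == "valid"
                 and (clearance == 0.0 or clear_of_branches(n, clearance))]
        if not cands:
            return None
        return int(rng.choice(cands))

    # ---- C2: graft a partner arbor through a bridge -----------------------
    if err.c2_partner is not None:
        p_soma = (np.asarray(err.c2_offset, float)
                  + work.xyz_um(min(n for n in nodes if nodes[n].parent_id == -1)))
        p_spec = replace(err.c2_partner, soma=tuple(p_soma))
        p_tree, _, _ = generate_arbor(p_spec)
        offset = next_id[0] - 1
        from dataclasses import replace as dr
        for nid, n in p_tree.nodes.items():
            nodes[nid + offset] = dr(n, id=nid + offset,
                                     parent_id=(n.parent_id + offset
                                                if n.parent_id != -1 else -1))
        next_id[0] = max(nodes) + 1
        work = NeuronTree(nodes, tree.unit, tree.voxel_size)
        partner_ids = {nid + offset for nid in p_tree.nodes}
        # bridge endpoints: interior node of the host closest to the partner,
        # then the partner interior node closest to it
        host_int = _interior_nodes(tree)
        p_int = [n for n in _interior_nodes(work) if n in partner_ids]
        p_pts = np.array([work.xyz_um(n) for n in p_int])
        best = min(host_int,
                   key=lambda n: float(np.min(np.linalg.norm(p_pts - work.xyz_um(n), axis=1))))
        u = best
        v = p_int[int(np.argmin(np.linalg.norm(p_pts - work.xyz_um(u), axis=1)))]
        # re-root the partner at v, then hang it from the bridge
        sub = work.subset(partner_ids).reroot(v)
        for nid, n in sub.nodes.items():
            nodes[nid] = n
        a, b = work.xyz_um(u), work.xyz_um(v)
        n_steps = max(2, int(np.ceil(np.linalg.norm(b - a) / _STEP)))
        bridge_pts = [a + (b - a) * (t / n_steps) for t in range(1, n_steps)]
        bridge_ids = _append_chain(nodes, next_id, u, bridge_pts)
        from dataclasses import replace as dr2
        nodes[v] = dr2(nodes[v], parent_id=bridge_ids[-1] if bridge_ids else u)
        work = NeuronTree(nodes, tree.unit, tree.voxel_size)
        for nid in partner_ids | set(bridge_ids):
            truth.labels[nid] = "C2"
        truth.merge_nodes.append((u, v))
        truth.foreign_nodes.setdefault("C2", set()).update(partner_ids | set(bridge_ids))
        used.add(u)

    # ---- C1: short tortuous noise leaves ----------------------------------
    placed = 0
    for _ in range(err.c1_count):
        # keep a margin from tips/branches so splitting a valid segment
        # never leaves a fragment below the length threshold
        att = pick_interior(clearance=8.0)
        if att is None:
            break
        used.add(att)
        length = rng.uniform(*err.c1_len_range)
        n_steps = max(3, int(round(length / 0.6)))
        pos = work.xyz_um(att).copy()
        pts = []
        for _ in range(n_steps):
            d = _unit(rng.normal(size=3))   # fresh random direction: tortuous
            pos = pos + d * (length / n_steps)
            pts.append(pos.copy())
        ids = _append_chain(nodes, next_id, att, pts, radius=0.5)
        for nid in ids:
            truth.labels[nid] = "C1"
        truth.foreign_nodes.setdefault("C1", set()).update(ids)
        work = NeuronTree(nodes, tree.unit, tree.voxel_size)
        placed += 1
    if placed < err.c1_count:
        log.warning("placed %d of %d requested C1 leaves", placed, err.c1_count)

    # ---- C3: straight passing fiber through two new bifurcations ----------
    ch = work.children_map()

    def node_arc_successor(nid: int, min_arc: float) -> int | None:
        """Follow single-child links until ``min_arc`` um away."""
        acc = 0.0
        cur = nid
        while len(ch[cur]) == 1:
            nxt = ch[cur][0]
            acc += float(np.linalg.norm(work.xyz_um(nxt) - work.xyz_um(cur)))
            cur = nxt
            if acc >= min_arc:
                return cur
        return None

    placed = 0
    for _ in range(err.c3_count):
        ch = work.children_map()
        cands = [n for n in _interior_nodes(work) if n not in used
                 and truth.labels.get(n) == "valid"
                 and clear_of_branches(n, 15.0)]
        rng.shuffle(cands)
        pair = None
        for n1 in cands:
            n2 = node_arc_successor(n1, 3.0)
            if n2 is not None and n2 not in used and len(ch[n2]) == 1 \
                    and truth.labels.get(n2) == "valid":
                pair = (n1, n2)
                break
        if pair is None:
            break
        n1, n2 = pair
        used.update(pair)
        tangent = _unit(work.xyz_um(n2) - work.xyz_um(n1))
        w = _perp(tangent, rng)
        new_ids = []
        for att, sgn in ((n1, -1.0), (n2, +1.0)):
            pos = work.xyz_um(att).copy()
            pts = []
            d = sgn * w
            n_steps = int(round(err.c3_fiber_len / _STEP))
            for _ in range(n_steps):
                d = _unit(d + 0.02 * rng.normal(size=3))
                pos = pos + d * _STEP
                pts.append(pos.copy())
            new_ids += _append_chain(nodes, next_id, att, pts)
        for nid in new_ids:
            truth.labels[nid] = "C3"
        truth.foreign_nodes.setdefault("C3", set()).update(new_ids)
        work = NeuronTree(nodes, tree.unit, tree.voxel_size)
        placed += 1
    if placed < err.c3_count:
        log.warning("placed %d of %d requested C3 fibers", placed, err.c3_count)

    # ---- C4: spurious link to a straight-through leaf pair (H) ------------
    placed = 0
    for _ in range(err.c4_count):
        att = pick_interior(clearance=12.0)
        if att is None:
            break
        used.add(att)
        ch = work.children_map()
        kid = ch[att][0]
        tangent = _unit(work.xyz_um(kid) - work.xyz_um(att))
        u = _perp(tangent, rng)
        v = _unit(np.cross(tangent, u))
        link_pts = [work.xyz_um(att) + u * (t * 1.0) for t in range(1, 4)]  # ~3 um
        link_ids = _append_chain(nodes, next_id, att, link_pts)
        j = link_ids[-1]
        new_ids = list(link_ids)
        jpos = nodes[j].xyz
        for sgn in (+1.0, -1.0):
            d = _unit(sgn * v + 0.09 * u)   # leaf pair at ~170 degrees
            pts = [jpos + d * (t * _STEP) for t in range(1, 9)]
            new_ids += _append_chain(nodes, next_id, j, pts)
        for nid in new_ids:
            truth.labels[nid] = "C4"
        truth.foreign_nodes.setdefault("C4", set()).update(new_ids)
        work = NeuronTree(nodes, tree.unit, tree.voxel_size)
        placed += 1
    if placed < err.c4_count:
        log.warning("placed %d of %d requested C4 loops", placed, err.c4_count)

    stree = build_segment_tree(work)
    return work, stree, truth


def merge_arbors(specs: list[ArborSpec], seed: int = 0
                 ) -> tuple[NeuronTree, dict[int, int], list[np.ndarray]]:
    """Entangle several arbors into one connected reconstruction.

    Arbor ``k`` is grafted onto the growing tree through a straight bridge
    between the closest interior-node pair, emulating a tracer merging
    close-by neurons.  Returns the merged tree, an owner map (node ->
    arbor index; bridge nodes get -1, they may legitimately land on either
    side of a separation), and the soma locations in arbor order.
    """
    if not specs:
        raise ValueError("need at least one arbor spec")
    rng = default_rng(seed)
    base, _, _ = generate_arbor(specs[0])
    nodes = dict(base.nodes)
    owner = {nid: 0 for nid in nodes}
    somas = [base.xyz_um(1)]
    next_id = [max(nodes) + 1]
    from dataclasses import replace as dr
    for k, sp in enumerate(specs[1:], start=1):
        p_tree, _, _ = generate_arbor(sp)
        offset = next_id[0] - 1
        pid_map = {}
        for nid, n in p_tree.nodes.items():
            pid_map[nid] = nid + offset
            nodes[nid + offset] = dr(n, id=nid + offset,
                                     parent_id=(n.parent_id + offset
                                                if n.parent_id != -1 else -1))
        next_id[0] = max(nodes) + 1
        somas.append(p_tree.xyz_um(1))
        work = NeuronTree(nodes, base.unit, base.voxel_size)
        partner_ids = set(pid_map.values())
        host_int = [n for n in _interior_nodes(work) if n not in partner_ids]
        p_int = [n for n in _interior_nodes(work) if n in partner_ids]
        p_pts = np.array([work.xyz_um(n) for n in p_int])
        u = min(host_int, key=lambda n: float(
            np.min(np.linalg.norm(p_pts - work.xyz_um(n), axis=1))))
        v = p_int[int(np.argmin(np.linalg.norm(p_pts - work.xyz_um(u), axis=1)))]
        sub = work.subset(partner_ids).reroot(v)
        for nid, n in sub.nodes.items():
            nodes[nid] = n
        a, b = work.xyz_um(u), work.xyz_um(v)
        n_steps = max(2, int(np.ceil(np.linalg.norm(b - a) / _STEP)))
        bridge_pts = [a + (b - a) * (t / n_steps) for t in range(1, n_steps)]
        bridge_ids = _append_chain(nodes, next_id, u, bridge_pts)
        nodes[v] = dr(nodes[v], parent_id=bridge_ids[-1] if bridge_ids else u)
        for nid in partner_ids:
            owner[nid] = k
        for nid in bridge_ids:
            owner[nid] = -1
    return NeuronTree(nodes, base.unit, base.voxel_size), owner, somas


def render_volume(tree: NeuronTree, snr: float = 5.0, psf_sigma: float = 1.0,
                  seed: int = 0, shape: tuple[int, int, int] | None = None,
                  bg_level: float = 20.0) -> np.ndarray:
    """Rasterize a tree into a 3D intensity volume (z, y, x), uint16.

    Tubes are drawn at the node radii, blurred by a Gaussian PSF of
    ``psf_sigma`` voxels, and degraded with Poisson-Gaussian noise; the
    mean foreground/background ratio equals ``snr``.  ``snr=inf`` with
    ``psf_sigma=0`` yields the clean binary tube mask.  Seed-deterministic.
    """
    from scipy.ndimage import gaussian_filter

    vs = np.asarray(tree.voxel_size, dtype=float)
    pts = []
    radii = []
    ch = tree.children_map()
    for nid, n in tree.nodes.items():
        a = tree.xyz_um(nid) / vs
        for c in ch[nid]:
            b = tree.xyz_um(c) / vs
            d = float(np.linalg.norm(b - a))
            steps = max(1, int(np.ceil(d / 0.5)))
            for t in range(steps + 1):
                pts.append(a + (b - a) * (t / steps))
                radii.append(max(n.radius / float(vs[:2].mean()), 1.0))
        if not ch[nid]:
            pts.append(a)
            radii.append(max(n.radius / float(vs[:2].mean()), 1.0))
    pts = np.array(pts)
    if shape is None:
        hi = pts.max(axis=0) + 6
        shape = (int(hi[2]) + 1, int(hi[1]) + 1, int(hi[0]) + 1)
    mask = np.zeros(shape, dtype=bool)
    for p, r in zip(pts, radii):
        x, y, z = (int(round(v)) for v in p)
        ri = int(np.ceil(r))
        zlo, zhi = max(z - ri, 0), min(z + ri + 1, shape[0])
        ylo, yhi = max(y - ri, 0), min(y + ri + 1, shape[1])
        xlo, xhi = max(x - ri, 0), min(x + ri + 1, shape[2])
        if zlo >= zhi or ylo >= yhi or xlo >= xhi:
            continue
        zz, yy, xx = np.mgrid[zlo:zhi, ylo:yhi, xlo:xhi]
        mask[zlo:zhi, ylo:yhi, xlo:xhi] |= \
            (zz - z) ** 2 + (yy - y) ** 2 + (xx - x) ** 2 <= r ** 2

    if np.isinf(snr) and psf_sigma == 0:
        return (mask.astype(np.uint16)) * 65535

    fg = bg_level * snr
    img = bg_level + (fg - bg_level) * mask.astype(float)
    if psf_sigma > 0:
        img = gaussian_filter(img, psf_sigma)
    rng = default_rng(seed)
    noisy = rng.poisson(img).astype(float) + rng.normal(0.0, 2.0, size=img.shape)
    return np.clip(noisy, 0, 65535).astype(np.uint16)
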