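"""Segment geometry features and population threshold calibration.

The pruning rules are driven by three calibrated thresholds:

* ``t_len`` — 1st percentile of leaf-segment lengths in gold-standard
  trees (default 6.6 micrometers): valid leaf segments are rarely shorter.
* ``t_lin`` — 1st percentile of segment *linearity*, the per-segment mean
  of the local PCA eigenvalue ratio lambda1/lambda2 (default 1.4): valid
  fibers are locally line-like, background noise is not.
* ``t_beta`` — 99th percentile of child-child branch angles at
  bifurcations: a child pair that continues almost straight through a
  junction (angle near 180 degrees) is the signature of a crossing, not a
  genuine bifurcation.

Linearity uses local PCA of the polyline coordinates (a window of nodes on
each side), so it needs no image volume.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict, replace

import numpy as np

from .segments import Segment, SegmentTree

__all__ = [
    "Thresholds",
    "SegmentFeatures",
    "segment_length",
    "node_anisotropy",
    "segment_linearity",
    "segment_angle",
    "direction_from",
    "calibrate_thresholds",
    "child_child_angles",
]

_EPS_FRAC = 1e-6   # floor on lambda2, lambda3 as a fraction of lambda1


@dataclass(frozen=True)
class Thresholds:
    """Tunable parameters of the pruning pipeline (lengths in micrometers,
    angles in degrees)."""

    t_len: float = 6.6            # leaf-length cut (1st pct of valid leaves)
    t_lin: float = 1.4            # linearity cut (1st pct of valid segments)
    t_beta: float = 140.0         # child-child angle outlier cut (99th pct)
    len_r: float = 5.0            # re-trace seed offset from the bifurcation
    long_path_len: float = 400.0  # fake-soma trigger on root-to-tip paths
    near_dist: float = 10.0       # max link length pairing two bifurcations
    delta_t: float = 15.0         # T-model tolerance around 90 degrees
    local_len: float = 5.0        # chord length for direction estimates
    window: int = 5               # PCA window (nodes each side)
    cap_ratio: float = 100.0      # cap on lambda1/lambda2 per node
    alpha: float = 0.7            # separation weight: angle vs distance mix
    lambda_d: float = 100.0       # separation weight distance decay (um)
    typical_branch_angle: float = 45.0  # forward child angle considered typical
    t_beta_low: float = 60.0      # image-free fallback: keep suspicious segment
                                  # iff its angle to the parent is >= this
    inflect_angle: float = 100.0  # tangent turn marking an inflection point
    inflect_window: float = 5.0   # arclength over which the turn is measured
    dist_thr: float = 3.0         # evaluation: node-to-polyline match radius
    cover_frac: float = 0.8       # evaluation: fraction of nodes within radius

    def validate(self) -> None:
        for name in ("t_len", "t_lin", "len_r", "long_path_len", "near_dist",
                     "local_len", "lambda_d", "dist_thr"):
            if getattr(self, name) <= 0:
                raise ValueError(f"threshold {name} must be strictly positive")
        if not 0 < self.t_beta <= 180:
            raise ValueError("t_beta must be in (0, 180]")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "Thresholds":
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown threshold keys: {sorted(unknown)}")
        thr = cls(**d)
        thr.validate()
        return thr

    def save(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)

    @classmethod
    def load(cls, path) -> "Thresholds":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


@dataclass
class SegmentFeatures:
    length: float
    linearity: float
    tangent_proximal: np.ndarray
    tangent_distal: np.ndarray


def segment_length(coords: np.ndarray) -> float:
    """Polyline length: sum of Euclidean distances between consecutive nodes."""
    coords = np.asarray(coords, dtype=float)
    if len(coords) < 2:
        return 0.0
    return float(np.linalg.norm(np.diff(coords, axis=0), axis=1).sum())


def node_anisotropy(coords: np.ndarray, index: int, window: int = 5):
    """Descending eigenvalues (lambda1, lambda2, lambda3) of the covariance
    of the node's local neighborhood along the polyline.

    The window spans ``window`` nodes on each side, clamped at segment
    ends.  lambda2 and lambda3 are floored at a small fraction of lambda1
    so ratios stay finite on exactly collinear windows.
    """
    coords = np.asarray(coords, dtype=float)
    lo = max(0, index - window)
    hi = min(len(coords), index + window + 1)
    pts = coords[lo:hi]
    if len(pts) < 2:
        return (0.0, 0.0, 0.0)
    cov = np.cov(pts.T) if len(pts) > 1 else np.zeros((3, 3))
    vals = np.linalg.eigvalsh(np.atleast_2d(cov))[::-1]
    vals = np.maximum(vals, 0.0)
    l1 = float(vals[0])
    floor = _EPS_FRAC * l1
    l2 = max(float(vals[1]) if len(vals) > 1 else 0.0, floor)
    l3 = max(float(vals[2]) if len(vals) > 2 else 0.0, floor)
    return (l1, l2, l3)


def segment_linearity(coords: np.ndarray, window: int = 5,
                      cap_ratio: float = 100.0) -> float:
    """Mean over nodes of lambda1/lambda2 (each ratio capped).

    A straight segment saturates at ``cap_ratio``; tortuous noise drops
    toward 1.  Invariant under rigid rotation and translation.
    """
    coords = np.asarray(coords, dtype=float)
    if len(coords) < 3:
        return cap_ratio  # too short to assess curvature: maximally line-like
    ratios = []
    for i in range(len(coords)):
        l1, l2, _ = node_anisotropy(coords, i, window)
        if l1 <= 0:
            ratios.append(1.0)
        else:
            ratios.append(min(l1 / l2, cap_ratio))
    return float(np.mean(ratios))


def direction_from(coords: np.ndarray, local_len: float) -> np.ndarray:
    """Unit chord from ``coords[0]`` to the point ``local_len`` along the
    polyline (clamped to the far end).  Raises on zero-length geometry."""
    coords = np.asarray(coords, dtype=float)
    if len(coords) < 2:
        raise ValueError("cannot estimate a direction from fewer than 2 nodes")
    acc = 0.0
    target = coords[-1]
    for i in range(1, len(coords)):
        acc += float(np.linalg.norm(coords[i] - coords[i - 1]))
        if acc >= local_len:
            target = coords[i]
            break
    v = target - coords[0]
    n = float(np.linalg.norm(v))
    if n == 0.0:
        raise ValueError("zero-length direction vector")
    return v / n


def _orient_from_node(stree: SegmentTree, seg_id: int, node_id: int) -> np.ndarray:
    s = stree.segments[seg_id]
    pts = stree.seg_coords(seg_id)
    if s.proximal == node_id:
        return pts
    if s.distal == node_id:
        return pts[::-1]
    raise ValueError(f"node {node_id} is not an endpoint of segment {seg_id}")


def segment_angle(stree: SegmentTree, s1: int, s2: int, at: int,
                  local_len: float = 5.0) -> float:
    """Angle in degrees between two segments at their shared node.

    Each direction is the chord from the shared node to the point
    ``local_len`` along the respective segment.  180 means collinear
    continuation; 0 means doubling back.  Symmetric in its arguments.
    """
    d1 = direction_from(_orient_from_node(stree, s1, at), local_len)
    d2 = direction_from(_orient_from_node(stree, s2, at), local_len)
    return angle_between(d1, d2)


def angle_between(d1: np.ndarray, d2: np.ndarray) -> float:
    c = float(np.clip(np.dot(d1, d2), -1.0, 1.0))
    return float(np.degrees(np.arccos(c)))


def child_child_angles(stree: SegmentTree, thr: Thresholds | None = None) -> list[float]:
    """All pairwise child-child angles at the tree's bifurcations."""
    local_len = thr.local_len if thr else 5.0
    out = []
    for sid in stree.bifurcation_segments():
        s = stree.segments[sid]
        kids = s.child_segs
        for i in range(len(kids)):
            for j in range(i + 1, len(kids)):
                try:
                    out.append(segment_angle(stree, kids[i], kids[j],
                                             s.distal, local_len))
                except ValueError:
                    continue
    return out


def _root_tip_path_lengths(stree: SegmentTree) -> list[float]:
    depth: dict[int, float] = {stree.soma_seg: stree.segments[stree.soma_seg].length}
    order = [stree.soma_seg]
    stack = [stree.soma_seg]
    while stack:
        sid = stack.pop()
        for c in stree.segments[sid].child_segs:
            depth[c] = depth[sid] + stree.segments[c].length
            order.append(c)
            stack.append(c)
    return [depth[s] for s in order if stree.segments[s].is_leaf]


def calibrate_thresholds(training: list[SegmentTree],
                         base: Thresholds | None = None) -> Thresholds:
    """Calibrate population thresholds from gold-standard segment trees.

    ``t_len`` is the 1st percentile of leaf-segment lengths, ``t_lin`` the
    1st percentile of segment linearity, ``t_beta`` the 99th percentile of
    child-child branch angles, and ``long_path_len`` the 99th percentile of
    root-to-tip path lengths.  Percentiles use linear interpolation between
    order statistics for cross-platform determinism.
    """
    if not training:
        raise ValueError("empty training set; pass explicit thresholds to use defaults")
    base = base or Thresholds()
    leaf_lens: list[float] = []
    linearities: list[float] = []
    angles: list[float] = []
    path_lens: list[float] = []
    for stree in training:
        for s in stree.segments.values():
            if len(s.node_ids) < 2:
                continue
            if s.is_leaf:
                leaf_lens.append(s.length)
            linearities.append(segment_linearity(stree.seg_coords(s.seg_id),
                                                 base.window, base.cap_ratio))
        angles.extend(child_child_angles(stree, base))
        path_lens.extend(_root_tip_path_lengths(stree))
    if not leaf_lens or not angles:
        raise ValueError("training set has no leaf segments or no bifurcations")
    return replace(
        base,
        t_len=float(np.percentile(leaf_lens, 1)),
        t_lin=float(np.percentile(linearities, 1)),
        t_beta=float(np.percentile(angles, 99)),
        long_path_len=float(np.percentile(path_lens, 99)) if path_lens
        else base.long_path_len,
    )
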