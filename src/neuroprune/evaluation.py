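"""Evaluation of pruning results against gold-standard reconstructions.

Because a pruning method removes but never adds segments, the reference
for scoring is the *best possible pruned* tree (BP): the maximal
soma-connected subset of the automated reconstruction whose segments match
the ground truth within a distance criterion.  Scoring is framed as a
detection problem where a true positive is a correctly pruned segment:

    precision = TP / (TP + FP),   sensitivity = TP / (TP + FN),
    F1 = harmonic mean,           MES = ((TN + FP) - FP) / ((TN + FP) + FN)

with both segment-count and segment-length weighting.  The Miss-Extra-
Score (MES) form above is the pruning reformulation of the classical
(S_G - S_miss) / (S_G + S_extra) reconstruction score and is algebraically
TN / (TN + FP + FN).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .segments import SegmentTree, prune_segments

__all__ = [
    "EvalCounts",
    "Metrics",
    "match_segments",
    "best_possible_pruned",
    "score_pruning",
    "metrics_from_counts",
    "mes",
    "compare_runs",
]


@dataclass
class EvalCounts:
    tp: float = 0
    fp: float = 0
    fn: float = 0
    tn: float = 0
    tp_len: float = 0.0
    fp_len: float = 0.0
    fn_len: float = 0.0
    tn_len: float = 0.0

    def pick(self, weight: str):
        if weight == "segment":
            return self.tp, self.fp, self.fn, self.tn
        if weight == "length":
            return self.tp_len, self.fp_len, self.fn_len, self.tn_len
        raise ValueError("weight must be 'segment' or 'length'")


@dataclass
class Metrics:
    precision: float | None
    sensitivity: float | None
    f1: float | None
    mes: float | None


def _point_to_polyline_dists(points: np.ndarray, edges_a: np.ndarray,
                             edges_b: np.ndarray) -> np.ndarray:
    """Min distance of each point to any edge [a_i, b_i] (vectorized)."""
    ab = edges_b - edges_a                              # (m, 3)
    ab2 = np.einsum("ij,ij->i", ab, ab)                 # (m,)
    ab2 = np.where(ab2 == 0, 1.0, ab2)
    out = np.empty(len(points))
    for k, p in enumerate(points):
        ap = p - edges_a                                # (m, 3)
        t = np.clip(np.einsum("ij,ij->i", ap, ab) / ab2, 0.0, 1.0)
        proj = edges_a + t[:, None] * ab
        out[k] = float(np.sqrt(((p - proj) ** 2).sum(axis=1).min()))
    return out


def _gt_edges(gt: SegmentTree):
    a_list, b_list = [], []
    for sid in gt.segments:
        pts = gt.seg_coords(sid)
        if len(pts) >= 2:
            a_list.append(pts[:-1])
            b_list.append(pts[1:])
    if not a_list:
        return None, None
    return np.vstack(a_list), np.vstack(b_list)


def match_segments(pred: SegmentTree, gt: SegmentTree, dist_thr: float = 3.0,
                   cover_frac: float = 0.8) -> dict[int, bool]:
    """Label each predicted segment as present in the ground truth.

    A segment is ``in_gt`` iff its mean node-to-GT-polyline distance is at
    most ``dist_thr`` *and* at least ``cover_frac`` of its nodes lie
    within ``dist_thr`` of the GT.  Both trees must share a coordinate
    frame.  Empty GT labels everything ``not_in_gt``.
    """
    ea, eb = _gt_edges(gt)
    labels: dict[int, bool] = {}
    for sid in pred.segments:
        if ea is None:
            labels[sid] = False
            continue
        pts = pred.seg_coords(sid)
        d = _point_to_polyline_dists(pts, ea, eb)
        labels[sid] = (float(d.mean()) <= dist_thr
                       and float((d <= dist_thr).mean()) >= cover_frac)
    return labels


def best_possible_pruned(auto: SegmentTree, gt: SegmentTree,
                         dist_thr: float = 3.0,
                         cover_frac: float = 0.8) -> SegmentTree:
    """Maximal soma-connected subset of ``auto`` matching the ground
    truth: every ``not_in_gt`` segment is removed with subtree semantics
    (a matching segment stranded behind a removed ancestor goes too)."""
    labels = match_segments(auto, gt, dist_thr, cover_frac)
    to_remove = [sid for sid, ok in labels.items()
                 if not ok and sid != auto.soma_seg]
    if not to_remove:
        return auto
    pruned, _ = prune_segments(auto, to_remove, "C2", "none")
    return pruned


def removed_kept_split(input_tree: SegmentTree, output_tree: SegmentTree):
    """Partition input segments into removed/kept given a pruned output.

    A segment counts as removed when none of its non-proximal nodes
    survive in the output; otherwise it is kept (rebuilt/merged segments
    keep all their nodes, so this is exact for subtree pruning)."""
    out_nodes = set(output_tree.source.nodes)
    removed, kept = [], []
    for sid, s in input_tree.segments.items():
        body = s.node_ids[1:] if len(s.node_ids) > 1 else s.node_ids
        (removed if not any(n in out_nodes for n in body) else kept).append(sid)
    return removed, kept


def score_pruning(input_tree: SegmentTree, output_tree: SegmentTree,
                  labels: dict[int, bool]) -> tuple[EvalCounts, Metrics, Metrics]:
    """Score a pruning run against a reference labeling of the input.

    ``labels[sid]`` is True when the reference (BP / GT matching) says the
    segment belongs to the neuron, i.e. *should be kept*.  TP = removed
    and should-remove; FP = removed but should-keep; FN = kept but
    should-remove; TN = kept and should-keep.  Returns the counts plus
    segment- and length-weighted metrics.  With nothing removed, precision
    (and F1) are undefined and flagged ``None``.
    """
    removed, kept = removed_kept_split(input_tree, output_tree)
    counts = EvalCounts()
    for sid in removed:
        ln = input_tree.segments[sid].length
        if labels[sid]:
            counts.fp += 1
            counts.fp_len += ln
        else:
            counts.tp += 1
            counts.tp_len += ln
    for sid in kept:
        ln = input_tree.segments[sid].length
        if labels[sid]:
            counts.tn += 1
            counts.tn_len += ln
        else:
            counts.fn += 1
            counts.fn_len += ln
    return (counts,
            metrics_from_counts(*counts.pick("segment")),
            metrics_from_counts(*counts.pick("length")))


def metrics_from_counts(tp: float, fp: float, fn: float, tn: float) -> Metrics:
    """Detection metrics from raw counts (segment numbers or lengths)."""
    prec = tp / (tp + fp) if (tp + fp) > 0 else None
    sens = tp / (tp + fn) if (tp + fn) > 0 else None
    if prec is not None and sens is not None and (prec + sens) > 0:
        f1 = 2 * prec * sens / (prec + sens)
    else:
        f1 = None
    return Metrics(prec, sens, f1, mes(tp, fp, fn, tn))


def mes(tp: float, fp: float, fn: float, tn: float) -> float | None:
    """Miss-Extra-Score in its pruning form
    ``((TN + FP) - FP) / ((TN + FP) + FN)`` (= TN / (TN + FP + FN))."""
    denom = (tn + fp) + fn
    if denom <= 0:
        return None
    return ((tn + fp) - fp) / denom


def compare_runs(m1: pd.DataFrame, m2: pd.DataFrame,
                 decimals: int = 4) -> pd.DataFrame:
    """Per-metric win/tie/loss percentages between two methods scored on
    the same neurons (rows = neuron ids, columns = metrics).  Values equal
    to ``decimals`` places count as ties; rows sum to 100."""
    if set(m1.index) != set(m2.index):
        diff = set(m1.index) ^ set(m2.index)
        raise ValueError(f"mismatched neuron sets; symmetric difference: {sorted(diff)}")
    if list(m1.columns) != list(m2.columns):
        raise ValueError("metric columns differ between the two tables")
    m2 = m2.loc[m1.index]
    rows = {}
    n = len(m1)
    for col in m1.columns:
        a = m1[col].round(decimals)
        b = m2[col].round(decimals)
        mask = a.notna() & b.notna()
        nn = int(mask.sum())
        if nn == 0:
            rows[col] = (math.nan, math.nan, math.nan)
            continue
        wins = float((a[mask] > b[mask]).sum()) / nn * 100
        ties = float((a[mask] == b[mask]).sum()) / nn * 100
        losses = float((a[mask] < b[mask]).sum()) / nn * 100
        rows[col] = (wins, ties, losses)
    return pd.DataFrame(rows, index=["m1_better_pct", "tie_pct", "m2_better_pct"]).T
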