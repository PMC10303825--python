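"""Step 1: iterative removal of noisy leaf segments (category C1).

Background noise in the image (imaging noise, irrelevant particles, halos
of strong signal) produces short, weakly linear leaf segments in automated
reconstructions.  Each iteration tests the current leaf segments against
the calibrated length and linearity thresholds, removes the offenders, and
repeats on the newly exposed leaves until a fixed point is reached.  The
soma segment is never removed.
"""

from __future__ import annotations

from .features import Thresholds, segment_linearity
from .segments import PruneReport, SegmentTree, prune_segments

__all__ = ["prune_noise"]


def prune_noise(stree: SegmentTree, thr: Thresholds,
                rule: str = "or") -> tuple[SegmentTree, PruneReport]:
    """Iteratively prune leaf segments violating ``t_len`` / ``t_lin``.

    ``rule`` combines the two tests: ``"or"`` (default) removes a leaf if
    its length is below ``t_len`` *or* its linearity below ``t_lin``;
    ``"and"`` requires both.  Each threshold is a 1st-percentile outlier
    cut on valid segments, so either violation already marks an outlier.
    Returns the pruned tree and a report of C1 removals per iteration.
    """
    if rule not in ("or", "and"):
        raise ValueError("rule must be 'or' or 'and'")
    report = PruneReport()
    iteration = 0
    while True:
        to_remove = []
        for sid in stree.leaf_segments():
            if sid == stree.soma_seg:
                continue
            s = stree.segments[sid]
            short = s.length < thr.t_len
            if rule == "or" and short:
                to_remove.append(sid)   # skip the PCA when length decides
                continue
            wiggly = segment_linearity(stree.seg_coords(sid), thr.window,
                                       thr.cap_ratio) < thr.t_lin
            if (short or wiggly) if rule == "or" else (short and wiggly):
                to_remove.append(sid)
        if not to_remove:
            break
        stree, rep = prune_segments(stree, to_remove, "C1", "none", iteration)
        report.extend(rep)
        iteration += 1
    return stree, report
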