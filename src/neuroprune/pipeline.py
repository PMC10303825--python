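"""Full pruning pipeline: soma retention, then steps 1 -> 2 -> 3.

The step order is fixed: the easy background-noise category first (so its
artifacts cannot persist into the structural steps), then multi-neuron
separation, then crossing pruning.  Step toggles allow ablation but never
reordering.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .crossings import run_step3
from .features import Thresholds
from .noise import prune_noise
from .segments import PruneReport, SegmentTree, build_segment_tree
from .separation import (SOMA_MAP_MAX_DIST, fake_soma_patch, map_soma,
                         separate_all)
from .swc import NeuronTree, keep_soma_component

log = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "run_pipeline"]

_KNOWN_KEYS = {"thresholds", "rule", "skip_steps", "seed", "verbosity",
               "soma_map_max_dist"}


@dataclass
class PipelineConfig:
    thresholds: Thresholds = field(default_factory=Thresholds)
    rule: str = "or"                       # step 1 combination rule
    skip_steps: tuple[str, ...] = ()       # subset of {"step1","step2","step3"}
    seed: int = 0
    verbosity: int = 0
    soma_map_max_dist: float = SOMA_MAP_MAX_DIST

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        unknown = set(d) - _KNOWN_KEYS
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        thr = Thresholds.from_dict(d.get("thresholds", {}))
        bad = set(d.get("skip_steps", ())) - {"step1", "step2", "step3"}
        if bad:
            raise ValueError(f"unknown steps in skip_steps: {sorted(bad)}")
        return cls(thresholds=thr, rule=d.get("rule", "or"),
                   skip_steps=tuple(d.get("skip_steps", ())),
                   seed=int(d.get("seed", 0)),
                   verbosity=int(d.get("verbosity", 0)),
                   soma_map_max_dist=float(d.get("soma_map_max_dist",
                                                 SOMA_MAP_MAX_DIST)))


def run_pipeline(tree: NeuronTree, somata, target_index: int = 0,
                 config: PipelineConfig | None = None,
                 image: np.ndarray | None = None
                 ) -> tuple[SegmentTree, PruneReport]:
    """Prune one reconstruction for the neuron of interest.

    ``somata`` lists 3D soma locations (native units of the tree), with
    ``target_index`` marking the neuron of interest.  Returns the pruned
    segment tree (rooted at the target soma) and a consolidated report.
    """
    cfg = config or PipelineConfig()
    thr = cfg.thresholds
    log.info("pipeline config: %s", cfg)
    if not somata:
        raise ValueError("at least one soma location is required "
                         "(multi-neuron input needs --somata)")
    target_soma = np.asarray(somata[target_index], dtype=float)

    kept = keep_soma_component(tree, target_soma)
    root = map_soma(kept, kept.xyz_um(map_soma(kept, target_soma,
                                               cfg.soma_map_max_dist)))
    stree = build_segment_tree(kept.reroot(root))
    report = PruneReport()

    if "step1" not in cfg.skip_steps:
        stree, rep = prune_noise(stree, thr, cfg.rule)
        report.extend(rep)

    if "step2" not in cfg.skip_steps:
        # somata of other neurons that map into this component
        extra = []
        for i, xyz in enumerate(somata):
            if i == target_index:
                continue
            try:
                map_soma(stree.source, xyz, cfg.soma_map_max_dist)
                extra.append(tuple(xyz))
            except ValueError:
                continue
        pseudo = [tuple(p) for p in fake_soma_patch(stree, thr)]
        all_somata = [tuple(target_soma)] + extra + pseudo
        # drop pseudo-somata colliding with a real soma's nearest node
        seen_nodes = set()
        somata_use = []
        for xyz in all_somata:
            try:
                nid = map_soma(stree.source, xyz, cfg.soma_map_max_dist)
            except ValueError:
                continue
            if nid in seen_nodes:
                continue
            seen_nodes.add(nid)
            somata_use.append(xyz)
        if len(somata_use) > 1:
            trees, rep = separate_all(stree, somata_use, 0, thr,
                                      cfg.soma_map_max_dist)
            stree = trees[0]
            report.extend(rep)

    if "step3" not in cfg.skip_steps:
        stree, rep = run_step3(stree, image, thr)
        report.extend(rep)

    return stree, report
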