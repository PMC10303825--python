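"""Shared fixtures: hand-built micro-trees and generated arbors."""

from __future__ import annotations

import numpy as np
import pytest

from neuroprune.features import Thresholds
from neuroprune.segments import build_segment_tree
from neuroprune.swc import NeuronTree, NodeRecord


def make_chain_tree(points, radius=1.0, root_type=1):
    """NeuronTree from a single polyline (first point is the root)."""
    nodes = {}
    for i, p in enumerate(points, start=1):
        nodes[i] = NodeRecord(i, root_type if i == 1 else 3, *map(float, p),
                              radius, i - 1 if i > 1 else -1)
    return NeuronTree(nodes)


class TreeBuilder:
    """Incremental builder for hand-crafted morphologies (coordinates um)."""

    def __init__(self, root=(0.0, 0.0, 0.0), radius=1.0):
        self.nodes = {1: NodeRecord(1, 1, *map(float, root), 5.0, -1)}
        self._next = 2

    def chain_to(self, parent: int, end, step: float = 1.0,
                 radius: float = 1.0) -> int:
        """Straight chain of nodes from ``parent`` to ``end``; returns the
        last node id."""
        a = self.nodes[parent].xyz
        b = np.asarray(end, dtype=float)
        n = max(1, int(np.ceil(np.linalg.norm(b - a) / step)))
        for t in range(1, n + 1):
            p = a + (b - a) * (t / n)
            nid = self._next
            self._next += 1
            self.nodes[nid] = NodeRecord(nid, 3, *p, radius, parent)
            parent = nid
        return parent

    def chain_dir(self, parent: int, direction, length: float,
                  step: float = 1.0, radius: float = 1.0) -> int:
        d = np.asarray(direction, dtype=float)
        d = d / np.linalg.norm(d)
        end = self.nodes[parent].xyz + d * length
        return self.chain_to(parent, end, step, radius)

    def tree(self) -> NeuronTree:
        return NeuronTree(dict(self.nodes))

    def segment_tree(self):
        return build_segment_tree(self.tree())


@pytest.fixture
def thresholds():
    return Thresholds()


@pytest.fixture
def builder():
    return TreeBuilder


@pytest.fixture
def simple_y():
    """Root -> trunk -> bifurcation with two 20 um leaves."""
    b = TreeBuilder()
    j = b.chain_dir(1, (1, 0, 0), 20.0)
    b.chain_dir(j, (1, 1, 0), 20.0)
    b.chain_dir(j, (1, -1, 0), 20.0)
    return b.segment_tree()
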