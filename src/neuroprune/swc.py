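"""Reading, validating and writing SWC neuron morphology files.

SWC is the standard 7-column text format for neuron reconstructions:
``id type x y z radius parent_id`` with ``parent_id = -1`` for a root.
Both space- and tab-delimited files are accepted; ``#`` lines are comments.

Coordinates may be stored in micrometers or in voxel units; a
:class:`NeuronTree` carries a unit tag and a voxel size so that all
geometric thresholds (which are defined in micrometers) can be applied
consistently.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace

import numpy as np

log = logging.getLogger(__name__)

__all__ = [
    "NodeRecord",
    "NeuronTree",
    "SwcParseError",
    "SwcValidationError",
    "read_swc",
    "write_swc",
    "keep_soma_component",
    "read_markers",
]


class SwcParseError(ValueError):
    """Malformed SWC line (reported with its line number)."""


class SwcValidationError(ValueError):
    """Structurally invalid SWC content (duplicate ids, dangling parents, cycles)."""


@dataclass(frozen=True)
class NodeRecord:
    """One SWC point: id, structure type, position, radius, parent id."""

    id: int
    type_code: int
    x: float
    y: float
    z: float
    radius: float
    parent_id: int

    @property
    def xyz(self) -> np.ndarray:
        return np.array([self.x, self.y, self.z], dtype=float)


@dataclass
class NeuronTree:
    """A (possibly multi-rooted) SWC point forest.

    ``nodes`` maps id -> :class:`NodeRecord`.  ``unit`` is ``"um"`` or
    ``"voxel"``; when ``"voxel"``, :meth:`xyz_um` scales by ``voxel_size``
    (micrometers per voxel, x/y/z).
    """

    nodes: dict[int, NodeRecord] = field(default_factory=dict)
    unit: str = "um"
    voxel_size: tuple[float, float, float] = (0.6, 0.6, 1.0)

    def __len__(self) -> int:
        return len(self.nodes)

    # -- structure ---------------------------------------------------------

    def roots(self) -> list[int]:
        return [n.id for n in self.nodes.values()
                if n.parent_id == -1 or n.parent_id not in self.nodes]

    def children_map(self) -> dict[int, list[int]]:
        ch: dict[int, list[int]] = {nid: [] for nid in self.nodes}
        for n in self.nodes.values():
            if n.parent_id in self.nodes and n.parent_id != n.id:
                ch[n.parent_id].append(n.id)
        return ch

    def validate(self) -> None:
        for n in self.nodes.values():
            if n.parent_id == n.id:
                raise SwcValidationError(f"node {n.id} is its own parent")
        dangling = [n.id for n in self.nodes.values()
                    if n.parent_id != -1 and n.parent_id not in self.nodes]
        if dangling:
            raise SwcValidationError(
                f"parent_id references missing nodes for ids: {sorted(dangling)}")
        # acyclicity: follow parents with a visited-set per walk
        state: dict[int, int] = {}  # 0 in progress, 1 done
        for start in self.nodes:
            path = []
            nid = start
            while nid in self.nodes and nid not in state:
                state[nid] = 0
                path.append(nid)
                nid = self.nodes[nid].parent_id
            if nid in state and state[nid] == 0:
                raise SwcValidationError(f"parent cycle involving node {nid}")
            for p in path:
                state[p] = 1

    def components(self) -> list[set[int]]:
        """Connected components of the parent graph (undirected sense)."""
        ch = self.children_map()
        seen: set[int] = set()
        comps = []
        for root in self.roots():
            if root in seen:
                continue
            comp = set()
            stack = [root]
            while stack:
                nid = stack.pop()
                if nid in comp:
                    continue
                comp.add(nid)
                stack.extend(ch[nid])
            seen |= comp
            comps.append(comp)
        return comps

    # -- geometry ----------------------------------------------------------

    def xyz_um(self, nid: int) -> np.ndarray:
        """Node position in micrometers regardless of storage unit."""
        p = self.nodes[nid].xyz
        if self.unit == "voxel":
            p = p * np.asarray(self.voxel_size, dtype=float)
        return p

    def coords_um(self) -> dict[int, np.ndarray]:
        return {nid: self.xyz_um(nid) for nid in self.nodes}

    # -- editing -----------------------------------------------------------

    def subset(self, keep: set[int]) -> "NeuronTree":
        """Restrict to ``keep``; nodes whose parent is dropped become roots."""
        nodes = {}
        for nid in self.nodes:
            if nid not in keep:
                continue
            n = self.nodes[nid]
            pid = n.parent_id if n.parent_id in keep else -1
            nodes[nid] = replace(n, parent_id=pid)
        return NeuronTree(nodes, self.unit, self.voxel_size)

    def renumbered(self) -> "NeuronTree":
        """Re-emit ids contiguously from 1, parents before children."""
        order: list[int] = []
        ch = self.children_map()
        for root in self.roots():
            stack = [root]
            while stack:
                nid = stack.pop()
                order.append(nid)
                stack.extend(reversed(ch[nid]))
        mapping = {nid: i + 1 for i, nid in enumerate(order)}
        nodes = {}
        for nid in order:
            n = self.nodes[nid]
            pid = mapping[n.parent_id] if n.parent_id in mapping else -1
            nodes[mapping[nid]] = replace(n, id=mapping[nid], parent_id=pid)
        return NeuronTree(nodes, self.unit, self.voxel_size)

    def reroot(self, new_root: int) -> "NeuronTree":
        """Flip parent pointers so ``new_root`` has parent -1 (same component)."""
        if new_root not in self.nodes:
            raise KeyError(new_root)
        chain = [new_root]
        nid = new_root
        while self.nodes[nid].parent_id in self.nodes:
            nid = self.nodes[nid].parent_id
            chain.append(nid)
        nodes = dict(self.nodes)
        for child, parent in zip(chain, chain[1:]):
            nodes[parent] = replace(nodes[parent], parent_id=child)
        nodes[new_root] = replace(nodes[new_root], parent_id=-1)
        return NeuronTree(nodes, self.unit, self.voxel_size)


def read_swc(path, unit: str = "um",
             voxel_size: tuple[float, float, float] = (0.6, 0.6, 1.0)) -> NeuronTree:
    """Parse an SWC file.

    Multiple roots and multiple connected components are permitted at read
    time; soma-component retention happens later in the pipeline.  Raises
    :class:`SwcParseError` on a malformed line (with its line number) and
    :class:`SwcValidationError` on duplicate ids or dangling parents.
    """
    nodes: dict[int, NodeRecord] = {}
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) < 7:
                raise SwcParseError(f"line {lineno}: expected 7 columns, got {len(parts)}")
            try:
                nid = int(float(parts[0]))
                tc = int(float(parts[1]))
                x, y, z, r = (float(v) for v in parts[2:6])
                pid = int(float(parts[6]))
            except ValueError as e:
                raise SwcParseError(f"line {lineno}: {e}") from None
            if nid <= 0:
                raise SwcParseError(f"line {lineno}: node id must be positive")
            if nid in nodes:
                raise SwcValidationError(f"line {lineno}: duplicate node id {nid}")
            nodes[nid] = NodeRecord(nid, tc, x, y, z, r, pid)
    tree = NeuronTree(nodes, unit=unit, voxel_size=voxel_size)
    tree.validate()
    return tree


def write_swc(tree: NeuronTree, path, renumber: bool = False) -> None:
    """Write a tree to SWC (coordinates at 4 decimals; round-trip safe).

    With ``renumber=True`` ids are re-emitted contiguously from 1 with
    remapped parent links (used after pruning).
    """
    t = tree.renumbered() if renumber else tree
    with open(path, "w") as fh:
        fh.write("# id type x y z radius parent\n")
        for n in t.nodes.values():
            fh.write(f"{n.id} {n.type_code} {n.x:.4f} {n.y:.4f} {n.z:.4f} "
                     f"{n.radius:.4f} {n.parent_id}\n")


def keep_soma_component(tree: NeuronTree, soma_location) -> NeuronTree:
    """Retain only the connected component containing the node nearest to
    the soma of interest; the component's own root stays the root.

    Discarded fragments (broken reconstruction pieces, other neurons'
    debris) are logged with their node counts.  Empty in -> empty out.
    Nearest node uses Euclidean distance in the file's native units; ties
    break toward the smallest id.
    """
    if not tree.nodes:
        return NeuronTree({}, tree.unit, tree.voxel_size)
    soma = np.asarray(soma_location, dtype=float)
    best_id, best_d = None, math.inf
    for nid in sorted(tree.nodes):
        d = float(np.linalg.norm(tree.nodes[nid].xyz - soma))
        if d < best_d - 1e-12:
            best_id, best_d = nid, d
    comps = tree.components()
    keep = next(c for c in comps if best_id in c)
    dropped = [c for c in comps if best_id not in c]
    if dropped:
        log.info("keep_soma_component: discarding %d fragment(s) with node counts %s",
                 len(dropped), sorted((len(c) for c in dropped), reverse=True))
    return tree.subset(keep)


def read_markers(path) -> list[tuple[float, float, float]]:
    """Read soma locations from a Vaa3D ``.marker`` CSV (x,y,z,...) or a
    plain whitespace ``x y z`` text file."""
    out = []
    with open(path) as fh:
        for raw in fh:
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split(",") if "," in line else line.split()
            if len(parts) < 3:
                continue
            out.append(tuple(float(v) for v in parts[:3]))
    return out
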