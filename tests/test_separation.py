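"""Step 2: inter-soma paths, bifurcation weights, split selection,
multi-neuron separation and the fake-soma patch."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from neuroprune.features import Thresholds
from neuroprune.segments import build_segment_tree
from neuroprune.separation import (best_separation_point, bifurcation_weight,
                                   fake_soma_patch, path_weights, separate_all,
                                   separate_pair, soma_path)
from neuroprune.synthetic import (ArborSpec, ErrorSpec, generate_arbor,
                                  inject_errors, merge_arbors)

from conftest import TreeBuilder


def brute_force_split(w_a, w_b):
    """Independent enumeration of W_s = sum_{i<=s} w_a + sum_{j>=s} w_b."""
    n = len(w_a)
    scores = {s: sum(w_a[:s]) + sum(w_b[s - 1:]) for s in range(1, n + 1)}
    best = max(scores.values())
    mid = math.ceil(n / 2)
    ties = [s for s, v in scores.items() if abs(v - best) <= 1e-12]
    return min(ties, key=lambda s: (abs(s - mid), s))


class TestBestSeparationPoint:
    def test_single_bifurcation_forced(self):
        assert best_separation_point([2.0], [1.0]) == 1

    def test_worked_example(self):
        # W_s for s=1..4: 8, 11, 10, 8 (the sums overlap at s)
        assert best_separation_point([3, 3, 0, 0], [0, 1, 2, 2]) == 2

    def test_all_equal_ties_break_to_midpoint(self):
        assert best_separation_point([1] * 5, [1] * 5) == 3
        assert best_separation_point([1] * 4, [1] * 4) == 2

    def test_matches_brute_force_on_random_vectors(self):
        rng = np.random.default_rng(7)
        for _ in range(300):
            n = int(rng.integers(1, 12))
            w_a = list(rng.normal(size=n))
            w_b = list(rng.normal(size=n))
            assert best_separation_point(w_a, w_b) == brute_force_split(w_a, w_b)

    @given(st.integers(min_value=1, max_value=10), st.integers())
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_label_swap_symmetry(self, n, seed):
        rng = np.random.default_rng(abs(seed) % 2**31)
        w_a = list(rng.normal(size=n))
        w_b = list(rng.normal(size=n))
        scores = [sum(w_a[:s]) + sum(w_b[s - 1:]) for s in range(1, n + 1)]
        best = max(scores)
        if sum(1 for v in scores if abs(v - best) <= 1e-9) > 1:
            return  # tie-breaking is midpoint-based, not swap-symmetric
        s = best_separation_point(w_a, w_b)
        s_swapped = best_separation_point(w_b[::-1], w_a[::-1])
        assert s_swapped == n - s + 1


def _path_fixture(child_dirs, bif_xs=(0.0,), soma_a=(-60, 0, 0),
                  soma_b=(60, 0, 0)):
    """Straight main path along x with off-path children at given x."""
    b = TreeBuilder(root=soma_a)
    last = 1
    for i, x in enumerate(bif_xs):
        last = b.chain_to(last, (x, 0, 0))
        for d in child_dirs[i]:
            b.chain_dir(last, d, 20.0)
    b.chain_to(last, soma_b)
    return b.segment_tree()


class TestBifurcationWeight:
    def test_forward_child_beats_doubling_back(self, thresholds):
        fwd = _path_fixture([[(1, 1, 0)]])          # 45 deg forward from A
        back = _path_fixture([[(-0.985, 0.174, 0)]])  # ~170 deg, doubling back
        p_fwd = soma_path(fwd, (-60, 0, 0), (60, 0, 0), max_dist=100)
        p_back = soma_path(back, (-60, 0, 0), (60, 0, 0), max_dist=100)
        assert bifurcation_weight(p_fwd, 0, "A", thresholds) > \
            bifurcation_weight(p_back, 0, "A", thresholds)

    def test_symmetric_geometry_equal_weights(self, thresholds):
        st = _path_fixture([[(0, 1, 0)]])  # perpendicular child, centered
        p = soma_path(st, (-60, 0, 0), (60, 0, 0), max_dist=100)
        wa = bifurcation_weight(p, 0, "A", thresholds)
        wb = bifurcation_weight(p, 0, "B", thresholds)
        assert wa == pytest.approx(wb, abs=1e-9)

    def test_weight_decays_with_distance_from_soma(self, thresholds):
        near = _path_fixture([[(0, 1, 0)]], bif_xs=(-40.0,))
        far = _path_fixture([[(0, 1, 0)]], bif_xs=(40.0,))
        p_near = soma_path(near, (-60, 0, 0), (60, 0, 0), max_dist=100)
        p_far = soma_path(far, (-60, 0, 0), (60, 0, 0), max_dist=100)
        assert bifurcation_weight(p_near, 0, "A", thresholds) > \
            bifurcation_weight(p_far, 0, "A", thresholds)


class TestSeparatePair:
    def test_symmetric_barbell_splits_at_center(self, thresholds):
        b = TreeBuilder(root=(-50, 0, 0))
        j = b.chain_to(1, (0, 0, 0))
        b.chain_dir(j, (0, 1, 0), 20.0)   # central bifurcation child
        b.chain_to(j, (50, 0, 0))
        st = b.segment_tree()
        res = separate_pair(st, (-50, 0, 0), (50, 0, 0), thresholds,
                            max_dist=100)
        assert res.split_index == 1
        na, nb = len(res.tree_a.source.nodes), len(res.tree_b.source.nodes)
        assert abs(na - nb) <= len(st.segments[0].node_ids)  # near-congruent
        all_nodes = set(st.source.nodes)
        assert set(res.tree_a.source.nodes) | set(res.tree_b.source.nodes) == all_nodes
        assert not set(res.tree_a.source.nodes) & set(res.tree_b.source.nodes)

    def test_recovers_generator_merge_point(self, thresholds):
        hits = 0
        trials = 15
        for seed in range(trials):
            tree, _, _ = generate_arbor(ArborSpec(seed=seed, n_tips=10))
            corrupted, cst, tr = inject_errors(
                tree, ErrorSpec(c2_partner=ArborSpec(seed=seed + 900, n_tips=6),
                                seed=seed))
            u, v = tr.merge_nodes[0]
            pb = next(n for n in tr.nodes_of("C2")
                      if corrupted.nodes[n].radius == 5.0)
            res = separate_pair(cst, corrupted.xyz_um(1), corrupted.xyz_um(pb),
                                thresholds)
            p = soma_path(cst, corrupted.xyz_um(1), corrupted.xyz_um(pb))
            idx = {n: i for i, n in enumerate(p.bifurcations)}
            s = res.split_index - 1
            if any(m in idx and abs(s - idx[m]) <= 1 for m in (u, v)):
                hits += 1
        assert hits / trials >= 0.9

    def test_soma_outside_support_errors(self, simple_y, thresholds):
        with pytest.raises(ValueError, match="um from the reconstruction"):
            separate_pair(simple_y, (0, 0, 0), (500, 500, 500), thresholds)

    def test_coincident_somata_error(self, simple_y, thresholds):
        with pytest.raises(ValueError, match="not distinct"):
            separate_pair(simple_y, (0, 0, 0), (0.1, 0, 0), thresholds)

    def test_no_bifurcation_cuts_mid_edge(self, thresholds):
        b = TreeBuilder(root=(-30, 0, 0))
        b.chain_to(1, (30, 0, 0))
        st = b.segment_tree()
        res = separate_pair(st, (-30, 0, 0), (30, 0, 0), thresholds)
        assert res.split_index == 0
        assert res.tree_a is not None and res.tree_b is not None


class TestSeparateAll:
    def test_single_soma_identity(self, thresholds):
        _, cst, _ = generate_arbor(ArborSpec(seed=3, n_tips=6))
        trees, rep = separate_all(cst, [cst.coords[1]], 0, thresholds)
        assert len(trees) == 1
        assert set(trees[0].source.nodes) == set(cst.source.nodes)
        assert rep.entries == []

    def test_three_chained_arbors_partition_to_owners(self, thresholds):
        specs = [ArborSpec(seed=i, n_tips=8, soma=(80 + 120 * i,
                                                   90 + 30 * (i % 2), 120))
                 for i in range(3)]
        tree, owner, somas = merge_arbors(specs, seed=9)
        cst = build_segment_tree(tree)
        trees, _ = separate_all(cst, somas, 0, thresholds)
        union = set()
        for i, t in enumerate(trees):
            tn = set(t.source.nodes)
            assert not union & tn
            union |= tn
            own = [owner[n] for n in tn if owner[n] >= 0]
            assert sum(1 for o in own if o == i) / len(own) >= 0.85
        assert union == set(tree.nodes)

    def test_nine_entangled_neurons_partition(self, thresholds):
        specs = [ArborSpec(seed=10 + i, n_tips=6,
                           soma=(60 + 95 * (i % 3), 60 + 95 * (i // 3), 120))
                 for i in range(9)]
        tree, owner, somas = merge_arbors(specs, seed=99)
        cst = build_segment_tree(tree)
        trees, _ = separate_all(cst, somas, 0, thresholds)
        union = set()
        for t in trees:
            tn = set(t.source.nodes)
            assert not union & tn
            union |= tn
        assert union == set(tree.nodes)
        assert len(trees) == 9


class TestFakeSomaPatch:
    def test_compact_arbor_no_pseudo_somata(self, thresholds):
        _, cst, _ = generate_arbor(ArborSpec(seed=5, n_tips=8))
        assert fake_soma_patch(cst, thresholds) == []

    def test_runaway_paths_return_their_tips(self, thresholds):
        b = TreeBuilder()
        j = b.chain_dir(1, (1, 0, 0), 30.0)
        b.chain_dir(j, (1, 1, 0), 30.0)
        end1 = b.chain_dir(j, (1, -1, 0), 450.0, step=3.0)  # runaway 1
        st = b.segment_tree()
        tips = fake_soma_patch(st, thresholds)
        assert len(tips) == 1
        assert np.allclose(tips[0], b.nodes[end1].xyz)
        b.chain_dir(j, (0, 0, 1), 500.0, step=3.0)          # runaway 2
        assert len(fake_soma_patch(b.segment_tree(), thresholds)) == 2
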