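"""Step 3: Y/T/X/H structural models, recursive pruning, degenerate-case
fallback and single-segment pseudo-X excision."""

import numpy as np
import pytest

from neuroprune.crossings import (assign_Y_roles, find_crossing_structures,
                                  prune_H, prune_single_segment_inflections,
                                  prune_X, prune_Y_T, resolve_degenerate,
                                  run_step3)
from neuroprune.features import Thresholds
from neuroprune.synthetic import ArborSpec, ErrorSpec, generate_arbor, inject_errors

from conftest import TreeBuilder


def _deg_dir(angle_deg, base=(1.0, 0.0)):
    a = np.radians(angle_deg)
    return (np.cos(a) * base[0] - np.sin(a) * base[1],
            np.sin(a) * base[0] + np.cos(a) * base[1], 0.0)


def _y_fixture(c1_dir, c2_dir, trunk_dir=(1, 0, 0), leaf_len=20.0):
    b = TreeBuilder(root=(-20, 0, 0))
    j = b.chain_dir(1, trunk_dir, 20.0)
    b.chain_dir(j, c1_dir, leaf_len)
    b.chain_dir(j, c2_dir, leaf_len)
    return b.segment_tree()


def _y_structs(st, thr):
    return [c for c in find_crossing_structures(st, thr)
            if c.model in ("Y", "T")]


class TestYRoles:
    def test_worked_angle_example(self, thresholds):
        # parent outward -x; angles: (P,c1)=178, (P,c2)=95, (c1,c2)=87
        st = _y_fixture(_deg_dir(2), _deg_dir(-85))
        c = _y_structs(st, thresholds)[0]
        r = c.roles
        assert r["S1"] == st.soma_seg           # parent in the S1 role
        assert c.parent_label == "S1"
        assert abs(c.angles[(r["S1"], r["S2"])] - 178) < 1.5
        assert abs(c.angles[(r["S2"], r["S3"])] - 87) < 1.5

    def test_equilateral_star_ties_to_smallest_ids(self, thresholds):
        st = _y_fixture(_deg_dir(-60), _deg_dir(60))  # all pairwise angles 120
        c = _y_structs(st, thresholds)[0]
        pair = sorted((c.roles["S1"], c.roles["S2"]))
        ids = sorted([st.soma_seg] + st.segments[st.soma_seg].child_segs)
        assert pair == ids[:2]

    def test_perpendicular_stub_is_s3(self, thresholds):
        st = _y_fixture(_deg_dir(0), _deg_dir(-90))  # straight-through + stub
        c = _y_structs(st, thresholds)[0]
        stub = [s for s in st.segments[st.soma_seg].child_segs
                if abs(c.angles[(st.soma_seg, s)] - 90) < 1][0]
        assert c.roles["S3"] == stub


class TestPruneYT:
    def test_parent_s1_typical_bifurcation_kept(self, thresholds):
        st = _y_fixture(_deg_dir(30), _deg_dir(-40))
        c = _y_structs(st, thresholds)[0]
        assert c.parent_label == "S1"
        assert prune_Y_T(st, c, thresholds)[0] == "keep"

    def test_parent_s3_removes_aligned_pair(self, thresholds):
        # trace entered through the stub: children continue straight through
        st = _y_fixture(_deg_dir(88), _deg_dir(-88), trunk_dir=(1, 0, 0))
        c = _y_structs(st, thresholds)[0]
        assert c.parent_label == "S3"
        decision, segs = prune_Y_T(st, c, thresholds)
        assert decision == "remove"
        assert set(segs) == set(st.segments[st.soma_seg].child_segs)

    def test_parent_s2_marks_s3_suspicious(self, thresholds):
        # continuation straight ahead, third branch tilted back toward parent
        st = _y_fixture(_deg_dir(0), (-np.cos(np.radians(75)),
                                      np.sin(np.radians(75)), 0))
        c = _y_structs(st, thresholds)[0]
        assert c.parent_label == "S2"
        decision, query = prune_Y_T(st, c, thresholds)
        assert decision == "suspicious"
        assert query.suspicious_seg == c.roles["S3"]


class TestGeometricFallback:
    def test_doubling_back_branch_pruned(self, thresholds):
        # S3 at 30 degrees to the parent while the through-pair is straight
        st = _y_fixture(_deg_dir(0), (-np.cos(np.radians(30)),
                                      np.sin(np.radians(30)), 0))
        c = _y_structs(st, thresholds)[0]
        decision, query = prune_Y_T(st, c, thresholds)
        assert decision == "suspicious"
        assert resolve_degenerate(st, query, None, thresholds) == "prune"

    def test_plausible_branch_kept(self, thresholds):
        st = _y_fixture(_deg_dir(0), (-np.cos(np.radians(75)),
                                      np.sin(np.radians(75)), 0))
        c = _y_structs(st, thresholds)[0]
        decision, query = prune_Y_T(st, c, thresholds)
        assert resolve_degenerate(st, query, None, thresholds) == "keep"


def _h_fixture(beta_deg, link_len=3.0):
    """Trunk to b1; children: straight continuation and a short link whose
    two children are leaves separated by ``beta_deg``."""
    b = TreeBuilder(root=(-20, 0, 0))
    b1 = b.chain_dir(1, (1, 0, 0), 20.0)
    b.chain_dir(b1, (1, 0, 0), 20.0)                   # native continuation
    j2 = b.chain_dir(b1, (0, 1, 0), link_len)          # link S5
    half = np.radians(beta_deg / 2)
    b.chain_dir(j2, (np.sin(half), np.cos(half), 0), 15.0)
    b.chain_dir(j2, (-np.sin(half), np.cos(half), 0), 15.0)
    return b.segment_tree()


class TestPruneH:
    def test_wide_leaf_pair_removed_with_link(self, thresholds):
        st = _h_fixture(beta_deg=170)
        xh = [c for c in find_crossing_structures(st, thresholds)
              if c.model == "XH"]
        assert len(xh) == 1
        decision, segs = prune_H(st, xh[0], thresholds)
        assert decision == "remove"
        assert len(segs) == 3
        assert xh[0].link_seg in segs

    def test_narrow_leaf_pair_kept(self, thresholds):
        st = _h_fixture(beta_deg=60)
        xh = [c for c in find_crossing_structures(st, thresholds)
              if c.model == "XH"]
        assert prune_H(st, xh[0], thresholds)[0] == "keep"

    def test_recursive_cascade_clears_stacked_structure(self, thresholds):
        # bA--linkA--bB--linkB--bC; clearing bC's straight-through pair
        # exposes a qualifying wide pair at bB on the next pass
        b = TreeBuilder(root=(-20, 0, 0))
        bA = b.chain_dir(1, (1, 0, 0), 20.0)
        b.chain_dir(bA, (1, 0, 0), 25.0)            # native continuation
        bB = b.chain_dir(bA, (0, 1, 0), 3.0)        # linkA
        b.chain_dir(bB, (0, -1, 0.2), 12.0)         # leafM (anti-link)
        bC = b.chain_dir(bB, (0, 1, 0), 3.0)        # linkB
        b.chain_dir(bC, (1, 0.05, 0), 12.0)         # straight-through pair
        b.chain_dir(bC, (-1, 0.05, 0), 12.0)
        st = b.segment_tree()
        out, rep = run_step3(st, None, thresholds)
        assert len(out.segments) == 1               # everything spurious gone
        assert any(e.model == "H" for e in rep.entries)
        assert len(rep.entries) >= 5


def _x_fixture(foreign_angle=90.0):
    """Native path with two close bifurcations carrying the two halves of a
    straight foreign fiber (traced as an X)."""
    b = TreeBuilder(root=(-30, 0, 0))
    b1 = b.chain_dir(1, (1, 0, 0), 30.0)
    a = np.radians(foreign_angle)
    b2 = b.chain_dir(b1, (1, 0, 0), 3.0)               # link S5 (native)
    b.chain_dir(b2, (1, 0, 0), 30.0)                   # native continuation
    b.chain_dir(b1, (-np.cos(a) * 0 - 0, -np.sin(a), 0), 25.0)  # lower half
    b.chain_dir(b2, (0, np.sin(a), 0), 25.0)           # upper half
    return b.segment_tree()


class TestPruneX:
    def test_straight_foreign_pair_pruned_native_kept(self, thresholds):
        st = _x_fixture()
        n_before = len(st.source.nodes)
        out, rep = run_step3(st, None, thresholds)
        assert any(e.model == "X" for e in rep.entries)
        removed = set(st.source.nodes) - set(out.source.nodes)
        ys = {round(st.coords[n][1], 1) for n in removed}
        assert all(abs(y) > 0 for y in ys)          # only off-axis (foreign)
        assert len(out.source.nodes) < n_before
        # the native path survives end to end as one merged segment
        assert len(out.segments) == 1

    def test_genuine_double_branch_untouched(self, thresholds):
        b = TreeBuilder(root=(-30, 0, 0))
        b1 = b.chain_dir(1, (1, 0, 0), 30.0)
        b2 = b.chain_dir(b1, (1, 0, 0), 4.0)
        b.chain_dir(b2, (1, 0, 0), 30.0)
        b.chain_dir(b1, (1, -1, 0), 25.0)           # 45-degree branches
        b.chain_dir(b2, (1, 1, 0), 25.0)
        st = b.segment_tree()
        out, rep = run_step3(st, None, thresholds)
        assert rep.entries == []
        assert set(out.source.nodes) == set(st.source.nodes)

    def test_h_prioritized_over_x_on_ambiguous_structure(self, thresholds):
        # the link's children are a wide leaf pair (H applies) AND one of
        # them forms a >t_beta angle with a brother (X would also apply)
        b = TreeBuilder(root=(-20, 0, 0))
        b1 = b.chain_dir(1, (1, 0, 0), 20.0)
        brother = b.chain_dir(b1, (0, -1, 0.05), 20.0)   # brother leaf
        j2 = b.chain_dir(b1, (1, 0.3, 0), 3.0)           # link
        b.chain_dir(j2, (0, 1, 0.05), 18.0)              # child opposite brother
        b.chain_dir(j2, (0.2, -1, 0), 18.0)              # wide pair partner
        st = b.segment_tree()
        xh = [c for c in find_crossing_structures(st, thresholds)
              if c.model == "XH"][0]
        assert prune_H(st, xh, thresholds)[0] == "remove"
        assert prune_X(st, xh, thresholds)[0] == "remove"
        out, rep = run_step3(st, None, thresholds)
        models = [e.model for e in rep.entries]
        assert "H" in models
        # H semantics: the link is removed, the brother at b1 survives
        assert any(e.seg_id == xh.link_seg for e in rep.entries)
        assert brother in out.source.nodes


class TestPseudoX:
    def _z_segment(self):
        b = TreeBuilder()
        p1 = b.chain_dir(1, (1, 0, 0), 30.0)
        p2 = b.chain_dir(p1, (-np.cos(np.radians(45)),
                              np.sin(np.radians(45)), 0), 8.0)
        b.chain_dir(p2, (1, 0, 0), 30.0)
        return b.segment_tree()

    def test_z_jump_excised_and_spliced(self, thresholds):
        st = self._z_segment()
        assert len(st.segments) == 1
        out, rep = prune_single_segment_inflections(st, thresholds)
        assert len(rep.entries) == 1
        assert rep.entries[0].model == "pseudoX"
        assert len(out.source.nodes) < len(st.source.nodes)
        # the distal run survives, re-attached across the excision
        xs = [out.coords[n][0] for n in out.source.nodes]
        assert max(xs) == pytest.approx(max(st.coords[n][0]
                                            for n in st.source.nodes), abs=1e-6)
        again, rep2 = prune_single_segment_inflections(out, thresholds)
        assert rep2.entries == []

    def test_smooth_arc_unchanged(self, thresholds):
        b = TreeBuilder()
        last = 1
        ang = 0.0
        for _ in range(40):
            ang += 4.0  # gentle 4-degree turns
            last = b.chain_dir(last, _deg_dir(ang), 2.0)
        st = b.segment_tree()
        out, rep = prune_single_segment_inflections(st, thresholds)
        assert rep.entries == []
        assert set(out.source.nodes) == set(st.source.nodes)

    def test_single_kink_is_not_a_pseudo_x(self, thresholds):
        b = TreeBuilder()
        p1 = b.chain_dir(1, (1, 0, 0), 30.0)
        b.chain_dir(p1, (-np.cos(np.radians(45)), np.sin(np.radians(45)), 0),
                    30.0)
        st = b.segment_tree()
        out, rep = prune_single_segment_inflections(st, thresholds)
        assert rep.entries == []


class TestRunStep3:
    def test_clean_arbor_identity(self, thresholds):
        _, st, _ = generate_arbor(ArborSpec(seed=2, n_tips=8))
        out, rep = run_step3(st, None, thresholds)
        assert rep.entries == []
        assert set(out.source.nodes) == set(st.source.nodes)

    def test_injected_crossings_removed_arbor_intact(self, thresholds):
        tree, _, _ = generate_arbor(ArborSpec(seed=4, n_tips=10))
        corrupted, cst, tr = inject_errors(tree, ErrorSpec(c3_count=2,
                                                           c4_count=2, seed=4))
        out, rep = run_step3(cst, None, thresholds)
        foreign = tr.nodes_of("C3") | tr.nodes_of("C4")
        removed = set(cst.source.nodes) - set(out.source.nodes)
        assert len(removed & foreign) / len(foreign) >= 0.8
        assert len(removed - foreign) / max(len(removed), 1) <= 0.1

    def test_idempotent_and_prune_only(self, thresholds):
        for seed in (5, 6):
            tree, _, _ = generate_arbor(ArborSpec(seed=seed, n_tips=8))
            corrupted, cst, _ = inject_errors(tree, ErrorSpec(c3_count=1,
                                                              c4_count=1,
                                                              seed=seed))
            once, _ = run_step3(cst, None, thresholds)
            assert set(once.source.nodes) <= set(cst.source.nodes)
            twice, rep2 = run_step3(once, None, thresholds)
            assert rep2.entries == []
            assert set(twice.source.nodes) == set(once.source.nodes)
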