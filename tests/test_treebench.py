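"""DIADEM-style matching, decomposed scores, cohort yield, seed scoring."""

import numpy as np
import pytest

from neuroskel import treebench as tb
from neuroskel.seed_segment import SeedInstance, SeedSet
from neuroskel.skeletonize import SkeletonTree, standardize
from neuroskel.treebench import MatchParams


def build_tree(rows):
    """rows: (id, type, (x, y, z), radius, parent)"""
    ids, types, xyz, radius, parent = zip(*rows)
    return SkeletonTree(list(ids), list(types), [list(p) for p in xyz], list(radius), list(parent))


def symmetric_tree():
    """Root with two symmetric subtrees: each an edge chain to one terminal."""
    return standardize(build_tree([
        (1, 1, (0, 0, 0), 2.0, -1),
        (2, 3, (10, 0, 0), 1.0, 1),
        (3, 3, (20, 0, 0), 1.0, 2),
        (4, 3, (-10, 0, 0), 1.0, 1),
        (5, 3, (-20, 0, 0), 1.0, 4),
    ]))


def comb_tree(n_leaves=5, step=20.0):
    """A backbone with one terminal twig per backbone node (n_leaves leaves)."""
    rows = [(1, 1, (0.0, 0.0, 0.0), 2.0, -1)]
    nid = 1
    prev_backbone = 1
    for k in range(n_leaves):
        nid += 1
        backbone = nid
        rows.append((backbone, 3, ((k + 1) * step, 0.0, 0.0), 1.0, prev_backbone))
        nid += 1
        rows.append((nid, 3, ((k + 1) * step, step, 0.0), 1.0, backbone))
        prev_backbone = backbone
    return standardize(build_tree(rows))


def delete_nodes(tree, drop_ids):
    keep = [k for k in range(tree.n_nodes) if int(tree.ids[k]) not in drop_ids]
    sub = SkeletonTree(
        tree.ids[keep], tree.types[keep], tree.xyz[keep], tree.radius[keep],
        [(-1 if int(p) in drop_ids else int(p)) for p in tree.parent[keep]],
    )
    return sub


class TestMatchNodes:
    def test_identical_trees_fully_matched(self):
        t = comb_tree()
        m = tb.match_nodes(t, t.copy())
        assert len(m.pairs) == t.n_nodes
        assert m.unmatched_gold == [] and m.unmatched_test == []
        assert all(g == x for g, x in m.pairs)

    def test_far_translation_gives_zero_matches(self):
        t = comb_tree()
        shifted = t.copy()
        shifted.xyz = shifted.xyz + 3 * MatchParams().dist_threshold
        m = tb.match_nodes(t, shifted)
        assert m.pairs == []

    def test_displaced_node_fails_ancestor_criterion(self):
        """A test node moved onto a different branch is rejected even though
        it sits within the distance gate of its gold twin."""
        gold = standardize(build_tree([
            (1, 1, (0, 0, 0), 1.0, -1),
            (2, 3, (30, 0, 0), 1.0, 1),     # A
            (3, 3, (30, 6, 0), 1.0, 2),     # B: on branch via A
            (4, 3, (30, 12, 0), 1.0, 3),    # C
            (5, 3, (-30, 0, 0), 1.0, 1),    # other branch
            (6, 3, (-30, 6, 0), 1.0, 5),
        ]))
        # test copy, but B re-parented onto the far branch with a long path
        test = standardize(build_tree([
            (1, 1, (0, 0, 0), 1.0, -1),
            (2, 3, (30, 0, 0), 1.0, 1),
            (4, 3, (30, 12, 0), 1.0, 2),
            (5, 3, (-30, 0, 0), 1.0, 1),
            (6, 3, (-30, 6, 0), 1.0, 5),
            (3, 3, (30, 6, 0), 1.0, 6),    # B now hangs off the far branch
        ]))
        m = tb.match_nodes(gold, test)
        g2t = m.gold_to_test()
        gold_b = int(np.where(np.all(gold.xyz == [30, 6, 0], axis=1))[0][0])
        # brute-force check of the three criteria confirms no valid pairing
        assert gold_b not in g2t

    def test_empty_gold_is_error_empty_test_unmatched(self):
        t = comb_tree()
        empty = SkeletonTree([], [], np.empty((0, 3)), [], [])
        with pytest.raises(ValueError):
            tb.match_nodes(empty, t)
        m = tb.match_nodes(t, empty)
        assert m.pairs == []
        assert m.unmatched_gold == list(range(t.n_nodes))


class TestDiadem:
    def test_identical_trees_score_exactly_one(self):
        for t in (symmetric_tree(), comb_tree()):
            assert tb.diadem_score(t, t.copy()) == 1.0

    def test_unmatched_everything_scores_zero(self):
        t = comb_tree()
        shifted = t.copy()
        shifted.xyz = shifted.xyz + 100.0
        assert tb.diadem_score(t, shifted) == 0.0

    def test_missing_symmetric_subtree_scores_half(self):
        gold = symmetric_tree()
        # drop the subtree at x<0 (nodes with negative x)
        drop = {int(gold.ids[k]) for k in range(gold.n_nodes) if gold.xyz[k, 0] < 0}
        test = standardize(delete_nodes(gold, drop))
        assert tb.diadem_score(gold, test) == pytest.approx(0.5)

    def test_leaf_subtree_removal_costs_its_weight(self):
        gold = comb_tree(4)
        from neuroskel.treebench import _subtree_terminal_counts, _branch_indices, _leaf_indices

        w = _subtree_terminal_counts(gold)
        crit = np.concatenate([_branch_indices(gold), _leaf_indices(gold)])
        total = w[crit].sum()
        # remove the most distal twig (a single terminal)
        leaf_idx = int(_leaf_indices(gold)[-1])
        test = standardize(delete_nodes(gold, {int(gold.ids[leaf_idx])}))
        expected = (total - 1) / total
        assert tb.diadem_score(gold, test) == pytest.approx(expected)

    def test_no_critical_nodes_is_error(self):
        single = build_tree([(1, 1, (0, 0, 0), 1.0, -1)])
        with pytest.raises(ValueError):
            tb.diadem_score(single, single)


class TestDecomposed:
    def test_identical_trees_all_ones(self):
        t = comb_tree()
        s = tb.decomposed_scores(t, t.copy())
        assert s.topology == 1.0 and s.recall == 1.0 and s.branch == 1.0
        assert s.leaf == 1.0 and s.direction == 1.0 and s.precision == 1.0

    def test_deleting_leaves_lowers_leaf_fraction(self):
        gold = comb_tree(5)
        from neuroskel.treebench import _leaf_indices

        leaves = _leaf_indices(gold)
        drop = {int(gold.ids[i]) for i in leaves[:2]}
        test = standardize(delete_nodes(gold, drop))
        s = tb.decomposed_scores(gold, test)
        assert s.leaf == pytest.approx(3 / 5)
        assert s.recall == pytest.approx((gold.n_nodes - 2) / gold.n_nodes)

    def test_reversed_parent_direction_counted(self):
        """Two branch nodes; the test places one branch node's parent on the
        opposite side, flipping its parent vector: direction drops to 1/2."""
        gold = standardize(build_tree([
            (1, 1, (0, 0, 0), 1.0, -1),
            (2, 3, (7, 0, 0), 1.0, 1),
            (3, 3, (12, 0, 0), 1.0, 2),    # branch A
            (4, 3, (18, 0, 0), 1.0, 3),
            (5, 3, (12, 6, 0), 1.0, 3),
            (6, 3, (0, 7, 0), 1.0, 1),
            (7, 3, (0, 12, 0), 1.0, 6),    # branch B
            (8, 3, (0, 18, 0), 1.0, 7),
            (9, 3, (-6, 12, 0), 1.0, 7),
        ]))
        test = standardize(build_tree([
            (1, 1, (0, 0, 0), 1.0, -1),
            (2, 3, (12.5, 0, 0), 1.0, 1),  # now on the far side of branch A
            (3, 3, (12, 0, 0), 1.0, 2),
            (4, 3, (18, 0, 0), 1.0, 3),
            (5, 3, (12, 6, 0), 1.0, 3),
            (6, 3, (0, 7, 0), 1.0, 1),
            (7, 3, (0, 12, 0), 1.0, 6),
            (8, 3, (0, 18, 0), 1.0, 7),
            (9, 3, (-6, 12, 0), 1.0, 7),
        ]))
        s = tb.decomposed_scores(gold, test)
        assert s.branch == 1.0  # both branch nodes matched
        assert s.direction == pytest.approx(0.5)

    def test_monotone_degradation(self):
        gold = comb_tree(5)
        s_full = tb.decomposed_scores(gold, gold.copy())
        from neuroskel.treebench import _leaf_indices

        test = standardize(delete_nodes(gold, {int(gold.ids[_leaf_indices(gold)[0]])}))
        s_del = tb.decomposed_scores(gold, test)
        assert s_del.recall <= s_full.recall
        assert s_del.leaf <= s_full.leaf


class TestCohortYield:
    def test_all_equal_scores_full_yield(self):
        assert tb.cohort_yield([0.7, 0.7, 0.7]) == 1.0

    def test_hand_computed_example(self):
        # mean .75, sample SD .5; all scores within 2 SD
        assert tb.cohort_yield([1, 1, 1, 0]) == 1.0

    def test_ten_scores_one_outlier(self):
        scores = [1, 1, 1, 1, 1, 1, 1, 1, 1, 0]
        mean = np.mean(scores)
        sd = np.std(scores, ddof=1)
        expected = np.mean([abs(s - mean) <= 2 * sd for s in scores])
        assert tb.cohort_yield(scores) == pytest.approx(expected)

    def test_fewer_than_two_is_error(self):
        with pytest.raises(ValueError):
            tb.cohort_yield([1.0])


class TestScoreSeeds:
    def _seedset(self, positions):
        insts = [
            SeedInstance(i + 1, np.zeros((1, 3), int), np.zeros((1, 3), int), tuple(p), 5.0)
            for i, p in enumerate(positions)
        ]
        return SeedSet(insts, (100, 100, 100), (1, 1, 1))

    def test_perfect_detection(self):
        gold = [((10, 10, 10), 5.0), ((50, 50, 50), 5.0)]
        det = self._seedset([(10, 10, 10), (50, 50, 50)])
        recall, precision, f1 = tb.score_seeds(det, gold)
        assert (recall, precision, f1) == (1.0, 1.0, 1.0)

    def test_spurious_detections_halve_precision(self):
        gold = [((10, 10, 10), 5.0), ((40, 40, 40), 5.0), ((70, 70, 70), 5.0)]
        det = self._seedset(
            [(10, 10, 10), (40, 40, 40), (70, 70, 70), (5, 90, 5), (90, 5, 90), (90, 90, 5)]
        )
        recall, precision, f1 = tb.score_seeds(det, gold)
        assert recall == 1.0
        assert precision == 0.5

    def test_one_radius_tolerance_boundary(self):
        gold = [((50, 50, 50), 10.0)]
        inside = self._seedset([(50, 50, 59)])  # 9 um away = 0.9 radii
        outside = self._seedset([(50, 50, 61)])  # 11 um away = 1.1 radii
        assert tb.score_seeds(inside, gold)[0] == 1.0
        assert tb.score_seeds(outside, gold)[0] == 0.0

    def test_empty_detections(self):
        recall, precision, f1 = tb.score_seeds(self._seedset([]), [((1, 1, 1), 2.0)])
        assert recall == 0.0
        assert precision is None and f1 is None

    def test_empty_gold_rejected(self):
        with pytest.raises(ValueError):
            tb.score_seeds(self._seedset([(1, 1, 1)]), [])


class TestScoreForests:
    def test_best_score_pairing_beats_fragments(self):
        gold = comb_tree(4)
        # a junk single-node tree rooted exactly at the gold root
        junk = build_tree([(1, 1, tuple(gold.xyz[gold.root_index()]), 1.0, -1)])
        real = gold.copy()
        real.xyz = real.xyz + 0.5  # slightly off but structurally right
        df = tb.score_forests([gold], [standardize(junk), standardize(real)], MatchParams())
        assert df.iloc[0]["topology"] > 0.9
        assert df.iloc[0]["test_tree"] == 1
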