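"""Skeleton accuracy metrics: DIADEM-style matching and decomposed scores.

The aggregate topology score follows the three-step DIADEM matching
procedure.  For each gold node:

1. candidate test nodes lie within a Euclidean ``dist_threshold`` (um);
2. a candidate must have a *matching ancestor*: some ancestor of the
   test node pairs with some ancestor of the gold node within the same
   threshold;
3. the path lengths gold-node -> gold-ancestor and test-node -> test-
   ancestor must agree within a relative ``path_tolerance``.

Conflicts are resolved greedily by smallest Euclidean distance and the
final matching is one-to-one.  The topology score then weights matched
gold *critical* nodes (branch + terminal nodes, the root excluded) by the
number of terminals in their subtree; identical trees score exactly 1.

The decomposed suite reports recall / branch / leaf / direction /
precision as plain fractions so the aggregate score's failure modes
(path breaks, collisions, misdirected branches) can be told apart.
Soma-detection scoring (recall / precision / F1 with a one-radius-width
tolerance) and the cohort yield statistic live here too.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .seed_segment import SeedSet
from .skeletonize import SkeletonTree

__all__ = [
    "MatchParams",
    "NodeMatch",
    "TreeScore",
    "match_nodes",
    "diadem_score",
    "decomposed_scores",
    "cohort_yield",
    "score_seeds",
    "score_forests",
]


@dataclass
class MatchParams:
    """Node matching tolerances: Euclidean gate (um) and relative path slack."""

    dist_threshold: float = 8.0
    path_tolerance: float = 0.2

    def __post_init__(self) -> None:
        if self.dist_threshold <= 0:
            raise ValueError("dist_threshold must be > 0")
        if not (0.0 < self.path_tolerance < 1.0):
            raise ValueError("path_tolerance must be in (0, 1)")


@dataclass
class NodeMatch:
    """One-to-one node correspondence between a gold and a test tree."""

    pairs: list[tuple[int, int]]  # (gold index, test index)
    unmatched_gold: list[int]
    unmatched_test: list[int]

    def gold_to_test(self) -> dict[int, int]:
        return dict(self.pairs)


@dataclass
class TreeScore:
    """Decomposed topological quality; fields are fractions in [0, 1].

    A category with no gold members (e.g. a tree without branch nodes)
    reports ``None`` (not applicable), never NaN.
    """

    topology: float
    recall: float
    branch: float | None
    leaf: float | None
    direction: float | None
    precision: float | None

    def as_dict(self) -> dict:
        return {
            "topology": self.topology,
            "recall": self.recall,
            "branch": self.branch,
            "leaf": self.leaf,
            "direction": self.direction,
            "precision": self.precision,
        }


# ---------------------------------------------------------------------------
# tree structure helpers


def _ancestors_with_path(tree: SkeletonTree):
    """Per node: list of (ancestor index, path length um) root-ward in order."""
    pidx = tree.parent_index()
    xyz = tree.xyz
    out = []
    for k in range(tree.n_nodes):
        acc = []
        u = k
        total = 0.0
        while pidx[u] != -1:
            p = int(pidx[u])
            total += float(np.linalg.norm(xyz[u] - xyz[p]))
            acc.append((p, total))
            u = p
        out.append(acc)
    return out


def _branch_indices(tree: SkeletonTree) -> np.ndarray:
    """Non-root nodes with >= 2 children."""
    counts = tree.children_counts()
    root = tree.root_index()
    idx = np.where(counts >= 2)[0]
    return idx[idx != root]


def _leaf_indices(tree: SkeletonTree) -> np.ndarray:
    """Non-root nodes with no children (terminals)."""
    counts = tree.children_counts()
    root = tree.root_index()
    idx = np.where(counts == 0)[0]
    return idx[idx != root]


def _subtree_terminal_counts(tree: SkeletonTree) -> np.ndarray:
    """Number of terminal nodes in each node's subtree (terminals count 1)."""
    pidx = tree.parent_index()
    counts = tree.children_counts()
    order = _topo_order(pidx)
    term = np.zeros(tree.n_nodes, np.int64)
    for u in reversed(order):
        if counts[u] == 0:
            term[u] = 1
    # accumulate child sums bottom-up
    for u in reversed(order):
        p = pidx[u]
        if p >= 0:
            term[p] += term[u]
    return term


def _topo_order(pidx: np.ndarray) -> list[int]:
    children: dict[int, list[int]] = {}
    roots = []
    for k, p in enumerate(pidx):
        if p == -1:
            roots.append(k)
        else:
            children.setdefault(int(p), []).append(k)
    order = []
    stack = list(reversed(roots))
    while stack:
        u = stack.pop()
        order.append(u)
        stack.extend(reversed(children.get(u, [])))
    return order


# ---------------------------------------------------------------------------
# matching


def _ancestor_consistent(
    g: int,
    t: int,
    gold_anc,
    test_anc,
    params: MatchParams,
    gold_xyz,
    test_xyz,
) -> bool:
    """Steps 2+3: some ancestor pair lies within the gate and agrees in path length."""
    ga = gold_anc[g]
    ta = test_anc[t]
    if not ga:
        return True  # gold root: distance criterion alone applies
    if not ta:
        return False
    for gi, glen in ga:
        for ti, tlen in ta:
            if np.linalg.norm(gold_xyz[gi] - test_xyz[ti]) <= params.dist_threshold:
                longer = max(glen, tlen)
                if longer == 0.0 or abs(glen - tlen) <= params.path_tolerance * longer:
                    return True
    return False


def match_nodes(gold: SkeletonTree, test: SkeletonTree, params: MatchParams | None = None) -> NodeMatch:
    """One-to-one gold/test node matching under the three DIADEM criteria.

    Candidate pairs within the distance gate are screened by the
    matching-ancestor and path-length criteria; conflicts among the
    surviving candidates are resolved by a global one-to-one assignment
    that prefers smaller Euclidean distances (maximum-cardinality,
    minimum-total-distance), so a node never stays unmatched merely
    because a neighbor claimed its closest candidate first when an
    alternative existed for the neighbor.  An empty gold tree is an
    error; an empty test tree leaves every gold node unmatched.
    """
    if params is None:
        params = MatchParams()
    if gold.n_nodes == 0:
        raise ValueError("empty gold tree")
    if test.n_nodes == 0:
        return NodeMatch([], list(range(gold.n_nodes)), [])

    gx, tx = gold.xyz, test.xyz
    diff = gx[:, None, :] - tx[None, :, :]
    dist = np.linalg.norm(diff, axis=2)
    cand = np.argwhere(dist <= params.dist_threshold)

    gold_anc = _ancestors_with_path(gold)
    test_anc = _ancestors_with_path(test)

    # any unmatched pair costs far more than the worst total distance of a
    # full matching, so minimizing cost maximizes cardinality first
    forbidden = 1e9
    cost = np.full(dist.shape, forbidden)
    for g, t in cand:
        g, t = int(g), int(t)
        if _ancestor_consistent(g, t, gold_anc, test_anc, params, gx, tx):
            cost[g, t] = dist[g, t]
    from scipy.optimize import linear_sum_assignment

    rows, cols = linear_sum_assignment(cost)
    gold_used = np.zeros(gold.n_nodes, bool)
    test_used = np.zeros(test.n_nodes, bool)
    pairs: list[tuple[int, int]] = []
    for g, t in zip(rows, cols):
        if cost[g, t] < forbidden:
            pairs.append((int(g), int(t)))
            gold_used[g] = True
            test_used[t] = True
    pairs.sort()
    return NodeMatch(
        pairs,
        [int(i) for i in np.where(~gold_used)[0]],
        [int(i) for i in np.where(~test_used)[0]],
    )


def diadem_score(gold: SkeletonTree, test: SkeletonTree, params: MatchParams | None = None) -> float:
    """Aggregate topology similarity in [0, 1]; 1 for a perfect match.

    Score = matched weight / total weight over gold *critical* nodes
    (branch + terminal nodes, root excluded), each weighted by the number
    of terminals in its subtree.
    """
    if params is None:
        params = MatchParams()
    crit = np.concatenate([_branch_indices(gold), _leaf_indices(gold)])
    if len(crit) == 0:
        raise ValueError("gold tree has no critical (branch or terminal) nodes")
    weights = _subtree_terminal_counts(gold)
    match = match_nodes(gold, test, params)
    matched = set(g for g, _ in match.pairs)
    total = float(weights[crit].sum())
    got = float(sum(weights[c] for c in crit if int(c) in matched))
    return got / total


def decomposed_scores(gold: SkeletonTree, test: SkeletonTree, params: MatchParams | None = None) -> TreeScore:
    """Recall / branch / leaf / direction / precision alongside the topology score.

    direction: among *matched* gold branch nodes, the fraction whose test
    node's parent-pointing unit vector has positive dot product with the
    gold node's.  Categories without gold members report None.
    """
    if params is None:
        params = MatchParams()
    match = match_nodes(gold, test, params)
    g2t = match.gold_to_test()
    matched = set(g2t)

    recall = len(matched) / gold.n_nodes
    precision = (len(matched) / test.n_nodes) if test.n_nodes else None

    def _fraction(indices: np.ndarray) -> float | None:
        if len(indices) == 0:
            return None
        return sum(1 for i in indices if int(i) in matched) / len(indices)

    b_idx = _branch_indices(gold)
    branch = _fraction(b_idx)
    leaf = _fraction(_leaf_indices(gold))

    gold_pidx = gold.parent_index()
    test_pidx = test.parent_index()
    matched_branches = [int(i) for i in b_idx if int(i) in matched]
    if matched_branches:
        good = 0
        usable = 0
        for g in matched_branches:
            t = g2t[g]
            gp, tp = int(gold_pidx[g]), int(test_pidx[t])
            if gp == -1 or tp == -1:
                continue
            gv = gold.xyz[gp] - gold.xyz[g]
            tv = test.xyz[tp] - test.xyz[t]
            gn, tn = np.linalg.norm(gv), np.linalg.norm(tv)
            if gn == 0 or tn == 0:
                continue
            usable += 1
            if float(np.dot(gv / gn, tv / tn)) > 0:
                good += 1
        direction = (good / usable) if usable else None
    else:
        direction = None

    topology = diadem_score(gold, test, params) if len(np.concatenate([b_idx, _leaf_indices(gold)])) else 0.0
    return TreeScore(topology, recall, branch, leaf, direction, precision)


# ---------------------------------------------------------------------------
# cohort and seed scoring


def cohort_yield(scores) -> float:
    """Fraction of topology scores within 2 sample standard deviations of the mean."""
    scores = np.asarray(list(scores), float)
    if len(scores) < 2:
        raise ValueError("cohort_yield needs at least 2 scores")
    mean = scores.mean()
    sd = scores.std(ddof=1)
    return float(np.mean(np.abs(scores - mean) <= 2.0 * sd))


def score_seeds(detected: SeedSet | list, gold: list[tuple]) -> tuple[float, float | None, float | None]:
    """Seed-detection (recall, precision, F1) with one-radius-width tolerance.

    ``gold`` is a list of ((z, y, x) um, radius um).  A detection matches
    a gold soma iff their centre distance is at most the gold radius;
    matching is greedy nearest, one-to-one.  Empty detections give recall
    0 and a not-applicable precision/F1.
    """
    if not gold:
        raise ValueError("gold seed list must be non-empty")
    if isinstance(detected, SeedSet):
        det_pos = [np.asarray(s.centroid_um, float) for s in detected]
    else:
        det_pos = [np.asarray(p, float) for p in detected]
    if not det_pos:
        return 0.0, None, None

    gold_pos = [np.asarray(p, float) for p, _ in gold]
    gold_rad = [float(r) for _, r in gold]
    claims = []
    for di, d in enumerate(det_pos):
        for gi, g in enumerate(gold_pos):
            dist = float(np.linalg.norm(d - g))
            if dist <= gold_rad[gi]:
                claims.append((dist, di, gi))
    claims.sort()
    det_used = set()
    gold_used = set()
    tp = 0
    for dist, di, gi in claims:
        if di in det_used or gi in gold_used:
            continue
        det_used.add(di)
        gold_used.add(gi)
        tp += 1
    recall = tp / len(gold_pos)
    precision = tp / len(det_pos)
    f1 = (2 * recall * precision / (recall + precision)) if (recall + precision) else 0.0
    return recall, precision, f1


def score_forests(
    gold_trees: list[SkeletonTree],
    test_trees: list[SkeletonTree],
    params: MatchParams | None = None,
) -> pd.DataFrame:
    """Score each gold tree against its best-matching test tree.

    Pairing is greedy one-to-one by descending topology score (ties by
    ascending root-to-root distance), so fragment or artifact trees
    whose roots happen to sit near a gold soma cannot displace the real
    reconstruction.  A gold tree with no paired test tree scores 0
    across the board.  Returns one row per gold tree.
    """
    if params is None:
        params = MatchParams()
    claims = []
    for gi, g in enumerate(gold_trees):
        groot = g.xyz[g.root_index()]
        for ti, t in enumerate(test_trees):
            troot = t.xyz[t.root_index()]
            dist = float(np.linalg.norm(groot - troot))
            topo = diadem_score(g, t, params)
            claims.append((-topo, dist, gi, ti))
    claims.sort()
    pair: dict[int, int] = {}
    test_used: set[int] = set()
    for neg_topo, dist, gi, ti in claims:
        if gi in pair or ti in test_used:
            continue
        pair[gi] = ti
        test_used.add(ti)

    rows = []
    for gi, g in enumerate(gold_trees):
        if gi in pair:
            score = decomposed_scores(g, test_trees[pair[gi]], params)
            row = score.as_dict()
            row["test_tree"] = pair[gi]
        else:
            row = {
                "topology": 0.0,
                "recall": 0.0,
                "branch": None,
                "leaf": None,
                "direction": None,
                "precision": None,
                "test_tree": None,
            }
        row["gold_tree"] = gi
        rows.append(row)
    return pd.DataFrame(rows)
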