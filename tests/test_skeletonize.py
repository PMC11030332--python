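"""Surface graphs, coarsening, local separators, tree building, standardization."""

import numpy as np
import pytest

from neuroskel import cell_segment as cs
from neuroskel import skeletonize as sk
from neuroskel.sparse_grid import SparseMask
from neuroskel.skeletonize import SkeletonTree, SurfaceGraph

from conftest import make_ball, make_tube_x, single_seed_set, random_connected_mask


def graph_from_edges(n, edges, positions):
    adjacency = [set() for _ in range(n)]
    for u, v in edges:
        adjacency[u].add(v)
        adjacency[v].add(u)
    return SurfaceGraph(np.asarray(positions, float), np.ones(n), adjacency, (1, 1, 1))


def path_graph(n, spacing=1.0):
    return graph_from_edges(
        n, [(i, i + 1) for i in range(n - 1)], [[0, 0, i * spacing] for i in range(n)]
    )


def instance_from(arr):
    return cs.CellInstance.from_mask(1, SparseMask(arr), (1,))


def tree_stats(tree: SkeletonTree):
    cc = tree.children_counts()
    root = tree.root_index()
    idx = np.arange(tree.n_nodes)
    branches = int(((cc >= 2) & (idx != root)).sum())
    leaves = int(((cc == 0) & (idx != root)).sum())
    return branches, leaves


class TestSurfaceToGraph:
    def test_solid_cube_gives_26_connected_vertices(self):
        arr = np.zeros((5, 5, 5), bool)
        arr[1:4, 1:4, 1:4] = True
        g = sk.surface_to_graph(instance_from(arr))
        assert g.n_vertices == 26
        assert g.n_components() == 1

    def test_single_voxel(self):
        arr = np.zeros((3, 3, 3), bool)
        arr[1, 1, 1] = True
        g = sk.surface_to_graph(instance_from(arr))
        assert g.n_vertices == 1
        assert len(g.edges()) == 0

    def test_edges_match_pairwise_adjacency_oracle(self, rng):
        arr = random_connected_mask(rng, (8, 8, 8), 0.5)
        g = sk.surface_to_graph(instance_from(arr))
        coords = np.argwhere(arr & _surface_of(arr))
        expected = set()
        for i in range(len(coords)):
            for j in range(i + 1, len(coords)):
                if np.max(np.abs(coords[i] - coords[j])) == 1:
                    expected.add((i, j))
        got = {tuple(e) for e in g.edges()}
        assert got == expected

    def test_positions_in_um(self):
        arr = np.zeros((3, 3, 3), bool)
        arr[1, 1, 1] = True
        inst = cs.CellInstance.from_mask(1, SparseMask(arr, (2.0, 0.5, 0.5)), (1,))
        g = sk.surface_to_graph(inst)
        assert np.allclose(g.positions[0], [2.0, 0.5, 0.5])

    def test_empty_instance_rejected(self):
        with pytest.raises(ValueError):
            sk.surface_to_graph(instance_from(np.zeros((3, 3, 3), bool)))


def _surface_of(arr):
    from neuroskel import sparse_grid

    return sparse_grid.extract_surface(SparseMask(arr)).data


class TestCoarsen:
    def test_zero_steps_identity(self):
        g = path_graph(6)
        out = sk.coarsen(g, 0)
        assert out.n_vertices == 6

    def test_component_count_preserved(self, rng):
        arr = random_connected_mask(rng, (10, 10, 10), 0.4)
        g = sk.surface_to_graph(instance_from(arr))
        before = g.n_components()
        for steps in (1, 2, 3):
            assert sk.coarsen(g, steps).n_components() == before

    def test_path8_one_step_perfect_matching(self):
        g = sk.coarsen(path_graph(8), 1)
        assert g.n_vertices == 4
        # contracted pairs sit at the midpoints of (0,1), (2,3), (4,5), (6,7)
        assert np.allclose(sorted(g.positions[:, 2]), [0.5, 2.5, 4.5, 6.5])
        assert np.all(g.weights == 2)

    def test_halving_bound(self, rng):
        arr = random_connected_mask(rng, (10, 10, 10), 0.5)
        g = sk.surface_to_graph(instance_from(arr))
        g1 = sk.coarsen(g, 1)
        assert g1.n_vertices >= (g.n_vertices + 1) // 2

    def test_weight_conservation(self, rng):
        arr = random_connected_mask(rng, (8, 8, 8), 0.5)
        g = sk.surface_to_graph(instance_from(arr))
        g2 = sk.coarsen(g, 2)
        assert g2.weights.sum() == g.weights.sum()


class TestLocalSeparators:
    def test_path_middle_vertex_is_separator(self):
        g = path_graph(7)
        sep = sk.find_local_separator(g, 3)
        assert sep is not None and sep.vertices == (3,)
        # removal yields two components
        assert sk._globally_separates({3}, g.adjacency)

    def test_star_hub_is_separator(self):
        g = graph_from_edges(4, [(0, 1), (0, 2), (0, 3)], [[0, 0, 0], [0, 0, 1], [0, 1, 0], [1, 0, 0]])
        sep = sk.find_local_separator(g, 0)
        assert sep is not None and sep.vertices == (0,)

    def test_complete_graph_has_no_separator(self):
        edges = [(i, j) for i in range(4) for j in range(i + 1, 4)]
        g = graph_from_edges(4, edges, [[0, 0, 0], [0, 0, 1], [0, 1, 0], [1, 0, 0]])
        for seed in range(4):
            assert sk.find_local_separator(g, seed) is None

    def test_separator_radius_and_centroid(self):
        g = path_graph(7, spacing=2.0)
        sep = sk.find_local_separator(g, 3)
        assert np.allclose(sep.centroid, [0, 0, 6.0])
        assert sep.radius == 0.0  # single vertex

    def test_collect_covers_tube_with_rings(self):
        arr = make_tube_x((16, 16, 50), 8, 8, 3, 4, 46)
        g = sk.coarsen(sk.surface_to_graph(instance_from(arr)), 2)
        cands = sk.collect_separators(g)
        assert len(cands) >= 4
        packed = sk.pack_separators(cands)
        # rings: radius close to the tube radius
        for sep in packed:
            assert 1.0 < sep.radius < 6.0


class TestPacking:
    def _sep(self, verts, centroid=(0.0, 0.0, 0.0)):
        return sk.Separator(tuple(verts), tuple(centroid), 1.0)

    def test_disjoint_candidates_all_kept(self):
        cands = [self._sep([0, 1]), self._sep([2, 3]), self._sep([4])]
        assert len(sk.pack_separators(cands)) == 3

    def test_overlap_resolved_smallest_first(self):
        a = self._sep([0, 1, 2])  # size 3
        b = self._sep([2, 3, 4, 5, 6])  # size 5, overlaps a
        c = self._sep([7, 8, 9, 10])  # size 4, disjoint
        kept = sk.pack_separators([b, a, c])
        assert [set(s.vertices) for s in kept] == [{0, 1, 2}, {7, 8, 9, 10}]

    def test_empty_candidates(self):
        assert sk.pack_separators([]) == []


class TestBuildTrees:
    def test_cylinder_gives_path_tree(self):
        arr = make_tube_x((20, 20, 70), 10, 10, 3, 5, 65)
        inst = instance_from(arr)
        seeds = single_seed_set(inst.mask, (10, 10, 5))
        tree = sk.skeletonize_instance(inst, seeds, coarsen_steps=2)[0]
        branches, leaves = tree_stats(tree)
        assert branches == 0
        assert leaves == 1
        # mean node radius within 30% of the true cylinder radius; nodes near axis
        mid = (tree.xyz[:, 0] > 12) & (tree.xyz[:, 0] < 58)  # x in SWC order
        assert abs(tree.radius[mid].mean() - 3.0) < 0.9
        dev = np.sqrt((tree.xyz[mid, 1] - 10) ** 2 + (tree.xyz[mid, 2] - 10) ** 2)
        assert dev.max() <= 1.5

    def test_sphere_gives_single_node(self):
        arr = make_ball((24, 24, 24), (12, 12, 12), 8)
        inst = instance_from(arr)
        seeds = single_seed_set(inst.mask, (12, 12, 4))
        tree = sk.skeletonize_instance(inst, seeds)[0]
        assert tree.n_nodes == 1
        assert np.allclose(tree.xyz[0], [12, 12, 12], atol=1.0)
        assert tree.radius[0] == pytest.approx(8.0, abs=1.5)

    def test_y_phantom_topology(self):
        zz, yy, xx = np.mgrid[0:40, 0:60, 0:60]
        trunk = ((zz - 20) ** 2 + (yy - 30) ** 2 <= 6.25) & (xx >= 5) & (xx <= 30)
        arm1 = ((zz - 20) ** 2 + (yy - (30 + (xx - 30) * 0.8)) ** 2 <= 6.25) & (xx > 30) & (xx <= 50) & (yy >= 30)
        arm2 = ((zz - 20) ** 2 + (yy - (30 - (xx - 30) * 0.8)) ** 2 <= 6.25) & (xx > 30) & (xx <= 50) & (yy < 30)
        inst = instance_from(trunk | arm1 | arm2)
        seeds = single_seed_set(inst.mask, (20, 30, 5))
        tree = sk.skeletonize_instance(inst, seeds)[0]
        branches, leaves = tree_stats(tree)
        assert branches == 1
        assert leaves == 2
        # rooted at the trunk end nearest the seed
        assert tree.xyz[tree.root_index(), 0] < 15

    def test_nodes_stay_inside_shape_envelope(self):
        arr = make_tube_x((20, 20, 50), 10, 10, 3, 5, 45)
        inst = instance_from(arr)
        seeds = single_seed_set(inst.mask, (10, 10, 5))
        tree = sk.skeletonize_instance(inst, seeds)[0]
        coords = np.argwhere(arr).astype(float)
        for k in range(tree.n_nodes):
            p = tree.xyz[k][::-1]  # zyx
            d = np.linalg.norm(coords - p, axis=1).min()
            assert d <= max(tree.radius[k], 2 * np.sqrt(3))

    def test_multi_seed_cluster_splits_nodes(self):
        arr = make_tube_x((14, 14, 60), 7, 7, 2.5, 3, 57)
        inst = cs.CellInstance.from_mask(1, SparseMask(arr), (1, 2))
        from neuroskel.seed_segment import SeedInstance, SeedSet

        s1 = SeedInstance(1, np.array([[7, 7, 3]]), np.array([[7, 7, 3]]), (7.0, 7.0, 3.0), 2.0)
        s2 = SeedInstance(2, np.array([[7, 7, 57]]), np.array([[7, 7, 57]]), (7.0, 7.0, 57.0), 2.0)
        seeds = SeedSet([s1, s2], arr.shape, (1, 1, 1))
        trees = sk.skeletonize_instance(inst, seeds)
        assert len(trees) == 2
        # nodes are partitioned, never duplicated
        n_nodes = sum(t.n_nodes for t in trees)
        all_pos = np.vstack([t.xyz for t in trees])
        assert len(np.unique(all_pos, axis=0)) == n_nodes


class TestStandardize:
    def _tree(self, rows):
        ids, types, xyz, radius, parent = [], [], [], [], []
        for r in rows:
            ids.append(r[0]); types.append(r[1]); xyz.append(r[2]); radius.append(r[3]); parent.append(r[4])
        return SkeletonTree(ids, types, xyz, radius, parent)

    def test_idempotent_on_standard_tree(self):
        t = self._tree([
            (1, 1, (0, 0, 0), 2.0, -1),
            (2, 3, (1, 0, 0), 1.0, 1),
            (3, 3, (2, 0, 0), 1.0, 2),
        ])
        s1 = sk.standardize(t)
        s2 = sk.standardize(s1)
        assert np.array_equal(s1.ids, s2.ids)
        assert np.array_equal(s1.parent, s2.parent)
        assert np.allclose(s1.xyz, s2.xyz)
        assert np.allclose(s1.radius, s2.radius)

    def test_child_before_parent_reordered(self):
        t = self._tree([
            (5, 3, (2, 0, 0), 1.0, 7),
            (7, 3, (1, 0, 0), 1.0, 9),
            (9, 1, (0, 0, 0), 2.0, -1),
        ])
        s = sk.standardize(t)
        assert list(s.ids) == [1, 2, 3]
        pidx = s.parent_index()
        assert all(pidx[k] < k for k in range(1, s.n_nodes))

    def test_coincident_nodes_merged_max_radius(self):
        t = self._tree([
            (1, 1, (0, 0, 0), 2.0, -1),
            (2, 3, (1, 0, 0), 1.0, 1),
            (3, 3, (1, 0, 0), 2.5, 2),  # coincides with node 2
            (4, 3, (2, 0, 0), 1.0, 3),
        ])
        s = sk.standardize(t)
        assert s.n_nodes == 3
        merged = s.radius[np.all(s.xyz == [1, 0, 0], axis=1)]
        assert merged[0] == 2.5

    def test_radius_floor(self):
        t = self._tree([(1, 1, (0, 0, 0), 0.01, -1), (2, 3, (1, 0, 0), 0.2, 1)])
        s = sk.standardize(t, min_radius=0.5)
        assert np.all(s.radius >= 0.5)

    def test_cycle_detected(self):
        t = self._tree([
            (1, 3, (0, 0, 0), 1.0, 2),
            (2, 3, (1, 0, 0), 1.0, 1),
        ])
        with pytest.raises(ValueError):
            sk.standardize(t)

    def test_multiple_roots_split_by_forest(self):
        t = self._tree([
            (1, 1, (0, 0, 0), 1.0, -1),
            (2, 3, (1, 0, 0), 1.0, 1),
            (3, 1, (9, 0, 0), 1.0, -1),
            (4, 3, (10, 0, 0), 1.0, 3),
        ])
        with pytest.raises(ValueError):
            sk.standardize(t)
        forest = sk.standardize_forest(t)
        assert len(forest) == 2
        assert all(f.n_nodes == 2 for f in forest)
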