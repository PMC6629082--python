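"""Simple-matching distance, neighbour joining and principal coordinates."""

import numpy as np
import pytest
from skbio import DistanceMatrix
from skbio.stats.ordination import pcoa as skbio_pcoa
from skbio.tree import nj as skbio_nj

from wheatpopgen.distance import (neighbor_joining, pcoa,
                                  simple_matching_distance,
                                  tree_path_distances)
from wheatpopgen.io import MISSING

from .conftest import make_matrix


class TestSimpleMatching:
    def test_identical_and_opposite_samples(self):
        doses = np.array([[0, 1, 2, 0], [0, 1, 2, 0], [2, 0, 1, 2]],
                         dtype=np.int8)
        dm = simple_matching_distance(make_matrix(doses))
        assert dm[0, 1] == pytest.approx(0.0)
        assert dm[0, 2] == pytest.approx(1.0)

    def test_hand_count_with_missing(self):
        # 10 loci, 4 mismatches among 8 comparable (2 missing in sample 2)
        s1 = np.array([0, 0, 0, 0, 2, 2, 2, 2, 0, 0], dtype=np.int8)
        s2 = np.array([2, 2, 2, 2, 2, 2, 2, 2, MISSING, MISSING],
                      dtype=np.int8)
        s3 = np.zeros(10, dtype=np.int8)
        dm = simple_matching_distance(make_matrix(np.vstack([s1, s2, s3])))
        assert dm[0, 1] == pytest.approx(0.5)

    def test_no_comparable_loci_is_error(self):
        doses = np.array([[0, MISSING], [MISSING, 0], [0, 0]], dtype=np.int8)
        with pytest.raises(ValueError, match="comparable"):
            simple_matching_distance(make_matrix(doses))


def random_additive_tree(rng, n_leaves):
    """Random binary tree with positive branch lengths and its leaf distances."""
    import itertools
    from skbio import TreeNode
    nodes = [TreeNode(name=f"L{i}", length=float(rng.uniform(0.1, 1.0)))
             for i in range(n_leaves)]
    while len(nodes) > 3:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        parent = TreeNode(length=float(rng.uniform(0.1, 1.0)))
        parent.extend([nodes[i], nodes[j]])
        nodes = [nodes[k] for k in range(len(nodes)) if k not in (i, j)]
        nodes.append(parent)
    root = TreeNode()
    for nd in nodes:
        root.append(nd)
    return root, root.tip_tip_distances()


class TestNeighborJoining:
    def test_four_taxon_additive_recovery(self):
        # tree ((A:1,B:2):1,(C:3,D:4)): split AB|CD with internal edge 1
        dm = DistanceMatrix(
            [[0, 3, 5, 6],
             [3, 0, 6, 7],
             [5, 6, 0, 7],
             [6, 7, 7, 0]], ids=list("ABCD"))
        tree = neighbor_joining(dm)
        back = tree_path_distances(tree)
        np.testing.assert_allclose(back.filter(dm.ids).data, dm.data,
                                   atol=1e-9)
        # exactly one internal edge, separating {A,B} from {C,D}
        internal = [n for n in tree.non_tips(include_self=False)]
        assert len(internal) == 1
        side = {t.name for t in internal[0].tips()}
        assert side in ({"A", "B"}, {"C", "D"})

    def test_ultrametric_three_taxa(self):
        dm = DistanceMatrix([[0, 2, 2], [2, 0, 2], [2, 2, 0]],
                            ids=list("ABC"))
        tree = neighbor_joining(dm)
        lengths = sorted(t.length for t in tree.tips())
        np.testing.assert_allclose(lengths, [1, 1, 1])

    def test_path_lengths_match_additive_input(self, rng):
        for n in (5, 8, 12):
            _, dm = random_additive_tree(rng, n)
            tree = neighbor_joining(DistanceMatrix(dm.data, ids=dm.ids))
            back = tree_path_distances(tree)
            np.testing.assert_allclose(back.filter(dm.ids).data, dm.data,
                                       atol=1e-9)

    def test_agrees_with_reference_nj_on_additive_input(self, rng):
        _, dm = random_additive_tree(rng, 10)
        dm = DistanceMatrix(dm.data, ids=dm.ids)
        ours = neighbor_joining(dm)
        ref = skbio_nj(dm)
        rf = ours.compare_rfd(ref)
        assert rf == 0.0

    def test_topology_invariant_to_input_permutation(self, rng):
        _, dm = random_additive_tree(rng, 9)
        perm = rng.permutation(len(dm.ids))
        dm_perm = DistanceMatrix(dm.data[np.ix_(perm, perm)],
                                 ids=[dm.ids[i] for i in perm])
        t1 = neighbor_joining(DistanceMatrix(dm.data, ids=dm.ids))
        t2 = neighbor_joining(dm_perm)
        assert t1.compare_rfd(t2) == 0.0

    def test_edge_count_and_small_input_rejed(self, rng):
        _, dm = random_additive_tree(rng, 7)
        tree = neighbor_joining(DistanceMatrix(dm.data, ids=dm.ids))
        n_edges = sum(1 for n in tree.traverse(include_self=False))
        assert n_edges == 2 * 7 - 3
        with pytest.raises(ValueError):
            neighbor_joining(DistanceMatrix([[0, 1], [1, 0]], ids=["a", "b"]))


class TestPcoa:
    def test_planar_points_reconstructed(self, rng):
        pts = rng.uniform(0, 10, size=(5, 2))
        D = np.sqrt(((pts[:, None, :] - pts[None, :, :]) ** 2).sum(-1))
        res = pcoa(DistanceMatrix(D, ids=list("abcde")), n_axes=2)
        back = np.sqrt(((res.coordinates[:, None, :]
                         - res.coordinates[None, :, :]) ** 2).sum(-1))
        np.testing.assert_allclose(back, D, atol=1e-9)
        np.testing.assert_allclose(res.coordinates.mean(axis=0), 0, atol=1e-9)

    def test_simplex_has_equal_eigenvalues(self):
        D = 1 - np.eye(4)
        res = pcoa(DistanceMatrix(D, ids=list("abcd")))
        np.testing.assert_allclose(res.eigenvalues,
                                   res.eigenvalues[0], rtol=1e-9)

    def test_agrees_with_reference_pcoa(self, rng):
        doses = rng.choice([0, 1, 2, MISSING], size=(12, 40),
                           p=[0.4, 0.1, 0.4, 0.1]).astype(np.int8)
        dm = simple_matching_distance(make_matrix(doses))
        ours = pcoa(dm, n_axes=3)
        ref = skbio_pcoa(dm, number_of_dimensions=3)
        ref_coords = ref.samples.to_numpy()
        for axis in range(3):
            a, b = ours.coordinates[:, axis], ref_coords[:, axis]
            assert min(np.abs(a - b).max(), np.abs(a + b).max()) < 1e-6

    def test_axis_request_truncated_to_positive_eigenvalues(self, rng):
        pts = rng.uniform(0, 1, size=(6, 2))
        D = np.sqrt(((pts[:, None, :] - pts[None, :, :]) ** 2).sum(-1))
        res = pcoa(DistanceMatrix(D, ids=list("abcdef")), n_axes=5)
        assert res.coordinates.shape[1] == 2


class TestSeparationProperties:
    def test_diverged_populations_separate_on_axis_one(self):
        from wheatpopgen.simulate import PanelSpec, generate_panel
        spec = PanelSpec(n_samples=80, n_loci=300, K=2, F=0.3, alpha=0.05,
                         missing_rate=0.05, seed=7)
        gm, _, truth = generate_panel(spec)
        labels = truth.Q.argmax(axis=1)
        dm = simple_matching_distance(gm)
        res = pcoa(dm, n_axes=1)
        x = res.coordinates[:, 0]
        from sklearn.metrics import silhouette_score
        assert silhouette_score(x.reshape(-1, 1), labels) > 0.5

    def test_tree_split_matches_strong_membership(self):
        from sklearn.metrics import adjusted_rand_score
        from wheatpopgen.simulate import PanelSpec, generate_panel
        from wheatpopgen.structure import assign_membership, run_admixture_mcmc
        spec = PanelSpec(n_samples=60, n_loci=200, K=2, F=0.3, alpha=0.05,
                         missing_rate=0.05, seed=13)
        gm, _, truth = generate_panel(spec)
        run = run_admixture_mcmc(gm, K=2, burn_in=500, iterations=1500, seed=4)
        members = assign_membership(run.Q, gm.sample_ids)
        strong = members["membership"] == "strong"
        from wheatpopgen.distance import main_split
        tree = neighbor_joining(simple_matching_distance(gm))
        inside = main_split(tree)
        tree_side = [s in inside for s in gm.sample_ids]
        ari = adjusted_rand_score(
            members.loc[strong, "subpopulation"],
            np.asarray(tree_side)[strong.to_numpy()])
        assert ari >= 0.9
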