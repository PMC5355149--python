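"""Min-max normalization and complete-linkage agglomeration."""

import itertools
import json

import numpy as np
import pandas as pd
import pytest
from scipy.cluster.hierarchy import cophenet, linkage

from metamine.clustering import (
    ClusterTree,
    export_heatmap_data,
    hierarchical_cluster,
    leaf_order,
    linear_normalize,
)


def naive_complete_linkage(X):
    """O(n^3) oracle: recompute the max pairwise distance between every pair
    of clusters at every step, same tie rule (smallest pair of lowest
    original row indices)."""
    n = len(X)
    dist = np.sqrt(((X[:, None, :] - X[None, :, :]) ** 2).sum(-1))
    clusters = {i: {i} for i in range(n)}
    merges = []
    next_id = n
    for _ in range(n - 1):
        best = None
        for a, b in itertools.combinations(sorted(clusters), 2):
            d = max(dist[i, j] for i in clusters[a] for j in clusters[b])
            key = (d, tuple(sorted((min(clusters[a]), min(clusters[b])))))
            if best is None or key < best[0]:
                best = (key, a, b)
        (d, _), a, b = best
        left, right = (a, b) if min(clusters[a]) <= min(clusters[b]) else (b, a)
        merges.append((left, right, float(d)))
        clusters[next_id] = clusters.pop(a) | clusters.pop(b)
        next_id += 1
    return merges


class TestLinearNormalize:
    def test_row_affine_map(self):
        out = linear_normalize(np.array([[0.0, 5.0, 10.0]]))
        assert np.allclose(out.to_numpy(), [[0.0, 0.5, 1.0]])

    def test_constant_row_maps_to_zeros(self):
        out = linear_normalize(np.array([[7.0, 7.0, 7.0]]))
        assert np.allclose(out.to_numpy(), 0.0)

    def test_unit_interval_row_unchanged(self):
        out = linear_normalize(np.array([[0.0, 1.0]]))
        assert np.allclose(out.to_numpy(), [[0.0, 1.0]])

    def test_global_mode(self):
        out = linear_normalize(np.array([[0.0, 2.0], [4.0, 8.0]]), mode="global")
        assert np.allclose(out.to_numpy(), [[0.0, 0.25], [0.5, 1.0]])

    def test_output_always_in_unit_interval(self):
        rng = np.random.default_rng(8)
        for mode in ("row", "global"):
            out = linear_normalize(rng.normal(size=(6, 4)) * 10, mode=mode).to_numpy()
            assert out.min() >= 0.0 and out.max() <= 1.0


class TestHierarchicalCluster:
    def test_single_row_error_names_the_minimum(self):
        with pytest.raises(ValueError, match="at least 2"):
            hierarchical_cluster(np.array([[1.0, 2.0]]))

    def test_three_row_example(self):
        # pairwise distances: d(0,1)=1, d(0,2)=sqrt(32), d(1,2)=5
        tree = hierarchical_cluster(np.array([[0.0, 0.0], [0.0, 1.0], [4.0, 4.0]]))
        first = tree.merges[0]
        assert (first[0], first[1]) == (0, 1) and first[2] == pytest.approx(1.0)

    def test_identical_rows_merge_first_at_zero(self):
        tree = hierarchical_cluster(np.array([[5.0, 5.0], [1.0, 1.0], [5.0, 5.0]]))
        assert tree.merges[0] == (0, 2, 0.0)

    def test_merge_sequence_equals_naive_oracle(self):
        rng = np.random.default_rng(31)
        for _ in range(100):
            n = int(rng.integers(3, 13))
            X = rng.random((n, 4))
            tree = hierarchical_cluster(X)
            assert [
                (l, r, pytest.approx(h, rel=1e-12)) for l, r, h in naive_complete_linkage(X)
            ] == tree.merges

    def test_ties_follow_the_naive_oracle_too(self):
        # grid points generate many equal distances
        X = np.array([[0, 0], [0, 1], [1, 0], [1, 1], [2, 0], [2, 1]], dtype=float)
        tree = hierarchical_cluster(X)
        assert tree.merges == [
            (l, r, pytest.approx(h)) for l, r, h in naive_complete_linkage(X)
        ]

    def test_heights_non_decreasing(self):
        rng = np.random.default_rng(41)
        for _ in range(20):
            tree = hierarchical_cluster(rng.random((10, 4)))
            heights = [h for _, _, h in tree.merges]
            assert all(b >= a - 1e-12 for a, b in zip(heights, heights[1:]))

    def test_agrees_with_scipy_complete_linkage(self):
        # independent implementation: cophenetic distances must coincide
        rng = np.random.default_rng(51)
        for _ in range(25):
            X = rng.random((9, 3))
            ours = cophenet(hierarchical_cluster(X).to_linkage())
            theirs = cophenet(linkage(X, method="complete"))
            assert np.allclose(ours, theirs)

    def test_invariant_to_row_permutation_up_to_relabeling(self):
        rng = np.random.default_rng(61)
        X = rng.random((8, 4))
        perm = rng.permutation(8)
        base = cophenet(hierarchical_cluster(X).to_linkage())
        shuffled = cophenet(hierarchical_cluster(X[perm]).to_linkage())
        base_sq = np.zeros((8, 8))
        idx = np.triu_indices(8, 1)
        base_sq[idx] = base
        base_sq += base_sq.T
        shuffled_sq = np.zeros((8, 8))
        shuffled_sq[idx] = shuffled
        shuffled_sq += shuffled_sq.T
        assert np.allclose(shuffled_sq, base_sq[np.ix_(perm, perm)])


class TestLeafOrder:
    def test_two_leaves_keep_original_order(self):
        tree = hierarchical_cluster(np.array([[0.0], [1.0]]))
        assert leaf_order(tree) == ["0", "1"]

    def test_three_leaf_grouping(self):
        tree = hierarchical_cluster(np.array([[0.0, 0.0], [0.0, 1.0], [4.0, 4.0]]))
        order = leaf_order(tree)
        assert set(order) == {"0", "1", "2"}
        assert abs(order.index("0") - order.index("1")) == 1  # merged pair adjacent

    def test_order_is_a_permutation_of_labels(self):
        rng = np.random.default_rng(71)
        df = pd.DataFrame(rng.random((9, 4)), index=[f"G{i}" for i in range(9)])
        tree = hierarchical_cluster(df)
        assert sorted(leaf_order(tree)) == sorted(df.index)


class TestExport:
    def test_heatmap_data_roundtrip_and_sidecar(self, tmp_path):
        rng = np.random.default_rng(81)
        df = pd.DataFrame(
            rng.random((3, 2)),
            index=["A", "B", "C"],
            columns=["invasion", "adhesion"],
        )
        tree = hierarchical_cluster(df)
        path = tmp_path / "heatmap.tsv"
        export_heatmap_data(df, tree, str(path))
        again = pd.read_csv(path, sep="\t", index_col="symbol")
        assert list(again.index) == leaf_order(tree)
        assert list(again.columns) == ["invasion", "adhesion"]
        assert np.allclose(again.to_numpy(), df.loc[leaf_order(tree)].to_numpy())
        sidecar = json.loads((tmp_path / "heatmap.tsv.tree.json").read_text())
        assert sidecar["leaf_order"] == leaf_order(tree)
        assert len(sidecar["merges"]) == 2
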