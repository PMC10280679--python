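from __future__ import annotations

import json

import numpy as np
import pytest

from stressid.data_model import Dataset
from stressid.hier_clustering import (
    ClusterConfig,
    ClusterNode,
    ClusterTree,
    agglomerating_phase,
    build_histogram,
    cluster,
    dividing_phase,
    find_split,
    merge_condition,
    split_class,
    tree_to_dot,
    tree_to_json,
)

from _oracles import oracle_find_split
from conftest import ari, make_cohort, planted_labels_as_ints


def dataset_1d(values, prefix="s"):
    values = np.asarray(values, dtype=float)
    return Dataset([f"{prefix}{i}" for i in range(len(values))], values[:, None], ["x"])


class TestBuildHistogram:
    def test_uniform_integers(self):
        ds = dataset_1d(np.arange(1, 101))
        hist = build_histogram(ds, dim=1, bins=10)
        assert hist.counts.tolist() == [10] * 10
        assert hist.counts.sum() == 100

    def test_identical_values_degenerate(self):
        hist = build_histogram(dataset_1d([4.0] * 10), dim=1, bins=4)
        assert hist.degenerate
        assert hist.counts.tolist() == [10]

    def test_two_groups(self):
        hist = build_histogram(dataset_1d([1, 1, 2, 9, 9]), dim=1, bins=2)
        assert hist.counts.tolist() == [3, 2]
        assert hist.edges[1] == 5.0

    def test_medians_per_bin(self):
        hist = build_histogram(dataset_1d([1, 1, 2, 9, 9]), dim=1, bins=2)
        assert hist.medians.tolist() == [1.0, 9.0]

    def test_errors(self):
        with pytest.raises(ValueError):
            build_histogram(np.empty((0, 1)), dim=1, bins=4)
        with pytest.raises(ValueError):
            build_histogram(dataset_1d([1, 2]), dim=2, bins=4)
        with pytest.raises(ValueError):
            build_histogram(dataset_1d([1, 2]), dim=1, bins=1)


class TestFindSplit:
    def test_two_blobs_split_between(self, rng):
        config = ClusterConfig(bins=8)
        values = np.concatenate(
            [rng.normal(0, 0.5, 20), rng.normal(10, 0.5, 20)]
        )
        pos = find_split(dataset_1d(values), config)
        assert pos is not None
        assert pos.dim == 1
        assert 2 < pos.threshold < 8
        oracle = oracle_find_split(values[:, None], bins=8)
        assert oracle is not None
        assert (pos.dim, pos.bin_index) == (oracle[0], oracle[1])
        assert pos.threshold == pytest.approx(oracle[2])

    def test_unimodal_returns_none(self, rng):
        config = ClusterConfig(bins=8)
        for _ in range(10):
            values = rng.normal(5, 1, 40)
            pos = find_split(dataset_1d(values), config)
            oracle = oracle_find_split(values[:, None], bins=8)
            assert pos is None and oracle is None

    def test_tiny_class_short_circuits(self):
        assert find_split(dataset_1d([1.0]), ClusterConfig()) is None
        assert find_split(dataset_1d([1.0, 9.0, 2.0]), ClusterConfig()) is None

    def test_oracle_equivalence_random(self, rng):
        config = ClusterConfig(bins=12)
        for _ in range(25):
            n = int(rng.integers(8, 120))
            d = int(rng.integers(1, 4))
            kind = rng.integers(0, 3)
            if kind == 0:
                X = rng.normal(5, 1, size=(n, d))
            elif kind == 1:
                X = rng.uniform(0, 10, size=(n, d))
            else:
                half = n // 2
                X = np.vstack(
                    [rng.normal(2, 0.6, (half, d)), rng.normal(8, 0.6, (n - half, d))]
                )
            pos = find_split(X, config)
            oracle = oracle_find_split(X, bins=12)
            if oracle is None:
                assert pos is None
            else:
                assert pos is not None
                assert (pos.dim, pos.bin_index) == (oracle[0], oracle[1])
                assert pos.threshold == pytest.approx(oracle[2])


class TestSplitClass:
    def test_partition_by_threshold(self):
        from stressid.hier_clustering import SplitPosition

        ds = dataset_1d([1, 2, 3, 7, 8])
        left, right = split_class(ds, SplitPosition(dim=1, threshold=5.0, bin_index=0))
        assert left.values.ravel().tolist() == [1, 2, 3]
        assert right.values.ravel().tolist() == [7, 8]

    def test_threshold_value_goes_left(self):
        from stressid.hier_clustering import SplitPosition

        ds = dataset_1d([1, 5, 9])
        left, right = split_class(ds, SplitPosition(dim=1, threshold=5.0, bin_index=0))
        assert left.values.ravel().tolist() == [1, 5]

    def test_empty_side_rejected(self):
        from stressid.hier_clustering import SplitPosition

        ds = dataset_1d([3, 4, 5])
        with pytest.raises(ValueError, match="empty subclass"):
            split_class(ds, SplitPosition(dim=1, threshold=0.0, bin_index=0))


def assert_split_conservation(node):
    if node.children is None:
        return
    left, right = node.children
    assert len(left.members) + len(right.members) == len(node.members)
    assert left.split_level == right.split_level == node.split_level + 1
    assert_split_conservation(left)
    assert_split_conservation(right)


class TestDividingPhase:
    def test_two_blobs_two_leaves(self):
        ds, labels = make_cohort(seed=3, n=100, proportions=(0.5, 0.5, 0.0))
        tree = dividing_phase(ds)
        assert len(tree.leaves()) == 2
        part = tree.partition()
        assert ari(part.labels_for(ds), planted_labels_as_ints(labels)) == 1.0

    def test_single_blob_single_leaf(self, rng):
        ds = dataset_1d(rng.normal(5, 1, 40))
        tree = dividing_phase(ds, ClusterConfig(bins=8))
        assert tree.root.is_leaf

    def test_singleton_dataset(self):
        tree = dividing_phase(dataset_1d([5.0]))
        assert tree.root.is_leaf and tree.max_level == 1

    def test_empty_dataset_rejected(self):
        with pytest.raises(ValueError, match="empty dataset"):
            dividing_phase(Dataset([], np.empty((0, 1)), ["x"]))

    def test_split_conservation(self):
        ds, _ = make_cohort(seed=5, n=150)
        tree = dividing_phase(ds)
        assert_split_conservation(tree.root)
        tree.partition().validate_against(ds)


# ---------------------------------------------------------------------------
# artificial trees for the agglomerating phase
# ---------------------------------------------------------------------------

def manual_split(node, ids_left, ids_right):
    left = ClusterNode(members=tuple(ids_left), split_level=node.split_level + 1)
    right = ClusterNode(members=tuple(ids_right), split_level=node.split_level + 1)
    node.set_children(left, right)
    return left, right


def blob_dataset(rng, centers, n_per=30, sigma=0.5):
    values = np.concatenate(
        [rng.normal(c, sigma, n_per) for c in centers]
    )
    return dataset_1d(values), [i // n_per for i in range(len(values))]


class TestMergeCondition:
    def test_halves_of_one_blob_merge(self, rng):
        ds = dataset_1d(np.sort(rng.normal(5, 1, 40)))
        config = ClusterConfig(bins=8)
        root = ClusterNode(members=tuple(ds.ids), split_level=1)
        left, right = manual_split(root, ds.ids[:20], ds.ids[20:])
        assert merge_condition(ds, left, right, config) is True
        assert merge_condition(ds, right, left, config) is True

    def test_far_blobs_refuse(self, rng):
        ds, _ = blob_dataset(rng, [0, 10], n_per=25)
        config = ClusterConfig(bins=8)
        root = ClusterNode(members=tuple(ds.ids), split_level=1)
        left, right = manual_split(root, ds.ids[:25], ds.ids[25:])
        assert merge_condition(ds, left, right, config) is False

    def test_duplicate_members_merge(self, rng):
        ds = dataset_1d(rng.normal(5, 1, 30))
        node = ClusterNode(members=tuple(ds.ids), split_level=2)
        assert merge_condition(ds, node, node, ClusterConfig(bins=8)) is True


class TestAgglomeratingPhase:
    def test_artificial_split_heals(self, rng):
        ds = dataset_1d(np.sort(rng.normal(5, 1, 40)))
        root = ClusterNode(members=tuple(ds.ids), split_level=1)
        manual_split(root, ds.ids[:20], ds.ids[20:])
        part = agglomerating_phase(
            ClusterTree(root=root, dataset=ds), ClusterConfig(bins=8)
        )
        assert part.k == 1

    def test_oversplit_three_blobs_recover(self, rng):
        ds, labels = blob_dataset(rng, [0, 10, 20], n_per=30)
        ids = ds.ids
        b0, b1, b2 = ids[:30], ids[30:60], ids[60:]
        root = ClusterNode(members=tuple(ids), split_level=1)
        n0, rest = manual_split(root, b0, b1 + b2)
        manual_split(n0, b0[:15], b0[15:])          # level-3 halves of blob 0
        n1, n2 = manual_split(rest, b1, b2)          # level-3 split of blobs 1|2
        manual_split(n1, b1[:15], b1[15:])           # level-4 halves of blob 1
        tree = ClusterTree(root=root, dataset=ds)
        assert len(tree.leaves()) == 5
        part = agglomerating_phase(tree, ClusterConfig(bins=8))
        assert part.k == 3
        assert ari(part.labels_for(ds), labels) >= 0.99

    def test_single_leaf_unchanged(self):
        ds = dataset_1d([1.0, 2.0, 3.0])
        tree = ClusterTree(
            root=ClusterNode(members=tuple(ds.ids), split_level=1), dataset=ds
        )
        part = agglomerating_phase(tree, ClusterConfig())
        assert part.k == 1 and part.member_ids() == frozenset(ds.ids)

    def test_merge_monotone(self):
        ds, _ = make_cohort(seed=11, n=200)
        tree = dividing_phase(ds)
        n_leaves = len(tree.leaves())
        part = agglomerating_phase(tree)
        assert part.k <= n_leaves


class TestCluster:
    def test_three_blob_cohort(self):
        ds, labels = make_cohort(seed=0, n=300)
        part, tree = cluster(ds)
        assert part.k == 3
        assert ari(part.labels_for(ds), planted_labels_as_ints(labels)) >= 0.95

    def test_uniform_cloud_single_cluster(self, rng):
        values = rng.uniform(0, 10, size=(200, 3))
        ds = Dataset([f"s{i}" for i in range(200)], values, ["x", "y", "z"])
        part, _ = cluster(ds)
        assert part.k == 1

    def test_singleton(self):
        part, tree = cluster(dataset_1d([7.0]))
        assert part.k == 1 and part.clusters[0] == frozenset({"s0"})

    def test_deterministic(self):
        ds, _ = make_cohort(seed=7, n=150)
        p1, _ = cluster(ds)
        p2, _ = cluster(ds)
        assert p1.clusters == p2.clusters

    def test_idempotent_on_recovered_clusters(self):
        ds, _ = make_cohort(seed=0, n=300)
        part, _ = cluster(ds)
        for members in part.clusters:
            sub = ds.subset(members)
            sub_part, _ = cluster(sub)
            assert sub_part.k == 1


class TestExports:
    def test_tree_json(self):
        ds, _ = make_cohort(seed=0, n=120)
        _, tree = cluster(ds)
        payload = json.loads(tree_to_json(tree))
        assert payload["split_level"] == 1
        assert payload["size"] == 120
        assert payload["tag"] == "1"

    def test_tree_dot(self):
        ds, _ = make_cohort(seed=0, n=120)
        tree = dividing_phase(ds)
        dot = tree_to_dot(tree)
        assert dot.startswith("digraph") and "->" in dot

    def test_tags_follow_levels(self):
        node = ClusterNode(members=("a",), split_level=3)
        assert node.tag == "123"
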