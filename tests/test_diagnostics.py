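import numpy as np
import pandas as pd
import pytest
from sklearn.decomposition import PCA as SkPCA

import msbatch as mb

from conftest import make_annotation, table_from_wide
from oracles import brute_average_linkage, brute_cramers_v, brute_fences


class TestSampleOrderSummary:
    def test_quartiles_and_fences_match_enumeration(self):
        vals = np.array([[1.0], [2.0], [3.0], [100.0]])
        t = table_from_wide(vals)
        ann = make_annotation(["s1"], ["B1"])
        row = mb.sample_order_summary(t, ann).iloc[0]
        q1, q3, n_out = brute_fences([1.0, 2.0, 3.0, 100.0])
        assert row["value"] == pytest.approx(2.5)
        assert row["q1"] == pytest.approx(q1) and q1 == pytest.approx(1.75)
        assert row["q3"] == pytest.approx(q3) and q3 == pytest.approx(27.25)
        assert row["n_outliers"] == n_out == 1  # upper fence 65.5 < 100

    def test_constant_sample_has_no_outliers(self):
        t = table_from_wide(np.full((5, 1), 3.0))
        ann = make_annotation(["s1"], ["B1"])
        row = mb.sample_order_summary(t, ann).iloc[0]
        assert row["q3"] - row["q1"] == 0 and row["n_outliers"] == 0

    def test_rows_follow_run_order_not_sample_name(self):
        t = table_from_wide(np.ones((2, 3)), samples=["zz", "aa", "mm"])
        ann = make_annotation(["zz", "aa", "mm"], ["B1"] * 3, run_order=[2, 3, 1])
        out = mb.sample_order_summary(t, ann)
        assert list(out["sample_id"]) == ["mm", "zz", "aa"]

    def test_random_samples_match_fence_oracle(self):
        rng = np.random.default_rng(14)
        vals = rng.normal(10, 2, size=(40, 5))
        t = table_from_wide(vals)
        ann = make_annotation([f"s{j + 1}" for j in range(5)], ["B1"] * 5)
        out = mb.sample_order_summary(t, ann).set_index("sample_id")
        for j in range(5):
            q1, q3, n_out = brute_fences(vals[:, j])
            row = out.loc[f"s{j + 1}"]
            assert row["q1"] == pytest.approx(q1)
            assert row["q3"] == pytest.approx(q3)
            assert row["n_outliers"] == n_out


class TestPca:
    def test_duplicated_samples_coincide(self):
        rng = np.random.default_rng(0)
        col = rng.normal(10, 1, 20)
        vals = np.column_stack([col, col, rng.normal(10, 1, 20), rng.normal(10, 1, 20)])
        res = mb.pca_scores(table_from_wide(vals))
        assert np.allclose(res.scores.loc["s1"], res.scores.loc["s2"], atol=1e-8)

    def test_rank_one_structure_gives_full_first_component(self):
        u = np.arange(1, 11, dtype=float)
        v = np.array([1.0, -1.0, 2.0, 0.5])
        res = mb.pca_scores(table_from_wide(np.outer(u, v)))
        assert res.variance_fraction[0] == pytest.approx(1.0, abs=1e-12)

    def test_two_cluster_simulation_separated_on_pc1(self):
        rng = np.random.default_rng(3)
        vals = rng.normal(10, 0.5, size=(50, 20))
        vals[:, 10:] += 2.0
        res = mb.pca_scores(table_from_wide(vals))
        samples = [f"s{j + 1}" for j in range(20)]
        pc1 = res.scores.loc[samples, "PC1"].to_numpy()
        assert len(set(np.sign(pc1[:10]))) == 1
        assert len(set(np.sign(pc1[10:]))) == 1
        assert np.sign(pc1[0]) != np.sign(pc1[10])

    def test_matches_sklearn_pca(self):
        rng = np.random.default_rng(21)
        vals = rng.normal(0, 1, size=(30, 10))
        res = mb.pca_scores(table_from_wide(vals))
        sk = SkPCA().fit(vals.T - vals.T.mean(axis=0))
        assert np.allclose(
            res.variance_fraction, sk.explained_variance_ratio_[: len(res.variance_fraction)],
            atol=1e-10,
        )
        samples = [f"s{j + 1}" for j in range(10)]
        assert np.allclose(
            np.abs(res.scores.loc[samples].to_numpy()),
            np.abs(sk.transform(vals.T - vals.T.mean(axis=0))),
            atol=1e-8,
        )

    def test_incomplete_features_dropped_and_reported(self):
        vals = np.random.default_rng(1).normal(10, 1, size=(10, 5))
        vals[0, 0] = np.nan
        res = mb.pca_scores(table_from_wide(vals))
        assert res.n_features_dropped == 1
        assert len(res.features_used) == 9

    def test_variance_fractions_sum_to_at_most_one_and_decrease(self):
        rng = np.random.default_rng(2)
        res = mb.pca_scores(table_from_wide(rng.normal(size=(20, 8))))
        vf = res.variance_fraction
        assert vf.sum() <= 1 + 1e-12
        assert (np.diff(vf) <= 1e-12).all()


class TestHierarchicalClustering:
    def test_closest_pair_merges_first(self):
        # d(A,B) < d(A,C) = d(B,C)
        vals = np.array([[0.0, 0.1, 5.0], [0.0, 0.0, 0.0]])
        rep = mb.hierarchical_cluster(table_from_wide(vals), linkage="complete")
        first = rep.merges[0]
        assert {int(first[0]), int(first[1])} == {0, 1}

    def test_duplicated_samples_merge_at_height_zero(self):
        col = np.arange(5, dtype=float)
        vals = np.column_stack([col, col, col + 3])
        rep = mb.hierarchical_cluster(table_from_wide(vals))
        assert rep.merges[0][2] == pytest.approx(0.0, abs=1e-12)

    def test_average_linkage_matches_brute_force_agglomeration(self):
        rng = np.random.default_rng(9)
        vals = rng.normal(0, 1, size=(15, 6))
        rep = mb.hierarchical_cluster(table_from_wide(vals), linkage="average")
        X = vals.T
        D = np.sqrt(((X[:, None, :] - X[None, :, :]) ** 2).sum(-1))
        expected = brute_average_linkage(D)
        assert np.allclose(sorted(rep.heights), expected, atol=1e-10)

    def test_merge_count_and_leaf_set(self):
        rng = np.random.default_rng(4)
        vals = rng.normal(size=(10, 7))
        rep = mb.hierarchical_cluster(table_from_wide(vals), distance="manhattan")
        assert rep.merges.shape[0] == 6
        assert sorted(rep.leaf_order) == [f"s{j + 1}" for j in range(7)]

    def test_ward_requires_euclidean(self):
        vals = np.random.default_rng(0).normal(size=(5, 4))
        with pytest.raises(ValueError, match="ward"):
            mb.hierarchical_cluster(table_from_wide(vals), distance="manhattan", linkage="ward")


class TestConfounding:
    def test_identical_factors_fully_confounded(self):
        ann = make_annotation(
            [f"s{j}" for j in range(8)], ["B1", "B2"] * 4, groups=["G1", "G2"] * 4
        )
        _, v = mb.confounding_report(ann, "batch", "group")
        assert v == pytest.approx(1.0)

    def test_diagonal_two_by_two_table(self):
        ann = make_annotation(
            [f"s{j}" for j in range(20)],
            ["B1"] * 10 + ["B2"] * 10,
            groups=["G1"] * 10 + ["G2"] * 10,
        )
        tab, v = mb.confounding_report(ann, "batch", "group")
        assert tab.to_numpy().tolist() == [[10, 0], [0, 10]]
        assert v == pytest.approx(1.0)
        assert v == pytest.approx(brute_cramers_v(tab.to_numpy()))

    def test_independent_random_factors_near_zero(self):
        rng = np.random.default_rng(123)
        n = 10000
        ann = make_annotation(
            [f"s{j}" for j in range(n)],
            rng.choice(["B1", "B2", "B3"], n),
            groups=rng.choice(["G1", "G2"], n),
        )
        tab, v = mb.confounding_report(ann, "batch", "group")
        assert v < 0.05
        assert v == pytest.approx(brute_cramers_v(tab.to_numpy()), abs=1e-12)


class TestFeatureTrend:
    def test_rows_in_run_order_and_missing_omitted(self):
        vals = np.array([[1.0, np.nan, 3.0, 4.0, 5.0]])
        t = table_from_wide(vals)
        ann = make_annotation(
            [f"s{j + 1}" for j in range(5)], ["B1"] * 5, run_order=[5, 4, 3, 2, 1]
        )
        out = mb.feature_trend(t, ann, ["f1"])
        assert list(out["run_order"]) == [1, 2, 3, 5]  # s2 missing, s1 last

    def test_unknown_feature_rejected(self):
        t = table_from_wide(np.ones((2, 3)))
        ann = make_annotation(["s1", "s2", "s3"], ["B1"] * 3)
        with pytest.raises(KeyError, match="nope"):
            mb.feature_trend(t, ann, ["nope"])

    def test_spike_in_filter_returns_flagged_features(self, fixture_dataset):
        table, ann, fann = fixture_dataset
        spikes = fann.spike_ins()
        assert spikes == ["P6_pep1", "P6_pep2"]
        out = mb.feature_trend(table, ann, spikes)
        assert set(out["feature_id"]) == set(spikes)
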