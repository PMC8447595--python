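import numpy as np
import pandas as pd
import pytest

import msbatch as mb

from conftest import make_annotation, table_from_wide


def annotated_table(seed=0, n_feat=80, n1=6, n2=6, rep_pair=True, batch_shift=1.0):
    """Two batches, optional replicate pair spanning them, protein structure."""
    rng = np.random.default_rng(seed)
    n = n1 + n2
    protein_signal = rng.normal(0, 0.8, size=(n_feat // 2, n))  # 2 peptides/protein
    Y = 10 + np.repeat(protein_signal, 2, axis=0) + rng.normal(0, 0.3, size=(n_feat, n))
    shifts = rng.normal(0, batch_shift, size=(n_feat, 1))
    Y[:, n1:] += shifts
    if rep_pair:
        Y[:, n1] = Y[:, 0] + rng.normal(0, 0.1, n_feat) + shifts[:, 0]
    samples = [f"s{j + 1}" for j in range(n)]
    rep = [None] * n
    if rep_pair:
        rep[0] = rep[n1] = "R1"
    ann = make_annotation(samples, ["B1"] * n1 + ["B2"] * n2, rep=rep)
    fann = mb.FeatureAnnotation(
        pd.DataFrame(
            {
                "feature_id": [f"f{i + 1}" for i in range(n_feat)],
                "protein_id": [f"P{i // 2 + 1}" for i in range(n_feat)],
                "is_spike_in": False,
            }
        )
    )
    return table_from_wide(Y), ann, fann


class TestSampleCorrelation:
    def test_duplicated_pair_is_replicate_with_r_one(self):
        col = np.random.default_rng(0).normal(10, 1, 60)
        vals = np.column_stack([col, col, col + np.random.default_rng(1).normal(0, 1, 60)])
        t = table_from_wide(vals)
        ann = make_annotation(
            ["s1", "s2", "s3"], ["B1", "B2", "B2"], rep=["R1", "R1", None]
        )
        summ = mb.sample_correlation_summary(t, ann, "batch", min_overlap=10)
        assert summ.coefficients["replicate"][0] == pytest.approx(1.0)

    def test_categories_partition_all_retained_pairs(self, fixture_dataset):
        table, ann, _ = fixture_dataset
        summ = mb.sample_correlation_summary(table, ann, "MS_batch", min_overlap=5)
        n_pairs = sum(len(v) for v in summ.coefficients.values())
        assert n_pairs + summ.n_excluded_pairs == 12 * 11 // 2
        # 2 replicate pairs by construction
        assert len(summ.coefficients["replicate"]) == 2

    def test_min_overlap_excludes_sparse_pairs(self):
        vals = np.full((40, 3), 10.0)
        vals[:, 0] += np.random.default_rng(0).normal(0, 1, 40)
        vals[20:, 1] = np.nan  # only 20 shared features with others
        vals[:, 2] += np.random.default_rng(1).normal(0, 1, 40)
        t = table_from_wide(vals)
        ann = make_annotation(["s1", "s2", "s3"], ["B1", "B1", "B2"])
        summ = mb.sample_correlation_summary(t, ann, "batch", min_overlap=30)
        assert summ.n_excluded_pairs == 2  # both pairs involving s2

    def test_batch_shift_gap_shrinks_after_centering(self):
        t, ann, _ = annotated_table(seed=5)
        before = mb.sample_correlation_summary(t, ann, "batch", min_overlap=10)
        corrected = mb.center_discrete(t, ann, "batch")
        after = mb.sample_correlation_summary(corrected, ann, "batch", min_overlap=10)
        gap_before = before.median("within_batch") - before.median("between_batch")
        gap_after = after.median("within_batch") - after.median("between_batch")
        assert gap_before > 0
        assert gap_after < gap_before


class TestPeptideCorrelation:
    def test_identical_profiles_r_one(self):
        rng = np.random.default_rng(2)
        row = rng.normal(10, 1, 30)
        vals = np.vstack([row, row, rng.normal(10, 1, 30), rng.normal(10, 1, 30)])
        t = table_from_wide(vals)
        fann = mb.FeatureAnnotation(
            pd.DataFrame(
                {
                    "feature_id": ["f1", "f2", "f3", "f4"],
                    "protein_id": ["P1", "P1", "P2", "P3"],
                }
            )
        )
        summ = mb.peptide_correlation_summary(t, fann, max_pairs=10, seed=0)
        assert summ.coefficients["same_protein"][0] == pytest.approx(1.0)

    def test_iid_noise_peptides_uncorrelated_on_average(self):
        rng = np.random.default_rng(7)
        vals = rng.normal(10, 1, size=(60, 200))
        t = table_from_wide(vals)
        fann = mb.FeatureAnnotation(
            pd.DataFrame(
                {
                    "feature_id": [f"f{i + 1}" for i in range(60)],
                    "protein_id": [f"P{i // 2 + 1}" for i in range(60)],
                }
            )
        )
        summ = mb.peptide_correlation_summary(t, fann, max_pairs=500, seed=1)
        assert abs(summ.mean("different_protein")) < 0.05

    def test_no_multipeptide_protein_rejected(self):
        t = table_from_wide(np.random.default_rng(0).normal(size=(3, 5)))
        fann = mb.FeatureAnnotation(
            pd.DataFrame(
                {"feature_id": ["f1", "f2", "f3"], "protein_id": ["P1", "P2", "P3"]}
            )
        )
        with pytest.raises(ValueError, match="more than one mapped peptide"):
            mb.peptide_correlation_summary(t, fann)

    def test_correction_shrinks_spurious_cross_protein_correlation(self):
        t, ann, fann = annotated_table(seed=11, batch_shift=1.5)
        before = mb.peptide_correlation_summary(t, fann, max_pairs=800, seed=3)
        corrected = mb.center_discrete(t, ann, "batch")
        after = mb.peptide_correlation_summary(corrected, fann, max_pairs=800, seed=3)
        assert abs(after.mean("different_protein")) < abs(before.mean("different_protein"))
        assert after.mean("same_protein") > after.mean("different_protein")


class TestCvByAbundance:
    def test_identical_replicates_zero_cv(self):
        vals = np.log2(np.array([[100.0, 100.0, 100.0]]))
        t = table_from_wide(vals)
        ann = make_annotation(["s1", "s2", "s3"], ["B1"] * 3, rep=["R1"] * 3)
        out = mb.cv_by_abundance(t, ann)
        assert out["cv"].iloc[0] == pytest.approx(0.0, abs=1e-12)

    def test_hand_computed_cv(self):
        # raw values 90 and 110: mean 100, sd 14.142 (n-1), CV 0.1414
        vals = np.log2(np.array([[90.0, 110.0]]))
        t = table_from_wide(vals)
        ann = make_annotation(["s1", "s2"], ["B1"] * 2, rep=["R1", "R1"])
        out = mb.cv_by_abundance(t, ann)
        assert out["cv"].iloc[0] == pytest.approx(0.14142, abs=1e-4)
        assert out["mean_log10_abundance"].iloc[0] == pytest.approx(2.0, abs=0.01)

    def test_no_replicate_group_rejected(self):
        t = table_from_wide(np.ones((2, 2)) * 10)
        ann = make_annotation(["s1", "s2"], ["B1", "B1"])
        with pytest.raises(ValueError, match="replicate"):
            mb.cv_by_abundance(t, ann)

    def test_centering_reduces_replicate_cv_for_most_features(self):
        rng = np.random.default_rng(13)
        n_feat, n = 100, 12
        Y = 10 + rng.normal(0, 0.1, size=(n_feat, n))
        Y[:, 6:] += rng.normal(0, 1.0, size=(n_feat, 1))  # batch shift
        t = table_from_wide(Y)
        ann = make_annotation(
            [f"s{j + 1}" for j in range(n)],
            ["B1"] * 6 + ["B2"] * 6,
            rep=["R1", None, None, "R2", None, None, "R1", None, None, "R2", None, None],
        )
        before = mb.cv_by_abundance(t, ann).set_index("feature_id")["cv"]
        corrected = mb.center_discrete(t, ann, "batch")
        after = mb.cv_by_abundance(corrected, ann).set_index("feature_id")["cv"]
        assert (after <= before + 1e-12).mean() >= 0.9


class TestQcCompare:
    def test_identical_tables_zero_deltas(self):
        t, ann, fann = annotated_table(seed=4)
        report = mb.qc_compare(t, t, ann, fann, "batch", pvca_factors=[], min_overlap=10)
        for key, d in report["delta"].items():
            assert d == pytest.approx(0.0, abs=1e-12), key

    def test_universe_mismatch_rejected(self):
        t, ann, fann = annotated_table(seed=4)
        permuted = t.copy()
        mapping = {"s1": "s2", "s2": "s1"}
        permuted["sample_id"] = permuted["sample_id"].map(lambda s: mapping.get(s, s))
        dropped = permuted.iloc[:-5]
        with pytest.raises(ValueError, match="universe"):
            mb.qc_compare(t, dropped, ann, fann, "batch", pvca_factors=[], min_overlap=10)

    def test_swapping_before_after_negates_deltas(self):
        t, ann, fann = annotated_table(seed=9)
        corrected = mb.center_discrete(t, ann, "batch")
        fwd = mb.qc_compare(t, corrected, ann, fann, "batch", pvca_factors=[], min_overlap=10)
        rev = mb.qc_compare(corrected, t, ann, fann, "batch", pvca_factors=[], min_overlap=10)
        for key in fwd["delta"]:
            assert fwd["delta"][key] == pytest.approx(-rev["delta"][key], abs=1e-10)
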