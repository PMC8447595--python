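import numpy as np
import pandas as pd
import pytest

import msbatch as mb

from conftest import make_annotation, table_from_wide


def two_batch_ann(n1=6, n2=6):
    n = n1 + n2
    return make_annotation(
        [f"s{j + 1}" for j in range(n)], ["B1"] * n1 + ["B2"] * n2
    )


class TestCenterDiscrete:
    def test_hand_example_medians(self):
        # batch1 [5,6,7] (median 6), batch2 [8,9,10] (median 9), global 7.5
        t = table_from_wide(np.array([[5.0, 6.0, 7.0, 8.0, 9.0, 10.0]]))
        ann = make_annotation([f"s{j + 1}" for j in range(6)], ["B1"] * 3 + ["B2"] * 3)
        out = mb.center_discrete(t, ann, "batch")
        assert np.allclose(np.sort(out["intensity"]), [6.5, 6.5, 7.5, 7.5, 8.5, 8.5])

    def test_single_batch_identity(self):
        t = table_from_wide(np.array([[1.0, 2.0], [3.0, 4.0]]))
        ann = make_annotation(["s1", "s2"], ["B1", "B1"])
        out = mb.center_discrete(t, ann, "batch")
        merged = t.merge(out, on=["feature_id", "sample_id"])
        assert np.allclose(merged["intensity_x"], merged["intensity_y"])

    def test_postcondition_sweep_over_seeded_features(self):
        rng = np.random.default_rng(17)
        vals = rng.normal(10, 2, size=(100, 12))
        vals[rng.random(vals.shape) < 0.1] = np.nan
        t = table_from_wide(vals)
        ann = two_batch_ann()
        out = mb.center_discrete(t, ann, "batch")
        joined = out.assign(batch=out["sample_id"].map(ann.batch_of("batch")))
        per_batch = joined.groupby(["feature_id", "batch"])["intensity"].median()
        glob = joined.groupby("feature_id")["intensity"].median()
        for (feat, _), med in per_batch.items():
            assert med == pytest.approx(glob[feat], abs=1e-12)

    def test_median_centering_idempotent(self):
        rng = np.random.default_rng(23)
        t = table_from_wide(rng.normal(10, 1, size=(30, 12)))
        ann = two_batch_ann()
        once = mb.center_discrete(t, ann, "batch")
        twice = mb.center_discrete(once, ann, "batch")
        merged = once.merge(twice, on=["feature_id", "sample_id"])
        assert np.allclose(merged["intensity_x"], merged["intensity_y"], atol=0)


class TestCorrectDrift:
    def test_preserves_per_batch_median_exactly(self):
        rng = np.random.default_rng(4)
        vals = 12.0 + rng.normal(0, 0.1, size=(5, 24))
        t = table_from_wide(vals)
        ann = two_batch_ann(12, 12)
        out, fits = mb.correct_drift(t, ann, "batch", span=0.75)
        for tab in (t, out):
            tab["_b"] = tab["sample_id"].map(ann.batch_of("batch"))
        med_in = t.groupby(["feature_id", "_b"])["intensity"].median()
        med_out = out.groupby(["feature_id", "_b"])["intensity"].median()
        assert np.allclose(med_in.sort_index(), med_out.sort_index(), atol=1e-10)

    def test_linear_drift_slope_reduced_tenfold(self):
        rng = np.random.default_rng(12)
        orders = np.arange(60, dtype=float)
        y = 10.0 + 0.02 * orders + rng.normal(0, 0.1, 60)
        t = table_from_wide(y[None, :])
        ann = make_annotation([f"s{j + 1}" for j in range(60)], ["B1"] * 60)
        out, _ = mb.correct_drift(t, ann, "batch", span=0.5)
        ordered = out.assign(o=out["sample_id"].map(ann.column("run_order"))).sort_values("o")
        slope = np.polyfit(ordered["o"], ordered["intensity"], 1)[0]
        assert abs(slope) < 0.002

    def test_small_batch_falls_back_untouched(self):
        vals = np.full((1, 11), 5.0)
        vals[0, 8:] = [7.0, 8.0, 9.0]  # batch 2 has only 3 samples
        t = table_from_wide(vals)
        ann = make_annotation(
            [f"s{j + 1}" for j in range(11)], ["B1"] * 8 + ["B2"] * 3
        )
        out, fits = mb.correct_drift(t, ann, "batch", min_points=8)
        fallbacks = [f for f in fits if f.fallback]
        assert len(fallbacks) == 1 and fallbacks[0].batch == "B2"
        b2 = out.loc[out["sample_id"].isin(["s9", "s10", "s11"])]
        assert sorted(b2["intensity"]) == [7.0, 8.0, 9.0]

    def test_small_batches_warn_about_overcorrection(self):
        rng = np.random.default_rng(1)
        t = table_from_wide(rng.normal(10, 1, size=(3, 20)))
        ann = two_batch_ann(10, 10)
        with pytest.warns(UserWarning, match="smaller than 25"):
            mb.correct_drift(t, ann, "batch")

    def test_drift_fit_export_covers_observed_orders(self):
        rng = np.random.default_rng(7)
        t = table_from_wide(rng.normal(10, 1, size=(2, 24)))
        ann = two_batch_ann(12, 12)
        _, fits = mb.correct_drift(t, ann, "batch")
        frame = mb.drift_fits_frame(fits)
        assert set(frame.columns) == {"feature_id", "batch", "run_order", "fitted"}
        assert len(frame) == 2 * 24  # every feature x observed order


class TestTwoStep:
    def test_linear_drift_no_noise_recovered_exactly(self):
        """Exactly linear per-batch drift, no noise: drift removal plus
        median centering returns each feature to a flat profile at its
        global median."""
        orders = np.arange(1, 31, dtype=float)
        base = 10.0
        y = np.where(orders <= 15, base + 0.1 * orders, base - 2 + 0.05 * orders)
        t = table_from_wide(np.vstack([y, y + 1]))
        ann = make_annotation(
            [f"s{j + 1}" for j in range(30)], ["B1"] * 15 + ["B2"] * 15
        )
        out, _ = mb.adjust_two_step(t, ann, "batch", span=0.8, discrete_method="median")
        joined = out.assign(batch=out["sample_id"].map(ann.batch_of("batch")))
        for feat, grp in joined.groupby("feature_id"):
            # flat profile: every per-batch median equals the feature's
            # global median after correction
            assert grp["intensity"].std() < 1e-8
            glob = grp["intensity"].median()
            for _, sub in grp.groupby("batch"):
                assert sub["intensity"].median() == pytest.approx(glob, abs=1e-8)

    def test_shift_only_data_equals_center_discrete_alone(self):
        rng = np.random.default_rng(3)
        vals = rng.normal(10, 0.2, size=(20, 40))
        vals[:, 20:] += rng.normal(0, 1, size=(20, 1))  # discrete shift only
        t = table_from_wide(vals)
        ann = two_batch_ann(20, 20)
        two_step, _ = mb.adjust_two_step(t, ann, "batch", discrete_method="median")
        direct = mb.center_discrete(t, ann, "batch")
        merged = two_step.merge(direct, on=["feature_id", "sample_id"])
        # drift step fits near-flat curves; residual differences are the
        # smoothing of iid noise only
        assert np.abs(merged["intensity_x"] - merged["intensity_y"]).mean() < 0.15

    def test_drift_only_data_makes_discrete_step_a_near_noop(self):
        spec = mb.SimulationSpec(seed=77, shift_sd=0.0, noise_sd=0.05, frac_affected=0.0)
        tab, ann, _, _ = mb.simulate(spec)
        drifted, _ = mb.correct_drift(tab, ann, "MS_batch", span=0.7)
        centered = mb.center_discrete(drifted, ann, "MS_batch")
        merged = drifted.merge(centered, on=["feature_id", "sample_id"])
        shifts = (merged["intensity_x"] - merged["intensity_y"]).abs()
        assert shifts.median() < 0.05

    def test_empty_table_passes_through(self):
        t = table_from_wide(np.empty((0, 0)))
        ann = two_batch_ann(1, 1)
        out, _ = mb.adjust_two_step(t, ann, "batch")
        assert len(out) == 0

    def test_missingness_pattern_never_altered(self):
        rng = np.random.default_rng(6)
        vals = rng.normal(10, 1, size=(30, 24))
        vals[rng.random(vals.shape) < 0.15] = np.nan
        t = table_from_wide(vals)
        ann = two_batch_ann(12, 12)
        out, _ = mb.adjust_two_step(t, ann, "batch", min_points=5)
        key = ["feature_id", "sample_id"]
        assert set(map(tuple, out[key].to_numpy())) == set(map(tuple, t[key].to_numpy()))
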