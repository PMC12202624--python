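"""Accuracy scoring, best-method fusion, binning and offset correction."""

import numpy as np
import pandas as pd
import pytest
from reefcover import (
    MethodSummary,
    apply_best,
    bin_by_reef_state,
    compare_annotation_methods,
    correct_with_offset,
    per_image_accuracy,
    select_best_method,
    summarize_method,
)
from reefcover.accuracy import assign_bin
from reefcover.categories import CORAL_CATEGORIES, ReefCoverError

from conftest import make_cover_table


def _summary(means: dict[str, float], method: str) -> MethodSummary:
    table = pd.DataFrame(
        {"mean_diff": means, "se": 0.1, "n_images": 100}
    )
    return MethodSummary(method=method, table=table)


class TestPerImageAccuracy:
    def test_worked_example(self):
        """Method reporting 5% branching where the expert saw 10% scores -5."""
        method = make_cover_table({"i1": {"branching": 5.0}}, method="ai")
        expert = make_cover_table({"i1": {"branching": 10.0}})
        acc = per_image_accuracy(method, expert, "ai")
        row = acc[acc["category"] == "branching"].iloc[0]
        assert row["diff_pct"] == -5.0

    def test_identical_tables_give_zero(self):
        vals = {"i1": {"branching": 12.0, "plating": 3.0},
                "i2": {"massive": 7.0, "other_coral": 1.0}}
        method = make_cover_table(vals, method="ai")
        expert = make_cover_table(vals)
        acc = per_image_accuracy(method, expert, "ai")
        assert (acc["diff_pct"] == 0.0).all()

    def test_elementwise_subtraction_oracle(self, rng):
        m_vals, e_vals = {}, {}
        for i in range(20):
            m_vals[f"i{i}"] = {c: float(rng.uniform(0, 20)) for c in CORAL_CATEGORIES}
            e_vals[f"i{i}"] = {c: float(rng.uniform(0, 20)) for c in CORAL_CATEGORIES}
        acc = per_image_accuracy(
            make_cover_table(m_vals, method="ai"), make_cover_table(e_vals), "ai"
        )
        for _, row in acc.iterrows():
            expected = m_vals[row["image_id"]][row["category"]] - \
                e_vals[row["image_id"]][row["category"]]
            assert row["diff_pct"] == pytest.approx(expected)

    def test_only_shared_images_scored(self):
        method = make_cover_table({"i1": {"branching": 5.0}, "i2": {"branching": 5.0}},
                                  method="ai")
        expert = make_cover_table({"i2": {"branching": 5.0}, "i3": {"branching": 5.0}})
        acc = per_image_accuracy(method, expert, "ai")
        assert set(acc["image_id"]) == {"i2"}

    def test_basis_mismatch_raises(self):
        method = make_cover_table({"i1": {"branching": 5.0}}, method="ai")
        expert = make_cover_table({"i1": {"branching": 5.0}})
        expert["basis"] = "total_image"
        with pytest.raises(ReefCoverError):
            per_image_accuracy(method, expert, "ai")


class TestSummaries:
    def test_single_image(self):
        acc = per_image_accuracy(
            make_cover_table({"i1": {"branching": 5.0, "plating": 15.0,
                                     "massive": 3.0, "other_coral": 2.0}},
                             method="ai"),
            make_cover_table({"i1": {"branching": 10.0, "plating": 10.0,
                                     "massive": 3.0, "other_coral": 2.0}}),
            "ai",
        )
        s = summarize_method(acc)
        assert s.mean_diff("branching") == -5.0
        assert s.mean_diff("plating") == 5.0
        assert s.mean_diff("total_coral") == 0.0

    def test_opposite_diffs_cancel(self):
        m = make_cover_table({"i1": {"branching": 5.0}, "i2": {"branching": 15.0}},
                             method="ai")
        e = make_cover_table({"i1": {"branching": 10.0}, "i2": {"branching": 10.0}})
        s = summarize_method(per_image_accuracy(m, e, "ai"))
        assert s.mean_diff("branching") == 0.0

    def test_streaming_mean_se_oracle(self, rng):
        diffs = rng.normal(0, 5, size=60)
        acc = pd.DataFrame({
            "image_id": [f"i{k}" for k in range(60)],
            "site_id": "s1", "method": "ai", "category": "massive",
            "diff_pct": diffs, "n_citizen_analyses": 0,
        })
        s = summarize_method(acc)
        assert s.mean_diff("massive") == pytest.approx(diffs.mean())
        assert s.table.loc["massive", "se"] == pytest.approx(
            diffs.std(ddof=1) / np.sqrt(60)
        )

    def test_translation_equivariance(self, rng):
        diffs = rng.normal(0, 5, size=30)
        base = pd.DataFrame({
            "image_id": [f"i{k}" for k in range(30)],
            "site_id": "s1", "method": "ai", "category": "plating",
            "diff_pct": diffs, "n_citizen_analyses": 0,
        })
        shifted = base.assign(diff_pct=base["diff_pct"] + 3.0)
        d = summarize_method(shifted).mean_diff("plating") - \
            summarize_method(base).mean_diff("plating")
        assert d == pytest.approx(3.0)


class TestBestMethod:
    def test_reported_bias_pattern(self):
        """AI wins branching (|-1.1| < |9.5|), citizen wins plating
        (|-0.99| < |-9.1|)."""
        ai = _summary({"branching": -1.1, "plating": -9.1,
                       "massive": -3.0, "other_coral": 6.9}, "ai")
        cit = _summary({"branching": 9.5, "plating": -0.99,
                        "massive": -0.1, "other_coral": 4.5}, "citizen")
        mapping = select_best_method(ai, cit)
        assert mapping == {"branching": "ai", "plating": "citizen",
                           "massive": "citizen", "other_coral": "citizen"}

    def test_tie_goes_to_ai(self):
        ai = _summary({c: 2.0 for c in CORAL_CATEGORIES}, "ai")
        cit = _summary({c: -2.0 for c in CORAL_CATEGORIES}, "citizen")
        assert set(select_best_method(ai, cit).values()) == {"ai"}

    def test_argmin_of_absolute_means(self, rng):
        a = {c: float(rng.normal(0, 5)) for c in CORAL_CATEGORIES}
        b = {c: float(rng.normal(0, 5)) for c in CORAL_CATEGORIES}
        mapping = select_best_method(_summary(a, "ai"), _summary(b, "citizen"))
        for c in CORAL_CATEGORIES:
            expected = "citizen" if abs(b[c]) < abs(a[c]) else "ai"
            assert mapping[c] == expected

    def test_apply_all_ai_returns_ai_table(self, rng):
        vals = {f"i{k}": {c: float(rng.uniform(0, 20)) for c in CORAL_CATEGORIES}
                for k in range(5)}
        evals = {f"i{k}": {c: float(rng.uniform(0, 20)) for c in CORAL_CATEGORIES}
                 for k in range(5)}
        ai = per_image_accuracy(make_cover_table(vals, method="ai"),
                                make_cover_table(evals), "ai")
        cit = per_image_accuracy(make_cover_table(vals, method="citizen"),
                                 make_cover_table(evals), "citizen")
        best = apply_best(ai, cit, {c: "ai" for c in CORAL_CATEGORIES})
        merged = best.merge(ai, on=["image_id", "category"], suffixes=("_b", "_a"))
        assert (merged["diff_pct_b"] == merged["diff_pct_a"]).all()
        assert (best["method"] == "best").all()

    def test_cellwise_selection(self, rng):
        vals = {f"i{k}": {c: float(rng.uniform(0, 20)) for c in CORAL_CATEGORIES}
                for k in range(8)}
        evals = {f"i{k}": {c: float(rng.uniform(0, 20)) for c in CORAL_CATEGORIES}
                 for k in range(8)}
        ai = per_image_accuracy(make_cover_table(vals, method="ai"),
                                make_cover_table(evals), "ai")
        cit_vals = {k: {c: v + 1.0 for c, v in d.items()} for k, d in vals.items()}
        cit = per_image_accuracy(make_cover_table(cit_vals, method="citizen"),
                                 make_cover_table(evals), "citizen")
        mapping = {"branching": "ai", "plating": "citizen",
                   "massive": "ai", "other_coral": "citizen"}
        best = apply_best(ai, cit, mapping)
        for _, row in best.iterrows():
            src = ai if mapping[row["category"]] == "ai" else cit
            ref = src[(src["image_id"] == row["image_id"]) &
                      (src["category"] == row["category"])]["diff_pct"].iloc[0]
            assert row["diff_pct"] == ref


class TestBinning:
    def test_bin_boundaries(self):
        assert assign_bin(9.99) == 0
        assert assign_bin(10.0) == 1
        assert assign_bin(100.0) == 9  # closed top bin

    def test_min_bin_filter(self):
        n = 79
        expert = make_cover_table(
            {f"i{k}": {"branching": 5.0} for k in range(n)})
        acc = pd.DataFrame({
            "image_id": [f"i{k}" for k in range(n)],
            "site_id": "s1", "method": "best", "category": "branching",
            "diff_pct": 1.0, "n_citizen_analyses": 0,
        })
        assert bin_by_reef_state(acc, expert, min_bin_images=80).empty
        assert len(bin_by_reef_state(acc, expert, min_bin_images=79)) == 1

    def test_bins_partition_images(self, rng):
        n = 300
        expert = make_cover_table(
            {f"i{k}": {"branching": float(rng.uniform(0, 100) * 0.9)}
             for k in range(n)})
        acc = pd.DataFrame({
            "image_id": [f"i{k}" for k in range(n)],
            "site_id": "s1", "method": "best", "category": "branching",
            "diff_pct": rng.normal(0, 3, n), "n_citizen_analyses": 0,
        })
        bins = bin_by_reef_state(acc, expert, min_bin_images=1)
        assert bins["n_images"].sum() == n

    def test_recovers_cover_dependent_bias(self, rng):
        """A configured bias profile (+5 below 30% expert cover, -5 above)
        shows up bin by bin."""
        n = 2000
        expert_cover = rng.uniform(0, 80, n)
        bias = np.where(expert_cover < 30.0, 5.0, -5.0)
        expert = make_cover_table(
            {f"i{k}": {"other_coral": float(expert_cover[k])} for k in range(n)})
        acc = pd.DataFrame({
            "image_id": [f"i{k}" for k in range(n)],
            "site_id": "s1", "method": "best", "category": "other_coral",
            "diff_pct": bias + rng.normal(0, 2, n), "n_citizen_analyses": 0,
        })
        bins = bin_by_reef_state(acc, expert, min_bin_images=50)
        for _, row in bins.iterrows():
            expected = 5.0 if row["bin_lo"] < 30.0 else -5.0
            assert row["mean_diff"] == pytest.approx(expected, abs=0.8)


class TestOffsetCorrection:
    def test_zero_offset_identity(self):
        tbl = make_cover_table({"i1": {"branching": 12.0}})
        out, n_clamped = correct_with_offset(tbl, {})
        pd.testing.assert_frame_equal(out, tbl)
        assert n_clamped == 0

    def test_clamp_at_zero_flagged(self):
        tbl = make_cover_table({"i1": {"branching": 3.0}})
        out, n_clamped = correct_with_offset(tbl, {"branching": 5.0})
        row = out[out["category"] == "branching"].iloc[0]
        assert row["cover_pct"] == 0.0
        assert n_clamped == 1

    def test_elementwise_oracle(self, rng):
        vals = {f"i{k}": {c: float(rng.uniform(0, 30)) for c in CORAL_CATEGORIES}
                for k in range(10)}
        offsets = {c: float(rng.normal(0, 4)) for c in CORAL_CATEGORIES}
        tbl = make_cover_table(vals, method="best")
        out, _ = correct_with_offset(tbl, offsets)
        for (_, orig), (_, corr) in zip(tbl.iterrows(), out.iterrows()):
            expected = np.clip(
                orig["cover_pct"] - offsets.get(orig["category"], 0.0), 0, 100)
            assert corr["cover_pct"] == pytest.approx(expected)


class TestAnnotationMethodComparison:
    def test_identical_tables(self, rng):
        vals = {f"i{k}": {c: float(rng.uniform(0, 15)) for c in CORAL_CATEGORIES}
                for k in range(10)}
        a = make_cover_table(vals, method="expert_detailed")
        b = make_cover_table(vals, method="expert_visual")
        cmp = compare_annotation_methods(a, b)
        assert cmp.mean_difference == 0.0
        assert cmp.n == 10

    def test_constant_shift_detected(self, rng):
        vals = {f"i{k}": {c: float(rng.uniform(5, 15)) for c in CORAL_CATEGORIES}
                for k in range(60)}
        shifted = {k: {"branching": d["branching"] + 2.0,
                       **{c: d[c] for c in CORAL_CATEGORIES if c != "branching"}}
                   for k, d in vals.items()}
        cmp = compare_annotation_methods(make_cover_table(vals),
                                         make_cover_table(shifted))
        assert cmp.mean_difference == pytest.approx(-2.0)
        assert cmp.p_value < 1e-6

    def test_type_i_error_rate(self):
        """Under the null (both protocols iid from the same distribution)
        the paired comparison rejects at ~ the nominal 5% rate."""
        rng = np.random.default_rng(99)
        reps, n, alpha = 500, 40, 0.05
        ids = [f"i{k}" for k in range(n)]

        def table(method):
            return pd.DataFrame({
                "image_id": np.repeat(ids, 4), "site_id": "s1", "reef_id": "r1",
                "method": method, "analyst_id": "a1", "basis": "colonisable",
                "category": np.tile(np.array(CORAL_CATEGORIES), n),
                "cover_pct": rng.normal(15, 3, 4 * n),
            })

        rejections = sum(
            compare_annotation_methods(table("expert_detailed"),
                                       table("expert_visual")).p_value < alpha
            for _ in range(reps)
        )
        assert rejections / reps == pytest.approx(alpha, abs=0.03)
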