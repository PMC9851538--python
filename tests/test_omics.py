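"""LC-MS filtering chain and group statistics.

The BH adjustment is checked against an independent brute-force step-up
oracle; filters are checked never to alter retained values.
"""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from organoidkit import (
    DataQualityError,
    OmicsSimConfig,
    ParameterError,
    bh_adjust,
    differential,
    filter_missing,
    filter_qc_cv,
    gen_omics_table,
    impute_min,
    run_lcms_pipeline,
    select_mrm,
    total_sum_normalize,
    zscore_matrix,
)
from organoidkit.omics import PIPELINE_ORDER

from conftest import build_table


def brute_force_bh(pvals):
    """Independent step-up BH: q_i = min over j>=i of m*p_(j)/j, capped at 1."""
    p = np.asarray(pvals, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    q_sorted = np.empty(m)
    running = np.inf
    for rank in range(m - 1, -1, -1):
        running = min(running, m * p[order[rank]] / (rank + 1))
        q_sorted[rank] = min(running, 1.0)
    q = np.empty(m)
    q[order] = q_sorted
    return q


class TestSelectMRM:
    def test_higher_signal_mrm_wins(self):
        t = build_table(
            {
                "M1_a": [100.0, 100, 100, 100, 100, 100],
                "M1_b": [10.0, 10, 10, 10, 10, 10],
            },
            ["DD", "DD", "DN", "DN", "QC", "QC"],
            analyte_ids={"M1_a": "M1", "M1_b": "M1"},
        )
        out = select_mrm(t)
        assert list(out.signal.columns) == ["M1_a"]

    def test_singletons_pass_through(self, toy_table):
        out = select_mrm(toy_table)
        assert list(out.signal.columns) == ["A", "B", "C"]
        pd.testing.assert_frame_equal(out.signal, toy_table.signal)

    def test_exact_tie_keeps_first_listed_and_logs(self):
        t = build_table(
            {
                "M1_a": [5.0, 5, 5, 5, 7, 9],
                "M1_b": [5.0, 5, 5, 5, 7, 9],
            },
            ["DD", "DD", "DN", "DN", "QC", "QC"],
            analyte_ids={"M1_a": "M1", "M1_b": "M1"},
        )
        out = select_mrm(t)
        assert list(out.signal.columns) == ["M1_a"]
        assert out.log[-1]["ties"] == ["M1"]


class TestFilterMissing:
    def test_75pct_missing_removed(self):
        t = build_table(
            {"A": [np.nan, np.nan, np.nan, 4.0, 5, 5], "B": [1.0, 2, 3, 4, 5, 5]},
            ["DD", "DD", "DN", "DN", "QC", "QC"],
        )
        out = filter_missing(t)
        assert list(out.signal.columns) == ["B"]
        assert out.log[-1]["removed"] == ["A"]

    def test_exactly_50pct_missing_retained(self):
        t = build_table(
            {"A": [np.nan, np.nan, 3.0, 4.0, 5, 5]},
            ["DD", "DD", "DN", "DN", "QC", "QC"],
        )
        out = filter_missing(t)
        assert list(out.signal.columns) == ["A"]

    def test_fully_observed_table_unchanged(self, toy_table):
        out = filter_missing(toy_table)
        pd.testing.assert_frame_equal(out.signal, toy_table.signal)


class TestImputeMin:
    def test_missing_cells_become_global_minimum(self):
        t = build_table(
            {"A": [np.nan, 7.0, 8.0, 9.0], "B": [5.0, 6.0, np.nan, 10.0]},
            ["DD", "DD", "DN", "DN"],
        )
        out = impute_min(t)
        assert out.signal.loc["S1", "A"] == 5.0
        assert out.signal.loc["S3", "B"] == 5.0
        assert not out.signal.isna().to_numpy().any()

    def test_no_missing_is_identity(self, toy_table):
        pd.testing.assert_frame_equal(impute_min(toy_table).signal, toy_table.signal)

    def test_global_min_crosses_features(self):
        # feature A's own minimum is 100 but the global minimum (2.0, in B)
        # is used for A's missing cell
        t = build_table(
            {"A": [np.nan, 100.0, 200.0, 300.0], "B": [2.0, 50.0, 60.0, 70.0]},
            ["DD", "DD", "DN", "DN"],
        )
        assert impute_min(t).signal.loc["S1", "A"] == 2.0
        assert impute_min(t, per_feature=True).signal.loc["S1", "A"] == 100.0

    def test_all_missing_rejected(self):
        t = build_table({"A": [np.nan, np.nan]}, ["DD", "DN"])
        with pytest.raises(DataQualityError):
            impute_min(t)


class TestFilterQcCv:
    def test_cv_50pct_removed_cv_10pct_retained(self, toy_table):
        # QC signals: A=(10,10,10) cv 0; B=(9,10,11) cv 0.1; C=(5,10,15) cv 0.5
        out = filter_qc_cv(toy_table)
        assert list(out.signal.columns) == ["A", "B"]
        assert out.log[-1]["removed"] == ["C"]

    def test_retained_values_untouched(self, toy_table):
        out = filter_qc_cv(toy_table)
        pd.testing.assert_frame_equal(out.signal, toy_table.signal[["A", "B"]])

    def test_fewer_than_two_qc_rejected(self):
        t = build_table({"A": [1.0, 2, 3]}, ["DD", "DN", "QC"])
        with pytest.raises(DataQualityError):
            filter_qc_cv(t)


class TestTotalSumNormalize:
    def test_sample_2_2_4_becomes_quarter_quarter_half(self):
        t = build_table(
            {"A": [2.0, 1], "B": [2.0, 1], "C": [4.0, 2]}, ["DD", "DN"]
        )
        out = total_sum_normalize(t)
        np.testing.assert_allclose(
            out.signal.loc["S1"].to_numpy(), [0.25, 0.25, 0.5]
        )

    def test_idempotent(self, toy_table):
        once = total_sum_normalize(toy_table)
        twice = total_sum_normalize(once)
        pd.testing.assert_frame_equal(once.signal, twice.signal)

    def test_rows_sum_to_one(self):
        table, _ = gen_omics_table(OmicsSimConfig(n_features=30, seed=5))
        out = total_sum_normalize(table)
        np.testing.assert_allclose(
            out.signal.sum(axis=1).to_numpy(), 1.0, atol=1e-12
        )

    def test_zero_total_sample_named(self):
        t = build_table({"A": [0.0, 1.0], "B": [0.0, 2.0]}, ["DD", "DN"])
        with pytest.raises(DataQualityError, match="S1"):
            total_sum_normalize(t)


class TestPipeline:
    def test_run_record_proves_canonical_order(self):
        table, _ = gen_omics_table(
            OmicsSimConfig(n_features=50, missing_frac=0.2, seed=8)
        )
        out = run_lcms_pipeline(table)
        assert tuple(e["step"] for e in out.log) == PIPELINE_ORDER

    def test_filters_only_remove_never_alter(self):
        table, _ = gen_omics_table(
            OmicsSimConfig(n_features=60, qc_cv=np.linspace(0.0, 0.6, 60), seed=9)
        )
        out = filter_qc_cv(table)
        pd.testing.assert_frame_equal(
            out.signal, table.signal[out.signal.columns]
        )


class TestBHAdjust:
    def test_textbook_example_all_point_zero_four(self):
        q = bh_adjust([0.01, 0.02, 0.03, 0.04])
        np.testing.assert_allclose(q, [0.04, 0.04, 0.04, 0.04])

    def test_single_p_unchanged(self):
        assert bh_adjust([0.2])[0] == pytest.approx(0.2)

    def test_out_of_range_rejected(self):
        with pytest.raises(ParameterError):
            bh_adjust([0.5, 1.2])

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(st.lists(st.floats(0.0, 1.0), min_size=1, max_size=50))
    def test_matches_brute_force_oracle(self, pvals):
        np.testing.assert_allclose(bh_adjust(pvals), brute_force_bh(pvals), atol=1e-12)

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(st.lists(st.floats(0.0, 1.0), min_size=2, max_size=30))
    def test_q_at_least_p_and_monotone(self, pvals):
        q = bh_adjust(pvals)
        p = np.asarray(pvals)
        assert (q >= p - 1e-12).all() and (q <= 1.0).all()
        order = np.argsort(p, kind="stable")
        assert (np.diff(q[order]) >= -1e-12).all()


class TestDifferential:
    def make_normalized(self, a_rows, b_rows):
        sig = {
            f"F{j}": [row[j] for row in a_rows + b_rows]
            for j in range(len(a_rows[0]))
        }
        t = build_table(sig, ["DD"] * len(a_rows) + ["DN"] * len(b_rows))
        return t

    def test_identical_groups_give_zero_log2fc(self):
        t = self.make_normalized([[1.0, 2.0], [3.0, 4.0]], [[1.0, 2.0], [3.0, 4.0]])
        res = differential(t, "DD", "DN")
        np.testing.assert_allclose(res.table["log2fc"], 0.0)

    def test_doubling_gives_log2fc_one(self):
        t = self.make_normalized([[1.0, 3.0], [1.0, 3.0]], [[2.0, 6.0], [2.0, 6.0]])
        res = differential(t, "DD", "DN")
        np.testing.assert_allclose(res.table["log2fc"], 1.0)

    def test_zero_group_mean_flagged_not_raised(self):
        t = self.make_normalized([[0.0, 1.0], [0.0, 2.0]], [[1.0, 2.0], [2.0, 4.0]])
        res = differential(t, "DD", "DN")
        assert bool(res.table["undefined_fc"].iloc[0])
        assert np.isnan(res.table["log2fc"].iloc[0])
        assert not res.table["undefined_fc"].iloc[1]

    def test_injected_effect_recovered_on_average(self):
        # 1000 independent features at log2fc = 1, n = 5/group, CV 20%
        cfg = OmicsSimConfig(
            n_per_group=5, n_features=1000, true_log2fc=1.0, sample_cv=0.2,
            n_qc=0, seed=12,
        )
        table, _ = gen_omics_table(cfg)
        res = differential(table, "DD", "DN")
        assert res.table["log2fc"].mean() == pytest.approx(1.0, abs=0.15)

    def test_sign_agreement_for_unit_effects_after_normalization(self):
        fc = np.where(np.arange(600) % 2 == 0, 1.0, -1.0)
        cfg = OmicsSimConfig(
            n_per_group=5, n_features=600, true_log2fc=fc, sample_cv=0.25,
            seed=13,
        )
        table, truth = gen_omics_table(cfg)
        out = run_lcms_pipeline(table)
        res = differential(out, "DD", "DN")
        est = res.table.loc[out.signal.columns, "log2fc"]
        agree = np.sign(est) == np.sign(truth.loc[out.signal.columns, "true_log2fc"])
        assert agree.mean() >= 0.99

    def test_welch_and_mannwhitney_selectable(self):
        table, _ = gen_omics_table(OmicsSimConfig(n_features=10, seed=14))
        for test in ("welch", "mannwhitney"):
            res = differential(table, "DD", "DN", test=test)
            assert res.table["p"].between(0, 1).all()


class TestZScoreMatrix:
    def test_1_2_3_becomes_minus1_0_1(self):
        t = build_table({"A": [1.0, 2.0, 3.0]}, ["DD", "DN", "DN"])
        hm = zscore_matrix(t)
        np.testing.assert_allclose(hm.z.loc["A"].to_numpy(), [-1.0, 0.0, 1.0])

    def test_constant_feature_all_zero_and_flagged(self):
        t = build_table({"A": [5.0, 5.0, 5.0], "B": [1.0, 2.0, 3.0]}, ["DD", "DN", "DN"])
        hm = zscore_matrix(t)
        assert hm.constant_features == ["A"]
        assert (hm.z.loc["A"] == 0.0).all()

    def test_rows_have_mean_zero_sd_one(self):
        table, _ = gen_omics_table(OmicsSimConfig(n_features=25, seed=15))
        hm = zscore_matrix(total_sum_normalize(table))
        np.testing.assert_allclose(hm.z.mean(axis=1), 0.0, atol=1e-9)
        np.testing.assert_allclose(hm.z.std(axis=1, ddof=1), 1.0, atol=1e-9)
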