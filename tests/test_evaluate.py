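"""Metrics, patient-wise cross-validation, aggregation and paired t-tests."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sstats

from conftest import P2_OUTPUTS
from ecgrecon import (
    EvalReport,
    PipelineConfig,
    compare_reports,
    cross_validate,
    make_patient_folds,
    make_pipeline,
    paired_ttest,
    pearson_r,
    rmse,
    summarize,
    write_report,
)


class TestPearson:
    def test_worked_values(self):
        assert pearson_r([1, 2, 3], [2, 4, 6]) == pytest.approx(1.0)
        assert pearson_r([1, 2, 3], [3, 2, 1]) == pytest.approx(-1.0)
        assert pearson_r([1, 2, 3, 4], [1, 3, 2, 4]) == pytest.approx(0.8)

    def test_symmetry_and_affine_invariance(self):
        rng = np.random.default_rng(0)
        x, y = rng.normal(size=(2, 100))
        assert pearson_r(x, y) == pytest.approx(pearson_r(y, x), abs=1e-15)
        assert pearson_r(2.5 * x + 1.0, y) == pytest.approx(pearson_r(x, y), abs=1e-12)

    def test_matches_scipy_oracle(self):
        rng = np.random.default_rng(42)
        for _ in range(200):
            n = rng.integers(5, 200)
            x = rng.normal(size=n)
            y = rng.normal(size=n)
            assert abs(pearson_r(x, y) - sstats.pearsonr(x, y).statistic) < 1e-12

    def test_constant_vector_undefined(self):
        with pytest.raises(ZeroDivisionError):
            pearson_r([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])


class TestRMSE:
    def test_worked_values(self):
        assert rmse([1.0, 2.0], [1.0, 2.0]) == 0.0
        assert rmse(np.zeros(7), np.ones(7)) == pytest.approx(1.0)
        assert rmse([0.0, 0.0], [3.0, 4.0]) == pytest.approx(np.sqrt(12.5))

    def test_matches_sklearn_oracle(self):
        from sklearn.metrics import mean_squared_error

        rng = np.random.default_rng(7)
        for _ in range(50):
            x, y = rng.normal(size=(2, 64))
            assert abs(rmse(x, y) - np.sqrt(mean_squared_error(x, y))) < 1e-12

    def test_shape_mismatch(self):
        with pytest.raises(ValueError):
            rmse(np.zeros(3), np.zeros(4))


class TestFolds:
    def test_sizes_and_determinism(self):
        pats = [f"p{i}" for i in range(10)]
        folds = make_patient_folds(pats, k=5, seed=3)
        counts = np.bincount(list(folds.values()), minlength=5)
        assert list(counts) == [2, 2, 2, 2, 2]
        assert folds == make_patient_folds(pats, k=5, seed=3)
        assert folds != make_patient_folds(pats, k=5, seed=4)

    def test_large_partition(self):
        pats = [f"p{i}" for i in range(10_000)]
        folds = make_patient_folds(pats, k=5, seed=0)
        counts = np.bincount(list(folds.values()), minlength=5)
        assert list(counts) == [2000] * 5
        assert set(folds) == set(pats)

    def test_uneven_sizes_differ_by_one(self):
        folds = make_patient_folds([f"p{i}" for i in range(13)], k=5, seed=1)
        counts = np.bincount(list(folds.values()), minlength=5)
        assert counts.max() - counts.min() <= 1

    def test_too_few_patients(self):
        with pytest.raises(ValueError):
            make_patient_folds(["a", "b"], k=5)


class _OraclePipeline:
    """Predicts the true output leads exactly."""

    output_names = P2_OUTPUTS

    def clone(self):
        return self

    def fit(self, items):
        return self

    def build_target(self, item):
        return item.record.subset(self.output_names)

    def predict(self, item):
        return self.build_target(item).copy()


class _ZeroPipeline(_OraclePipeline):
    def predict(self, item):
        return np.zeros_like(self.build_target(item))


class TestCrossValidate:
    def test_perfect_pipeline(self, global_cohort):
        folds = make_patient_folds(
            [it.record.patient_id for it in global_cohort.items], k=5, seed=0
        )
        report = cross_validate(_OraclePipeline(), global_cohort.items, folds)
        assert np.allclose(report.per_record["r"], 1.0)
        assert np.all(report.per_record["rmse"] == 0.0)
        # every record in exactly one test fold
        assert len(report.per_record) == len(global_cohort.items) * len(P2_OUTPUTS)

    def test_zero_pipeline(self, global_cohort):
        folds = make_patient_folds(
            [it.record.patient_id for it in global_cohort.items], k=5, seed=0
        )
        report = cross_validate(_ZeroPipeline(), global_cohort.items, folds)
        assert report.n_undefined_r == len(report.per_record)
        assert report.per_record["r"].isna().all()
        it = global_cohort.items[0]
        row = report.per_record[
            (report.per_record.record_id == it.record.record_id)
            & (report.per_record.lead == "V1")
        ]
        rms_amp = float(np.sqrt(np.mean(it.record.lead("V1") ** 2)))
        assert row["rmse"].iloc[0] == pytest.approx(rms_amp)

    def test_p2_on_global_cohort(self, global_cohort):
        folds = make_patient_folds(
            [it.record.patient_id for it in global_cohort.items], k=5, seed=0
        )
        pipe = make_pipeline(PipelineConfig(variant="p2"))
        report = cross_validate(pipe, global_cohort.items, folds)
        assert report.per_record["r"].mean() >= 0.9999

    def test_missing_fold_assignment(self, global_cohort):
        with pytest.raises(ValueError):
            cross_validate(_OraclePipeline(), global_cohort.items, {"nobody": 0})


class TestPairedTTest:
    def test_worked_value(self):
        res = paired_ttest([1.0, 2.0, 3.0], [0.0, 0.0, 0.0])
        assert res.t == pytest.approx(3.4641, abs=1e-4)
        assert res.df == 2
        assert res.p == pytest.approx(0.0742, abs=1e-4)

    def test_matches_scipy(self):
        rng = np.random.default_rng(11)
        a, b = rng.normal(size=(2, 30))
        res = paired_ttest(a, b)
        ref = sstats.ttest_rel(a, b)
        assert res.t == pytest.approx(ref.statistic, abs=1e-12)
        assert res.p == pytest.approx(ref.pvalue, abs=1e-12)

    def test_antisymmetry(self):
        rng = np.random.default_rng(12)
        a, b = rng.normal(size=(2, 20))
        fwd, rev = paired_ttest(a, b), paired_ttest(b, a)
        assert fwd.t == pytest.approx(-rev.t)
        assert fwd.p == pytest.approx(rev.p)

    def test_degenerate_cases(self):
        same = paired_ttest([1.0, 2.0], [1.0, 2.0])
        assert (same.t, same.p, same.degenerate) == (0.0, 1.0, True)
        shifted = paired_ttest([2.0, 3.0], [1.0, 2.0])
        assert shifted.p == 0.0 and shifted.degenerate


def tiny_report(values, lead="V1"):
    rows = [
        {"record_id": f"r{i}", "patient_id": f"p{i}", "fold": 0, "lead": lead,
         "r": v, "rmse": 1.0 - v}
        for i, v in enumerate(values)
    ]
    return EvalReport(per_record=pd.DataFrame(rows), pipeline="toy")


class TestSummarize:
    def test_single_record_all_ones(self):
        rows = [
            {"record_id": "r0", "patient_id": "p0", "fold": 0, "lead": lead, "r": 1.0, "rmse": 0.0}
            for lead in P2_OUTPUTS
        ]
        report = EvalReport(per_record=pd.DataFrame(rows))
        tables = summarize(report)
        assert np.allclose(tables["r"]["median"], 1.0)
        assert np.allclose(tables["r"]["mean"], 1.0)
        assert np.allclose(tables["r"]["sd"], 0.0)

    def test_sd_convention(self):
        tables = summarize(tiny_report([0.8, 1.0]))
        assert tables["r"].loc["V1", "median"] == pytest.approx(0.9)
        assert tables["r"].loc["V1", "mean"] == pytest.approx(0.9)
        assert tables["r"].loc["V1", "sd"] == pytest.approx(0.1414, abs=1e-4)
        # population SD is available via the ddof switch
        assert summarize(tiny_report([0.8, 1.0]), sd_ddof=0)["r"].loc[
            "V1", "sd"
        ] == pytest.approx(0.1)

    def test_average_row_is_mean_of_lead_rows(self, global_cohort):
        folds = make_patient_folds(
            [it.record.patient_id for it in global_cohort.items], k=5, seed=0
        )
        pipe = make_pipeline(PipelineConfig(variant="p2"))
        report = cross_validate(pipe, global_cohort.items, folds)
        table = summarize(report)["r"]
        lead_rows = table.drop(index="Average")
        np.testing.assert_allclose(table.loc["Average"], lead_rows.mean(axis=0))
        for col in ("q1", "q3", "min", "max"):
            assert col in table.columns

    def test_permutation_invariance(self):
        rep = tiny_report([0.5, 0.7, 0.9, 1.0])
        shuffled = EvalReport(
            per_record=rep.per_record.sample(frac=1.0, random_state=1).reset_index(drop=True)
        )
        pd.testing.assert_frame_equal(summarize(rep)["r"], summarize(shuffled)["r"])


class TestCompareReports:
    def test_self_comparison_flagged_equal(self):
        rep = tiny_report([0.5, 0.7, 0.9])
        comps = compare_reports(rep, rep)
        assert len(comps) == 1
        assert comps[0]["t"] == 0.0 and comps[0]["p"] == 1.0
        assert not comps[0]["significant"]

    def test_disjoint_reports_rejected(self):
        a = tiny_report([0.5, 0.7])
        b = tiny_report([0.5, 0.7], lead="V4")
        with pytest.raises(ValueError):
            compare_reports(a, b)


class TestReportExport:
    def test_files_written(self, tmp_path, global_cohort):
        folds = make_patient_folds(
            [it.record.patient_id for it in global_cohort.items], k=5, seed=0
        )
        pipe = make_pipeline(PipelineConfig(variant="p2"))
        report = cross_validate(pipe, global_cohort.items, folds, collect_traces=1)
        out = write_report(report, tmp_path / "rep")
        assert (out / "per_record.csv").exists()
        assert (out / "aggregates.json").exists()
        traces = list((out / "traces").glob("*.csv"))
        assert len(traces) == 1
        frame = pd.read_csv(traces[0])
        assert "V1_original" in frame.columns and "V1_reconstructed" in frame.columns
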