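"""Reconstruction analysis: per-record per-lead Pearson r and RMSE,
patient-wise k-fold cross-validation, aggregate tables and paired t-tests.

Correlation and RMSE are computed per record per lead over all samples of the
record, then aggregated across test records pooled over folds (medians, means,
SDs, quartiles).  Records with a constant original or predicted
signal have undefined correlation; they are excluded from the r aggregates and
counted.  Paired t-tests compare two pipelines' per-record per-lead RMSE
values from the same folds, two-sided, with no multiple-testing correction
(raw p < 0.05 marks significance).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sstats

__all__ = [
    "pearson_r",
    "rmse",
    "make_patient_folds",
    "cross_validate",
    "paired_ttest",
    "PairedTTest",
    "EvalReport",
    "summarize",
    "compare_reports",
    "write_report",
]

SIGNIFICANCE_ALPHA = 0.05


def pearson_r(x: np.ndarray, y: np.ndarray) -> float:
    """Pearson correlation coefficient, r = sum((x-x̄)(y-ȳ)) / sqrt(sum(x-x̄)² sum(y-ȳ)²).

    Raises ``ZeroDivisionError`` when either vector is constant (the
    denominator vanishes); cross-validation reports these as missing.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError(f"x and y must be equal-length vectors, got {x.shape} vs {y.shape}")
    if x.size < 2:
        raise ValueError("need at least 2 samples")
    xd = x - x.mean()
    yd = y - y.mean()
    denom = math.sqrt(float(xd @ xd) * float(yd @ yd))
    if denom == 0.0:
        raise ZeroDivisionError("correlation undefined: constant input vector")
    return float(xd @ yd) / denom


def rmse(x: np.ndarray, y: np.ndarray) -> float:
    """Root mean squared error sqrt(mean((y - x)²)) between original x and
    prediction y, in mV."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError(f"shape mismatch: {x.shape} vs {y.shape}")
    if x.size < 1:
        raise ValueError("need at least 1 sample")
    return float(np.sqrt(np.mean((y - x) ** 2)))


def make_patient_folds(
    patient_ids: Sequence[str], k: int = 5, seed: int = 0
) -> dict[str, int]:
    """Partition distinct patients into k folds of near-equal size (±1),
    deterministically for a seed.  All records of a patient share its fold."""
    distinct = sorted(set(patient_ids))
    if len(distinct) < k:
        raise ValueError(f"need at least {k} distinct patients, got {len(distinct)}")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(distinct))
    folds: dict[str, int] = {}
    for pos, idx in enumerate(order):
        folds[distinct[idx]] = pos % k
    return folds


@dataclass
class PairedTTest:
    t: float
    p: float
    df: int
    degenerate: bool = False


def paired_ttest(errors_a: Sequence[float], errors_b: Sequence[float]) -> PairedTTest:
    """Classical paired t-test on per-record error values (two-sided).

    Degenerate cases: all-zero differences give (t=0, p=1); zero-variance
    nonzero differences give p=0; both are flagged.
    """
    a = np.asarray(errors_a, dtype=float)
    b = np.asarray(errors_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("paired samples must be equal-length vectors")
    if a.size < 2:
        raise ValueError("need at least 2 pairs")
    d = a - b
    n = d.size
    sd = d.std(ddof=1)
    if sd == 0.0:
        if np.all(d == 0.0):
            return PairedTTest(t=0.0, p=1.0, df=n - 1, degenerate=True)
        return PairedTTest(t=math.copysign(math.inf, d.mean()), p=0.0, df=n - 1, degenerate=True)
    t = float(d.mean() / (sd / math.sqrt(n)))
    p = float(2.0 * sstats.t.sf(abs(t), df=n - 1))
    return PairedTTest(t=t, p=p, df=n - 1)


@dataclass
class EvalReport:
    """Cross-validation results: one row per (record, lead) plus metadata."""

    per_record: pd.DataFrame  # record_id, patient_id, fold, lead, r, rmse
    pipeline: str = ""
    n_undefined_r: int = 0
    comparisons: list[dict] = field(default_factory=list)

    @property
    def leads(self) -> list[str]:
        return list(dict.fromkeys(self.per_record["lead"]))


def cross_validate(
    pipeline,
    items: Sequence,
    folds: Mapping[str, int],
    *,
    collect_traces: int = 0,
) -> EvalReport:
    """Patient-wise cross-validation of one reconstruction pipeline.

    For each fold the pipeline is re-fitted on all out-of-fold patients'
    records and evaluated on the in-fold records; per-record per-lead r and
    RMSE are pooled across folds.  ``collect_traces`` keeps reconstructed-vs-
    original traces for that many test records (for later export).
    """
    for it in items:
        if it.record.patient_id not in folds:
            raise ValueError(f"patient {it.record.patient_id!r} has no fold assignment")
    k = max(folds.values()) + 1
    rows = []
    n_undefined = 0
    traces: list[dict] = []
    for fold in range(k):
        train = [it for it in items if folds[it.record.patient_id] != fold]
        test = [it for it in items if folds[it.record.patient_id] == fold]
        if not train or not test:
            raise ValueError(f"fold {fold} has an empty train or test split")
        train_pats = {it.record.patient_id for it in train}
        test_pats = {it.record.patient_id for it in test}
        assert not train_pats & test_pats, "patient leaked across the fold boundary"
        fitted = pipeline.clone().fit(train)
        for it in test:
            Y = fitted.build_target(it)
            Yhat = fitted.predict(it)
            for j, lead in enumerate(fitted.output_names):
                try:
                    r_val = pearson_r(Y[:, j], Yhat[:, j])
                except ZeroDivisionError:
                    r_val = np.nan
                    n_undefined += 1
                rows.append(
                    {
                        "record_id": it.record.record_id,
                        "patient_id": it.record.patient_id,
                        "fold": fold,
                        "lead": lead,
                        "r": r_val,
                        "rmse": rmse(Y[:, j], Yhat[:, j]),
                    }
                )
            if len(traces) < collect_traces:
                traces.append(
                    {
                        "record_id": it.record.record_id,
                        "leads": list(fitted.output_names),
                        "original": Y,
                        "reconstructed": Yhat,
                    }
                )
    report = EvalReport(
        per_record=pd.DataFrame(rows),
        pipeline=getattr(getattr(pipeline, "config", None), "variant", ""),
        n_undefined_r=n_undefined,
    )
    report.traces = traces  # type: ignore[attr-defined]
    return report


def _column_stats(values: np.ndarray, ddof: int) -> dict[str, float]:
    values = values[~np.isnan(values)]
    if values.size == 0:
        return {k: math.nan for k in ("median", "mean", "sd", "q1", "q3", "min", "max")}
    return {
        "median": float(np.median(values)),
        "mean": float(np.mean(values)),
        "sd": float(np.std(values, ddof=ddof)) if values.size > ddof else 0.0,
        "q1": float(np.percentile(values, 25)),
        "q3": float(np.percentile(values, 75)),
        "min": float(np.min(values)),
        "max": float(np.max(values)),
    }


def summarize(report: EvalReport, *, sd_ddof: int = 1) -> dict[str, pd.DataFrame]:
    """Aggregate tables: per-lead median/mean/SD (plus an unweighted Average
    row) for r and RMSE, box-plot summaries (quartiles, min, max), and
    significance markers for any attached comparisons.

    SD is the sample SD by default (``sd_ddof=1``; set 0 for the population
    convention — the distinction is immaterial at cohort scale but a fixed
    choice keeps outputs deterministic).
    """
    if report.per_record.empty:
        raise ValueError("empty report")
    out: dict[str, pd.DataFrame] = {}
    for metric in ("r", "rmse"):
        rows = {}
        for lead in report.leads:
            vals = report.per_record.loc[report.per_record["lead"] == lead, metric].to_numpy()
            rows[lead] = _column_stats(vals, sd_ddof)
        table = pd.DataFrame(rows).T
        table.loc["Average"] = table.mean(axis=0)
        out[metric] = table
    if report.comparisons:
        out["significance"] = pd.DataFrame(report.comparisons)
    return out


def compare_reports(report_a: EvalReport, report_b: EvalReport) -> list[dict]:
    """Per-lead paired t-tests on RMSE between two reports sharing records.

    Rows are aligned on (record_id, lead); disjoint reports raise.
    """
    a = report_a.per_record.set_index(["record_id", "lead"])
    b = report_b.per_record.set_index(["record_id", "lead"])
    common = a.index.intersection(b.index)
    if common.empty:
        raise ValueError("reports share no (record, lead) pairs")
    comparisons = []
    for lead in report_a.leads:
        idx = [ix for ix in common if ix[1] == lead]
        if len(idx) < 2:
            continue
        res = paired_ttest(a.loc[idx, "rmse"].to_numpy(), b.loc[idx, "rmse"].to_numpy())
        comparisons.append(
            {
                "lead": lead,
                "pipeline_a": report_a.pipeline,
                "pipeline_b": report_b.pipeline,
                "t": res.t,
                "p": res.p,
                "df": res.df,
                "significant": bool(res.p < SIGNIFICANCE_ALPHA),
                "degenerate": res.degenerate,
                "better": (
                    "equal"
                    if res.t == 0
                    else (report_b.pipeline or "b") if res.t > 0 else (report_a.pipeline or "a")
                ),
            }
        )
    return comparisons


def write_report(report: EvalReport, directory: str | Path, *, sd_ddof: int = 1) -> Path:
    """Export per-record CSV, aggregate JSON, and any collected traces."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    report.per_record.to_csv(directory / "per_record.csv", index=False)
    tables = summarize(report, sd_ddof=sd_ddof)
    payload = {
        "pipeline": report.pipeline,
        "n_undefined_r": report.n_undefined_r,
        "sd_convention": f"ddof={sd_ddof} (sample SD when 1)",
        "multiple_testing_correction": "none (raw p < 0.05)",
        "aggregates": {
            metric: tables[metric].to_dict(orient="index") for metric in ("r", "rmse")
        },
        "comparisons": report.comparisons,
    }
    (directory / "aggregates.json").write_text(json.dumps(payload, indent=1))
    traces = getattr(report, "traces", [])
    if traces:
        tdir = directory / "traces"
        tdir.mkdir(exist_ok=True)
        for tr in traces:
            frame = pd.DataFrame(
                {
                    **{f"{l}_original": tr["original"][:, j] for j, l in enumerate(tr["leads"])},
                    **{f"{l}_reconstructed": tr["reconstructed"][:, j] for j, l in enumerate(tr["leads"])},
                }
            )
            frame.to_csv(tdir / f"{tr['record_id']}.csv", index=False)
    return directory
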