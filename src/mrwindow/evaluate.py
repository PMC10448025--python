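"""Quantitative evaluation: MRE, MAE, Pearson's rho, and the naive baseline.

Metrics over T aligned (prediction, truth) pairs:

    MRE = (1/T) * sum |(yhat_t - y_t) / y_t| * 100        [percent]
    MAE = (1/T) * sum |yhat_t - y_t|                      [intensity units]
    rho = cov(yhat, y) / (sd(yhat) * sd(y))               [dimensionless]

computed separately for WL and WW and stratified by operator, plus an
across-operator average row (the mean of the operator-level metrics).  The
naive baseline predicts, for every test record of a condition, the
training-set mean WL/WW of that condition pooled over all operators — it
ignores both observer identity and the image's histogram.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .core import ImagingCondition, WindowSetting, WindowingRecord
from .errors import ValidationError
from .predict import Prediction

logger = logging.getLogger(__name__)

#: Column order of the emitted report.
REPORT_COLUMNS = [
    "method",
    "operator",
    "MRE_WL",
    "MAE_WL",
    "rho_WL",
    "MRE_WW",
    "MAE_WW",
    "rho_WW",
    "T",
]


def _check_lengths(pred: np.ndarray, truth: np.ndarray) -> None:
    if pred.shape != truth.shape:
        raise ValidationError(
            f"prediction/truth length mismatch: {pred.shape} vs {truth.shape}"
        )


def mre(pred: Sequence[float], truth: Sequence[float]) -> float:
    """Mean relative error in percent; truth values must be nonzero."""
    p = np.asarray(pred, dtype=float)
    t = np.asarray(truth, dtype=float)
    _check_lengths(p, t)
    zero = np.nonzero(t == 0)[0]
    if zero.size:
        raise ValidationError(
            f"relative error undefined: truth is zero at index {zero[0]}"
        )
    return float(np.mean(np.abs((p - t) / t)) * 100.0)


def mae(pred: Sequence[float], truth: Sequence[float]) -> float:
    """Mean absolute error in the inputs' (intensity) units."""
    p = np.asarray(pred, dtype=float)
    t = np.asarray(truth, dtype=float)
    _check_lengths(p, t)
    return float(np.mean(np.abs(p - t)))


def pearson(pred: Sequence[float], truth: Sequence[float]) -> float:
    """Pearson correlation, population (1/T) normalization throughout."""
    p = np.asarray(pred, dtype=float)
    t = np.asarray(truth, dtype=float)
    _check_lengths(p, t)
    if p.size < 2:
        raise ValidationError("correlation needs at least 2 pairs")
    sp = p.std()  # population normalization; cancels either way
    st = t.std()
    if sp == 0 or st == 0:
        raise ValidationError("correlation undefined for a constant input")
    cov = np.mean((p - p.mean()) * (t - t.mean()))
    return float(cov / (sp * st))


def naive_baseline(
    train: Sequence[WindowingRecord],
) -> Dict[ImagingCondition, WindowSetting]:
    """Per-condition mean native WL/WW over the training set, all operators pooled."""
    if not train:
        raise ValidationError("naive baseline needs at least one training record")
    by_cond: Dict[ImagingCondition, List[WindowingRecord]] = {}
    for r in train:
        by_cond.setdefault(r.condition, []).append(r)
    return {
        cond: WindowSetting(
            wl=float(np.mean([r.window.wl for r in recs])),
            ww=float(np.mean([r.window.ww for r in recs])),
        )
        for cond, recs in by_cond.items()
    }


@dataclass
class EvaluationReport:
    """Operator-stratified metric table for one or more methods."""

    table: pd.DataFrame  # REPORT_COLUMNS

    def to_text(self) -> str:
        """Human-readable aligned table."""
        df = self.table.copy()
        for c in df.columns:
            if c.startswith(("MRE", "MAE")):
                df[c] = df[c].map(lambda v: f"{v:.1f}")
            elif c.startswith("rho"):
                df[c] = df[c].map(lambda v: f"{v:.2f}")
        return df.to_string(index=False)

    def write(self, path, delimiter: str = "\t") -> None:
        self.table.to_csv(path, sep=delimiter, index=False)

    def average_row(self, method: str) -> pd.Series:
        sel = self.table[
            (self.table["method"] == method) & (self.table["operator"] == "Average")
        ]
        if sel.empty:
            raise ValidationError(f"no Average row for method {method!r}")
        return sel.iloc[0]


def _metric_row(p_wl, t_wl, p_ww, t_ww) -> Dict[str, float]:
    return {
        "MRE_WL": mre(p_wl, t_wl),
        "MAE_WL": mae(p_wl, t_wl),
        "rho_WL": pearson(p_wl, t_wl),
        "MRE_WW": mre(p_ww, t_ww),
        "MAE_WW": mae(p_ww, t_ww),
        "rho_WW": pearson(p_ww, t_ww),
        "T": len(p_wl),
    }


def evaluate(
    pairs: pd.DataFrame,
    method: str = "framework",
    operators: Optional[Sequence[int]] = None,
) -> EvaluationReport:
    """Metric table from aligned pairs.

    ``pairs`` needs columns operator, wl_pred, wl_true, ww_pred, ww_true
    (one row per evaluated record).  Rows are stratified by operator; the
    Average row is the mean of the operator-level metrics.  An operator
    stratum that is empty or too small for a correlation is skipped with a
    warning.
    """
    required = {"operator", "wl_pred", "wl_true", "ww_pred", "ww_true"}
    missing = required - set(pairs.columns)
    if missing:
        raise ValidationError(f"pairs missing column(s): {sorted(missing)}")
    operators = operators or sorted(pairs["operator"].unique())
    rows = []
    for op in operators:
        grp = pairs[pairs["operator"] == op]
        if len(grp) < 2:
            warnings.warn(f"operator {op}: stratum too small ({len(grp)}); skipped")
            continue
        row = {"method": method, "operator": f"Operator-{op}"}
        row.update(
            _metric_row(
                grp["wl_pred"].to_numpy(),
                grp["wl_true"].to_numpy(),
                grp["ww_pred"].to_numpy(),
                grp["ww_true"].to_numpy(),
            )
        )
        rows.append(row)
    if not rows:
        raise ValidationError("no evaluable operator stratum")
    df = pd.DataFrame(rows)
    avg = {"method": method, "operator": "Average"}
    for c in REPORT_COLUMNS[2:-1]:
        avg[c] = float(df[c].mean())
    avg["T"] = int(df["T"].sum())
    # pooled alternative, logged for comparison with the per-operator mean
    pooled = _metric_row(
        pairs["wl_pred"].to_numpy(),
        pairs["wl_true"].to_numpy(),
        pairs["ww_pred"].to_numpy(),
        pairs["ww_true"].to_numpy(),
    )
    logger.debug("pooled-record average metrics (not reported): %s", pooled)
    df = pd.concat([df, pd.DataFrame([avg])], ignore_index=True)
    return EvaluationReport(table=df[REPORT_COLUMNS])


def align_predictions(
    predictions: Sequence[Prediction], test: Sequence[WindowingRecord]
) -> pd.DataFrame:
    """Join framework predictions with test records on (series, operator)."""
    by_key = {(p.series_id, p.operator): p for p in predictions}
    rows = []
    for r in test:
        p = by_key.get((r.series_id, r.operator))
        if p is None:
            raise ValidationError(
                f"no prediction for series {r.series_id!r}, operator {r.operator}"
            )
        rows.append(
            {
                "operator": r.operator,
                "wl_pred": p.window.wl,
                "wl_true": r.window.wl,
                "ww_pred": p.window.ww,
                "ww_true": r.window.ww,
            }
        )
    return pd.DataFrame(rows)


def align_naive(
    baseline: Dict[ImagingCondition, WindowSetting],
    test: Sequence[WindowingRecord],
    per_operator: bool = False,
    train: Optional[Sequence[WindowingRecord]] = None,
) -> pd.DataFrame:
    """Pair each test record with the naive per-condition mean.

    With ``per_operator=True`` (sensitivity variant) the baseline is
    recomputed per operator from ``train`` instead of pooling operators.
    """
    if per_operator:
        if train is None:
            raise ValidationError("per-operator naive baseline needs train records")
        tables = {
            op: naive_baseline([r for r in train if r.operator == op])
            for op in sorted({r.operator for r in train})
        }
    rows = []
    for r in test:
        table = tables[r.operator] if per_operator else baseline
        w = table.get(r.condition)
        if w is None:
            raise ValidationError(
                f"condition {r.condition.label!r} absent from the training set"
            )
        rows.append(
            {
                "operator": r.operator,
                "wl_pred": w.wl,
                "wl_true": r.window.wl,
                "ww_pred": w.ww,
                "ww_true": r.window.ww,
            }
        )
    return pd.DataFrame(rows)


def compare_methods(
    framework: EvaluationReport, naive: EvaluationReport
) -> EvaluationReport:
    """Stack the two methods' tables into one report."""
    return EvaluationReport(
        table=pd.concat([naive.table, framework.table], ignore_index=True)
    )
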