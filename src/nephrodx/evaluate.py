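"""Diagnostic-accuracy arithmetic: contingency tables, correctness categories,
and chi-square comparison of accuracies.

Metric computation is exact (integer cells, ``decimal`` division) until the
final formatting step, which rounds half-up to one decimal on the percentage
scale; undefined metrics raise typed errors instead of returning NaN.
"""

from __future__ import annotations

import decimal
from dataclasses import dataclass
from typing import Sequence

import pandas as pd
from scipy import stats

from .errors import DegenerateTableError, SchemaError, UndefinedMetricError


def percent(numerator: int, denominator: int, ndigits: int = 1) -> float:
    """``100 * numerator / denominator`` rounded half-up to ``ndigits`` decimals."""
    if denominator <= 0:
        raise UndefinedMetricError("percentage with empty denominator")
    with decimal.localcontext() as ctx:
        ctx.prec = 50
        value = decimal.Decimal(100 * numerator) / decimal.Decimal(denominator)
        quantum = decimal.Decimal(1).scaleb(-ndigits)
        return float(value.quantize(quantum, rounding=decimal.ROUND_HALF_UP))


@dataclass(frozen=True)
class ContingencyTable:
    """TP/FP/FN/TN counts of a binary test against a gold standard."""

    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self) -> None:
        for name in ("tp", "fp", "fn", "tn"):
            v = getattr(self, name)
            if not (isinstance(v, int) and v >= 0):
                raise ValueError(f"{name} must be a nonnegative integer, got {v!r}")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


def build_contingency(predicted: Sequence[bool], truth: Sequence[bool]) -> ContingencyTable:
    """Count (predicted, truth) pairs into the four cells; lengths must match."""
    if len(predicted) != len(truth):
        raise ValueError(f"length mismatch: {len(predicted)} predictions vs {len(truth)} truths")
    if len(predicted) == 0:
        raise ValueError("cannot build a contingency table from empty inputs")
    tp = fp = fn = tn = 0
    for p, t in zip(predicted, truth):
        if p and t:
            tp += 1
        elif p and not t:
            fp += 1
        elif not p and t:
            fn += 1
        else:
            tn += 1
    return ContingencyTable(tp=tp, fp=fp, fn=fn, tn=tn)


def sensitivity(t: ContingencyTable) -> float:
    """``100 * TP / (TP + FN)``, one decimal, round-half-up."""
    if t.tp + t.fn == 0:
        raise UndefinedMetricError("sensitivity undefined: no condition-positive cases")
    return percent(t.tp, t.tp + t.fn)


def specificity(t: ContingencyTable) -> float:
    """``100 * TN / (FP + TN)``, one decimal, round-half-up."""
    if t.fp + t.tn == 0:
        raise UndefinedMetricError("specificity undefined: no condition-negative cases")
    return percent(t.tn, t.fp + t.tn)


def accuracy(t: ContingencyTable) -> float:
    """``100 * (TP + TN) / total``, one decimal, round-half-up."""
    if t.total == 0:
        raise UndefinedMetricError("accuracy undefined: empty table")
    return percent(t.tp + t.tn, t.total)


@dataclass(frozen=True)
class AccuracyBreakdown:
    """Per-patient correctness of the joint (AKI, CKD) call."""

    completely_correct: int
    partially_correct: int
    completely_incorrect: int

    @property
    def total(self) -> int:
        return self.completely_correct + self.partially_correct + self.completely_incorrect

    def percentages(self) -> dict[str, float]:
        return {
            "completely_correct": percent(self.completely_correct, self.total),
            "partially_correct": percent(self.partially_correct, self.total),
            "completely_incorrect": percent(self.completely_incorrect, self.total),
        }


def correctness_categories(per_patient: Sequence[tuple[bool, bool]]) -> AccuracyBreakdown:
    """Classify each (aki_correct, ckd_correct) pair; counts conserve the total."""
    if len(per_patient) == 0:
        raise ValueError("per_patient list must be nonempty")
    both = one = neither = 0
    for aki_ok, ckd_ok in per_patient:
        n_ok = int(bool(aki_ok)) + int(bool(ckd_ok))
        if n_ok == 2:
            both += 1
        elif n_ok == 1:
            one += 1
        else:
            neither += 1
    return AccuracyBreakdown(completely_correct=both, partially_correct=one,
                             completely_incorrect=neither)


@dataclass(frozen=True)
class ChiSquareResult:
    statistic: float
    df: int
    p_value: float


def compare_accuracy(correct_a: int, correct_b: int, n: int,
                     yates: bool = False) -> ChiSquareResult:
    """Pearson chi-square (df=1) comparing two correct-of-n proportions.

    The 2x2 table is ``[[correct_a, n-correct_a], [correct_b, n-correct_b]]``;
    no continuity correction unless ``yates`` is set. A zero marginal makes
    the test undefined and raises :class:`DegenerateTableError`.
    """
    if n < 1 or not (0 <= correct_a <= n and 0 <= correct_b <= n):
        raise ValueError("counts must satisfy 0 <= correct <= n and n >= 1")
    table = [[correct_a, n - correct_a], [correct_b, n - correct_b]]
    if min(correct_a + correct_b, 2 * n - correct_a - correct_b) == 0:
        raise DegenerateTableError(f"zero marginal in {table}")
    statistic, p, df, _ = stats.chi2_contingency(table, correction=yates)
    return ChiSquareResult(statistic=float(statistic), df=int(df), p_value=float(p))


# ---------------------------------------------------------------------------
# Run-level evaluation
# ---------------------------------------------------------------------------

_JOIN_KEYS = ("patient_id", "admit_date")


def _to_frame(obj) -> pd.DataFrame:
    if isinstance(obj, pd.DataFrame):
        return obj.copy()
    return pd.read_csv(obj, dtype=str, keep_default_na=False)


def _bool_col(df: pd.DataFrame, col: str) -> pd.Series:
    truthy = {"1", "true", "t", "yes", "y"}
    return df[col].map(lambda v: bool(v) if isinstance(v, bool)
                       else str(v).strip().lower() in truthy)


def evaluate_run(predictions, reference, *,
                 mechanisms: bool = True) -> dict:
    """Join a diagnosis table against a reference and compute the full report.

    ``predictions`` and ``reference`` are DataFrames or CSV paths with
    ``patient_id`` (plus ``admit_date`` when present in both) and boolean
    ``aki``/``ckd`` columns. Unmatched keys are listed and excluded with a
    warning entry; zero overlap is an error. The report contains the AKI and
    CKD contingency blocks with sensitivity/specificity/accuracy, the
    completely/partially/completely-incorrect breakdown, and — when the
    reference carries a ``mechanisms`` column — the FN/FP cause tally.
    """
    pred = _to_frame(predictions)
    ref = _to_frame(reference)
    for name, df in (("predictions", pred), ("reference", ref)):
        missing = [c for c in ("patient_id", "aki", "ckd") if c not in df.columns]
        if missing:
            raise SchemaError(f"{name} table is missing column(s): {missing}")

    keys = [k for k in _JOIN_KEYS if k in pred.columns and k in ref.columns]
    pred = pred.assign(_aki_p=_bool_col(pred, "aki"), _ckd_p=_bool_col(pred, "ckd"))
    ref = ref.assign(_aki_r=_bool_col(ref, "aki"), _ckd_r=_bool_col(ref, "ckd"))
    merged = pred.merge(ref, on=keys, how="outer", indicator=True,
                        suffixes=("_pred", "_ref"))
    unmatched = merged.loc[merged["_merge"] != "both", keys]
    matched = merged[merged["_merge"] == "both"]
    if matched.empty:
        raise ValueError("predictions and reference share no keys")

    aki_table = build_contingency(matched["_aki_p"].tolist(), matched["_aki_r"].tolist())
    ckd_table = build_contingency(matched["_ckd_p"].tolist(), matched["_ckd_r"].tolist())
    breakdown = correctness_categories(list(zip(
        (matched["_aki_p"] == matched["_aki_r"]).tolist(),
        (matched["_ckd_p"] == matched["_ckd_r"]).tolist(),
    )))

    def _block(t: ContingencyTable) -> dict:
        block = {"tp": t.tp, "fp": t.fp, "fn": t.fn, "tn": t.tn, "total": t.total,
                 "accuracy_pct": accuracy(t)}
        try:
            block["sensitivity_pct"] = sensitivity(t)
        except UndefinedMetricError:
            block["sensitivity_pct"] = None
        try:
            block["specificity_pct"] = specificity(t)
        except UndefinedMetricError:
            block["specificity_pct"] = None
        return block

    report = {
        "n": int(len(matched)),
        "n_unmatched": int(len(unmatched)),
        "unmatched_keys": unmatched.astype(str).to_dict("records"),
        "aki": _block(aki_table),
        "ckd": _block(ckd_table),
        "breakdown": {
            "counts": {
                "completely_correct": breakdown.completely_correct,
                "partially_correct": breakdown.partially_correct,
                "completely_incorrect": breakdown.completely_incorrect,
            },
            "percentages": breakdown.percentages(),
        },
    }

    if mechanisms and "mechanisms" in ref.columns:
        mech = matched["mechanisms"].fillna("")
        fn_aki = matched["_aki_r"] & ~matched["_aki_p"]
        fp_aki = matched["_aki_p"] & ~matched["_aki_r"]
        fn_ckd = matched["_ckd_r"] & ~matched["_ckd_p"]
        report["error_mechanisms"] = {
            "aki_false_negative": mech[fn_aki].value_counts().to_dict(),
            "aki_false_positive": mech[fp_aki].value_counts().to_dict(),
            "ckd_false_negative": mech[fn_ckd].value_counts().to_dict(),
        }
    return report


def compare_reports(report_a: dict, report_b: dict, label_a: str = "a",
                    label_b: str = "b") -> dict:
    """Chi-square accuracy comparison between two evaluation reports on one cohort."""
    if report_a["n"] != report_b["n"]:
        raise ValueError("reports cover different cohort sizes")
    n = report_a["n"]
    out: dict = {"n": n}
    for condition in ("aki", "ckd"):
        ca = report_a[condition]["tp"] + report_a[condition]["tn"]
        cb = report_b[condition]["tp"] + report_b[condition]["tn"]
        chi = compare_accuracy(ca, cb, n)
        out[condition] = {
            f"{label_a}_correct": ca, f"{label_b}_correct": cb,
            f"{label_a}_accuracy_pct": percent(ca, n),
            f"{label_b}_accuracy_pct": percent(cb, n),
            "chi2": chi.statistic, "df": chi.df, "p_value": chi.p_value,
        }
    return out


def report_to_text(report: dict) -> str:
    """Human-readable rendering of an evaluation report."""
    lines = [f"n = {report['n']} (unmatched keys excluded: {report['n_unmatched']})"]
    for condition in ("aki", "ckd"):
        b = report[condition]
        lines.append(f"[{condition.upper()}] TP {b['tp']}  FP {b['fp']}  "
                     f"FN {b['fn']}  TN {b['tn']}")
        lines.append(f"  sensitivity {b['sensitivity_pct']}%  "
                     f"specificity {b['specificity_pct']}%  accuracy {b['accuracy_pct']}%")
    pct = report["breakdown"]["percentages"]
    cnt = report["breakdown"]["counts"]
    lines.append(f"completely correct {cnt['completely_correct']} ({pct['completely_correct']}%), "
                 f"partially correct {cnt['partially_correct']} ({pct['partially_correct']}%), "
                 f"completely incorrect {cnt['completely_incorrect']} "
                 f"({pct['completely_incorrect']}%)")
    if "error_mechanisms" in report:
        lines.append(f"error mechanisms: {report['error_mechanisms']}")
    return "\n".join(lines)
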