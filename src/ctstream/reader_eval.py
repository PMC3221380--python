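"""Diagnostic-accuracy statistics for reader studies.

Binary reader calls are cross-classified against a ground-truth vector
(in the reference study: the first reader's workstation reading) into a
2x2 contingency table, from which sensitivity, specificity and accuracy
derive. Interrater agreement uses unweighted Cohen's kappa. A separate
rule flags per-case discrepancies in ASPECTS grading (the 10-point score
of early ischemic change in the middle-cerebral-artery territory): a
difference of more than one point between readers counts as a discrepancy.

Percentages are reported both at full precision and truncated (floored,
not rounded) to a fixed number of decimals, which is how study tables in
this literature are typically printed: 100*100/105 = 95.238 prints as
95.23.
"""

from __future__ import annotations

import csv
import math
from collections import Counter
from dataclasses import dataclass

import numpy as np

from .errors import UndefinedKappaError, UndefinedMetricError


@dataclass(frozen=True)
class ContingencyTable:
    """TP/FP/TN/FN counts of binary calls against truth."""

    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self):
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise ValueError("contingency counts must be non-negative")

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


@dataclass(frozen=True)
class DiagnosticMetrics:
    """Sensitivity / specificity / accuracy, as percentages."""

    sensitivity: float
    specificity: float
    accuracy: float

    def truncated(self, decimals: int = 2) -> "DiagnosticMetrics":
        """Floor each percentage to ``decimals`` decimals (printed form)."""
        return DiagnosticMetrics(
            *(truncate(v, decimals)
              for v in (self.sensitivity, self.specificity, self.accuracy))
        )


def truncate(value: float, decimals: int) -> float:
    """Truncate toward zero at ``decimals`` decimals (94.117 -> 94.11)."""
    factor = 10 ** decimals
    return math.trunc(value * factor + 1e-9) / factor


def contingency(truth, calls) -> ContingencyTable:
    """Cross-classify binary reader calls against binary truth."""
    truth = np.asarray(truth, dtype=bool)
    calls = np.asarray(calls, dtype=bool)
    if truth.shape != calls.shape:
        raise ValueError("truth and calls must have equal length")
    return ContingencyTable(
        tp=int(np.sum(truth & calls)),
        fp=int(np.sum(~truth & calls)),
        tn=int(np.sum(~truth & ~calls)),
        fn=int(np.sum(truth & ~calls)),
    )


def metrics(t: ContingencyTable) -> DiagnosticMetrics:
    """Sensitivity, specificity and accuracy of a 2x2 table, in percent."""
    if t.n == 0:
        raise UndefinedMetricError("undefined metric: empty table")
    if t.tp + t.fn == 0:
        raise UndefinedMetricError("undefined metric: sensitivity (no positives)")
    if t.tn + t.fp == 0:
        raise UndefinedMetricError("undefined metric: specificity (no negatives)")
    return DiagnosticMetrics(
        sensitivity=100.0 * t.tp / (t.tp + t.fn),
        specificity=100.0 * t.tn / (t.tn + t.fp),
        accuracy=100.0 * (t.tp + t.tn) / t.n,
    )


def cohen_kappa(calls_r1, calls_r2) -> float:
    """Unweighted Cohen's kappa between two categorical rating vectors.

    kappa = (p_o - p_e) / (1 - p_e) with expected agreement from marginal
    products. Identical non-constant vectors give exactly 1.0; two raters
    constant in the same category leave kappa undefined.
    """
    a = list(calls_r1)
    b = list(calls_r2)
    if len(a) != len(b):
        raise ValueError("rating vectors must have equal length")
    n = len(a)
    if n == 0:
        raise ValueError("rating vectors must be non-empty")
    po = sum(x == y for x, y in zip(a, b)) / n
    ca, cb = Counter(a), Counter(b)
    categories = set(ca) | set(cb)
    pe = sum((ca.get(c, 0) / n) * (cb.get(c, 0) / n) for c in categories)
    if pe >= 1.0 - 1e-15:
        raise UndefinedKappaError(
            "kappa undefined: both raters constant in the same category"
        )
    return (po - pe) / (1.0 - pe)


def aspects_discrepancy(scores_r1, scores_r2) -> np.ndarray:
    """Per-case discrepancy flags: |score1 - score2| > 1.

    ASPECTS scores are integers in [0, 10]; a one-point difference is
    tolerated, anything larger is a reading discrepancy.
    """
    s1 = np.asarray(scores_r1)
    s2 = np.asarray(scores_r2)
    if s1.shape != s2.shape:
        raise ValueError("score vectors must have equal length")
    for s in (s1, s2):
        if np.any((s < 0) | (s > 10)):
            raise ValueError("ASPECTS scores must lie in [0, 10]")
    return np.abs(s1.astype(int) - s2.astype(int)) > 1


# ---------------------------------------------------------------------------
# CSV I/O and study-table reproduction
# ---------------------------------------------------------------------------

CSV_FIELDS = ("case_id", "finding", "truth", "reader", "call", "aspects")


def read_responses_csv(path):
    """Read reader responses from CSV with columns case_id, finding,
    truth, reader, call, aspects (aspects may be blank)."""
    rows = []
    with open(path, newline="") as fh:
        for rec in csv.DictReader(fh):
            rows.append({
                "case_id": rec["case_id"],
                "finding": rec["finding"],
                "truth": rec["truth"].strip() in ("1", "true", "True"),
                "reader": int(rec["reader"]),
                "call": rec["call"].strip() in ("1", "true", "True"),
                "aspects": int(rec["aspects"]) if rec.get("aspects") else None,
            })
    return rows


def write_responses_csv(path, rows) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.DictWriter(fh, fieldnames=CSV_FIELDS)
        writer.writeheader()
        for row in rows:
            writer.writerow({k: row.get(k, "") for k in CSV_FIELDS})


def vectors_from_counts(
    tp: int, fp: int, tn: int, fn: int
) -> tuple[np.ndarray, np.ndarray]:
    """Truth/call vectors realizing given contingency counts (canonical order)."""
    truth = np.array([True] * (tp + fn) + [False] * (fp + tn))
    calls = np.array([True] * tp + [False] * fn + [True] * fp + [False] * tn)
    return truth, calls


def reproduce_study_tables():
    """Recompute every printed metric cell from its packaged TP/FP/TN/FN
    counts; returns a list of dicts with computed and printed values."""
    from .study_data import STUDY_ROWS

    report = []
    for row in STUDY_ROWS:
        table = ContingencyTable(tp=row.tp, fp=row.fp, tn=row.tn, fn=row.fn)
        m = metrics(table)
        entry = {"reader": row.reader, "finding": row.finding,
                 "table": table, "full_precision": m}
        for name, printed in (("sensitivity", row.sensitivity),
                              ("specificity", row.specificity),
                              ("accuracy", row.accuracy)):
            decimals = len(printed.split(".")[1]) if "." in printed else 0
            computed = truncate(getattr(m, name), decimals)
            entry[name] = {
                "printed": float(printed),
                "computed": computed,
                "match": abs(computed - float(printed)) < 1e-9,
            }
        report.append(entry)
    return report
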