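"""Overlap metrics for binary segmentation masks.

Dice, Jaccard, precision, and recall per class, computed from pixel-level
confusion counts and aggregated over an evaluation set either as a mean of
per-case metrics (default; every volume weighs equally) or by pooling the
counts first.

Degenerate conventions: a case with empty ground truth and an empty
prediction scores 1.0 on every metric (the model correctly found nothing);
empty ground truth with a non-empty prediction scores 0.0.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

CLASS_NAMES = ("liver", "tumor")
METRIC_NAMES = ("dice", "jaccard", "precision", "recall")


@dataclass
class ConfusionCounts:
    tp: int = 0
    fp: int = 0
    fn: int = 0
    tn: int = 0

    def __add__(self, other: "ConfusionCounts") -> "ConfusionCounts":
        return ConfusionCounts(self.tp + other.tp, self.fp + other.fp,
                               self.fn + other.fn, self.tn + other.tn)

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


@dataclass
class MetricReport:
    """Per-class metrics as percentages, plus provenance."""

    per_class: dict      # class name -> {metric name -> percentage}
    n_cases: int
    mode: str            # "per_case_mean" or "pooled"


def confusion(pred_mask, true_mask) -> ConfusionCounts:
    pred = np.asarray(pred_mask).astype(bool)
    true = np.asarray(true_mask).astype(bool)
    if pred.shape != true.shape:
        raise ValueError(
            f"prediction shape {pred.shape} != truth shape {true.shape}")
    tp = int(np.count_nonzero(pred & true))
    fp = int(np.count_nonzero(pred & ~true))
    fn = int(np.count_nonzero(~pred & true))
    tn = int(np.count_nonzero(~pred & ~true))
    return ConfusionCounts(tp, fp, fn, tn)


def metric_suite(c: ConfusionCounts) -> dict:
    """Dice, Jaccard, precision, recall as fractions in [0, 1]."""
    if c.tp + c.fp + c.fn == 0:
        return {m: 1.0 for m in METRIC_NAMES}

    def ratio(num, den):
        return num / den if den > 0 else 0.0

    return {
        "dice": ratio(2 * c.tp, 2 * c.tp + c.fp + c.fn),
        "jaccard": ratio(c.tp, c.tp + c.fp + c.fn),
        "precision": ratio(c.tp, c.tp + c.fp),
        "recall": ratio(c.tp, c.tp + c.fn),
    }


def aggregate(case_counts: list[dict], mode: str = "per_case_mean"
              ) -> MetricReport:
    """Aggregate per-case confusion counts into a report.

    ``case_counts`` is a list of {class name -> ConfusionCounts} mappings,
    one entry per evaluation case (volume).
    """
    if not case_counts:
        raise ValueError("cannot aggregate an empty evaluation set")
    if mode not in ("per_case_mean", "pooled"):
        raise ValueError(f"unknown aggregation mode {mode!r}")
    classes = list(case_counts[0])
    per_class = {}
    for cls in classes:
        if mode == "per_case_mean":
            suites = [metric_suite(cc[cls]) for cc in case_counts]
            vals = {m: float(np.mean([s[m] for s in suites]))
                    for m in METRIC_NAMES}
        else:
            total = ConfusionCounts()
            for cc in case_counts:
                total = total + cc[cls]
            vals = metric_suite(total)
        per_class[cls] = {m: 100.0 * v for m, v in vals.items()}
    return MetricReport(per_class=per_class, n_cases=len(case_counts),
                        mode=mode)


def format_report(report: MetricReport, title: str = "") -> str:
    """Tab-separated table: one row per class, one column per metric."""
    lines = []
    if title:
        lines.append(title)
    lines.append("\t".join(["class"] + [m.capitalize() for m in METRIC_NAMES]))
    for cls, vals in report.per_class.items():
        lines.append("\t".join([cls] + [f"{vals[m]:.2f}" for m in METRIC_NAMES]))
    lines.append(f"# n_cases={report.n_cases}\tmode={report.mode}")
    return "\n".join(lines)


def report_to_dict(report: MetricReport) -> dict:
    return {"per_class": report.per_class, "n_cases": report.n_cases,
            "mode": report.mode}


__all__ = ["ConfusionCounts", "MetricReport", "confusion", "metric_suite",
           "aggregate", "format_report", "report_to_dict", "CLASS_NAMES",
           "METRIC_NAMES"]
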