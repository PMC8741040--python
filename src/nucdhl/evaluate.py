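"""Classification metrics, curves and model-comparison reports.

AUROC is computed by the rank (Mann-Whitney concordance) formulation and AUPR
by step integration of the precision-recall curve (the average-precision
convention). Classes are encoded normal = 0, cancer = 1 everywhere. With a
single-class input the threshold metrics are still reported but AUROC/AUPR
are undefined and returned as ``None`` rather than 0.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .exceptions import ArgumentError, AuditError

#: Train-minus-validation AUROC gap beyond which a run is flagged as high
#: variance (overfitting). Package convention; reports carry the flag only.
OVERFIT_GAP = 0.1


@dataclass
class MetricsReport:
    accuracy: float
    auroc: Optional[float]
    aupr: Optional[float]
    precision: float
    recall: float
    confusion: tuple[int, int, int, int]  # (TN, FP, FN, TP)
    roc_curve: np.ndarray = field(repr=False)  # columns: fpr, tpr
    pr_curve: np.ndarray = field(repr=False)   # columns: recall, precision
    split: str = "validation"
    n: int = 0

    def as_dict(self) -> dict:
        tn, fp, fn, tp = self.confusion
        return {
            "split": self.split, "n": self.n, "accuracy": self.accuracy,
            "auroc": self.auroc, "aupr": self.aupr,
            "precision": self.precision, "recall": self.recall,
            "tn": tn, "fp": fp, "fn": fn, "tp": tp,
        }


def auroc_rank(labels: np.ndarray, scores: np.ndarray) -> float:
    """AUROC via mean positive-score rank (ties counted half)."""
    labels = np.asarray(labels)
    scores = np.asarray(scores, dtype=float)
    n_pos = int(labels.sum())
    n_neg = len(labels) - n_pos
    if n_pos == 0 or n_neg == 0:
        raise ArgumentError("AUROC undefined for single-class labels")
    ranks = rankdata(scores)
    return float((ranks[labels == 1].sum() - n_pos * (n_pos + 1) / 2.0)
                 / (n_pos * n_neg))


def aupr_step(labels: np.ndarray, scores: np.ndarray) -> float:
    """Area under the precision-recall curve by step integration
    (sum of precision times recall increments over descending thresholds)."""
    labels = np.asarray(labels)
    scores = np.asarray(scores, dtype=float)
    n_pos = int(labels.sum())
    if n_pos == 0 or n_pos == len(labels):
        raise ArgumentError("AUPR undefined for single-class labels")
    order = np.argsort(-scores, kind="mergesort")
    y = labels[order]
    s = scores[order]
    tp = np.cumsum(y)
    fp = np.cumsum(1 - y)
    # evaluate only at distinct-threshold boundaries
    boundary = np.r_[s[1:] != s[:-1], True]
    tp, fp = tp[boundary], fp[boundary]
    precision = tp / (tp + fp)
    recall = tp / n_pos
    drecall = np.diff(np.r_[0.0, recall])
    return float(np.sum(precision * drecall))


def _roc_points(labels: np.ndarray, scores: np.ndarray) -> np.ndarray:
    order = np.argsort(-scores, kind="mergesort")
    y = labels[order]
    s = scores[order]
    tp = np.cumsum(y)
    fp = np.cumsum(1 - y)
    boundary = np.r_[s[1:] != s[:-1], True]
    tp, fp = tp[boundary], fp[boundary]
    n_pos, n_neg = tp[-1], fp[-1]
    tpr = np.r_[0.0, tp / max(n_pos, 1)]
    fpr = np.r_[0.0, fp / max(n_neg, 1)]
    return np.column_stack([fpr, tpr])


def _pr_points(labels: np.ndarray, scores: np.ndarray) -> np.ndarray:
    order = np.argsort(-scores, kind="mergesort")
    y = labels[order]
    s = scores[order]
    tp = np.cumsum(y)
    fp = np.cumsum(1 - y)
    boundary = np.r_[s[1:] != s[:-1], True]
    tp, fp = tp[boundary], fp[boundary]
    n_pos = tp[-1]
    precision = tp / (tp + fp)
    recall = tp / max(n_pos, 1)
    return np.column_stack([np.r_[0.0, recall], np.r_[1.0, precision]])


def compute_metrics(labels, probabilities, threshold: float = 0.5,
                    split: str = "validation") -> MetricsReport:
    """Full metric panel for one set of cancer probabilities.

    ``labels`` are 0/1 (normal/cancer); ``probabilities`` are p(cancer).
    Deterministic; raises on length mismatch.
    """
    labels = np.asarray(labels).astype(int)
    scores = np.asarray(probabilities, dtype=float)
    if labels.shape != scores.shape:
        raise ArgumentError("labels and probabilities must have equal length")
    if labels.size == 0:
        raise ArgumentError("compute_metrics needs at least one sample")
    pred = (scores >= threshold).astype(int)
    tp = int(np.sum((pred == 1) & (labels == 1)))
    tn = int(np.sum((pred == 0) & (labels == 0)))
    fp = int(np.sum((pred == 1) & (labels == 0)))
    fn = int(np.sum((pred == 0) & (labels == 1)))
    single_class = labels.min() == labels.max()
    return MetricsReport(
        accuracy=(tp + tn) / labels.size,
        auroc=None if single_class else auroc_rank(labels, scores),
        aupr=None if single_class else aupr_step(labels, scores),
        precision=tp / (tp + fp) if (tp + fp) else 0.0,
        recall=tp / (tp + fn) if (tp + fn) else 0.0,
        confusion=(tn, fp, fn, tp),
        roc_curve=(np.zeros((0, 2)) if single_class else _roc_points(labels, scores)),
        pr_curve=(np.zeros((0, 2)) if single_class else _pr_points(labels, scores)),
        split=split,
        n=int(labels.size),
    )


def comparison_report(runs: list[tuple[str, dict[str, MetricsReport]]],
                      out_dir=None) -> pd.DataFrame:
    """Side-by-side model x split x metric table with an overfitting flag.

    ``runs`` maps a model name to its per-split reports. Runs must agree on
    their split definitions (same sample count per split name) — a mismatch
    raises :class:`AuditError`. A train-vs-validation AUROC gap above
    :data:`OVERFIT_GAP` flags the model as high variance. With ``out_dir``
    set, the table and confusion-matrix grid are written as CSV and the
    metric panels as PNG.
    """
    if not runs:
        raise ArgumentError("comparison_report needs at least one run")
    split_sizes: dict[str, int] = {}
    rows = []
    for name, reports in runs:
        for split, rep in reports.items():
            if split in split_sizes and split_sizes[split] != rep.n:
                raise AuditError(
                    f"split {split!r} size mismatch across runs: "
                    f"{split_sizes[split]} vs {rep.n} ({name})")
            split_sizes.setdefault(split, rep.n)
            rows.append({"model": name, **rep.as_dict()})
    table = pd.DataFrame(rows)

    flags = {}
    for name, reports in runs:
        gap = None
        if "train" in reports and "validation" in reports:
            tr, va = reports["train"].auroc, reports["validation"].auroc
            if tr is not None and va is not None:
                gap = tr - va
        flags[name] = "high variance" if (gap is not None and gap > OVERFIT_GAP) else ""
    table["flag"] = table["model"].map(flags)

    if out_dir is not None:
        from pathlib import Path

        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        table.to_csv(out_dir / "comparison.csv", index=False)
        metrics = ["accuracy", "auroc", "aupr", "precision", "recall"]
        fig, axes = plt.subplots(1, len(metrics), figsize=(4 * len(metrics), 3.2))
        for ax, metric in zip(np.atleast_1d(axes), metrics):
            pivot = table.pivot_table(index="model", columns="split", values=metric)
            pivot.plot.bar(ax=ax, legend=(metric == "accuracy"))
            ax.set_title(metric)
            ax.set_ylim(0, 1.05)
        fig.tight_layout()
        fig.savefig(out_dir / "comparison.png", dpi=100)
        plt.close(fig)
    return table


def write_metrics(report: MetricsReport, out_dir, name: str) -> None:
    """Metrics JSON plus ROC/PR curve CSVs for one run."""
    import json
    from pathlib import Path

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    with open(out_dir / f"{name}_metrics.json", "w") as fh:
        json.dump(report.as_dict(), fh, indent=2)
    pd.DataFrame(report.roc_curve, columns=["fpr", "tpr"]).to_csv(
        out_dir / f"{name}_roc.csv", index=False)
    pd.DataFrame(report.pr_curve, columns=["recall", "precision"]).to_csv(
        out_dir / f"{name}_pr.csv", index=False)
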