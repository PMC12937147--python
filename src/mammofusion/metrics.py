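"""Binary-classification evaluation.

Confusion-matrix metrics (sensitivity, specificity, accuracy, precision,
F1, classification error rate), ROC/AUC, Cohen's kappa, and the
cross-validation aggregate: every fold's TPR interpolated onto a common
101-point FPR grid, reported as mean curve with a +/-1 SD band and
mean AUC +/- SD.

Metrics with a zero denominator are reported as ``None`` (undefined) rather
than zero, so they drop out of fold means instead of distorting them.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field

import numpy as np
from sklearn.metrics import roc_curve as _sk_roc_curve

__all__ = ["ConfusionCounts", "confusion_metrics", "roc_curve_auc",
           "mean_roc", "cohens_kappa", "evaluate_fold", "EvaluationReport",
           "FPR_GRID_POINTS"]

FPR_GRID_POINTS = 101


@dataclass
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self):
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")
        if self.total == 0:
            raise ValueError("confusion counts sum to zero")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn

    @classmethod
    def from_predictions(cls, y_true, y_prob, threshold: float = 0.5
                         ) -> "ConfusionCounts":
        y = np.asarray(y_true).astype(int).reshape(-1)
        pred = (np.asarray(y_prob).reshape(-1) >= threshold).astype(int)
        return cls(tp=int(((pred == 1) & (y == 1)).sum()),
                   fp=int(((pred == 1) & (y == 0)).sum()),
                   tn=int(((pred == 0) & (y == 0)).sum()),
                   fn=int(((pred == 0) & (y == 1)).sum()))


def _ratio(num: int, den: int) -> float | None:
    return num / den if den else None


def confusion_metrics(c: ConfusionCounts) -> dict[str, float | None]:
    """Sen, Spc, Acc, Pre, F1 and CER from a confusion matrix."""
    sen = _ratio(c.tp, c.tp + c.fn)
    spc = _ratio(c.tn, c.tn + c.fp)
    acc = (c.tp + c.tn) / c.total
    pre = _ratio(c.tp, c.tp + c.fp)
    if pre is None or sen is None or (pre + sen) == 0:
        f1 = None
    else:
        f1 = 2.0 * pre * sen / (pre + sen)
    return {"sensitivity": sen, "specificity": spc, "accuracy": acc,
            "precision": pre, "f1": f1, "cer": 1.0 - acc}


def roc_curve_auc(scores, labels) -> tuple[np.ndarray, np.ndarray, float]:
    """ROC curve by threshold sweep over unique scores, trapezoidal AUC.

    Tied scores collapse into one threshold step.  Returns (fpr, tpr, auc).
    """
    y = np.asarray(labels).astype(int).reshape(-1)
    s = np.asarray(scores, dtype=np.float64).reshape(-1)
    if y.size != s.size:
        raise ValueError("scores and labels differ in length")
    if len(np.unique(y)) < 2:
        raise ValueError("ROC requires both classes to be present")
    fpr, tpr, _ = _sk_roc_curve(y, s, drop_intermediate=False)
    auc = float(np.trapezoid(tpr, fpr))
    return fpr, tpr, auc


def cohens_kappa(c: ConfusionCounts) -> float | None:
    """Chance-corrected agreement, kappa = (p_o - p_e) / (1 - p_e)."""
    n = c.total
    p_o = (c.tp + c.tn) / n
    p_yes = ((c.tp + c.fp) / n) * ((c.tp + c.fn) / n)
    p_no = ((c.fn + c.tn) / n) * ((c.fp + c.tn) / n)
    p_e = p_yes + p_no
    if p_e == 1.0:
        return None  # degenerate marginals: agreement is fully determined
    return (p_o - p_e) / (1.0 - p_e)


def mean_roc(fold_curves: list[tuple[np.ndarray, np.ndarray]]) -> dict:
    """Fold-averaged ROC on a common FPR grid with a +/-1 SD band."""
    if len(fold_curves) < 2:
        raise ValueError("mean_roc needs at least two folds")
    grid = np.linspace(0.0, 1.0, FPR_GRID_POINTS)
    interp = []
    aucs = []
    for fpr, tpr in fold_curves:
        t = np.interp(grid, fpr, tpr)
        t[0], t[-1] = 0.0, 1.0  # pin ROC endpoints
        interp.append(t)
        aucs.append(float(np.trapezoid(tpr, fpr)))
    interp = np.vstack(interp)
    return {"fpr_grid": grid, "mean_tpr": interp.mean(axis=0),
            "sd_tpr": interp.std(axis=0, ddof=0),
            "mean_auc": float(np.mean(aucs)), "sd_auc": float(np.std(aucs, ddof=0)),
            "fold_aucs": aucs}


def evaluate_fold(y_true, y_prob, threshold: float = 0.5) -> dict:
    """All scalar metrics plus the ROC curve for one fold's predictions."""
    counts = ConfusionCounts.from_predictions(y_true, y_prob, threshold)
    out = {"counts": asdict(counts)}
    out.update(confusion_metrics(counts))
    out["kappa"] = cohens_kappa(counts)
    fpr, tpr, auc = roc_curve_auc(y_prob, y_true)
    out["auc"] = auc
    out["roc"] = (fpr, tpr)
    return out


@dataclass
class EvaluationReport:
    """Per-fold metrics plus fold-mean/SD aggregates and the mean ROC."""

    folds: list[dict] = field(default_factory=list)

    SCALARS = ("sensitivity", "specificity", "accuracy", "precision", "f1",
               "cer", "auc", "kappa")

    def add_fold(self, y_true, y_prob, threshold: float = 0.5) -> dict:
        res = evaluate_fold(y_true, y_prob, threshold)
        self.folds.append(res)
        return res

    def aggregate(self) -> dict:
        out = {}
        for key in self.SCALARS:
            vals = [f[key] for f in self.folds if f.get(key) is not None]
            out[key] = {"mean": float(np.mean(vals)) if vals else None,
                        "sd": float(np.std(vals, ddof=0)) if vals else None,
                        "n_defined": len(vals)}
        if len(self.folds) >= 2:
            out["mean_roc"] = mean_roc([f["roc"] for f in self.folds])
        return out

    def to_dict(self) -> dict:
        def clean(obj):
            if isinstance(obj, dict):
                return {k: clean(v) for k, v in obj.items()}
            if isinstance(obj, (list, tuple)):
                return [clean(v) for v in obj]
            if isinstance(obj, np.ndarray):
                return obj.tolist()
            if isinstance(obj, (np.floating, np.integer)):
                return obj.item()
            return obj

        return clean({"folds": self.folds, "aggregate": self.aggregate()})

    def fold_table(self):
        """Per-fold scalar metrics as a DataFrame (one row per fold)."""
        import pandas as pd

        rows = []
        for i, f in enumerate(self.folds):
            row = {"fold": i}
            row.update({k: f[k] for k in self.SCALARS})
            row.update(f["counts"])
            rows.append(row)
        return pd.DataFrame(rows)

    def plot_roc(self, path) -> None:
        """Per-fold curves, fold-mean curve and shaded +/-1 SD band."""
        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        agg = self.aggregate()["mean_roc"]
        fig, ax = plt.subplots(figsize=(5, 5))
        for i, f in enumerate(self.folds):
            fpr, tpr = f["roc"]
            ax.plot(fpr, tpr, lw=0.8, alpha=0.5, label=f"fold {i} (AUC={f['auc']:.3f})")
        ax.plot(agg["fpr_grid"], agg["mean_tpr"], "b-", lw=2,
                label=f"mean (AUC={agg['mean_auc']:.3f}±{agg['sd_auc']:.3f})")
        ax.fill_between(agg["fpr_grid"],
                        np.clip(agg["mean_tpr"] - agg["sd_tpr"], 0, 1),
                        np.clip(agg["mean_tpr"] + agg["sd_tpr"], 0, 1),
                        color="b", alpha=0.15, label="±1 SD")
        ax.plot([0, 1], [0, 1], "k--", lw=0.8)
        ax.set_xlabel("False positive rate")
        ax.set_ylabel("True positive rate")
        ax.legend(loc="lower right", fontsize=7)
        fig.tight_layout()
        fig.savefig(path, dpi=120)
        plt.close(fig)
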