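"""Evaluation surfaces: confusion matrix, P/R/F1, one-vs-rest ROC/AUC,
accuracy/loss curves, and the ablation harness (Conv1D / Conv2D /
Conv2D+Attention / full CNN-ECA on envelope input)."""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn import metrics as skm

from .errors import ValidationError
from .model import (TrainConfig, TrainedModel, desk_train_config, predict_proba,
                    train_model, variant_spec, VARIANTS)
from .preprocess import EnvelopeConfig, extract_envelope
from .synth import read_session, find_sessions
from .windows import WindowConfig, WindowSet, segment_session, split_windows


def confusion_matrix(y_true, y_pred, n_classes: int) -> np.ndarray:
    """Count matrix: entry [i, j] = true class i predicted as class j."""
    y_true = np.asarray(y_true, dtype=int)
    y_pred = np.asarray(y_pred, dtype=int)
    if y_true.shape != y_pred.shape:
        raise ValidationError("y_true and y_pred must have equal length")
    if y_true.size == 0:
        return np.zeros((n_classes, n_classes), dtype=int)
    labels = np.concatenate([y_true, y_pred])
    if labels.min() < 0 or labels.max() >= n_classes:
        raise ValidationError("labels out of range")
    return skm.confusion_matrix(y_true, y_pred, labels=np.arange(n_classes))


def classification_metrics(cm: np.ndarray) -> dict:
    """Per-class precision/recall/F1 (+ macro averages) and accuracy from a
    confusion matrix.  Zero-denominator metrics are reported as 0 with a
    warning."""
    cm = np.asarray(cm)
    if cm.ndim != 2 or cm.shape[0] != cm.shape[1]:
        raise ValidationError("confusion matrix must be square")
    if np.any(cm < 0):
        raise ValidationError("confusion matrix counts must be non-negative")
    diag = np.diag(cm).astype(float)
    col = cm.sum(axis=0).astype(float)
    row = cm.sum(axis=1).astype(float)
    if np.any(col == 0) or np.any(row == 0):
        warnings.warn("zero-support class: its precision/recall reported as 0",
                      stacklevel=2)
    with np.errstate(divide="ignore", invalid="ignore"):
        precision = np.where(col > 0, diag / np.maximum(col, 1), 0.0)
        recall = np.where(row > 0, diag / np.maximum(row, 1), 0.0)
        pr = precision + recall
        f1 = np.where(pr > 0, 2 * precision * recall / np.maximum(pr, 1e-300), 0.0)
    total = cm.sum()
    return {
        "precision": precision, "recall": recall, "f1": f1,
        "macro_precision": float(precision.mean()),
        "macro_recall": float(recall.mean()),
        "macro_f1": float(f1.mean()),
        "accuracy": float(diag.sum() / total) if total > 0 else 0.0,
    }


def roc_auc_ovr(scores: np.ndarray, y_true) -> dict:
    """Per-class one-vs-rest ROC curves and AUC + macro AUC.

    Ties are handled by the threshold sweep (equivalent to rank averaging /
    the Mann-Whitney statistic).  Classes without both a positive and a
    negative example are skipped with a warning.
    """
    scores = np.asarray(scores, dtype=float)
    y_true = np.asarray(y_true, dtype=int)
    if scores.ndim != 2 or scores.shape[0] != y_true.shape[0]:
        raise ValidationError("scores must be [n, n_classes] aligned with y_true")
    curves, aucs = {}, {}
    for c in range(scores.shape[1]):
        pos = y_true == c
        if pos.all() or not pos.any():
            warnings.warn(f"class {c} lacks positives or negatives; skipped",
                          stacklevel=2)
            continue
        fpr, tpr, _ = skm.roc_curve(pos.astype(int), scores[:, c])
        curves[c] = (fpr, tpr)
        aucs[c] = float(skm.auc(fpr, tpr))
    macro = float(np.mean(list(aucs.values()))) if aucs else float("nan")
    return {"curves": curves, "auc": aucs, "macro_auc": macro}


@dataclass
class EvaluationReport:
    split: str
    n_evaluated: int
    accuracy: float
    loss: float
    confusion: np.ndarray            # raw counts
    confusion_normalized: np.ndarray  # row-normalised (rows with support > 0)
    per_class: dict
    roc: dict

    def to_dict(self) -> dict:
        return {
            "split": self.split,
            "n_evaluated": self.n_evaluated,
            "accuracy": self.accuracy,
            "loss": self.loss,
            "confusion": self.confusion.tolist(),
            "confusion_normalized": self.confusion_normalized.tolist(),
            "precision": self.per_class["precision"].tolist(),
            "recall": self.per_class["recall"].tolist(),
            "f1": self.per_class["f1"].tolist(),
            "macro_precision": self.per_class["macro_precision"],
            "macro_recall": self.per_class["macro_recall"],
            "macro_f1": self.per_class["macro_f1"],
            "auc": {str(k): v for k, v in self.roc["auc"].items()},
            "macro_auc": self.roc["macro_auc"],
        }


def evaluate_model(tm: TrainedModel, ws: WindowSet, split: str = "test") -> EvaluationReport:
    x, y = ws.subset(split)
    if len(x) == 0:
        raise ValidationError(f"{split} split is empty")
    probs = predict_proba(tm, x)
    preds = probs.argmax(axis=1)
    n_classes = tm.spec.n_classes
    cm = confusion_matrix(y, preds, n_classes)
    row = cm.sum(axis=1, keepdims=True)
    cm_norm = np.where(row > 0, cm / np.maximum(row, 1), 0.0)
    loss = float(-np.mean(np.log(np.clip(probs[np.arange(len(y)), y], 1e-12, None))))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        per_class = classification_metrics(cm)
        roc = roc_auc_ovr(probs, y)
    return EvaluationReport(split, len(y), per_class["accuracy"], loss,
                            cm, cm_norm, per_class, roc)


def save_report(report: EvaluationReport, out_dir: str | Path,
                history: pd.DataFrame | None = None, plots: bool = False) -> Path:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    (out_dir / "report.json").write_text(json.dumps(report.to_dict(), indent=2))
    np.savetxt(out_dir / "confusion.csv", report.confusion, fmt="%d", delimiter=",")
    for c, (fpr, tpr) in report.roc["curves"].items():
        np.savetxt(out_dir / f"roc_class{c}.csv",
                   np.column_stack([fpr, tpr]), delimiter=",",
                   header="fpr,tpr", comments="")
    if plots:
        _plot_report(report, history, out_dir)
    return out_dir


def _plot_report(report, history, out_dir: Path) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    if history is not None:
        fig, axes = plt.subplots(1, 2, figsize=(10, 4))
        axes[0].plot(history["epoch"], history["train_loss"], label="train")
        axes[0].plot(history["epoch"], history["val_loss"], label="val")
        axes[0].set_xlabel("epoch"); axes[0].set_ylabel("loss"); axes[0].legend()
        axes[1].plot(history["epoch"], history["train_acc"], label="train")
        axes[1].plot(history["epoch"], history["val_acc"], label="val")
        axes[1].set_xlabel("epoch"); axes[1].set_ylabel("accuracy"); axes[1].legend()
        fig.tight_layout(); fig.savefig(out_dir / "curves.png", dpi=100); plt.close(fig)

    fig, ax = plt.subplots(figsize=(5, 4))
    im = ax.imshow(report.confusion_normalized, cmap="Blues", vmin=0, vmax=1)
    fig.colorbar(im); ax.set_xlabel("predicted"); ax.set_ylabel("true")
    fig.tight_layout(); fig.savefig(out_dir / "confusion.png", dpi=100); plt.close(fig)

    fig, ax = plt.subplots(figsize=(5, 4))
    for c, (fpr, tpr) in report.roc["curves"].items():
        ax.plot(fpr, tpr, label=f"class {c} (AUC={report.roc['auc'][c]:.3f})")
    ax.plot([0, 1], [0, 1], "k--", lw=0.5)
    ax.set_xlabel("FPR"); ax.set_ylabel("TPR"); ax.legend(fontsize=6)
    fig.tight_layout(); fig.savefig(out_dir / "roc.png", dpi=100); plt.close(fig)


# -- ablation harness -------------------------------------------------------

@dataclass
class AblationResult:
    table: pd.DataFrame      # rows: variant, seed, accuracy, loss

    def aggregate(self) -> pd.DataFrame:
        return self.table.groupby("variant")[["accuracy", "loss"]].agg(["mean", "std"])

    def mean_accuracy(self, variant: str) -> float:
        return float(self.table.loc[self.table.variant == variant, "accuracy"].mean())


def ablation_window_sets(recs, window_cfg: WindowConfig,
                         env_cfg: EnvelopeConfig | None = None):
    """Raw and envelope WindowSets with identical provenance and split."""
    env_recs = [extract_envelope(r, env_cfg) for r in recs]
    ws_raw = split_windows(segment_session(recs, window_cfg), window_cfg)
    ws_env = split_windows(segment_session(env_recs, window_cfg), window_cfg)
    if not (np.array_equal(ws_raw.split, ws_env.split)
            and np.array_equal(ws_raw.labels, ws_env.labels)
            and np.array_equal(ws_raw.rec_ids.astype(str), ws_env.rec_ids.astype(str))
            and np.array_equal(ws_raw.starts, ws_env.starts)):
        raise ValidationError("raw and envelope window sets diverged")
    return ws_raw, ws_env


def run_ablation(data_dir, seeds, train_cfg: TrainConfig | None = None,
                 window_cfg: WindowConfig | None = None,
                 env_cfg: EnvelopeConfig | None = None,
                 compact: bool = True) -> AblationResult:
    """Train all four variants per seed on identical splits.

    Raw-signal variants (conv1d, conv2d, conv2d_eca) consume raw windows;
    the full CNN-ECA consumes envelope windows.  Every run starts from a
    fresh initialisation.
    """
    window_cfg = window_cfg or WindowConfig()
    recs = []
    for sess_dir in find_sessions(data_dir):
        sess, manifest = read_session(sess_dir)
        if manifest.get("envelope"):
            raise ValidationError("ablation expects raw (non-envelope) sessions")
        recs.extend(sess)
    if not recs:
        raise ValidationError(f"no sessions found under {data_dir}")
    ws_raw, ws_env = ablation_window_sets(recs, window_cfg, env_cfg)
    n_classes = int(ws_raw.labels.max()) + 1
    rows = []
    for seed in seeds:
        for variant in VARIANTS:
            ws = ws_env if variant == "full" else ws_raw
            spec = variant_spec(variant, ws.window_len, ws.n_channels,
                                n_classes, compact=compact)
            cfg = train_cfg or desk_train_config()
            tm = train_model(spec, ws, TrainConfig(
                learning_rate=cfg.learning_rate, epochs=cfg.epochs,
                batch_size=cfg.batch_size, seed=int(seed)))
            report = evaluate_model(tm, ws, "test")
            rows.append({"variant": variant, "seed": int(seed),
                         "accuracy": report.accuracy, "loss": report.loss})
    return AblationResult(pd.DataFrame(rows))
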