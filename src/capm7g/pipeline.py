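"""Dataset assembly, training, prediction and evaluation.

The experimental protocol: balanced positive/negative window sets, a
stratified 8:2 train/test split, 4-fold cross-validation on the training
portion, Adam training (lr 0.001, default 100 epochs) of the capsule
classifier, and evaluation by accuracy, recall, specificity, F1, MCC and
ROC/PR AUC.

Ablation switches: ``encoder_mode="onehot"`` replaces FCGR images with
one-hot strips (the without-CGR variant); ``use_capsnet=False`` swaps in
a CNN+MLP head; ``use_reconstruction=False`` drops the reconstruction
term from the loss.
"""

from __future__ import annotations

import warnings
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import yaml
from sklearn.metrics import auc as _trapezoid_auc
from sklearn.metrics import precision_recall_curve, roc_curve
from sklearn.model_selection import StratifiedKFold, train_test_split

from .capsnet import (
    CapsuleNet,
    CapsuleNetConfig,
    CnnMlpBaseline,
    load_checkpoint,
    make_optimizer,
    save_checkpoint,
)
from .cgr import encode_windows
from .sequences import RnaWindow, onehot_encode

POSITIVE_CAPSULE = 1  # digit capsule index of the m7G class


# ---------------------------------------------------------------------------
# dataset assembly and splitting
# ---------------------------------------------------------------------------


@dataclass
class DatasetSplit:
    """Stratified train/test split plus k folds over the training part."""

    train: list[RnaWindow]
    test: list[RnaWindow]
    folds: list[tuple[np.ndarray, np.ndarray]]
    seed: int


def build_dataset(
    positives: Sequence[RnaWindow],
    negative_source: Sequence[RnaWindow],
    seed: int = 0,
) -> list[RnaWindow]:
    """Balance positives with an equal number of sampled negatives.

    ``negative_source`` is a pool of candidate negative windows (each
    centered on a G that is not a known modification site); exactly
    ``len(positives)`` of them are drawn without replacement, seeded.
    Returns the shuffled, labeled, balanced set.
    """
    if not positives:
        raise ValueError("no positive windows given")
    n = len(positives)
    pool = list(negative_source)
    if len(pool) < n:
        raise ValueError(
            f"insufficient negative candidates: need {n}, have {len(pool)} "
            f"(deficit {n - len(pool)})"
        )
    rng = np.random.default_rng(seed)
    chosen = rng.choice(len(pool), size=n, replace=False)
    labeled: list[RnaWindow] = []
    for w in positives:
        labeled.append(RnaWindow(w.id, w.sequence, 1, w.center_index, w.source))
    for i in chosen:
        w = pool[i]
        labeled.append(RnaWindow(w.id, w.sequence, 0, w.center_index, w.source))
    order = rng.permutation(len(labeled))
    return [labeled[i] for i in order]


def split_dataset(
    windows: Sequence[RnaWindow],
    ratio: float = 0.8,
    k: int = 4,
    seed: int = 0,
    stratified: bool = True,
) -> DatasetSplit:
    """Stratified ``ratio``:(1-ratio) split + ``k`` folds on the train part."""
    if len(windows) < 10:
        raise ValueError("need at least 10 windows to split")
    labels = np.array([w.label for w in windows])
    if stratified and len(np.unique(labels)) < 2:
        raise ValueError("stratified split requires both classes present")
    idx = np.arange(len(windows))
    train_idx, test_idx = train_test_split(
        idx,
        test_size=1.0 - ratio,
        random_state=seed,
        stratify=labels if stratified else None,
        shuffle=True,
    )
    train = [windows[i] for i in train_idx]
    test = [windows[i] for i in test_idx]
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    train_labels = np.array([w.label for w in train])
    folds = [
        (tr.copy(), va.copy())
        for tr, va in skf.split(np.zeros(len(train)), train_labels)
    ]
    return DatasetSplit(train=train, test=test, folds=folds, seed=seed)


# ---------------------------------------------------------------------------
# evaluation
# ---------------------------------------------------------------------------


@dataclass
class ConfusionCounts:
    TP: int = 0
    TN: int = 0
    FP: int = 0
    FN: int = 0

    @property
    def total(self) -> int:
        return self.TP + self.TN + self.FP + self.FN


@dataclass
class PredictionRecord:
    """Per-sequence output: capsule probabilities and the argmax label."""

    id: str
    p_positive: float
    p_negative: float
    predicted_label: int
    true_label: Optional[int] = None


@dataclass
class EvaluationReport:
    accuracy: float
    recall: float
    specificity: float
    f1: float
    mcc: float
    roc_auc: float
    pr_auc: float
    confusion: ConfusionCounts
    per_fold: Optional[list] = None

    def to_dict(self) -> dict:
        d = asdict(self)
        return d


def confusion_from_records(records: Sequence[PredictionRecord]) -> ConfusionCounts:
    cc = ConfusionCounts()
    for r in records:
        if r.true_label is None:
            raise ValueError(f"record {r.id!r} has no true label")
        if r.true_label == 1:
            if r.predicted_label == 1:
                cc.TP += 1
            else:
                cc.FN += 1
        else:
            if r.predicted_label == 1:
                cc.FP += 1
            else:
                cc.TN += 1
    return cc


def metrics_from_confusion(cc: ConfusionCounts) -> dict[str, float]:
    """Accuracy, recall, specificity, F1 and MCC from raw counts.

        accuracy    = (TP + TN) / (TP + TN + FP + FN)
        recall      = TP / (TP + FN)
        specificity = TN / (TN + FP)
        F1          = 2 TP / (2 TP + FN + FP)
        MCC         = (TP*TN - FP*FN) /
                      sqrt((TP+FP)(TP+FN)(TN+FP)(TN+FN))

    Ratios with zero denominators are reported as NaN with a warning.
    """
    TP, TN, FP, FN = cc.TP, cc.TN, cc.FP, cc.FN

    def ratio(num, den, name):
        if den == 0:
            warnings.warn(f"{name} undefined (zero denominator)")
            return float("nan")
        return num / den

    accuracy = ratio(TP + TN, cc.total, "accuracy")
    recall = ratio(TP, TP + FN, "recall")
    specificity = ratio(TN, TN + FP, "specificity")
    f1 = ratio(2 * TP, 2 * TP + FN + FP, "F1")
    denom = (TP + FP) * (TP + FN) * (TN + FP) * (TN + FN)
    if denom == 0:
        warnings.warn("MCC undefined (zero denominator)")
        mcc = float("nan")
    else:
        mcc = float((TP * TN - FP * FN) / np.sqrt(float(denom)))
    return {
        "accuracy": accuracy,
        "recall": recall,
        "specificity": specificity,
        "f1": f1,
        "mcc": mcc,
    }


def roc_pr_auc(
    scores: np.ndarray, labels: np.ndarray
) -> tuple[float, float]:
    """ROC and PR AUC by trapezoidal integration over score thresholds."""
    labels = np.asarray(labels)
    if len(np.unique(labels)) < 2:
        warnings.warn("AUC undefined: only one class present")
        return float("nan"), float("nan")
    fpr, tpr, _ = roc_curve(labels, scores)
    roc_auc = float(_trapezoid_auc(fpr, tpr))
    precision, recall, _ = precision_recall_curve(labels, scores)
    pr_auc = float(_trapezoid_auc(recall, precision))
    return roc_auc, pr_auc


def evaluate(records: Sequence[PredictionRecord]) -> EvaluationReport:
    """Full evaluation of labeled prediction records."""
    cc = confusion_from_records(records)
    m = metrics_from_confusion(cc)
    scores = np.array([r.p_positive for r in records])
    labels = np.array([r.true_label for r in records])
    roc_auc, pr_auc = roc_pr_auc(scores, labels)
    return EvaluationReport(
        accuracy=m["accuracy"],
        recall=m["recall"],
        specificity=m["specificity"],
        f1=m["f1"],
        mcc=m["mcc"],
        roc_auc=roc_auc,
        pr_auc=pr_auc,
        confusion=cc,
    )


# ---------------------------------------------------------------------------
# training
# ---------------------------------------------------------------------------


@dataclass
class TrainSettings:
    """Optimization protocol and ablation switches."""

    epochs: int = 100
    lr: float = 0.001
    batch_size: int = 32
    seed: int = 0
    encoder_mode: str = "fcgr"  # or "onehot" (the without-CGR ablation)
    use_capsnet: bool = True  # False -> CNN+MLP baseline
    use_reconstruction: bool = True  # False -> alpha = 0


@dataclass
class TrainedModel:
    """A trained network plus everything needed to encode new inputs."""

    model: object
    encoder_mode: str
    window_length: int
    config: CapsuleNetConfig

    def encode(self, windows: Sequence[RnaWindow]) -> np.ndarray:
        for w in windows:
            if len(w) != self.window_length:
                raise ValueError(
                    f"window {w.id!r} has length {len(w)}, model was trained "
                    f"on length {self.window_length}"
                )
        if self.encoder_mode == "fcgr":
            return encode_windows(windows, self.config.image_shape[0])
        return np.stack([onehot_encode(w) for w in windows])

    def predict_proba(
        self, windows: Sequence[RnaWindow], batch_size: int = 64
    ) -> np.ndarray:
        images = self.encode(windows)
        out = [
            self.model.predict_proba(images[i : i + batch_size])
            for i in range(0, len(images), batch_size)
        ]
        return np.concatenate(out)

    def save(self, path: str | Path) -> None:
        save_checkpoint(
            self.model,
            path,
            extra={
                "encoder_mode": self.encoder_mode,
                "window_length": self.window_length,
            },
        )

    @classmethod
    def load(cls, path: str | Path) -> "TrainedModel":
        model, extra = load_checkpoint(path)
        return cls(
            model=model,
            encoder_mode=extra["encoder_mode"],
            window_length=extra["window_length"],
            config=model.config,
        )


@dataclass
class TrainResult:
    trained: TrainedModel
    log: list[dict]
    best_epoch: int
    best_val_mcc: float


def _build_model(config: CapsuleNetConfig, settings: TrainSettings, window_length: int):
    cfg = config
    if settings.encoder_mode == "onehot":
        cfg = config.onehot_variant(window_length)
    elif settings.encoder_mode != "fcgr":
        raise ValueError(f"unknown encoder_mode {settings.encoder_mode!r}")
    if settings.use_capsnet:
        return CapsuleNet(cfg)
    return CnnMlpBaseline(cfg)


def train(
    train_windows: Sequence[RnaWindow],
    val_windows: Sequence[RnaWindow],
    config: CapsuleNetConfig,
    settings: TrainSettings,
) -> TrainResult:
    """Train a model, selecting the epoch with the best validation MCC.

    Raises ``RuntimeError`` if the loss diverges to NaN.
    """
    if not train_windows:
        raise ValueError("empty training set")
    window_length = len(train_windows[0])
    model = _build_model(config, settings, window_length)
    trained = TrainedModel(
        model=model,
        encoder_mode=settings.encoder_mode,
        window_length=window_length,
        config=model.config,
    )
    X = trained.encode(train_windows)
    y = np.array([w.label for w in train_windows], dtype=int)
    opt = make_optimizer(model, lr=settings.lr)
    rng = np.random.default_rng(settings.seed)
    log: list[dict] = []
    best = {"mcc": -np.inf, "epoch": -1, "weights": None}
    for epoch in range(settings.epochs):
        order = rng.permutation(len(X))
        epoch_losses = []
        for start in range(0, len(X), settings.batch_size):
            sel = order[start : start + settings.batch_size]
            opt.zero_grad()
            loss, _parts = model.loss(
                X[sel], y[sel], use_reconstruction=settings.use_reconstruction
            )
            value = float(loss.data)
            if not np.isfinite(value):
                raise RuntimeError(
                    f"training diverged: loss={value} at epoch {epoch}, "
                    f"batch starting {start}"
                )
            loss.backward()
            opt.step()
            epoch_losses.append(value)
        entry = {"epoch": epoch, "train_loss": float(np.mean(epoch_losses))}
        if val_windows:
            records = predict(trained, val_windows)
            report = evaluate(records)
            entry.update(
                val_mcc=report.mcc,
                val_accuracy=report.accuracy,
                val_roc_auc=report.roc_auc,
            )
            mcc = report.mcc if np.isfinite(report.mcc) else -1.0
            if mcc > best["mcc"]:
                best = {
                    "mcc": mcc,
                    "epoch": epoch,
                    "weights": {
                        k: t.data.copy() for k, t in model.parameters().items()
                    },
                }
        log.append(entry)
    if best["weights"] is not None:
        for k, t in model.parameters().items():
            t.data = best["weights"][k]
    return TrainResult(
        trained=trained,
        log=log,
        best_epoch=best["epoch"],
        best_val_mcc=float(best["mcc"]) if np.isfinite(best["mcc"]) else float("nan"),
    )


def predict(
    trained: TrainedModel, windows: Sequence[RnaWindow]
) -> list[PredictionRecord]:
    """One record per window, in input order.

    The predicted label is the argmax over the two capsule probabilities
    (ties go to the positive class).
    """
    probs = trained.predict_proba(windows)
    records = []
    for w, p in zip(windows, probs):
        p_pos = float(p[POSITIVE_CAPSULE])
        p_neg = float(p[1 - POSITIVE_CAPSULE])
        records.append(
            PredictionRecord(
                id=w.id,
                p_positive=p_pos,
                p_negative=p_neg,
                predicted_label=1 if p_pos >= p_neg else 0,
                true_label=w.label,
            )
        )
    return records


def records_to_frame(records: Sequence[PredictionRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "id": [r.id for r in records],
            "p_m7G": [r.p_positive for r in records],
            "p_normal": [r.p_negative for r in records],
            "label": [r.predicted_label for r in records],
        }
    )


def write_predictions(records: Sequence[PredictionRecord], path: str | Path) -> None:
    records_to_frame(records).to_csv(path, sep="\t", index=False)


def cross_validate(
    split: DatasetSplit,
    config: CapsuleNetConfig,
    settings: TrainSettings,
) -> tuple[list[EvaluationReport], dict]:
    """Train/evaluate each fold with identical settings; aggregate mean/sd."""
    reports = []
    for tr_idx, va_idx in split.folds:
        tr = [split.train[i] for i in tr_idx]
        va = [split.train[i] for i in va_idx]
        result = train(tr, va, config, settings)
        reports.append(evaluate(predict(result.trained, va)))
    metrics = ("accuracy", "recall", "specificity", "f1", "mcc", "roc_auc", "pr_auc")
    aggregate = {}
    for name in metrics:
        vals = np.array([getattr(r, name) for r in reports], dtype=float)
        aggregate[name] = {
            "mean": float(np.nanmean(vals)),
            "sd": float(np.nanstd(vals, ddof=1)) if len(vals) > 1 else 0.0,
        }
    return reports, aggregate


# ---------------------------------------------------------------------------
# configuration files
# ---------------------------------------------------------------------------


def load_config(path: str | Path) -> tuple[CapsuleNetConfig, TrainSettings]:
    """Read a flat YAML mapping into (CapsuleNetConfig, TrainSettings).

    Keys are matched by field name; unknown keys are an error. Tuple-valued
    architecture fields accept YAML lists.
    """
    raw = yaml.safe_load(Path(path).read_text()) or {}
    net_fields = set(CapsuleNetConfig.__dataclass_fields__)
    train_fields = set(TrainSettings.__dataclass_fields__)
    net_kwargs, train_kwargs = {}, {}
    for key, value in raw.items():
        if isinstance(value, list):
            value = tuple(
                tuple(v) if isinstance(v, list) else v for v in value
            )
        if key in net_fields:
            net_kwargs[key] = value
        if key in train_fields:  # seed is shared: goes to both
            train_kwargs[key] = value
        if key not in net_fields and key not in train_fields:
            raise ValueError(f"{path}: unknown configuration key {key!r}")
    return CapsuleNetConfig(**net_kwargs), TrainSettings(**train_kwargs)
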