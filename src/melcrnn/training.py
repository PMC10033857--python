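"""Loss, splitting, optimisation loop, metrics, and the parameter-sweep harness.

Training follows the reference protocol: Adam at learning rate 1e-4 on the
cross-entropy loss, batch size 64, an 8:2 shuffled train/test split, Xavier
initialisation.  Evaluation reports accuracy, precision, recall and F1 from
the confusion matrix of argmax predictions; the binary scheme treats the
fatigue class as positive, the three-class scheme macro-averages.

``parameter_sweep`` retrains the model over a named grid of front-end /
segmentation settings (n_fft, hop, n_mels, rate, patch_len) and emits one
table row per value with the four metrics, marking the best-accuracy row —
the layout used for hyperparameter ablation reports.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from sklearn.metrics import confusion_matrix

from .errors import ConfigError
from .io import Recording, resample
from .labeling import LabelScheme, PerclosTrace, Segment, build_dataset
from .model import LogMelCRNN, ModelConfig, build_model, xavier_init
from .nn.optim import Adam, softmax_cross_entropy
from .spectral import SpectralConfig

__all__ = [
    "TrainConfig",
    "Metrics",
    "cross_entropy",
    "train_test_split",
    "train",
    "desk_scale_configs",
    "evaluate",
    "parameter_sweep",
    "format_sweep_table",
]


@dataclass(frozen=True)
class TrainConfig:
    optimizer: str = "adam"
    learning_rate: float = 1.0e-4
    batch_size: int = 64
    epochs: int = 50
    split_ratio: float = 0.8
    seed: int = 0
    group_key: Optional[str] = None
    select_best: bool = False  # keep the epoch with best eval accuracy instead of the last

    def __post_init__(self):
        if self.optimizer != "adam":
            raise ConfigError(f"only the adam optimizer is supported, got {self.optimizer!r}")
        if not 0 < self.split_ratio < 1:
            raise ConfigError(f"split_ratio must be in (0, 1), got {self.split_ratio}")
        if self.batch_size < 1 or self.epochs < 1:
            raise ConfigError("batch_size and epochs must be >= 1")


@dataclass(frozen=True)
class Metrics:
    """The four standard classification scores plus the confusion matrix."""

    accuracy: float
    precision: float
    recall: float
    f1: float
    averaging: str  # "binary_positive" or "macro"
    confusion: np.ndarray = field(repr=False, default=None)

    def as_dict(self) -> dict:
        return {"accuracy": self.accuracy, "precision": self.precision,
                "recall": self.recall, "f1": self.f1}


def cross_entropy(true_dist: Sequence[float], pred_dist: Sequence[float]) -> float:
    """Cross-entropy sum_k -P_k * ln(p_k) between a one-hot truth and a prediction.

    Zero predicted probability at the true class is clamped at 1e-12 (with a
    warning) so the loss stays finite.
    """
    p_true = np.asarray(true_dist, dtype=float)
    p_pred = np.asarray(pred_dist, dtype=float)
    if p_true.shape != p_pred.shape:
        raise ValueError(f"shape mismatch {p_true.shape} vs {p_pred.shape}")
    if abs(p_pred.sum() - 1.0) > 1e-6:
        raise ValueError(f"predicted distribution sums to {p_pred.sum()}, not 1")
    if p_pred[p_true > 0].min(initial=np.inf) <= 0:
        warnings.warn("zero predicted probability at the true class; clamping at 1e-12",
                      stacklevel=2)
    return float(-(p_true * np.log(np.maximum(p_pred, 1e-12))).sum())


def train_test_split(segments: list[Segment], ratio: float = 0.8, seed: int = 0,
                     groups: Optional[Sequence] = None,
                     stratify: bool = False) -> tuple[list[Segment], list[Segment]]:
    """Shuffle and split 8:2 (by default); with ``groups``, whole groups stay
    on one side and the ratio is approximated by group sizes.  ``stratify``
    applies the shuffle-and-split per class so both sides keep the label
    proportions (useful for small balanced datasets)."""
    n = len(segments)
    if n < 2:
        raise ValueError("need at least two segments to split")
    rng = np.random.default_rng(seed)
    if stratify and groups is None:
        labels = np.asarray([s.label for s in segments])
        train_parts, test_parts = [], []
        for cls in np.unique(labels):
            idx = rng.permutation(np.flatnonzero(labels == cls))
            k = int(round(len(idx) * ratio))
            train_parts.append(idx[:k])
            test_parts.append(idx[k:])
        train_idx = rng.permutation(np.concatenate(train_parts))
        test_idx = rng.permutation(np.concatenate(test_parts))
        if len(train_idx) == 0 or len(test_idx) == 0:
            raise ValueError(f"ratio {ratio} leaves an empty side for n={n}")
    elif groups is None:
        order = rng.permutation(n)
        n_train = int(round(n * ratio))
        if n_train == 0 or n_train == n:
            raise ValueError(f"ratio {ratio} leaves an empty side for n={n}")
        train_idx, test_idx = order[:n_train], order[n_train:]
    else:
        groups = np.asarray(groups)
        if groups.shape[0] != n:
            raise ValueError("groups must have one entry per segment")
        uniq = rng.permutation(np.unique(groups))
        target = ratio * n
        train_groups, count = [], 0
        for g in uniq:
            if count < target:
                train_groups.append(g)
                count += int((groups == g).sum())
        mask = np.isin(groups, train_groups)
        if mask.all() or not mask.any():
            raise ValueError("grouped split left one side empty; adjust ratio or groups")
        train_idx = np.flatnonzero(mask)
        test_idx = np.flatnonzero(~mask)
    return [segments[i] for i in train_idx], [segments[i] for i in test_idx]


def _batch(segments: list[Segment]) -> tuple[np.ndarray, np.ndarray]:
    x = np.stack([s.patches for s in segments]).astype(np.float32)
    y = np.asarray([s.label for s in segments])
    return x, y


def predict(model: LogMelCRNN, segments: list[Segment], batch_size: int = 64) -> np.ndarray:
    """Evaluation-mode argmax predictions (ties resolve to the lowest index)."""
    preds = []
    for i in range(0, len(segments), batch_size):
        x, _ = _batch(segments[i : i + batch_size])
        preds.append(model.predict_proba(x).argmax(axis=1))
    return np.concatenate(preds)


def _metrics_from_confusion(conf: np.ndarray, averaging: str) -> Metrics:
    total = conf.sum()
    acc = float(np.trace(conf) / total)
    with np.errstate(invalid="ignore", divide="ignore"):
        prec_k = np.diag(conf) / conf.sum(axis=0)
        rec_k = np.diag(conf) / conf.sum(axis=1)
    prec_k = np.nan_to_num(prec_k)
    rec_k = np.nan_to_num(rec_k)
    if averaging == "binary_positive":
        prec, rec = float(prec_k[1]), float(rec_k[1])
        f1 = 0.0 if prec + rec == 0 else 2 * prec * rec / (prec + rec)
    else:
        with np.errstate(invalid="ignore", divide="ignore"):
            f1_k = np.where(prec_k + rec_k > 0, 2 * prec_k * rec_k / (prec_k + rec_k), 0.0)
        prec, rec, f1 = float(prec_k.mean()), float(rec_k.mean()), float(f1_k.mean())
    return Metrics(accuracy=acc, precision=prec, recall=rec, f1=float(f1),
                   averaging=averaging, confusion=conf)


def evaluate(model: LogMelCRNN, segments: list[Segment], scheme: LabelScheme,
             batch_size: int = 64) -> Metrics:
    """Confusion-matrix metrics of the model on a labeled dataset."""
    if not segments:
        raise ValueError("cannot evaluate on an empty dataset")
    z = scheme.n_classes
    y_true = np.asarray([s.label for s in segments])
    y_pred = predict(model, segments, batch_size)
    conf = confusion_matrix(y_true, y_pred, labels=np.arange(z))
    averaging = "binary_positive" if z == 2 else "macro"
    return _metrics_from_confusion(conf, averaging)


def train(model: LogMelCRNN, train_segments: list[Segment], cfg: TrainConfig,
          eval_segments: Optional[list[Segment]] = None,
          scheme: Optional[LabelScheme] = None) -> tuple[LogMelCRNN, pd.DataFrame]:
    """Adam / cross-entropy training loop.

    Returns the trained model and a per-epoch history with the mean batch
    loss, training accuracy, and (when ``eval_segments`` is given) the four
    evaluation metrics.  By default the final-epoch parameters are kept;
    ``cfg.select_best`` restores the epoch with the best eval accuracy.
    """
    if not train_segments:
        raise ValueError("empty training set")
    opt = Adam(model.parameters(), lr=cfg.learning_rate)
    rng = np.random.default_rng(cfg.seed)
    rows = []
    best = (-1.0, None)
    for epoch in range(cfg.epochs):
        model.train()
        order = rng.permutation(len(train_segments))
        losses, hits, count = [], 0, 0
        for i in range(0, len(order), cfg.batch_size):
            batch = [train_segments[j] for j in order[i : i + cfg.batch_size]]
            x, y = _batch(batch)
            opt.zero_grad()
            logits = model.forward(x)
            loss = softmax_cross_entropy(logits, y)
            if not np.isfinite(loss.data):
                raise RuntimeError(
                    f"non-finite loss at epoch {epoch}, batch {i // cfg.batch_size}, "
                    f"lr {cfg.learning_rate}")
            loss.backward()
            opt.step()
            losses.append(float(loss.data))
            hits += int((logits.data.argmax(axis=1) == y).sum())
            count += len(y)
        row = {"epoch": epoch, "loss": float(np.mean(losses)), "train_accuracy": hits / count}
        if eval_segments is not None and scheme is not None:
            m = evaluate(model, eval_segments, scheme, cfg.batch_size)
            row.update({f"eval_{k}": v for k, v in m.as_dict().items()})
            if cfg.select_best and m.accuracy > best[0]:
                best = (m.accuracy, [p.data.copy() for p in model.parameters()])
        rows.append(row)
    if cfg.select_best and best[1] is not None:
        for p, data in zip(model.parameters(), best[1]):
            p.data[...] = data
    return model, pd.DataFrame(rows)


def desk_scale_configs(n_classes: int = 2) -> tuple[ModelConfig, TrainConfig]:
    """Model/training sizes for single-CPU experiments on synthetic data.

    The architecture is unchanged (three conv blocks, two-layer BiRNN,
    FC-ReLU-FC classifier) but with 16/32/64 conv channels; the strongly
    separable synthetic task converges within a few epochs at the standard
    learning rate, so six epochs at batch 16 with a stratified 8:2 split
    keep a full train+evaluate cycle in the low minutes on one CPU core.
    """
    return (ModelConfig(conv_widths=(16, 32, 64), n_classes=n_classes),
            TrainConfig(epochs=6, batch_size=16))


# ---------------------------------------------------------------------------
# Parameter sweep (hyperparameter ablation tables)
# ---------------------------------------------------------------------------

_SWEEPABLE = ("n_fft", "hop", "n_mels", "rate", "patch_len")


def _run_grid_point(param: str, value, recording: Recording, trace: PerclosTrace,
                    scheme: LabelScheme, spectral: SpectralConfig,
                    model_cfg: ModelConfig, train_cfg: TrainConfig,
                    window_len: int, patch_len: int) -> Metrics:
    sp = spectral
    rec = recording
    if param == "n_fft":
        sp = sp.with_(n_fft=int(value), n_mels=min(sp.n_mels, int(value) // 2 + 1))
    elif param == "hop":
        sp = sp.with_(hop=int(value))
    elif param == "n_mels":
        sp = sp.with_(n_mels=int(value))
    elif param == "rate":
        rec = resample(recording, float(value))
        sp = sp.with_(rate=float(value))
    elif param == "patch_len":
        patch_len = int(value)
    else:
        raise ConfigError(f"cannot sweep {param!r}; choose from {_SWEEPABLE}")
    segments = build_dataset(rec, trace, scheme, window_len=window_len, patch_len=patch_len)
    tr, te = train_test_split(segments, train_cfg.split_ratio, train_cfg.seed)
    cfg = replace(model_cfg, n_classes=scheme.n_classes)
    model = xavier_init(build_model(cfg, sp), train_cfg.seed)
    model, _ = train(model, tr, train_cfg)
    return evaluate(model, te, scheme, train_cfg.batch_size)


def parameter_sweep(grid: dict[str, Sequence], recording: Recording, trace: PerclosTrace,
                    scheme: LabelScheme, spectral: SpectralConfig | None = None,
                    model_cfg: ModelConfig | None = None,
                    train_cfg: TrainConfig | None = None,
                    window_len: int = 1600, patch_len: int = 200) -> pd.DataFrame:
    """Train and evaluate once per grid value; one report row per value.

    ``grid`` maps parameter names (n_fft, hop, n_mels, rate, patch_len) to
    value lists.  Rows carry the four metrics in percent; the best-accuracy
    row per parameter is flagged.  Invalid grid points are reported as
    failed rows and the sweep continues.
    """
    spectral = spectral or SpectralConfig()
    model_cfg = model_cfg or ModelConfig()
    train_cfg = train_cfg or TrainConfig()
    rows = []
    for param, values in grid.items():
        for value in values:
            row = {"parameter": param, "value": value, "best": False, "failed": False,
                   "reason": ""}
            try:
                m = _run_grid_point(param, value, recording, trace, scheme, spectral,
                                    model_cfg, train_cfg, window_len, patch_len)
                row.update({k: 100.0 * v for k, v in m.as_dict().items()})
            except (ConfigError, ValueError) as exc:
                row.update({"failed": True, "reason": str(exc),
                            "accuracy": np.nan, "precision": np.nan,
                            "recall": np.nan, "f1": np.nan})
            rows.append(row)
    df = pd.DataFrame(rows)
    for param in grid:
        sub = df[(df.parameter == param) & (~df.failed)]
        if len(sub):
            df.loc[sub.accuracy.idxmax(), "best"] = True
    return df


def format_sweep_table(df: pd.DataFrame, parameter: str) -> str:
    """Render one parameter's sweep as a four-metric text table."""
    sub = df[df.parameter == parameter]
    header = f"{parameter:<12}{'Accuracy %':>12}{'Precision %':>13}{'Recall %':>10}{'F1 score %':>12}"
    lines = [header]
    for _, row in sub.iterrows():
        mark = "*" if row.best else " "
        if row.failed:
            lines.append(f"{row.value!s:<12}failed: {row.reason}")
        else:
            lines.append(
                f"{row.value!s:<11}{mark}{row.accuracy:>11.2f}{row.precision:>13.2f}"
                f"{row.recall:>10.2f}{row.f1:>12.2f}")
    return "\n".join(lines)
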