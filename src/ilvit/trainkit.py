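"""Training toolkit: loss, metrics, AdamW + cosine schedule, train/eval.

Defaults mirror the study protocol: AdamW (lr 1e-4, eps 1e-8, betas
(0.9, 0.999), weight decay 1e-4), batch size 32, cosine annealing to
lr_min 1e-6 with linear warmup from 1e-6, 500 epochs.  One integer seed
derives independent streams for parameter initialisation, data order and
augmentation.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict

import numpy as np

from .datapipe import LabeledImageSet, eval_transform, train_transform
from .model import ILViT, ModelConfig, build_model
from .tensor import Tensor, no_grad

__all__ = [
    "TrainConfig", "ClassificationReport", "cross_entropy",
    "confusion_matrix", "micro_accuracy", "per_class_metrics",
    "cosine_lr", "AdamW", "train", "evaluate",
    "save_checkpoint", "load_checkpoint",
]


@dataclass
class TrainConfig:
    lr: float = 1e-4
    eps: float = 1e-8
    betas: tuple = (0.9, 0.999)
    weight_decay: float = 1e-4
    batch_size: int = 32
    epochs: int = 500
    warmup_epochs: int = 20
    lr_min: float = 1e-6
    warmup_lr_init: float = 1e-6
    seed: int = 0
    max_steps: int | None = None      # optional hard step budget
    augment: bool = False             # training-time augmentation pipeline

    def __post_init__(self):
        if self.lr_min > self.lr:
            raise ValueError("lr_min must not exceed lr")
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")


# --------------------------------------------------------------------------
# loss
# --------------------------------------------------------------------------

def cross_entropy(pred, labels, from_logits: bool = True) -> Tensor:
    """Mean over the batch of −log p(true class).

    ``pred`` is (N, C) logits by default; with ``from_logits=False`` it is
    taken as probabilities on the simplex (clamped at 1e-12, so a zero
    probability on the true class yields a large finite loss).
    """
    labels = np.asarray(labels, dtype=np.int64)
    pred = pred if isinstance(pred, Tensor) else Tensor(pred)
    n = pred.shape[0]
    if from_logits:
        shift = pred.data.max(axis=-1, keepdims=True)       # constant, no grad
        z = pred - shift
        log_p = z - z.exp().sum(axis=-1, keepdims=True).log()
    else:
        clamped = np.maximum(pred.data, 1e-12)      # avoid -inf at p_true = 0
        log_p = Tensor._make(np.log(clamped), (pred,), None)
        if log_p.requires_grad:
            log_p._backward = lambda g, p=pred, c=clamped: p._accum(g / c)
    picked = log_p[np.arange(n), labels]
    return -picked.mean()


# --------------------------------------------------------------------------
# metrics
# --------------------------------------------------------------------------

def confusion_matrix(y_true, y_pred, num_classes: int) -> np.ndarray:
    """C×C counts, rows = true class, columns = predicted class."""
    y_true = np.asarray(y_true, dtype=np.int64)
    y_pred = np.asarray(y_pred, dtype=np.int64)
    conf = np.zeros((num_classes, num_classes), dtype=np.int64)
    np.add.at(conf, (y_true, y_pred), 1)
    return conf


def micro_accuracy(conf: np.ndarray, literal: bool = False) -> float:
    """Micro-averaged accuracy: trace / total.

    ``literal=True`` evaluates the written form Σ TP / Σ (TP + FP + FN)
    instead, whose denominator double-counts every error (each off-
    diagonal entry is one class's FP and another's FN).
    """
    conf = _check_conf(conf)
    tp = np.trace(conf)
    if literal:
        fp = conf.sum(axis=0) - np.diag(conf)
        fn = conf.sum(axis=1) - np.diag(conf)
        denom = tp + fp.sum() + fn.sum()
    else:
        denom = conf.sum()
    return float(tp / denom) if denom else 0.0


@dataclass
class ClassificationReport:
    confusion: np.ndarray
    accuracy: float                       # micro accuracy = trace / total
    per_class_accuracy: list              # per-class recall (diagonal / row sum)
    per_class_precision: list
    per_class_recall: list
    class_names: tuple | None = None

    def table(self) -> str:
        names = self.class_names or tuple(
            f"class{i}" for i in range(len(self.per_class_recall)))
        lines = ["class,accuracy,precision,recall"]
        for i, name in enumerate(names):
            lines.append(f"{name},{self.per_class_accuracy[i]:.4f},"
                         f"{self.per_class_precision[i]:.4f},"
                         f"{self.per_class_recall[i]:.4f}")
        lines.append(f"overall,{self.accuracy:.4f},,")
        return "\n".join(lines)


def _check_conf(conf) -> np.ndarray:
    conf = np.asarray(conf)
    if conf.ndim != 2 or conf.shape[0] != conf.shape[1]:
        raise ValueError("confusion matrix must be square")
    if np.any(conf < 0) or not np.issubdtype(conf.dtype, np.integer):
        raise ValueError("confusion matrix must hold non-negative integer counts")
    return conf


def per_class_metrics(conf, class_names=None) -> ClassificationReport:
    """Precision_i = TP/(TP+FP), recall_i = TP/(TP+FN); zero denominators
    yield 0 with a warning.  Per-class accuracy is the class recall (the
    convention of per-class report tables)."""
    conf = _check_conf(conf)
    tp = np.diag(conf).astype(np.float64)
    col = conf.sum(axis=0).astype(np.float64)
    row = conf.sum(axis=1).astype(np.float64)
    if np.any(col == 0) or np.any(row == 0):
        warnings.warn("zero-denominator class in confusion matrix; metric set to 0")
    with np.errstate(invalid="ignore", divide="ignore"):
        precision = np.where(col > 0, tp / np.maximum(col, 1e-300), 0.0)
        recall = np.where(row > 0, tp / np.maximum(row, 1e-300), 0.0)
    return ClassificationReport(
        confusion=conf, accuracy=micro_accuracy(conf),
        per_class_accuracy=list(recall), per_class_precision=list(precision),
        per_class_recall=list(recall), class_names=class_names)


# --------------------------------------------------------------------------
# optimizer and schedule
# --------------------------------------------------------------------------

def cosine_lr(epoch: float, cfg: TrainConfig) -> float:
    """Linear warmup from ``warmup_lr_init`` to ``lr`` over
    ``warmup_epochs``, then cosine annealing to ``lr_min`` at the final
    epoch.  ``epoch`` may be fractional (stepped per optimizer step)."""
    if cfg.warmup_epochs > 0 and epoch < cfg.warmup_epochs:
        frac = epoch / cfg.warmup_epochs
        return cfg.warmup_lr_init + frac * (cfg.lr - cfg.warmup_lr_init)
    span = max(cfg.epochs - cfg.warmup_epochs, 1e-12)
    t = min((epoch - cfg.warmup_epochs) / span, 1.0)
    return cfg.lr_min + 0.5 * (cfg.lr - cfg.lr_min) * (1.0 + np.cos(np.pi * t))


class AdamW:
    """Decoupled weight-decay Adam; decay skipped for rank-1 parameters
    (biases, norm gains)."""

    def __init__(self, params, cfg: TrainConfig):
        self.params = list(params)
        self.cfg = cfg
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]
        self.t = 0
        self.lr = cfg.lr

    def step(self):
        b1, b2 = self.cfg.betas
        self.t += 1
        bc1 = 1.0 - b1 ** self.t
        bc2 = 1.0 - b2 ** self.t
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self.m[i] = b1 * self.m[i] + (1 - b1) * g
            self.v[i] = b2 * self.v[i] + (1 - b2) * g * g
            update = (self.m[i] / bc1) / (np.sqrt(self.v[i] / bc2) + self.cfg.eps)
            if p.data.ndim > 1 and self.cfg.weight_decay:
                update = update + self.cfg.weight_decay * p.data
            p.data = p.data - self.lr * update

    def zero_grad(self):
        for p in self.params:
            p.grad = None


# --------------------------------------------------------------------------
# train / evaluate
# --------------------------------------------------------------------------

def _prepare_inputs(ds: LabeledImageSet, size: int, augment: bool,
                    rng: np.random.Generator | None = None) -> np.ndarray:
    tf = (lambda im: train_transform(im, size=size, rng=rng)) if augment \
        else (lambda im: eval_transform(im, size=size))
    return np.stack([tf(im) for im in ds.images])


def train(model_cfg: ModelConfig, train_cfg: TrainConfig, dataset: LabeledImageSet,
          model: ILViT | None = None, log=None):
    """Train a model on a labeled image set; returns ``(model, history)``.

    History is one dict per optimizer step (step, epoch, lr, loss,
    batch accuracy), ready to be dumped as JSON lines.  Divergence (NaN
    loss) aborts with a diagnostic.
    """
    if len(dataset) == 0:
        raise ValueError("dataset is empty")
    seed_seq = np.random.SeedSequence(train_cfg.seed)
    init_seed, order_seed, aug_seed = [
        int(s.generate_state(1)[0] % (2 ** 31)) for s in seed_seq.spawn(3)]
    if model is None:
        model = build_model(model_cfg, seed=init_seed)
    model.train()
    order_rng = np.random.default_rng(order_seed)
    aug_rng = np.random.default_rng(aug_seed)
    x_all = _prepare_inputs(dataset, model_cfg.image_size, False)
    y_all = np.asarray(dataset.labels, dtype=np.int64)
    n = len(dataset)
    steps_per_epoch = max(1, int(np.ceil(n / train_cfg.batch_size)))
    opt = AdamW(model.parameters(), train_cfg)
    history = []
    step = 0
    total_steps = train_cfg.max_steps or train_cfg.epochs * steps_per_epoch
    for epoch in range(train_cfg.epochs):
        perm = order_rng.permutation(n)
        if train_cfg.augment:
            x_epoch = _prepare_inputs(dataset, model_cfg.image_size, True, aug_rng)
        else:
            x_epoch = x_all
        for start in range(0, n, train_cfg.batch_size):
            idx = perm[start:start + train_cfg.batch_size]
            xb, yb = Tensor(x_epoch[idx]), y_all[idx]
            opt.lr = cosine_lr(step / steps_per_epoch, train_cfg)
            logits = model(xb)
            loss = cross_entropy(logits, yb)
            if not np.isfinite(loss.item()):
                raise FloatingPointError(
                    f"training diverged at step {step}: loss={loss.item()}")
            opt.zero_grad()
            loss.backward()
            opt.step()
            acc = float((logits.data.argmax(axis=-1) == yb).mean())
            rec = {"step": step, "epoch": epoch, "lr": opt.lr,
                   "loss": loss.item(), "batch_accuracy": acc}
            history.append(rec)
            if log is not None:
                log.write(json.dumps(rec) + "\n")
            step += 1
            if step >= total_steps:
                return model, history
    return model, history


def evaluate(model: ILViT, dataset: LabeledImageSet,
             batch_size: int = 32, noise_sigma: float = 0.0,
             noise_seed: int = 0) -> ClassificationReport:
    """Deterministic, side-effect-free evaluation → classification report.

    ``noise_sigma`` adds Gaussian perturbation on the [0,1] intensity
    scale before standardization (the robustness protocol).
    """
    from .datapipe import IMAGENET_MEAN, IMAGENET_STD, add_gaussian_noise, normalize
    from PIL import Image as _Image
    model.eval()
    size = model.cfg.image_size
    noise_rng = np.random.default_rng(noise_seed)
    xs = []
    for im in dataset.images:
        img = _Image.fromarray(im).resize((size, size), _Image.BILINEAR)
        x01 = np.asarray(img, dtype=np.float64) / 255.0
        if noise_sigma > 0:
            x01 = add_gaussian_noise(x01, noise_sigma, rng=noise_rng)
        xs.append(normalize(x01.transpose(2, 0, 1)))
    x_all = np.stack(xs)
    y_all = np.asarray(dataset.labels, dtype=np.int64)
    preds = []
    with no_grad():
        for start in range(0, len(dataset), batch_size):
            logits = model(Tensor(x_all[start:start + batch_size]))
            preds.append(logits.data.argmax(axis=-1))
    conf = confusion_matrix(y_all, np.concatenate(preds), dataset.num_classes)
    model.train()
    return per_class_metrics(conf, class_names=dataset.class_names)


# --------------------------------------------------------------------------
# checkpoints (weights as npz + embedded config)
# --------------------------------------------------------------------------

def save_checkpoint(model: ILViT, path: str):
    arrays = {f"p{i}": a for i, a in enumerate(model.state_arrays())}
    np.savez(path, config=json.dumps(model.cfg.to_dict()), **arrays)


def load_checkpoint(path: str) -> ILViT:
    data = np.load(path, allow_pickle=False)
    cfg = ModelConfig.from_dict(json.loads(str(data["config"])))
    model = build_model(cfg, seed=0)
    arrays = [data[f"p{i}"] for i in range(len(data.files) - 1)]
    model.load_arrays(arrays)
    return model
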