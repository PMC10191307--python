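"""Subject-wise splitting, the optimization loop, and fine-tuning.

Training minimizes the IF- or RW-weighted cross-entropy with Adam
(default learning rate 0.00015, batch size 50, up to 200 optimization
epochs); the snapshot with the best validation selection metric (weighted
F1 by default) is returned. Transfer learning re-trains all parameters of
a pretrained model at a reduced learning rate (default 0.00001). Windows
never cross subject-night boundaries, and no subject appears in more than
one split or fold.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np

from .autograd import Tensor
from .inference import predict_series
from .losses import if_weights, loss_if, loss_rw, one_hot, rw_weight_matrices
from .metrics import ConfusionMatrix, classifier_metrics, confusion
from .model import (VARIANTS, ModelConfig, NormStats, SleepStager,
                    channel_matrix, make_windows)
from .preprocess import EpochSeries
from .stages import scheme

log = logging.getLogger(__name__)


@dataclass
class SplitSpec:
    """Subject-wise train/val/test split fractions (default 75/12.5/12.5%)."""

    fractions: tuple[float, float, float] = (0.75, 0.125, 0.125)
    seed: int = 0
    n_val: int | None = None    # explicit counts override the fractions
    n_test: int | None = None

    def __post_init__(self):
        if not np.isclose(sum(self.fractions), 1.0, atol=1e-9):
            raise ValueError("split fractions must sum to 1")


def split_subjects(subject_ids, spec: SplitSpec) -> tuple[list, list, list]:
    """Disjoint (train, val, test) id lists, deterministic given the seed.

    Train receives floor(f_train * n); the remainder is split evenly with
    validation first. Explicit ``n_val``/``n_test`` counts override this
    (cohort reports sometimes fix round held-out sizes).
    """
    ids = list(subject_ids)
    n = len(ids)
    if n < 3:
        raise ValueError("need at least 3 subjects to form three splits")
    order = np.random.default_rng(spec.seed).permutation(n)
    ids = [ids[i] for i in order]
    if spec.n_val is not None or spec.n_test is not None:
        n_val = spec.n_val or 0
        n_test = spec.n_test or 0
    else:
        n_train = int(np.floor(spec.fractions[0] * n))
        rest = n - n_train
        n_val = int(np.ceil(rest / 2))
        n_test = rest - n_val
    n_train = n - n_val - n_test
    if min(n_train, n_val, n_test) < 1:
        raise ValueError("too few subjects for a nonempty three-way split")
    return (ids[:n_train], ids[n_train:n_train + n_val], ids[n_train + n_val:])


@dataclass
class TrainConfig:
    scheme: str = "three"
    variant: str = "act-hr"
    window: int = 12
    hidden: int = 128
    conv_channels: int = 64
    attention: str = "general"
    loss: str = "if"                  # "if" or "rw"
    lr: float = 0.00015
    fine_tune_lr: float = 0.00001
    batch_size: int = 50
    n_epochs: int = 200               # optimization epochs
    steps_per_epoch: int | None = None  # cap on minibatches per epoch
    selection: str = "weighted_f1"    # or "accuracy", "loss"
    seed: int = 0

    def __post_init__(self):
        if self.loss not in ("if", "rw"):
            raise ValueError("loss must be 'if' or 'rw'")
        if self.selection not in ("weighted_f1", "accuracy", "loss"):
            raise ValueError("selection must be weighted_f1, accuracy or loss")
        if min(self.lr, self.fine_tune_lr) <= 0 or self.batch_size < 1 or self.n_epochs < 0:
            raise ValueError("rates and counts must be positive")


class Adam:
    """Adam optimizer over autograd parameters."""

    def __init__(self, params: list[Tensor], lr: float,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8):
        self.params = params
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in params]
        self.v = [np.zeros_like(p.data) for p in params]

    def step(self) -> None:
        self.t += 1
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * p.grad
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * p.grad**2
            mhat = self.m[i] / (1 - self.b1**self.t)
            vhat = self.v[i] / (1 - self.b2**self.t)
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


def _window_dataset(cohort: list[EpochSeries], variant: str, L: int,
                    norm: NormStats) -> tuple[np.ndarray, np.ndarray]:
    """Concatenate per-subject windows and targets (windows never span subjects)."""
    xs, ys = [], []
    for s in cohort:
        if s.stage is None:
            raise ValueError(f"subject {s.subject_id!r} has no stage labels")
        w, starts = make_windows(norm.apply(channel_matrix(s, variant)), L)
        xs.append(w)
        ys.append(s.stage.codes[starts[:, None] + np.arange(L)])
    return np.concatenate(xs), np.concatenate(ys)


def _validation_metric(model: SleepStager, X: np.ndarray, Y: np.ndarray,
                       loss_fn, selection: str) -> float:
    probs = model.predict_proba(X)
    if selection == "loss":
        return -float(loss_fn(Tensor(probs), one_hot(Y, probs.shape[-1])).data)
    pred = probs.argmax(axis=-1).ravel()
    true = Y.ravel()
    K = probs.shape[-1]
    cm = np.zeros((K, K), dtype=np.int64)
    np.add.at(cm, (pred, true), 1)
    m = classifier_metrics(ConfusionMatrix(cm))
    return m["accuracy"] if selection == "accuracy" else m["weighted_f1"]


def _run_loop(model: SleepStager, lr: float, cohort_train: list[EpochSeries],
              cohort_val: list[EpochSeries], config: TrainConfig,
              norm: NormStats) -> tuple[dict, list[dict]]:
    sch = scheme(config.scheme)
    Xtr, Ytr = _window_dataset(cohort_train, config.variant, config.window, norm)
    Xva, Yva = _window_dataset(cohort_val, config.variant, config.window, norm)
    counts = np.bincount(np.concatenate([s.stage.codes for s in cohort_train]),
                         minlength=sch.K)
    if config.loss == "if":
        w = if_weights(counts)
        loss_fn = lambda p, y: loss_if(p, y, w)
    else:
        w = rw_weight_matrices(counts / counts.sum())
        loss_fn = lambda p, y: loss_rw(p, y, w)

    opt = Adam(model.parameters(), lr)
    rng = np.random.default_rng(config.seed + 1)
    best = {"params": model.copy_params(), "metric": -np.inf, "epoch": -1}
    history: list[dict] = []
    B = Xtr.shape[0]
    for ep in range(config.n_epochs):
        order = rng.permutation(B)
        if config.steps_per_epoch is not None:
            order = order[: config.steps_per_epoch * config.batch_size]
        losses = []
        for i in range(0, order.size, config.batch_size):
            idx = order[i:i + config.batch_size]
            model.zero_grad()
            probs = model.forward(Xtr[idx])
            loss = loss_fn(probs, one_hot(Ytr[idx], sch.K))
            lval = float(loss.data)
            if not np.isfinite(lval):
                raise RuntimeError(
                    f"training diverged: non-finite loss at epoch {ep}, "
                    f"step {i // config.batch_size} (lr={lr}, loss={config.loss})")
            loss.backward()
            opt.step()
            losses.append(lval)
        val = _validation_metric(model, Xva, Yva, loss_fn, config.selection)
        history.append({"epoch": ep, "train_loss": float(np.mean(losses)),
                        "val_metric": val})
        if val > best["metric"]:
            best = {"params": model.copy_params(), "metric": val, "epoch": ep}
        log.debug("epoch %d: train loss %.4f, val %s %.4f", ep,
                  history[-1]["train_loss"], config.selection, val)
    if best["epoch"] >= 0:
        model.load_params(best["params"])
    return best, history


def train_model(cohort_train: list[EpochSeries], cohort_val: list[EpochSeries],
                config: TrainConfig) -> tuple[SleepStager, NormStats, list[dict]]:
    """Train from scratch; returns (best model, normalization, history)."""
    if not cohort_train or not cohort_val:
        raise ValueError("train and validation cohorts must be nonempty")
    sch = scheme(config.scheme)
    channels = VARIANTS[config.variant]
    norm = NormStats.fit([channel_matrix(s, config.variant) for s in cohort_train],
                         channels)
    model = SleepStager(ModelConfig(
        n_channels=len(channels), n_classes=sch.K, window=config.window,
        conv_channels=config.conv_channels, hidden=config.hidden,
        attention=config.attention, seed=config.seed))
    _, history = _run_loop(model, config.lr, cohort_train, cohort_val, config, norm)
    return model, norm, history


def fine_tune(model: SleepStager, norm: NormStats,
              cohort_train: list[EpochSeries], cohort_val: list[EpochSeries],
              config: TrainConfig) -> tuple[SleepStager, list[dict]]:
    """Fine-tune all parameters of a pretrained model at the reduced rate."""
    sch = scheme(config.scheme)
    channels = VARIANTS[config.variant]
    if model.config.n_channels != len(channels):
        raise ValueError(f"pretrained model expects {model.config.n_channels} "
                         f"channels but variant {config.variant!r} has {len(channels)}")
    if model.config.n_classes != sch.K:
        raise ValueError("pretrained model's class count does not match the scheme")
    if config.n_epochs == 0:
        return model, []
    _, history = _run_loop(model, config.fine_tune_lr, cohort_train, cohort_val,
                           config, norm)
    return model, history


def evaluate_cohort(model: SleepStager, norm: NormStats,
                    cohort: list[EpochSeries], config: TrainConfig) -> dict:
    """Mode-voted night-level evaluation over a labeled cohort."""
    sch = scheme(config.scheme)
    cms = []
    for s in cohort:
        pred = predict_series(model, channel_matrix(s, config.variant), sch,
                              norm, epoch_s=s.epoch_s)
        cms.append(confusion(pred, s.stage))
    pooled = cms[0]
    for cm in cms[1:]:
        pooled = pooled + cm
    return {"confusion": pooled, "metrics": classifier_metrics(pooled),
            "per_subject": [classifier_metrics(cm) for cm in cms]}


def make_folds(n: int, k: int) -> list[np.ndarray]:
    """Balanced contiguous index folds; the first n % k folds get one extra."""
    if k > n:
        raise ValueError("more folds than subjects")
    sizes = np.full(k, n // k)
    sizes[: n % k] += 1
    edges = np.concatenate([[0], np.cumsum(sizes)])
    return [np.arange(edges[i], edges[i + 1]) for i in range(k)]


def cross_validate(cohort: list[EpochSeries], k: int,
                   config: TrainConfig) -> dict:
    """Subject-wise k-fold cross-validation reporting overall accuracy."""
    n = len(cohort)
    rng = np.random.default_rng(config.seed)
    order = rng.permutation(n)
    folds = make_folds(n, k)
    accs = []
    for fi, fold in enumerate(folds):
        test_idx = set(order[fold].tolist())
        rest = [i for i in order if i not in test_idx]
        n_val = max(1, len(rest) // 8)
        val = [cohort[i] for i in rest[:n_val]]
        train = [cohort[i] for i in rest[n_val:]]
        test = [cohort[i] for i in sorted(test_idx)]
        model, norm, _ = train_model(train, val, replace(config, seed=config.seed + fi))
        res = evaluate_cohort(model, norm, test, config)
        accs.append(res["metrics"]["accuracy"])
    accs = np.asarray(accs)
    return {"fold_accuracy": accs.tolist(), "mean": float(accs.mean()),
            "sd": float(accs.std(ddof=1)) if accs.size > 1 else 0.0}
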