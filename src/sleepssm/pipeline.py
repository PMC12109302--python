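"""Cross-subject training and evaluation.

Subjects — never epochs — are partitioned into k folds, so a test
subject's data can never influence training (asserted at run time).
Training follows the reference protocol: Adam (lr 0.001), weighted
cross-entropy with inverse-frequency class weights recomputed on each
fold's training labels, batch size 128, 100 epochs, a single global
seed feeding separate derived streams for splitting, initialisation,
shuffling and dropout.  Because the whole stack is plain NumPy, two runs
with the same configuration and seed are bitwise identical.

Smaller budgets (fewer epochs, smaller batches) are plain config
changes; the defaults are the full protocol.
"""

from __future__ import annotations

import json
import time
import warnings
from dataclasses import asdict, dataclass, field

import numpy as np

from .data import Recording
from .metrics import MetricsReport, confusion_matrix
from .model import ModelConfig, VARIANTS, build_model

N_CLASSES = 5


@dataclass
class TrainConfig:
    learning_rate: float = 0.001
    batch_size: int = 128
    epochs: int = 100
    folds: int = 5
    seed: int = 0
    weighted_loss: bool = True

    def __post_init__(self):
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")
        if self.folds < 2:
            raise ValueError("folds must be >= 2")

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class FoldSplit:
    """subject_id -> fold index; folds are subject-disjoint by construction."""

    assignment: dict[str, int]
    folds: int

    def fold_subjects(self, fold: int) -> list[str]:
        return sorted(s for s, f in self.assignment.items() if f == fold)

    def train_subjects(self, fold: int) -> list[str]:
        return sorted(s for s, f in self.assignment.items() if f != fold)


def kfold_split_subjects(subject_ids: list[str], k: int,
                         seed: int) -> FoldSplit:
    """Random, even, deterministic assignment of subjects to k folds."""
    ids = list(subject_ids)
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate subject ids")
    if len(ids) < k:
        raise ValueError(f"{len(ids)} subjects cannot fill {k} folds")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(ids))
    assignment = {ids[j]: int(i % k) for i, j in enumerate(order)}
    return FoldSplit(assignment=assignment, folds=k)


def class_weights(label_counts: np.ndarray) -> np.ndarray:
    """Inverse-frequency weights w_c = N / (K·N_c) over the K present
    classes, rescaled to mean 1 over those classes; absent classes get 0."""
    counts = np.asarray(label_counts, dtype=np.float64)
    if counts.sum() == 0:
        raise ValueError("all class counts are zero")
    present = counts > 0
    if not present.all():
        warnings.warn(
            f"classes absent from training labels: "
            f"{np.flatnonzero(~present).tolist()}; weight 0 assigned")
    k = int(present.sum())
    w = np.zeros_like(counts)
    w[present] = counts.sum() / (k * counts[present])
    w[present] *= k / w[present].sum()  # mean 1 over present classes
    return w


class Adam:
    """Standard Adam (β1=0.9, β2=0.999, ε=1e-8) over a parameter dict."""

    def __init__(self, params: dict, lr: float,
                 betas=(0.9, 0.999), eps: float = 1e-8):
        self.params = params
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = {k: np.zeros_like(p.data) for k, p in params.items()}
        self.v = {k: np.zeros_like(p.data) for k, p in params.items()}

    def step(self) -> None:
        self.t += 1
        b1t = 1.0 - self.b1**self.t
        b2t = 1.0 - self.b2**self.t
        for k, p in self.params.items():
            if p.grad is None:
                continue
            g = p.grad
            self.m[k] = self.b1 * self.m[k] + (1 - self.b1) * g
            self.v[k] = self.b2 * self.v[k] + (1 - self.b2) * g * g
            update = (self.lr * (self.m[k] / b1t)
                      / (np.sqrt(self.v[k] / b2t) + self.eps))
            p.data = p.data - update.astype(p.data.dtype)


def weighted_cross_entropy(logits, y: np.ndarray,
                           weights: np.ndarray):
    """Mean over the batch of w_y · (−log p_y), normalised by Σ w_y."""
    logp = logits.log_softmax(axis=-1)
    w = weights[y]
    picked = logp[np.arange(len(y)), y]
    return -(picked * w).sum() * (1.0 / max(w.sum(), 1e-12))


def _derived_seed(ss: np.random.SeedSequence) -> int:
    return int(ss.generate_state(1)[0] % (2**31))


def train_model(x: np.ndarray, y: np.ndarray, cfg: TrainConfig,
                variant: str = "full",
                model_config: ModelConfig | None = None,
                log=None) -> tuple:
    """Train one model on (x, y); returns (model, per-epoch loss history).

    The training set must contain at least two classes.  ``cfg.epochs=0``
    returns the freshly initialised model untouched.
    """
    if variant not in VARIANTS:
        raise ValueError(f"unknown variant {variant!r}")
    x = np.asarray(x)
    y = np.asarray(y, dtype=np.int64)
    if len(x) == 0:
        raise ValueError("empty training set")
    if len(np.unique(y)) < 2:
        raise ValueError("training set contains a single class")
    init_ss, shuffle_ss, dropout_ss = np.random.SeedSequence(
        cfg.seed).spawn(3)
    model = build_model(variant, model_config, seed=_derived_seed(init_ss))
    shuffle_rng = np.random.default_rng(shuffle_ss)
    dropout_rng = np.random.default_rng(dropout_ss)
    counts = np.bincount(y, minlength=N_CLASSES)
    weights = (class_weights(counts) if cfg.weighted_loss
               else np.ones(N_CLASSES))
    weights = weights.astype(np.float64)
    params = model.parameters()
    opt = Adam(params, lr=cfg.learning_rate)
    x = x.astype(model.config.dtype)
    history = []
    for epoch in range(cfg.epochs):
        order = shuffle_rng.permutation(len(x))
        losses = []
        for i in range(0, len(order), cfg.batch_size):
            idx = order[i:i + cfg.batch_size]
            model.zero_grad()
            logits = model.forward(x[idx], training=True, rng=dropout_rng)
            loss = weighted_cross_entropy(logits, y[idx], weights)
            loss.backward()
            opt.step()
            losses.append(float(loss.data))
        history.append(float(np.mean(losses)))
        if log is not None:
            log({"epoch": epoch, "loss": history[-1]})
    return model, history


def _collect(recordings: list[Recording], subjects: set[str]):
    xs, ys = [], []
    for rec in recordings:
        if rec.subject_id in subjects:
            x, y = rec.to_arrays()
            xs.append(x)
            ys.append(y)
    if not xs:
        return (np.empty((0, 2, 0)), np.empty(0, dtype=np.int64))
    return np.concatenate(xs), np.concatenate(ys)


@dataclass
class CrossValResult:
    split: FoldSplit
    fold_reports: list[MetricsReport]
    pooled: MetricsReport
    mean_over_folds: dict[str, float]
    histories: list[list[float]] = field(default_factory=list)

    def summary(self) -> dict:
        return {
            "acc": self.pooled.acc, "mf1": self.pooled.mf1,
            "kappa": self.pooled.kappa, "sen": self.pooled.sen,
            "spec": self.pooled.spec, "pre": self.pooled.pre,
            "n_epochs": self.pooled.n_epochs,
            "mean_over_folds": self.mean_over_folds,
        }


def cross_validate(recordings: list[Recording], cfg: TrainConfig,
                   variant: str = "full",
                   model_config: ModelConfig | None = None,
                   log=None) -> CrossValResult:
    """k-fold cross-subject evaluation.

    Per fold: train on the other k−1 folds' subjects, evaluate on the
    held-out subjects.  The train/test subject sets are asserted
    disjoint.  Metrics are reported per fold, pooled over all test
    epochs, and as the unweighted mean of per-fold values.
    """
    ids = [rec.subject_id for rec in recordings]
    split = kfold_split_subjects(ids, cfg.folds, cfg.seed)
    fold_reports, histories = [], []
    pooled_cm = np.zeros((N_CLASSES, N_CLASSES), dtype=np.int64)
    for fold in range(cfg.folds):
        test_subjects = set(split.fold_subjects(fold))
        train_subjects = set(split.train_subjects(fold))
        if train_subjects & test_subjects:
            raise AssertionError(
                f"subject leakage in fold {fold}: "
                f"{sorted(train_subjects & test_subjects)}")
        x_tr, y_tr = _collect(recordings, train_subjects)
        x_te, y_te = _collect(recordings, test_subjects)
        t0 = time.time()
        model, hist = train_model(x_tr, y_tr, cfg, variant, model_config,
                                  log=None)
        y_hat = model.predict(x_te)
        cm = confusion_matrix(y_te, y_hat)
        pooled_cm += cm
        report = MetricsReport.from_confusion(cm)
        fold_reports.append(report)
        histories.append(hist)
        if log is not None:
            log({"fold": fold, "acc": report.acc, "kappa": report.kappa,
                 "n_test": int(len(y_te)), "seconds": time.time() - t0})
    pooled = MetricsReport.from_confusion(pooled_cm)
    mean_over_folds = {
        key: float(np.mean([getattr(r, key) for r in fold_reports]))
        for key in ("acc", "mf1", "kappa", "sen", "spec", "pre")
    }
    return CrossValResult(split=split, fold_reports=fold_reports,
                          pooled=pooled, mean_over_folds=mean_over_folds,
                          histories=histories)


def holdout_fold(recordings: list[Recording], cfg: TrainConfig,
                 variant: str = "full",
                 model_config: ModelConfig | None = None,
                 fold: int = 0) -> MetricsReport:
    """Train/evaluate a single subject-disjoint fold (the ablation
    protocol: cheaper than full CV, same leakage guarantees)."""
    ids = [rec.subject_id for rec in recordings]
    split = kfold_split_subjects(ids, cfg.folds, cfg.seed)
    test_subjects = set(split.fold_subjects(fold))
    x_tr, y_tr = _collect(recordings, set(ids) - test_subjects)
    x_te, y_te = _collect(recordings, test_subjects)
    model, _ = train_model(x_tr, y_tr, cfg, variant, model_config)
    return MetricsReport.from_labels(y_te, model.predict(x_te))


def ablation_study(recordings: list[Recording], cfg: TrainConfig,
                   variants=("full", "cnn_se", "ssm_only"),
                   seeds=(0, 1, 2),
                   model_config: ModelConfig | None = None,
                   log=None) -> dict[str, list[float]]:
    """Hold-out-fold accuracy of each variant over several training
    seeds (data and split stay fixed; only training randomness moves)."""
    out: dict[str, list[float]] = {v: [] for v in variants}
    for seed in seeds:
        run_cfg = TrainConfig(**{**cfg.to_dict(), "seed": int(seed)})
        for v in variants:
            rep = holdout_fold(recordings, run_cfg, v, model_config)
            out[v].append(rep.acc)
            if log is not None:
                log({"variant": v, "seed": int(seed), "acc": rep.acc})
    return out


def write_run_log(path, records: list[dict]) -> None:
    """JSON-lines run log."""
    with open(path, "w") as f:
        for rec in records:
            f.write(json.dumps(rec) + "\n")
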