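"""Training loop, tenfold cross-validation, metrics, and permutation testing.

The protocol: subjects are stratified into 10 portions with near-equal class
balance; in loop i, portion i is the test set, portion i+1 (mod 10) the
validation set, and the remaining portions the training set — with 210
subjects this gives the canonical 21 / 21 / 168 split.  Models train with
Adam (categorical cross-entropy), base learning rate 1e-4 decayed by 0.1
every 20 epochs, batch size 11, 60 epochs; the validation set selects the
best-epoch checkpoint (ties go to the latest epoch).  Reported metrics (all
in percent): ACC, PRE, SPE, SEN, F1S, AUC, summarized as mean +/- sd across
folds.  Statistical significance is assessed by retraining on label-permuted
training sets and comparing test accuracies.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
from sklearn.metrics import roc_auc_score

from ._nn import Adam
from ._tensor import Tensor
from .model import (FusionNet, Prediction, batch_loss, predict_batch,
                    subjects_to_array)
from .volumes import Subject

logger = logging.getLogger("adfuse")

__all__ = [
    "TrainConfig", "FoldPlan", "MetricsReport", "PermutationResult",
    "make_folds", "train_model", "evaluate_metrics", "cross_validate",
    "permutation_test", "learning_rate_at",
]


@dataclass
class TrainConfig:
    """Optimization settings (defaults follow the reference protocol)."""

    batch_size: int = 11
    epochs: int = 60
    lr: float = 1e-4
    lr_decay: float = 0.1
    lr_step_epochs: int = 20
    seed: int = 0

    def __post_init__(self):
        if min(self.batch_size, self.lr_step_epochs) <= 0 or self.epochs < 0:
            raise ValueError("batch_size/epochs/lr_step_epochs must be positive")
        if self.lr <= 0:
            raise ValueError("lr must be positive")


def learning_rate_at(cfg: TrainConfig, epoch: int) -> float:
    """LR for a 1-based epoch index: lr * decay^floor((epoch-1)/step)."""
    return cfg.lr * cfg.lr_decay ** ((epoch - 1) // cfg.lr_step_epochs)


@dataclass
class FoldPlan:
    """Rotating test/validation/train partition over stratified portions."""

    portions: list[np.ndarray]

    @property
    def n_loops(self) -> int:
        return len(self.portions)

    def loop(self, i: int) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """(test, validation, train) index arrays for loop i."""
        k = self.n_loops
        test = self.portions[i]
        val = self.portions[(i + 1) % k]
        train = np.concatenate(
            [self.portions[j] for j in range(k) if j not in (i, (i + 1) % k)])
        return test, val, train


def make_folds(labels: np.ndarray, n_portions: int = 10, seed: int = 0) -> FoldPlan:
    """Stratified portions with remainders dealt round-robin.

    Each class's subjects are shuffled and dealt one at a time to consecutive
    portions, the deal pointer carrying over between classes so portion sizes
    stay as equal as possible (210 subjects -> ten portions of exactly 21).
    """
    labels = np.asarray(labels)
    n = labels.shape[0]
    if n < n_portions:
        raise ValueError(f"need at least {n_portions} subjects, got {n}")
    classes = np.unique(labels)
    if classes.size < 2:
        raise ValueError("both classes must be present")
    rng = np.random.default_rng(seed)
    portions: list[list[int]] = [[] for _ in range(n_portions)]
    pointer = 0
    for cls in classes:
        idx = np.flatnonzero(labels == cls)
        if idx.size < n_portions:
            logger.warning(
                "class %r has %d members for %d portions; stratification is "
                "best-effort", cls, idx.size, n_portions)
        rng.shuffle(idx)
        for i in idx:
            portions[pointer % n_portions].append(int(i))
            pointer += 1
    return FoldPlan([np.sort(np.array(p, dtype=np.int64)) for p in portions])


@dataclass
class MetricsReport:
    """Per-fold metric table (percent scale) with mean +/- sd summaries."""

    folds: list[dict[str, float]] = field(default_factory=list)

    METRICS = ("ACC", "PRE", "SPE", "SEN", "F1S", "AUC")

    def add(self, entry: dict[str, float]) -> None:
        self.folds.append(entry)

    def _values(self, metric: str) -> np.ndarray:
        vals = np.array([f[metric] for f in self.folds], dtype=float)
        return vals[~np.isnan(vals)]

    def mean(self, metric: str) -> float:
        vals = self._values(metric)
        return float(vals.mean()) if vals.size else float("nan")

    def sd(self, metric: str) -> float:
        vals = self._values(metric)
        return float(vals.std(ddof=1)) if vals.size > 1 else 0.0

    def summary(self) -> dict[str, tuple[float, float]]:
        return {m: (self.mean(m), self.sd(m)) for m in self.METRICS}

    def to_frame(self):
        import pandas as pd
        return pd.DataFrame(self.folds)

    def __str__(self) -> str:
        parts = [f"{m} {self.mean(m):.2f} +/- {self.sd(m):.2f}"
                 for m in self.METRICS]
        return "; ".join(parts)


def evaluate_metrics(y_true: np.ndarray, y_pred: np.ndarray,
                     scores: np.ndarray | None = None) -> dict[str, float]:
    """Confusion-matrix metrics in percent; AD (label 1) is positive.

    ``scores`` are positive-class probabilities for AUC.  Metrics undefined on
    a single-class fold come back as NaN with a logged warning rather than a
    silent 0.
    """
    y_true = np.asarray(y_true).astype(int)
    y_pred = np.asarray(y_pred).astype(int)
    tp = int(np.sum((y_true == 1) & (y_pred == 1)))
    tn = int(np.sum((y_true == 0) & (y_pred == 0)))
    fp = int(np.sum((y_true == 0) & (y_pred == 1)))
    fn = int(np.sum((y_true == 1) & (y_pred == 0)))
    n = y_true.size

    def ratio(num, den, name):
        if den == 0:
            logger.warning("%s undefined (zero denominator); reporting NaN", name)
            return float("nan")
        return 100.0 * num / den

    acc = ratio(tp + tn, n, "ACC")
    pre = ratio(tp, tp + fp, "PRE")
    sen = ratio(tp, tp + fn, "SEN")
    spe = ratio(tn, tn + fp, "SPE")
    if np.isnan(pre) or np.isnan(sen) or (pre + sen) == 0:
        f1 = float("nan")
        logger.warning("F1S undefined; reporting NaN")
    else:
        f1 = 2.0 * pre * sen / (pre + sen)
    if scores is None or np.unique(y_true).size < 2:
        auc = float("nan")
        if scores is not None:
            logger.warning("AUC undefined on a single-class fold; reporting NaN")
    else:
        auc = 100.0 * float(roc_auc_score(y_true, np.asarray(scores)))
    return {"ACC": acc, "PRE": pre, "SPE": spe, "SEN": sen, "F1S": f1, "AUC": auc}


def _iterate_batches(n: int, batch_size: int, rng: np.random.Generator):
    order = rng.permutation(n)
    for start in range(0, n, batch_size):
        yield order[start:start + batch_size]


def train_model(model: FusionNet, x_train: np.ndarray, y_train: np.ndarray,
                x_val: np.ndarray | None = None, y_val: np.ndarray | None = None,
                cfg: TrainConfig | None = None) -> dict:
    """Train in place; returns the per-epoch history.

    With a validation set, the parameters of the best validation-accuracy
    epoch (ties -> latest) are restored at the end.  History records, per
    epoch: train loss/accuracy, validation loss/accuracy (if any), learning
    rate, and the per-block attention-gate values.
    """
    cfg = cfg or TrainConfig()
    if x_train.shape[0] == 0:
        raise ValueError("empty training set")
    rng = np.random.default_rng(cfg.seed)
    opt = Adam(model.parameters(), lr=cfg.lr)
    history = {"epoch": [], "lr": [], "train_loss": [], "train_acc": [],
               "val_loss": [], "val_acc": [], "gates": []}
    best_state, best_acc, best_epoch = None, -1.0, -1
    for epoch in range(1, cfg.epochs + 1):
        opt.lr = learning_rate_at(cfg, epoch)
        model.train()
        losses, hits, seen = [], 0, 0
        for batch in _iterate_batches(x_train.shape[0], cfg.batch_size, rng):
            xb = x_train[batch]
            yb = y_train[batch]
            logits, _ = model(Tensor(xb))
            loss_t = batch_loss(logits, yb)
            opt.zero_grad()
            loss_t.backward()
            opt.step()
            losses.append(float(loss_t.data))
            hits += int(np.sum(np.argmax(logits.data, axis=1) == yb))
            seen += yb.size
        train_loss = float(np.mean(losses))
        train_acc = hits / seen
        val_loss, val_acc = float("nan"), float("nan")
        if x_val is not None and x_val.shape[0] > 0:
            preds = predict_batch(model, x_val, batch_size=cfg.batch_size)
            probs = np.stack([p.probs for p in preds])
            yv = np.asarray(y_val)
            eps = float(np.finfo(np.float32).tiny)
            val_loss = float(np.mean(-np.log(
                np.maximum(probs[np.arange(yv.size), yv], eps))))
            val_acc = float(np.mean(np.argmax(probs, axis=1) == yv))
            if val_acc >= best_acc:  # >= so ties pick the latest epoch
                best_acc, best_epoch = val_acc, epoch
                best_state = model.state_dict()
        history["epoch"].append(epoch)
        history["lr"].append(opt.lr)
        history["train_loss"].append(train_loss)
        history["train_acc"].append(train_acc)
        history["val_loss"].append(val_loss)
        history["val_acc"].append(val_acc)
        history["gates"].append(model.gates())
        logger.info("epoch %d lr %.2e train loss %.4f acc %.3f val acc %.3f "
                    "gates %s", epoch, opt.lr, train_loss, train_acc, val_acc,
                    model.gates())
    if best_state is not None:
        model.load_state_dict(best_state)
        history["best_epoch"] = best_epoch
    model.eval()
    return history


def _model_factory(factory, seed: int) -> FusionNet:
    model = factory(seed)
    if not isinstance(model, FusionNet):
        raise TypeError("model factory must return a FusionNet")
    return model


def cross_validate(subjects: list[Subject], model_factory, cfg: TrainConfig | None = None,
                   n_portions: int = 10, seed: int = 0) -> MetricsReport:
    """Rotating-portion cross-validation with a fresh model per loop.

    ``model_factory(seed)`` must build an untrained :class:`FusionNet`.
    """
    cfg = cfg or TrainConfig()
    x, y = subjects_to_array(subjects)
    plan = make_folds(y, n_portions=n_portions, seed=seed)
    report = MetricsReport()
    for i in range(plan.n_loops):
        test_idx, val_idx, train_idx = plan.loop(i)
        model = _model_factory(model_factory, seed + i)
        fold_cfg = replace(cfg, seed=cfg.seed + i)
        train_model(model, x[train_idx], y[train_idx], x[val_idx], y[val_idx],
                    fold_cfg)
        preds = predict_batch(model, x[test_idx], batch_size=cfg.batch_size)
        y_pred = np.array([p.y for p in preds])
        scores = np.array([p.probs[1] for p in preds])
        entry = evaluate_metrics(y[test_idx], y_pred, scores)
        entry["fold"] = i
        report.add(entry)
        logger.info("fold %d: %s", i, entry)
    return report


@dataclass
class PermutationResult:
    """Observed vs. label-permuted test accuracies and the empirical p-value.

    p = (1 + #{permuted >= observed}) / (1 + n_perm).
    """

    observed: float
    permuted: np.ndarray
    p_value: float


def permutation_test(subjects: list[Subject], model_factory,
                     cfg: TrainConfig | None = None, n_perm: int = 1000,
                     seed: int = 0, holdout_fraction: float = 0.2) -> PermutationResult:
    """Label-permutation significance test of the classifier.

    One stratified train/test split is fixed; the observed model trains on the
    true training labels, then ``n_perm`` replicates retrain on permuted
    training labels.  Test labels are never permuted.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    cfg = cfg or TrainConfig()
    x, y = subjects_to_array(subjects)
    n_portions = max(2, int(round(1.0 / holdout_fraction)))
    plan = make_folds(y, n_portions=n_portions, seed=seed)
    test_idx = plan.portions[0]
    train_idx = np.concatenate(plan.portions[1:])

    def run(train_labels: np.ndarray, run_seed: int) -> float:
        model = _model_factory(model_factory, run_seed)
        run_cfg = replace(cfg, seed=run_seed)
        train_model(model, x[train_idx], train_labels, None, None, run_cfg)
        preds = predict_batch(model, x[test_idx], batch_size=cfg.batch_size)
        return float(np.mean(np.array([p.y for p in preds]) == y[test_idx]))

    observed = run(y[train_idx], seed)
    rng = np.random.default_rng(seed + 1)
    permuted = np.empty(n_perm)
    for j in range(n_perm):
        perm_labels = rng.permutation(y[train_idx])
        permuted[j] = run(perm_labels, seed + 2 + j)
        logger.info("permutation %d/%d: acc %.3f (observed %.3f)",
                    j + 1, n_perm, permuted[j], observed)
    p = (1.0 + np.sum(permuted >= observed)) / (1.0 + n_perm)
    return PermutationResult(observed=observed, permuted=permuted,
                             p_value=float(p))
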