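"""Training loop, data-splitting protocols, and confusion-matrix evaluation.

Three splitting protocols assess generalisation at increasing difficulty:

``dataset_dependent``
    within every dataset, a stratified 4:1 train/validation split per class
    (largest-remainder rounding), then pooled across datasets and shuffled —
    the model sees every recording during training.
``dataset_independent``
    leave-one-dataset-out: one fold per dataset, whose clips are the
    validation set — the model never sees the held-out recording.
``group_independent``
    leave-one-group-out over a dataset -> group map (in the pain studies the
    groups are the inducer/dose categories) — the model never sees the
    held-out condition.

Training uses Adam (lr 5e-4), batch size 25, up to 30 epochs with early
stopping on validation loss.  Evaluation reports the four standard indices
with grooming as the positive class: accuracy, sensitivity, specificity,
precision; fold reports are macro-averaged (mean of per-fold metrics) with
pooled micro counts also available.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .feature_sampling import ClipSample, stack_samples
from .msrc_model import MSRCModel
from .nn import Adam, softmax_cross_entropy

__all__ = [
    "TrainConfig",
    "SplitPlan",
    "TrainHistory",
    "EvalReport",
    "make_split",
    "train",
    "evaluate",
    "aggregate_reports",
]

SCHEMES = ("dataset_dependent", "dataset_independent", "group_independent")


@dataclass(frozen=True)
class TrainConfig:
    """Optimisation hyperparameters (Adam, lr 5e-4, batch 25, <= 30 epochs)."""

    learning_rate: float = 5e-4
    batch_size: int = 25
    max_epochs: int = 30
    patience: int = 5
    shuffle: bool = True
    seed: int = 0

    def __post_init__(self):
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")
        if self.learning_rate < 0:
            raise ValueError("learning_rate must be >= 0")


@dataclass(frozen=True)
class SplitPlan:
    """Folds of (train clip ids, validation clip ids) for one scheme."""

    scheme: str
    folds: list[tuple[list[str], list[str]]]
    grouping: dict[str, str] | None = None


def _largest_remainder_train_count(n: int, ratio: float) -> int:
    return int(np.floor(n * ratio + 0.5))


def make_split(manifest: pd.DataFrame, scheme: str, ratio: float = 0.8,
               seed: int = 0, grouping: dict[str, str] | None = None) -> SplitPlan:
    """Build a :class:`SplitPlan` from a clip manifest.

    ``manifest`` needs columns ``clip_id``, ``dataset`` and ``label``.
    ``ratio`` is the training fraction for the dataset-dependent scheme
    (default 0.8, i.e. 4:1).  ``grouping`` maps dataset -> group and is
    required for the group-independent scheme.
    """
    if scheme not in SCHEMES:
        raise ValueError(f"unknown scheme {scheme!r}; one of {SCHEMES}")
    for col in ("clip_id", "dataset", "label"):
        if col not in manifest.columns:
            raise ValueError(f"manifest is missing column {col!r}")
    rng = np.random.default_rng(np.random.SeedSequence([seed, 31]))
    datasets = sorted(manifest["dataset"].unique())

    if scheme == "dataset_dependent":
        train_ids: list[str] = []
        val_ids: list[str] = []
        for ds in datasets:
            sub = manifest[manifest["dataset"] == ds]
            for label in sorted(sub["label"].unique()):
                ids = sub.loc[sub["label"] == label, "clip_id"].tolist()
                ids = [ids[i] for i in rng.permutation(len(ids))]
                n_train = _largest_remainder_train_count(len(ids), ratio)
                train_ids.extend(ids[:n_train])
                val_ids.extend(ids[n_train:])
        train_ids = [train_ids[i] for i in rng.permutation(len(train_ids))]
        val_ids = [val_ids[i] for i in rng.permutation(len(val_ids))]
        return SplitPlan(scheme, [(train_ids, val_ids)])

    if len(datasets) < 2:
        raise ValueError(f"{scheme} needs at least 2 datasets, found {len(datasets)}")

    if scheme == "dataset_independent":
        folds = []
        for ds in datasets:
            val = manifest.loc[manifest["dataset"] == ds, "clip_id"].tolist()
            tr = manifest.loc[manifest["dataset"] != ds, "clip_id"].tolist()
            tr = [tr[i] for i in rng.permutation(len(tr))]
            folds.append((tr, val))
        return SplitPlan(scheme, folds)

    # group_independent
    if grouping is None:
        raise ValueError("group_independent scheme requires a dataset -> group map")
    missing = [ds for ds in datasets if ds not in grouping]
    if missing:
        raise ValueError(f"datasets missing from grouping map: {missing}")
    groups = sorted(set(grouping[ds] for ds in datasets))
    if len(groups) < 2:
        raise ValueError("group_independent needs at least 2 groups")
    ds_group = manifest["dataset"].map(grouping)
    folds = []
    for g in groups:
        val = manifest.loc[ds_group == g, "clip_id"].tolist()
        tr = manifest.loc[ds_group != g, "clip_id"].tolist()
        tr = [tr[i] for i in rng.permutation(len(tr))]
        folds.append((tr, val))
    return SplitPlan(scheme, folds, grouping=dict(grouping))


# ---------------------------------------------------------------------------
# training


@dataclass
class TrainHistory:
    """Per-epoch losses/accuracies plus the early-stopping outcome."""

    train_loss: list[float] = field(default_factory=list)
    train_acc: list[float] = field(default_factory=list)
    val_loss: list[float] = field(default_factory=list)
    val_acc: list[float] = field(default_factory=list)
    best_epoch: int = -1
    stopped_early: bool = False

    @property
    def best_val_acc(self) -> float:
        if self.best_epoch < 0 or not self.val_acc:
            return float("nan")
        return self.val_acc[self.best_epoch]


def _as_arrays(samples):
    if isinstance(samples, (list, tuple)) and samples and isinstance(samples[0], ClipSample):
        return stack_samples(list(samples))
    return samples  # already (images, flow_x, flow_y)


def _eval_loss_acc(model: MSRCModel, arrays, labels, batch_size: int):
    images, fx, fy = arrays
    n = len(labels)
    losses, correct = [], 0
    for i in range(0, n, batch_size):
        sl = slice(i, min(i + batch_size, n))
        logits = model.forward(images[sl], fx[sl], fy[sl], train=False)
        loss, _ = softmax_cross_entropy(logits, labels[sl])
        losses.append(loss * (sl.stop - sl.start))
        correct += int((logits.argmax(axis=1) == labels[sl]).sum())
    return float(np.sum(losses) / n), correct / n


def train(model: MSRCModel, samples, labels, config: TrainConfig | None = None,
          val_samples=None, val_labels=None) -> TrainHistory:
    """Mini-batch training with shuffling and early stopping on validation loss.

    ``samples`` is a list of :class:`ClipSample` (or a pre-stacked
    ``(images, flow_x, flow_y)`` tuple); ``labels`` the 0/1 class array
    (1 = grooming).  When a validation set is given, training stops after
    ``patience`` epochs without improvement in validation loss and the best
    epoch's weights are restored.  A fixed seed gives a reproducible history
    on one device.
    """
    config = config or TrainConfig()
    labels = np.asarray(labels, dtype=np.int64)
    arrays = _as_arrays(samples)
    if len(labels) == 0:
        raise ValueError("empty training set")
    if len(labels) != len(arrays[0]):
        raise ValueError(f"{len(arrays[0])} samples but {len(labels)} labels")
    has_val = val_samples is not None and val_labels is not None
    if has_val:
        val_arrays = _as_arrays(val_samples)
        val_labels = np.asarray(val_labels, dtype=np.int64)

    opt = Adam(model.params(), lr=config.learning_rate)
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 47]))
    history = TrainHistory()
    best_loss = np.inf
    best_state = None
    epochs_since_best = 0
    images, fx, fy = arrays
    n = len(labels)

    for epoch in range(config.max_epochs):
        order = rng.permutation(n) if config.shuffle else np.arange(n)
        epoch_losses, correct = [], 0
        for i in range(0, n, config.batch_size):
            idx = order[i : i + config.batch_size]
            logits = model.forward(images[idx], fx[idx], fy[idx], train=True)
            loss, dlogits = softmax_cross_entropy(logits, labels[idx])
            opt.zero_grad()
            model.backward(dlogits)
            opt.step()
            epoch_losses.append(loss * len(idx))
            correct += int((logits.argmax(axis=1) == labels[idx]).sum())
        history.train_loss.append(float(np.sum(epoch_losses) / n))
        history.train_acc.append(correct / n)

        if has_val:
            vloss, vacc = _eval_loss_acc(model, val_arrays, val_labels, config.batch_size)
            history.val_loss.append(vloss)
            history.val_acc.append(vacc)
            if vloss < best_loss - 1e-12:
                best_loss = vloss
                history.best_epoch = epoch
                best_state = ([p.value.copy() for p in model.params()],
                              model.bn.running_mean.copy(), model.bn.running_var.copy())
                epochs_since_best = 0
            else:
                epochs_since_best += 1
                if epochs_since_best >= config.patience:
                    history.stopped_early = True
                    break
        else:
            history.best_epoch = epoch

    if best_state is not None:
        values, rmean, rvar = best_state
        for p, v in zip(model.params(), values):
            p.value[...] = v
        model.bn.running_mean[...] = rmean
        model.bn.running_var[...] = rvar
    return history


# ---------------------------------------------------------------------------
# evaluation


@dataclass(frozen=True)
class EvalReport:
    """Confusion counts and the four standard indices (positive = grooming)."""

    tp: int
    fp: int
    tn: int
    fn: int

    @classmethod
    def from_predictions(cls, y_true, y_pred) -> "EvalReport":
        y_true = np.asarray(y_true, dtype=np.int64)
        y_pred = np.asarray(y_pred, dtype=np.int64)
        if y_true.shape != y_pred.shape:
            raise ValueError(
                f"label/prediction length mismatch: {y_true.shape} vs {y_pred.shape}")
        return cls(
            tp=int(np.sum((y_true == 1) & (y_pred == 1))),
            fp=int(np.sum((y_true == 0) & (y_pred == 1))),
            tn=int(np.sum((y_true == 0) & (y_pred == 0))),
            fn=int(np.sum((y_true == 1) & (y_pred == 0))),
        )

    @staticmethod
    def _ratio(num: int, den: int, name: str) -> float:
        if den == 0:
            warnings.warn(f"{name} undefined (zero denominator); reporting NaN",
                          stacklevel=3)
            return float("nan")
        return num / den

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.tn + self.fn

    @property
    def accuracy(self) -> float:
        return self._ratio(self.tp + self.tn, self.n, "accuracy")

    @property
    def sensitivity(self) -> float:
        return self._ratio(self.tp, self.tp + self.fn, "sensitivity")

    @property
    def specificity(self) -> float:
        return self._ratio(self.tn, self.tn + self.fp, "specificity")

    @property
    def precision(self) -> float:
        return self._ratio(self.tp, self.tp + self.fp, "precision")

    def as_dict(self) -> dict:
        return {
            "tp": self.tp, "fp": self.fp, "tn": self.tn, "fn": self.fn,
            "accuracy": self.accuracy, "sensitivity": self.sensitivity,
            "specificity": self.specificity, "precision": self.precision,
        }


def evaluate(model: MSRCModel, samples, labels, batch_size: int = 25) -> EvalReport:
    """Confusion-matrix evaluation of a trained model on labelled samples."""
    labels = np.asarray(labels, dtype=np.int64)
    images, fx, fy = _as_arrays(samples)
    preds = []
    for i in range(0, len(labels), batch_size):
        sl = slice(i, min(i + batch_size, len(labels)))
        preds.append(model.predict(images[sl], fx[sl], fy[sl]))
    return EvalReport.from_predictions(labels, np.concatenate(preds))


def aggregate_reports(reports: list[EvalReport]) -> dict:
    """Macro (mean of per-fold metrics) and micro (pooled counts) summaries."""
    if not reports:
        raise ValueError("no fold reports to aggregate")
    metrics = ("accuracy", "sensitivity", "specificity", "precision")
    macro = {m: float(np.mean([getattr(r, m) for r in reports])) for m in metrics}
    pooled = EvalReport(
        tp=sum(r.tp for r in reports), fp=sum(r.fp for r in reports),
        tn=sum(r.tn for r in reports), fn=sum(r.fn for r in reports))
    return {"macro": macro, "micro": pooled}
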