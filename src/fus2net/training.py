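"""Training harness: stratified k-fold cross-validation, optimizer
selection, and the batch-mode epoch loop with on-the-fly augmentation.

The published procedure trains with batch size 16 for a fixed budget of 53
epochs per fold under stratified ("hierarchical") tenfold cross-validation,
using one of Adam / RMSprop / SGD at default hyperparameters and a 2-class
softmax cross-entropy loss. Class balancing by flip oversampling is, by
default, performed inside each fold's training split only, so mirrored
copies of a held-out image can never leak into training; ``paper_mode=True``
reproduces the published order (balance once, before splitting).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from sklearn.model_selection import StratifiedKFold

from .arch import Fus2NetConfig, ModelHandle, build_fus2net
from .data import LabeledDataset
from .evaluation import EvalResult, evaluate_model
from .nn import OPTIMIZERS, Optimizer, softmax_cross_entropy
from .preprocess import AugmentConfig, as_batch, augment, balance_by_flip


@dataclass
class TrainConfig:
    optimizer: str = "adam"
    batch_size: int = 16
    epochs_per_fold: int = 53
    k_folds: int = 10
    use_augmentation: bool = True
    #: toggles dropout 0.5 + L2 0.05 together (off -> both zero)
    use_regularization: bool = True
    #: "per_fold" (default, leakage-safe), "paper" (balance before CV), "none"
    balance_mode: str = "per_fold"
    #: minority images to flip; "auto" = (majority - minority) // 2
    balance_n_select: int | str = "auto"
    augment_config: AugmentConfig = field(default_factory=AugmentConfig)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")
        if self.epochs_per_fold < 1:
            raise ValueError("epochs_per_fold must be >= 1")
        if self.k_folds < 2:
            raise ValueError("k_folds must be >= 2")
        if self.optimizer not in OPTIMIZERS:
            raise ValueError(
                f"unknown optimizer {self.optimizer!r}; choose from {sorted(OPTIMIZERS)}"
            )
        if self.balance_mode not in ("per_fold", "paper", "none"):
            raise ValueError("balance_mode must be per_fold | paper | none")


@dataclass
class FoldAssignment:
    """Fold index per sample; folds partition the dataset and preserve the
    global class proportions to within one sample per class per fold."""

    fold_index: np.ndarray
    k: int

    def test_indices(self, fold: int) -> np.ndarray:
        return np.flatnonzero(self.fold_index == fold)

    def train_indices(self, fold: int) -> np.ndarray:
        return np.flatnonzero(self.fold_index != fold)


@dataclass
class TrainHistory:
    train_loss: list[float] = field(default_factory=list)
    train_accuracy: list[float] = field(default_factory=list)
    val_loss: list[float] = field(default_factory=list)
    val_accuracy: list[float] = field(default_factory=list)


def stratified_kfold(labels, k: int, seed: int) -> FoldAssignment:
    """Deterministic stratified fold assignment (shuffled within classes)."""
    labels = np.asarray(labels)
    n = len(labels)
    if k > n:
        raise ValueError(f"k={k} exceeds n={n}")
    assignment = np.full(n, -1, dtype=np.int64)
    classes, counts = np.unique(labels, return_counts=True)
    if counts.min() >= k:
        skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
        for fold, (_, test_idx) in enumerate(skf.split(np.zeros(n), labels)):
            assignment[test_idx] = fold
    else:
        # degenerate classes (fewer members than folds): deal each class's
        # shuffled members round-robin, rotating the starting fold so fold
        # sizes stay within one of each other
        rng = np.random.default_rng(seed)
        offset = 0
        for cls in classes:
            idx = np.flatnonzero(labels == cls)
            rng.shuffle(idx)
            for i, j in enumerate(idx):
                assignment[j] = (offset + i) % k
            offset = (offset + len(idx)) % k
    return FoldAssignment(fold_index=assignment, k=k)


def reserve_holdout(
    dataset: LabeledDataset, n_per_class: int, seed: int
) -> tuple[LabeledDataset, LabeledDataset]:
    """Reserve ``n_per_class`` images of each class for final evaluation.

    Mirrors the clinical protocol of holding out 50 benign + 50 malignant
    images from the 1052-image collection, leaving 952 for training.
    Returns (training set, held-out set); selection is seeded and without
    replacement.
    """
    rng = np.random.default_rng(seed)
    held: set[int] = set()
    labels = [s.label for s in dataset]
    for lab in sorted(set(labels)):
        idx = [i for i, l in enumerate(labels) if l == lab]
        if len(idx) < n_per_class:
            raise ValueError(f"class {lab!r} has fewer than {n_per_class} samples")
        held.update(rng.choice(idx, size=n_per_class, replace=False).tolist())
    train_idx = [i for i in range(len(dataset)) if i not in held]
    return dataset.subset(train_idx), dataset.subset(sorted(held))


def make_optimizer(name: str) -> Optimizer:
    """Instantiate Adam / RMSprop / SGD with default hyperparameters."""
    try:
        cls = OPTIMIZERS[name.lower()]
    except KeyError:
        raise ValueError(
            f"unknown optimizer {name!r}; choose from {sorted(OPTIMIZERS)}"
        ) from None
    return cls()


def _epoch_pass(model, X, y, *, optimizer, batch_size, train, aug_cfg=None, rng=None,
                samples=None):
    """One pass over (X, y); updates weights when ``train`` is True."""
    net = model.network
    n = len(y)
    losses, correct = [], 0
    order = rng.permutation(n) if train else np.arange(n)
    for start in range(0, n, batch_size):
        idx = order[start : start + batch_size]
        if train and aug_cfg is not None and aug_cfg.enabled:
            batch = as_batch([augment(samples[i], aug_cfg, rng) for i in idx])
        elif samples is not None:
            batch = as_batch([samples[i] for i in idx])
        else:
            batch = X[idx]
        yb = y[idx]
        logits = net.forward(batch, training=train)
        loss, dlogits = softmax_cross_entropy(logits, yb)
        loss += net.l2_penalty()
        if train:
            net.backward(dlogits)
            optimizer.step(net.trainable_arrays())
        losses.append(loss * len(idx))
        correct += int(np.sum(np.argmax(logits, axis=1) == yb))
    return sum(losses) / n, correct / n


def train_fold(
    model: ModelHandle,
    train_split: LabeledDataset,
    val_split: LabeledDataset,
    cfg: TrainConfig,
    fold_seed: int | None = None,
) -> tuple[ModelHandle, TrainHistory]:
    """Run ``epochs_per_fold`` epochs of mini-batch optimization.

    Augmentation (when enabled) is drawn per batch on the training split
    only; validation images pass through resize + standardization untouched.
    """
    if len(train_split) == 0 or len(val_split) == 0:
        raise ValueError("train and validation splits must be non-empty")
    seed = cfg.seed if fold_seed is None else fold_seed
    rng = np.random.default_rng(seed)
    model.network.seed_dropout(seed)
    optimizer = make_optimizer(cfg.optimizer)
    y_train = train_split.labels_int()
    y_val = val_split.labels_int()
    X_val = as_batch(val_split.samples)
    aug = cfg.augment_config if cfg.use_augmentation else None
    history = TrainHistory()
    for _ in range(cfg.epochs_per_fold):
        tr_loss, tr_acc = _epoch_pass(
            model, None, y_train,
            optimizer=optimizer, batch_size=cfg.batch_size, train=True,
            aug_cfg=aug, rng=rng, samples=train_split.samples,
        )
        va_loss, va_acc = _epoch_pass(
            model, X_val, y_val,
            optimizer=optimizer, batch_size=cfg.batch_size, train=False,
        )
        history.train_loss.append(tr_loss)
        history.train_accuracy.append(tr_acc)
        history.val_loss.append(va_loss)
        history.val_accuracy.append(va_acc)
    return model, history


def _auto_n_select(ds: LabeledDataset) -> int:
    counts = ds.class_counts
    hi, lo = max(counts.values()), min(counts.values())
    return (hi - lo) // 2


def _arch_for(cfg: TrainConfig, arch_cfg: Fus2NetConfig, fold: int) -> Fus2NetConfig:
    kwargs = {"seed": arch_cfg.seed + 1000 * fold}
    if not cfg.use_regularization:
        kwargs.update(dropout_rate=0.0, l2_factor=0.0)
    return replace(arch_cfg, **kwargs)


@dataclass
class CrossValResult:
    fold_results: list[EvalResult]
    histories: list[TrainHistory]
    fold_assignment: FoldAssignment

    def mean_metrics(self) -> dict[str, float]:
        out = {}
        for key in ("accuracy", "sensitivity", "specificity", "precision", "auc"):
            vals = [getattr(r, key) for r in self.fold_results]
            out[key] = float(np.nanmean(vals))
        return out


def cross_validate(
    dataset: LabeledDataset,
    cfg: TrainConfig,
    arch_cfg: Fus2NetConfig | None = None,
) -> CrossValResult:
    """Stratified k-fold cross-validation with a fresh model per fold.

    ``dataset`` must already be resized/channel-converted to the network
    input geometry. Balancing follows ``cfg.balance_mode``; every sample is
    evaluated exactly once, on the fold where it is held out.
    """
    arch_cfg = arch_cfg or Fus2NetConfig()
    work = dataset
    if cfg.balance_mode == "paper":
        n_sel = _auto_n_select(work) if cfg.balance_n_select == "auto" else cfg.balance_n_select
        work = balance_by_flip(work, n_sel, np.random.default_rng(cfg.seed))
    labels = work.labels_int()
    folds = stratified_kfold(labels, cfg.k_folds, cfg.seed)
    fold_results, histories = [], []
    for fold in range(cfg.k_folds):
        train_ds = work.subset(folds.train_indices(fold))
        val_ds = work.subset(folds.test_indices(fold))
        if cfg.balance_mode == "per_fold":
            n_sel = (
                _auto_n_select(train_ds)
                if cfg.balance_n_select == "auto"
                else cfg.balance_n_select
            )
            if n_sel > 0:
                train_ds = balance_by_flip(
                    train_ds, n_sel, np.random.default_rng(cfg.seed + fold)
                )
        model = build_fus2net(_arch_for(cfg, arch_cfg, fold))
        model, history = train_fold(model, train_ds, val_ds, cfg,
                                    fold_seed=cfg.seed + fold)
        fold_results.append(evaluate_model(model, val_ds))
        histories.append(history)
    return CrossValResult(fold_results, histories, folds)
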