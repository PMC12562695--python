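"""Training recipe: combined cross-entropy + Dice loss, AdamW, early
stopping on validation Dice, and subject-grouped data splitting.

Subject grouping is the one non-negotiable piece of the protocol: repeat
scans of the same subject are strongly correlated, so all of a subject's
scans must live on the same side of every train/validation/test boundary.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from . import autograd as ag
from .errors import ConfigError, InsufficientDataError, ShapeError, TrainingDivergedError
from .net import Net3D2D, ProbMask
from .preprocess import NetInput
from .types import EnFaceMask, ScanRecord

__all__ = [
    "TrainConfig", "FoldAssignment",
    "dice_loss", "combined_loss", "make_grouped_folds", "split_train_val", "fit",
]

_EPS = 1e-6


@dataclass(frozen=True)
class TrainConfig:
    """Optimization hyperparameters.

    Defaults follow the clinical-scale recipe: 450 epochs, batch 32,
    patience 70, AdamW at learning rate 5e-5, equal cross-entropy and Dice
    weights. Reduced experiments override epochs/batch/learning rate.
    """

    epochs: int = 450
    batch_size: int = 32
    patience: int = 70
    learning_rate: float = 5e-5
    weight_decay: float = 1e-2
    loss_weights: tuple[float, float] = (1.0, 1.0)  # (w_ce, w_dice)
    val_fraction: float = 0.2
    #: global gradient-norm clip; guards against the occasional divergent
    #: trajectory at aggressive learning rates (0 disables)
    grad_clip_norm: float = 5.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not (1 <= self.patience <= self.epochs):
            raise ConfigError("patience must satisfy 1 <= patience <= epochs")
        w_ce, w_dice = self.loss_weights
        if w_ce < 0 or w_dice < 0 or w_ce + w_dice == 0:
            raise ConfigError("loss weights must be >= 0 and not both zero")
        if not (0.0 < self.val_fraction < 1.0):
            raise ConfigError("val_fraction must lie in (0, 1)")


@dataclass
class FoldAssignment:
    """Subject-grouped fold assignment: record_id -> fold index."""

    n_folds: int
    fold_of: dict[str, int]

    def records_in_fold(self, records: Sequence[ScanRecord], k: int) -> list[ScanRecord]:
        return [r for r in records if self.fold_of[r.record_id] == k]

    def records_not_in_fold(self, records: Sequence[ScanRecord], k: int) -> list[ScanRecord]:
        return [r for r in records if self.fold_of[r.record_id] != k]


def _grid_of(m) -> np.ndarray:
    if isinstance(m, (EnFaceMask, ProbMask)):
        return np.asarray(m.grid, np.float64)
    return np.asarray(m, np.float64)


def dice_loss(pred, target) -> float:
    """Soft Dice loss: 1 - (2*sum(p*t) + eps) / (sum(p) + sum(t) + eps)."""
    p, t = _grid_of(pred), _grid_of(target)
    if p.shape != t.shape:
        raise ShapeError(f"shape mismatch: {p.shape} vs {t.shape}")
    inter = float((p * t).sum())
    denom = float(p.sum() + t.sum())
    return 1.0 - (2.0 * inter + _EPS) / (denom + _EPS)


def combined_loss(pred, target, weights: tuple[float, float] = (1.0, 1.0)) -> float:
    """w_ce * mean binary cross-entropy + w_dice * Dice loss."""
    w_ce, w_dice = weights
    if w_ce < 0 or w_dice < 0 or w_ce + w_dice == 0:
        raise ConfigError("loss weights must be >= 0 and not both zero")
    p, t = _grid_of(pred), _grid_of(target)
    if p.shape != t.shape:
        raise ShapeError(f"shape mismatch: {p.shape} vs {t.shape}")
    pc = np.clip(p, 1e-7, 1.0 - 1e-7)
    ce = float(-(t * np.log(pc) + (1.0 - t) * np.log(1.0 - pc)).mean())
    return w_ce * ce + w_dice * dice_loss(pred, target)


def make_grouped_folds(records: Sequence[ScanRecord], n_folds: int,
                       seed: int) -> FoldAssignment:
    """Deal subjects into folds, keeping each subject's scans together.

    Subjects are shuffled by the seed, ordered by descending scan count
    (stable, so ties stay shuffled), then dealt round-robin — balancing
    scans per fold even when some subjects have many repeat visits.
    """
    by_subject: dict[str, list[ScanRecord]] = {}
    for r in records:
        by_subject.setdefault(r.subject_id, []).append(r)
    subjects = list(by_subject)
    if len(subjects) < n_folds:
        raise InsufficientDataError(
            f"{len(subjects)} subjects cannot fill {n_folds} folds"
        )
    rng = np.random.default_rng(seed)
    rng.shuffle(subjects)
    subjects.sort(key=lambda s: -len(by_subject[s]))  # stable sort
    fold_of: dict[str, int] = {}
    for i, s in enumerate(subjects):
        for r in by_subject[s]:
            fold_of[r.record_id] = i % n_folds
    return FoldAssignment(n_folds=n_folds, fold_of=fold_of)


def split_train_val(train_records: Sequence[ScanRecord], val_fraction: float,
                    seed: int) -> tuple[list[ScanRecord], list[ScanRecord]]:
    """Subject-granular train/validation split.

    Validation receives ceil(val_fraction * n_subjects) subjects; no subject
    spans both sides.
    """
    subjects = sorted({r.subject_id for r in train_records})
    if len(subjects) < 2:
        raise InsufficientDataError("need >= 2 subjects to split train/validation")
    n_val = math.ceil(val_fraction * len(subjects))
    if n_val >= len(subjects):
        raise InsufficientDataError("validation split would leave no training subjects")
    rng = np.random.default_rng(seed)
    rng.shuffle(subjects)
    val_set = set(subjects[:n_val])
    train = [r for r in train_records if r.subject_id not in val_set]
    val = [r for r in train_records if r.subject_id in val_set]
    return train, val


def _stack_batch(samples: Sequence[NetInput], use_nir: bool):
    vol = np.stack([s.volume for s in samples])[:, None]
    nir = np.stack([s.nir for s in samples])[:, None] if use_nir else None
    tgt = np.stack([np.asarray(s.target.grid, np.float32) for s in samples])
    return vol.astype(np.float32), nir, tgt


def _batch_loss(logits: ag.Tensor, targets: np.ndarray,
                weights: tuple[float, float]) -> ag.Tensor:
    """Autograd version of the combined loss, averaged over the batch."""
    w_ce, w_dice = weights
    terms = []
    if w_ce > 0:
        terms.append(ag.mul(ag.tmean(ag.bce_with_logits(logits, targets)),
                            ag.Tensor(np.float32(w_ce))))
    if w_dice > 0:
        p = ag.sigmoid(logits)
        t = targets.astype(np.float32)
        inter = ag.tsum(ag.mul(p, ag.Tensor(t)), axis=(1, 2))
        denom = ag.add(ag.tsum(p, axis=(1, 2)),
                       ag.Tensor(t.sum(axis=(1, 2))))
        dsc = ag.div(ag.add(ag.mul(inter, ag.Tensor(np.float32(2.0))),
                            ag.Tensor(np.float32(_EPS))),
                     ag.add(denom, ag.Tensor(np.float32(_EPS))))
        dice_l = ag.tmean(ag.sub(ag.Tensor(np.ones(dsc.shape, np.float32)), dsc))
        terms.append(ag.mul(dice_l, ag.Tensor(np.float32(w_dice))))
    total = terms[0]
    for t_ in terms[1:]:
        total = ag.add(total, t_)
    return total


def _mean_val_dsc(net: Net3D2D, val: Sequence[NetInput], use_nir: bool,
                  batch_size: int) -> float:
    from .evaluate import dsc as _dsc  # local import to avoid module cycle

    scores = []
    for i in range(0, len(val), batch_size):
        chunk = val[i:i + batch_size]
        vol, nir, tgt = _stack_batch(chunk, use_nir)
        logits = net.forward_batch(vol, nir)
        pred = (logits.data >= 0.0).astype(np.uint8)  # sigmoid(z) >= .5 <=> z >= 0
        for j in range(len(chunk)):
            scores.append(_dsc(EnFaceMask(grid=pred[j], binary=True),
                               EnFaceMask(grid=tgt[j].astype(np.uint8), binary=True)))
    return float(np.mean(scores))


def _clip_grad_norm(params, max_norm: float) -> None:
    total = 0.0
    for p in params:
        if p.grad is not None:
            total += float((p.grad.astype(np.float64) ** 2).sum())
    norm = math.sqrt(total)
    if norm > max_norm:
        scale = np.float32(max_norm / (norm + 1e-12))
        for p in params:
            if p.grad is not None:
                p.grad = p.grad * scale


def fit(net: Net3D2D, train: Sequence[NetInput], val: Sequence[NetInput],
        config: TrainConfig) -> tuple[Net3D2D, list[dict]]:
    """Optimize the network; returns it restored to the best-validation epoch.

    Per epoch: minibatch AdamW updates of the combined loss on ``train``,
    then mean Dice on ``val``. Stops when ``config.epochs`` are exhausted or
    validation Dice has not improved for ``config.patience`` consecutive
    epochs. The history has one row per epoch: epoch, train_loss, val_dsc.
    """
    if not train or not val:
        raise InsufficientDataError("fit requires non-empty train and val sets")
    use_nir = net.config.in_channels == 2
    rng = np.random.default_rng(config.seed)
    opt = ag.AdamW(net.parameters(), lr=config.learning_rate,
                   weight_decay=config.weight_decay)

    best_dsc = -np.inf
    best_state: Optional[dict[str, np.ndarray]] = None
    best_epoch = -1
    no_improve = 0
    history: list[dict] = []

    for epoch in range(config.epochs):
        order = rng.permutation(len(train))
        losses = []
        for i in range(0, len(train), config.batch_size):
            idx = order[i:i + config.batch_size]
            vol, nir, tgt = _stack_batch([train[j] for j in idx], use_nir)
            logits = net.forward_batch(vol, nir)
            loss = _batch_loss(logits, tgt, config.loss_weights)
            lv = float(loss.data)
            if not np.isfinite(lv):
                raise TrainingDivergedError(
                    f"non-finite loss {lv} at epoch {epoch}, step {i // config.batch_size}"
                )
            opt.zero_grad()
            loss.backward()
            if config.grad_clip_norm > 0:
                _clip_grad_norm(net.parameters(), config.grad_clip_norm)
            opt.step()
            losses.append(lv)
        val_dsc = _mean_val_dsc(net, val, use_nir, config.batch_size)
        history.append({"epoch": epoch, "train_loss": float(np.mean(losses)),
                        "val_dsc": val_dsc})
        if val_dsc > best_dsc:
            best_dsc = val_dsc
            best_state = {k: v.copy() for k, v in net.state_dict().items()}
            best_epoch = epoch
            no_improve = 0
        else:
            no_improve += 1
            if no_improve >= config.patience:
                break
    if best_state is not None:
        net.load_state_dict(best_state)
    for row in history:
        row["best_epoch"] = best_epoch
    return net, history
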