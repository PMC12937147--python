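"""Training protocol: weighted loss, case-level stratified splits, CV.

The optimisation recipe is Adam at 1e-4, batch size 16, class-imbalance
handling via inverse-class-frequency weights in the binary cross-entropy,
learning-rate reduction by 0.1 after a five-epoch validation-loss plateau,
and early stopping on validation loss (patience 10 epochs by default; the
plateau patience is part of the published recipe, the stopping patience is
this package's choice) up to 100 epochs.

All splitting is at the *case* level: a breast's CC and MLO views travel
inside one ``PairedSample``, and multiple samples sharing a case id are
kept in the same partition, so no view of a case can leak across splits.
"""

from __future__ import annotations

import copy
import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from sklearn.model_selection import StratifiedKFold

from .data import PairedSample
from .model import MammoFusionNet, ModelConfig, batch_from_samples
from .nn import Adam, autograd as ag
from .nn.autograd import Tensor

logger = logging.getLogger(__name__)

__all__ = ["TrainConfig", "class_weights", "weighted_bce",
           "stratified_case_split", "stratified_kfold", "train_model",
           "predict"]

EPS = 1e-7  # probability clamp for the log terms


@dataclass
class TrainConfig:
    initial_lr: float = 1e-4
    batch_size: int = 16
    max_epochs: int = 100
    lr_reduce_factor: float = 0.1
    lr_plateau_patience: int = 5
    early_stop_patience: int = 10
    split_fraction: float = 0.7
    n_folds: int = 5
    use_class_weights: bool = True
    seed: int = 0

    def __post_init__(self):
        if not (0.0 < self.split_fraction < 1.0):
            raise ValueError("split_fraction must lie in (0, 1)")
        if self.n_folds < 2:
            raise ValueError("n_folds must be >= 2")


def class_weights(labels: Sequence[int]) -> dict[int, float]:
    """Inverse-class-frequency weights, w_c = N / (2 * N_c).

    The minority class receives the larger weight, and the weighted mean of
    the per-sample weights is exactly 1.
    """
    labels = np.asarray(labels)
    counts = {c: int((labels == c).sum()) for c in (0, 1)}
    if min(counts.values()) == 0:
        raise ValueError(f"both classes must be present; got counts {counts}")
    n = labels.size
    return {c: n / (2.0 * nc) for c, nc in counts.items()}


def weighted_bce(y, y_hat, weights=None):
    """Weighted binary cross-entropy,
    -(1/N) sum_i w_{y_i} [y_i log(p_i) + (1 - y_i) log(1 - p_i)].

    ``weights`` maps class -> weight (or is a per-sample array); all-ones
    when omitted.  Accepts ``y_hat`` as a ``Tensor`` (differentiable path,
    used by the training loop) or a plain array (returns a float).
    Probabilities at exactly 0 or 1 are clamped to [EPS, 1 - EPS].
    """
    y_arr = np.asarray(y, dtype=np.float64).reshape(-1)
    if y_arr.size == 0:
        raise ValueError("empty batch")
    if weights is None:
        w = np.ones_like(y_arr)
    elif isinstance(weights, dict):
        w = np.array([weights[int(t)] for t in y_arr])
    else:
        w = np.asarray(weights, dtype=np.float64).reshape(-1)
    if isinstance(y_hat, Tensor):
        p = ag.clip(ag.reshape(y_hat, (-1,)), EPS, 1.0 - EPS)
        ll = ag.mul(Tensor(y_arr), ag.log(p)) + ag.mul(Tensor(1.0 - y_arr),
                                                       ag.log(1.0 - p))
        return ag.mul(ag.tmean(ag.mul(Tensor(w), ll)), -1.0)
    p = np.asarray(y_hat, dtype=np.float64).reshape(-1)
    if ((p <= 0) | (p >= 1)).any():
        logger.warning("weighted_bce: probabilities clamped to [%g, %g]", EPS, 1 - EPS)
        p = np.clip(p, EPS, 1.0 - EPS)
    return float(-(w * (y_arr * np.log(p) + (1 - y_arr) * np.log(1 - p))).mean())


# ---------------------------------------------------------------------------
# case-level splitting
# ---------------------------------------------------------------------------

def _case_groups(samples: Sequence[PairedSample]) -> tuple[list[str], dict[str, list[int]], list[int]]:
    """Group sample indices by case id; group label = max member label."""
    groups: dict[str, list[int]] = {}
    for i, s in enumerate(samples):
        groups.setdefault(s.case_id, []).append(i)
    case_ids = sorted(groups)
    case_labels = [max(samples[i].label for i in groups[cid]) for cid in case_ids]
    return case_ids, groups, case_labels


def stratified_case_split(samples: Sequence[PairedSample], fraction: float = 0.7,
                          seed: int = 0) -> tuple[list[PairedSample], list[PairedSample]]:
    """Stratified train/test split at the case level.

    Per class, ``floor(fraction * n_cases)`` cases go to training.  Samples
    sharing a case id always land in the same partition.  The returned
    samples carry ``partition`` tags ("train"/"test").
    """
    if not (0.0 < fraction < 1.0):
        raise ValueError("fraction must lie in (0, 1)")
    case_ids, groups, case_labels = _case_groups(samples)
    rng = np.random.default_rng(seed)
    train_idx: list[int] = []
    test_idx: list[int] = []
    for c in (0, 1):
        cls_cases = [cid for cid, lab in zip(case_ids, case_labels) if lab == c]
        if len(cls_cases) < 2:
            raise ValueError(f"class {c} has fewer than 2 cases ({len(cls_cases)})")
        order = rng.permutation(len(cls_cases))
        n_train = int(np.floor(fraction * len(cls_cases)))
        for rank, j in enumerate(order):
            target = train_idx if rank < n_train else test_idx
            target.extend(groups[cls_cases[j]])
    train = [samples[i] for i in sorted(train_idx)]
    test = [samples[i] for i in sorted(test_idx)]
    for s in train:
        s.partition = "train"
    for s in test:
        s.partition = "test"
    return train, test


def stratified_kfold(samples: Sequence[PairedSample], k: int = 5, seed: int = 0
                     ) -> list[tuple[list[PairedSample], list[PairedSample]]]:
    """Stratified k-fold at the case level (scikit-learn fold assignment).

    Validation folds partition the cases; per-fold class proportions are
    within one sample of the global proportions when each case contributes
    one sample.
    """
    case_ids, groups, case_labels = _case_groups(samples)
    counts = {c: case_labels.count(c) for c in (0, 1)}
    if min(counts.values()) < k:
        raise ValueError(f"each class needs >= {k} cases for {k}-fold CV; got {counts}")
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    folds = []
    for train_cases, val_cases in skf.split(case_ids, case_labels):
        train = [samples[i] for ci in train_cases for i in groups[case_ids[ci]]]
        val = [samples[i] for ci in val_cases for i in groups[case_ids[ci]]]
        folds.append((train, val))
    return folds


# ---------------------------------------------------------------------------
# optimisation loop
# ---------------------------------------------------------------------------

def predict(model: MammoFusionNet, samples: Sequence[PairedSample],
            batch_size: int = 16) -> np.ndarray:
    """Inference-mode malignancy probabilities for a list of samples."""
    model.eval()
    probs = []
    for i in range(0, len(samples), batch_size):
        cc, mlo, _ = batch_from_samples(samples[i:i + batch_size])
        probs.append(model(cc, mlo).data.reshape(-1))
    return np.concatenate(probs) if probs else np.empty(0)


def train_model(train_samples: Sequence[PairedSample],
                val_samples: Sequence[PairedSample],
                model_config: ModelConfig | None = None,
                train_config: TrainConfig | None = None,
                ) -> tuple[MammoFusionNet, list[dict]]:
    """Optimise the network on a (train, validation) sample split.

    Returns the model restored to its best-validation-loss weights plus a
    per-epoch log of train/validation loss, accuracy and learning rate.
    """
    mc = model_config or ModelConfig()
    tc = train_config or TrainConfig()
    model = MammoFusionNet(mc)
    opt = Adam(model.parameters(), lr=tc.initial_lr)
    rng = np.random.default_rng(tc.seed)

    y_train = [s.label for s in train_samples]
    weights = class_weights(y_train) if tc.use_class_weights else None

    cc_all, mlo_all, y_all = batch_from_samples(list(train_samples))
    best_loss, best_state, best_epoch = np.inf, None, -1
    plateau, stale, lr = 0, 0, tc.initial_lr
    log: list[dict] = []

    for epoch in range(tc.max_epochs):
        model.train()
        order = rng.permutation(len(train_samples))
        train_losses, hits, seen = [], 0, 0
        for i in range(0, len(order), tc.batch_size):
            idx = order[i:i + tc.batch_size]
            prob = model(cc_all[idx], mlo_all[idx])
            loss = weighted_bce(y_all[idx], prob, weights)
            if not np.isfinite(loss.data):
                raise RuntimeError(
                    f"non-finite training loss at epoch {epoch}, batch {i // tc.batch_size}")
            opt.zero_grad()
            loss.backward()
            opt.step()
            train_losses.append(float(loss.data))
            hits += int(((prob.data.reshape(-1) >= 0.5) == (y_all[idx] >= 0.5)).sum())
            seen += len(idx)

        val_prob = predict(model, val_samples, tc.batch_size)
        y_val = np.array([s.label for s in val_samples], dtype=np.float64)
        val_loss = weighted_bce(y_val, val_prob, weights)
        val_acc = float(((val_prob >= 0.5) == (y_val >= 0.5)).mean())
        log.append({"epoch": epoch, "train_loss": float(np.mean(train_losses)),
                    "val_loss": val_loss, "lr": lr,
                    "train_acc": hits / max(seen, 1), "val_acc": val_acc})

        if val_loss < best_loss - 1e-12:
            best_loss, best_epoch = val_loss, epoch
            best_state = copy.deepcopy(model.state_dict())
            plateau, stale = 0, 0
        else:
            plateau += 1
            stale += 1
            if plateau >= tc.lr_plateau_patience:
                lr *= tc.lr_reduce_factor
                opt.lr = lr
                plateau = 0
                logger.info("epoch %d: validation plateau, lr -> %g", epoch, lr)
            if stale >= tc.early_stop_patience:
                logger.info("epoch %d: early stop (best epoch %d)", epoch, best_epoch)
                break

    if best_state is not None:
        model.load_state_dict(best_state)
    model.eval()
    return model, log
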