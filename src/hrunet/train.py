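"""Training protocol: weighted Dice loss, Adam fine-tuning loop, k-fold
cross-validation split, and softmax-averaged ensemble prediction.

The loss (see :mod:`hrunet.nn.functional`) is the class-weighted Dice
loss with default weights (0.5, 0.5) for background and plaque.  The
optimizer is Adam with the study's settings: learning rate 1e-4,
beta1 0.9, beta2 0.999, epsilon 1e-8, batch size 4, 100 epochs.  Those
defaults describe fine-tuning a pretrained encoder; from-scratch smoke
runs typically pass a larger learning rate and far fewer steps.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .augment import AugmentedPair
from .model import HRUNet, ModelConfig, build_hrunet
from .nn import Adam, one_hot, softmax_dice_loss_grad, weighted_dice_loss

__all__ = ["TrainConfig", "FoldPlan", "dice_loss", "make_folds",
           "train_fold", "fit", "ensemble_predict", "ensemble_predict_mask"]


@dataclass(frozen=True)
class TrainConfig:
    lr: float = 1e-4
    beta1: float = 0.9
    beta2: float = 0.999
    epsilon: float = 1e-8
    epochs: int = 100
    batch_size: int = 4
    class_weights: tuple[float, float] = (0.5, 0.5)
    seed: int = 0
    folds: int = 10

    def __post_init__(self):
        if self.lr <= 0:
            raise ValueError("lr must be positive")
        if any(w < 0 for w in self.class_weights):
            raise ValueError("class_weights must be non-negative")
        if self.folds < 2:
            raise ValueError("folds must be >= 2")
        if self.epochs < 1 or self.batch_size < 1:
            raise ValueError("epochs and batch_size must be >= 1")


@dataclass(frozen=True)
class FoldPlan:
    fold_assignments: np.ndarray  # (n,) int fold index per sample
    k: int

    def test_indices(self, fold: int) -> np.ndarray:
        return np.flatnonzero(self.fold_assignments == fold)

    def train_indices(self, fold: int) -> np.ndarray:
        return np.flatnonzero(self.fold_assignments != fold)


def dice_loss(pred: np.ndarray, label_onehot: np.ndarray,
              weights=(0.5, 0.5)) -> float:
    """Weighted Dice loss between a softmax ProbMap and a one-hot label.

    Accepts single images (C, H, W) or batches (B, C, H, W); sums run
    over all pixels of each image and the batch is averaged.
    """
    pred = np.asarray(pred, dtype=np.float32)
    label_onehot = np.asarray(label_onehot, dtype=np.float32)
    if pred.ndim == 3:
        pred, label_onehot = pred[None], label_onehot[None]
    return weighted_dice_loss(pred, label_onehot, weights)


def make_folds(n: int, k: int, seed: int = 0) -> FoldPlan:
    """Deterministic shuffled partition into k folds of near-equal size."""
    if n < k:
        raise ValueError(f"need n >= k, got n={n}, k={k}")
    if k < 2:
        raise ValueError(f"k must be >= 2, got {k}")
    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    assign = np.empty(n, dtype=np.int64)
    # cyclic assignment over a shuffled order: fold sizes differ by <= 1
    assign[order] = np.arange(n) % k
    return FoldPlan(fold_assignments=assign, k=k)


def _stack_pairs(pairs: list[AugmentedPair]):
    images = np.stack([np.asarray(p.image, dtype=np.float32) for p in pairs])[:, None]
    labels = np.stack([np.asarray(p.label) for p in pairs]).astype(np.int64)
    return images, labels


def fit(model: HRUNet, pairs: list[AugmentedPair], config: TrainConfig,
        max_steps: int | None = None) -> list[float]:
    """Run the training loop; returns the per-epoch mean loss history.

    The pair pool is reshuffled every epoch with the run seed.  If
    ``max_steps`` is given, optimization stops after that many gradient
    steps (history then has one entry per completed or partial epoch).
    """
    if not pairs:
        raise ValueError("empty training set")
    images, labels = _stack_pairs(pairs)
    targets = one_hot(labels, n_classes=model.config.n_classes)
    opt = Adam(model.params(), lr=config.lr, beta1=config.beta1,
               beta2=config.beta2, eps=config.epsilon)
    rng = np.random.default_rng(config.seed)
    n = len(pairs)
    history: list[float] = []
    steps = 0
    for _epoch in range(config.epochs):
        order = rng.permutation(n)
        losses = []
        for start in range(0, n, config.batch_size):
            idx = order[start:start + config.batch_size]
            logits = model.forward(images[idx], training=True)
            loss, dlogits, _ = softmax_dice_loss_grad(
                logits, targets[idx], weights=config.class_weights)
            opt.zero_grad()
            model.backward(dlogits)
            opt.step()
            losses.append(loss)
            steps += 1
            if max_steps is not None and steps >= max_steps:
                history.append(float(np.mean(losses)))
                return history
        history.append(float(np.mean(losses)))
    return history


def train_fold(train_samples: list[AugmentedPair], config: TrainConfig,
               model_config: ModelConfig,
               max_steps: int | None = None) -> tuple[HRUNet, list[float]]:
    """Train one cross-validation fold on an already-augmented pool."""
    model = build_hrunet(model_config)
    history = fit(model, train_samples, config, max_steps=max_steps)
    return model, history


def ensemble_predict(models: list[HRUNet], image: np.ndarray) -> np.ndarray:
    """Per-pixel arithmetic mean of the k models' softmax outputs.

    The mean of normalized probability vectors is itself normalized, so
    the result is still a valid ProbMap; harden with ``argmax`` over the
    channel axis (see :func:`ensemble_predict_mask`).
    """
    if not models:
        raise ValueError("empty model list")
    acc = models[0].predict_proba(image)
    for m in models[1:]:
        acc = acc + m.predict_proba(image)
    return (acc / len(models)).astype(np.float32)


def ensemble_predict_mask(models: list[HRUNet], image: np.ndarray) -> np.ndarray:
    return ensemble_predict(models, image).argmax(axis=1).astype(np.uint8)
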