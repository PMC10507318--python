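"""Training protocol: alpha-weighted binary cross-entropy, fixed budget.

All models are trained with Adam (lr 1e-3, coupled weight decay 1e-3,
batch size 256) for ``8e4 / N`` epochs, which keeps the total number of
gradient steps near ``8e4 / 256 ~ 312`` regardless of the training-set
size N.  The loss reweights positive examples by ``(1 - alpha) / alpha``
where alpha is the positive ratio of the *observed* labels, so that
positive and negative examples contribute equally whatever the class
balance.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .models import ClassifierModel
from .nn import Adam
from .nn.autograd import Tensor
from .synthetic_data import Dataset, encode_dataset

LOSS_EPS = 1e-7


@dataclass
class TrainConfig:
    learning_rate: float = 1e-3
    weight_decay: float = 1e-3
    batch_size: int = 256
    seed: int = 0

    def __post_init__(self):
        if self.learning_rate <= 0 or self.weight_decay < 0:
            raise ValueError("rates must be positive")
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")


@dataclass
class TrainingRecord:
    epoch_losses: list[float] = field(default_factory=list)
    final_train_accuracy: float = float("nan")
    steps: int = 0
    seed: int = 0


def weighted_bce(y, t, alpha: float):
    """Class-rebalanced binary cross-entropy for one prediction or a batch.

    ``-[ ((1-alpha)/alpha) * t * log y + (1-t) * log(1-y) ]`` with scores
    clamped to ``[eps, 1-eps]`` (eps = 1e-7) so the loss stays finite.
    Accepts floats or arrays and returns the element-wise loss.
    """
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must be in (0, 1)")
    y = np.clip(np.asarray(y, dtype=float), LOSS_EPS, 1.0 - LOSS_EPS)
    t = np.asarray(t, dtype=float)
    w = (1.0 - alpha) / alpha
    return -(w * t * np.log(y) + (1.0 - t) * np.log1p(-y))


def _weighted_bce_tensor(y: Tensor, t: np.ndarray, alpha: float) -> Tensor:
    """Batch-mean loss on the autograd tape (same formula as weighted_bce)."""
    y = y.clip(LOSS_EPS, 1.0 - LOSS_EPS)
    w = (1.0 - alpha) / alpha
    t = t.astype(float)
    loss = -(w * t * y.log() + (1.0 - t) * (1.0 - y).log())
    return loss.mean()


def epochs_for(N: int) -> int:
    """Epoch count ``8e4 / N``, rounded half-up, floored at 1."""
    if N < 1:
        raise ValueError("N must be >= 1")
    return max(1, int(np.floor(8e4 / N + 0.5)))


def train(
    model: ClassifierModel,
    ds: Dataset,
    cfg: TrainConfig | None = None,
) -> tuple[ClassifierModel, TrainingRecord]:
    """Fit ``model`` on a training dataset under the fixed protocol.

    Deterministic given (model seed, dataset, cfg.seed).  Returns the
    model (trained in place) and a per-epoch loss trace.
    """
    if ds.role != "train":
        raise ValueError("can only train on a train-role dataset")
    cfg = cfg or TrainConfig()
    tokens, labels = encode_dataset(ds)
    alpha = ds.observed_alpha()
    if not 0.0 < alpha < 1.0:
        raise ValueError(
            "observed labels are single-class; the loss weight is undefined"
        )
    rng = np.random.default_rng(cfg.seed)
    model.train()
    model.set_rng(rng)
    opt = Adam(
        model.parameters(),
        lr=cfg.learning_rate,
        weight_decay=cfg.weight_decay,
    )
    record = TrainingRecord(seed=cfg.seed)
    n_epochs = epochs_for(ds.N)
    for _ in range(n_epochs):
        order = rng.permutation(ds.N)
        epoch_loss = 0.0
        n_batches = 0
        for start in range(0, ds.N, cfg.batch_size):
            idx = order[start : start + cfg.batch_size]
            opt.zero_grad()
            scores = model(tokens[idx])
            loss = _weighted_bce_tensor(scores, labels[idx], alpha)
            loss.backward()
            opt.step()
            epoch_loss += loss.item()
            n_batches += 1
            record.steps += 1
        record.epoch_losses.append(epoch_loss / n_batches)
    model.eval()
    preds = model.predict_scores(tokens) > 0.5
    record.final_train_accuracy = float((preds == labels).mean())
    return model, record
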