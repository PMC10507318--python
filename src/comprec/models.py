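"""The four small classifier families and their capacity ledger.

Every model embeds the token sequence (PAD, A, C, G, U) into learned
4-dimensional vectors (PAD frozen at zero), applies one characteristic
layer, and finishes with the shared two-layer head
``linear(U) - batchnorm - ReLU - dropout - linear(1) - sigmoid``:

* **MLP** — flatten, then ``linear(H) - batchnorm - ReLU - dropout``.
* **Att** — sinusoidal positional encoding added to the embeddings, a
  kernel-1 convolution projecting 4 -> H channels, then a residual
  multi-head self-attention block with H heads (head size 1):
  ``batchnorm(h1 + dropout(self_attention(h1)))``, flattened.
* **LSTM** — one bidirectional recurrent layer with H units per
  direction (no internal dropout); the per-position outputs (2H each)
  are flattened.
* **CNN** — outer concatenation of all position pairs (T x T x 8), a
  3x3 convolution with H feature maps, ``batchnorm - ReLU - dropout``,
  flattened.

Capacity is controlled by the (H, U) grid below; the headline quantity
is ``log10`` of the trainable-parameter count C.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np

from . import nn
from .nn.autograd import Tensor

FAMILIES = ("MLP", "Att", "LSTM", "CNN")
CAPACITY_LEVELS = (2.70, 3.00, 3.50, 4.15, 4.75, 5.50)

#: (H, U) per family and nominal log10 parameter-count level.
CAPACITY_TABLE: dict[str, dict[float, tuple[int, int]]] = {
    "MLP": {
        2.70: (5, 5),
        3.00: (10, 10),
        3.50: (30, 30),
        4.15: (80, 80),
        4.75: (200, 200),
        5.50: (500, 500),
    },
    "Att": {
        2.70: (2, 9),
        3.00: (4, 12),
        3.50: (6, 24),
        4.15: (12, 60),
        4.75: (24, 120),
        5.50: (80, 180),
    },
    "LSTM": {
        2.70: (2, 5),
        3.00: (3, 8),
        3.50: (4, 18),
        4.15: (10, 35),
        4.75: (16, 78),
        5.50: (48, 145),
    },
    "CNN": {
        2.70: (1, 1),
        3.00: (1, 2),
        3.50: (2, 4),
        4.15: (4, 9),
        4.75: (8, 16),
        5.50: (20, 36),
    },
}

EMBEDDING_DIM = 4
VOCAB_SIZE = 5  # PAD + 4 bases


class CapacityLookupError(KeyError):
    pass


def capacity_lookup(family: str, level: float) -> tuple[int, int]:
    """The (H, U) pair for a family at a nominal log10-C level."""
    try:
        return CAPACITY_TABLE[family][level]
    except KeyError:
        raise CapacityLookupError(
            f"no capacity entry for family={family!r}, level={level!r}"
        ) from None


@dataclass(frozen=True)
class ArchitectureSpec:
    family: str
    H: int
    U: int
    dropout_rate: float = 0.1
    input_length: int = 24
    embedding_dim: int = EMBEDDING_DIM

    def __post_init__(self):
        if self.family not in FAMILIES:
            raise ValueError(f"unknown family {self.family!r}")
        if self.H < 1 or self.U < 1:
            raise ValueError("H and U must be >= 1")

    @classmethod
    def from_level(
        cls, family: str, level: float, **kwargs
    ) -> "ArchitectureSpec":
        H, U = capacity_lookup(family, level)
        return cls(family=family, H=H, U=U, **kwargs)


class _Head(nn.Module):
    """Shared tail: linear(U) - batchnorm - ReLU - dropout - linear(1) - sigmoid."""

    def __init__(self, in_features: int, U: int, dropout: float, rng):
        self.fc1 = nn.Linear(in_features, U, rng)
        self.bn = nn.BatchNorm(U)
        self.drop = nn.Dropout(dropout)
        self.fc2 = nn.Linear(U, 1, rng)

    def forward(self, x: Tensor) -> Tensor:
        x = self.drop(self.bn(self.fc1(x)).relu())
        return self.fc2(x).sigmoid().reshape(x.shape[0])


class ClassifierModel(nn.Module):
    """Base class: tokens (B, T) -> positivity scores in (0, 1)."""

    def __init__(self, spec: ArchitectureSpec, seed: int):
        self.spec = spec
        self.seed = seed
        rng = np.random.default_rng(seed)
        self.embedding = nn.Embedding(VOCAB_SIZE, spec.embedding_dim, rng)
        self._build(spec, rng)

    def _build(self, spec, rng):  # pragma: no cover - abstract
        raise NotImplementedError

    def _features(self, x: Tensor) -> Tensor:  # pragma: no cover - abstract
        raise NotImplementedError

    def forward(self, tokens: np.ndarray) -> Tensor:
        if tokens.ndim != 2 or tokens.shape[1] != self.spec.input_length:
            raise ValueError(
                f"expected tokens of shape (B, {self.spec.input_length}), "
                f"got {tokens.shape}"
            )
        return self.head(self._features(self.embedding(tokens)))

    def predict_scores(self, tokens: np.ndarray, batch_size: int = 4096) -> np.ndarray:
        """Deterministic evaluation-mode scores, computed in batches."""
        was_training = self.training
        self.eval()
        out = []
        with nn.no_grad():
            for start in range(0, tokens.shape[0], batch_size):
                out.append(self.forward(tokens[start : start + batch_size]).data)
        if was_training:
            self.train()
        return np.concatenate(out) if out else np.empty(0)


class MLPModel(ClassifierModel):
    def _build(self, spec, rng):
        d_in = spec.input_length * spec.embedding_dim
        self.fc = nn.Linear(d_in, spec.H, rng)
        self.bn = nn.BatchNorm(spec.H)
        self.drop = nn.Dropout(spec.dropout_rate)
        self.head = _Head(spec.H, spec.U, spec.dropout_rate, rng)

    def _features(self, x: Tensor) -> Tensor:
        B = x.shape[0]
        x = x.reshape(B, self.spec.input_length * self.spec.embedding_dim)
        return self.drop(self.bn(self.fc(x)).relu())


class AttModel(ClassifierModel):
    def _build(self, spec, rng):
        self.pos_enc = nn.sinusoidal_positional_encoding(
            spec.input_length, spec.embedding_dim
        )
        self.proj = nn.Linear(spec.embedding_dim, spec.H, rng)  # conv, kernel 1
        self.attn = nn.MultiHeadSelfAttention(spec.H, spec.H, rng)
        self.drop = nn.Dropout(spec.dropout_rate)
        self.bn = nn.BatchNorm(spec.H)
        self.head = _Head(spec.input_length * spec.H, spec.U, spec.dropout_rate, rng)

    def _features(self, x: Tensor) -> Tensor:
        h1 = self.proj(x + self.pos_enc)
        h2 = self.bn(h1 + self.drop(self.attn(h1)))
        return h2.reshape(x.shape[0], self.spec.input_length * self.spec.H)


class LSTMModel(ClassifierModel):
    def _build(self, spec, rng):
        self.lstm = nn.BiLSTM(spec.embedding_dim, spec.H, rng)
        self.head = _Head(
            spec.input_length * 2 * spec.H, spec.U, spec.dropout_rate, rng
        )

    def _features(self, x: Tensor) -> Tensor:
        out = self.lstm(x)
        return out.reshape(x.shape[0], self.spec.input_length * 2 * self.spec.H)


class CNNModel(ClassifierModel):
    def _build(self, spec, rng):
        self.conv = nn.Conv3x3(2 * spec.embedding_dim, spec.H, rng)
        self.bn = nn.BatchNorm(spec.H)
        self.drop = nn.Dropout(spec.dropout_rate)
        self.head = _Head(
            spec.input_length**2 * spec.H, spec.U, spec.dropout_rate, rng
        )

    def _features(self, x: Tensor) -> Tensor:
        B, T, D = x.shape
        # outer concatenation: (i, j) cell holds [enc(i), enc(j)], T x T x 2D
        rows = x.reshape(B, T, 1, D) + Tensor(np.zeros((B, T, T, D)))
        cols = x.reshape(B, 1, T, D) + Tensor(np.zeros((B, T, T, D)))
        outer = nn.concat([rows, cols], axis=-1)
        h = self.drop(self.bn(self.conv(outer)).relu())
        return h.reshape(B, T * T * self.spec.H)


_MODEL_CLASSES = {
    "MLP": MLPModel,
    "Att": AttModel,
    "LSTM": LSTMModel,
    "CNN": CNNModel,
}


def build_model(spec: ArchitectureSpec, seed: int = 0) -> ClassifierModel:
    """Construct a freshly initialized classifier for a spec."""
    return _MODEL_CLASSES[spec.family](spec, seed)


def count_parameters(model: ClassifierModel) -> int:
    """Trainable parameters, excluding the frozen PAD embedding row."""
    total = sum(p.data.size for p in model.parameters())
    return total - EMBEDDING_DIM  # the PAD row never trains


def log10_capacity(model: ClassifierModel) -> float:
    return math.log10(count_parameters(model))


def save_checkpoint(model: ClassifierModel, path: str | Path) -> None:
    arrays = {
        f"param_{i}": p.data for i, p in enumerate(model.parameters())
    }
    bn_state = {}
    for i, m in enumerate(model.modules()):
        if isinstance(m, nn.BatchNorm):
            bn_state[f"bn_{i}_mean"] = m.running_mean
            bn_state[f"bn_{i}_var"] = m.running_var
    np.savez(
        path,
        spec=np.array(list(asdict(model.spec).items()), dtype=object),
        seed=model.seed,
        **arrays,
        **bn_state,
    )


def load_checkpoint(path: str | Path) -> ClassifierModel:
    data = np.load(path, allow_pickle=True)
    raw = dict(data["spec"])
    spec = ArchitectureSpec(
        family=str(raw["family"]),
        H=int(raw["H"]),
        U=int(raw["U"]),
        dropout_rate=float(raw["dropout_rate"]),
        input_length=int(raw["input_length"]),
        embedding_dim=int(raw["embedding_dim"]),
    )
    model = build_model(spec, seed=int(data["seed"]))
    for i, p in enumerate(model.parameters()):
        p.data = data[f"param_{i}"]
    for i, m in enumerate(model.modules()):
        if isinstance(m, nn.BatchNorm):
            m.running_mean = data[f"bn_{i}_mean"]
            m.running_var = data[f"bn_{i}_var"]
    return model
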