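"""Accuracy at a threshold, the exact oracle, simulations and probes.

Accuracy of a scoring function f on a dataset D with threshold theta is

    A(f, D, theta) = (1/N) sum_i [ t_i 1{f(x_i) > theta}
                                   + (1 - t_i) 1{f(x_i) <= theta} ]

measured against the *observed* labels (so an oracle scored on a
mislabelled training set lands at 1 - mu in expectation).  Ties at the
threshold count as predicted negative.  Headline numbers are means over
repeated simulations, each of which draws a fresh partition, fresh
datasets and a fresh model from its repetition seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .models import ArchitectureSpec, ClassifierModel, build_model
from .synthetic_data import (
    Dataset,
    HairpinExample,
    complement_base,
    enumerate_strands,
    encode_dataset,
    full_balanced_dataset,
    generate_dataset,
    is_complementary,
    make_example,
    partition_sequence_space,
)
from .training import TrainConfig, TrainingRecord, train

DEFAULT_THETA = 0.5


@dataclass(frozen=True)
class AccuracyResult:
    accuracy: float
    theta: float
    n_examples: int
    role: str

    @property
    def n_correct(self) -> int:
        return int(round(self.accuracy * self.n_examples))


def oracle_classifier(e: HairpinExample) -> int:
    """Ground-truth label by brute-force Watson-Crick check of every pair."""
    return int(is_complementary(e.s, e.s_bar))


class OracleModel:
    """The exact complementarity check wrapped as a scoring function.

    Scores are 1 - eps / eps so any threshold in (0, 1) reproduces the
    hard oracle decision.  Used to validate the accuracy bookkeeping and
    as the reference every trained model is compared to.
    """

    def __init__(self, ds: Dataset):
        self._scores = np.array(
            [0.999999 if oracle_classifier(e) else 1e-6 for e in ds.examples]
        )

    def predict_scores(self, tokens: np.ndarray, batch_size: int = 0) -> np.ndarray:
        return self._scores


def accuracy(model, ds: Dataset, theta: float = DEFAULT_THETA) -> AccuracyResult:
    """Thresholded accuracy of any scorer exposing ``predict_scores``."""
    if ds.N == 0:
        raise ValueError("empty dataset")
    if not 0.0 < theta < 1.0:
        raise ValueError("theta must be in (0, 1)")
    if isinstance(model, OracleModel):
        scores = model.predict_scores(np.empty(0))
    else:
        tokens, _ = encode_dataset(ds)
        scores = model.predict_scores(tokens)
    t = ds.observed_labels()
    pred_pos = scores > theta
    correct = np.where(t == 1, pred_pos, ~pred_pos)
    return AccuracyResult(
        accuracy=float(correct.mean()),
        theta=theta,
        n_examples=ds.N,
        role=ds.role,
    )


# ---------------------------------------------------------------------------
# Simulations


@dataclass(frozen=True)
class GenParams:
    """Dataset-generation coordinates for one experiment cell."""

    L_train: int
    N: int
    alpha: float = 0.5
    mu: float = 0.0
    L_test: int | None = None  # defaults to L_train
    loop_length: int = 4
    train_fraction: float = 0.5
    test_size: int = 10_000  # within-length test-set size
    full_test_set: bool | None = None  # default: full set iff extrapolating

    @property
    def test_length(self) -> int:
        return self.L_test if self.L_test is not None else self.L_train

    @property
    def use_full_test(self) -> bool:
        if self.full_test_set is not None:
            return self.full_test_set
        return self.test_length != self.L_train


def _child_seeds(rep_seed: int, n: int) -> list[int]:
    state = np.random.SeedSequence(rep_seed).generate_state(n)
    return [int(s) & 0x7FFFFFFF for s in state]


def build_simulation_data(
    gp: GenParams, rep_seed: int
) -> tuple[Dataset, Dataset]:
    """Fresh train/test datasets for one repetition.

    Within-length runs share one disjoint partition of the 4^L space;
    extrapolation runs evaluate on the balanced set built from all
    strands of the test length (which never overlap the shorter training
    strands).
    """
    part_seed, train_seed, test_seed = _child_seeds(rep_seed, 3)
    if gp.use_full_test:
        if gp.test_length == gp.L_train:
            pool = partition_sequence_space(
                gp.L_train, part_seed, gp.train_fraction
            )
            train_pool, test_pool = pool.train_pool, pool.test_pool
        else:
            train_pool = tuple(enumerate_strands(gp.L_train))
            test_pool = tuple(enumerate_strands(gp.test_length))
        test_ds = full_balanced_dataset(test_pool, gp.loop_length, test_seed)
    else:
        pool = partition_sequence_space(
            gp.L_train, part_seed, gp.train_fraction
        )
        train_pool, test_pool = pool.train_pool, pool.test_pool
        test_ds = generate_dataset(
            test_pool,
            gp.test_size,
            0.5,
            0.0,
            gp.loop_length,
            role="test",
            seed=test_seed,
        )
    train_ds = generate_dataset(
        train_pool,
        gp.N,
        gp.alpha,
        gp.mu,
        gp.loop_length,
        role="train",
        seed=train_seed,
    )
    return train_ds, test_ds


def run_simulation(
    family: str,
    level: float,
    gp: GenParams,
    rep_seed: int,
    theta: float = DEFAULT_THETA,
    return_model: bool = False,
):
    """One full repetition: partition -> datasets -> model -> train -> score."""
    _, _, _, model_seed, opt_seed = _child_seeds(rep_seed, 5)
    train_ds, test_ds = build_simulation_data(gp, rep_seed)
    input_length = 20 + gp.loop_length
    spec = ArchitectureSpec.from_level(family, level, input_length=input_length)
    model = build_model(spec, seed=model_seed)
    model, record = train(model, train_ds, TrainConfig(seed=opt_seed))
    train_acc = accuracy(model, train_ds, theta)
    test_acc = accuracy(model, test_ds, theta)
    if return_model:
        return train_acc, test_acc, model, record
    return train_acc, test_acc


@dataclass
class SimulationSummary:
    """Aggregated train/test accuracies over repetitions of one cell."""

    train_accuracies: list[float]
    test_accuracies: list[float]
    coordinates: dict = field(default_factory=dict)

    @property
    def repetitions(self) -> int:
        return len(self.test_accuracies)

    def _stats(self, values: Sequence[float]) -> dict[str, float]:
        arr = np.asarray(values, dtype=float)
        return {
            "mean": float(arr.mean()),
            "sd": float(arr.std(ddof=1)) if arr.size > 1 else 0.0,
            "min": float(arr.min()),
            "max": float(arr.max()),
        }

    @property
    def train(self) -> dict[str, float]:
        return self._stats(self.train_accuracies)

    @property
    def test(self) -> dict[str, float]:
        return self._stats(self.test_accuracies)


def summarize_simulations(
    family: str,
    level: float,
    gp: GenParams,
    repetitions: int,
    base_seed: int,
    theta: float = DEFAULT_THETA,
) -> SimulationSummary:
    """Repeat a simulation cell; repetition r uses seed base_seed + r."""
    train_accs, test_accs = [], []
    for r in range(repetitions):
        tr, te = run_simulation(family, level, gp, base_seed + r, theta)
        train_accs.append(tr.accuracy)
        test_accs.append(te.accuracy)
    return SimulationSummary(
        train_accuracies=train_accs,
        test_accuracies=test_accs,
        coordinates={
            "family": family,
            "level": level,
            "N": gp.N,
            "L_train": gp.L_train,
            "L_test": gp.test_length,
            "alpha": gp.alpha,
            "mu": gp.mu,
            "base_seed": base_seed,
        },
    )


# ---------------------------------------------------------------------------
# Positivity-score probes


def mismatch_pairs(example: HairpinExample, pairs: Sequence[int]) -> HairpinExample:
    """Break the given base pairs of a positive example.

    Pair position p is counted from the apical loop outward, so pair 1 is
    ``s_L . s_bar_1``.  Each targeted ``s_bar`` base is replaced by its
    own Watson-Crick complement, which can never pair with the original
    partner, so the substitution is guaranteed to break the pair.
    """
    s_bar = list(example.s_bar)
    for p in pairs:
        if not 1 <= p <= len(s_bar):
            raise ValueError(f"pair position {p} outside [1, {len(s_bar)}]")
        s_bar[p - 1] = complement_base(s_bar[p - 1])
    mutated = "".join(s_bar)
    label = int(is_complementary(example.s, mutated))
    return HairpinExample(
        s=example.s,
        loop=example.loop,
        s_bar=mutated,
        true_label=label,
        observed_label=label,
    )


def default_probe_triple() -> list[HairpinExample]:
    """The canonical length-8 probes: the positive ACGUACGU hairpin and its
    two 3-mismatch variants (pairs 6-8 next to the open end; pairs 2-4
    next to the loop)."""
    s = "ACGUACGU"
    positive = HairpinExample(
        s=s, loop="GAAA", s_bar="ACGUACGU", true_label=1, observed_label=1
    )
    upper = mismatch_pairs(positive, [6, 7, 8])
    lower = mismatch_pairs(positive, [2, 3, 4])
    return [positive, upper, lower]


@dataclass
class ProbeResult:
    probes: list[HairpinExample]
    scores: np.ndarray  # (n_models, n_probes)
    theta: float = DEFAULT_THETA

    def mean_scores(self) -> np.ndarray:
        return self.scores.mean(axis=0)


def probe_scores(
    models: Sequence[ClassifierModel],
    probes: Sequence[HairpinExample] | None = None,
    theta: float = DEFAULT_THETA,
) -> ProbeResult:
    """Score each probe sequence with each trained model."""
    probes = list(probes) if probes is not None else default_probe_triple()
    ds = Dataset(
        examples=list(probes),
        L=probes[0].L,
        alpha=float(np.mean([p.true_label for p in probes])),
        mu=0.0,
        role="test",
        loop_length=len(probes[0].loop),
        seed=-1,
    )
    tokens, _ = encode_dataset(ds)
    scores = np.stack([m.predict_scores(tokens) for m in models])
    return ProbeResult(probes=list(probes), scores=scores, theta=theta)
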