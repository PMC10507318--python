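"""Synthetic hairpin datasets for learning Watson-Crick complementarity.

Each example is a hairpin-shaped sequence over the RNA alphabet
``{A, C, G, U}``: a strand ``s`` of length ``L <= 10``, a random apical
loop (default 4 nt), and a second strand ``s_bar`` of the same length.
The example is positive when ``s_bar`` is the exact complement ``s*`` of
``s`` (every position ``i`` of ``s`` Watson-Crick pairs with position
``L + 1 - i`` of ``s_bar``), negative otherwise.

Datasets are drawn from a disjoint train/test partition of the full
``4^L`` strand space so that no ``s`` is shared between roles.  Training
sets support a controllable positive ratio ``alpha`` and an independent
label-flip probability ``mu``; test sets are always balanced and
correctly labelled.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

ALPHABET = ("A", "C", "G", "U")
COMPLEMENT = {"A": "U", "U": "A", "C": "G", "G": "C"}
MAX_STRAND_LENGTH = 10
DEFAULT_LOOP_LENGTH = 4

#: Fixed token ids used by every model and featurizer.
TOKEN_IDS = {"PAD": 0, "A": 1, "C": 2, "G": 3, "U": 4}

_BASE_TO_ID = np.zeros(128, dtype=np.int64)
for _b, _i in TOKEN_IDS.items():
    if _b != "PAD":
        _BASE_TO_ID[ord(_b)] = _i


class InvalidAlphabetError(ValueError):
    """A symbol outside {A, C, G, U} was supplied."""


def validate_strand(s: str, max_length: int = MAX_STRAND_LENGTH) -> str:
    if not 1 <= len(s) <= max_length:
        raise ValueError(
            f"strand length {len(s)} outside [1, {max_length}]: {s!r}"
        )
    for b in s:
        if b not in COMPLEMENT:
            raise InvalidAlphabetError(f"symbol {b!r} not in {ALPHABET}")
    return s


def complement_base(b: str) -> str:
    """Watson-Crick partner of one base: A<->U, C<->G."""
    try:
        return COMPLEMENT[b]
    except KeyError:
        raise InvalidAlphabetError(f"symbol {b!r} not in {ALPHABET}") from None


def exact_complement(s: str) -> str:
    """The unique strand ``s*`` fully complementary to ``s``.

    Both strands are read 5'->3', so ``s*`` is the reverse of the
    base-wise complement: ``s_i = c(s*_{L+1-i})`` for every position.
    """
    validate_strand(s)
    return "".join(COMPLEMENT[b] for b in reversed(s))


def is_complementary(s: str, s_bar: str) -> bool:
    """Exhaustive base-by-base Watson-Crick check of ``s`` against ``s_bar``."""
    if len(s) != len(s_bar):
        raise ValueError("strands of unequal length cannot be fully paired")
    return all(
        s[i] == COMPLEMENT[s_bar[len(s) - 1 - i]] for i in range(len(s))
    )


def enumerate_strands(L: int) -> list[str]:
    """All ``4^L`` strands of length ``L``, lexicographic in (A, C, G, U)."""
    if not 1 <= L <= MAX_STRAND_LENGTH:
        raise ValueError(f"L={L} outside [1, {MAX_STRAND_LENGTH}]")
    return ["".join(p) for p in itertools.product(ALPHABET, repeat=L)]


def _random_strand(L: int, rng: np.random.Generator) -> str:
    return "".join(ALPHABET[i] for i in rng.integers(0, 4, size=L))


@dataclass(frozen=True)
class HairpinExample:
    """One labelled hairpin: strand, apical loop, opposite strand."""

    s: str
    loop: str
    s_bar: str
    true_label: int
    observed_label: int

    def __post_init__(self):
        if len(self.s) != len(self.s_bar):
            raise ValueError("|s| != |s_bar|")

    @property
    def L(self) -> int:
        return len(self.s)

    @property
    def is_mislabelled(self) -> bool:
        return self.observed_label != self.true_label

    @property
    def sequence(self) -> str:
        """Concatenated 5'->3' hairpin sequence (no padding symbols)."""
        return self.s + self.loop + self.s_bar


@dataclass(frozen=True)
class SequencePartition:
    """Disjoint split of the full 4^L strand space into train/test pools."""

    L: int
    train_pool: tuple[str, ...]
    test_pool: tuple[str, ...]
    seed: int

    def __post_init__(self):
        if set(self.train_pool) & set(self.test_pool):
            raise ValueError("train and test pools intersect")


@dataclass
class Dataset:
    """A labelled example collection with its generation metadata.

    ``alpha`` is the positive ratio by *true* label at construction time;
    under ``mu > 0`` the observed positive fraction drifts away from it.
    """

    examples: list[HairpinExample]
    L: int
    alpha: float
    mu: float
    role: str
    loop_length: int
    seed: int

    @property
    def N(self) -> int:
        return len(self.examples)

    def true_labels(self) -> np.ndarray:
        return np.array([e.true_label for e in self.examples], dtype=np.int64)

    def observed_labels(self) -> np.ndarray:
        return np.array(
            [e.observed_label for e in self.examples], dtype=np.int64
        )

    def observed_alpha(self) -> float:
        """Positive ratio computed from observed labels (the loss-weight alpha)."""
        return float(self.observed_labels().mean())


def partition_sequence_space(
    L: int, seed: int, train_fraction: float = 0.5
) -> SequencePartition:
    """Randomly split all 4^L strands into disjoint train/test pools.

    A shuffled exact split is used so pool sizes are deterministic:
    ``round(train_fraction * 4^L)`` strands go to the train pool.
    """
    if not 0.0 < train_fraction < 1.0:
        raise ValueError("train_fraction must be in (0, 1)")
    strands = enumerate_strands(L)
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(strands))
    n_train = int(round(train_fraction * len(strands)))
    n_train = min(max(n_train, 1), len(strands) - 1)
    train = tuple(strands[i] for i in order[:n_train])
    test = tuple(strands[i] for i in order[n_train:])
    return SequencePartition(L=L, train_pool=train, test_pool=test, seed=seed)


def make_example(
    s: str,
    loop_length: int,
    positive: bool,
    rng: np.random.Generator,
) -> HairpinExample:
    """Build one example: uniform random loop; ``s_bar = s*`` if positive,
    otherwise uniform over the ``4^L - 1`` strands different from ``s*``."""
    if not 3 <= loop_length <= 7:
        raise ValueError("loop_length must be in [3, 7]")
    validate_strand(s)
    loop = _random_strand(loop_length, rng)
    s_star = exact_complement(s)
    if positive:
        s_bar = s_star
    else:
        # rejection sampling over Sigma^L \ {s*}; acceptance >= 1 - 4^-L
        while True:
            s_bar = _random_strand(len(s), rng)
            if s_bar != s_star:
                break
    label = int(positive)
    return HairpinExample(
        s=s, loop=loop, s_bar=s_bar, true_label=label, observed_label=label
    )


def apply_mislabelling(
    ds: Dataset, mu: float, rng: np.random.Generator
) -> Dataset:
    """Flip each observed label independently with probability ``mu``.

    Only training sets may be corrupted; test sets are correctly labelled
    by contract.
    """
    if ds.role != "train":
        raise ValueError("mislabelling applies to train datasets only")
    if not 0.0 <= mu <= 0.5:
        raise ValueError("mu must be in [0, 1/2]")
    flips = rng.random(ds.N) < mu
    examples = [
        replace(e, observed_label=1 - e.observed_label) if f else e
        for e, f in zip(ds.examples, flips)
    ]
    return replace(ds, examples=examples, mu=mu)


def generate_dataset(
    pool: Sequence[str],
    N: int,
    alpha: float,
    mu: float,
    loop_length: int = DEFAULT_LOOP_LENGTH,
    role: str = "train",
    seed: int = 0,
) -> Dataset:
    """Draw a labelled dataset whose ``s`` values come from ``pool``.

    Train role: ``round(alpha * N)`` positives, then independent label
    flips with probability ``mu``.  Test role: ``alpha`` is forced to 1/2,
    ``mu`` to 0, and exactly ``N/2`` positives and ``N/2`` negatives are
    produced.  Strands are drawn uniformly with replacement, so ``N`` may
    exceed the pool size.
    """
    if len(pool) == 0:
        raise ValueError("empty strand pool")
    if role not in ("train", "test"):
        raise ValueError(f"unknown role {role!r}")
    rng = np.random.default_rng(seed)
    L = len(pool[0])

    if role == "test":
        if mu not in (0, 0.0):
            raise ValueError("test datasets must have mu = 0")
        if N % 2:
            raise ValueError("test datasets need even N for exact balance")
        n_pos = N // 2
        alpha = 0.5
    else:
        if not 0.0 < alpha < 1.0:
            raise ValueError("alpha must be in (0, 1)")
        n_pos = int(round(alpha * N))

    pool = list(pool)
    idx = rng.integers(0, len(pool), size=N)
    positives = np.zeros(N, dtype=bool)
    positives[:n_pos] = True  # draws are i.i.d., so order carries no bias
    examples = [
        make_example(pool[i], loop_length, bool(p), rng)
        for i, p in zip(idx, positives)
    ]
    ds = Dataset(
        examples=examples,
        L=L,
        alpha=n_pos / N,
        mu=0.0,
        role=role,
        loop_length=loop_length,
        seed=seed,
    )
    if role == "train" and mu > 0:
        ds = apply_mislabelling(ds, mu, rng)
    return ds


def full_balanced_dataset(
    pool: Iterable[str],
    loop_length: int = DEFAULT_LOOP_LENGTH,
    seed: int = 0,
) -> Dataset:
    """One positive and one negative example per strand in ``pool``.

    Used for full-space evaluations, e.g. the balanced set built from all
    4^8 sequences of length 8 in the extrapolation experiments.
    """
    pool = list(pool)
    if not pool:
        raise ValueError("empty strand pool")
    rng = np.random.default_rng(seed)
    loop_length = int(loop_length)
    examples: list[HairpinExample] = []
    for s in pool:
        examples.append(make_example(s, loop_length, True, rng))
        examples.append(make_example(s, loop_length, False, rng))
    return Dataset(
        examples=examples,
        L=len(pool[0]),
        alpha=0.5,
        mu=0.0,
        role="test",
        loop_length=loop_length,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# Fixed-size token encoding


def encode(
    example: HairpinExample, max_strand_length: int = MAX_STRAND_LENGTH
) -> np.ndarray:
    """Token layout ``PAD^{m-L} s a s_bar PAD^{m-L}`` with m = max length.

    Total length is ``2 m + loop_length`` (24 with the defaults); the PAD
    id is 0 and bases map to A=1, C=2, G=3, U=4.
    """
    L = example.L
    if L > max_strand_length:
        raise ValueError(f"L={L} exceeds max_strand_length={max_strand_length}")
    pad = np.zeros(max_strand_length - L, dtype=np.int64)
    mid = _BASE_TO_ID[np.frombuffer(example.sequence.encode(), dtype=np.uint8)]
    return np.concatenate([pad, mid, pad])


def encode_dataset(
    ds: Dataset, max_strand_length: int = MAX_STRAND_LENGTH
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized encoding: (N, 2m + loop) token matrix and observed labels."""
    m = max_strand_length
    L = ds.L
    if L > m:
        raise ValueError(f"L={L} exceeds max_strand_length={m}")
    seqs = "".join(e.sequence for e in ds.examples)
    mid = _BASE_TO_ID[np.frombuffer(seqs.encode(), dtype=np.uint8)]
    mid = mid.reshape(ds.N, 2 * L + ds.loop_length)
    pad = np.zeros((ds.N, m - L), dtype=np.int64)
    tokens = np.concatenate([pad, mid, pad], axis=1)
    return tokens, ds.observed_labels()


# ---------------------------------------------------------------------------
# Serialization

_FASTA_KEYS = ("idx", "true", "obs", "L", "loop")


def export_fasta(ds: Dataset, path: str | Path) -> None:
    """One record per example; the header carries labels and geometry."""
    records = []
    for i, e in enumerate(ds.examples):
        rid = (
            f"ex{i}|idx={i}|true={e.true_label}|obs={e.observed_label}"
            f"|L={e.L}|loop={len(e.loop)}"
        )
        records.append(SeqRecord(Seq(e.sequence), id=rid, description=""))
    SeqIO.write(records, str(path), "fasta")


def import_fasta(path: str | Path) -> Dataset:
    """Rebuild a Dataset from an :func:`export_fasta` file."""
    examples = []
    L = loop_length = None
    for rec in SeqIO.parse(str(path), "fasta"):
        fields = dict(p.split("=") for p in rec.id.split("|")[1:])
        L = int(fields["L"])
        loop_length = int(fields["loop"])
        seq = str(rec.seq)
        examples.append(
            HairpinExample(
                s=seq[:L],
                loop=seq[L : L + loop_length],
                s_bar=seq[L + loop_length :],
                true_label=int(fields["true"]),
                observed_label=int(fields["obs"]),
            )
        )
    if not examples:
        raise ValueError(f"no records in {path}")
    true = np.array([e.true_label for e in examples])
    mis = np.array([e.is_mislabelled for e in examples])
    return Dataset(
        examples=examples,
        L=L,
        alpha=float(true.mean()),
        mu=float(mis.mean()),
        role="train" if mis.any() else "test",
        loop_length=loop_length,
        seed=-1,
    )


def to_csv(ds: Dataset, path: str | Path) -> None:
    import pandas as pd

    pd.DataFrame(
        {
            "id": range(ds.N),
            "s": [e.s for e in ds.examples],
            "loop": [e.loop for e in ds.examples],
            "s_bar": [e.s_bar for e in ds.examples],
            "true_label": [e.true_label for e in ds.examples],
            "observed_label": [e.observed_label for e in ds.examples],
        }
    ).to_csv(path, index=False)


def from_csv(path: str | Path) -> Dataset:
    import pandas as pd

    df = pd.read_csv(path)
    examples = [
        HairpinExample(
            s=r.s,
            loop=r.loop,
            s_bar=r.s_bar,
            true_label=int(r.true_label),
            observed_label=int(r.observed_label),
        )
        for r in df.itertuples()
    ]
    mis = np.array([e.is_mislabelled for e in examples])
    return Dataset(
        examples=examples,
        L=len(examples[0].s),
        alpha=float(np.mean([e.true_label for e in examples])),
        mu=float(mis.mean()),
        role="train" if mis.any() else "test",
        loop_length=len(examples[0].loop),
        seed=-1,
    )
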