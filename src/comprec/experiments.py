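"""Experiment grids: mislabel robustness, length extrapolation, positivity
sweep, the combined regime, and the classical baselines.

A grid cell is (family, capacity level, N, alpha, mu, L_train, L_test);
every cell is repeated over seeds (repetition r uses base_seed + r) and
the results land in a long-form table with one row per repetition plus an
aggregated table of means.  Runs are resumable: rows already present in
an output file are not recomputed.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

from .baselines import METHODS, run_baseline_simulation
from .evaluation import GenParams, run_simulation
from .models import CAPACITY_LEVELS, FAMILIES

EXPERIMENT_NAMES = (
    "mislabels",
    "length_extrapolation",
    "alpha_sweep",
    "combined",
    "baselines",
)

DEFAULT_N_GRID = (125, 250, 500, 1000, 2000, 4000, 8000)
DEFAULT_ALPHA_GRID = (0.05, 0.1, 0.2, 0.3, 0.4, 0.5, 0.6, 0.7, 0.8, 0.9, 0.95)

LONG_COLUMNS = [
    "family",
    "level",
    "N",
    "alpha",
    "mu",
    "L_train",
    "L_test",
    "repetition",
    "train_accuracy",
    "test_accuracy",
]
KEY_COLUMNS = LONG_COLUMNS[:8]


@dataclass(frozen=True)
class ExperimentSpec:
    name: str
    families: tuple[str, ...] = FAMILIES
    capacity_levels: tuple[float, ...] = CAPACITY_LEVELS
    N_grid: tuple[int, ...] = DEFAULT_N_GRID
    L_train: int = 8
    L_test: int = 8
    alpha: float = 0.5
    alpha_grid: tuple[float, ...] = DEFAULT_ALPHA_GRID
    mu: float = 0.0
    repetitions: int = 50
    base_seed: int = 0
    loop_length: int = 4

    def __post_init__(self):
        if self.name not in EXPERIMENT_NAMES:
            raise ValueError(f"unknown experiment {self.name!r}")


def preset(name: str, **overrides) -> ExperimentSpec:
    """The named study conditions; override grids/repetitions as needed."""
    presets = {
        # within-length, label noise 20%, balanced classes
        "mislabels": dict(L_train=8, L_test=8, mu=0.2, alpha=0.5),
        # correctly labelled, trained short, tested on all length-8
        "length_extrapolation": dict(L_train=6, L_test=8, mu=0.0, alpha=0.5),
        # positivity-rate sweep at (N, L, mu) = (500, 6, 0); only alpha
        # differs between the skewed train set and the balanced test set
        "alpha_sweep": dict(
            L_train=6, L_test=6, mu=0.0, N_grid=(500,)
        ),
        # few examples, mislabels and skewed positivity at once
        "combined": dict(L_train=6, L_test=8, mu=0.2, alpha=0.4),
        # classical methods in the mislabel regime
        "baselines": dict(
            L_train=8, L_test=8, mu=0.2, alpha=0.5, families=METHODS
        ),
    }
    if name not in presets:
        raise ValueError(f"unknown experiment {name!r}")
    return ExperimentSpec(name=name, **{**presets[name], **overrides})


@dataclass
class GridResult:
    long: pd.DataFrame
    spec: ExperimentSpec

    def aggregated(self) -> pd.DataFrame:
        return (
            self.long.groupby(KEY_COLUMNS[:7], as_index=False)[
                ["train_accuracy", "test_accuracy"]
            ]
            .mean()
            .sort_values(KEY_COLUMNS[:7])
            .reset_index(drop=True)
        )


class MissingSliceError(KeyError):
    pass


def _cells(spec: ExperimentSpec) -> Iterable[dict]:
    alphas = spec.alpha_grid if spec.name == "alpha_sweep" else (spec.alpha,)
    levels = (
        (float("nan"),) if spec.name == "baselines" else spec.capacity_levels
    )
    for family in spec.families:
        for level in levels:
            for N in spec.N_grid:
                for alpha in alphas:
                    yield dict(
                        family=family,
                        level=level,
                        N=N,
                        alpha=alpha,
                        mu=spec.mu,
                        L_train=spec.L_train,
                        L_test=spec.L_test,
                    )


def run_experiment(
    spec: ExperimentSpec,
    scale: str = "full",
    out_dir: str | Path | None = None,
    progress: bool = False,
) -> GridResult:
    """Run every cell of the grid through the simulation pipeline.

    ``scale="reduced"`` cuts repetitions to 10.  With ``out_dir`` set,
    the long-form table is written after each cell and existing rows are
    skipped on re-runs; per-cell failures are recorded and the run
    continues.
    """
    if scale not in ("full", "reduced"):
        raise ValueError("scale must be 'full' or 'reduced'")
    reps = 10 if scale == "reduced" else spec.repetitions
    out_path = None
    done: set[tuple] = set()
    rows: list[dict] = []
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        out_path = out_dir / f"{spec.name}_long.csv"
        if out_path.exists():
            prev = pd.read_csv(out_path)
            rows = prev.to_dict("records")
            done = {tuple(r[k] for k in KEY_COLUMNS) for r in rows}

    failures: list[dict] = []
    for cell in _cells(spec):
        for rep in range(reps):
            key_row = {**cell, "repetition": rep}
            key = tuple(key_row[k] for k in KEY_COLUMNS)
            if key in done:
                continue
            rep_seed = spec.base_seed + rep
            gp = GenParams(
                L_train=cell["L_train"],
                N=cell["N"],
                alpha=cell["alpha"],
                mu=cell["mu"],
                L_test=cell["L_test"],
                loop_length=spec.loop_length,
            )
            try:
                if spec.name == "baselines" or cell["family"] in METHODS:
                    tr, te = run_baseline_simulation(
                        cell["family"], gp, rep_seed
                    )
                else:
                    tr, te = run_simulation(
                        cell["family"], cell["level"], gp, rep_seed
                    )
            except Exception as exc:  # record and keep going
                failures.append({**key_row, "error": repr(exc)})
                continue
            rows.append(
                {
                    **key_row,
                    "train_accuracy": tr.accuracy,
                    "test_accuracy": te.accuracy,
                }
            )
            if progress:
                print(
                    f"{spec.name} {cell['family']} level={cell['level']} "
                    f"N={cell['N']} alpha={cell['alpha']} rep={rep} "
                    f"seed={rep_seed}: train={tr.accuracy:.3f} "
                    f"test={te.accuracy:.3f}",
                    flush=True,
                )
        if out_path is not None:
            pd.DataFrame(rows, columns=LONG_COLUMNS).to_csv(
                out_path, index=False
            )

    long = pd.DataFrame(rows, columns=LONG_COLUMNS)
    result = GridResult(long=long, spec=spec)
    if out_path is not None:
        result.aggregated().to_csv(
            out_dir / f"{spec.name}_summary.csv", index=False
        )
        if failures:
            pd.DataFrame(failures).to_csv(
                out_dir / f"{spec.name}_failures.csv", index=False
            )
    return result


def crossover_curve(
    results: GridResult, family: str, level: float
) -> pd.DataFrame:
    """Mean train/test accuracy vs N for one (family, capacity) slice."""
    df = results.long
    mask = (df["family"] == family) & (
        df["level"].isna() if np.isnan(level) else df["level"] == level
    )
    sel = df[mask]
    if sel.empty:
        raise MissingSliceError(f"no rows for family={family}, level={level}")
    return (
        sel.groupby("N", as_index=False)[["train_accuracy", "test_accuracy"]]
        .mean()
        .rename(
            columns={
                "train_accuracy": "mean_train_accuracy",
                "test_accuracy": "mean_test_accuracy",
            }
        )
        .sort_values("N")
        .reset_index(drop=True)
    )


def alpha_sweep_curve(results: GridResult) -> pd.DataFrame:
    """Mean test accuracy vs alpha per (family, capacity level)."""
    if results.spec.name != "alpha_sweep":
        raise MissingSliceError("results are not from an alpha_sweep run")
    df = results.long
    if df.empty:
        raise MissingSliceError("empty results")
    return (
        df.groupby(["family", "level", "alpha"], as_index=False)[
            ["test_accuracy"]
        ]
        .mean()
        .rename(columns={"test_accuracy": "mean_test_accuracy"})
        .sort_values(["family", "level", "alpha"])
        .reset_index(drop=True)
    )
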