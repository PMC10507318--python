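"""Sensitivity to the training positivity rate.

Sweeps the fraction alpha of positive examples in a 500-example length-6
training set (labels clean) and evaluates on balanced test data.  The
loss already reweights classes, yet extreme rates in either direction
hurt; the curve is left-skewed — too few positives is worse than too
many, because positives carry the full Watson-Crick pattern.

Reduced scale: one family/capacity, 3 repetitions, a thinned alpha grid.
"""

import argparse
from pathlib import Path

from comprec.experiments import alpha_sweep_curve, preset, run_experiment

parser = argparse.ArgumentParser(description=__doc__)
parser.add_argument("--family", default="MLP")
parser.add_argument("--level", type=float, default=3.50)
parser.add_argument(
    "--alphas", nargs="+", type=float,
    default=[0.05, 0.1, 0.3, 0.5, 0.7, 0.9, 0.95],
)
parser.add_argument("--repetitions", type=int, default=3)
parser.add_argument("--seed", type=int, default=0)
parser.add_argument("--out-dir", type=Path, default=Path("results"))
args = parser.parse_args()

spec = preset(
    "alpha_sweep",
    families=(args.family,),
    capacity_levels=(args.level,),
    alpha_grid=tuple(args.alphas),
    repetitions=args.repetitions,
    base_seed=args.seed,
)
result = run_experiment(spec, scale="full", out_dir=args.out_dir,
                        progress=True)
curve = alpha_sweep_curve(result)
print("\nmean test accuracy vs training positivity rate:")
print(curve.to_string(index=False))

mid = curve.loc[curve.alpha == 0.5, "mean_test_accuracy"]
lo = curve.loc[curve.alpha == min(args.alphas), "mean_test_accuracy"]
hi = curve.loc[curve.alpha == max(args.alphas), "mean_test_accuracy"]
if not (mid.empty or lo.empty or hi.empty):
    print(
        f"\nalpha=0.5: {float(mid.iloc[0]):.3f}; "
        f"alpha={min(args.alphas)}: {float(lo.iloc[0]):.3f}; "
        f"alpha={max(args.alphas)}: {float(hi.iloc[0]):.3f}"
    )
    if float(hi.iloc[0]) > float(lo.iloc[0]):
        print("-> left-skewed: many positives hurt less than few positives")
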