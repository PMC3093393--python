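"""Parameter-recovery experiment: simulate cohorts from known observers,
refit, and tabulate how well (sigma1, sigma2) come back.

Default grid spans noise ratios 1.0, 1.3 and 2.0 at the probe noise level
the analyses target.  Fits that run into the scale-unidentified regime
(noise of order the whole range) are counted separately in `n_bound`.
About half a minute per cell at 10 replicates.
"""

import argparse
from pathlib import Path

from contraction_bias import TaskConfig, parameter_recovery_experiment

GRID = [(0.20, 0.20), (0.26, 0.20), (0.40, 0.20)]


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=0)
    ap.add_argument("--n-reps", type=int, default=10)
    ap.add_argument("--outdir", type=Path, default=Path("results/recovery"))
    args = ap.parse_args()
    args.outdir.mkdir(parents=True, exist_ok=True)

    table = parameter_recovery_experiment(
        GRID, cohort_config=TaskConfig(), n_subjects=9,
        n_reps=args.n_reps, seed=args.seed)
    table.to_csv(args.outdir / "recovery.csv", index=False)

    cols = ["sigma1_true", "sigma2_true", "sigma1_mean", "sigma2_mean",
            "ratio_true", "ratio_mean", "n_bound", "n_flat"]
    print(table[cols].to_string(index=False))
    # the equal-noise cell produces a near-flat curve whose fitted ratio is
    # a quotient of two barely-constrained numbers; monotonicity is only a
    # meaningful check across the biased cells
    biased = table[table["ratio_true"] > 1].sort_values("ratio_true")
    mono = biased["ratio_mean"].is_monotonic_increasing
    print(f"fitted ratio monotone across biased cells: {mono}")


if __name__ == "__main__":
    main()
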