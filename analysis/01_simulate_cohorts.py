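"""Simulate the three synthetic cohorts the downstream analyses consume.

Designs: a standard task with first-bar lengths uniform in log scale on
150-600 px (10 subjects) or 50-200 px (9 subjects), and a modified task on
100-400 px (10 subjects) in which a random half of the trials carry an
interference flag that doubles the memory noise sigma1.  Every subject
completes 500 trials, half of them "impossible" (equal bars).  Observers
sit at the operating point sigma1/sigma2 = 0.26/0.20 (normalized log-range
units, a 1.3 noise ratio) with mild between-subject spread.

Writes trials.csv + truth.json per cohort under results/cohorts/.
"""

import argparse
from pathlib import Path

from contraction_bias import ParamDistribution, TaskConfig, generate_cohort, write_trials, write_truth

COHORTS = {
    "standard_150_600": (
        TaskConfig(range_px=(150.0, 600.0), n_trials=500), 10,
        ParamDistribution(sigma1=(0.22, 0.30), sigma2=(0.17, 0.23)),
    ),
    "standard_50_200": (
        TaskConfig(range_px=(50.0, 200.0), n_trials=500), 9,
        ParamDistribution(sigma1=(0.22, 0.30), sigma2=(0.17, 0.23)),
    ),
    "modified_100_400": (
        TaskConfig(range_px=(100.0, 400.0), n_trials=500, interference_fraction=0.5), 10,
        ParamDistribution(sigma1=(0.22, 0.30), sigma2=(0.17, 0.23),
                          interference_multiplier=2.0),
    ),
}


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=0)
    ap.add_argument("--outdir", type=Path, default=Path("results/cohorts"))
    args = ap.parse_args()
    args.outdir.mkdir(parents=True, exist_ok=True)
    for i, (name, (cfg, n_subjects, dist)) in enumerate(COHORTS.items()):
        trials, truth = generate_cohort(n_subjects, cfg, dist, seed=args.seed * 100 + i)
        write_trials(args.outdir / f"{name}.csv", trials)
        write_truth(args.outdir / f"{name}_truth.json", truth)
        n_imp = int(trials["is_impossible"].sum())
        print(f"{name}: {n_subjects} subjects, {len(trials)} trials "
              f"({n_imp} impossible) -> {args.outdir / (name + '.csv')}")


if __name__ == "__main__":
    main()
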