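# contraction-bias

A Bayesian ideal-observer account of the **contraction bias** in delayed
magnitude comparison, as a tested simulation-and-analysis pipeline.

When people compare two sequentially presented magnitudes — here, the
lengths of two bars separated by a retention delay — their reports are
systematically pulled toward the centre of the stimulus distribution:
small first bars are remembered as larger, large ones as smaller. This
package implements the normative explanation of that bias and the full
analysis chain used to study it, for researchers in psychophysics and
computational cognitive neuroscience who want to simulate such
experiments, analyse trial tables, or fit the observer model.

## The model

Log lengths `L1, L2` are encoded as noisy representations
`R_i = L_i + z_i`, `z_i ~ N(0, σ_i²)`, with memory noise `σ1 ≥ σ2`. With
a uniform prior `Pr(L)` over the log stimulus range, Bayes' rule gives a
truncated-Gaussian posterior `Pr(L_i | R_i)` for each bar. The observer
reports "L1 > L2" whenever

    Pr(L1 > L2 | R1, R2) = ∫∫_{l1>l2} Pr(l1|R1) Pr(l2|R2) dl1 dl2  >  1/2,

and the response probability for given stimuli marginalizes this rule
over the noise. Because the noisier first-bar posterior is shrunk toward
the prior centre more strongly, the model reproduces the contraction
bias on "impossible" trials (`L1 = L2`), predicts that the bias curve
translates with the prior, and predicts that extra memory noise (e.g.
from an interfering secondary task) steepens it.

## Layout

* `src/contraction_bias/` — the library: `observer.py` (posteriors,
  comparison probability, decision boundary, response curves),
  `simulate.py` (task designs and synthetic cohorts), `analysis.py`
  (response curves, psychometric fits, pairs-bootstrap slope CIs),
  `fitting.py` (global-bias subtraction, (σ1, σ2) least-squares fit,
  parameter recovery), `io.py`/`cli.py` (CSV trial tables, JSON configs,
  `contraction-bias` command with `simulate/analyze/fit/recover`).
* `analysis/` — numbered narrative drivers reproducing each analysis on
  synthetic cohorts, writing tables under `results/`.
* `docs/methods.md` — model, numerics, and design decisions.

## Worked example

```
$ python analysis/01_simulate_cohorts.py --seed 1
$ python analysis/02_standard_task_analysis.py --seed 1
response-curve slope: -0.289, 95% basic bootstrap CI [-0.357, -0.220]
psychometric width sigma = 0.398 (PSE +0.0081)
accuracy by |delta| (%):
 abs_delta  percent_correct      sem
     0.075        55.959563 1.306455
     0.150        64.293872 1.610064
     0.300        78.234700 1.204264
first-20 vs last-20 slope difference: -0.281 CI [-0.668, 0.094] (stationary)
```

Ten simulated subjects with memory noise 30% above probe noise show a
clearly negative impossible-trial slope (−0.29: the fraction of
"first longer" reports falls by ~0.29 of its range across the log
stimulus range — the contraction bias), accuracy ordered by difficulty,
and no early-vs-late drift. Continuing,

```
$ python analysis/03_prior_shift.py --seed 1
150-600 px slope: -0.289 [-0.357, -0.220]
 50-200 px slope: -0.333 [-0.405, -0.262]
difference:       +0.043 [-0.058, 0.138]
no slope change across priors - the bias translated with the range
$ python analysis/04_interference.py --seed 1
slope difference (interfered - standard): -0.515 [-0.642, -0.388]
```

shows the two signature predictions: translating the stimulus range
leaves the normalized slope unchanged, while doubling σ1 on interfered
trials makes it significantly steeper. `05_observer_fit.py` fits
(σ1, σ2) back from the population-average curve and
`06_parameter_recovery.py` tabulates recovery over a grid of true
values (see `docs/methods.md` on the scale-identifiability caveat).

## Acceptance script

```
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

recomputes the package's quantitative target from scratch: the
least-squares slope of the observer's 0.5-probability decision boundary
(`r2` vs `r1` over the central half of a unit uniform prior, σ1 = 0.3,
σ2 = 0.2), found by bracketed root-finding on the comparison
probability. The model's claim is that this slope is below 1 — the
geometric signature of the contraction bias.
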