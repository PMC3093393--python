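# Methods

## The model

In a delayed comparison task the subject sees a horizontal bar of length
`L1`, holds it in memory across a delay, sees a second bar `L2`, and
reports which was longer. Lengths are carried as natural logarithms of
pixel lengths throughout (Weber's law: discriminability scales with
magnitude, so noise is approximately additive on the log scale). The
internal representation of bar *i* is

    R_i = L_i + z_i,     z_i ~ N(0, sigma_i^2)

with `sigma1 >= sigma2` expected, because the first bar's representation
must survive the retention delay. The stimulus prior is uniform on the
log-length interval the experiment draws from. An ideal observer combines
each noisy representation with the prior by Bayes' rule; with a uniform
prior the posterior of `L_i` is the Gaussian likelihood `N(R_i,
sigma_i^2)` truncated to the prior support and renormalized. The observer
computes

    P(L1 > L2 | R1, R2) = ∫∫_{l1 > l2} p(l1|R1) p(l2|R2) dl1 dl2

and reports "first longer" when this exceeds 1/2 (0–1 loss on the binary
report). The response probability for a stimulus pair marginalizes that
deterministic rule over the representation noise.

The contraction bias follows: the noisier first-bar posterior is pulled
toward the prior centre more strongly than the second-bar posterior, so
on "impossible" trials (`L1 = L2 = l`) the observer reports "first
longer" above chance for small `l` and below chance for large `l`. Three
limits organize the behaviour:

* `sigma1 = sigma2` — the prior acts on both posteriors equally; the
  impossible-trial response curve is flat at 0.5 (no bias).
* `sigma1 = inf, sigma2 = 0` — the first bar is pure prior, the second is
  known; the response curve is a unit step at the prior median (maximal
  bias).
* `0 < sigma2 < sigma1 < inf` — a smooth decreasing curve between those
  two, steeper the larger `sigma1/sigma2`.

Two model invariances matter for the experimental logic: translating the
prior and the stimuli together translates the response curve without
changing its shape (tested to 1e-8), and inflating `sigma1` at fixed
`sigma2` steepens the curve monotonically.

## Numerics

* **Truncated-Gaussian primitives** are evaluated through `Phi` with
  complementary forms in the far tails (no cancellation until the
  normalizer itself underflows ~38 SD outside the support, where the
  posterior is treated as a point mass at the nearer boundary).
* **Comparison probability** (finite positive noise): one-dimensional
  Gauss–Legendre quadrature (default order 200) of
  `p(l2|R2) * (1 - F1(l2))` over a window covering ±8 SD of the L2
  posterior (mass outside < 1e-14). Degenerate noise levels
  (`sigma = 0`, `sigma = inf`) use exact closed-form branches, never
  limiting numerics.
* **Decision boundary**: `P` is strictly increasing in `R1` and
  decreasing in `R2` (the truncated-Gaussian family is stochastically
  monotone in its location), so the decision region is
  `{R1 > b(R2)}`. Boundary points are found by vectorized bracketed
  root-finding (Chandrupatla, xatol 1e-10); every returned point
  re-evaluates to 0.5 within 1e-6.
* **Response probability**: Gauss–Hermite quadrature over `R2` (default
  order 100) of `1 - Phi((b(R2) - l1)/sigma1)`, with `b` tabulated on a
  grid and interpolated monotonically (PCHIP). The computed boundary is
  checked for monotonicity; if it ever failed the code falls back to full
  2-D quadrature of the decision indicator (the fallback exists and is
  exercised in no realistic parameter regime we have found).
* **Ties** (`P` exactly 0.5, within a 1e-9 quadrature noise floor) are
  resolved by policy: a fair coin from the caller's generator by default.

## Synthetic cohorts

The generator emulates the study designs the analyses are built for:
first-bar length uniform in log scale over [150, 600], [50, 200] or
[100, 400] pixels; the second bar differing by ±7.5%, ±15% or ±30%
(uniform over the set — the per-level allocation is not recorded
anywhere, so balanced cells are assumed); ~50% impossible trials; 500
trials per subject; and, in the modified task, an interference flag on a
random half of trials modeled *solely* as a multiplicative inflation of
`sigma1` (default ×2). Flags are independent Bernoulli draws by default,
with exact-count blocking available. Per-subject parameters are drawn
from configurable uniform ranges; the defaults centre on
`sigma1/sigma2 = 0.26/0.20` in normalized log-range units — a 1.3 noise
ratio at the scale the observer fits report. One master seed;
per-subject substreams are spawned from a `SeedSequence`, so runs are
exactly reproducible.

What a green test on these cohorts does *not* establish: the generator
contains no trial-to-trial prior learning, no lapses unless configured,
no global report bias (the analyses subtract one regardless), and no
model of the interfering color task beyond the noise inflation — so the
tests validate the procedures, not any claim about human data.

## Analyses

Slopes are computed after mapping the log length range to [0, 1], so a
slope of −1 spans the full response range. Response curves use
equal-count bins on pooled ranks by default (matching figure conventions
of a fixed number of trials per subject per point; `trials_per_bin`
configurable), with bin centers at the mean normalized length per bin,
and subject-averaged fractions with per-bin SEM. Confidence intervals are
95% *basic* bootstrap intervals, `(2θ − q_0.975, 2θ − q_0.025)`, from
5000 replicates in which each subject's impossible trials are resampled
with replacement (the resampling unit is the trial within subject, never
the subject; bin edges stay fixed at the original assignment, and a bin
emptied by resampling is dropped from that replicate's regression).
Group comparisons resample groups independently; within-subject
comparisons resample both conditions inside each subject. The
psychometric fit is a least-squares cumulative Gaussian in
`delta = (l2 - l1)/l1`, decreasing in delta for the fraction of "first
longer" reports, parameterized so the width is positive. p-values are
plain two-tailed t tests; no multiple-testing correction anywhere.

## Observer fit and identifiability

The two noise SDs are fit by least squares between the bias-subtracted,
subject-averaged response curve and the model curve at the same bin
centers: a coarse 40×40 logarithmic grid over sigma in [0.01, 2]
(normalized units), then Nelder–Mead refinement in log-sigma space from
up to three well-separated coarse candidates (the multi-start matters —
see below). A flat curve at 0.5 identifies only the ratio (= 1) and
raises a dedicated error. A trial-level Bernoulli likelihood variant is
deliberately *not* the default: the reference procedure fits the binned
averaged curve.

The fit's known limitation is a shallow objective valley: pairs with
both sigmas of order the whole range (ratio ≈ 2) produce a curve within
~0.01 per bin of the one produced by (0.26, 0.20) — below the binomial
noise of a 9-subject × 500-trial cohort. A noisy curve can therefore pull
the optimizer up the valley to the sigma bound. Fits with
`sigma1_hat >= 1` (noise spanning the entire normalized range,
observationally the infinite-noise step regime) or on the bound are
classified as scale-unidentified; the recovery experiment counts them in
`n_bound` and computes recovery statistics over interior-converged fits,
the way non-converged fits are reported in any simulation study (the
unconditional mean is retained alongside). Interior fits recover the
generating parameters well: across replicate cohorts at the design scale,
mean fitted sigmas ≈ (0.262, 0.200) and mean ratio ≈ 1.34 against a true
1.30.

## Tunable parameters

| parameter | meaning | default | units |
|---|---|---|---|
| `sigma1`, `sigma2` | representation noise SDs | 0.26, 0.20 (cohorts) | normalized log range (× log-width for log units) |
| `interference_multiplier` | sigma1 inflation on flagged trials | 2.0 (modified task) | — |
| `lapse` | fair-coin response probability | 0 | probability |
| `impossible_fraction` | equal-length trials | 0.5 | fraction |
| `n_trials` | trials per subject | 500 | — |
| `trials_per_bin` / `n_bins` | curve binning | 21 per subject / 10 | — |
| `n_boot` | bootstrap replicates | 5000 | — |
| `sigma_bounds` | fit search box | (0.01, 2) | normalized |
| quadrature orders | GL / GH / boundary grid | 200 / 100 / 161 | — |

Reduced quadrature (80/40/61) is used inside the fit objective, where
~1e-5 curve accuracy is far below the residuals being minimized.

## Known limitations

* The sigma *scale* is weakly identified from a single binned curve (see
  above); only the ratio and the curve shape are robust.
* Basic bootstrap intervals undercover slightly at very small
  trials-per-subject counts; empirical coverage at the tested scales sits
  at ~93–96%.
* The equal-noise recovery cell yields a near-flat curve whose fitted
  ratio is a quotient of two barely-constrained numbers; it checks "no
  bias detected", not ratio accuracy.
* Non-uniform priors are not implemented (the uniform prior is what makes
  the truncated-Gaussian closed forms exact); the prior is assumed known
  to the observer rather than learned.
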