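"""Behavioral analyses for delayed comparison trial tables.

Implements the standard pipeline for quantifying the contraction bias:

* psychometric (cumulative-Gaussian) fits to the non-impossible trials,
* response curves on the impossible trials — the fraction of 'first
  longer' reports binned on normalized log length,
* ordinary least-squares slopes of those curves, with 95% basic bootstrap
  confidence intervals obtained by resampling each subject's impossible
  trials with replacement,
* group and within-subject slope comparisons, a first-vs-last trial-window
  comparison, accuracy broken down by difficulty, and the correlation
  between psychometric width and response-curve slope.

Slopes are computed after normalizing the log length range to [0, 1], so a
slope of -1 corresponds to a full swing of the response fraction across
the stimulus range.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.optimize import least_squares
from scipy.special import ndtr

from ._exceptions import (
    DegenerateDataError,
    DegenerateFitError,
    EmptyBinError,
    InsufficientTrialsError,
    OutOfRangeError,
    SubjectMismatchError,
    TooFewReplicatesError,
)
from .curves import ResponseCurve, SlopeEstimate

__all__ = [
    "normalize_log_lengths",
    "PsychometricFit",
    "fit_psychometric",
    "compute_response_curve",
    "fit_response_slope",
    "basic_interval",
    "bootstrap_slope_ci",
    "bootstrap_slope_difference",
    "windowed_slope_comparison",
    "accuracy_by_difficulty",
    "slope_sigma_correlation",
]


def normalize_log_lengths(lengths_px, range_px, tol: float = 1e-9):
    """Map pixel lengths onto [0, 1] in log space.

    ``x -> (log x - log lo) / (log hi - log lo)``.  Values outside the
    declared range beyond a relative tolerance raise
    :class:`OutOfRangeError`.
    """
    lo, hi = range_px
    if not 0 < lo < hi:
        raise OutOfRangeError(f"invalid pixel range {range_px}")
    x = np.asarray(lengths_px, dtype=float)
    if np.any(x < lo * (1 - tol)) or np.any(x > hi * (1 + tol)):
        raise OutOfRangeError("lengths outside the declared pixel range")
    out = (np.log(x) - np.log(lo)) / (np.log(hi) - np.log(lo))
    return np.clip(out, 0.0, 1.0)


def denormalize_log_lengths(x, range_px):
    """Inverse of :func:`normalize_log_lengths`."""
    lo, hi = range_px
    return np.exp(np.log(lo) + np.asarray(x, dtype=float) * (np.log(hi) - np.log(lo)))


def signed_deltas(trials: pd.DataFrame) -> np.ndarray:
    """delta = (l2 - l1)/l1, the signed fractional length difference."""
    l1 = trials["l1_px"].to_numpy(dtype=float)
    l2 = trials["l2_px"].to_numpy(dtype=float)
    return (l2 - l1) / l1


def _first_longer(trials: pd.DataFrame) -> np.ndarray:
    resp = trials["response"]
    if resp.isna().any():
        raise InsufficientTrialsError("table contains trials without responses")
    return resp.to_numpy(dtype=float) == 1


# ---------------------------------------------------------------------------
# psychometric curve
# ---------------------------------------------------------------------------

@dataclass
class PsychometricFit:
    """Cumulative-Gaussian fit to the fraction of 'first longer' vs delta.

    The fraction of 'first longer' reports decreases with
    delta = (l2 - l1)/l1, so the fitted model is
    ``f(delta) = Phi((mu - delta) / sigma_psych)`` with ``sigma_psych > 0``:
    ``mu`` is the point of subjective equality and ``sigma_psych`` the
    psychometric width (both in fraction units).
    """

    mu: float
    sigma_psych: float
    rss: float


def fit_psychometric(trials: pd.DataFrame) -> PsychometricFit:
    """Least-squares error-function fit to the per-delta response fractions."""
    t = trials[~trials["is_impossible"].astype(bool)]
    if len(t) == 0:
        raise InsufficientTrialsError("no non-impossible trials")
    deltas = np.round(signed_deltas(t), 9)
    first = _first_longer(t)
    levels = np.unique(deltas)
    if levels.size < 2:
        raise DegenerateFitError("need >= 2 distinct delta levels")
    frac = np.array([first[deltas == d].mean() for d in levels])
    if np.allclose(frac, frac[0]):
        raise DegenerateFitError("all response fractions equal; psychometric fit undefined")

    def resid(theta):
        mu, log_sigma = theta
        return ndtr((mu - levels) / np.exp(log_sigma)) - frac

    sol = least_squares(resid, x0=[0.0, np.log(0.15)], xtol=1e-15, ftol=1e-15, gtol=1e-15)
    mu, sigma = sol.x[0], float(np.exp(sol.x[1]))
    return PsychometricFit(mu=float(mu), sigma_psych=sigma, rss=float(np.sum(sol.fun ** 2)))


# ---------------------------------------------------------------------------
# response curves
# ---------------------------------------------------------------------------

def _impossible(trials: pd.DataFrame) -> pd.DataFrame:
    imp = trials[trials["is_impossible"].astype(bool)]
    if len(imp) == 0:
        raise InsufficientTrialsError("no impossible trials in the table")
    return imp


def _resolve_n_bins(imp: pd.DataFrame, n_bins, trials_per_bin) -> int:
    if (n_bins is None) == (trials_per_bin is None):
        raise ValueError("specify exactly one of n_bins or trials_per_bin")
    if n_bins is not None:
        return int(n_bins)
    # figure-caption convention: each data point is `trials_per_bin`
    # impossible trials per subject
    per_subject = imp.groupby("subject_id").size().mean()
    return max(1, int(per_subject // trials_per_bin))


def _bin_index(x: np.ndarray, n_bins: int, binning: str) -> np.ndarray:
    """Bin assignment on normalized lengths; equal-count uses pooled ranks."""
    if binning == "equal_width":
        idx = np.minimum((x * n_bins).astype(int), n_bins - 1)
        return idx
    if binning != "equal_count":
        raise ValueError(f"unknown binning {binning!r}")
    order = np.argsort(x, kind="stable")
    idx = np.empty(x.size, dtype=int)
    # split pooled ranks into n_bins nearly equal chunks
    splits = np.array_split(order, n_bins)
    for b, chunk in enumerate(splits):
        idx[chunk] = b
    return idx


def _curve_from_assignment(x, first, subj, bin_idx, n_bins, average_subjects):
    centers = np.full(n_bins, np.nan)
    counts = np.zeros(n_bins, dtype=int)
    for b in range(n_bins):
        m = bin_idx == b
        counts[b] = int(np.sum(m))
        if counts[b]:
            centers[b] = float(np.mean(x[m]))
    if np.any(counts == 0):
        raise EmptyBinError("a requested bin contains no trials")
    subjects = np.unique(subj)
    if average_subjects and subjects.size > 1:
        per = np.full((subjects.size, n_bins), np.nan)
        for i, s in enumerate(subjects):
            ms = subj == s
            for b in range(n_bins):
                m = ms & (bin_idx == b)
                if np.any(m):
                    per[i, b] = float(np.mean(first[m]))
        n_sub = np.sum(~np.isnan(per), axis=0)
        fractions = np.nanmean(per, axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            sem = np.nanstd(per, axis=0, ddof=1) / np.sqrt(n_sub)
    else:
        fractions = np.array([float(np.mean(first[bin_idx == b])) for b in range(n_bins)])
        sem = None
    return ResponseCurve(bin_centers=centers, fractions=fractions, counts=counts, sem=sem)


def compute_response_curve(
    trials: pd.DataFrame,
    range_px,
    n_bins: int | None = None,
    trials_per_bin: int | None = None,
    binning: str = "equal_count",
    average_subjects: bool = True,
) -> ResponseCurve:
    """Response curve on the impossible trials.

    Bins the impossible trials on normalized log length (equal-count bins
    by default, mirroring figure construction where each data point holds a
    fixed number of trials per subject; equal-width optional) and returns
    the per-bin fraction of 'first longer' reports.  With several subjects
    the curve is the average of per-subject curves, with a per-bin SEM.
    """
    imp = _impossible(trials)
    nb = _resolve_n_bins(imp, n_bins, trials_per_bin)
    x = normalize_log_lengths(imp["l1_px"].to_numpy(dtype=float), range_px)
    first = _first_longer(imp).astype(float)
    subj = imp["subject_id"].to_numpy()
    bin_idx = _bin_index(x, nb, binning)
    return _curve_from_assignment(x, first, subj, bin_idx, nb, average_subjects)


def fit_response_slope(curve: ResponseCurve) -> float:
    """Unweighted OLS slope of the binned fractions on the bin centers."""
    if len(curve) < 2:
        raise InsufficientTrialsError("need >= 2 bins for a slope")
    return float(np.polyfit(curve.bin_centers, curve.fractions, 1)[0])


# ---------------------------------------------------------------------------
# pairs bootstrap
# ---------------------------------------------------------------------------

def basic_interval(theta_hat: float, boot_stats, level: float = 0.95):
    """Basic bootstrap interval ``(2*theta - q_hi, 2*theta - q_lo)``."""
    alpha = 0.5 * (1.0 - level)
    q_lo, q_hi = np.quantile(np.asarray(boot_stats, dtype=float), [alpha, 1.0 - alpha])
    return 2.0 * theta_hat - q_hi, 2.0 * theta_hat - q_lo


class _SubjectResampler:
    """Precomputed per-subject structures for fast within-subject
    resampling of impossible trials under a fixed bin assignment."""

    def __init__(self, imp: pd.DataFrame, range_px, n_bins: int, binning: str):
        x = normalize_log_lengths(imp["l1_px"].to_numpy(dtype=float), range_px)
        first = _first_longer(imp).astype(float)
        subj = imp["subject_id"].to_numpy()
        self.n_bins = n_bins
        self.bin_idx = _bin_index(x, n_bins, binning)
        self.x = x
        self.first = first
        self.subj = subj
        self.subjects = np.unique(subj)
        self.centers = np.array([np.mean(x[self.bin_idx == b]) for b in range(n_bins)])
        # per subject: one-hot (n_trials, n_bins) membership and responses
        self.per_subject = []
        for s in self.subjects:
            m = subj == s
            B = np.zeros((int(np.sum(m)), n_bins))
            B[np.arange(B.shape[0]), self.bin_idx[m]] = 1.0
            self.per_subject.append((B, first[m]))

    def observed_slope(self) -> float:
        frac = self._avg_fractions([(B.sum(axis=0), (B * f[:, None]).sum(axis=0))
                                    for B, f in self.per_subject])
        return self._slopes(frac[None, :])[0]

    def boot_slopes(self, n_boot: int, rng: np.random.Generator) -> np.ndarray:
        sums = []
        for B, f in self.per_subject:
            n = B.shape[0]
            counts = rng.multinomial(n, np.full(n, 1.0 / n), size=n_boot).astype(float)
            tot = counts @ B                      # (n_boot, n_bins)
            hit = counts @ (B * f[:, None])
            sums.append((tot, hit))
        frac = self._avg_fractions(sums)
        return self._slopes(frac)

    def _avg_fractions(self, sums):
        # average per-subject fractions, skipping subject-bins left empty
        # by the resampling
        tots = np.stack([t for t, _ in sums])     # (n_subj, ..., n_bins)
        hits = np.stack([h for _, h in sums])
        with np.errstate(invalid="ignore", divide="ignore"):
            per = hits / tots
        per[tots == 0] = np.nan
        with np.errstate(invalid="ignore"):
            return np.nanmean(per, axis=0)

    def _slopes(self, frac: np.ndarray) -> np.ndarray:
        """Row-wise OLS slope vs self.centers, ignoring NaN bins."""
        x = self.centers
        mask = ~np.isnan(frac)
        y = np.where(mask, frac, 0.0)
        w = mask.astype(float)
        n = w.sum(axis=1)
        sx = (w * x).sum(axis=1)
        sy = y.sum(axis=1)
        sxx = (w * x * x).sum(axis=1)
        sxy = (x * y).sum(axis=1)
        denom = n * sxx - sx * sx
        with np.errstate(invalid="ignore", divide="ignore"):
            out = (n * sxy - sx * sy) / denom
        out[denom == 0] = np.nan
        return out


def bootstrap_slope_ci(
    trials: pd.DataFrame,
    range_px,
    n_boot: int = 5000,
    level: float = 0.95,
    seed: int | np.random.SeedSequence | None = None,
    n_bins: int | None = None,
    trials_per_bin: int | None = None,
    binning: str = "equal_count",
) -> SlopeEstimate:
    """Slope of the subject-averaged response curve with a 95% basic
    bootstrap CI.

    Per replicate, each subject's impossible trials are resampled with
    replacement (the resampling unit is the trial within subject, never
    the subject), the subject-averaged curve is recomputed on the original
    bin assignment, and the OLS slope refitted; the basic interval is
    ``(2*s - q_hi, 2*s - q_lo)`` from the replicate quantiles.
    """
    if n_boot < 100:
        raise TooFewReplicatesError("n_boot must be >= 100")
    imp = _impossible(trials)
    if n_bins is None and trials_per_bin is None:
        n_bins = 10
    nb = _resolve_n_bins(imp, n_bins, trials_per_bin)
    rs = _SubjectResampler(imp, range_px, nb, binning)
    theta = rs.observed_slope()
    rng = np.random.default_rng(seed)
    slopes = rs.boot_slopes(n_boot, rng)
    slopes = slopes[~np.isnan(slopes)]
    if slopes.size < 100:
        raise TooFewReplicatesError("too many degenerate bootstrap replicates")
    lo, hi = basic_interval(theta, slopes, level)
    return SlopeEstimate(slope=theta, ci_lo=lo, ci_hi=hi, n_boot=n_boot, level=level)


def bootstrap_slope_difference(
    a: pd.DataFrame,
    b: pd.DataFrame,
    paired: bool = False,
    range_px_a=None,
    range_px_b=None,
    n_boot: int = 5000,
    level: float = 0.95,
    seed: int | np.random.SeedSequence | None = None,
    n_bins: int = 10,
    binning: str = "equal_count",
) -> SlopeEstimate:
    """Bootstrap CI on the slope difference (a minus b).

    Unpaired mode resamples the two groups independently; paired mode
    requires identical subject sets and resamples both conditions within
    each subject.  Either way the replicate statistic is the difference of
    the two subject-averaged curve slopes, and the basic interval is
    reported.
    """
    if n_boot < 100:
        raise TooFewReplicatesError("n_boot must be >= 100")
    if range_px_a is None or range_px_b is None:
        raise ValueError("range_px_a and range_px_b are required")
    imp_a, imp_b = _impossible(a), _impossible(b)
    if paired:
        sa = set(imp_a["subject_id"].unique())
        sb = set(imp_b["subject_id"].unique())
        if sa != sb:
            raise SubjectMismatchError("paired mode requires identical subject sets")
    rs_a = _SubjectResampler(imp_a, range_px_a, n_bins, binning)
    rs_b = _SubjectResampler(imp_b, range_px_b, n_bins, binning)
    theta = rs_a.observed_slope() - rs_b.observed_slope()
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    ss_a, ss_b = ss.spawn(2)
    sl_a = rs_a.boot_slopes(n_boot, np.random.default_rng(ss_a))
    sl_b = rs_b.boot_slopes(n_boot, np.random.default_rng(ss_b))
    diffs = sl_a - sl_b
    diffs = diffs[~np.isnan(diffs)]
    if diffs.size < 100:
        raise TooFewReplicatesError("too many degenerate bootstrap replicates")
    lo, hi = basic_interval(theta, diffs, level)
    return SlopeEstimate(slope=theta, ci_lo=lo, ci_hi=hi, n_boot=n_boot, level=level)


def windowed_slope_comparison(
    trials: pd.DataFrame,
    range_px,
    first_k: int = 20,
    last_k: int = 20,
    n_boot: int = 5000,
    level: float = 0.95,
    seed: int | np.random.SeedSequence | None = None,
    n_bins: int = 5,
    binning: str = "equal_count",
) -> SlopeEstimate:
    """Contraction bias early vs late: slope difference between each
    subject's first ``first_k`` and last ``last_k`` impossible trials
    (paired bootstrap; a CI covering 0 indicates the bias is already at
    its final level within the first trials)."""
    imp = _impossible(trials)
    firsts, lasts = [], []
    for s, g in imp.groupby("subject_id"):
        g = g.sort_values("trial_index")
        if len(g) < first_k + last_k:
            raise InsufficientTrialsError(
                f"subject {s} has {len(g)} impossible trials; "
                f"needs >= {first_k + last_k}"
            )
        firsts.append(g.iloc[:first_k])
        lasts.append(g.iloc[-last_k:])
    a = pd.concat(firsts, ignore_index=True)
    b = pd.concat(lasts, ignore_index=True)
    return bootstrap_slope_difference(
        a, b, paired=True, range_px_a=range_px, range_px_b=range_px,
        n_boot=n_boot, level=level, seed=seed, n_bins=n_bins, binning=binning,
    )


# ---------------------------------------------------------------------------
# accuracy and correlation
# ---------------------------------------------------------------------------

def accuracy_by_difficulty(trials: pd.DataFrame, group_by: str = "interfered") -> pd.DataFrame:
    """Percent correct per |delta| level and condition, averaged over
    subjects, with a paired two-tailed t test between conditions.

    A response is correct when it names the truly longer bar.  Returns one
    row per (|delta|, condition) with columns ``abs_delta, condition,
    percent_correct, sem, n_subjects, t_stat, p_value`` (the t statistic is
    attached to both rows of a level when exactly two conditions exist).
    """
    t = trials[~trials["is_impossible"].astype(bool)].copy()
    if len(t) == 0:
        raise InsufficientTrialsError("no non-impossible trials")
    deltas = signed_deltas(t)
    first = _first_longer(t)
    t["abs_delta"] = np.round(np.abs(deltas), 9)
    t["correct"] = np.where(deltas < 0, first, ~first).astype(float)
    cond = t[group_by].astype(bool) if group_by in t.columns else t[group_by]
    t["_cond"] = cond.to_numpy()

    per = (t.groupby(["abs_delta", "_cond", "subject_id"])["correct"]
             .mean().mul(100.0).rename("pc").reset_index())
    rows = []
    for level, g in per.groupby("abs_delta"):
        conds = sorted(g["_cond"].unique())
        t_stat = p_val = np.nan
        if len(conds) == 2:
            wide = g.pivot(index="subject_id", columns="_cond", values="pc").dropna()
            if len(wide) >= 2:
                res = stats.ttest_rel(wide[conds[0]], wide[conds[1]])
                t_stat, p_val = float(res.statistic), float(res.pvalue)
        for c in conds:
            vals = g.loc[g["_cond"] == c, "pc"].to_numpy()
            rows.append({
                "abs_delta": float(level),
                "condition": c,
                "percent_correct": float(np.mean(vals)),
                "sem": float(np.std(vals, ddof=1) / np.sqrt(len(vals))) if len(vals) > 1 else np.nan,
                "n_subjects": int(len(vals)),
                "t_stat": t_stat,
                "p_value": p_val,
            })
    return pd.DataFrame(rows).sort_values(["abs_delta", "condition"]).reset_index(drop=True)


def slope_sigma_correlation(sigma_values, slopes):
    """Pearson correlation between per-subject psychometric widths and
    response-curve slopes, with the t-based two-tailed p-value.

    A negative correlation means noisier subjects show a stronger
    contraction bias (a more negative slope)."""
    sig = np.asarray(sigma_values, dtype=float)
    sl = np.asarray(slopes, dtype=float)
    if sig.size != sl.size or sig.size < 3:
        raise DegenerateDataError("need >= 3 paired (sigma, slope) values")
    if np.ptp(sig) == 0 or np.ptp(sl) == 0:
        raise DegenerateDataError("correlation undefined for a constant variable")
    res = stats.pearsonr(sig, sl)
    return float(res.statistic), float(res.pvalue)
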