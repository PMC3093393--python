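"""Synthetic delayed-comparison experiments.

Generates trial tables matching the study designs this package analyses —
a first bar drawn uniformly in log scale from a pixel range, a second bar
differing by a signed fraction (or equal, on "impossible" trials), and an
optional interference flag marking trials on which a distracting secondary
task inflates the memory noise of the first bar — and simulates the
responses of Bayesian ideal observers, singly or as heterogeneous cohorts.

Trial tables are pandas DataFrames with columns
``subject_id, trial_index, l1_px, l2_px, is_impossible, interfered,
response`` (response: 1 = 'first longer', 2 = 'second longer', NA = not
yet simulated).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._exceptions import InvalidConfigError, InvalidParameterError
from .observer import ObserverParams, UniformLogPrior, _pfl_core, _tie_value

__all__ = [
    "TRIAL_COLUMNS",
    "TaskConfig",
    "SubjectModel",
    "ParamDistribution",
    "generate_trials",
    "simulate_responses",
    "generate_cohort",
]

TRIAL_COLUMNS = [
    "subject_id", "trial_index", "l1_px", "l2_px",
    "is_impossible", "interfered", "response",
]

DEFAULT_DELTAS = (-0.30, -0.15, -0.075, 0.075, 0.15, 0.30)


@dataclass(frozen=True)
class TaskConfig:
    """Design of one delayed comparison session.

    Defaults follow the standard task: first-bar lengths uniform in log
    scale on [150, 600] pixels, second bar differing by ±7.5/15/30%, half
    the trials "impossible" (equal lengths), 500 trials per subject.  The
    modified (interference) task sets ``interference_fraction = 0.5``.
    """

    range_px: tuple[float, float] = (150.0, 600.0)
    deltas: tuple[float, ...] = DEFAULT_DELTAS
    impossible_fraction: float = 0.5
    interference_fraction: float = 0.0
    n_trials: int = 500
    exact_counts: bool = False  # block to exact counts instead of Bernoulli draws

    def __post_init__(self):
        lo, hi = self.range_px
        if not (0 < lo < hi):
            raise InvalidConfigError(f"pixel range must satisfy 0 < lo < hi, got {self.range_px}")
        if not 0.0 <= self.impossible_fraction <= 1.0:
            raise InvalidConfigError("impossible_fraction must lie in [0, 1]")
        if not 0.0 <= self.interference_fraction <= 1.0:
            raise InvalidConfigError("interference_fraction must lie in [0, 1]")
        if self.n_trials < 1:
            raise InvalidConfigError("n_trials must be >= 1")
        if len(self.deltas) == 0 and self.impossible_fraction < 1.0:
            raise InvalidConfigError("empty delta set with impossible_fraction < 1")
        if any(d <= -1.0 for d in self.deltas):
            raise InvalidConfigError("deltas must exceed -1 (lengths stay positive)")

    @property
    def log_range(self) -> tuple[float, float]:
        return (math.log(self.range_px[0]), math.log(self.range_px[1]))

    @property
    def log_width(self) -> float:
        lo, hi = self.log_range
        return hi - lo

    def prior(self) -> UniformLogPrior:
        """The stimulus prior implied by the design (known-range observer)."""
        return UniformLogPrior(*self.log_range)


@dataclass(frozen=True)
class SubjectModel:
    """One simulated subject: observer noise plus the interference effect.

    The secondary task is modeled solely as inflated memory noise: on
    interfered trials sigma1 is multiplied by ``interference_multiplier``.
    """

    params: ObserverParams
    interference_multiplier: float = 1.0

    def __post_init__(self):
        if self.interference_multiplier < 1.0:
            raise InvalidParameterError("interference_multiplier must be >= 1")


def _draw_flags(n: int, fraction: float, rng: np.random.Generator, exact: bool) -> np.ndarray:
    if exact:
        k = int(round(n * fraction))
        flags = np.zeros(n, dtype=bool)
        flags[rng.permutation(n)[:k]] = True
        return flags
    return rng.random(n) < fraction


def generate_trials(
    cfg: TaskConfig,
    rng: np.random.Generator,
    subject_id: str = "s00",
) -> pd.DataFrame:
    """Generate one subject's trial sequence (responses absent).

    log(l1) is i.i.d. uniform on the log pixel range; impossible and
    interference flags are independent draws at the configured fractions
    (or exact-count blocks); non-impossible trials get
    ``l2 = l1 * (1 + delta)`` with delta uniform on the configured set.
    """
    n = cfg.n_trials
    log_lo, log_hi = cfg.log_range
    l1 = np.exp(rng.uniform(log_lo, log_hi, size=n))
    impossible = _draw_flags(n, cfg.impossible_fraction, rng, cfg.exact_counts)
    interfered = _draw_flags(n, cfg.interference_fraction, rng, cfg.exact_counts)
    l2 = l1.copy()
    n_diff = int(np.sum(~impossible))
    if n_diff:
        deltas = rng.choice(np.asarray(cfg.deltas, dtype=float), size=n_diff)
        l2[~impossible] = l1[~impossible] * (1.0 + deltas)
    return pd.DataFrame({
        "subject_id": subject_id,
        "trial_index": np.arange(n, dtype=np.int64),
        "l1_px": l1,
        "l2_px": l2,
        "is_impossible": impossible,
        "interfered": interfered,
        "response": pd.array([pd.NA] * n, dtype="Int64"),
    })


def simulate_responses(
    trials: pd.DataFrame,
    model: SubjectModel,
    prior: UniformLogPrior,
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Fill in the observer's responses for every trial.

    Per trial, representations ``R1 ~ N(log l1, s1^2)`` (with sigma1
    inflated by the interference multiplier on flagged trials) and
    ``R2 ~ N(log l2, sigma2^2)`` are drawn, the Bayesian decision rule is
    applied, and with probability ``lapse`` the report is replaced by a
    fair coin.  Deterministic under a fixed generator state.
    """
    p = model.params
    n = len(trials)
    out = trials.copy()
    l1 = np.log(trials["l1_px"].to_numpy(dtype=float))
    l2 = np.log(trials["l2_px"].to_numpy(dtype=float))
    interfered = trials["interfered"].to_numpy(dtype=bool)
    mult = np.where(interfered, model.interference_multiplier, 1.0)

    s2 = p.sigma2
    if math.isinf(p.sigma1):
        s1 = p.sigma1  # inf * finite multiplier is still inf
        r1 = l1
    else:
        s1 = p.sigma1 * mult
        r1 = l1 + (s1 * rng.standard_normal(n) if p.sigma1 > 0 else 0.0)
    r2 = l2 + (s2 * rng.standard_normal(n) if (s2 > 0 and not math.isinf(s2)) else 0.0)
    if math.isinf(s2):
        r2 = l2

    if p.sigma1 == 0 and s2 == 0:
        ties = r1 == r2
        cmp_p = np.where(r1 > r2, 1.0, 0.0)
        cmp_p[ties] = 0.5
    else:
        if math.isinf(p.sigma1):
            s1_arg: float | np.ndarray = math.inf
        elif p.sigma1 == 0:
            s1_arg = 0.0
        elif np.all(mult == 1.0):
            s1_arg = float(p.sigma1)
        else:
            s1_arg = s1  # per-trial sigma1 (interference inflation)
        cmp_p = np.asarray(_pfl_core(r1, r2, s1_arg, s2, prior), dtype=float)

    first = cmp_p > 0.5
    tie_mask = cmp_p == 0.5
    if np.any(tie_mask):
        if p.tie_break == "random":
            first = first.copy()
            first[tie_mask] = rng.random(int(np.sum(tie_mask))) < 0.5
        # report_second_longer: leave as False
    resp = np.where(first, 1, 2)
    if p.lapse > 0:
        lapse_mask = rng.random(n) < p.lapse
        coin = rng.integers(1, 3, size=n)
        resp = np.where(lapse_mask, coin, resp)
    out["response"] = pd.array(resp, dtype="Int64")
    return out


@dataclass(frozen=True)
class ParamDistribution:
    """Per-subject parameter draws for cohort simulation.

    Each of ``sigma1``, ``sigma2`` and ``interference_multiplier`` is a
    constant or a ``(low, high)`` interval sampled uniformly per subject.
    Sigmas are expressed in units of the normalized log range (the scale on
    which fits are reported); they are converted to log units with the task's
    log width at simulation time.  Defaults are the operating point the
    analyses target: sigma1/sigma2 = 0.26/0.20 — a memory/probe noise
    ratio of 1.3.
    """

    sigma1: float | tuple[float, float] = 0.26
    sigma2: float | tuple[float, float] = 0.20
    interference_multiplier: float | tuple[float, float] = 1.0
    lapse: float = 0.0
    tie_break: str = "random"
    units: str = "normalized"  # or "log"

    def __post_init__(self):
        if self.units not in ("normalized", "log"):
            raise InvalidParameterError("units must be 'normalized' or 'log'")

    def draw(self, rng: np.random.Generator) -> tuple[float, float, float]:
        def _one(v):
            if isinstance(v, tuple):
                return float(rng.uniform(*v))
            return float(v)
        return _one(self.sigma1), _one(self.sigma2), _one(self.interference_multiplier)


def generate_cohort(
    n_subjects: int,
    cfg: TaskConfig,
    dist: ParamDistribution | None = None,
    seed: int | np.random.SeedSequence = 0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate a cohort of Bayesian observers on a common task design.

    Returns ``(trials, truth)``: the concatenated trial table and a
    per-subject table of the true generating parameters (for parameter
    recovery).  One master seed; per-subject substreams are spawned from
    it so cohorts of different sizes share their leading subjects.
    """
    if n_subjects < 1:
        raise InvalidParameterError("n_subjects must be >= 1")
    dist = dist or ParamDistribution()
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    param_ss, *subj_ss = ss.spawn(n_subjects + 1)
    param_rng = np.random.default_rng(param_ss)
    prior = cfg.prior()
    scale = cfg.log_width if dist.units == "normalized" else 1.0

    tables, truth_rows = [], []
    for i in range(n_subjects):
        sid = f"s{i:02d}"
        s1_n, s2_n, mult = dist.draw(param_rng)
        params = ObserverParams(sigma1=s1_n * scale, sigma2=s2_n * scale,
                                tie_break=dist.tie_break, lapse=dist.lapse)
        model = SubjectModel(params=params, interference_multiplier=mult)
        rng = np.random.default_rng(subj_ss[i])
        trials = generate_trials(cfg, rng, subject_id=sid)
        tables.append(simulate_responses(trials, model, prior, rng))
        truth_rows.append({
            "subject_id": sid,
            "sigma1_log": params.sigma1,
            "sigma2_log": params.sigma2,
            "sigma1_norm": params.sigma1 / cfg.log_width,
            "sigma2_norm": params.sigma2 / cfg.log_width,
            "interference_multiplier": mult,
            "lapse": dist.lapse,
        })
    trials = pd.concat(tables, ignore_index=True)
    truth = pd.DataFrame(truth_rows)
    return trials, truth
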