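"""Bayesian ideal observer for delayed comparison of two magnitudes.

The observer sees two bars in sequence and reports which was longer.
Lengths are carried as natural logarithms of pixel lengths (Weber's law),
and the internal representation of bar ``i`` is ``R_i = L_i + z_i`` with
``z_i ~ N(0, sigma_i^2)``.  The stimulus prior is uniform on an interval of
log length.  Bayes' rule then gives a truncated-Gaussian posterior for each
bar, the observer computes ``P(L1 > L2 | R1, R2)`` from the two posteriors,
and reports 'first longer' whenever that probability exceeds one half.

Because the first bar must be held in memory across the delay, its noise
``sigma1`` typically exceeds ``sigma2``; the prior then pulls the first
bar's posterior toward the centre of the range more strongly than the
second bar's, which is the contraction bias.

All probabilities returned here are dimensionless in [0, 1]; all lengths
are log pixels.  Degenerate noise levels (``sigma = 0`` and
``sigma = inf``) are handled by exact closed-form branches, never by
limiting numerics.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from functools import lru_cache

import numpy as np
from scipy.interpolate import PchipInterpolator
from scipy.optimize import elementwise
from scipy.special import ndtr, ndtri

from ._exceptions import InvalidParameterError, NoRootError
from .curves import ResponseCurve

__all__ = [
    "UniformLogPrior",
    "ObserverParams",
    "Representation",
    "PosteriorSpec",
    "posterior_density",
    "posterior_cdf",
    "prob_first_longer",
    "decide",
    "decision_boundary",
    "response_probability",
    "model_response_curve",
]

# Default quadrature orders: Gauss-Legendre over the truncated support for
# the comparison probability, Gauss-Hermite over representation noise for
# the response probability.  Both are overridable per call.
GL_ORDER = 200
GH_ORDER = 100

# Gaussian mass beyond 8 SD is ~1e-15; used to localize quadrature windows.
_WINDOW_SD = 8.0

_SQRT2 = math.sqrt(2.0)
_INV_SQRTPI = 1.0 / math.sqrt(math.pi)
_INV_SQRT2PI = 1.0 / math.sqrt(2.0 * math.pi)

Representation = float
"""A noisy internal representation of a log length (finite real)."""


@lru_cache(maxsize=8)
def _leggauss(n: int):
    return np.polynomial.legendre.leggauss(n)


@lru_cache(maxsize=8)
def _hermgauss(n: int):
    x, w = np.polynomial.hermite.hermgauss(n)
    return x, w * _INV_SQRTPI  # weights for E[f(Z)] with Z standard normal / sqrt(2)


@dataclass(frozen=True)
class UniformLogPrior:
    """Uniform prior over log bar length on ``[lo, hi]`` (log pixels)."""

    lo: float
    hi: float

    def __post_init__(self):
        if not (np.isfinite(self.lo) and np.isfinite(self.hi)):
            raise InvalidParameterError("prior bounds must be finite")
        if not self.lo < self.hi:
            raise InvalidParameterError(f"prior requires lo < hi, got [{self.lo}, {self.hi}]")

    @property
    def width(self) -> float:
        return self.hi - self.lo

    @property
    def median(self) -> float:
        return 0.5 * (self.lo + self.hi)

    def density(self, x):
        x = np.asarray(x, dtype=float)
        return np.where((x >= self.lo) & (x <= self.hi), 1.0 / self.width, 0.0)

    def cdf(self, x):
        x = np.asarray(x, dtype=float)
        return np.clip((x - self.lo) / self.width, 0.0, 1.0)

    def shifted(self, c: float) -> "UniformLogPrior":
        return UniformLogPrior(self.lo + c, self.hi + c)


_TIE_BREAKS = ("random", "report_second_longer")


@dataclass(frozen=True)
class ObserverParams:
    """Noise parameters of the ideal observer.

    sigma1, sigma2
        SDs of the representation noise of the first (memorized) and
        second (probe) bar, in log units.  ``0`` and ``inf`` are legal.
    tie_break
        Policy at a comparison probability of exactly 0.5.
    lapse
        Probability of replacing the decision with a fair coin.
    """

    sigma1: float
    sigma2: float
    tie_break: str = "random"
    lapse: float = 0.0

    def __post_init__(self):
        if self.sigma1 < 0 or self.sigma2 < 0 or math.isnan(self.sigma1) or math.isnan(self.sigma2):
            raise InvalidParameterError("noise SDs must be >= 0")
        if not 0.0 <= self.lapse < 0.5:
            raise InvalidParameterError("lapse must lie in [0, 0.5)")
        if self.tie_break not in _TIE_BREAKS:
            raise InvalidParameterError(f"tie_break must be one of {_TIE_BREAKS}")


@dataclass(frozen=True)
class PosteriorSpec:
    """Posterior of a log length given representation ``r`` and noise ``sigma``."""

    r: float
    sigma: float
    prior: UniformLogPrior

    def __post_init__(self):
        if not np.isfinite(self.r):
            raise InvalidParameterError("representation must be finite")
        if self.sigma < 0 or math.isnan(self.sigma):
            raise InvalidParameterError("sigma must be >= 0")


# ---------------------------------------------------------------------------
# truncated-Gaussian primitives (vectorized, tail-safe)
# ---------------------------------------------------------------------------

def _phi_diff(b, a):
    """Phi(b) - Phi(a) for b >= a, avoiding cancellation in the upper tail."""
    return np.where(a > 0, ndtr(-a) - ndtr(-b), ndtr(b) - ndtr(a))


def _tg_cdf(x, r, sigma, lo, hi):
    """CDF at ``x`` of a Gaussian N(r, sigma^2) truncated to [lo, hi]."""
    a = (lo - r) / sigma
    b = (hi - r) / sigma
    z = _phi_diff(b, a)
    t = (np.clip(x, lo, hi) - r) / sigma
    num = _phi_diff(np.minimum(t, b), a)
    with np.errstate(divide="ignore", invalid="ignore"):
        out = num / z
    # z underflows only when r sits > ~38 SD outside the range: point mass
    # at the nearer boundary.
    fallback = np.where(x >= np.clip(r, lo, hi), 1.0, 0.0)
    return np.where(z > 0, np.clip(out, 0.0, 1.0), fallback)


def _tg_pdf(x, r, sigma, lo, hi):
    a = (lo - r) / sigma
    b = (hi - r) / sigma
    z = _phi_diff(b, a)
    t = (x - r) / sigma
    with np.errstate(divide="ignore", invalid="ignore"):
        dens = _INV_SQRT2PI * np.exp(-0.5 * t * t) / (sigma * z)
    inside = (x >= lo) & (x <= hi) & (z > 0)
    return np.where(inside, dens, 0.0)


def _tg_mean(r, sigma, lo, hi):
    a = (lo - r) / sigma
    b = (hi - r) / sigma
    z = _phi_diff(b, a)
    pa = _INV_SQRT2PI * np.exp(-0.5 * a * a)
    pb = _INV_SQRT2PI * np.exp(-0.5 * b * b)
    with np.errstate(divide="ignore", invalid="ignore"):
        m = r + sigma * (pa - pb) / z
    return np.where(z > 0, np.clip(m, lo, hi), np.clip(r, lo, hi))


def _tg_median(r, sigma, lo, hi):
    """Median of N(r, sigma^2) truncated to [lo, hi], accurate in both tails.

    The median t* (standardized) solves Phi(t*) = (Phi(a) + Phi(b)) / 2;
    evaluated through whichever tail keeps precision.  When the mass
    underflows entirely (r > ~38 SD outside the range) the median clips to
    the nearer boundary.
    """
    a = (lo - r) / sigma
    b = (hi - r) / sigma
    q = 0.5 * (ndtr(a) + ndtr(b))       # lower-tail form
    qc = 0.5 * (ndtr(-a) + ndtr(-b))    # upper-tail form
    with np.errstate(invalid="ignore"):
        t = np.where(q < 0.5, ndtri(q), -ndtri(qc))
    med = np.clip(r + sigma * t, lo, hi)
    saturated = (q <= 0.0) | (qc <= 0.0) | ~np.isfinite(t)
    return np.where(saturated, np.clip(r, lo, hi), med)


# ---------------------------------------------------------------------------
# posterior (Bayes' rule with a uniform prior)
# ---------------------------------------------------------------------------

def posterior_density(spec: PosteriorSpec, x):
    """Posterior density of the log length at ``x``.

    With a uniform prior the posterior is the Gaussian likelihood
    ``N(x; r, sigma^2)`` restricted to the prior support and renormalized.
    ``sigma = inf`` returns the prior density (the measurement carries no
    information); ``sigma = 0`` is a point mass, whose density is undefined
    at the continuum level — query :func:`posterior_cdf` instead.
    """
    x = np.asarray(x, dtype=float)
    prior = spec.prior
    if spec.sigma == 0:
        raise InvalidParameterError(
            "sigma=0 gives a point-mass posterior with no density; use posterior_cdf"
        )
    if np.isinf(spec.sigma):
        return prior.density(x)
    return _tg_pdf(x, spec.r, spec.sigma, prior.lo, prior.hi)


def posterior_cdf(spec: PosteriorSpec, x):
    """Cumulative posterior probability of the log length up to ``x``."""
    x = np.asarray(x, dtype=float)
    prior = spec.prior
    if spec.sigma == 0:
        point = min(max(spec.r, prior.lo), prior.hi)
        return np.where(x >= point, 1.0, 0.0)
    if np.isinf(spec.sigma):
        return prior.cdf(x)
    return _tg_cdf(x, spec.r, spec.sigma, prior.lo, prior.hi)


# ---------------------------------------------------------------------------
# comparison probability  P(L1 > L2 | R1, R2)
# ---------------------------------------------------------------------------

def _pfl_generic(r1, r2, s1, s2, prior: UniformLogPrior, n_quad: int):
    """Both noises finite and positive; 1-D quadrature over the L2 posterior.

    P = integral over l2 of p(l2 | r2) * (1 - F1(l2)) dl2, where F1 is the
    posterior CDF of L1.  The Gauss-Legendre window is localized to the
    effective support of the L2 posterior (mass outside < ~1e-14).
    """
    r1 = np.asarray(r1, dtype=float)
    r2 = np.asarray(r2, dtype=float)
    s1 = np.broadcast_to(np.asarray(s1, dtype=float), np.broadcast_shapes(r1.shape, r2.shape))
    lo, hi = prior.lo, prior.hi
    c2 = np.clip(r2, lo, hi)
    a = np.maximum(lo, c2 - _WINDOW_SD * s2)
    b = np.minimum(hi, c2 + _WINDOW_SD * s2)
    nodes, wts = _leggauss(n_quad)
    half = 0.5 * (b - a)
    mid = 0.5 * (a + b)
    x = mid[..., None] + half[..., None] * nodes
    p2 = _tg_pdf(x, r2[..., None], s2, lo, hi)
    f1 = _tg_cdf(x, r1[..., None], s1[..., None], lo, hi)
    p = half * np.sum(wts * p2 * (1.0 - f1), axis=-1)
    # if the L2 normalizer underflowed (r2 > ~38 SD outside the range) the
    # posterior is numerically a point mass at the nearer boundary
    z2 = _phi_diff((hi - r2) / s2, (lo - r2) / s2)
    if np.any(z2 <= 0):
        point = 1.0 - _tg_cdf(c2, r1, s1, lo, hi)
        p = np.where(z2 <= 0, point, p)
    return np.clip(p, 0.0, 1.0)


def _pfl_core(r1, r2, s1, s2, prior: UniformLogPrior, n_quad: int = GL_ORDER):
    """Vectorized P(L1 > L2 | R1, R2).

    ``s2`` must be scalar; ``s1`` may be an array (interference inflates
    sigma1 on a per-trial basis) but degenerate values (0, inf) are only
    supported as scalars.
    """
    lo, hi, w = prior.lo, prior.hi, prior.width
    r1 = np.asarray(r1, dtype=float)
    r2 = np.asarray(r2, dtype=float)
    s1_arr = np.asarray(s1, dtype=float)
    s1_scalar = s1_arr.ndim == 0
    s2 = float(s2)

    if s1_scalar and np.isinf(s1_arr) and np.isinf(s2):
        return np.broadcast_arrays(r1 * 0.0, r2 * 0.0)[0] + 0.5
    if s1_scalar and np.isinf(s1_arr):
        # posterior of L1 is the prior: P = P(U > L2) with U ~ prior
        if s2 == 0:
            e2 = np.clip(r2, lo, hi)
        else:
            e2 = _tg_mean(r2, s2, lo, hi)
        return np.clip(1.0 - (e2 - lo) / w, 0.0, 1.0) + 0.0 * r1
    if np.isinf(s2):
        if s1_scalar and s1_arr == 0:
            e1 = np.clip(r1, lo, hi)
        else:
            e1 = _tg_mean(r1, s1_arr, lo, hi)
        return np.clip((e1 - lo) / w, 0.0, 1.0) + 0.0 * r2
    if s2 == 0:
        c2 = np.clip(r2, lo, hi)
        if s1_scalar and s1_arr == 0:
            c1 = np.clip(r1, lo, hi)
            if np.any(c1 == c2):
                raise InvalidParameterError(
                    "sigma1 = sigma2 = 0 with equal representations: comparison "
                    "undefined except via tie_break downstream"
                )
            return np.where(c1 > c2, 1.0, 0.0)
        return 1.0 - _tg_cdf(c2, r1, s1_arr, lo, hi)
    if s1_scalar and s1_arr == 0:
        c1 = np.clip(r1, lo, hi)
        return _tg_cdf(c1, r2, s2, lo, hi) + 0.0 * r2
    return _pfl_generic(r1, r2, s1_arr, s2, prior, n_quad)


def prob_first_longer(
    r1: float,
    r2: float,
    params: ObserverParams,
    prior: UniformLogPrior,
    n_quad: int = GL_ORDER,
) -> float:
    """Probability that the first bar is longer, given both representations.

    Integrates the two independent posteriors over the half-plane
    ``l1 > l2`` by deterministic quadrature (closed forms in the degenerate
    noise limits).  The lapse rate and tie-break policy play no role here;
    they act downstream in :func:`decide`.
    """
    return float(_pfl_core(float(r1), float(r2), params.sigma1, params.sigma2, prior, n_quad))


_TIE_TOL = 1e-9  # quadrature noise floor: |p - 0.5| below this is a tie


def decide(
    r1: float,
    r2: float,
    params: ObserverParams,
    prior: UniformLogPrior,
    rng: np.random.Generator | None = None,
) -> str:
    """Single-trial report: 'first_longer' iff P(L1 > L2 | R1, R2) > 0.5.

    A tie (0.5 up to the quadrature noise floor) is resolved by the
    tie-break policy (default: a fair coin from the supplied generator).
    """
    try:
        p = prob_first_longer(r1, r2, params, prior)
    except InvalidParameterError:
        p = 0.5  # both sigmas zero with equal representations: pure tie
    if p > 0.5 + _TIE_TOL:
        return "first_longer"
    if p < 0.5 - _TIE_TOL:
        return "second_longer"
    if params.tie_break == "report_second_longer":
        return "second_longer"
    if rng is None:
        raise InvalidParameterError("tie_break='random' requires an rng at a tie")
    return "first_longer" if rng.random() < 0.5 else "second_longer"


# ---------------------------------------------------------------------------
# decision boundary
# ---------------------------------------------------------------------------

def _find_root_vec(f, lo_b, hi_b, args=(), xatol=1e-10):
    # f must be elementwise in x; companion arrays go through `args` so the
    # solver can shrink them along with its active set
    res = elementwise.find_root(f, (lo_b, hi_b), args=args,
                                tolerances=dict(xatol=xatol, fatol=1e-12))
    return np.asarray(res.x, dtype=float), np.asarray(res.success)


def decision_boundary(
    params: ObserverParams,
    prior: UniformLogPrior,
    r1_grid,
    n_quad: int = GL_ORDER,
    xatol: float = 1e-10,
) -> np.ndarray:
    """Locus of representation pairs where the comparison is ambivalent.

    For each ``r1`` in the grid, finds the ``r2`` at which
    ``P(L1 > L2 | r1, r2) = 0.5``; returns an (n, 2) array of (r1, r2)
    pairs.  With ``sigma1 > sigma2`` the slope of this locus (r2 against
    r1) is below 1: the noisier first representation is shrunk toward the
    prior centre more strongly.
    """
    s1, s2 = params.sigma1, params.sigma2
    if not (0 < s2 < math.inf and 0 < s1 < math.inf):
        raise InvalidParameterError("decision_boundary requires finite positive sigmas")
    r1 = np.atleast_1d(np.asarray(r1_grid, dtype=float))
    # P is strictly decreasing in r2, from ~1 (r2 far below range) to ~0.
    pad = _WINDOW_SD * max(s1, s2) + prior.width
    lo_b, hi_b = prior.lo - pad, prior.hi + pad

    def f(r2, r1_active):
        return _pfl_core(r1_active, r2, s1, s2, prior, n_quad) - 0.5

    root, ok = _find_root_vec(f, np.full_like(r1, lo_b), np.full_like(r1, hi_b),
                              args=(r1,), xatol=xatol)
    resid = np.abs(_pfl_core(r1, root, s1, s2, prior, n_quad) - 0.5)
    if not (np.all(ok) and np.all(resid < 1e-6)):
        raise NoRootError("boundary root not bracketed/converged for some r1 values")
    return np.column_stack([r1, root])


def _boundary_r1_of_r2(r2_values, s1, s2, prior: UniformLogPrior, n_quad: int = GL_ORDER):
    """For each r2, the r1 with comparison probability exactly 0.5.

    P is strictly increasing in r1 (the truncated-Gaussian family is
    stochastically increasing in its location), so the decision region is
    ``{r1 > boundary(r2)}``.
    """
    r2 = np.atleast_1d(np.asarray(r2_values, dtype=float))
    pad = _WINDOW_SD * max(s1, s2) + prior.width
    # outside the range the threshold r1 scales like (s1/s2)^2 times the
    # r2 offset (both posteriors collapse onto the boundary exponentially)
    ratio2 = max(s1 / s2, s2 / s1) ** 2
    span = ratio2 * np.max(np.abs(r2 - prior.median)) + pad

    def f(r1, r2_active):
        return _pfl_core(r1, r2_active, s1, s2, prior, n_quad) - 0.5

    for _ in range(6):
        lo_b = np.full_like(r2, prior.median - span)
        hi_b = np.full_like(r2, prior.median + span)
        root, ok = _find_root_vec(f, lo_b, hi_b, args=(r2,))
        if np.all(ok):
            return root
        span *= 4.0
    raise NoRootError("boundary root not bracketed for some r2 values")


def _build_boundary_interpolant(s1, s2, prior, r2_lo, r2_hi, n_grid=161, n_quad=GL_ORDER):
    """Monotone interpolant of the boundary r1(r2), or None if the computed
    boundary is not monotone (caller falls back to full 2-D quadrature)."""
    grid = np.linspace(r2_lo, r2_hi, n_grid)
    b = _boundary_r1_of_r2(grid, s1, s2, prior, n_quad)
    db = np.diff(b)
    if np.any(db < -1e-7):
        return None
    b = np.maximum.accumulate(b)  # remove root-finder jitter below tolerance
    # PCHIP needs strictly increasing ordinates only in x; ties in b are fine
    return PchipInterpolator(grid, b, extrapolate=True)


# ---------------------------------------------------------------------------
# response probability  P(report 'L1>L2' | L1, L2)
# ---------------------------------------------------------------------------

def _tie_value(params: ObserverParams) -> float:
    return 0.0 if params.tie_break == "report_second_longer" else 0.5


def _response_prob_core(l1, l2, params: ObserverParams, prior: UniformLogPrior,
                        gh_order: int, gl_order: int, boundary=None):
    """Vectorized decision probability before the lapse mixture.

    Marginalizes the deterministic Bayesian decision over the Gaussian
    representation noise.  Generic case: the decision region is
    ``{R1 > b(R2)}`` with ``b`` the 0.5-probability boundary, giving
    ``P = E_{R2}[1 - Phi((b(R2) - l1)/sigma1)]`` by Gauss-Hermite
    quadrature; degenerate noise levels use exact branches.
    """
    s1, s2 = params.sigma1, params.sigma2
    lo, hi, m = prior.lo, prior.hi, prior.median
    l1 = np.asarray(l1, dtype=float)
    l2 = np.asarray(l2, dtype=float)
    tie = _tie_value(params)

    if s1 == 0 and s2 == 0:
        if np.any(l1 == l2):
            raise InvalidParameterError("sigma1 = sigma2 = 0 requires l1 != l2")
        return np.where(np.clip(l1, lo, hi) > np.clip(l2, lo, hi), 1.0, 0.0)
    if np.isinf(s1) and np.isinf(s2):
        # every trial is an exact tie at comparison probability 0.5
        return np.full(np.broadcast_shapes(l1.shape, l2.shape), tie)
    if np.isinf(s1):
        if s2 == 0:
            out = np.where(l2 < m, 1.0, 0.0)
            return np.where(l2 == m, tie, out) + 0.0 * l1
        # report 'first longer' iff the L2 posterior mean is below the prior
        # median, i.e. iff R2 < median
        return ndtr((m - l2) / s2) + 0.0 * l1
    if np.isinf(s2):
        if s1 == 0:
            c1 = np.clip(l1, lo, hi)
            out = np.where(c1 > m, 1.0, 0.0)
            return np.where(c1 == m, tie, out) + 0.0 * l2
        return ndtr((l1 - m) / s1) + 0.0 * l2
    if s2 == 0:
        # R2 = l2 exactly; report first iff posterior median of L1 exceeds l2
        return _resp_sigma2_zero(l1, l2, s1, prior)
    if s1 == 0:
        return _resp_sigma1_zero(l1, l2, s2, prior)

    nodes, wts = _hermgauss(gh_order)
    r2 = l2[..., None] + _SQRT2 * s2 * nodes
    if boundary is None:
        boundary = _build_boundary_interpolant(
            s1, s2, prior, float(np.min(r2)), float(np.max(r2)), n_quad=gl_order
        )
    if boundary is None:  # non-monotone boundary: full 2-D quadrature
        return _resp_2d_fallback(l1, l2, s1, s2, prior, gh_order, gl_order, tie)
    b = boundary(r2)
    p = np.sum(wts * ndtr((l1[..., None] - b) / s1), axis=-1)
    return np.clip(p, 0.0, 1.0)


def _resp_sigma2_zero(l1, l2, s1, prior):
    """sigma2 = 0, 0 < sigma1 < inf.  The decision threshold in R1 solves
    median(posterior(R1)) = l2; the posterior median is strictly increasing
    in R1 with range (lo, hi)."""
    shape = np.broadcast_shapes(np.shape(l1), np.shape(l2))
    l1 = np.atleast_1d(l1)
    l2 = np.atleast_1d(l2)
    l1b, l2b = np.broadcast_arrays(l1, l2)
    out = np.empty(l1b.shape, dtype=float)
    lo, hi = prior.lo, prior.hi
    below = l2b <= lo
    above = l2b >= hi
    out[below] = 1.0
    out[above] = 0.0
    interior = ~(below | above)
    if np.any(interior):
        targets = l2b[interior]

        def f(r, t):
            return _tg_median(r, s1, lo, hi) - t

        lo_b = np.full(targets.shape, lo - 40.0 * (s1 + prior.width))
        hi_b = np.full(targets.shape, hi + 40.0 * (s1 + prior.width))
        root, ok = _find_root_vec(f, lo_b, hi_b, args=(targets,))
        if not np.all(ok):
            raise NoRootError("median threshold not bracketed")
        out[interior] = ndtr((l1b[interior] - root) / s1)
    return out.reshape(shape)


def _resp_sigma1_zero(l1, l2, s2, prior):
    """sigma1 = 0, 0 < sigma2 < inf (mirror case)."""
    shape = np.broadcast_shapes(np.shape(l1), np.shape(l2))
    l1 = np.atleast_1d(l1)
    l2 = np.atleast_1d(l2)
    l1b, l2b = np.broadcast_arrays(l1, l2)
    out = np.empty(l1b.shape, dtype=float)
    lo, hi = prior.lo, prior.hi
    c1 = np.clip(l1b, lo, hi)
    below = l1b <= lo
    above = l1b >= hi
    out[below] = 0.0
    out[above] = 1.0
    interior = ~(below | above)
    if np.any(interior):
        targets = c1[interior]

        def f(r, t):
            return _tg_median(r, s2, lo, hi) - t

        lo_b = np.full(targets.shape, lo - 40.0 * (s2 + prior.width))
        hi_b = np.full(targets.shape, hi + 40.0 * (s2 + prior.width))
        root, ok = _find_root_vec(f, lo_b, hi_b, args=(targets,))
        if not np.all(ok):
            raise NoRootError("median threshold not bracketed")
        out[interior] = ndtr((root - l2b[interior]) / s2)
    return out.reshape(shape)


def _resp_2d_fallback(l1, l2, s1, s2, prior, gh_order, gl_order, tie):
    nodes, wts = _hermgauss(gh_order)
    l1 = np.atleast_1d(l1)
    l2 = np.atleast_1d(l2)
    l1b, l2b = np.broadcast_arrays(l1, l2)
    out = np.empty(l1b.shape, dtype=float)
    for idx in np.ndindex(l1b.shape):
        r1 = l1b[idx] + _SQRT2 * s1 * nodes
        r2 = l2b[idx] + _SQRT2 * s2 * nodes
        p = _pfl_core(r1[:, None], r2[None, :], s1, s2, prior, gl_order)
        ind = np.where(p > 0.5, 1.0, np.where(p < 0.5, 0.0, tie))
        out[idx] = float(wts @ ind @ wts)
    return out


def response_probability(
    l1: float,
    l2: float,
    params: ObserverParams,
    prior: UniformLogPrior,
    gh_order: int = GH_ORDER,
    gl_order: int = GL_ORDER,
) -> float:
    """Probability that the observer reports 'first longer' on a trial with
    true log lengths ``l1``, ``l2`` (the decision marginalized over
    representation noise).  The lapse rate mixes the result with 0.5."""
    if params.sigma1 == 0 and params.sigma2 == 0 and l1 == l2:
        raise InvalidParameterError("sigma1 = sigma2 = 0 requires l1 != l2")
    p = float(_response_prob_core(np.asarray(float(l1)), np.asarray(float(l2)),
                                  params, prior, gh_order, gl_order))
    return (1.0 - params.lapse) * p + 0.5 * params.lapse


def model_response_curve(
    params: ObserverParams,
    prior: UniformLogPrior,
    grid,
    gh_order: int = GH_ORDER,
    gl_order: int = GL_ORDER,
    n_boundary: int = 161,
) -> ResponseCurve:
    """Model response curve on impossible trials (``l1 = l2 = l``).

    Evaluates the response probability along ``grid`` (log lengths inside
    the prior support) and returns a curve on normalized coordinates
    ``(l - lo)/(hi - lo)``.  With ``sigma1 > sigma2`` the curve decreases
    in ``l`` — the contraction-bias signature; with equal noise it is flat
    at 0.5, and in the no-memory limit it is a unit step at the prior
    median.
    """
    grid = np.atleast_1d(np.asarray(grid, dtype=float))
    if np.any(grid < prior.lo - 1e-12) or np.any(grid > prior.hi + 1e-12):
        raise InvalidParameterError("grid must lie within the prior support")
    s1, s2 = params.sigma1, params.sigma2
    boundary = None
    if 0 < s1 < math.inf and 0 < s2 < math.inf:
        nodes, _ = _hermgauss(gh_order)
        span = _SQRT2 * s2 * float(np.max(np.abs(nodes)))
        boundary = _build_boundary_interpolant(
            s1, s2, prior, float(np.min(grid)) - span, float(np.max(grid)) + span,
            n_grid=n_boundary, n_quad=gl_order,
        )
        p = _response_prob_core(grid, grid, params, prior, gh_order, gl_order,
                                boundary=boundary)
    else:
        p = _response_prob_core(grid, grid, params, prior, gh_order, gl_order)
    p = (1.0 - params.lapse) * p + 0.5 * params.lapse
    centers = (grid - prior.lo) / prior.width
    return ResponseCurve(bin_centers=centers, fractions=np.asarray(p, dtype=float))
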