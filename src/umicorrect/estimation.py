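"""Method-of-moments estimation of (E, D) from censored read counts.

Given the read counts of the UMIs that survived the error-correction
threshold T, the efficiency E and depth D are chosen so that the model's
T-censored mean and variance match the sample mean and variance.

For T = 0 the system inverts in closed form:

    D = m,    E = (1 - v') / (1 + v')   with  v' = (v - m) / m^2

(v' clamped to [0, 1]).  For T > 0 the system is solved numerically by
nested bracketed root-finding: the censored mean is strictly increasing in
D at fixed E, so D is solved by a 1-D bracketed search, and an outer
bracketed search over E drives the censored-variance residual to zero.

The fitted parameters yield the loss l = P(C < T), and the observed UMI
count is corrected for the molecules lost below the threshold as
n_tot = n_obs / (1 - l).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq

from .branching import FamilySizeDensity
from .readcount import ReadCountModel

__all__ = [
    "SampleMoments",
    "ParamEstimate",
    "CorrectedCount",
    "sample_moments",
    "fit_uncensored",
    "fit_censored",
    "estimate_loss",
    "correct_count",
]

#: Search domain for the depth parameter (reads per UMI).
D_BOUNDS = (1e-4, 1e6)

#: Convergence tolerances: parameters and residuals.
PARAM_TOL = 1e-6
RESID_TOL = 1e-8


@dataclass(frozen=True)
class SampleMoments:
    """Observed summary of the censored per-UMI read counts of one gene."""

    n_obs: int
    mean: float
    variance: float


@dataclass(frozen=True)
class ParamEstimate:
    efficiency: float
    depth: float
    converged: bool
    #: True when a parameter was clamped to the edge of the search domain
    #: (e.g. under-dispersed data pinning E at 1).
    at_boundary: bool


@dataclass(frozen=True)
class CorrectedCount:
    n_obs: int
    loss: float
    n_total: float


def sample_moments(counts, threshold: int = 0) -> SampleMoments:
    """Unbiased sample mean/variance of surviving read counts.

    ``counts`` must already be filtered to values >= threshold; with fewer
    than two observations the variance (and with none, the mean) is NaN.
    """
    c = np.asarray(counts, dtype=float)
    if c.size and threshold > 0 and c.min() < threshold:
        raise ValueError("counts below the threshold must be filtered upstream")
    n = int(c.size)
    mean = float(c.mean()) if n else math.nan
    var = float(c.var(ddof=1)) if n >= 2 else math.nan
    return SampleMoments(n, mean, var)


def fit_uncensored(m: float, v: float) -> ParamEstimate:
    """Closed-form moment inversion for uncensored counts (T = 0)."""
    if not m > 0:
        raise ValueError(f"sample mean must be > 0, got {m}")
    vprime = (v - m) / (m * m)
    clamped = not 0.0 <= vprime <= 1.0
    vprime = min(max(vprime, 0.0), 1.0)
    e = (1.0 - vprime) / (1.0 + vprime)
    return ParamEstimate(e, m, converged=True, at_boundary=clamped)


def _censored_mean_at(model: ReadCountModel, d: float, t: int) -> float:
    """Censored mean at depth d; degenerate tails map to the limit max(T,1)."""
    try:
        return model.with_depth(d).censored_moments(t)[0]
    except FloatingPointError:
        return float(max(t, 1))


def _solve_depth(
    model: ReadCountModel, m: float, t: int, xtol: float = 1e-14
) -> tuple[float, bool]:
    """Depth matching the censored mean m at the model's efficiency.

    The censored mean is strictly increasing in D, from max(T, 1) as D -> 0
    to infinity; returns (depth, at_boundary).
    """
    lo, hi = D_BOUNDS
    f_lo = _censored_mean_at(model, lo, t) - m
    if f_lo >= 0:
        return lo, True
    f_hi = _censored_mean_at(model, hi, t) - m
    if f_hi <= 0:
        return hi, True
    # the censored mean can be extremely flat in D under deep censoring,
    # so the inner solve runs at (near) machine precision; the cost is a
    # handful of extra bisection steps
    ld = brentq(
        lambda x: _censored_mean_at(model, math.exp(x), t) - m,
        math.log(lo),
        math.log(hi),
        xtol=xtol,
        rtol=4 * np.finfo(float).eps,
    )
    return math.exp(ld), False


def fit_censored(
    m: float,
    v: float,
    threshold: int,
    table: FamilySizeDensity,
) -> ParamEstimate:
    """Solve the censored moment equations for (E, D).

    If the observed moment pair lies outside the model's attainable region
    the estimate is clamped to the nearest boundary of the search domain
    (``at_boundary`` set, ``converged`` false).
    """
    t = int(threshold)
    if t == 0:
        return fit_uncensored(m, v)
    if not m > t - 1:
        raise ValueError(f"censored mean {m} unattainable with threshold {t}")
    if v < 0:
        raise ValueError("sample variance must be >= 0")

    cache: dict[float, tuple[float, bool]] = {}

    def var_residual(e: float, xtol: float = 1e-14) -> float:
        model = ReadCountModel(e, 1.0, table)
        d, d_clamped = _solve_depth(model, m, t, xtol=xtol)
        cache[e] = (d, d_clamped)
        try:
            cv = model.with_depth(d).censored_moments(t)[1]
        except FloatingPointError:
            cv = 0.0
        return cv - v

    # The residual is evaluated at every efficiency column of the table
    # first.  Under heavy censoring the residual curve between columns
    # carries the columns' independent Monte-Carlo noise and can show
    # spurious sign changes, so root refinement is restricted to the
    # bracket whose endpoint residual is smallest.
    nodes = [float(e) for e in table.e_grid]
    res = np.array([var_residual(e, xtol=1e-9) for e in nodes])

    best = int(np.argmin(np.abs(res)))
    if abs(res[best]) <= RESID_TOL:
        e_hat = nodes[best]
        boundary = best in (0, len(nodes) - 1)
        converged = True
    else:
        sign_change = np.nonzero(res[:-1] * res[1:] < 0)[0]
        if sign_change.size:
            end_mag = np.minimum(
                np.abs(res[sign_change]), np.abs(res[sign_change + 1])
            )
            i = int(sign_change[np.argmin(end_mag)])
            e_hat = brentq(
                lambda e: var_residual(e, xtol=1e-9),
                nodes[i],
                nodes[i + 1],
                xtol=1e-12,
                rtol=8.9e-16,
            )
            boundary, converged = False, True
        else:
            # moment pair outside the attainable region: clamp E to the
            # better-fitting edge of the search domain
            e_hat = nodes[0] if abs(res[0]) <= abs(res[-1]) else nodes[-1]
            boundary, converged = True, False

    var_residual(e_hat)  # polish D at full precision
    d_hat, d_clamped = cache[e_hat]
    return ParamEstimate(
        float(e_hat), float(d_hat), converged and not d_clamped,
        boundary or d_clamped,
    )


def estimate_loss(
    est: ParamEstimate, threshold: int, table: FamilySizeDensity
) -> float:
    """Loss P(C < T) implied by a fitted parameter estimate."""
    return ReadCountModel(est.efficiency, est.depth, table).loss(int(threshold))


def correct_count(n_obs: int, loss: float) -> CorrectedCount:
    """Scale the observed UMI count up by the estimated loss (n/(1-l))."""
    if not 0.0 <= loss < 1.0:
        raise ValueError(f"loss must lie in [0, 1), got {loss}")
    return CorrectedCount(int(n_obs), float(loss), n_obs / (1.0 - loss))
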