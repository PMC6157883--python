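"""James-Stein-type shrinkage of gene-specific loss estimates.

Raw per-gene loss estimates are noisy for genes with few observed UMIs.
Writing ``s`` for the between-gene variance of the true loss and ``u`` for
the proportionality constant of the estimator variance (assumed u / n for a
gene with n observed UMIs), the MSE-optimal convex combination of the raw
gene estimate and the library-wide estimate is

    l_shr = lambda * l_raw + (1 - lambda) * l_all,
    lambda = s / (s + u / n).

(s, u) are fitted by weighted least squares on the squared deviations
(l_raw - l_bar)^2, whose expectation is s + u/n, with weights
w(n) = n / (1 + n/100) that emphasise moderately observed genes.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np

__all__ = [
    "ShrinkagePrior",
    "regression_weight",
    "fit_prior",
    "shrinkage_lambda",
    "shrink",
]


@dataclass(frozen=True)
class ShrinkagePrior:
    """Library-level quantities driving the per-gene shrinkage weights."""

    loss_all: float  # library-wide loss estimate
    loss_bar: float  # unweighted mean of the valid raw gene losses
    s: float  # between-gene variance of the true loss
    u: float  # estimator-variance constant: Var(l_raw) ~ u / n_obs


def regression_weight(n) -> np.ndarray | float:
    """Regression weight w(n) = n / (1 + n/100).

    Grows linearly for small n and saturates at 100, concentrating the
    (s, u) regression on genes with a moderate number of observations.
    """
    n = np.asarray(n, dtype=float)
    if np.any(n < 0):
        raise ValueError("n must be >= 0")
    out = n / (1.0 + n / 100.0)
    return out if out.ndim else float(out)


def _wls_su(y: np.ndarray, x: np.ndarray, w: np.ndarray) -> tuple[float, float]:
    """Minimize sum w (y - s - u x)^2 subject to s, u >= 0 (clip & refit)."""
    design = np.column_stack((np.ones_like(x), x))
    sw = np.sqrt(w)
    coef, *_ = np.linalg.lstsq(design * sw[:, None], y * sw, rcond=None)
    s, u = coef
    if s < 0.0:
        s = 0.0
        denom = float(w @ (x * x))
        u = float(w @ (x * y)) / denom if denom > 0 else 0.0
    if u < 0.0:
        u = 0.0
        s = float(w @ y) / float(w.sum())
    return max(s, 0.0), max(u, 0.0)


def fit_prior(loss_raw, n_obs, loss_all: float) -> ShrinkagePrior:
    """Fit the shrinkage prior (s, u) from valid raw gene estimates.

    Parameters
    ----------
    loss_raw, n_obs
        Raw loss estimate and surviving-UMI count per gene, for the genes
        with a valid raw fit (entries with NaN loss are ignored).
    loss_all
        Library-wide loss estimate, the shrinkage target.
    """
    loss_raw = np.asarray(loss_raw, dtype=float)
    n_obs = np.asarray(n_obs, dtype=float)
    ok = np.isfinite(loss_raw) & (n_obs > 0)
    loss_raw, n_obs = loss_raw[ok], n_obs[ok]
    if loss_raw.size < 2 or np.unique(n_obs).size < 2:
        warnings.warn(
            "fewer than 2 valid raw estimates with distinct n_obs; "
            "falling back to pure global shrinkage (s = 0)",
            stacklevel=2,
        )
        loss_bar = float(loss_raw.mean()) if loss_raw.size else float(loss_all)
        return ShrinkagePrior(float(loss_all), loss_bar, 0.0, 0.0)
    loss_bar = float(loss_raw.mean())
    y = (loss_raw - loss_bar) ** 2
    x = 1.0 / n_obs
    w = regression_weight(n_obs)
    s, u = _wls_su(y, x, np.asarray(w))
    return ShrinkagePrior(float(loss_all), loss_bar, s, u)


def shrinkage_lambda(prior: ShrinkagePrior, n) -> np.ndarray | float:
    """Optimal shrinkage coefficient lambda = s / (s + u/n) for n UMIs."""
    n = np.asarray(n, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        denom = prior.s + prior.u / n
        lam = np.where(denom > 0, prior.s / np.where(denom > 0, denom, 1.0), 0.0)
    lam = np.where(n <= 0, 0.0, lam)
    out = np.clip(lam, 0.0, 1.0)
    return out if out.ndim else float(out)


def shrink(loss_raw, loss_all: float, lam) -> np.ndarray | float:
    """Convex combination lambda*l_raw + (1-lambda)*l_all, clamped to [0,1)."""
    loss_raw = np.asarray(loss_raw, dtype=float)
    lam = np.asarray(lam, dtype=float)
    if np.any((lam < 0) | (lam > 1)):
        raise ValueError("lambda must lie in [0, 1]")
    out = lam * loss_raw + (1.0 - lam) * loss_all
    out = np.clip(out, 0.0, math.nextafter(1.0, 0.0))
    return out if out.ndim else float(out)
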