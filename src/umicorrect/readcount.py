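"""Per-UMI read-count distribution: Poisson sampling of amplified families.

Sequencing is modelled as Poissonian sampling from the amplified library:
conditional on the normalized family size ``F`` of a UMI, its read count is
``C | F ~ Poisson(F * D)`` where ``D`` is the mean number of reads per UMI.
Marginally

    P(C = k) = integral_0^inf  Poisson(k; x D) f_F(x; E) dx,

evaluated by the midpoint rule on the pre-computed density grid.  Closed
forms exist for the first two moments: E(C) = D and
V(C) = D + D^2 (1-E)/(1+E).

An error-correction threshold ``T`` discards UMIs with fewer than T reads;
the observable distribution is then the T-censored version of C, and the
*loss* l = P(C < T) is the expected fraction of true molecules whose UMIs
are either unsequenced or filtered out.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq
from scipy.special import gammaln
from scipy.stats import poisson

from .branching import FamilySizeDensity

__all__ = ["ReadCountModel", "poisson_loss_baseline"]

#: Probabilities below this are clamped to zero.
PROB_FLOOR = 1e-300

#: Censored moments are refused when the surviving probability mass
#: P(C >= T) falls below this (the loss is then numerically 1).
MIN_TAIL_MASS = 1e-12


@dataclass(frozen=True)
class ReadCountModel:
    """Read-count distribution for one (efficiency, depth) parameter pair.

    The family-size density column for ``efficiency`` is extracted from the
    table once at construction; ``with_depth`` re-uses it, which keeps
    root-finding over D cheap.
    """

    efficiency: float
    depth: float
    table: FamilySizeDensity

    def __post_init__(self) -> None:
        if not self.depth > 0:
            raise ValueError(f"depth must be > 0, got {self.depth}")
        col = self.table.column(self.efficiency)  # validates the range
        w = col * self.table.widths
        x = self.table.x_mid
        object.__setattr__(self, "_weights", w)
        object.__setattr__(self, "_rates", self.depth * x)
        # quadrature moments of F: total mass and first two raw moments
        object.__setattr__(self, "_z", float(w.sum()))
        object.__setattr__(self, "_fm1", float(w @ x))
        object.__setattr__(self, "_fm2", float(w @ (x * x)))

    def with_depth(self, depth: float) -> "ReadCountModel":
        new = object.__new__(ReadCountModel)
        object.__setattr__(new, "efficiency", self.efficiency)
        object.__setattr__(new, "depth", float(depth))
        object.__setattr__(new, "table", self.table)
        if not depth > 0:
            raise ValueError(f"depth must be > 0, got {depth}")
        object.__setattr__(new, "_weights", self._weights)
        object.__setattr__(new, "_rates", depth * self.table.x_mid)
        object.__setattr__(new, "_z", self._z)
        object.__setattr__(new, "_fm1", self._fm1)
        object.__setattr__(new, "_fm2", self._fm2)
        return new

    # -- distribution ------------------------------------------------------

    def pmf(self, k):
        """P(C = k), midpoint-rule mixture of Poisson pmfs over the grid."""
        k = np.asarray(k)
        if np.any(k < 0):
            raise ValueError("read count k must be >= 0")
        kk = np.atleast_1d(k).astype(float)
        # Poisson pmf in log space (cheaper than scipy.stats for the small
        # k blocks the censored-moment path evaluates constantly)
        log_rates = np.log(self._rates)
        logp = (
            kk[:, None] * log_rates[None, :]
            - self._rates[None, :]
            - gammaln(kk + 1.0)[:, None]
        )
        vals = np.exp(logp) @ self._weights
        vals[vals < PROB_FLOOR] = 0.0
        return vals if k.ndim else float(vals[0])

    @property
    def total_mass(self) -> float:
        """Total probability mass under the quadrature measure (~1)."""
        return self._z

    def moments(self) -> tuple[float, float]:
        """Closed-form (mean, variance): D and D + D^2 (1-E)/(1+E)."""
        d, e = self.depth, self.efficiency
        return d, d + d * d * (1.0 - e) / (1.0 + e)

    def loss(self, threshold: int) -> float:
        """l = P(C < T), the expected fraction of molecules filtered out."""
        t = _check_threshold(threshold)
        if t == 0:
            return 0.0
        return float(min(self.pmf(np.arange(t)).sum(), 1.0))

    def censored_moments(self, threshold: int) -> tuple[float, float]:
        """Mean and variance of C conditional on C >= T.

        The infinite sums are rewritten as E(C) - sum_{k<T} k P(C=k) (and
        analogously for the second moment) so that only T pmf values are
        needed.  The total mass and uncensored moments entering the rewrite
        are taken under the same midpoint-rule quadrature as the pmf
        (E(C) = D m1, E(C^2) = D m1 + D^2 m2 with m1, m2 the quadrature
        moments of F), so the rewrite stays exact even when the surviving
        tail mass is comparable to the quadrature error.
        """
        t = _check_threshold(threshold)
        if t == 0:
            return self.moments()
        d = self.depth
        q_mean = d * self._fm1
        q_m2 = d * self._fm1 + d * d * self._fm2
        ks = np.arange(t)
        p = self.pmf(ks)
        tail = self._z - p.sum()
        if tail < MIN_TAIL_MASS:
            raise FloatingPointError(
                f"P(C >= {t}) < {MIN_TAIL_MASS:g} at (E={self.efficiency}, "
                f"D={self.depth}); loss is numerically 1"
            )
        m1 = (q_mean - (ks * p).sum()) / tail
        m2 = (q_m2 - (ks * ks * p).sum()) / tail
        return m1, max(m2 - m1 * m1, 0.0)

    def dump_pmf(self, path, tail_mass: float = 1e-10) -> None:
        """Write the pmf as two-column text (k, P(C=k)) for diagnostics."""
        p = self.pmf_series(tail_mass)
        with open(path, "w") as fh:
            fh.write("k\tprobability\n")
            for k, val in enumerate(p):
                fh.write(f"{k}\t{val:.6g}\n")

    def pmf_series(self, tail_mass: float = 1e-10) -> np.ndarray:
        """pmf values for k = 0, 1, ... until the tail is negligible.

        Accumulates until the cumulative mass exceeds ``1 - tail_mass`` and
        k has passed D + 10 sqrt(V(C)) (the low-efficiency right tail is
        heavy).
        """
        mean, var = self.moments()
        k_min = int(mean + 10.0 * math.sqrt(var))
        out = []
        cum = 0.0
        block = 0
        while True:
            ks = np.arange(block * 256, (block + 1) * 256)
            p = self.pmf(ks)
            out.append(p)
            cum += p.sum()
            block += 1
            if cum > 1.0 - tail_mass and ks[-1] >= k_min:
                break
            if ks[-1] > 10 * k_min + 10_000:  # safety stop
                break
        return np.concatenate(out)


def _check_threshold(t) -> int:
    ti = int(t)
    if ti != t or ti < 0:
        raise ValueError(f"threshold must be a non-negative integer, got {t}")
    return ti


def _censored_poisson_mean(lam: float, t: int) -> float:
    # sum_{k>=t} k pmf(k) = lam * P(C >= t-1), exact and cancellation-free
    tail = poisson.sf(t - 1, lam)
    if tail <= 0.0:
        return float(t)
    return lam * poisson.sf(t - 2, lam) / tail


def poisson_loss_baseline(censored_mean: float, threshold: int) -> float:
    """Loss estimated under a pure-Poisson read-count model.

    Fits the Poisson rate so that the T-censored Poisson mean matches the
    observed censored mean, then returns P(Poisson < T).  Equivalent to
    assuming 100% amplification efficiency; ignoring the family-size
    dispersion makes this a lower bound on the branching-model loss at the
    same censored mean, and it is known to underestimate real losses badly.
    """
    t = _check_threshold(threshold)
    if t == 0:
        return 0.0
    if not censored_mean > t - 1:
        raise ValueError(
            f"censored mean {censored_mean} unattainable with threshold {t}"
        )

    def resid(log_lam: float) -> float:
        return _censored_poisson_mean(math.exp(log_lam), t) - censored_mean

    lo, hi = math.log(1e-8), math.log(1e6)
    rlo, rhi = resid(lo), resid(hi)
    if rlo > 0 or rhi < 0:
        raise ValueError(
            f"no Poisson rate matches censored mean {censored_mean} at T={t}"
        )
    lam = math.exp(brentq(resid, lo, hi, xtol=1e-12, rtol=1e-14))
    return float(poisson.cdf(t - 1, lam))
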