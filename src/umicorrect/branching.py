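"""Galton-Watson model of PCR amplification.

PCR is modelled as a branching process: during each cycle every molecule of
a molecular family is duplicated independently with probability ``E`` (the
reaction *efficiency*).  Starting from a single UMI-labelled molecule the
family size after cycle ``i`` follows

    M_0 = 1,    M_i = M_{i-1} + Binomial(M_{i-1}, E),

with mean ``(1+E)^i`` and variance
``((1-E)/(1+E)) (1+E)^i ((1+E)^i - 1)``.  The rescaled family size
``M_i / (1+E)^i`` converges almost surely; its limit ``F`` (the *normalized
family size*, mean 1, variance ``(1-E)/(1+E)``) captures the shape of the
family-size distribution independently of the cycle count.  ``F`` has no
known closed-form density, so this module pre-computes it by simulation on a
grid of efficiencies and sizes and exposes a fast interpolable table used by
the read-count model downstream.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import CubicSpline

__all__ = [
    "simulate_family",
    "simulate_families",
    "family_moments",
    "simulate_normalized_family",
    "variance_F",
    "FamilySizeDensity",
    "build_density_table",
    "default_density_table",
    "default_x_grid",
    "default_e_grid",
]

#: Simulate the branching process until (1+E)^i exceeds this value; the
#: residual relative error of V[F] is then at most 1/CONVERGENCE_TARGET.
CONVERGENCE_TARGET = 1.0e4

#: Hard cap on the number of simulated PCR cycles (only relevant for
#: efficiencies far below the supported grid).
MAX_CYCLES = 2000


def _check_efficiency(e: float, positive: bool = False) -> float:
    e = float(e)
    low = 0.0
    if (e < low or e > 1.0) or (positive and e == 0.0):
        bound = "(0, 1]" if positive else "[0, 1]"
        raise ValueError(f"efficiency must lie in {bound}, got {e}")
    return e


def simulate_families(
    e: float, cycles: int, size: int, rng: np.random.Generator
) -> np.ndarray:
    """Draw ``size`` independent family sizes M_cycles (vectorized)."""
    e = _check_efficiency(e)
    if cycles < 0:
        raise ValueError("cycles must be >= 0")
    m = np.ones(size, dtype=np.int64)
    for _ in range(int(cycles)):
        m += rng.binomial(m, e)
    return m


def simulate_family(e: float, cycles: int, rng: np.random.Generator) -> int:
    """Family size of a single molecule after ``cycles`` PCR cycles."""
    return int(simulate_families(e, cycles, 1, rng)[0])


def family_moments(e: float, cycles: int) -> tuple[float, float]:
    """Exact mean and variance of the family size after ``cycles`` cycles.

    mean = (1+E)^i, variance = ((1-E)/(1+E)) (1+E)^i ((1+E)^i - 1).
    """
    e = _check_efficiency(e)
    if cycles < 0:
        raise ValueError("cycles must be >= 0")
    g = (1.0 + e) ** cycles
    mean = g
    var = (1.0 - e) / (1.0 + e) * g * (g - 1.0)
    return mean, var


def variance_F(e: float) -> float:
    """Variance (1-E)/(1+E) of the normalized family size F."""
    e = _check_efficiency(e, positive=True)
    return (1.0 - e) / (1.0 + e)


def _cycles_to_convergence(e: float) -> int:
    return min(MAX_CYCLES, math.ceil(math.log(CONVERGENCE_TARGET) / math.log1p(e)))


def simulate_normalized_family(
    e: float, rng: np.random.Generator, size: int | None = None
):
    """Draw from the limiting normalized family size F = lim M_i/(1+E)^i.

    The process is run until ``(1+E)^i`` reaches :data:`CONVERGENCE_TARGET`,
    at which point the variance of the rescaled size is within a relative
    ``1/CONVERGENCE_TARGET`` of its limit (1-E)/(1+E).  ``E=0`` is rejected:
    the family never grows and the limit construction degenerates.
    """
    e = _check_efficiency(e, positive=True)
    n = 1 if size is None else int(size)
    cycles = _cycles_to_convergence(e)
    m = simulate_families(e, cycles, n, rng)
    f = m / (1.0 + e) ** cycles
    return float(f[0]) if size is None else f


def default_x_grid() -> np.ndarray:
    """Bin edges for the normalized-size axis.

    Width 0.01 on [0, 2] (offset so every integer-ish size, in particular
    x=1, is a bin *midpoint*), then geometrically widening bins up to 50.
    """
    fine = np.concatenate(([0.0], 0.005 + 0.01 * np.arange(201)))
    edges = [fine]
    w, x = 0.01, fine[-1]
    tail = []
    while x < 50.0:
        w *= 1.06
        x = min(x + w, 50.0)
        tail.append(x)
    edges.append(np.asarray(tail))
    return np.concatenate(edges)


def default_e_grid() -> np.ndarray:
    """Supported efficiencies: 0.02 to 0.92 in steps of 0.02, then 0.005.

    The grid is refined above 0.92 because the two modes of the family-size
    density sharpen and shift quickly as E approaches 1, and a 0.02 spacing
    no longer interpolates them accurately.
    """
    coarse = np.round(np.arange(1, 47) * 0.02, 10)
    fine = np.round(0.92 + 0.005 * np.arange(1, 9), 10)
    finest = np.round(0.96 + 0.0025 * np.arange(1, 17), 10)
    return np.concatenate((coarse, fine, finest))


@dataclass
class FamilySizeDensity:
    """Pre-computed density f_F(x; E) of the normalized family size.

    Stored on a grid of efficiencies (rows) and bin midpoints along x
    (columns); ``densities[i, j]`` is the Monte-Carlo estimate of the
    density at ``(e_grid[i], x_mid[j])``.  Evaluation interpolates with a
    cubic spline across E and piecewise-linearly along x, clipped at 0;
    outside the x grid the density is 0, outside the E grid evaluation
    fails (no extrapolation).
    """

    e_grid: np.ndarray
    x_edges: np.ndarray
    densities: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.e_grid = np.asarray(self.e_grid, dtype=float)
        self.x_edges = np.asarray(self.x_edges, dtype=float)
        self.densities = np.asarray(self.densities, dtype=float)
        if self.densities.shape != (self.e_grid.size, self.x_edges.size - 1):
            raise ValueError("densities shape does not match grids")
        # off-node interpolation across E needs enough columns for a spline
        self._spline = (
            CubicSpline(self.e_grid, self.densities, axis=0)
            if self.e_grid.size >= 4
            else None
        )

    @property
    def x_mid(self) -> np.ndarray:
        return 0.5 * (self.x_edges[:-1] + self.x_edges[1:])

    @property
    def widths(self) -> np.ndarray:
        return np.diff(self.x_edges)

    def _check_e(self, e: float) -> float:
        e = float(e)
        if not (self.e_grid[0] <= e <= self.e_grid[-1]):
            raise ValueError(
                f"efficiency {e} outside table range "
                f"[{self.e_grid[0]}, {self.e_grid[-1]}]; no extrapolation"
            )
        return e

    def column(self, e: float) -> np.ndarray:
        """Density values over ``x_mid`` at efficiency ``e`` (interpolated)."""
        e = self._check_e(e)
        idx = np.searchsorted(self.e_grid, e)
        if idx < self.e_grid.size and self.e_grid[idx] == e:
            return self.densities[idx]
        if self._spline is None:
            raise ValueError(
                "table has fewer than 4 efficiency columns; only exact "
                "grid-node efficiencies can be evaluated"
            )
        return np.clip(self._spline(e), 0.0, None)

    def density(self, x, e: float):
        """Interpolated density f_F(x; E); 0 beyond the end of the x grid."""
        col = self.column(e)
        x = np.asarray(x, dtype=float)
        out = np.interp(x, self.x_mid, col, left=col[0], right=0.0)
        out = np.where(x > self.x_edges[-1], 0.0, out)
        if np.any(x < 0):
            raise ValueError("normalized family size x must be >= 0")
        return out if out.ndim else float(out)

    def cdf(self, x, e: float):
        """CDF of F at efficiency ``e`` via midpoint-rule accumulation."""
        col = self.column(e)
        cum = np.concatenate(([0.0], np.cumsum(col * self.widths)))
        return np.interp(np.asarray(x, dtype=float), self.x_edges, cum)

    def sample(self, e: float, size: int, rng: np.random.Generator) -> np.ndarray:
        """Inverse-CDF draws of F (uniform within bins) at efficiency ``e``."""
        col = self.column(e)
        mass = col * self.widths
        cum = np.cumsum(mass)
        total = cum[-1]
        u = rng.random(size) * total
        j = np.searchsorted(cum, u, side="right")
        j = np.minimum(j, mass.size - 1)
        prev = np.where(j > 0, cum[j - 1], 0.0)
        frac = np.where(mass[j] > 0, (u - prev) / mass[j], 0.5)
        return self.x_edges[j] + frac * self.widths[j]

    # -- persistence -------------------------------------------------------

    def save(self, path) -> None:
        """Write a self-describing tab-separated text file (lossless)."""
        with open(path, "w") as fh:
            fh.write("# umicorrect family-size density table v1\n")
            for key, val in sorted(self.meta.items()):
                fh.write(f"# meta\t{key}\t{val}\n")
            fh.write(
                "# e_grid\t" + "\t".join(repr(float(v)) for v in self.e_grid) + "\n"
            )
            fh.write(
                "# x_edges\t"
                + "\t".join(repr(float(v)) for v in self.x_edges)
                + "\n"
            )
            for row in self.densities:
                fh.write("\t".join(repr(float(v)) for v in row) + "\n")

    @classmethod
    def load(cls, path) -> "FamilySizeDensity":
        meta: dict = {}
        e_grid = x_edges = None
        rows = []
        with open(path) as fh:
            for line in fh:
                line = line.rstrip("\n")
                if line.startswith("# meta\t"):
                    _, key, val = line.split("\t", 2)
                    meta[key] = val
                elif line.startswith("# e_grid\t"):
                    e_grid = np.array([float(v) for v in line.split("\t")[1:]])
                elif line.startswith("# x_edges\t"):
                    x_edges = np.array([float(v) for v in line.split("\t")[1:]])
                elif line.startswith("#"):
                    continue
                else:
                    rows.append([float(v) for v in line.split("\t")])
        if e_grid is None or x_edges is None:
            raise ValueError(f"{path}: missing e_grid/x_edges header")
        return cls(e_grid, x_edges, np.array(rows), meta)


def build_density_table(
    e_grid=None,
    x_edges=None,
    replicates: int = 1_000_000,
    rng: np.random.Generator | None = None,
    seed: int | None = None,
) -> FamilySizeDensity:
    """Monte-Carlo estimate of f_F(x; E) on a grid of efficiencies.

    For each efficiency the branching process is simulated ``replicates``
    times until convergence of the rescaled size, and the draws are binned
    on ``x_edges`` (density = count / (replicates * bin width)).

    Parameters
    ----------
    replicates
        Draws per efficiency.  At least 1e4; the default resolves the
        narrow bimodal structure at high efficiencies.
    """
    if e_grid is None:
        e_grid = default_e_grid()
    if x_edges is None:
        x_edges = default_x_grid()
    e_grid = np.asarray(e_grid, dtype=float)
    x_edges = np.asarray(x_edges, dtype=float)
    if np.any(e_grid <= 0) or np.any(e_grid > 1):
        raise ValueError("e_grid must lie within (0, 1]")
    if replicates < 10_000:
        raise ValueError(
            f"replicates={replicates} insufficient for a stable density grid "
            "(need >= 10000 per efficiency)"
        )
    if rng is None:
        rng = np.random.default_rng(seed)
    widths = np.diff(x_edges)
    dens = np.empty((e_grid.size, widths.size))
    for i, e in enumerate(e_grid):
        f = simulate_normalized_family(e, rng, size=replicates)
        counts, _ = np.histogram(f, bins=x_edges)
        dens[i] = counts / (replicates * widths)
    meta = {
        "replicates": replicates,
        "seed": seed,
        "convergence_target": CONVERGENCE_TARGET,
    }
    return FamilySizeDensity(e_grid, x_edges, dens, meta)


_DEFAULT_TABLE: FamilySizeDensity | None = None

#: Seed and size of the lazily built shared table; fixed so that results
#: are reproducible across runs without shipping a table file.
DEFAULT_TABLE_SEED = 424242
DEFAULT_TABLE_REPLICATES = 100_000


def default_density_table() -> FamilySizeDensity:
    """Shared density table, built once per process with a fixed seed."""
    global _DEFAULT_TABLE
    if _DEFAULT_TABLE is None:
        _DEFAULT_TABLE = build_density_table(
            replicates=DEFAULT_TABLE_REPLICATES, seed=DEFAULT_TABLE_SEED
        )
    return _DEFAULT_TABLE
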