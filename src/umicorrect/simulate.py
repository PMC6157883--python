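"""Synthetic UMI libraries drawn from the amplification + sequencing model.

Generates per-UMI read-count tables from the same generative model the
estimator assumes: per gene, each of ``n_true`` molecules receives an
independent normalized family size F (at the gene's efficiency) and a read
count Poisson(F * D).  UMIs with zero reads are unobservable and omitted
from the output table.  Optionally, *phantom* UMIs — artifacts with no
originating molecule, characterised by low read counts — are injected with
a truth label so that filtering can be evaluated.

Family sizes are drawn by inverse-CDF sampling from the pre-computed
density table rather than by re-running the branching process per UMI;
the two agree to Kolmogorov-Smirnov distance < 0.01.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .branching import FamilySizeDensity, default_density_table

__all__ = [
    "GeneScenario",
    "PhantomConfig",
    "simulate_gene_counts",
    "simulate_library",
    "depth_scaled_scenarios",
    "read_scenarios",
    "write_scenarios",
]


@dataclass(frozen=True)
class GeneScenario:
    """True molecule count and amplification parameters for one gene."""

    gene: str
    n_true: int
    efficiency: float
    depth: float

    def __post_init__(self) -> None:
        if self.n_true < 0:
            raise ValueError("n_true must be >= 0")


@dataclass(frozen=True)
class PhantomConfig:
    """Injection model for phantom UMIs (an artifact convention, not part
    of the mechanistic model: real phantom generation is not modelled,
    only their signature of markedly low read counts).

    ``rate`` is the expected number of phantoms per true molecule; read
    counts are geometric on {1, 2, ...} with the given mean.
    """

    rate: float = 0.2
    mean_reads: float = 1.5

    def __post_init__(self) -> None:
        if self.rate < 0:
            raise ValueError("rate must be >= 0")
        if self.mean_reads < 1:
            raise ValueError("mean_reads must be >= 1 (support starts at 1)")

    def sample_reads(self, size: int, rng: np.random.Generator) -> np.ndarray:
        return rng.geometric(1.0 / self.mean_reads, size=size)


def simulate_gene_counts(
    scn: GeneScenario,
    rng: np.random.Generator,
    table: FamilySizeDensity | None = None,
) -> np.ndarray:
    """Per-UMI read counts for one gene (length n_true, zeros included)."""
    if table is None:
        table = default_density_table()
    if scn.n_true == 0:
        return np.empty(0, dtype=np.int64)
    f = table.sample(scn.efficiency, scn.n_true, rng)
    return rng.poisson(f * scn.depth)


def simulate_library(
    scenarios,
    rng: np.random.Generator,
    phantoms: PhantomConfig | None = None,
    table: FamilySizeDensity | None = None,
) -> pd.DataFrame:
    """Simulate a UMI table (columns gene, umi, reads, phantom).

    True UMIs with zero reads are omitted (they are unobservable); phantom
    UMIs are appended per gene with Poisson(rate * n_true) multiplicity.
    The ``phantom`` column is the simulation truth label; writers of the
    canonical three-column table drop it.
    """
    if table is None:
        table = default_density_table()
    scenarios = list(scenarios)
    genes = [s.gene for s in scenarios]
    if len(set(genes)) != len(genes):
        raise ValueError("gene identifiers must be unique")
    frames = []
    for scn in scenarios:
        counts = simulate_gene_counts(scn, rng, table)
        idx = np.nonzero(counts > 0)[0]
        frames.append(
            pd.DataFrame(
                {
                    "gene": scn.gene,
                    "umi": [f"{scn.gene}:umi{i}" for i in idx],
                    "reads": counts[idx].astype(np.int64),
                    "phantom": False,
                }
            )
        )
        if phantoms is not None and phantoms.rate > 0:
            n_ph = int(rng.poisson(phantoms.rate * scn.n_true))
            reads = phantoms.sample_reads(n_ph, rng)
            frames.append(
                pd.DataFrame(
                    {
                        "gene": scn.gene,
                        "umi": [f"{scn.gene}:phantom{j}" for j in range(n_ph)],
                        "reads": reads.astype(np.int64),
                        "phantom": True,
                    }
                )
            )
    frames = [f for f in frames if len(f)]
    if not frames:
        return pd.DataFrame(
            {"gene": pd.Series(dtype=str), "umi": pd.Series(dtype=str),
             "reads": pd.Series(dtype=np.int64),
             "phantom": pd.Series(dtype=bool)}
        )
    return pd.concat(frames, ignore_index=True)


def depth_scaled_scenarios(scenarios, target_mean_depth: float):
    """Rescale all depths by a common factor to hit a target mean depth.

    Mirrors low-depth designs where gene-specific depths are scaled so the
    unweighted average across genes equals e.g. one read per molecule.
    """
    scenarios = list(scenarios)
    if not scenarios:
        raise ValueError("scenarios must be non-empty")
    mean_depth = sum(s.depth for s in scenarios) / len(scenarios)
    if mean_depth <= 0:
        raise ValueError("mean depth must be > 0")
    factor = target_mean_depth / mean_depth
    return [
        GeneScenario(s.gene, s.n_true, s.efficiency, s.depth * factor)
        for s in scenarios
    ]


def write_scenarios(scenarios, path) -> None:
    pd.DataFrame(
        [(s.gene, s.n_true, s.efficiency, s.depth) for s in scenarios],
        columns=["gene", "n_true", "efficiency", "depth"],
    ).to_csv(path, sep="\t", index=False)


def read_scenarios(path) -> list[GeneScenario]:
    df = pd.read_csv(path, sep="\t")
    required = {"gene", "n_true", "efficiency", "depth"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    return [
        GeneScenario(str(r.gene), int(r.n_true), float(r.efficiency), float(r.depth))
        for r in df.itertuples()
    ]
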