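import numpy as np
import pytest
from hypothesis import settings

from umicorrect import branching

settings.register_profile("repeatable", derandomize=True, deadline=None)
settings.load_profile("repeatable")

#: One seeded density table shared by the whole session.  100k replicates
#: per efficiency keeps the build under ~20 s while satisfying all table
#: invariants; tests needing tighter Monte-Carlo accuracy build small
#: single-node tables at 1e6 replicates via ``node_table``.
TABLE_SEED = 20260923
TABLE_REPLICATES = 100_000


@pytest.fixture(scope="session")
def density_table() -> branching.FamilySizeDensity:
    return branching.build_density_table(
        replicates=TABLE_REPLICATES, seed=TABLE_SEED
    )


@pytest.fixture(scope="session")
def node_table():
    """Factory for high-precision density tables at exact efficiencies.

    Single-column tables avoid interpolation error entirely, leaving only
    the (small) Monte-Carlo error of 1e6 draws; used as the model side of
    oracle-equivalence checks.
    """
    cache: dict = {}

    def make(e: float, replicates: int = 1_000_000) -> branching.FamilySizeDensity:
        key = (round(e, 6), replicates)
        if key not in cache:
            seed = int(round(e * 1_000_000)) % (2**31)
            cache[key] = branching.build_density_table(
                e_grid=[e], replicates=replicates, seed=seed
            )
        return cache[key]

    return make


def two_sample_ks(a: np.ndarray, b: np.ndarray) -> float:
    grid = np.sort(np.concatenate([a, b]))
    ca = np.searchsorted(np.sort(a), grid, side="right") / a.size
    cb = np.searchsorted(np.sort(b), grid, side="right") / b.size
    return float(np.abs(ca - cb).max())
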