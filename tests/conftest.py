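import numpy as np
import pandas as pd
import pytest

from hierflux import CountsSimConfig, HierarchySimConfig, simulate_counts
from hierflux.dominance import WinLossMatrix


@pytest.fixture
def steep_events():
    """Event stream from 5 near-deterministic hierarchies."""
    from hierflux import simulate_hierarchy_events

    cfg = HierarchySimConfig(n_groups=5, n_events_per_group=82, steepness=4.0, seed=3)
    return simulate_hierarchy_events(cfg)


@pytest.fixture
def null_events():
    """Exchangeable (steepness 0) event stream, 8 groups."""
    from hierflux import simulate_hierarchy_events

    cfg = HierarchySimConfig(n_groups=8, n_events_per_group=82, steepness=0.0, seed=9)
    return simulate_hierarchy_events(cfg)


@pytest.fixture
def small_counts():
    """2000-gene count matrix with 200 planted DES:DOM DEGs at |log2FC| = 1."""
    planted = [(g, "DES:DOM", 1.0 if g % 2 else -1.0) for g in range(200)]
    cfg = CountsSimConfig(n_genes=2000, planted_degs=planted, seed=11,
                          library_size_range=(800_000, 1_200_000))
    return simulate_counts(cfg)


def random_matrix(rng, n=4, max_events=6):
    W = rng.integers(0, max_events + 1, size=(n, n))
    np.fill_diagonal(W, 0)
    return WinLossMatrix(ids=[f"m{k}" for k in range(n)], W=W)
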