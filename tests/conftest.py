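import warnings

import numpy as np
import pytest

from geniche import synthdata

warnings.filterwarnings("ignore", category=FutureWarning)
warnings.filterwarnings("ignore", category=UserWarning)


@pytest.fixture(scope="session")
def clinal_ds():
    """Clinal landscape: 50 slope-2.5 adaptive loci among 500, 8 sites."""
    cfg = synthdata.LandscapeConfig(
        n_sites=8, inds_per_site=15, n_loci=500, n_adaptive=50,
        cline_slope=2.5, seed=1,
    )
    return synthdata.simulate_dataset(cfg)


@pytest.fixture(scope="session")
def null_ds():
    """No selection anywhere: cline slope 0, no adaptive loci."""
    cfg = synthdata.LandscapeConfig(
        n_sites=8, inds_per_site=25, n_loci=1000, n_adaptive=0,
        cline_slope=0.0, seed=7,
    )
    return synthdata.simulate_dataset(cfg)


@pytest.fixture(scope="session")
def two_island_ds():
    """Two strongly drifted populations (Balding-Nichols FST 0.3)."""
    cfg = synthdata.LandscapeConfig(
        n_sites=2, inds_per_site=30, n_loci=300, n_adaptive=0,
        cline_slope=0.0, fst_neutral=0.3, seed=3,
    )
    return synthdata.simulate_dataset(cfg)


def brute_force_bh(pvals):
    """Independent step-up BH for oracle comparisons."""
    p = np.asarray(pvals, dtype=float)
    n = len(p)
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * n / (np.arange(n) + 1)
    # step-up: running minimum from the largest rank down
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(n)
    out[order] = np.minimum(adj, 1.0)
    return out
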