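"""Shared fixtures and independent oracles for the test suite."""

import numpy as np
import pytest

from microsojourn.inference import AbundanceSeries


def brute_force_interior_runs(signs):
    """Independent oracle: scan maximal same-sign runs with a direct loop.

    Returns a list of (start, end, sign) index tuples for runs that are
    interior: an observation exists immediately before and after the run
    (necessarily with a different value, since runs are maximal).  Zero
    entries terminate runs and start none.
    """
    runs = []
    n = len(signs)
    i = 0
    while i < n:
        if signs[i] == 0:
            i += 1
            continue
        j = i
        while j + 1 < n and signs[j + 1] == signs[i]:
            j += 1
        if i > 0 and j < n - 1:
            runs.append((i, j + 1, signs[i]))
        i = j + 1
    return runs


def gamma_poisson_series(mean, cv, depth, n, seed, asv_id="asv", host_id="h"):
    """Synthetic reads with gamma latent abundance and Poisson sampling."""
    rng = np.random.default_rng(seed)
    x = rng.gamma(cv**-2, mean * cv**2, n)
    depths = np.full(n, int(depth))
    counts = np.minimum(rng.poisson(depths * x), depths)
    return AbundanceSeries(asv_id, np.arange(n), counts, depths, host_id)


@pytest.fixture
def rng():
    return np.random.default_rng(0)


@pytest.fixture(scope="session")
def dense_series():
    """A well-sampled gamma-Poisson series (mean counts ~100)."""
    return gamma_poisson_series(1e-2, 0.8, 1e4, 200, seed=11)
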