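import numpy as np
import pytest

from fetalhap.core import SiteTable
from fetalhap.simulate import SimParams, simulate_pedigree, simulate_plasma

SMALL_CHROMS = ("chr21", "chr22", "chrX")


@pytest.fixture(scope="session")
def small_params():
    """A three-chromosome genome at the default operating point."""
    return SimParams(n_autosomal_sites=12_000, n_chrx_sites=1_500,
                     chroms=SMALL_CHROMS, seed=11)


@pytest.fixture(scope="session")
def small_truth(small_params):
    return simulate_pedigree(small_params)


@pytest.fixture(scope="session")
def small_counts(small_params, small_truth):
    return simulate_plasma(small_truth, small_params)


@pytest.fixture()
def tiny_sites():
    """Ten autosomal sites on one chromosome."""
    n = 10
    pos = np.arange(1, n + 1) * 1000
    return SiteTable(["chr1"] * n, pos, ["A"] * n, ["G"] * n)


def enumerate_paths(log_emission, log_trans):
    """Brute-force path probabilities for a tiny HMM chain.

    Independent oracle for Viterbi and forward-backward: enumerates all
    S^T state paths under a uniform initial distribution and returns
    (paths, log-probabilities) as arrays.
    """
    import itertools

    T, S = log_emission.shape
    paths = np.array(list(itertools.product(range(S), repeat=T)), dtype=int)
    logp = np.full(len(paths), np.log(1.0 / S))
    for i, p in enumerate(paths):
        lp = logp[i] + log_emission[0, p[0]]
        for t in range(1, T):
            lp += log_trans[t - 1, p[t - 1], p[t]] + log_emission[t, p[t]]
        logp[i] = lp
    return paths, logp
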