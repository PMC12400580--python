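import numpy as np
import pytest

from formula_nettarget import (
    BenchmarkConfig,
    generate_benchmark,
    generate_deg_tables,
)


@pytest.fixture(scope="session")
def benchmark():
    """Default benchmark dataset at the pinned seed, shared across tests."""
    dataset, truth = generate_benchmark(BenchmarkConfig(seed=0))
    return dataset, truth


@pytest.fixture(scope="session")
def deg_pair():
    model, treatment, truth = generate_deg_tables(BenchmarkConfig(seed=0))
    return model, treatment, truth


# ---------------------------------------------------------------------------
# Independent oracles
# ---------------------------------------------------------------------------


def pbin_pmf_enumerated(p):
    """Poisson-binomial PMF by exhaustive subset enumeration (n <= ~16).

    Sums prod_{i in A} p_i * prod_{j not in A} (1-p_j) over every subset A,
    binned by |A| — the defining sum, independent of the convolution DP.
    """
    p = np.asarray(p, dtype=float)
    n = p.size
    out = np.zeros(n + 1)
    for mask in range(1 << n):
        prob = 1.0
        k = 0
        for i in range(n):
            if mask >> i & 1:
                prob *= p[i]
                k += 1
            else:
                prob *= 1.0 - p[i]
        out[k] += prob
    return out


def hypergeom_tail_bruteforce(N, K, n, k):
    """Upper-tail hypergeometric by direct binomial-coefficient summation."""
    from math import comb

    total = comb(N, n)
    acc = 0
    for i in range(k, min(K, n) + 1):
        acc += comb(K, i) * comb(N - K, n - i)
    return acc / total


def bh_adjust_stepup(pvals):
    """Hand-rolled BH step-up: p*m/rank then cumulative min from the top."""
    p = np.asarray(pvals, dtype=float)
    m = p.size
    order = np.argsort(p, kind="stable")
    adj = np.empty(m)
    running = 1.0
    for rank_from_top, idx in enumerate(order[::-1]):
        rank = m - rank_from_top
        running = min(running, p[idx] * m / rank)
        adj[idx] = running
    return adj
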