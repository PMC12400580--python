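"""Poisson-binomial recurrence statistic and holistic-target calling.

The network-target view holds that a formula's therapeutic effect lives in
a network of proteins recurrently targeted by its many constituent
compounds, not in a single target. Given each compound i an inclusion
probability p_i (the chance that a particular protein appears in that
compound's truncated target profile under the null), the number of profiles
K containing a given protein follows a Poisson-binomial distribution:

    P(K = k) = sum over k-subsets A of  prod_{i in A} p_i
                                        prod_{j not in A} (1 - p_j)

A protein observed in k_obs profiles is called a *holistic target* when the
upper tail P(K >= k_obs) is small after multiple-testing correction —
recurrence across compounds beyond what profile sizes alone explain.

The PMF is computed by the standard O(n^2) convolution recursion (each
compound contributes a Bernoulli factor), never by subset enumeration;
linear space is adequate because formulas have at most a few hundred
compounds, keeping the dynamic programme well-conditioned.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data_io import TargetProfile
from .enrichment import bh_adjust

__all__ = [
    "PriorModel",
    "HolisticTargetResult",
    "AccuracyResult",
    "pbin_pmf",
    "pbin_tail",
    "holistic_targets",
    "holistic_frame",
    "literature_accuracy",
]

#: Default background universe: approximate human protein-coding gene count.
DEFAULT_UNIVERSE_SIZE = 20000


@dataclass
class PriorModel:
    """Null inclusion probabilities p_i for each compound's profile.

    Under the default estimator p_i = |profile_i| / universe_size: a
    protein picked at random lands in a size-m profile drawn from a
    universe of N genes with probability m/N.
    """

    universe_size: int = DEFAULT_UNIVERSE_SIZE
    p: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.universe_size <= 0:
            raise ValueError("universe_size must be positive")
        for cid, pi in self.p.items():
            if not 0.0 <= pi <= 1.0:
                raise ValueError(
                    f"inclusion probability for {cid!r} outside [0,1]: {pi}"
                )

    @classmethod
    def from_profiles(
        cls,
        profiles: list[TargetProfile],
        universe_size: int = DEFAULT_UNIVERSE_SIZE,
    ) -> "PriorModel":
        p = {
            prof.compound_id: len(prof.targets) / universe_size
            for prof in profiles
        }
        return cls(universe_size=universe_size, p=p)


@dataclass(frozen=True)
class HolisticTargetResult:
    """Recurrence call for one gene across the compound profiles."""

    gene: str
    k_obs: int
    tail_p: float
    adjusted_p: float
    significant: bool


@dataclass(frozen=True)
class AccuracyResult:
    """Literature-coverage accuracy of one compound's predicted targets."""

    compound_id: str
    n_predicted: int
    n_supported: int
    accuracy_pct: float


# ---------------------------------------------------------------------------
# Poisson-binomial core
# ---------------------------------------------------------------------------


def pbin_pmf(p) -> np.ndarray:
    """Poisson-binomial PMF over 0..n successes for probabilities ``p``.

    Computed by iterated convolution with each Bernoulli(p_i) factor:
    after compound i, v[k] = v[k]*(1-p_i) + v[k-1]*p_i. O(n^2) time,
    O(n) space.
    """
    p = np.asarray(p, dtype=float)
    if p.ndim != 1:
        raise ValueError("p must be a 1-D sequence of probabilities")
    if p.size and (np.min(p) < 0.0 or np.max(p) > 1.0):
        raise ValueError("all probabilities must lie in [0, 1]")
    n = p.size
    v = np.zeros(n + 1)
    v[0] = 1.0
    for i, pi in enumerate(p):
        # in-place length-(i+2) update; reversed order avoids aliasing
        v[1 : i + 2] = v[1 : i + 2] * (1.0 - pi) + v[: i + 1] * pi
        v[0] *= 1.0 - pi
    return v


def pbin_tail(p, k: int) -> float:
    """Upper-tail probability P(K >= k) of the Poisson-binomial count."""
    p = np.asarray(p, dtype=float)
    if k < 0:
        raise ValueError(f"k must be non-negative, got {k}")
    n = p.size
    if k > n + 1:
        raise ValueError(f"k={k} exceeds n+1={n + 1}")
    if k == 0:
        return 1.0
    if k == n + 1:
        return 0.0
    pmf = pbin_pmf(p)
    # sum smallest terms first for accuracy in the far tail
    return float(np.sum(pmf[k:][::-1]))


def holistic_targets(
    profiles: list[TargetProfile],
    prior: PriorModel,
    alpha: float = 0.05,
    correction: str = "bh",
) -> list[HolisticTargetResult]:
    """Call holistic targets across compound target profiles.

    For every gene appearing in at least one profile, counts the number of
    profiles containing it (k_obs), computes the Poisson-binomial upper
    tail over all compounds' inclusion probabilities, applies the chosen
    multiple-testing correction across genes, and flags significance at
    ``alpha``. Results are sorted by (tail_p asc, k_obs desc, gene asc).
    """
    if not profiles:
        raise ValueError("holistic_targets requires at least one profile")
    if not 0.0 < alpha < 1.0:
        raise ValueError(f"alpha must lie in (0,1), got {alpha}")
    if correction not in ("bh", "none"):
        raise ValueError(f"unknown correction {correction!r}")
    missing = [
        prof.compound_id for prof in profiles if prof.compound_id not in prior.p
    ]
    if missing:
        raise ValueError(f"prior lacks inclusion probabilities for {missing}")

    p_vec = np.array([prior.p[prof.compound_id] for prof in profiles])
    counts: dict[str, int] = {}
    for prof in profiles:
        for gene in prof.gene_set:
            counts[gene] = counts.get(gene, 0) + 1

    # The prior is per-compound, so a single PMF serves every gene.
    pmf = pbin_pmf(p_vec)
    tail = np.concatenate([np.cumsum(pmf[::-1])[::-1], [0.0]])
    tail = np.minimum(tail, 1.0)

    genes = sorted(counts)
    tail_ps = np.array([tail[counts[g]] for g in genes])
    if correction == "bh":
        adj = np.asarray(bh_adjust(tail_ps))
    else:
        adj = tail_ps.copy()

    results = [
        HolisticTargetResult(
            gene=g,
            k_obs=counts[g],
            tail_p=float(tp),
            adjusted_p=float(ap),
            significant=bool(ap <= alpha),
        )
        for g, tp, ap in zip(genes, tail_ps, adj)
    ]
    results.sort(key=lambda r: (r.tail_p, -r.k_obs, r.gene))
    return results


def holistic_frame(results: list[HolisticTargetResult]) -> pd.DataFrame:
    """Tabulate holistic-target results for writing."""
    return pd.DataFrame(
        [
            {
                "gene": r.gene,
                "k_obs": r.k_obs,
                "tail_p": r.tail_p,
                "adjusted_p": r.adjusted_p,
                "significant": r.significant,
            }
            for r in results
        ],
        columns=["gene", "k_obs", "tail_p", "adjusted_p", "significant"],
    )


# ---------------------------------------------------------------------------
# Literature-coverage accuracy
# ---------------------------------------------------------------------------


def literature_accuracy(
    predicted: set[str] | frozenset[str],
    supported: set[str] | frozenset[str],
    compound_id: str = "",
) -> AccuracyResult:
    """Fraction of predicted targets with direct literature support.

    accuracy_pct = 100 * |predicted ∩ supported| / |predicted|. Indirect
    support through interaction paths is out of scope; only the direct
    intersection is counted.
    """
    if not predicted:
        raise ValueError("predicted target set is empty: accuracy undefined")
    n_pred = len(predicted)
    n_sup = len(set(predicted) & set(supported))
    return AccuracyResult(
        compound_id=compound_id,
        n_predicted=n_pred,
        n_supported=n_sup,
        accuracy_pct=100.0 * n_sup / n_pred,
    )
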