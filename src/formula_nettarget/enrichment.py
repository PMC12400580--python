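"""Hypergeometric over-representation testing and the syndrome screen.

Gene-set enrichment here is the classical one-sided hypergeometric (Fisher)
test: drawing n query genes from a background of N, the probability of
seeing at least k inside a K-gene set,

    p = P(i >= k) = sum_{i=k}^{min(K,n)} C(K,i) C(N-K, n-i) / C(N,n).

Two conventions coexist deliberately: syndrome screening of individual
compounds uses RAW p-values at the stated threshold, while pathway/function
enrichment applies Benjamini-Hochberg correction across the collection.

The screen nominates the formula's bioactive compounds group (BCG): a
compound qualifies when its profile is significantly enriched in at least
``min_syndromes`` syndrome gene sets AND it passes the provenance flag —
sourced from a sovereign (JUN) herb or carried as a pharmacopoeia
quality-control marker.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

from .data_io import (
    CompoundRecord,
    GeneSetCollection,
    HerbRecord,
    TargetProfile,
)

__all__ = [
    "EnrichmentResult",
    "ScreenMatrix",
    "ComparisonReport",
    "hypergeom_tail",
    "bh_adjust",
    "enrich_gene_sets",
    "screen_bcg",
    "compare_bcg_formula",
]


@dataclass(frozen=True)
class EnrichmentResult:
    """One hypergeometric gene-set test.

    N: background size; K: set genes within the background; n: query genes
    within the background; k: overlap between query and set.
    """

    set_name: str
    N: int
    K: int
    n: int
    k: int
    p_value: float
    adjusted_p: float


@dataclass
class ScreenMatrix:
    """Compound x syndrome screen with the recorded selection rule.

    ``results[compound_id][set_name]`` holds the full test; ``p_frame`` is
    the raw p-value matrix; ``selected_bcg`` lists the nominated compounds.
    """

    results: dict[str, dict[str, EnrichmentResult]]
    p_frame: pd.DataFrame
    selected_bcg: list[str]
    selection_rule: dict = field(default_factory=dict)


@dataclass
class ComparisonReport:
    """Set-level overlap between the BCG's and the whole formula's
    enriched collections."""

    shared: list[str]
    bcg_only: list[str]
    formula_only: list[str]
    per_set: pd.DataFrame  # set_name, p_bcg, adj_bcg, p_formula, adj_formula


# ---------------------------------------------------------------------------
# Primitives
# ---------------------------------------------------------------------------


def hypergeom_tail(N: int, K: int, n: int, k: int) -> float:
    """Exact upper-tail hypergeometric probability P(i >= k)."""
    if not 0 <= K <= N:
        raise ValueError(f"need 0 <= K <= N, got K={K}, N={N}")
    if not 0 <= n <= N:
        raise ValueError(f"need 0 <= n <= N, got n={n}, N={N}")
    if not 0 <= k <= min(K, n):
        raise ValueError(
            f"need 0 <= k <= min(K, n) = {min(K, n)}, got k={k}"
        )
    if k == 0:
        return 1.0
    return float(hypergeom.sf(k - 1, N, K, n))


def bh_adjust(p_values: Sequence[float]) -> list[float]:
    """Benjamini-Hochberg step-up adjusted p-values, input order preserved."""
    p = np.asarray(list(p_values), dtype=float)
    if p.size == 0:
        return []
    if np.min(p) < 0.0 or np.max(p) > 1.0:
        raise ValueError("p-values must lie in [0, 1]")
    _, adj, _, _ = multipletests(p, method="fdr_bh")
    return [float(x) for x in adj]


# ---------------------------------------------------------------------------
# Collection-level enrichment
# ---------------------------------------------------------------------------


def enrich_gene_sets(
    query: Iterable[str],
    collection: GeneSetCollection,
    background: set[str] | str | int = "auto",
) -> list[EnrichmentResult]:
    """Test a query gene list against every set in a collection.

    ``background`` may be an explicit gene set, the string "auto" (union of
    all collection genes and the query), or an integer universe size (in
    which case no intersection filtering is applied: K = |set|,
    n = |query|). BH adjustment runs across the whole collection; results
    are sorted by (adjusted_p, set_name).
    """
    query_set = {g for g in query}
    if isinstance(background, int):
        N = background
        eff_query = query_set
        set_sizes = {name: len(collection.genes(name)) for name in collection.names()}
        overlaps = {
            name: len(query_set & collection.genes(name))
            for name in collection.names()
        }
    else:
        if background == "auto":
            bg = set(collection.all_genes()) | query_set
        else:
            bg = set(background)
        N = len(bg)
        eff_query = query_set & bg
        set_sizes = {
            name: len(collection.genes(name) & bg)
            for name in collection.names()
        }
        overlaps = {
            name: len(eff_query & collection.genes(name))
            for name in collection.names()
        }
    if not eff_query:
        raise ValueError("query is empty after intersection with background")
    n = len(eff_query)
    names = sorted(collection.names())
    raw = [
        hypergeom_tail(N, set_sizes[name], n, overlaps[name])
        for name in names
    ]
    adj = bh_adjust(raw)
    results = [
        EnrichmentResult(
            set_name=name,
            N=N,
            K=set_sizes[name],
            n=n,
            k=overlaps[name],
            p_value=p,
            adjusted_p=a,
        )
        for name, p, a in zip(names, raw, adj)
    ]
    results.sort(key=lambda r: (r.adjusted_p, r.set_name))
    return results


# ---------------------------------------------------------------------------
# Syndrome screen
# ---------------------------------------------------------------------------


def screen_bcg(
    profiles: list[TargetProfile],
    syndromes: GeneSetCollection,
    compounds: list[CompoundRecord],
    herbs: list[HerbRecord],
    alpha: float = 0.05,
    min_syndromes: int = 1,
    background_size: int | None = None,
    require_flag: bool = True,
) -> ScreenMatrix:
    """Screen every compound's profile against the syndrome gene sets.

    A compound is selected into the BCG iff the number of syndromes with
    raw p < ``alpha`` is at least ``min_syndromes`` and (when
    ``require_flag``) the compound is a quality-control marker OR sourced
    from a JUN herb. The background defaults to the 20000-gene universe.
    ``require_flag=False`` reduces the screen to its statistical component,
    used e.g. for null calibration.
    """
    if not 0.0 < alpha < 1.0:
        raise ValueError(f"alpha must lie in (0,1), got {alpha}")
    if len(syndromes) == 0:
        raise ValueError("syndrome collection is empty")
    if min_syndromes < 0:
        raise ValueError("min_syndromes must be non-negative")
    from .network_target import DEFAULT_UNIVERSE_SIZE

    N = background_size if background_size is not None else DEFAULT_UNIVERSE_SIZE
    by_id = {c.compound_id: c for c in compounds}
    missing = [p.compound_id for p in profiles if p.compound_id not in by_id]
    if missing:
        raise ValueError(f"profiles reference unknown compounds {missing}")
    jun_herbs = {h.herb_id for h in herbs if h.role == "JUN"}

    set_names = sorted(syndromes.names())
    results: dict[str, dict[str, EnrichmentResult]] = {}
    p_rows = []
    selected: list[str] = []
    for prof in sorted(profiles, key=lambda p: p.compound_id):
        comp = by_id[prof.compound_id]
        n = len(prof.targets)
        row: dict[str, EnrichmentResult] = {}
        raw = []
        for name in set_names:
            genes = syndromes.genes(name)
            K = len(genes)
            k = len(prof.gene_set & genes)
            p = hypergeom_tail(N, K, n, k)
            row[name] = EnrichmentResult(
                set_name=name, N=N, K=K, n=n, k=k, p_value=p, adjusted_p=p
            )
            raw.append(p)
        results[prof.compound_id] = row
        p_rows.append(raw)
        n_sig = sum(p < alpha for p in raw)
        flag = comp.quality_control_marker or bool(
            set(comp.herb_ids) & jun_herbs
        )
        if n_sig >= min_syndromes and (flag or not require_flag):
            selected.append(prof.compound_id)

    p_frame = pd.DataFrame(
        p_rows,
        index=[p.compound_id for p in sorted(profiles, key=lambda p: p.compound_id)],
        columns=set_names,
    )
    rule = {
        "alpha": alpha,
        "min_syndromes": min_syndromes,
        "p_value_kind": "raw",
        "flag_logic": "quality_control_marker OR sourced-from-JUN",
        "require_flag": require_flag,
        "background_size": N,
    }
    return ScreenMatrix(
        results=results,
        p_frame=p_frame,
        selected_bcg=selected,
        selection_rule=rule,
    )


# ---------------------------------------------------------------------------
# BCG vs whole formula
# ---------------------------------------------------------------------------


def compare_bcg_formula(
    bcg_profiles: list[TargetProfile],
    all_profiles: list[TargetProfile],
    collection: GeneSetCollection,
    prior,
    alpha: float = 0.05,
) -> ComparisonReport:
    """Compare the BCG's and the whole formula's enriched gene sets.

    Runs holistic-target calling on each profile family, enriches both
    significant-gene lists against ``collection`` (BH within each family),
    and reports sets significant (adjusted p <= alpha) in both, in the BCG
    only, and in the formula only.
    """
    from .network_target import holistic_targets

    if not bcg_profiles:
        raise ValueError("bcg_profiles is empty")
    all_ids = {p.compound_id for p in all_profiles}
    stray = [p.compound_id for p in bcg_profiles if p.compound_id not in all_ids]
    if stray:
        raise ValueError(f"BCG compounds not in the formula: {stray}")

    def _sig_genes(profiles):
        res = holistic_targets(profiles, prior, alpha=alpha, correction="bh")
        genes = {r.gene for r in res if r.significant}
        if not genes:  # fall back to all profiled genes to keep the test defined
            genes = {r.gene for r in res}
        return genes

    enr_bcg = {
        r.set_name: r
        for r in enrich_gene_sets(
            _sig_genes(bcg_profiles), collection, background=prior.universe_size
        )
    }
    enr_all = {
        r.set_name: r
        for r in enrich_gene_sets(
            _sig_genes(all_profiles), collection, background=prior.universe_size
        )
    }
    sig_bcg = {n for n, r in enr_bcg.items() if r.adjusted_p <= alpha}
    sig_all = {n for n, r in enr_all.items() if r.adjusted_p <= alpha}
    per_set = pd.DataFrame(
        [
            {
                "set_name": name,
                "p_bcg": enr_bcg[name].p_value,
                "adj_bcg": enr_bcg[name].adjusted_p,
                "p_formula": enr_all[name].p_value,
                "adj_formula": enr_all[name].adjusted_p,
            }
            for name in sorted(collection.names())
        ]
    )
    return ComparisonReport(
        shared=sorted(sig_bcg & sig_all),
        bcg_only=sorted(sig_bcg - sig_all),
        formula_only=sorted(sig_all - sig_bcg),
        per_set=per_set,
    )
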