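"""Differential-expression filtering and expression-reversal analysis.

A gene is a DEG when |log2 fold change| > 1 and adjusted p < 0.05 (strict
inequalities, configurable cuts). Treatment *reverses* a gene when it is a
DEG in the disease-vs-control contrast and a DEG of opposite sign in the
treatment-vs-disease contrast — full DEG status in both contrasts, the
strict reading of reversal; ``trend=True`` relaxes the treatment-side cuts
to sign-only for exploration. Genes absent from either table are never
called reversed (no imputation).
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import pandas as pd

from .data_io import DEGTable, PPIEdgeList, normalize_gene
from .multilayer import MultiLayerNetwork


@dataclass
class ReversalResult:
    """Genes whose expression change the treatment reversed.

    ``records`` has one row per reversed gene: lfc_model, lfc_treatment,
    padj_model, padj_treatment.
    """

    reversed_genes: list[str]
    records: pd.DataFrame
    lfc_cut: float
    padj_cut: float


def filter_degs(
    table: DEGTable, lfc_cut: float = 1.0, padj_cut: float = 0.05
) -> DEGTable:
    """Keep rows with |log2FC| > lfc_cut and adjusted p < padj_cut."""
    if lfc_cut < 0:
        raise ValueError(f"lfc_cut must be non-negative, got {lfc_cut}")
    frame = table.frame
    kept = frame[
        (frame["log2_fold_change"].abs() > lfc_cut)
        & (frame["adjusted_p"] < padj_cut)
    ].reset_index(drop=True)
    return DEGTable(contrast_label=table.contrast_label, frame=kept)


def find_reversed(
    model_contrast: DEGTable,
    treatment_contrast: DEGTable,
    lfc_cut: float = 1.0,
    padj_cut: float = 0.05,
    trend: bool = False,
) -> ReversalResult:
    """Find genes the treatment reversed relative to the disease model.

    ``model_contrast`` must be oriented disease-vs-control and
    ``treatment_contrast`` treatment-vs-disease; identical contrast labels
    are rejected as an orientation mistake.
    """
    if model_contrast.contrast_label == treatment_contrast.contrast_label:
        raise ValueError(
            "both inputs carry the same contrast label "
            f"{model_contrast.contrast_label!r}: orientation mistake?"
        )
    model_degs = filter_degs(model_contrast, lfc_cut, padj_cut).frame
    if trend:
        treat = treatment_contrast.frame
    else:
        treat = filter_degs(treatment_contrast, lfc_cut, padj_cut).frame
    merged = model_degs.merge(
        treat, on="gene", suffixes=("_model", "_treatment")
    )
    rev = merged[
        merged["log2_fold_change_model"] * merged["log2_fold_change_treatment"]
        < 0
    ]
    rev = rev.sort_values("gene", kind="stable").reset_index(drop=True)
    records = pd.DataFrame(
        {
            "gene": rev["gene"],
            "lfc_model": rev["log2_fold_change_model"],
            "lfc_treatment": rev["log2_fold_change_treatment"],
            "padj_model": rev["adjusted_p_model"],
            "padj_treatment": rev["adjusted_p_treatment"],
        }
    )
    return ReversalResult(
        reversed_genes=list(records["gene"]),
        records=records,
        lfc_cut=lfc_cut,
        padj_cut=padj_cut,
    )


def map_to_network(
    genes: list[str],
    net: MultiLayerNetwork,
    ppi: PPIEdgeList,
    min_score: float = 0.7,
) -> nx.Graph:
    """Induce the subnetwork of ``genes`` plus their direct PPI neighbours
    within the target layer.

    Returns an undirected graph whose nodes carry ``status`` ("reversed"
    or "neighbor"); edges are the qualifying PPI edges among included
    nodes. Genes absent from the target layer become singletons only if
    they are in the query.
    """
    targets = set(net.nodes_in_layer("target"))
    query = {normalize_gene(g) for g in genes}
    sub = nx.Graph()
    for g in sorted(query):
        sub.add_node(g, status="reversed")
    qualifying = [
        (a, b, s) for a, b, s in ppi.edges if s >= min_score
    ]
    for a, b, _ in qualifying:
        if a in query and b in targets and b not in sub:
            sub.add_node(b, status="neighbor")
        if b in query and a in targets and a not in sub:
            sub.add_node(a, status="neighbor")
    included = set(sub.nodes)
    for a, b, score in qualifying:
        if a in included and b in included:
            sub.add_edge(a, b, weight=score)
    return sub
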