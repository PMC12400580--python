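"""Herb -> target -> function multilayer network construction and export.

The network has three node layers: herbs (annotated with their JUN / CHEN /
ZUO_SHI role), targets (gene symbols), and functions (gene sets, each
assigned a module class: cellular_process, immune_response,
signal_transduction, or unassigned). Edge types are constrained by layer:
herb_target (herb -> target), ppi (target -- target, confidence-filtered),
and target_function (target -> function).

Exports target Cytoscape-compatible formats: SIF (edge type as interaction
token), GraphML (all attributes), and a node-table/edge-table TSV pair that
round-trips losslessly.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import networkx as nx
import pandas as pd

from .data_io import DataIOError, GeneSetCollection, HerbRecord, PPIEdgeList

logger = logging.getLogger("formula_nettarget")

LAYERS = ("herb", "target", "function")
EDGE_TYPES = ("herb_target", "ppi", "target_function")
MODULE_CLASSES = (
    "cellular_process",
    "immune_response",
    "signal_transduction",
    "unassigned",
)

#: Keyword fallback for assigning function sets to module classes. The
#: tripartition in the source analysis is curated, so this is only a
#: default; an explicit mapping always wins.
DEFAULT_CLASS_KEYWORDS = (
    ("immun", "immune_response"),
    ("signal", "signal_transduction"),
    ("cell", "cellular_process"),
    ("cycle", "cellular_process"),
    ("prolif", "cellular_process"),
    ("apopto", "cellular_process"),
)

_ALLOWED_ENDPOINTS = {
    "herb_target": ("herb", "target"),
    "ppi": ("target", "target"),
    "target_function": ("target", "function"),
}


@dataclass
class MultiLayerNetwork:
    """Typed three-layer network.

    ``nodes`` maps node_id -> attribute dict (always containing "layer";
    herbs carry "role", functions carry "module_class"). ``edges`` is a
    list of (source, sink, edge_type, weight-or-None).
    """

    nodes: dict[str, dict] = field(default_factory=dict)
    edges: list[tuple[str, str, str, float | None]] = field(
        default_factory=list
    )
    build_report: dict = field(default_factory=dict)

    def add_node(self, node_id: str, layer: str, **attrs) -> None:
        if layer not in LAYERS:
            raise ValueError(f"unknown layer {layer!r}")
        self.nodes[node_id] = {"layer": layer, **attrs}

    def add_edge(
        self,
        source: str,
        sink: str,
        edge_type: str,
        weight: float | None = None,
    ) -> None:
        if edge_type not in EDGE_TYPES:
            raise ValueError(f"unknown edge_type {edge_type!r}")
        for endpoint in (source, sink):
            if endpoint not in self.nodes:
                raise ValueError(
                    f"edge endpoint {endpoint!r} is not a node"
                )
        want = _ALLOWED_ENDPOINTS[edge_type]
        got = (self.nodes[source]["layer"], self.nodes[sink]["layer"])
        if got != want:
            raise ValueError(
                f"{edge_type} edge must connect {want[0]}->{want[1]}, "
                f"got {got[0]}->{got[1]}"
            )
        self.edges.append((source, sink, edge_type, weight))

    def nodes_in_layer(self, layer: str) -> list[str]:
        return sorted(
            n for n, a in self.nodes.items() if a["layer"] == layer
        )

    def edges_of_type(self, edge_type: str) -> list[tuple]:
        return [e for e in self.edges if e[2] == edge_type]

    def validate(self) -> None:
        """Check layer bipartiteness and endpoint existence."""
        for source, sink, edge_type, _ in self.edges:
            want = _ALLOWED_ENDPOINTS[edge_type]
            got = (self.nodes[source]["layer"], self.nodes[sink]["layer"])
            if got != want:
                raise ValueError(
                    f"invalid {edge_type} edge {source}->{sink}: "
                    f"layers {got}"
                )

    def to_networkx(self) -> nx.DiGraph:
        g = nx.DiGraph()
        for node_id, attrs in self.nodes.items():
            g.add_node(node_id, **attrs)
        for source, sink, edge_type, weight in self.edges:
            attrs = {"edge_type": edge_type}
            if weight is not None:
                attrs["weight"] = weight
            g.add_edge(source, sink, **attrs)
        return g

    def __eq__(self, other) -> bool:
        if not isinstance(other, MultiLayerNetwork):
            return NotImplemented
        return self.nodes == other.nodes and sorted(
            self.edges, key=_edge_key
        ) == sorted(other.edges, key=_edge_key)


def _edge_key(e):
    source, sink, edge_type, weight = e
    return (edge_type, source, sink, -1.0 if weight is None else weight)


# ---------------------------------------------------------------------------
# Construction
# ---------------------------------------------------------------------------


def assign_module_class(
    set_name: str,
    module_classes: Mapping[str, str] | None,
    allow_unassigned: bool = False,
) -> str:
    """Resolve a function set's module class: explicit map, then keyword
    rules, then 'unassigned' (hard error unless allowed)."""
    if module_classes and set_name in module_classes:
        cls = module_classes[set_name]
        if cls not in MODULE_CLASSES:
            raise ValueError(
                f"unknown module class {cls!r} for set {set_name!r}"
            )
        return cls
    lowered = set_name.lower()
    for keyword, cls in DEFAULT_CLASS_KEYWORDS:
        if keyword in lowered:
            return cls
    if allow_unassigned:
        return "unassigned"
    raise ValueError(
        f"no module class for function set {set_name!r}; provide a mapping "
        f"or pass allow_unassigned"
    )


def build_multilayer(
    herbs: list[HerbRecord],
    herb_targets: Mapping[str, set[str] | frozenset[str]],
    ppi: PPIEdgeList,
    min_ppi_score: float = 0.7,
    function_annotations: GeneSetCollection | None = None,
    module_classes: Mapping[str, str] | None = None,
    allow_unassigned: bool = False,
) -> MultiLayerNetwork:
    """Assemble the herb -> target -> function network.

    The target layer is the union of ``herb_targets`` values. PPI edges are
    kept iff both endpoints are targets and score >= ``min_ppi_score``
    (0.7, the conventional high-confidence cutoff for STRING-style scores).
    Function genes absent from the target layer are skipped silently but
    counted in ``build_report``.
    """
    herb_by_id = {h.herb_id: h for h in herbs}
    unknown = [hid for hid in herb_targets if hid not in herb_by_id]
    if unknown:
        raise ValueError(f"herb_targets references unknown herbs {unknown}")

    net = MultiLayerNetwork()
    target_layer: set[str] = set()
    for genes in herb_targets.values():
        target_layer |= set(genes)
    for herb_id in sorted(herb_targets):
        herb = herb_by_id[herb_id]
        net.add_node(herb_id, "herb", role=herb.role, name=herb.name)
    for gene in sorted(target_layer):
        net.add_node(gene, "target")

    n_skipped = 0
    if function_annotations is not None:
        for set_name in sorted(function_annotations.names()):
            cls = assign_module_class(
                set_name, module_classes, allow_unassigned
            )
            genes = function_annotations.genes(set_name)
            covered = sorted(genes & target_layer)
            n_skipped += len(genes) - len(covered)
            net.add_node(set_name, "function", module_class=cls)
            for gene in covered:
                net.add_edge(gene, set_name, "target_function")

    for herb_id in sorted(herb_targets):
        for gene in sorted(set(herb_targets[herb_id])):
            net.add_edge(herb_id, gene, "herb_target")

    n_ppi_dropped = 0
    for a, b, score in ppi.edges:
        if score >= min_ppi_score and a in target_layer and b in target_layer:
            net.add_edge(a, b, "ppi", weight=score)
        else:
            n_ppi_dropped += 1

    net.build_report = {
        "n_herbs": len(herb_targets),
        "n_targets": len(target_layer),
        "n_functions": 0
        if function_annotations is None
        else len(function_annotations),
        "n_function_genes_skipped": n_skipped,
        "n_ppi_dropped": n_ppi_dropped,
        "min_ppi_score": min_ppi_score,
    }
    net.validate()
    return net


# ---------------------------------------------------------------------------
# Export / import
# ---------------------------------------------------------------------------


def export_network(
    net: MultiLayerNetwork, fmt: str, out_prefix: str | Path
) -> list[Path]:
    """Write the network as 'sif', 'graphml', or 'tsv_pair'.

    Returns the list of files written. The tsv_pair export (node table +
    edge table) is the lossless round-trip format.
    """
    out_prefix = Path(out_prefix)
    out_prefix.parent.mkdir(parents=True, exist_ok=True)
    if fmt == "sif":
        path = out_prefix.with_suffix(".sif")
        with open(path, "w", encoding="utf-8") as fh:
            for source, sink, edge_type, _ in sorted(
                net.edges, key=_edge_key
            ):
                fh.write(f"{source}\t{edge_type}\t{sink}\n")
        return [path]
    if fmt == "graphml":
        path = out_prefix.with_suffix(".graphml")
        nx.write_graphml(net.to_networkx(), path)
        return [path]
    if fmt == "tsv_pair":
        node_path = Path(str(out_prefix) + ".nodes.tsv")
        edge_path = Path(str(out_prefix) + ".edges.tsv")
        node_rows = [
            {
                "node_id": node_id,
                "layer": attrs["layer"],
                "role": attrs.get("role", ""),
                "module_class": attrs.get("module_class", ""),
                "name": attrs.get("name", ""),
            }
            for node_id, attrs in sorted(net.nodes.items())
        ]
        pd.DataFrame(
            node_rows,
            columns=["node_id", "layer", "role", "module_class", "name"],
        ).to_csv(node_path, sep="\t", index=False)
        edge_rows = [
            {
                "source": source,
                "sink": sink,
                "edge_type": edge_type,
                "weight": "" if weight is None else repr(weight),
            }
            for source, sink, edge_type, weight in sorted(
                net.edges, key=_edge_key
            )
        ]
        pd.DataFrame(
            edge_rows, columns=["source", "sink", "edge_type", "weight"]
        ).to_csv(edge_path, sep="\t", index=False)
        return [node_path, edge_path]
    raise ValueError(f"unknown export format {fmt!r}")


def import_network_tsv(out_prefix: str | Path) -> MultiLayerNetwork:
    """Rebuild a network from its tsv_pair export."""
    node_path = Path(str(out_prefix) + ".nodes.tsv")
    edge_path = Path(str(out_prefix) + ".edges.tsv")
    for p in (node_path, edge_path):
        if not p.exists():
            raise DataIOError(f"network table not found: {p}")
    net = MultiLayerNetwork()
    nodes = pd.read_csv(node_path, sep="\t", dtype=str, keep_default_na=False)
    for _, row in nodes.iterrows():
        attrs = {}
        if row["role"]:
            attrs["role"] = row["role"]
        if row["module_class"]:
            attrs["module_class"] = row["module_class"]
        if row["name"]:
            attrs["name"] = row["name"]
        net.add_node(row["node_id"], row["layer"], **attrs)
    edges = pd.read_csv(edge_path, sep="\t", dtype=str, keep_default_na=False)
    for _, row in edges.iterrows():
        weight = None if row["weight"] == "" else float(row["weight"])
        net.add_edge(row["source"], row["sink"], row["edge_type"], weight)
    net.validate()
    return net
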