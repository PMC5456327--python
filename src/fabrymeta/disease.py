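"""Disease-association ranking and regulatory-network overlay.

Diseases are ranked by the number of genes they share with a query list
(the statistic tabulated by DisGeNET-style shared-gene analyses); the
regulatory overlay restricts miRNA/TF -> target edge collections to
targets in the query and enforces the minimum-two-networks convention.

The package ships the curated DisGeNET v2.1 disease-gene association
tables for the Fabry-disease naive and ERT query sets as plain TSVs
under ``fabrymeta/data``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Iterable

import networkx as nx
import pandas as pd

from fabrymeta.errors import FormatError, ValidationError
from fabrymeta.io_formats import RegulatoryEdge, write_sif

logger = logging.getLogger(__name__)

_DATA_FILES = {
    "naive": "fabry_disease_associations_naive.tsv",
    "ERT": "fabry_disease_associations_ert.tsv",
}


@dataclass(frozen=True)
class DiseaseAssociation:
    """One disease with its annotated gene set."""

    disease_name: str
    gene_set: frozenset[str]

    def __post_init__(self) -> None:
        if not self.gene_set:
            raise ValidationError(
                f"disease {self.disease_name!r} has an empty gene set")


def read_disease_table(path: str | Path) -> list[DiseaseAssociation]:
    """Read a disease table: disease_name TAB comma-separated genes."""
    df = pd.read_csv(path, sep="\t", dtype=str, encoding="utf-8")
    for col in ("disease_name", "genes"):
        if col not in df.columns:
            raise FormatError(f"disease table {path} missing column {col!r}")
    out = []
    for row in df.itertuples(index=False):
        genes = frozenset(g.strip() for g in str(row.genes).split(",")
                          if g.strip())
        out.append(DiseaseAssociation(row.disease_name, genes))
    return out


def load_fabry_disease_table(group: str) -> list[DiseaseAssociation]:
    """Packaged DisGeNET v2.1 association table for one patient group."""
    if group not in _DATA_FILES:
        raise ValidationError(f"group must be one of {sorted(_DATA_FILES)}")
    ref = resources.files("fabrymeta") / "data" / _DATA_FILES[group]
    with resources.as_file(ref) as path:
        return read_disease_table(path)


def fabry_query_genes(group: str) -> frozenset[str]:
    """Disease-annotated query gene list for one patient group.

    The packaged tables list, per disease, its intersection with the
    group's query; the union of those intersections recovers the set of
    query genes that carry any disease annotation (25 genes for the
    naive group, 14 for ERT).
    """
    table = load_fabry_disease_table(group)
    return frozenset().union(*(d.gene_set for d in table))


def rank_shared_genes(
    query,
    diseases: Iterable[DiseaseAssociation],
) -> pd.DataFrame:
    """Rank diseases by the number of genes shared with the query.

    Only diseases sharing at least one gene appear; rows are sorted by
    descending shared_count with alphabetical disease_name tie-break,
    and shared_genes are alphabetical.
    """
    q = frozenset(query)
    if not q:
        raise ValidationError("query gene set is empty")
    rows = []
    for d in diseases:
        shared = sorted(q & d.gene_set)
        if shared:
            rows.append((d.disease_name, len(shared), ",".join(shared),
                         len(q)))
    out = pd.DataFrame(rows, columns=["disease_name", "shared_count",
                                      "shared_genes", "query_size"])
    return out.sort_values(["shared_count", "disease_name"],
                           ascending=[False, True]).reset_index(drop=True)


@dataclass(frozen=True)
class Overlay:
    """Regulatory overlay result: graph plus a human-readable status."""

    graph: nx.DiGraph
    status: str
    n_networks: int

    @property
    def empty(self) -> bool:
        return self.graph.number_of_edges() == 0


def regulatory_overlay(
    query,
    edges: Iterable[RegulatoryEdge],
    min_networks: int = 2,
    directions: dict | None = None,
) -> Overlay:
    """Restrict regulator -> target edges to targets in the query.

    Follows the CyTargetLinker convention: if fewer than ``min_networks``
    distinct source networks were loaded, the overlay is empty with an
    explanatory status rather than an exception. Regulator nodes carry
    their kind and per-target edge count; target nodes carry a direction
    attribute when directions are supplied.
    """
    if min_networks < 1:
        raise ValidationError("min_networks must be >= 1")
    edges = list(edges)
    q = frozenset(query)
    networks = {e.network_id for e in edges}
    if len(networks) < min_networks:
        status = (f"only {len(networks)} regulatory network(s) loaded; "
                  f"minimum required is {min_networks} - overlay skipped")
        logger.warning(status)
        return Overlay(nx.DiGraph(), status, len(networks))
    graph = nx.DiGraph()
    kept = 0
    for e in edges:
        if e.target in q:
            graph.add_node(e.regulator, node_type="regulator", kind=e.kind)
            attrs = {"node_type": "target"}
            if directions is not None and e.target in directions:
                attrs["direction"] = directions[e.target]
            graph.add_node(e.target, **attrs)
            graph.add_edge(e.regulator, e.target, network_id=e.network_id,
                           kind=e.kind)
            kept += 1
    for node, data in graph.nodes(data=True):
        if data.get("node_type") == "regulator":
            graph.nodes[node]["n_targets"] = graph.out_degree(node)
    status = (f"{kept} edge(s) onto {sum(1 for _, d in graph.nodes(data=True) if d.get('node_type') == 'target')} "
              f"target(s) from {len(networks)} network(s)")
    return Overlay(graph, status, len(networks))


def write_overlay_sif(overlay: Overlay, path: str | Path) -> None:
    rows = sorted((u, d["kind"], v)
                  for u, v, d in overlay.graph.edges(data=True))
    write_sif(rows, path)


def write_overlay_graphml(overlay: Overlay, path: str | Path) -> None:
    nx.write_graphml(overlay.graph, path)
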