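"""Cofactor-protein network views and the PPI-augmented network.

The augmented network keeps the cofactor-interacting proteins that appear in
the PPI graph, plus the non-catalog first-degree neighbors shared by at
least two of them — bridging proteins between catalog-rich regions of the
interactome — and labels every edge by its endpoint roles (cc: both catalog,
cn: catalog-neighbor, nn: neighbor-neighbor).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Dict, Tuple

import networkx as nx
import numpy as np
import pandas as pd

from .types import (
    AugmentedNetwork,
    CofactorTable,
    EDGE_CC,
    EDGE_CN,
    EDGE_NN,
    ROLE_COFACTOR,
    ROLE_NEIGHBOR,
    edge_key,
)

logger = logging.getLogger(__name__)


@dataclass
class AssemblyReport:
    n_cofactor_proteins_mapped: int
    n_cofactor_proteins_unmapped: int
    n_neighbors_kept: int
    n_neighbors_rejected: int
    edge_counts: Dict[str, int]

    def to_dict(self) -> Dict[str, object]:
        return {
            "n_cofactor_proteins_mapped": self.n_cofactor_proteins_mapped,
            "n_cofactor_proteins_unmapped": self.n_cofactor_proteins_unmapped,
            "n_neighbors_kept": self.n_neighbors_kept,
            "n_neighbors_rejected": self.n_neighbors_rejected,
            "edge_counts": dict(self.edge_counts),
            "n_edges_total": sum(self.edge_counts.values()),
        }


def build_bipartite_view(catalog: CofactorTable) -> pd.DataFrame:
    """Binary cofactor x protein incidence: rows = cofactors, columns =
    proteins. Row sums give each cofactor's number of interacting proteins,
    column sums each protein's number of required cofactors."""
    cofactors = sorted(catalog.cofactors)
    proteins = sorted(catalog.proteins)
    pidx = {p: j for j, p in enumerate(proteins)}
    cidx = {c: i for i, c in enumerate(cofactors)}
    m = np.zeros((len(cofactors), len(proteins)), dtype=int)
    for p, c in catalog.pairs:
        m[cidx[c], pidx[p]] = 1
    return pd.DataFrame(m, index=pd.Index(cofactors, name="cofactor_id"),
                        columns=pd.Index(proteins, name="protein_id"))


def assemble_augmented_network(
    catalog: CofactorTable, ppi: nx.Graph
) -> Tuple[AugmentedNetwork, AssemblyReport]:
    """Extract the catalog-protein subnetwork plus bridging neighbors.

    Node set: catalog proteins present in the PPI, together with non-catalog
    proteins adjacent to >= 2 catalog proteins. Edge set: the PPI subgraph
    induced on that node set (so edges between two rejected neighbors cannot
    appear). Catalog proteins absent from the PPI are dropped silently from
    the network but surfaced in the report.
    """
    catalog_proteins = catalog.proteins
    mapped = {n for n in ppi.nodes if n in catalog_proteins}
    if not mapped:
        logger.warning("no catalog protein maps into the PPI; augmented network is empty")

    kept_neighbors = set()
    rejected = 0
    for node in ppi.nodes:
        if node in catalog_proteins:
            continue
        n_catalog_nbrs = sum(1 for nbr in ppi.adj[node] if nbr in mapped)
        if n_catalog_nbrs >= 2:
            kept_neighbors.add(node)
        elif n_catalog_nbrs == 1:
            rejected += 1

    nodes = mapped | kept_neighbors
    sub = ppi.subgraph(nodes).copy()
    roles = {
        n: (ROLE_COFACTOR if n in catalog_proteins else ROLE_NEIGHBOR) for n in sub.nodes
    }
    classes: Dict[Tuple[str, str], str] = {}
    for u, v in sub.edges:
        n_cof = (roles[u] == ROLE_COFACTOR) + (roles[v] == ROLE_COFACTOR)
        classes[edge_key(u, v)] = {2: EDGE_CC, 1: EDGE_CN, 0: EDGE_NN}[n_cof]

    net = AugmentedNetwork(graph=sub, node_roles=roles, edge_classes=classes)
    counts = net.edge_class_counts()
    report = AssemblyReport(
        n_cofactor_proteins_mapped=len(mapped),
        n_cofactor_proteins_unmapped=len(catalog_proteins - mapped),
        n_neighbors_kept=len(kept_neighbors),
        n_neighbors_rejected=rejected,
        edge_counts=counts,
    )
    return net, report
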