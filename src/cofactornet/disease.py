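"""Cofactor-disease bipartite network: weighted incidence, enrichment of
cofactor-interacting proteins among disease genes, and nestedness.

A disease is linked to a cofactor when one of its genes codes for a protein
interacting with that cofactor; the edge weight counts those shared
proteins. Nestedness — the degree to which the cofactor repertoires of
narrow diseases are subsets of the repertoires of broad ones — is measured
matrix-wide by NODF (nestedness metric based on overlap and decreasing
fill, 0-100) on the binary support, and per disease by a normalized nested
rank in [0, 1]: 0 for the most broadly connected disease, 1 for the
narrowest.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Dict, List, Optional, Set

import numpy as np
import pandas as pd

from .stats import bh_adjust, hypergeom_right_tail, percentage
from .types import (
    CofactorTable,
    DiseaseGeneMap,
    EnrichmentResult,
    ValidationError,
)

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# Incidence
# ---------------------------------------------------------------------------


@dataclass
class CofactorDiseaseIncidence:
    """disease x cofactor matrix; weights[d, c] = number of proteins that
    interact with cofactor c and belong to disease d's gene set. Diseases
    with an all-zero row are dropped."""

    weights: pd.DataFrame  # rows = diseases, columns = cofactors
    gene_counts: Dict[str, int]  # total genes per retained disease
    catalog_gene_counts: Dict[str, int]  # cofactor-interacting genes per disease

    @property
    def diseases(self) -> List[str]:
        return list(self.weights.index)

    @property
    def cofactors(self) -> List[str]:
        return list(self.weights.columns)

    def support(self) -> pd.DataFrame:
        return (self.weights > 0).astype(int)


def build_incidence(
    catalog: CofactorTable, diseases: DiseaseGeneMap
) -> CofactorDiseaseIncidence:
    cofactors = sorted(catalog.cofactors)
    rows = {}
    gene_counts = {}
    catalog_gene_counts = {}
    for disease in diseases.diseases:
        genes = diseases.entries[disease]
        weights = [len(catalog.proteins_for(c) & genes) for c in cofactors]
        if sum(weights) == 0:
            continue
        rows[disease] = weights
        gene_counts[disease] = len(genes)
        catalog_gene_counts[disease] = len(genes & catalog.proteins)
    if not rows:
        logger.warning("no disease shares a gene with the catalog; empty incidence")
    df = pd.DataFrame.from_dict(rows, orient="index", columns=cofactors)
    df.index.name = "disease_id"
    return CofactorDiseaseIncidence(
        weights=df, gene_counts=gene_counts, catalog_gene_counts=catalog_gene_counts
    )


def write_incidence_mtx(incidence: CofactorDiseaseIncidence, path) -> None:
    """Export the weighted incidence as MatrixMarket coordinate triplets
    (rows = diseases, columns = cofactors, 1-based indices)."""
    w = incidence.weights
    triplets = [
        (i + 1, j + 1, int(w.iat[i, j]))
        for i in range(w.shape[0])
        for j in range(w.shape[1])
        if w.iat[i, j] > 0
    ]
    with open(path, "w") as fh:
        fh.write("%%MatrixMarket matrix coordinate integer general\n")
        fh.write(f"%rows: {' '.join(incidence.diseases)}\n")
        fh.write(f"%cols: {' '.join(incidence.cofactors)}\n")
        fh.write(f"{w.shape[0]} {w.shape[1]} {len(triplets)}\n")
        for i, j, v in triplets:
            fh.write(f"{i} {j} {v}\n")


def write_incidence_graphml(incidence: CofactorDiseaseIncidence, path) -> None:
    """Export the weighted incidence as a bipartite GraphML network
    (node attribute ``kind`` in {disease, cofactor}, edge attribute
    ``weight`` = number of shared proteins)."""
    import networkx as nx

    g = nx.Graph()
    for d in incidence.diseases:
        g.add_node(d, kind="disease")
    for c in incidence.cofactors:
        g.add_node(c, kind="cofactor")
    w = incidence.weights
    for d in incidence.diseases:
        for c in incidence.cofactors:
            weight = int(w.loc[d, c])
            if weight > 0:
                g.add_edge(d, c, weight=weight)
    nx.write_graphml(g, path)


# ---------------------------------------------------------------------------
# Enrichment of catalog proteins among disease genes
# ---------------------------------------------------------------------------


def disease_gene_enrichment(
    catalog_proteins: Set[str],
    disease_genes: Set[str],
    universe: Set[str],
) -> EnrichmentResult:
    """Right-tail hypergeometric p for observing at least k cofactor-
    interacting genes among the disease genes, over the given gene
    universe."""
    universe = set(universe)
    if not set(catalog_proteins) <= universe:
        raise ValidationError("catalog proteins not contained in the universe")
    if not set(disease_genes) <= universe:
        raise ValidationError("disease genes not contained in the universe")
    N = len(universe)
    K = len(set(catalog_proteins))
    n = len(set(disease_genes))
    k = len(set(catalog_proteins) & set(disease_genes))
    p = hypergeom_right_tail(k, N, K, n)
    return EnrichmentResult(universe_size=N, marked=K, drawn=n, observed=k, p_value=p)


def disease_enrichment_table(
    catalog: CofactorTable,
    diseases: DiseaseGeneMap,
    universe: Set[str],
) -> pd.DataFrame:
    """Per-disease enrichment with BH adjustment across diseases."""
    universe = set(universe)
    catalog_in = catalog.proteins & universe
    rows = []
    for disease in diseases.diseases:
        genes = diseases.entries[disease] & universe
        if not genes:
            continue
        res = disease_gene_enrichment(catalog_in, genes, universe)
        rows.append(
            {
                "disease_id": disease,
                "n_genes": res.drawn,
                "n_catalog_genes": res.observed,
                "p_value": res.p_value,
            }
        )
    df = pd.DataFrame(rows, columns=["disease_id", "n_genes", "n_catalog_genes", "p_value"])
    if len(df):
        df["q_value"] = bh_adjust(df["p_value"].to_numpy())
    else:
        df["q_value"] = []
    return df


# ---------------------------------------------------------------------------
# Nestedness
# ---------------------------------------------------------------------------


def nodf(matrix) -> float:
    """NODF of a binary matrix, in [0, 100].

    For every unordered pair of rows (and of columns), the pair contributes
    the paired overlap — the percentage of the sparser line's presences also
    found in the denser line — but only when the marginal totals strictly
    decrease (equal fills contribute 0). NODF is the mean contribution over
    all row pairs and column pairs; it depends only on the set structure,
    not on the input ordering. Matrices with fewer than 2 rows or columns
    are degenerate and score 0.
    """
    m = np.asarray(matrix)
    if m.ndim != 2 or m.shape[0] < 2 or m.shape[1] < 2:
        logger.warning("degenerate matrix for NODF; defined as 0")
        return 0.0
    if not np.isin(m, (0, 1)).all():
        raise ValidationError("NODF requires a binary matrix")

    def axis_terms(mat: np.ndarray) -> List[float]:
        fills = mat.sum(axis=1)
        terms = []
        for i in range(mat.shape[0]):
            for j in range(i + 1, mat.shape[0]):
                hi, lo = (i, j) if fills[i] > fills[j] else (j, i)
                if fills[hi] == fills[lo] or fills[lo] == 0:
                    terms.append(0.0)
                else:
                    overlap = int(np.logical_and(mat[hi], mat[lo]).sum())
                    terms.append(100.0 * overlap / fills[lo])
        return terms

    terms = axis_terms(m) + axis_terms(m.T)
    return float(np.mean(terms))


@dataclass
class NestednessResult:
    matrix_nodf: float
    per_disease_index: Dict[str, float]
    row_order: List[str]  # broadest repertoire first
    excluded: List[str]  # diseases below the gene-count filter


def disease_nestedness_index(
    incidence: CofactorDiseaseIncidence, min_genes: int = 5
) -> NestednessResult:
    """Rank diseases by how nested their cofactor repertoire is.

    Diseases with more than ``min_genes`` cofactor-interacting genes are
    retained (strict inequality); rows are packed into the maximally nested
    order — descending repertoire size, ties broken by descending total
    overlap with the other rows, then by id — and each disease's index is
    its normalized rank (rank - 1)/(n - 1), so the disease whose repertoire
    contains every other's gets 0 and the narrowest gets 1.
    """
    retained = [
        d for d in incidence.diseases if incidence.catalog_gene_counts[d] > min_genes
    ]
    excluded = [d for d in incidence.diseases if d not in retained]
    if len(retained) < 2:
        logger.warning("fewer than 2 diseases retained; single index 0")
        return NestednessResult(
            matrix_nodf=0.0,
            per_disease_index={d: 0.0 for d in retained},
            row_order=retained,
            excluded=excluded,
        )
    support = incidence.support().loc[retained]
    # a cofactor linked to no retained disease is not a node of the
    # bipartite network; drop its empty column before measuring nestedness
    support = support.loc[:, support.sum(axis=0) > 0]
    mat = support.to_numpy()
    row_sums = mat.sum(axis=1)
    overlaps = mat @ mat.T
    np.fill_diagonal(overlaps, 0)
    total_overlap = overlaps.sum(axis=1)
    order = sorted(
        range(len(retained)),
        key=lambda i: (-row_sums[i], -total_overlap[i], retained[i]),
    )
    ordered_ids = [retained[i] for i in order]
    n = len(ordered_ids)
    index = {d: rank / (n - 1) for rank, d in enumerate(ordered_ids)}
    return NestednessResult(
        matrix_nodf=nodf(mat),
        per_disease_index=index,
        row_order=ordered_ids,
        excluded=excluded,
    )


# ---------------------------------------------------------------------------
# Report
# ---------------------------------------------------------------------------


def disease_report(
    incidence: CofactorDiseaseIncidence,
    nestedness: NestednessResult,
    diseases: DiseaseGeneMap,
    n_cofactors_in_catalog: Optional[int] = None,
) -> pd.DataFrame:
    """Per-retained-disease summary: gene counts, cofactor-interacting gene
    counts and share, number of distinct cofactors and its share of all
    studied cofactors (integer percentages), and the nestedness index."""
    if n_cofactors_in_catalog is None:
        n_cofactors_in_catalog = len(incidence.cofactors)
    support = incidence.support()
    rows = []
    for disease in nestedness.row_order:
        n_genes = incidence.gene_counts[disease]
        n_cat = incidence.catalog_gene_counts[disease]
        n_cof = int(support.loc[disease].sum())
        rows.append(
            {
                "disease_id": disease,
                "n_genes": n_genes,
                "n_cofactor_genes": n_cat,
                "pct_cofactor_genes": int(percentage(n_cat, n_genes, 0)),
                "n_cofactors": n_cof,
                "pct_of_studied_cofactors": int(percentage(n_cof, n_cofactors_in_catalog, 0)),
                "nestedness_index": nestedness.per_disease_index[disease],
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "disease_id",
            "n_genes",
            "n_cofactor_genes",
            "pct_cofactor_genes",
            "n_cofactors",
            "pct_of_studied_cofactors",
            "nestedness_index",
        ],
    )
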