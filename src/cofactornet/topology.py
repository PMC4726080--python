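"""Protein-protein connectivity analysis: hub detection with a permutation
significance test, and per-cofactor tissue co-expression against size-matched
random gene groups.

Both tests are one-sided "greater" (the hypotheses are directional: are
catalog proteins more connected / more co-expressed than random sets?) and
use the add-one permutation estimator p = (1 + #{null >= obs}) / (B + 1),
which is never exactly zero.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import FrozenSet, Iterable, List, Optional, Set, Union

import networkx as nx
import numpy as np

from .stats import round_half_up
from .types import ExpressionMatrix, PermutationTestResult, ValidationError

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# Hubs
# ---------------------------------------------------------------------------


@dataclass
class HubAnalysis:
    hub_fraction_threshold: float
    hubs: FrozenSet[str]
    observed_cofactor_hub_count: int
    test: PermutationTestResult


def detect_hubs(ppi: nx.Graph, threshold: float = 0.02) -> FrozenSet[str]:
    """Top ``round(threshold * n)`` most-connected proteins (half-up
    rounding; degree ties at the cutoff broken lexicographically by id)."""
    if not 0.0 < threshold < 1.0:
        raise ValidationError(f"hub threshold must be in (0, 1), got {threshold}")
    n = ppi.number_of_nodes()
    if n == 0:
        raise ValidationError("empty graph")
    count = int(round_half_up(threshold * n))
    ranked = sorted(ppi.nodes, key=lambda v: (-ppi.degree(v), v))
    return frozenset(ranked[:count])


def hub_permutation_test(
    ppi: nx.Graph,
    catalog_proteins: Set[str],
    threshold: float = 0.02,
    n_perm: int = 10000,
    seed: int = 0,
    null_universe: str = "noncatalog",
) -> HubAnalysis:
    """Are catalog proteins over-represented among hubs?

    observed = hub fraction among catalog proteins; each null sample is the
    hub fraction in a uniform draw (without replacement) of the same size
    from the non-catalog proteins (``null_universe='all'`` draws from every
    node instead).
    """
    nodes = sorted(ppi.nodes)
    catalog_in = set(catalog_proteins) & set(nodes)
    if catalog_in != set(catalog_proteins):
        missing = set(catalog_proteins) - catalog_in
        raise ValidationError(f"{len(missing)} catalog proteins absent from the graph")
    if null_universe not in ("noncatalog", "all"):
        raise ValidationError(f"unknown null_universe {null_universe!r}")
    m = len(catalog_in)
    hubs = detect_hubs(ppi, threshold)
    observed_count = len(hubs & catalog_in)
    observed = observed_count / m if m else 0.0

    if null_universe == "noncatalog":
        pool = [v for v in nodes if v not in catalog_in]
    else:
        pool = nodes
    if len(pool) < m:
        raise ValidationError(
            f"null universe ({len(pool)}) smaller than catalog ({m})"
        )
    is_hub = np.array([v in hubs for v in pool])
    rng = np.random.default_rng(seed)
    # Vectorised sampling without replacement: smallest-m random keys per row.
    keys = rng.random((n_perm, len(pool)))
    idx = np.argpartition(keys, m - 1, axis=1)[:, :m]
    null = is_hub[idx].mean(axis=1)
    test = PermutationTestResult.from_null(observed, null, seed)
    return HubAnalysis(
        hub_fraction_threshold=threshold,
        hubs=hubs,
        observed_cofactor_hub_count=observed_count,
        test=test,
    )


# ---------------------------------------------------------------------------
# Co-expression
# ---------------------------------------------------------------------------

MIN_GROUP_SIZE = 10  # cofactors interacting with fewer proteins are excluded


@dataclass
class CoexpressionExcluded:
    """Marker for a gene group too small to test (not an error)."""

    cofactor_id: Optional[str]
    group_size: int
    reason: str


@dataclass
class CoexpressionResult:
    cofactor_id: Optional[str]
    group_size: int
    mean_pairwise_r: float
    test: PermutationTestResult


def mean_pairwise_correlation(corr: np.ndarray, idx: np.ndarray) -> float:
    """Mean of Pearson r over all unordered pairs of the given gene indices
    in a precomputed gene-gene correlation matrix."""
    sub = corr[np.ix_(idx, idx)]
    m = len(idx)
    return float((sub.sum() - np.trace(sub)) / (m * (m - 1)))


def _correlation_matrix(values: np.ndarray) -> np.ndarray:
    # rows = genes; constant rows must be removed by the caller
    return np.corrcoef(values)


def coexpression_test(
    expr: ExpressionMatrix,
    group: Iterable[str],
    n_perm: int = 10000,
    seed: int = 0,
    cofactor_id: Optional[str] = None,
    corr: Optional[np.ndarray] = None,
    log_transform: bool = False,
) -> Union[CoexpressionResult, CoexpressionExcluded]:
    """Mean pairwise Pearson r across tissues of a gene group, against
    size-matched uniform random groups from all expressed genes.

    Genes absent from the matrix are dropped by intersection; genes with
    zero variance across tissues (Pearson r undefined) are excluded and
    logged. Groups smaller than 10 after intersection return an explicit
    excluded marker rather than a result.

    ``corr`` may carry a precomputed gene-gene correlation matrix over the
    matrix's variable genes (as produced internally) to amortise repeated
    calls; it is recomputed when omitted. ``log_transform`` applies
    log2(x + 1) before correlating (off by default: raw abundances are
    correlated as provided).
    """
    values = expr.data.to_numpy(dtype=float)
    if log_transform:
        values = np.log2(values + 1.0)
    variable = values.std(axis=1) > 0.0
    genes = np.array(expr.genes)
    n_constant_dropped = int((~variable).sum())
    var_genes = genes[variable]
    gene_pos = {g: i for i, g in enumerate(var_genes)}

    requested = set(group)
    member_idx = np.array(sorted(gene_pos[g] for g in requested if g in gene_pos))
    n_zero_var = len(requested & set(genes)) - len(member_idx)
    if n_zero_var:
        logger.info("co-expression group %s: dropped %d zero-variance genes",
                    cofactor_id, n_zero_var)
    if len(member_idx) < MIN_GROUP_SIZE:
        return CoexpressionExcluded(
            cofactor_id=cofactor_id,
            group_size=len(member_idx),
            reason=f"fewer than {MIN_GROUP_SIZE} genes after intersection",
        )

    if corr is None:
        corr = _correlation_matrix(values[variable])
    m = len(member_idx)
    observed = mean_pairwise_correlation(corr, member_idx)

    rng = np.random.default_rng(seed)
    n_genes = len(var_genes)
    # mean pairwise r per draw = (sum_{i,j in S} C_ij - m) / (m(m-1));
    # draws sampled without replacement via smallest-m random keys, the
    # submatrix sums gathered in chunks to bound memory.
    null = np.empty(n_perm)
    chunk = max(1, int(2e7 // (m * m)) or 1)
    done = 0
    while done < n_perm:
        b = min(chunk, n_perm - done)
        keys = rng.random((b, n_genes))
        draws = np.argpartition(keys, m - 1, axis=1)[:, :m]
        sub = corr[draws[:, :, None], draws[:, None, :]]
        null[done : done + b] = (sub.sum(axis=(1, 2)) - m) / (m * (m - 1))
        done += b
    test = PermutationTestResult.from_null(observed, null, seed)
    return CoexpressionResult(
        cofactor_id=cofactor_id,
        group_size=m,
        mean_pairwise_r=observed,
        test=test,
    )


def coexpression_by_cofactor(
    expr: ExpressionMatrix,
    catalog,
    n_perm: int = 10000,
    seed: int = 0,
    log_transform: bool = False,
) -> List[Union[CoexpressionResult, CoexpressionExcluded]]:
    """Run the co-expression test for every cofactor, sharing one
    correlation matrix across calls."""
    values = expr.data.to_numpy(dtype=float)
    if log_transform:
        values = np.log2(values + 1.0)
    variable = values.std(axis=1) > 0.0
    corr = _correlation_matrix(values[variable])
    out: List[Union[CoexpressionResult, CoexpressionExcluded]] = []
    for i, cof in enumerate(sorted(catalog.cofactors)):
        out.append(
            coexpression_test(
                expr,
                catalog.proteins_for(cof),
                n_perm=n_perm,
                seed=seed + i,
                cofactor_id=cof,
                corr=corr,
                log_transform=log_transform,
            )
        )
    return out
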