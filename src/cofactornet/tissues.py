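"""Tissue-specificity classification in the six atlas-style categories and
the per-tissue share of cofactor-interacting proteins among tissue-enriched
proteins.

Categories (mutually exclusive, evaluated in this precedence order; "detected"
means abundance >= detection threshold, fold defaults to 5):

* tissue_enriched — one tissue at least ``fold`` times higher than every
  other tissue (and detected there);
* group_enriched — a group of 2-7 tissues each at least ``fold`` times every
  tissue outside the group;
* tissue_enhanced — some tissue at least ``fold`` times the mean over all
  tissues (and detected there);
* expressed_in_all — detected in every tissue;
* mixed — detected in at least one but not all tissues, not elevated;
* not_detected — detected nowhere.

The group-enriched search sorts tissues by descending abundance and tests
prefixes of size 2-7 only: any qualifying group must contain the top-k
tissues (every member must exceed ``fold`` times every non-member, so no
non-member can out-rank a member), making the greedy prefix scan equivalent
to exhaustive subset search.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .stats import percentage
from .types import (
    CofactorTable,
    ExpressionMatrix,
    PermutationTestResult,
    ValidationError,
)

CATEGORIES = (
    "tissue_enriched",
    "group_enriched",
    "tissue_enhanced",
    "expressed_in_all",
    "mixed",
    "not_detected",
)

MAX_GROUP_SIZE = 7


@dataclass
class GeneClassification:
    category: str
    evidence: Tuple[str, ...]  # enriching tissue(s), empty for the rest


def classify_gene(
    profile: Sequence[float],
    tissue_ids: Sequence[str],
    detection_threshold: float = 1.0,
    fold: float = 5.0,
) -> GeneClassification:
    """Classify one expression profile; see module docstring for the rules."""
    values = np.asarray(profile, dtype=float)
    if len(values) < 2:
        raise ValidationError("profile needs at least 2 tissues")
    if np.isnan(values).any():
        raise ValidationError("NaN in expression profile")
    if (values < 0).any():
        raise ValidationError("negative expression value")
    tissue_ids = list(tissue_ids)

    order = sorted(range(len(values)), key=lambda i: (-values[i], tissue_ids[i]))
    v = values[order]
    detected = values >= detection_threshold

    # tissue enriched: top tissue >= fold * all others
    if detected[order[0]] and v[0] >= fold * v[1]:
        return GeneClassification("tissue_enriched", (tissue_ids[order[0]],))

    # group enriched: prefix of 2..7 tissues each >= fold * all the rest
    max_g = min(MAX_GROUP_SIZE, len(values) - 1)
    for g in range(2, max_g + 1):
        if detected[order[g - 1]] and v[g - 1] >= fold * v[g]:
            return GeneClassification(
                "group_enriched", tuple(tissue_ids[i] for i in order[:g])
            )

    # tissue enhanced: some tissue >= fold * mean over all tissues
    mean = float(values.mean())
    enhanced = [
        i for i in order if detected[i] and values[i] >= fold * mean
    ]
    if enhanced:
        return GeneClassification("tissue_enhanced", tuple(tissue_ids[i] for i in enhanced))

    if detected.all():
        return GeneClassification("expressed_in_all", ())
    if detected.any():
        return GeneClassification("mixed", ())
    return GeneClassification("not_detected", ())


@dataclass
class TissueClassification:
    by_gene: Dict[str, GeneClassification]
    detection_threshold: float
    fold: float

    def category_of(self, gene_id: str) -> str:
        return self.by_gene[gene_id].category

    def genes_in(self, category: str) -> List[str]:
        return sorted(g for g, c in self.by_gene.items() if c.category == category)


def classify_all(
    expr: ExpressionMatrix,
    catalog: Optional[CofactorTable] = None,
    detection_threshold: float = 1.0,
    fold: float = 5.0,
) -> Tuple[TissueClassification, pd.DataFrame]:
    """Classify every gene; the count table tallies each category overall and
    split into catalog (cofactor-interacting) vs other genes, with
    percentages over each group's own classified-gene denominator."""
    tissues = expr.tissues
    by_gene = {
        g: classify_gene(expr.profile(g), tissues, detection_threshold, fold)
        for g in expr.genes
    }
    classification = TissueClassification(by_gene, detection_threshold, fold)
    catalog_proteins = catalog.proteins if catalog is not None else frozenset()
    rows = []
    n_total = len(by_gene)
    n_cat = sum(1 for g in by_gene if g in catalog_proteins)
    n_non = n_total - n_cat
    for category in CATEGORIES:
        genes = classification.genes_in(category)
        k_cat = sum(1 for g in genes if g in catalog_proteins)
        k_non = len(genes) - k_cat
        rows.append(
            {
                "category": category,
                "n_genes": len(genes),
                "pct_genes": percentage(len(genes), n_total, 1) if n_total else 0.0,
                "n_catalog": k_cat,
                "pct_catalog": percentage(k_cat, n_cat, 1) if n_cat else 0.0,
                "n_other": k_non,
                "pct_other": percentage(k_non, n_non, 1) if n_non else 0.0,
            }
        )
    return classification, pd.DataFrame(rows)


def enriched_share_table(
    classification: TissueClassification, catalog: CofactorTable
) -> pd.DataFrame:
    """Per-tissue share of cofactor-interacting proteins among
    tissue-enriched proteins (percentage rounded to the nearest integer).
    Tissues with zero enriched proteins are omitted."""
    catalog_proteins = catalog.proteins
    per_tissue: Dict[str, List[str]] = {}
    for gene, cls in classification.by_gene.items():
        if cls.category == "tissue_enriched":
            per_tissue.setdefault(cls.evidence[0], []).append(gene)
    rows = []
    for tissue, genes in per_tissue.items():
        n_cat = sum(1 for g in genes if g in catalog_proteins)
        rows.append(
            {
                "tissue": tissue,
                "n_enriched_cofactor_proteins": n_cat,
                "n_enriched_proteins": len(genes),
                "pct": int(percentage(n_cat, len(genes), 0)),
            }
        )
    df = pd.DataFrame(
        rows,
        columns=["tissue", "n_enriched_cofactor_proteins", "n_enriched_proteins", "pct"],
    )
    return df.sort_values(["pct", "tissue"], ascending=[False, True], ignore_index=True)


def compare_expressed_in_all(
    classification: TissueClassification,
    catalog: CofactorTable,
    n_perm: int = 10000,
    seed: int = 0,
    null_universe: str = "all",
) -> PermutationTestResult:
    """Are catalog genes over-represented among expressed-in-all genes?

    observed = expressed_in_all fraction among catalog genes; null samples
    are the same fraction in size-matched uniform draws from all classified
    genes (or from non-catalog genes with ``null_universe='noncatalog'``).
    """
    genes = sorted(classification.by_gene)
    catalog_genes = [g for g in genes if g in catalog.proteins]
    if not catalog_genes or len(catalog_genes) == len(genes):
        raise ValidationError("need both catalog and non-catalog classified genes")
    if null_universe == "all":
        pool = genes
    elif null_universe == "noncatalog":
        pool = [g for g in genes if g not in catalog.proteins]
    else:
        raise ValidationError(f"unknown null_universe {null_universe!r}")
    m = len(catalog_genes)
    if len(pool) < m:
        raise ValidationError("null universe smaller than the catalog gene set")
    in_all = np.array([classification.category_of(g) == "expressed_in_all" for g in pool])
    observed = float(
        np.mean([classification.category_of(g) == "expressed_in_all" for g in catalog_genes])
    )
    rng = np.random.default_rng(seed)
    keys = rng.random((n_perm, len(pool)))
    idx = np.argpartition(keys, m - 1, axis=1)[:, :m]
    null = in_all[idx].mean(axis=1)
    return PermutationTestResult.from_null(observed, null, seed)
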