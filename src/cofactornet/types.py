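"""Core domain types shared by every pipeline stage.

The analysis links four layers of biology: micronutrient-derived cofactors
(metal ions, vitamin-derived organic molecules, in-vivo metabolites), the
proteins that require or bind them, the protein-protein interaction (PPI)
network those proteins live in, and the diseases their genes associate with.
Protein and gene identifiers are deliberately a single opaque id space: the
catalogs this pipeline emulates use them interchangeably.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, FrozenSet, Iterable, List, Tuple

import networkx as nx
import numpy as np
import pandas as pd


class FormatError(ValueError):
    """Raised when an input file does not have the expected layout."""


class ValidationError(ValueError):
    """Raised when an in-memory object violates a domain invariant."""


# ---------------------------------------------------------------------------
# Cofactor catalog
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CofactorRecord:
    """One curated cofactor-protein interaction."""

    protein_id: str
    cofactor_id: str
    source: str = "user"
    has_binding_site_variant: bool = False


class CofactorTable:
    """Curated catalog of cofactor-protein interactions.

    (protein, cofactor) pairs are unique: duplicate records (typically the
    same interaction reported by several source databases) are collapsed, the
    source tags merged with ``;`` and the binding-site-variant flags OR-ed.
    """

    def __init__(self, records: Iterable[CofactorRecord]):
        merged: Dict[Tuple[str, str], CofactorRecord] = {}
        for rec in records:
            if not rec.protein_id:
                raise ValidationError("empty protein_id in cofactor table")
            if not rec.cofactor_id:
                raise ValidationError("empty cofactor_id in cofactor table")
            key = (rec.protein_id, rec.cofactor_id)
            if key in merged:
                prev = merged[key]
                sources = sorted(set(prev.source.split(";")) | set(rec.source.split(";")))
                merged[key] = CofactorRecord(
                    protein_id=rec.protein_id,
                    cofactor_id=rec.cofactor_id,
                    source=";".join(sources),
                    has_binding_site_variant=prev.has_binding_site_variant
                    or rec.has_binding_site_variant,
                )
            else:
                merged[key] = rec
        if not merged:
            raise ValidationError("cofactor table is empty")
        self._records: List[CofactorRecord] = [merged[k] for k in sorted(merged)]
        self._by_cofactor: Dict[str, set] = {}
        self._by_protein: Dict[str, set] = {}
        for rec in self._records:
            self._by_cofactor.setdefault(rec.cofactor_id, set()).add(rec.protein_id)
            self._by_protein.setdefault(rec.protein_id, set()).add(rec.cofactor_id)

    @classmethod
    def from_pairs(cls, pairs: Iterable[Tuple[str, str]], source: str = "user") -> "CofactorTable":
        return cls(CofactorRecord(p, c, source) for p, c in pairs)

    @property
    def records(self) -> List[CofactorRecord]:
        return list(self._records)

    @property
    def proteins(self) -> FrozenSet[str]:
        return frozenset(self._by_protein)

    @property
    def cofactors(self) -> FrozenSet[str]:
        return frozenset(self._by_cofactor)

    @property
    def pairs(self) -> List[Tuple[str, str]]:
        return [(r.protein_id, r.cofactor_id) for r in self._records]

    def proteins_for(self, cofactor_id: str) -> FrozenSet[str]:
        return frozenset(self._by_cofactor.get(cofactor_id, set()))

    def cofactors_for(self, protein_id: str) -> FrozenSet[str]:
        return frozenset(self._by_protein.get(protein_id, set()))

    def summary(self) -> Dict[str, int]:
        return {
            "n_cofactors": len(self._by_cofactor),
            "n_proteins": len(self._by_protein),
            "n_unique_pairs": len(self._records),
        }

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "protein_id": [r.protein_id for r in self._records],
                "cofactor_id": [r.cofactor_id for r in self._records],
                "source": [r.source for r in self._records],
                "binding_site_variant": [r.has_binding_site_variant for r in self._records],
            }
        )

    def __len__(self) -> int:
        return len(self._records)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, CofactorTable):
            return NotImplemented
        return self._records == other._records


# ---------------------------------------------------------------------------
# PPI graph helpers (a PPI graph is a plain networkx.Graph: simple, undirected)
# ---------------------------------------------------------------------------


def clean_ppi(edges: Iterable[Tuple[str, str]]) -> Tuple[nx.Graph, int]:
    """Build a simple undirected graph, dropping self-loops and duplicate
    pairs in either orientation. Returns (graph, n_dropped_records)."""
    g = nx.Graph()
    dropped = 0
    for a, b in edges:
        if a == b:
            dropped += 1
            continue
        if g.has_edge(a, b):
            dropped += 1
            continue
        g.add_edge(a, b)
    return g, dropped


# ---------------------------------------------------------------------------
# Augmented network (catalog proteins + bridging neighbors)
# ---------------------------------------------------------------------------

ROLE_COFACTOR = "cofactor_protein"
ROLE_NEIGHBOR = "neighbor"

EDGE_CC = "cc"  # cofactor-protein -- cofactor-protein
EDGE_CN = "cn"  # cofactor-protein -- neighbor
EDGE_NN = "nn"  # neighbor -- neighbor


def edge_key(u: str, v: str) -> Tuple[str, str]:
    return (u, v) if u <= v else (v, u)


@dataclass
class AugmentedNetwork:
    """PPI subgraph on cofactor-interacting proteins plus the first-degree
    neighbors shared by at least two of them, with role/class labels."""

    graph: nx.Graph
    node_roles: Dict[str, str]
    edge_classes: Dict[Tuple[str, str], str]

    def edge_class_counts(self) -> Dict[str, int]:
        counts = {EDGE_CC: 0, EDGE_CN: 0, EDGE_NN: 0}
        for cls in self.edge_classes.values():
            counts[cls] += 1
        return counts

    def validate(self) -> None:
        if set(self.node_roles) != set(self.graph.nodes):
            raise ValidationError("node_roles does not cover the node set")
        if len(self.edge_classes) != self.graph.number_of_edges():
            raise ValidationError("edge_classes does not cover the edge set")
        for (u, v), cls in self.edge_classes.items():
            ru, rv = self.node_roles[u], self.node_roles[v]
            n_cof = (ru == ROLE_COFACTOR) + (rv == ROLE_COFACTOR)
            expected = {2: EDGE_CC, 1: EDGE_CN, 0: EDGE_NN}[n_cof]
            if cls != expected:
                raise ValidationError(f"edge ({u},{v}) labeled {cls}, roles imply {expected}")


# ---------------------------------------------------------------------------
# Expression matrix
# ---------------------------------------------------------------------------


class ExpressionMatrix:
    """Nonnegative gene x tissue abundance matrix (processed values, e.g.
    FPKM-like) used by both the co-expression and the tissue classification
    stages."""

    def __init__(self, data: pd.DataFrame):
        if data.shape[1] < 2:
            raise ValidationError("expression matrix needs at least 2 tissues")
        if data.index.has_duplicates:
            raise ValidationError("duplicate gene ids in expression matrix")
        values = data.to_numpy(dtype=float)
        if np.isnan(values).any():
            raise ValidationError("NaN values in expression matrix")
        if (values < 0).any():
            raise ValidationError("negative values in expression matrix")
        self.data = data.astype(float)

    @property
    def genes(self) -> List[str]:
        return list(self.data.index)

    @property
    def tissues(self) -> List[str]:
        return list(self.data.columns)

    def profile(self, gene_id: str) -> np.ndarray:
        return self.data.loc[gene_id].to_numpy()

    def __contains__(self, gene_id: str) -> bool:
        return gene_id in self.data.index


# ---------------------------------------------------------------------------
# Disease gene sets
# ---------------------------------------------------------------------------

SOURCE_OMIM = "omim_like"
SOURCE_GWAS = "gwas_like"


@dataclass
class DiseaseGeneMap:
    """disease id -> gene set, tagged by the kind of catalog it emulates
    (Mendelian/OMIM-like vs complex-trait/GWAS-like)."""

    entries: Dict[str, FrozenSet[str]]
    source: str = SOURCE_GWAS

    def __post_init__(self) -> None:
        for disease, genes in self.entries.items():
            if not genes:
                raise ValidationError(f"disease {disease!r} has an empty gene set")
        self.entries = {d: frozenset(g) for d, g in self.entries.items()}

    @property
    def diseases(self) -> List[str]:
        return sorted(self.entries)

    def __len__(self) -> int:
        return len(self.entries)


# ---------------------------------------------------------------------------
# Statistical result records
# ---------------------------------------------------------------------------


@dataclass
class PermutationTestResult:
    """One-sided (greater) permutation test with the add-one estimator:
    p = (1 + #{null >= observed}) / (n_perm + 1), never exactly 0."""

    observed: float
    null_samples: np.ndarray
    p_value: float
    n_perm: int
    seed: int

    @classmethod
    def from_null(
        cls, observed: float, null_samples: np.ndarray, seed: int
    ) -> "PermutationTestResult":
        null_samples = np.asarray(null_samples, dtype=float)
        n_perm = len(null_samples)
        p = (1 + int(np.count_nonzero(null_samples >= observed))) / (n_perm + 1)
        return cls(float(observed), null_samples, p, n_perm, int(seed))


@dataclass
class EnrichmentResult:
    """Right-tail hypergeometric enrichment: probability of drawing at least
    ``observed`` marked elements when ``drawn`` are sampled without
    replacement from a universe of ``universe_size`` containing ``marked``
    marked elements."""

    universe_size: int
    marked: int
    drawn: int
    observed: int
    p_value: float
    q_value: float = float("nan")

    def __post_init__(self) -> None:
        if not 0 <= self.observed <= min(self.marked, self.drawn) <= self.universe_size:
            raise ValidationError(
                f"inconsistent enrichment counts N={self.universe_size} "
                f"K={self.marked} n={self.drawn} k={self.observed}"
            )
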