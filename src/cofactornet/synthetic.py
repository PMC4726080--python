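"""Synthetic input generators with planted, parameter-controlled structure.

Real inputs to this pipeline are mined from curated databases (cofactor
catalogs, a human interactome, multi-tissue RNAseq, disease-gene catalogs)
that cannot be redistributed or re-mined reproducibly. These generators
emulate each input class at a configurable scale, planting the structures
the downstream stages are designed to recover:

* a cofactor catalog whose per-protein cofactor counts match a target mean
  (defaults sized to the curated scale: 49 cofactors, ~2,300 proteins,
  ~1.23 cofactors per protein);
* a PPI graph with planted dense modules over a sparse background
  (planted-partition model) to exercise module detection;
* a gene x tissue expression matrix with co-expressed groups sharing a
  latent tissue profile, tissue-enriched genes, and not-detected genes;
* disease gene sets whose induced disease x cofactor incidence is perfectly
  nested, noisily nested, or random.

Every generator is a pure function of (spec, inputs): the same seed gives
byte-identical output, and ground truth is returned separately, never
encoded in identifiers the pipeline could read.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass
from typing import Dict, FrozenSet, List, Sequence, Set, Tuple

import networkx as nx
import numpy as np
import pandas as pd

from .types import (
    CofactorRecord,
    CofactorTable,
    DiseaseGeneMap,
    ExpressionMatrix,
    ValidationError,
)

# 49 cofactor names at the scale of the curated vocabulary: inorganic ions
# (including the non-specific "metal" / "metal cation" requirement tokens)
# and organic / in-vivo-produced metabolites.
DEFAULT_COFACTOR_VOCABULARY: Tuple[str, ...] = (
    "Mg", "Zn", "Ca", "Mn", "Fe", "Cu", "Co", "Ni", "Mo", "K",
    "Na", "Se", "W", "V", "Cd", "metal", "metal cation",
    "NAD", "NADP", "FAD", "FMN", "CoA", "CoQ", "SAM", "GSH", "THF",
    "MTHF", "TPP", "PLP", "BH4", "LA", "PQQ", "MPT", "MPT-Mo", "AMP",
    "AB12", "MeB12", "heme", "biotin", "ascorbate", "retinoic acid",
    "vitamin D3", "alpha-tocopherol", "Fe-S", "siroheme", "TTQ", "F420",
    "ATP", "GTP",
)

NESTEDNESS_SHAPES = ("perfectly_nested", "noisy_nested", "random")

SOURCES = ("uniprot", "cofactor_db", "expasy", "metal_macie")


@dataclass
class SyntheticSpec:
    """All knobs for the synthetic inputs, with defaults at curated scale.

    ``pair_density`` is the per-protein probability of each additional
    cofactor beyond the mandatory first one (count = 1 + Binomial(n_cofactors
    - 1, pair_density)); the default targets a mean of ~1.23 cofactors per
    protein, the ratio of unique interactions to proteins in the curated
    catalog (2,840 / 2,301).
    """

    seed: int = 0
    n_cofactors: int = 49
    n_proteins: int = 2301
    pair_density: float = 0.23 / 48
    n_extra_proteins: int = 3500  # non-catalog proteins (catalog proteins are
    # a minority of the interactome, as in the curated networks)
    n_modules: int = 12
    module_size: int = 15
    intra_module_edge_prob: float = 0.9
    background_edge_prob: float = 0.002
    n_tissues: int = 16
    n_coexpr_groups: int = 10
    coexpr_noise_sd: float = 0.5
    n_background_genes: int = 1000
    enriched_fraction: float = 0.08
    enriched_fold: float = 10.0
    not_detected_fraction: float = 0.02
    n_diseases: int = 20
    nestedness_shape: str = "noisy_nested"
    detection_threshold: float = 1.0

    def validate(self) -> None:
        if self.n_cofactors < 1:
            raise ValidationError("n_cofactors must be >= 1")
        if self.n_proteins < 1:
            raise ValidationError("n_proteins must be >= 1")
        for name in ("pair_density", "intra_module_edge_prob", "background_edge_prob",
                     "enriched_fraction", "not_detected_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValidationError(f"{name} must be in [0, 1], got {v}")
        if self.module_size < 1:
            raise ValidationError("module_size must be >= 1")
        if self.n_tissues < 2:
            raise ValidationError("n_tissues must be >= 2")
        if self.coexpr_noise_sd < 0:
            raise ValidationError("coexpr_noise_sd must be >= 0")
        if self.detection_threshold < 0:
            raise ValidationError("detection_threshold must be >= 0")
        if self.nestedness_shape not in NESTEDNESS_SHAPES:
            raise ValidationError(
                f"nestedness_shape must be one of {NESTEDNESS_SHAPES}"
            )
        if self.nestedness_shape == "perfectly_nested" and self.n_diseases < 2:
            raise ValidationError("perfectly_nested needs n_diseases >= 2")


def substream(spec: SyntheticSpec, stage: str) -> np.random.Generator:
    """Per-stage random substream: (global seed, stage tag) so regenerating
    one input never perturbs another stage's draws."""
    return np.random.default_rng(
        [int(spec.seed) & 0x7FFFFFFF, zlib.crc32(stage.encode())]
    )


def _protein_ids(n: int) -> List[str]:
    return [f"P{i:05d}" for i in range(n)]


# ---------------------------------------------------------------------------
# Cofactor catalog
# ---------------------------------------------------------------------------


def generate_cofactor_table(spec: SyntheticSpec) -> CofactorTable:
    """Catalog of cofactor-protein interactions.

    Each protein gets one primary cofactor drawn from a popularity-skewed
    distribution (abundant metals such as Mg/Zn dominate real catalogs) and
    ``Binomial(n_cofactors - 1, pair_density)`` additional distinct ones, so
    a tunable fraction of proteins interacts with more than one cofactor.
    """
    spec.validate()
    rng = substream(spec, "catalog")
    if spec.n_cofactors <= len(DEFAULT_COFACTOR_VOCABULARY):
        cofactors = list(DEFAULT_COFACTOR_VOCABULARY[: spec.n_cofactors])
    else:
        extra = [f"CF{i:03d}" for i in range(spec.n_cofactors - len(DEFAULT_COFACTOR_VOCABULARY))]
        cofactors = list(DEFAULT_COFACTOR_VOCABULARY) + extra
    popularity = 1.0 / (np.arange(spec.n_cofactors) + 1.0)
    popularity /= popularity.sum()

    records: List[CofactorRecord] = []
    proteins = _protein_ids(spec.n_proteins)
    n_extra = rng.binomial(spec.n_cofactors - 1, spec.pair_density, size=spec.n_proteins)
    for pid, k_extra in zip(proteins, n_extra):
        primary = int(rng.choice(spec.n_cofactors, p=popularity))
        chosen = {primary}
        if k_extra > 0:
            others = [i for i in range(spec.n_cofactors) if i != primary]
            chosen.update(rng.choice(others, size=min(k_extra, len(others)), replace=False))
        for ci in sorted(chosen):
            records.append(
                CofactorRecord(
                    protein_id=pid,
                    cofactor_id=cofactors[ci],
                    source=str(rng.choice(SOURCES)),
                    has_binding_site_variant=bool(rng.random() < 0.1),
                )
            )
    return CofactorTable(records)


# ---------------------------------------------------------------------------
# PPI with planted modules
# ---------------------------------------------------------------------------


def generate_ppi_with_planted_modules(
    spec: SyntheticSpec, catalog: CofactorTable
) -> Tuple[nx.Graph, List[FrozenSet[str]]]:
    """Planted-partition PPI: dense modules over a sparse background.

    Nodes are the catalog proteins plus ``n_extra_proteins`` non-catalog
    proteins; planted modules are drawn over a random shuffle of all nodes
    so they mix catalog and neighbor proteins. Intra-module pairs get an
    edge with probability ``intra_module_edge_prob``, every other pair with
    ``background_edge_prob``.
    """
    spec.validate()
    rng = substream(spec, "ppi")
    nodes = sorted(catalog.proteins) + [f"N{i:05d}" for i in range(spec.n_extra_proteins)]
    n = len(nodes)
    if spec.n_modules * spec.module_size > n:
        raise ValidationError(
            f"cannot plant {spec.n_modules} modules of {spec.module_size} in {n} proteins"
        )
    shuffled = list(nodes)
    rng.shuffle(shuffled)
    modules: List[FrozenSet[str]] = []
    for m in range(spec.n_modules):
        members = shuffled[m * spec.module_size : (m + 1) * spec.module_size]
        modules.append(frozenset(members))

    g = nx.Graph()
    g.add_nodes_from(nodes)
    intra_pairs: Set[Tuple[str, str]] = set()
    for members in modules:
        mem = sorted(members)
        for i in range(len(mem)):
            for j in range(i + 1, len(mem)):
                intra_pairs.add((mem[i], mem[j]))
    if intra_pairs:
        ordered = sorted(intra_pairs)
        keep = rng.random(len(ordered)) < spec.intra_module_edge_prob
        g.add_edges_from(p for p, k in zip(ordered, keep) if k)

    # Background: Binomial count over non-intra pairs, positions uniform
    # without replacement (equivalent in law to per-pair Bernoulli draws).
    total_pairs = n * (n - 1) // 2
    n_bg_pairs = total_pairs - len(intra_pairs)
    if n_bg_pairs > 0 and spec.background_edge_prob > 0:
        m_bg = int(rng.binomial(n_bg_pairs, spec.background_edge_prob))
        chosen: Set[Tuple[str, str]] = set()
        while len(chosen) < m_bg:
            need = m_bg - len(chosen)
            ii = rng.integers(0, n, size=max(2 * need, 16))
            jj = rng.integers(0, n, size=max(2 * need, 16))
            for a, b in zip(ii, jj):
                if a == b:
                    continue
                u, v = nodes[min(a, b)], nodes[max(a, b)]
                pair = (u, v)
                if pair in intra_pairs or pair in chosen or g.has_edge(u, v):
                    continue
                chosen.add(pair)
                if len(chosen) == m_bg:
                    break
        g.add_edges_from(chosen)
    return g, modules


# ---------------------------------------------------------------------------
# Expression matrix
# ---------------------------------------------------------------------------


def generate_expression(
    spec: SyntheticSpec, catalog: CofactorTable
) -> Tuple[ExpressionMatrix, Dict[str, object]]:
    """Gene x tissue expression with planted structure.

    * Co-expressed groups: the protein sets of the ``n_coexpr_groups``
      largest cofactors (>= 10 proteins) share a latent tissue profile,
      scaled per gene and perturbed by additive Gaussian noise of sd
      ``coexpr_noise_sd``, clipped at zero.
    * Tissue-enriched genes: a fraction of the remaining genes gets one
      tissue at ``enriched_fold`` times a flat baseline.
    * Not-detected genes: all-zero rows.
    * Background genes (catalog leftovers plus ``n_background_genes``
      non-catalog genes) draw independent per-tissue abundances.

    Returns the matrix and a ground-truth dict with the planted labels.
    """
    spec.validate()
    rng = substream(spec, "expression")
    tissues = [f"tissue_{i:02d}" for i in range(spec.n_tissues)]
    catalog_genes = sorted(catalog.proteins)
    background_genes = [f"G{i:05d}" for i in range(spec.n_background_genes)]
    genes = catalog_genes + background_genes
    n_genes = len(genes)
    values = np.zeros((n_genes, spec.n_tissues))
    gene_index = {g: i for i, g in enumerate(genes)}

    # Co-expressed groups = protein sets of the largest cofactors.
    eligible = sorted(
        (c for c in catalog.cofactors if len(catalog.proteins_for(c)) >= 10),
        key=lambda c: (-len(catalog.proteins_for(c)), c),
    )
    group_cofactors = eligible[: spec.n_coexpr_groups]
    coexpr_groups: Dict[str, List[str]] = {}
    assigned: Set[str] = set()
    for cof in group_cofactors:
        members = [g for g in sorted(catalog.proteins_for(cof)) if g not in assigned]
        if len(members) < 2:
            continue
        latent = rng.gamma(shape=2.0, scale=2.0, size=spec.n_tissues) + 1.0
        for g in members:
            scale = rng.uniform(0.5, 2.0)
            noise = rng.normal(0.0, spec.coexpr_noise_sd, size=spec.n_tissues)
            values[gene_index[g]] = np.clip(latent * scale + noise, 0.0, None)
        coexpr_groups[cof] = members
        assigned.update(members)

    remaining = [g for g in genes if g not in assigned]
    rng.shuffle(remaining)
    n_enriched = int(round(spec.enriched_fraction * len(remaining)))
    n_zero = int(round(spec.not_detected_fraction * len(remaining)))
    enriched_genes = remaining[:n_enriched]
    zero_genes = remaining[n_enriched : n_enriched + n_zero]
    other_genes = remaining[n_enriched + n_zero :]

    tissue_enriched: Dict[str, str] = {}
    for g in enriched_genes:
        t = int(rng.integers(spec.n_tissues))
        base = rng.uniform(1.0, 3.0)
        profile = np.full(spec.n_tissues, base)
        profile += np.clip(rng.normal(0.0, spec.coexpr_noise_sd, spec.n_tissues), -base * 0.2, base * 0.2)
        profile[t] = base * spec.enriched_fold
        values[gene_index[g]] = np.clip(profile, 0.0, None)
        tissue_enriched[g] = tissues[t]

    for g in other_genes:
        values[gene_index[g]] = rng.gamma(shape=3.0, scale=2.0, size=spec.n_tissues)

    df = pd.DataFrame(values, index=pd.Index(genes, name="gene_id"), columns=tissues)
    ground_truth = {
        "coexpr_groups": coexpr_groups,
        "tissue_enriched": tissue_enriched,
        "not_detected": sorted(zero_genes),
    }
    return ExpressionMatrix(df), ground_truth


# ---------------------------------------------------------------------------
# Disease gene maps
# ---------------------------------------------------------------------------

_MIN_CHAIN = 6  # smallest cofactor repertoire in the nested chain; keeps
# every planted disease above the default min-genes nestedness filter.


def generate_disease_map(
    spec: SyntheticSpec, catalog: CofactorTable, source: str = "gwas_like"
) -> Tuple[DiseaseGeneMap, Dict[str, object]]:
    """Disease -> gene sets whose induced disease x cofactor incidence has
    the requested shape.

    ``perfectly_nested``: disease i's cofactor repertoire is a strict
    superset of disease i+1's (a prefix chain over the cofactor list); gene
    sets are built from single-cofactor proteins only, so the induced
    incidence support is exactly the planted repertoire.
    ``noisy_nested``: the nested chain plus a few random extra genes.
    ``random``: independent uniform gene samples.

    Ground truth holds the planted repertoire per disease and the nested
    order (broadest repertoire first); disease identifiers are shuffled so
    the order cannot be read off the ids.
    """
    spec.validate()
    rng = substream(spec, f"disease_{source}")
    single = {
        c: sorted(p for p in catalog.proteins_for(c) if len(catalog.cofactors_for(p)) == 1)
        for c in catalog.cofactors
    }
    # Cofactors usable for exact planting, richest first.
    usable = sorted((c for c in single if single[c]), key=lambda c: (-len(single[c]), c))

    labels = [f"D{i:03d}" for i in range(spec.n_diseases)]
    shuffled_labels = list(labels)
    rng.shuffle(shuffled_labels)

    entries: Dict[str, FrozenSet[str]] = {}
    supports: Dict[str, FrozenSet[str]] = {}
    order: List[str] = []

    if spec.nestedness_shape in ("perfectly_nested", "noisy_nested"):
        longest = _MIN_CHAIN + spec.n_diseases - 1
        if longest > len(usable):
            raise ValidationError(
                f"need {longest} cofactors with single-cofactor proteins for a "
                f"nested chain of {spec.n_diseases} diseases, have {len(usable)}"
            )
        for i in range(spec.n_diseases):
            did = shuffled_labels[i]
            repertoire = usable[: longest - i]
            genes: Set[str] = set()
            for c in repertoire:
                genes.add(str(rng.choice(single[c])))
            if spec.nestedness_shape == "noisy_nested":
                n_noise = int(rng.integers(0, 3))
                pool = sorted(catalog.proteins)
                genes.update(rng.choice(pool, size=n_noise, replace=False))
            entries[did] = frozenset(genes)
            supports[did] = frozenset(repertoire)
            order.append(did)
    else:  # random
        pool = sorted(catalog.proteins)
        for i in range(spec.n_diseases):
            did = shuffled_labels[i]
            size = int(rng.integers(_MIN_CHAIN, 3 * _MIN_CHAIN))
            genes = set(rng.choice(pool, size=min(size, len(pool)), replace=False))
            entries[did] = frozenset(genes)
            supports[did] = frozenset(
                c for g in genes for c in catalog.cofactors_for(g)
            )
        order = sorted(entries, key=lambda d: (-len(supports[d]), d))

    # Non-catalog genes do not alter the induced incidence; add a few so the
    # maps also exercise gene-level enrichment against a mixed universe.
    bg_pool = [f"G{i:05d}" for i in range(spec.n_background_genes)]
    if bg_pool:
        entries = {
            d: frozenset(set(gs) | set(rng.choice(bg_pool, size=min(3, len(bg_pool)), replace=False)))
            for d, gs in entries.items()
        }

    dmap = DiseaseGeneMap(entries=dict(entries), source=source)
    ground_truth = {
        "order": order,
        "supports": {d: sorted(s) for d, s in supports.items()},
    }
    return dmap, ground_truth


# ---------------------------------------------------------------------------
# Convenience: generate and write every input class
# ---------------------------------------------------------------------------


def generate_universe(
    catalog: CofactorTable,
    expr: ExpressionMatrix,
    disease_maps: Sequence[DiseaseGeneMap],
) -> FrozenSet[str]:
    """Gene universe: every identifier seen in any input (a stand-in for a
    genome-wide symbol list)."""
    genes: Set[str] = set(catalog.proteins) | set(expr.genes)
    for dmap in disease_maps:
        for gs in dmap.entries.values():
            genes |= gs
    return frozenset(genes)


def simulate_all(spec: SyntheticSpec, outdir) -> Dict[str, object]:
    """Generate all four input classes, write them as TSV under ``outdir``
    plus a ``ground_truth.json``, and return the ground truth."""
    import json
    from pathlib import Path

    from . import io as cio

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    catalog = generate_cofactor_table(spec)
    ppi, modules = generate_ppi_with_planted_modules(spec, catalog)
    expr, expr_truth = generate_expression(spec, catalog)
    gwas, gwas_truth = generate_disease_map(spec, catalog, source="gwas_like")
    omim, omim_truth = generate_disease_map(spec, catalog, source="omim_like")
    universe = generate_universe(catalog, expr, [gwas, omim])

    cio.write_cofactor_table(catalog, outdir / "catalog.tsv")
    cio.write_ppi(ppi, outdir / "ppi.tsv")
    cio.write_expression(expr, outdir / "expression.tsv")
    cio.write_disease_map(gwas, outdir / "diseases_gwas.tsv")
    cio.write_disease_map(omim, outdir / "diseases_omim.tsv")
    cio.write_gene_list(universe, outdir / "universe.tsv")

    truth = {
        "planted_modules": [sorted(m) for m in modules],
        "expression": expr_truth,
        "diseases_gwas": gwas_truth,
        "diseases_omim": omim_truth,
    }
    with open(outdir / "ground_truth.json", "w") as fh:
        json.dump(truth, fh, indent=1, sort_keys=True)
    return truth
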