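"""MCODE-style module detection and per-module cofactor over-representation.

The detector follows the original molecular-complex-detection scheme:

1. *Vertex weighting.* For each vertex v, take the subgraph induced by its
   closed neighborhood N[v], find the highest k-core of that subgraph, and
   set weight(v) = k_max * density(k_max-core), with density = 2m / (n(n-1))
   (graphs are simple, so the loop-free convention applies). Vertices with
   degree below ``degree_cutoff`` get weight 0.
2. *Seeded growth.* Seeds are taken in descending weight (ties broken by
   lexicographic id, making output independent of input order). Growth is a
   breadth-first expansion from the seed: an unassigned neighbor joins when
   its weight exceeds seed_weight * (1 - node_score_cutoff), up to
   ``max_depth`` levels. Modules are vertex-disjoint: a vertex claimed by
   one module is never revisited.
3. *Post-processing.* ``haircut`` iteratively removes members with fewer
   than two intra-module connections (so singly-connected proteins never
   remain in a module). ``fluff`` (off by default) adds unclaimed neighbors
   whose closed-neighborhood density exceeds the fluff density threshold.

Modules smaller than ``min_report_size`` are still computed but filtered
from the report.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Dict, FrozenSet, List, Optional, Sequence, Set

import networkx as nx
import pandas as pd

from .stats import bh_adjust, hypergeom_right_tail, percentage
from .types import AugmentedNetwork, CofactorTable, EnrichmentResult, ValidationError

logger = logging.getLogger(__name__)


@dataclass
class McodeParams:
    degree_cutoff: int = 2
    node_score_cutoff: float = 0.2
    k_core: int = 2
    max_depth: int = 100
    haircut: bool = True
    fluff: bool = False
    fluff_density: float = 0.1
    min_report_size: int = 10

    def validate(self) -> None:
        if not 0.0 <= self.node_score_cutoff <= 1.0:
            raise ValidationError("node_score_cutoff must be in [0, 1]")
        if self.min_report_size < 1:
            raise ValidationError("min_report_size must be >= 1")
        if self.degree_cutoff < 0 or self.k_core < 0 or self.max_depth < 1:
            raise ValidationError("invalid MCODE parameters")


@dataclass
class Module:
    members: FrozenSet[str]
    seed: str
    score: float  # module density * size, the classic complex score

    def __len__(self) -> int:
        return len(self.members)


@dataclass
class ModuleSet:
    modules: List[Module]  # reported modules (size >= min_report_size)
    all_modules: List[Module]  # every detected module, any size
    vertex_weights: Dict[str, float]


def _density(n_nodes: int, n_edges: int) -> float:
    if n_nodes < 2:
        return 0.0
    return 2.0 * n_edges / (n_nodes * (n_nodes - 1))


def mcode_vertex_weight(graph: nx.Graph, v: str, degree_cutoff: int = 2) -> float:
    """Weight of one vertex: core number of the highest k-core of its closed
    neighborhood times that core's density; 0 below the degree cutoff."""
    if v not in graph:
        raise KeyError(f"vertex {v!r} not in graph")
    if graph.degree(v) < degree_cutoff:
        return 0.0
    closed = set(graph.adj[v]) | {v}
    sub = graph.subgraph(closed)
    cores = nx.core_number(sub)
    k_max = max(cores.values())
    if k_max == 0:
        return 0.0
    core_nodes = [u for u, c in cores.items() if c >= k_max]
    core_sub = sub.subgraph(core_nodes)
    return k_max * _density(core_sub.number_of_nodes(), core_sub.number_of_edges())


def mcode_vertex_weights(graph: nx.Graph, degree_cutoff: int = 2) -> Dict[str, float]:
    return {v: mcode_vertex_weight(graph, v, degree_cutoff) for v in graph.nodes}


def _haircut(graph: nx.Graph, members: Set[str]) -> Set[str]:
    # Iteratively strip members with < 2 intra-module connections.
    members = set(members)
    changed = True
    while changed and len(members) > 1:
        sub = graph.subgraph(members)
        singly = {u for u in members if sub.degree(u) < 2}
        changed = bool(singly)
        members -= singly
    return members


def mcode_find_modules(
    net: AugmentedNetwork | nx.Graph, params: Optional[McodeParams] = None
) -> ModuleSet:
    """Detect dense modules by seeded growth over MCODE vertex weights."""
    params = params or McodeParams()
    params.validate()
    graph = net.graph if isinstance(net, AugmentedNetwork) else net
    weights = mcode_vertex_weights(graph, params.degree_cutoff)

    order = sorted(graph.nodes, key=lambda v: (-weights[v], v))
    assigned: Set[str] = set()
    all_modules: List[Module] = []
    for seed in order:
        if seed in assigned or weights[seed] <= 0.0:
            continue
        threshold = weights[seed] * (1.0 - params.node_score_cutoff)
        members = {seed}
        frontier = [seed]
        depth = 0
        while frontier and depth < params.max_depth:
            nxt: List[str] = []
            for u in frontier:
                for nbr in sorted(graph.adj[u]):
                    if nbr in members or nbr in assigned:
                        continue
                    if weights[nbr] > threshold:
                        members.add(nbr)
                        nxt.append(nbr)
            frontier = nxt
            depth += 1

        # Filter: keep only modules containing a k_core-core.
        sub = graph.subgraph(members)
        if sub.number_of_nodes() == 0:
            continue
        if max(nx.core_number(sub).values(), default=0) < params.k_core:
            assigned |= members  # claimed but not a module
            continue
        if params.haircut:
            members = _haircut(graph, members)
        if params.fluff:
            extra = set()
            for u in sorted(members):
                for nbr in sorted(graph.adj[u]):
                    if nbr in members or nbr in assigned or nbr in extra:
                        continue
                    closed = set(graph.adj[nbr]) | {nbr}
                    csub = graph.subgraph(closed)
                    if _density(csub.number_of_nodes(), csub.number_of_edges()) > params.fluff_density:
                        extra.add(nbr)
            members |= extra
        if not members:
            continue
        assigned |= members
        msub = graph.subgraph(members)
        score = _density(msub.number_of_nodes(), msub.number_of_edges()) * len(members)
        all_modules.append(Module(members=frozenset(members), seed=seed, score=score))

    all_modules.sort(key=lambda m: (-m.score, -len(m.members), min(m.members)))
    reported = [m for m in all_modules if len(m) >= params.min_report_size]
    return ModuleSet(modules=reported, all_modules=all_modules, vertex_weights=weights)


# ---------------------------------------------------------------------------
# Per-module cofactor over-representation and Table-style reporting
# ---------------------------------------------------------------------------


@dataclass
class ModuleEnrichment:
    module_index: int
    cofactor_id: str
    result: EnrichmentResult


def module_cofactor_enrichment(
    modules: ModuleSet,
    catalog: CofactorTable,
    universe: Set[str],
) -> List[ModuleEnrichment]:
    """One right-tail hypergeometric test per (module, cofactor): universe =
    network proteins, marked = proteins interacting with the cofactor, drawn
    = module members. BH-adjusted across all tests."""
    universe = set(universe)
    results: List[ModuleEnrichment] = []
    for mi, module in enumerate(modules.modules):
        members = module.members & universe
        if not members:
            logger.warning("module %d has no members in the universe; skipped", mi)
            continue
        for cof in sorted(catalog.cofactors):
            marked = catalog.proteins_for(cof) & universe
            if not marked:
                continue
            k = len(members & marked)
            p = hypergeom_right_tail(k, len(universe), len(marked), len(members))
            results.append(
                ModuleEnrichment(
                    module_index=mi,
                    cofactor_id=cof,
                    result=EnrichmentResult(
                        universe_size=len(universe),
                        marked=len(marked),
                        drawn=len(members),
                        observed=k,
                        p_value=p,
                    ),
                )
            )
    if results:
        qs = bh_adjust([r.result.p_value for r in results])
        for r, q in zip(results, qs):
            r.result.q_value = float(q)
    return results


def module_report(
    modules: ModuleSet,
    catalog: CofactorTable,
    enrichment: Optional[Sequence[ModuleEnrichment]] = None,
    q_cutoff: float = 0.05,
) -> pd.DataFrame:
    """Per-module summary: size, number and percentage of cofactor-interacting
    proteins (percentage rounded half-up to 1 decimal), and the list of
    cofactors those proteins interact with (restricted to BH-significant
    cofactors when enrichment results are supplied)."""
    catalog_proteins = catalog.proteins
    rows = []
    for mi, module in enumerate(modules.modules):
        cof_members = module.members & catalog_proteins
        if enrichment is not None:
            cofs = sorted(
                e.cofactor_id
                for e in enrichment
                if e.module_index == mi and e.result.q_value <= q_cutoff
            )
        else:
            cofs = sorted({c for p in cof_members for c in catalog.cofactors_for(p)})
        rows.append(
            {
                "module": mi + 1,
                "n_proteins": len(module.members),
                "n_cofactor_proteins": len(cof_members),
                "pct_cofactor_proteins": percentage(len(cof_members), len(module.members), 1),
                "cofactors": ", ".join(cofs),
            }
        )
    return pd.DataFrame(
        rows,
        columns=["module", "n_proteins", "n_cofactor_proteins", "pct_cofactor_proteins", "cofactors"],
    )
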