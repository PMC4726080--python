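"""Readers and writers for the tabular and graph formats the pipeline touches.

Formats are deliberately plain: TSV with a header for tables, a two-column
edge list (or GraphML) for PPI networks, GraphML with ``role`` node
attributes and ``edge_class`` edge attributes for augmented networks.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Dict, Iterable, Mapping, Optional, Union

import networkx as nx
import pandas as pd
import yaml

from .types import (
    AugmentedNetwork,
    CofactorRecord,
    CofactorTable,
    DiseaseGeneMap,
    ExpressionMatrix,
    FormatError,
    ValidationError,
    clean_ppi,
    edge_key,
)

logger = logging.getLogger(__name__)

PathLike = Union[str, Path]

# Minimal built-in alias map standardising cofactor spellings. The curated
# catalogs write the same chemical many ways ("Mg2+", "magnesium", "Mg");
# aliases are configuration, not code: extend or replace via a YAML file
# passed to read_cofactor_table(aliases=...). Lookup is case-insensitive on
# the trimmed name; unknown names are kept as trimmed input.
DEFAULT_COFACTOR_ALIASES: Dict[str, str] = {
    "mg2+": "Mg",
    "magnesium": "Mg",
    "mn2+": "Mn",
    "manganese": "Mn",
    "zn2+": "Zn",
    "zinc": "Zn",
    "ca2+": "Ca",
    "calcium": "Ca",
    "cu2+": "Cu",
    "copper": "Cu",
    "fe2+": "Fe",
    "fe3+": "Fe",
    "iron": "Fe",
    "metal ion": "metal",
    "metal-ion": "metal",
    "nad+": "NAD",
    "nadh": "NAD",
    "nadp+": "NADP",
    "nadph": "NADP",
    "pyridoxal phosphate": "PLP",
    "pyridoxal 5'-phosphate": "PLP",
    "coenzyme a": "CoA",
    "coenzyme q": "CoQ",
    "s-adenosylmethionine": "SAM",
    "glutathione": "GSH",
    "tetrahydrofolate": "THF",
    "thiamine pyrophosphate": "TPP",
    "tetrahydrobiopterin": "BH4",
}


def load_cofactor_aliases(path: PathLike) -> Dict[str, str]:
    """Load a {written name -> canonical name} alias map from YAML."""
    with open(path) as fh:
        data = yaml.safe_load(fh)
    if not isinstance(data, dict):
        raise FormatError(f"alias file {path} must contain a mapping")
    return {str(k).strip().casefold(): str(v).strip() for k, v in data.items()}


def normalize_cofactor_name(name: str, aliases: Optional[Mapping[str, str]] = None) -> str:
    aliases = DEFAULT_COFACTOR_ALIASES if aliases is None else aliases
    trimmed = " ".join(str(name).split())
    return aliases.get(trimmed.casefold(), trimmed)


# ---------------------------------------------------------------------------
# Cofactor table
# ---------------------------------------------------------------------------

_TRUTHY = {"1", "true", "yes", "y", "t"}


def read_cofactor_table(
    path: PathLike, aliases: Optional[Mapping[str, str]] = None
) -> CofactorTable:
    """Read a TSV catalog with header columns ``protein_id``, ``cofactor_id``
    and optional ``source`` / ``binding_site_variant``.

    Cofactor names are normalized (whitespace-trimmed, alias-mapped) and
    duplicate (protein, cofactor) pairs collapsed with merged source tags.
    """
    try:
        df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    except pd.errors.EmptyDataError:
        raise ValidationError(f"cofactor table {path} is empty") from None
    for col in ("protein_id", "cofactor_id"):
        if col not in df.columns:
            raise FormatError(f"cofactor table {path} is missing mandatory column {col!r}")
    if len(df) == 0:
        raise ValidationError(f"cofactor table {path} has no records")
    records = []
    for row in df.itertuples(index=False):
        variant = getattr(row, "binding_site_variant", "")
        records.append(
            CofactorRecord(
                protein_id=str(row.protein_id).strip(),
                cofactor_id=normalize_cofactor_name(row.cofactor_id, aliases),
                source=str(getattr(row, "source", "") or "user"),
                has_binding_site_variant=str(variant).strip().casefold() in _TRUTHY,
            )
        )
    table = CofactorTable(records)
    s = table.summary()
    logger.info(
        "read %s: %d cofactors, %d proteins, %d unique pairs",
        path, s["n_cofactors"], s["n_proteins"], s["n_unique_pairs"],
    )
    return table


def write_cofactor_table(table: CofactorTable, path: PathLike) -> None:
    df = table.to_frame()
    df["binding_site_variant"] = df["binding_site_variant"].map({True: "true", False: "false"})
    df.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# PPI edge lists
# ---------------------------------------------------------------------------


def read_ppi(path: PathLike, fmt: Optional[str] = None) -> nx.Graph:
    """Read a PPI network from a two-column TSV edge list or GraphML.

    The result is a simple undirected graph: self-loops and duplicate pairs
    (in either orientation) are dropped and the number of dropped records is
    logged.
    """
    path = Path(path)
    if fmt is None:
        fmt = "graphml" if path.suffix == ".graphml" else "tsv"
    if fmt == "graphml":
        raw = nx.read_graphml(path)
        g, dropped = clean_ppi((str(u), str(v)) for u, v in raw.edges())
        g.add_nodes_from(str(n) for n in raw.nodes())
    elif fmt == "tsv":
        edges = []
        nodes = []
        with open(path) as fh:
            for lineno, line in enumerate(fh, start=1):
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                fields = line.split("\t")
                if len(fields) == 1:
                    fields = line.split()
                if len(fields) != 2:
                    raise FormatError(
                        f"{path}:{lineno}: expected 2 fields, got {len(fields)}"
                    )
                edges.append((fields[0], fields[1]))
        g, dropped = clean_ppi(edges)
    else:
        raise ValueError(f"unknown PPI format {fmt!r}")
    if dropped:
        logger.info("read %s: dropped %d self-loop/duplicate records", path, dropped)
    if g.number_of_edges() == 0:
        logger.warning("read %s: empty PPI graph", path)
    return g


def write_ppi(graph: nx.Graph, path: PathLike) -> None:
    with open(path, "w") as fh:
        for u, v in sorted(edge_key(u, v) for u, v in graph.edges()):
            fh.write(f"{u}\t{v}\n")


# ---------------------------------------------------------------------------
# Augmented networks (GraphML with role / edge_class attributes)
# ---------------------------------------------------------------------------


def write_network(net: AugmentedNetwork, path: PathLike) -> None:
    """Write an augmented network as GraphML; node roles and edge classes are
    carried as attributes so a round-trip reproduces them."""
    net.validate()
    g = nx.Graph()
    for node, role in net.node_roles.items():
        g.add_node(node, role=role)
    for (u, v), cls in net.edge_classes.items():
        g.add_edge(u, v, edge_class=cls)
    nx.write_graphml(g, path)


def read_network(path: PathLike) -> AugmentedNetwork:
    g = nx.read_graphml(path)
    roles = {str(n): data["role"] for n, data in g.nodes(data=True)}
    classes = {
        edge_key(str(u), str(v)): data["edge_class"] for u, v, data in g.edges(data=True)
    }
    clean = nx.Graph()
    clean.add_nodes_from(roles)
    clean.add_edges_from(classes)
    net = AugmentedNetwork(graph=clean, node_roles=roles, edge_classes=classes)
    net.validate()
    return net


# ---------------------------------------------------------------------------
# Expression matrices
# ---------------------------------------------------------------------------


def read_expression(path: PathLike) -> ExpressionMatrix:
    """Read a gene x tissue TSV; first column = gene id, remaining columns =
    tissue abundances."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.shape[1] < 2:
        raise FormatError(f"expression matrix {path} needs >= 2 tissue columns")
    return ExpressionMatrix(df)


def write_expression(expr: ExpressionMatrix, path: PathLike) -> None:
    expr.data.to_csv(path, sep="\t", index_label="gene_id", float_format="%.6g")


# ---------------------------------------------------------------------------
# Disease gene maps (long TSV: disease_id <tab> gene_id)
# ---------------------------------------------------------------------------


def read_disease_map(path: PathLike, source: str) -> DiseaseGeneMap:
    df = pd.read_csv(path, sep="\t", dtype=str)
    for col in ("disease_id", "gene_id"):
        if col not in df.columns:
            raise FormatError(f"disease map {path} is missing mandatory column {col!r}")
    entries: Dict[str, set] = {}
    for row in df.itertuples(index=False):
        entries.setdefault(str(row.disease_id), set()).add(str(row.gene_id))
    if not entries:
        raise ValidationError(f"disease map {path} has no records")
    return DiseaseGeneMap(entries={d: frozenset(g) for d, g in entries.items()}, source=source)


def write_disease_map(dmap: DiseaseGeneMap, path: PathLike) -> None:
    with open(path, "w") as fh:
        fh.write("disease_id\tgene_id\n")
        for disease in sorted(dmap.entries):
            for gene in sorted(dmap.entries[disease]):
                fh.write(f"{disease}\t{gene}\n")


def read_gene_list(path: PathLike) -> frozenset:
    """Read a one-column gene universe list (header optional, '#' comments)."""
    genes = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#") or line == "gene_id":
                continue
            genes.append(line.split("\t")[0])
    return frozenset(genes)


def write_gene_list(genes: Iterable[str], path: PathLike) -> None:
    with open(path, "w") as fh:
        fh.write("gene_id\n")
        for g in sorted(genes):
            fh.write(f"{g}\n")
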