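"""Bipartite miRNA→target network assembly, degree/hub summaries and
regulator-class gene labelling, with GraphML/SIF export."""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Sequence

import networkx as nx
import pandas as pd

from .io_formats import MTITable, normalize_gene_symbol

__all__ = [
    "filter_mti",
    "build_network",
    "mirna_degree_ranking",
    "classify_genes_by_regulators",
    "export_network",
    "read_network",
]

MIRNA = "mirna"
GENE = "gene"


def filter_mti(
    mti: MTITable,
    mirna_set: Iterable[str],
    gene_set: Iterable[str],
) -> list[tuple[str, str, str]]:
    """Edges whose miRNA is in ``mirna_set`` and whose (normalized) gene is
    in ``gene_set``; input order preserved."""
    mirnas = set(mirna_set)
    genes = {normalize_gene_symbol(g) for g in gene_set}
    return [(m, g, e) for m, g, e in mti.edges if m in mirnas and g in genes]


def build_network(
    edges: Sequence[tuple[str, str, str] | tuple[str, str]],
    mirna_status: dict[str, str] | None = None,
    gene_pathways: dict[str, Sequence[str]] | None = None,
    keep_isolates: bool = False,
    declared_mirnas: Iterable[str] = (),
    declared_genes: Iterable[str] = (),
) -> nx.DiGraph:
    """Directed bipartite graph miRNA→gene with annotations.

    ``mirna_status`` maps miRNA id → DEM status (e.g. co_down / co_up /
    other); ``gene_pathways`` maps gene → member pathway list.  Duplicate
    edges collapse.  Declared nodes without edges are dropped unless
    ``keep_isolates``.  A node typed both miRNA and gene is an error.
    """
    mirna_status = dict(mirna_status or {})
    gene_pathways = {normalize_gene_symbol(g): list(v) for g, v in (gene_pathways or {}).items()}
    g = nx.DiGraph()

    mirna_nodes = set(declared_mirnas)
    gene_nodes = {normalize_gene_symbol(x) for x in declared_genes}
    for edge in edges:
        mirna, gene = edge[0], normalize_gene_symbol(edge[1])
        mirna_nodes.add(mirna)
        gene_nodes.add(gene)
    overlap = mirna_nodes & gene_nodes
    if overlap:
        raise ValueError(f"node(s) typed both miRNA and gene: {sorted(overlap)}")

    for m in sorted(mirna_nodes):
        g.add_node(m, kind=MIRNA, status=mirna_status.get(m, "other"))
    for gene in sorted(gene_nodes):
        g.add_node(gene, kind=GENE, pathways="|".join(gene_pathways.get(gene, [])))
    for edge in edges:
        mirna, gene = edge[0], normalize_gene_symbol(edge[1])
        evidence = edge[2] if len(edge) > 2 else ""
        g.add_edge(mirna, gene, relation="targets", evidence=evidence)

    if not keep_isolates:
        g.remove_nodes_from([n for n in list(g) if g.degree(n) == 0])
    _assert_bipartite(g)
    return g


def _assert_bipartite(g: nx.DiGraph) -> None:
    for u, v in g.edges:
        if g.nodes[u]["kind"] != MIRNA or g.nodes[v]["kind"] != GENE:
            raise ValueError(f"non-bipartite edge {u}->{v}")


def mirna_degree_ranking(g: nx.DiGraph) -> tuple[pd.DataFrame, int]:
    """(ranking, n_active) where ranking lists miRNAs by descending
    out-degree (ties lexicographic) and n_active counts miRNAs with
    degree >= 1."""
    rows = [
        (n, g.out_degree(n))
        for n, data in g.nodes(data=True)
        if data["kind"] == MIRNA
    ]
    rows.sort(key=lambda r: (-r[1], r[0]))
    df = pd.DataFrame(rows, columns=["mirna", "out_degree"])
    return df, int((df["out_degree"] >= 1).sum())


def classify_genes_by_regulators(
    g: nx.DiGraph,
    down_set: Iterable[str],
    up_set: Iterable[str],
) -> dict[str, str]:
    """Label each gene node by its incident regulators: down_only when all
    incoming miRNAs are in ``down_set`` (and there is at least one edge),
    up_only symmetrically, mixed when both sets contribute, none when the
    gene has no edges."""
    down = set(down_set)
    up = set(up_set)
    out: dict[str, str] = {}
    for n, data in g.nodes(data=True):
        if data["kind"] != GENE:
            continue
        regulators = set(g.predecessors(n))
        if not regulators:
            out[n] = "none"
            continue
        has_down = bool(regulators & down)
        has_up = bool(regulators & up)
        if has_down and has_up:
            out[n] = "mixed"
        elif has_down and regulators <= down:
            out[n] = "down_only"
        elif has_up and regulators <= up:
            out[n] = "up_only"
        else:
            out[n] = "mixed" if (has_down or has_up) else "none"
    return out


def export_network(g: nx.DiGraph, path: str | Path, format: str = "graphml") -> Path:
    """Write the network as GraphML (with node kind/status attributes) or
    SIF (``<mirna> targets <gene>`` lines)."""
    path = Path(path)
    if format == "graphml":
        nx.write_graphml(g, path)
    elif format == "sif":
        with open(path, "w") as fh:
            for u, v, data in sorted(g.edges(data=True)):
                fh.write(f"{u}\t{data.get('relation', 'targets')}\t{v}\n")
    else:
        raise ValueError(f"unknown network format {format!r}")
    return path


def read_network(path: str | Path, format: str = "graphml") -> nx.DiGraph:
    """Re-import a network written by :func:`export_network`."""
    path = Path(path)
    if format == "graphml":
        return nx.read_graphml(path)
    if format == "sif":
        g = nx.DiGraph()
        for line in path.read_text().splitlines():
            if not line.strip():
                continue
            u, relation, v = line.split("\t")
            g.add_node(u, kind=MIRNA)
            g.add_node(v, kind=GENE)
            g.add_edge(u, v, relation=relation)
        return g
    raise ValueError(f"unknown network format {format!r}")
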