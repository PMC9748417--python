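"""Per-cell-type gene-interaction graph.

Nodes are the member union of the cell type's communication pathways; edges
are the PPI pairs with both endpoints among the nodes.  Each edge carries
the cosine similarity of its two genes' normalized expression vectors across
the cells of that type (in [0, 1] since expression is nonnegative); each
node carries a two-label potential (probability the gene is present / absent
in the type) filled in by the empirical-Bayes stage.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd

from .preprocess import CellTypeProfile
from .resources_io import LabeledExpression, PPIEdgeList

logger = logging.getLogger("elbp")


def cosine(u: np.ndarray, v: np.ndarray) -> float:
    """Cosine similarity with the all-zero-vector convention cos := 0."""
    nu = float(np.linalg.norm(u))
    nv = float(np.linalg.norm(v))
    if nu == 0.0 or nv == 0.0:
        return 0.0
    return float(np.dot(u, v) / (nu * nv))


@dataclass
class GeneGraph:
    """Undirected gene graph for one cell type.

    ``graph`` node attribute ``psi_pos`` is the +1-label potential (the -1
    potential is its complement); edge attribute ``cos`` is the edge cosine.
    """

    cell_type: object
    graph: nx.Graph

    @property
    def nodes(self) -> set:
        return set(self.graph.nodes)

    @property
    def edges(self) -> set:
        return {tuple(sorted(e)) for e in self.graph.edges}

    def has_potentials(self) -> bool:
        return all("psi_pos" in d for _, d in self.graph.nodes(data=True))


def build_gene_graph(profile: CellTypeProfile, ppi: PPIEdgeList) -> GeneGraph:
    """Pathway-member union intersected with PPI edges; isolated nodes kept."""
    comm = profile.communication_pathways
    if comm.empty:
        raise ValueError(
            f"build_gene_graph: no communication pathways for cell type "
            f"{profile.cell_type!r}"
        )
    nodes: set = set()
    for members in comm["members"]:
        nodes |= set(members)
    if not nodes:
        raise ValueError("build_gene_graph: empty node set")

    g = nx.Graph()
    g.add_nodes_from(sorted(nodes))
    for a, b in ppi.edge_set():
        if a in nodes and b in nodes:
            g.add_edge(a, b)
    return GeneGraph(cell_type=profile.cell_type, graph=g)


def edge_cosines(
    gg: GeneGraph, expr: LabeledExpression, norm: pd.DataFrame, cell_type=None
) -> GeneGraph:
    """Attach per-edge cosines over the cells of ``cell_type``.

    Edges with an endpoint absent from the expression matrix are removed
    (logged count); the nodes themselves stay.
    """
    if cell_type is None:
        cell_type = gg.cell_type
    cols = expr.cells_of_type(cell_type)
    present = set(norm.index)

    dropped = 0
    for a, b in list(gg.graph.edges):
        if a not in present or b not in present:
            gg.graph.remove_edge(a, b)
            dropped += 1
            continue
        u = norm.loc[a].to_numpy()[cols]
        v = norm.loc[b].to_numpy()[cols]
        gg.graph.edges[a, b]["cos"] = cosine(u, v)
    if dropped:
        logger.warning(
            "edge_cosines: removed %d edges with endpoints absent from the matrix",
            dropped,
        )
    return gg


def set_node_potentials(
    gg: GeneGraph, psi_pos: dict, default: float = 0.5
) -> GeneGraph:
    """Attach ψ(+1) per node; genes without a computed prior get ``default``
    (an uninformative potential)."""
    for node in gg.graph.nodes:
        p = float(psi_pos.get(node, default))
        if not (0.0 <= p <= 1.0):
            raise ValueError(f"potential for {node!r} outside [0, 1]: {p}")
        gg.graph.nodes[node]["psi_pos"] = p
    return gg


def graph_tables(gg: GeneGraph) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Node and edge TSV-ready frames (gene / gene_a, gene_b, cos)."""
    nodes = pd.DataFrame(
        {
            "gene": sorted(gg.graph.nodes),
            "psi_pos": [
                gg.graph.nodes[n].get("psi_pos", np.nan) for n in sorted(gg.graph.nodes)
            ],
        }
    )
    rows = [
        (a, b, d.get("cos", np.nan))
        for a, b, d in sorted(gg.graph.edges(data=True), key=lambda e: (e[0], e[1]))
    ]
    edges = pd.DataFrame(rows, columns=["gene_a", "gene_b", "cos"])
    return nodes, edges
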