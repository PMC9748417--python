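"""Binary-label Markov random field over a gene graph, solved by loopy
belief propagation, followed by belief-threshold trimming.

The joint over labels L ∈ {+1, −1} factorizes into node potentials ψ(V_i)
(the empirical-Bayes priors) and pairwise potentials derived from the edge
cosine c:

    ψ(l_i, l_j) = (1 + c)/2   if l_i == l_j
                  (1 − c)/2   otherwise

so an edge with cosine 0 is uninformative and cosine 1 enforces agreement.
Messages are passed synchronously (flooding), normalized each round and
damped; the belief S(V_i) — the approximate marginal probability of label
+1 — is the node potential times the incoming message product, normalized.
On trees this is exact.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from .graph_build import GeneGraph

logger = logging.getLogger("elbp")

LABELS = (+1, -1)


@dataclass
class BeliefResult:
    """Beliefs and trim state for one cell type's graph."""

    cell_type: object
    beliefs: pd.Series  # gene -> S(V_i), probability of label +1
    converged: bool
    iterations: int
    trimmed_nodes: list = field(default_factory=list)
    trimmed_graph: nx.Graph | None = None


def _edge_potential(cos: float) -> np.ndarray:
    """2x2 label-compatibility matrix, rows l_i in (+1,-1), cols l_j."""
    same = (1.0 + cos) / 2.0
    diff = (1.0 - cos) / 2.0
    return np.array([[same, diff], [diff, same]])


def lbp_infer(
    gg: GeneGraph,
    damping: float = 0.5,
    tol: float = 1e-6,
    max_iter: int = 200,
) -> BeliefResult:
    """Run synchronous loopy belief propagation to per-node beliefs.

    Messages start uniform; the damped update is
    ``m_new = (1 − damping) · m_proposed + damping · m_old``; iteration
    stops when the largest message change drops below ``tol``.  On graphs
    where LBP does not converge within ``max_iter`` the current beliefs are
    returned with ``converged=False`` (warning logged), never an exception.
    """
    if not 0.0 <= damping < 1.0:
        raise ValueError("damping must be in [0, 1)")
    g = gg.graph
    nodes = sorted(g.nodes)
    if not nodes:
        raise ValueError("lbp_infer: empty graph")
    for n in nodes:
        if "psi_pos" not in g.nodes[n]:
            raise ValueError(f"lbp_infer: node {n!r} has no potential set")

    psi = {n: np.array([g.nodes[n]["psi_pos"], 1.0 - g.nodes[n]["psi_pos"]]) for n in nodes}
    pot = {}
    for a, b, d in g.edges(data=True):
        if "cos" not in d:
            raise ValueError(f"lbp_infer: edge ({a!r}, {b!r}) has no cosine set")
        m = _edge_potential(float(d["cos"]))
        pot[(a, b)] = m
        pot[(b, a)] = m.T  # symmetric here, kept explicit

    # directed messages m[(i, j)]: message from i to j, over j's labels
    msgs = {(a, b): np.array([0.5, 0.5]) for a, b in pot}
    neighbors = {n: sorted(g.neighbors(n)) for n in nodes}

    iterations = 0
    converged = len(msgs) == 0
    for iterations in range(1, max_iter + 1):
        new_msgs = {}
        delta = 0.0
        for (i, j), old in msgs.items():
            prod = psi[i].copy()
            for k in neighbors[i]:
                if k != j:
                    prod = prod * msgs[(k, i)]
            prop = pot[(i, j)].T @ prod  # sum over l_i
            s = prop.sum()
            prop = prop / s if s > 0 else np.array([0.5, 0.5])
            new = (1.0 - damping) * prop + damping * old
            new /= new.sum()
            new_msgs[(i, j)] = new
            delta = max(delta, float(np.abs(new - old).max()))
        msgs = new_msgs
        if delta < tol:
            converged = True
            break
    if not converged and msgs:
        logger.warning(
            "lbp_infer: no convergence after %d iterations (last delta %.2e)",
            max_iter, delta,
        )

    beliefs = {}
    for n in nodes:
        b = psi[n].copy()
        for k in neighbors[n]:
            b = b * msgs[(k, n)]
        s = b.sum()
        b = b / s if s > 0 else np.array([0.5, 0.5])
        beliefs[n] = float(b[0])
    return BeliefResult(
        cell_type=gg.cell_type,
        beliefs=pd.Series(beliefs, name="belief").sort_index(),
        converged=converged,
        iterations=iterations if msgs else 0,
    )


def trim_graph(
    result: BeliefResult, gg: GeneGraph, threshold: float = 0.7
) -> nx.Graph:
    """Remove nodes whose belief is strictly below ``threshold``.

    A node at exactly the threshold is kept.  Fills ``result.trimmed_nodes``
    and ``result.trimmed_graph`` and returns the induced subgraph; an empty
    result is allowed (logged), not an error.
    """
    kept = [g for g, s in result.beliefs.items() if s >= threshold]
    result.trimmed_nodes = sorted(kept)
    result.trimmed_graph = gg.graph.subgraph(result.trimmed_nodes).copy()
    if not kept:
        logger.warning(
            "trim_graph: no node of cell type %r reached belief %.2f",
            result.cell_type, threshold,
        )
    return result.trimmed_graph


def belief_table(results: dict) -> pd.DataFrame:
    """Long-format belief table: cell_type, gene, belief, kept."""
    rows = []
    for ct, res in results.items():
        kept = set(res.trimmed_nodes)
        for gene, s in res.beliefs.items():
            rows.append((ct, gene, s, gene in kept))
    return pd.DataFrame(rows, columns=["cell_type", "gene", "belief", "kept"])
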