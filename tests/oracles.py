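"""Independent reference implementations used only to check the package.

These deliberately share no code with the implementation: marginals come
from explicit enumeration of the joint over all label assignments, and the
over-representation p-value from enumerating subsets.
"""

import itertools
import math

import numpy as np


def exact_marginals(nodes, edges, psi_pos, edge_cos):
    """Brute-force P(label=+1) per node for the pairwise binary MRF.

    ``psi_pos``: node -> potential of label +1 (label -1 gets 1 - value).
    ``edge_cos``: (a, b) -> cosine; pairwise potential (1+c)/2 on agreement,
    (1-c)/2 on disagreement.
    """
    nodes = list(nodes)
    pos = {n: i for i, n in enumerate(nodes)}
    marg = np.zeros(len(nodes))
    total = 0.0
    for labels in itertools.product((0, 1), repeat=len(nodes)):  # 0 == +1
        w = 1.0
        for n in nodes:
            p = psi_pos[n]
            w *= p if labels[pos[n]] == 0 else (1.0 - p)
        for (a, b), c in edge_cos.items():
            same = labels[pos[a]] == labels[pos[b]]
            w *= (1.0 + c) / 2.0 if same else (1.0 - c) / 2.0
        total += w
        for n in nodes:
            if labels[pos[n]] == 0:
                marg[pos[n]] += w
    return {n: marg[pos[n]] / total for n in nodes}


def enumeration_overrep_p(universe, members, degs):
    """P(overlap >= observed) over all equally likely DEG subsets of the
    universe, by explicit enumeration (universe must be small)."""
    universe = sorted(universe)
    members = set(members) & set(universe)
    degs = set(degs)
    observed = len(members & degs)
    n_hits = 0
    n_total = 0
    for subset in itertools.combinations(universe, len(degs)):
        n_total += 1
        if len(members & set(subset)) >= observed:
            n_hits += 1
    return n_hits / n_total


def random_tree_edges(n, rng):
    """A labelled tree on 0..n-1: each node joins a random earlier node."""
    return [(int(rng.integers(0, i)), i) for i in range(1, n)]


def nb_moments(alpha, beta):
    """Gamma(shape, rate)-Poisson marginal mean and variance."""
    return alpha / beta, alpha * (1 + beta) / beta**2
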