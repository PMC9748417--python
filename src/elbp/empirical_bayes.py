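"""Empirical-Bayes node priors from a Gamma-Poisson count model.

For each cell type k a positive reference set (cells of type k, at most 200)
and a negative reference set (200 cells not of type k) are drawn.  Gene
counts are modelled as Poisson(θ) with θ ~ Gamma(α, β) (shape/rate), whose
marginal moments are

    E(x) = α/β,        Var(x) = α(1+β)/β²

— the negative-binomial mean/variance pair.  Half of each reference set
(seeded split) estimates (α, β) by inverting these moments; the held-out
half yields the posterior mean rate θ as the average single-observation
posterior mean (x+α)/(1+β).  The node prior is the normalized odds

    ψ(+1) = θ₊ / (θ₊ + θ₋),     ψ(−1) = 1 − ψ(+1).

Genes that are zero in more than half of a type's cells are excluded from
prior estimation (they keep an uninformative ψ = 0.5 downstream); a gene
zero in exactly half is kept.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .resources_io import LabeledExpression

logger = logging.getLogger("elbp")

#: relative variance bump applied when a gene is not overdispersed (v <= m),
#: where the moment inversion is undefined; yields a tight, near-Poisson prior.
UNDERDISPERSION_EPS = 1e-3


@dataclass
class ReferenceSets:
    """Positive / negative reference cells for one cell type."""

    cell_type: object
    positive_cells: pd.Index
    negative_cells: pd.Index
    seed: int

    def __post_init__(self) -> None:
        if len(set(self.positive_cells) & set(self.negative_cells)):
            raise ValueError("positive and negative reference sets overlap")


@dataclass
class GammaPrior:
    """Gamma(shape=alpha, rate=beta) prior on the Poisson rate."""

    alpha: float
    beta: float

    def __post_init__(self) -> None:
        if not (np.isfinite(self.alpha) and np.isfinite(self.beta)):
            raise ValueError("non-finite Gamma parameters")
        if self.alpha <= 0 or self.beta <= 0:
            raise ValueError(f"Gamma parameters must be positive: {self}")

    @property
    def mean(self) -> float:
        return self.alpha / self.beta


def build_reference_sets(
    expr: LabeledExpression, cell_type, n: int = 200, seed: int = 0
) -> ReferenceSets:
    """Sample the reference cell sets, uniformly without replacement.

    All type-k cells are taken when fewer than ``n`` exist; likewise for the
    negative set (logged).  Deterministic per seed.
    """
    rng = np.random.default_rng(seed)
    in_idx = expr.cells_of_type(cell_type)
    out_mask = np.ones(expr.n_cells, dtype=bool)
    out_mask[in_idx] = False
    out_idx = np.flatnonzero(out_mask)
    if len(out_idx) == 0:
        raise ValueError(f"no cells outside type {cell_type!r} for the negative set")

    def pick(idx: np.ndarray) -> np.ndarray:
        if len(idx) <= n:
            return idx
        return np.sort(rng.choice(idx, size=n, replace=False))

    pos = pick(in_idx)
    if len(in_idx) < n:
        logger.info(
            "build_reference_sets: type %r has %d < %d cells; using all",
            cell_type, len(in_idx), n,
        )
    neg = pick(out_idx)
    if len(out_idx) < n:
        logger.info(
            "build_reference_sets: only %d cells outside type %r; using all",
            len(out_idx), cell_type,
        )
    return ReferenceSets(
        cell_type=cell_type,
        positive_cells=expr.cell_ids[pos],
        negative_cells=expr.cell_ids[neg],
        seed=seed,
    )


def filter_sparse_genes(
    expr: LabeledExpression, cell_type, max_zero_frac: float = 0.5
) -> list:
    """Genes whose zero fraction within type-k cells is <= ``max_zero_frac``
    (strictly-more-than-half-zero genes are removed)."""
    cols = expr.cells_of_type(cell_type)
    zero_frac = (expr.counts[:, cols] == 0).mean(axis=1)
    return expr.gene_ids[zero_frac <= max_zero_frac].tolist()


def estimate_gamma_params(counts: np.ndarray) -> GammaPrior:
    """Method-of-moments (α, β) from a count vector: β = m/(v−m), α = m²/(v−m).

    Requires overdispersion (v > m); otherwise the variance is clamped to
    m·(1+ε) — the near-Poisson limit — with a logged warning.  An all-zero
    vector gets a vanishingly small prior mean.
    """
    x = np.asarray(counts, dtype=float)
    if x.size < 2:
        raise ValueError("estimate_gamma_params: need at least 2 observations")
    m = float(x.mean())
    v = float(x.var(ddof=1))
    if m == 0.0:
        logger.warning("estimate_gamma_params: all-zero counts; near-zero prior")
        return GammaPrior(alpha=1e-6, beta=1.0)
    if v <= m:
        logger.debug(
            "estimate_gamma_params: underdispersed (m=%.4g, v=%.4g); clamping", m, v
        )
        v = m * (1.0 + UNDERDISPERSION_EPS)
    beta = m / (v - m)
    alpha = m * beta
    return GammaPrior(alpha=alpha, beta=beta)


def posterior_theta(
    counts: np.ndarray, prior: GammaPrior, mode: str = "per_cell"
) -> float:
    """Posterior mean rate over held-out cells.

    ``per_cell`` (default): mean of the single-observation posterior means
    (x+α)/(1+β), i.e. (x̄+α)/(1+β) — a convex combination of the held-out
    sample mean and the prior mean, so the estimate always shrinks toward
    α/β.  ``joint``: the conjugate joint-posterior mean (Σx+α)/(n+β).
    """
    x = np.asarray(counts, dtype=float)
    if x.size == 0:
        raise ValueError("posterior_theta: empty held-out set")
    if mode == "per_cell":
        return float((x + prior.alpha).mean() / (1.0 + prior.beta))
    if mode == "joint":
        return float((x.sum() + prior.alpha) / (x.size + prior.beta))
    raise ValueError(f"unknown mode {mode!r}; expected 'per_cell' or 'joint'")


def prior_prob(theta_pos: float, theta_neg: float, label: int = +1) -> float:
    """ψ(label) = θ_label / (θ₊ + θ₋); the two labels sum to one exactly."""
    if theta_pos < 0 or theta_neg < 0:
        raise ValueError("negative theta")
    total = theta_pos + theta_neg
    if total == 0:
        raise ValueError("prior_prob: both thetas are zero")
    if label == +1:
        return theta_pos / total
    if label == -1:
        # exact complement so the two labels always sum to one
        return 1.0 - theta_pos / total
    raise ValueError(f"label must be +1 or -1, got {label}")


def _split_half(ids: np.ndarray, rng: np.random.Generator):
    """Seeded 50/50 partition; the estimation half gets the ceil."""
    perm = rng.permutation(len(ids))
    half = (len(ids) + 1) // 2
    return ids[perm[:half]], ids[perm[half:]]


def compute_node_priors(
    expr: LabeledExpression,
    genes,
    cell_type,
    n: int = 200,
    seed: int = 0,
    max_zero_frac: float = 0.5,
    theta_mode: str = "per_cell",
) -> pd.DataFrame:
    """Full prior chain for a set of graph genes in one cell type.

    Returns a frame (gene, theta_pos, theta_neg, psi_pos) covering the genes
    that are present in the matrix and pass the sparsity filter; other genes
    are absent from the frame and should receive an uninformative ψ = 0.5.
    """
    refs = build_reference_sets(expr, cell_type, n=n, seed=seed)
    eligible = set(filter_sparse_genes(expr, cell_type, max_zero_frac=max_zero_frac))
    rng = np.random.default_rng(seed)

    pos_idx = expr.cell_ids.get_indexer(refs.positive_cells)
    neg_idx = expr.cell_ids.get_indexer(refs.negative_cells)
    pos_fit, pos_hold = _split_half(pos_idx, rng)
    neg_fit, neg_hold = _split_half(neg_idx, rng)
    if min(len(pos_fit), len(pos_hold), len(neg_fit), len(neg_hold)) < 2:
        raise ValueError(
            "compute_node_priors: reference sets too small for a 50/50 split"
        )

    gene_pos = {g: i for i, g in enumerate(expr.gene_ids)}
    rows = []
    for gene in genes:
        if gene not in gene_pos or gene not in eligible:
            continue
        gi = gene_pos[gene]
        thetas = {}
        for lab, fit, hold in ((+1, pos_fit, pos_hold), (-1, neg_fit, neg_hold)):
            prior = estimate_gamma_params(expr.counts[gi, fit])
            thetas[lab] = posterior_theta(
                expr.counts[gi, hold], prior, mode=theta_mode
            )
        total = thetas[+1] + thetas[-1]
        psi = 0.5 if total == 0 else prior_prob(thetas[+1], thetas[-1], +1)
        rows.append((gene, thetas[+1], thetas[-1], psi))
    return pd.DataFrame(rows, columns=["gene", "theta_pos", "theta_neg", "psi_pos"])
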