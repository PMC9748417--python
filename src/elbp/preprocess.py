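"""QC filtering, normalization, per-cell-type DEG detection and pathway
over-representation, ending in the "communication pathways" that seed each
cell type's gene graph.

Cluster labels are an input: clustering, UMAP and doublet removal happen
upstream and are out of scope here.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.stats
from statsmodels.stats.multitest import multipletests

from .resources_io import GeneSetCollection, LabeledExpression, LigandReceptorTable

logger = logging.getLogger("elbp")

#: library-size target for per-cell normalization (counts per 10k).
NORM_TARGET = 1e4


@dataclass
class CellTypeProfile:
    """Per-cell-type marker genes and their enriched pathways.

    ``degs`` is sorted by p ascending; ``communication_pathways`` is the
    subset of ``enriched_pathways`` whose DEG-overlap contains at least one
    ligand or receptor gene.  Both pathway frames carry the full member set
    (column ``members``) alongside the DEG overlap (column ``overlap``): the
    gene graph is built from the member union of the communication pathways.
    """

    cell_type: object
    degs: pd.DataFrame = field(default_factory=pd.DataFrame)
    enriched_pathways: pd.DataFrame = field(default_factory=pd.DataFrame)
    communication_pathways: pd.DataFrame = field(default_factory=pd.DataFrame)


# ---------------------------------------------------------------------------
# QC and normalization
# ---------------------------------------------------------------------------

def qc_filter_cells(
    expr: LabeledExpression,
    min_umi: int = 200,
    max_mito: float = 0.35,
    mito_prefix: str = "MT-",
) -> LabeledExpression:
    """Drop low-quality cells: UMI strictly below ``min_umi`` or
    mitochondrial fraction strictly above ``max_mito``.

    Boundary cells (UMI == min_umi, mito == max_mito) are retained.  When
    ``mito_fraction`` was not supplied it is computed from genes whose id
    starts with ``mito_prefix``; if no gene matches, the mito filter is
    skipped (logged).  The input is never mutated.
    """
    umi = expr.counts.sum(axis=0)
    keep = umi >= min_umi

    if expr.mito_fraction is not None:
        mito = expr.mito_fraction.to_numpy()
        keep &= mito <= max_mito
    else:
        is_mito = expr.gene_ids.str.startswith(mito_prefix)
        if is_mito.any():
            with np.errstate(invalid="ignore"):
                mito = np.where(
                    umi > 0, expr.counts[is_mito].sum(axis=0) / np.maximum(umi, 1), 0.0
                )
            keep &= mito <= max_mito
        else:
            logger.info(
                "qc_filter_cells: no mito_fraction and no %r genes; "
                "skipping mitochondrial filter",
                mito_prefix,
            )

    if not keep.any():
        raise ValueError(
            "qc_filter_cells removed every cell; review min_umi/max_mito thresholds"
        )
    n_removed = int((~keep).sum())
    if n_removed:
        logger.info("qc_filter_cells: removed %d of %d cells", n_removed, expr.n_cells)
    return expr.subset_cells(np.flatnonzero(keep))


def normalize_log(expr: LabeledExpression, target_sum: float = NORM_TARGET) -> pd.DataFrame:
    """Library-size normalize each cell to ``target_sum`` counts, then log1p.

    Returns a genes x cells float DataFrame indexed like the input.  A cell
    with zero total counts cannot be scaled and is a hard error.
    """
    lib = expr.counts.sum(axis=0).astype(float)
    zero = lib == 0
    if zero.any():
        raise ValueError(
            f"normalize_log: cell {expr.cell_ids[np.flatnonzero(zero)[0]]!r} "
            "has zero total counts"
        )
    norm = np.log1p(expr.counts / lib * target_sum)
    return pd.DataFrame(norm, index=expr.gene_ids, columns=expr.cell_ids)


# ---------------------------------------------------------------------------
# DEG detection
# ---------------------------------------------------------------------------

def find_degs(
    expr: LabeledExpression,
    cell_type,
    alpha: float = 0.05,
    norm: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """One-vs-rest Wilcoxon rank-sum markers for ``cell_type``.

    Tests every gene's normalized expression in the target type against all
    other cells, Bonferroni-adjusts the two-sided p-values (family-wise
    error control at ``alpha``), and returns genes with ``p_adj < alpha``
    and a positive effect (mean normalized expression higher in the target
    type), sorted by p ascending.

    Columns: gene, effect, p, p_adj.
    """
    if norm is None:
        norm = normalize_log(expr)
    in_idx = expr.cells_of_type(cell_type)
    out_mask = np.ones(expr.n_cells, dtype=bool)
    out_mask[in_idx] = False
    out_idx = np.flatnonzero(out_mask)
    if len(in_idx) < 2 or len(out_idx) < 2:
        raise ValueError(
            f"find_degs: need >=2 cells in type {cell_type!r} and in the rest "
            f"(got {len(in_idx)} vs {len(out_idx)})"
        )

    x = norm.to_numpy()[:, in_idx]
    y = norm.to_numpy()[:, out_idx]
    effect = x.mean(axis=1) - y.mean(axis=1)

    # genes constant across all tested cells carry no evidence
    const = (x.min(axis=1) == x.max(axis=1)) & (y.min(axis=1) == y.max(axis=1)) & (
        x[:, 0] == y[:, 0]
    )
    with np.errstate(invalid="ignore", divide="ignore"):
        res = scipy.stats.mannwhitneyu(
            x, y, axis=1, alternative="two-sided", method="asymptotic"
        )
    p = np.asarray(res.pvalue, dtype=float)
    p[~np.isfinite(p)] = 1.0
    p[const] = 1.0
    p = np.clip(p, 0.0, 1.0)

    p_adj = np.minimum(p * expr.n_genes, 1.0)  # Bonferroni
    df = pd.DataFrame(
        {"gene": expr.gene_ids, "effect": effect, "p": p, "p_adj": p_adj}
    )
    df = df[(df["p_adj"] < alpha) & (df["effect"] > 0)]
    df = df.sort_values(
        ["p", "effect", "gene"], ascending=[True, False, True]
    ).reset_index(drop=True)
    return df


# ---------------------------------------------------------------------------
# pathway over-representation
# ---------------------------------------------------------------------------

def enrich_pathways(
    degs,
    gene_sets: GeneSetCollection,
    universe,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """One-sided hypergeometric over-representation of ``degs`` in each set,
    Benjamini-Hochberg adjusted; keeps ``p_adj < alpha``.

    ``universe`` must contain every DEG.  Set members outside the universe
    are ignored for the test but retained in the ``members`` column.

    Columns: pathway, members, overlap, p, p_adj.
    """
    deg_set = set(degs)
    universe = set(universe)
    if not deg_set <= universe:
        missing = sorted(deg_set - universe)
        raise ValueError(f"enrich_pathways: DEGs outside universe: {missing[:5]}")
    if not deg_set:
        return pd.DataFrame(columns=["pathway", "members", "overlap", "p", "p_adj"])

    M, N = len(universe), len(deg_set)
    rows = []
    for name, members in gene_sets.sets.items():
        members_in = members & universe
        overlap = sorted(members_in & deg_set)
        n = len(members_in)
        k = len(overlap)
        p = float(scipy.stats.hypergeom.sf(k - 1, M, n, N)) if n else 1.0
        rows.append((name, sorted(members), overlap, min(p, 1.0)))
    if not rows:
        return pd.DataFrame(columns=["pathway", "members", "overlap", "p", "p_adj"])
    df = pd.DataFrame(rows, columns=["pathway", "members", "overlap", "p"])
    df["p_adj"] = multipletests(df["p"].to_numpy(), method="fdr_bh")[1]
    df = df[df["p_adj"] < alpha]
    return df.sort_values(["p", "pathway"]).reset_index(drop=True)


def select_communication_pathways(
    enriched: pd.DataFrame, lr: LigandReceptorTable
) -> pd.DataFrame:
    """Keep enriched pathways whose DEG overlap contains at least one ligand
    or receptor gene from the pair table."""
    if enriched.empty or len(lr) == 0:
        return enriched.iloc[0:0]
    lr_genes = lr.genes
    keep = enriched["overlap"].map(lambda genes: bool(set(genes) & lr_genes))
    return enriched[keep].reset_index(drop=True)


def profile_cell_type(
    expr: LabeledExpression,
    cell_type,
    gene_sets: GeneSetCollection,
    lr: LigandReceptorTable,
    alpha_deg: float = 0.05,
    alpha_enrich: float = 0.05,
    norm: pd.DataFrame | None = None,
) -> CellTypeProfile:
    """DEGs -> enriched pathways -> communication pathways for one type."""
    degs = find_degs(expr, cell_type, alpha=alpha_deg, norm=norm)
    enriched = enrich_pathways(
        degs["gene"].tolist(), gene_sets, expr.gene_ids, alpha=alpha_enrich
    )
    comm = select_communication_pathways(enriched, lr)
    return CellTypeProfile(
        cell_type=cell_type,
        degs=degs,
        enriched_pathways=enriched,
        communication_pathways=comm,
    )
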