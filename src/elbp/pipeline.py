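"""End-to-end orchestration: QC -> DEGs -> communication pathways -> gene
graphs -> empirical-Bayes priors -> loopy BP -> trimming -> interaction,
TF-regulon and panel scoring.

All stage functions remain independently usable; this module only wires
them together with one configuration object and one seed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import pandas as pd

from . import empirical_bayes, graph_build, mrf_lbp, preprocess, scoring
from .resources_io import LabeledExpression, LigandReceptorTable, PPIEdgeList

logger = logging.getLogger("elbp")


@dataclass
class PipelineConfig:
    """Tunable knobs for every stage (defaults follow the method's stated
    thresholds: UMI >= 200, mito <= 35%, p_adj < 0.05, 200 reference cells,
    half-zero sparse-gene cut, belief trim at 0.7)."""

    min_umi: int = 200
    max_mito: float = 0.35
    mito_prefix: str = "MT-"
    alpha_deg: float = 0.05
    alpha_enrich: float = 0.05
    alpha_tf: float = 0.05
    ref_n: int = 200
    max_zero_frac: float = 0.5
    theta_mode: str = "per_cell"
    damping: float = 0.5
    tol: float = 1e-6
    max_iter: int = 200
    trim_threshold: float = 0.7
    cosine_mode: str = "subsample"

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        unknown = set(d) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)


@dataclass
class PipelineResult:
    expr: LabeledExpression
    norm: pd.DataFrame
    profiles: dict = field(default_factory=dict)   # type -> CellTypeProfile
    graphs: dict = field(default_factory=dict)     # type -> GeneGraph
    beliefs: dict = field(default_factory=dict)    # type -> BeliefResult
    interactions: scoring.InteractionScores | None = None
    tf_scores: dict = field(default_factory=dict)  # type -> TFRegulonScores
    panels: dict = field(default_factory=dict)     # type -> DataFrame


def run_pipeline(
    expr: LabeledExpression,
    gene_sets,
    lr: LigandReceptorTable,
    ppi: PPIEdgeList,
    tf_targets: dict,
    config: PipelineConfig | None = None,
    seed: int = 0,
) -> PipelineResult:
    """Run every stage on one dataset.

    Cell types without communication pathways, or whose trimmed network is
    empty, simply contribute nothing downstream (logged) — the run itself
    never fails for lack of signal.
    """
    cfg = config or PipelineConfig()
    expr = preprocess.qc_filter_cells(
        expr, min_umi=cfg.min_umi, max_mito=cfg.max_mito, mito_prefix=cfg.mito_prefix
    )
    norm = preprocess.normalize_log(expr)
    result = PipelineResult(expr=expr, norm=norm)

    for k, cell_type in enumerate(expr.cell_types):
        profile = preprocess.profile_cell_type(
            expr, cell_type, gene_sets, lr,
            alpha_deg=cfg.alpha_deg, alpha_enrich=cfg.alpha_enrich, norm=norm,
        )
        result.profiles[cell_type] = profile
        if profile.communication_pathways.empty:
            logger.info("pipeline: no communication pathways for %r; skipped",
                        cell_type)
            continue

        gg = graph_build.build_gene_graph(profile, ppi)
        graph_build.edge_cosines(gg, expr, norm)
        priors = empirical_bayes.compute_node_priors(
            expr, sorted(gg.nodes), cell_type,
            n=cfg.ref_n, seed=seed + k, max_zero_frac=cfg.max_zero_frac,
            theta_mode=cfg.theta_mode,
        )
        graph_build.set_node_potentials(
            gg, dict(zip(priors["gene"], priors["psi_pos"])), default=0.5
        )
        result.graphs[cell_type] = gg

        belief = mrf_lbp.lbp_infer(
            gg, damping=cfg.damping, tol=cfg.tol, max_iter=cfg.max_iter
        )
        mrf_lbp.trim_graph(belief, gg, threshold=cfg.trim_threshold)
        result.beliefs[cell_type] = belief

    result.interactions = scoring.score_interactions(
        lr, result.beliefs, expr, norm, mode=cfg.cosine_mode, seed=seed
    )

    for cell_type, belief in result.beliefs.items():
        if not belief.trimmed_nodes:
            continue
        tfs = scoring.score_tfs(
            tf_targets, belief, expr, norm, expr.gene_ids, alpha=cfg.alpha_tf
        )
        result.tf_scores[cell_type] = tfs
        membership = {
            row["pathway"]: set(row["members"])
            for _, row in result.profiles[cell_type].communication_pathways.iterrows()
        }
        result.panels[cell_type] = scoring.extract_panel(
            tfs, belief, cell_type, pathway_membership=membership
        )
    return result
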