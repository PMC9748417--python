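"""Interaction and regulon scoring on the trimmed networks.

* CGscore — connection strength of a ligand-receptor pair between an
  ordered pair of cell types: S(ligand in sender) × cross-type cosine ×
  S(receptor in receiver).  Scored only when the ligand survives trimming
  in the sender and the receptor in the receiver.
* CTscore — the mean CGscore of an ordered cell-type pair; the highest
  CTscore flags the most strongly interacting types.
* TFscore — for transcription factors whose database targets are
  over-represented in a type's trimmed network (raw hypergeometric
  p < 0.05, per source database), the mean over regulon genes of
  belief × cosine(gene, TF) within that type.
* Panel extraction — the overlap of TF regulon genes with the trimmed
  ligand/receptor network of a cell type, with per-gene provenance.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.stats
from statsmodels.stats.multitest import multipletests

from .graph_build import cosine
from .mrf_lbp import BeliefResult
from .resources_io import GeneSetCollection, LabeledExpression, LigandReceptorTable

logger = logging.getLogger("elbp")


@dataclass
class InteractionScores:
    """CGscores per (sender, receiver, ligand, receptor) and the CTscore
    matrix over ordered cell-type pairs (sorted descending)."""

    cg: pd.DataFrame
    ct: pd.DataFrame

    def ct_score(self, type_i, type_j) -> float:
        row = self.ct[(self.ct["type_i"] == type_i) & (self.ct["type_j"] == type_j)]
        if row.empty:
            raise KeyError(f"no CTscore for ordered pair ({type_i!r}, {type_j!r})")
        return float(row["ct_score"].iloc[0])


@dataclass
class TFRegulonScores:
    """Per (TF, cell type, source db): enrichment p, p_adj, TFscore and the
    regulon (targets ∩ trimmed network)."""

    scores: pd.DataFrame
    regulons: dict = field(default_factory=dict)  # (cell_type, tf) -> sorted genes


# ---------------------------------------------------------------------------
# ligand-receptor scoring
# ---------------------------------------------------------------------------

def cg_score(belief_i: float, belief_j: float, cross_cos: float) -> float:
    """Product S_i · cos · S_j; bounded by min(S_i, S_j)."""
    for name, v in (("belief_i", belief_i), ("belief_j", belief_j),
                    ("cross_cos", cross_cos)):
        if not 0.0 <= v <= 1.0:
            raise ValueError(f"{name} outside [0, 1]: {v}")
    return belief_i * cross_cos * belief_j


def cross_type_cosine(
    expr: LabeledExpression,
    norm: pd.DataFrame,
    ligand: str,
    type_i,
    receptor: str,
    type_j,
    mode: str = "subsample",
    seed: int = 0,
) -> float:
    """Cosine between a ligand vector in the sender type and a receptor
    vector in the receiver type.

    The two vectors live over different cells, so a pairing rule is needed:

    * ``subsample`` — both types are down-sampled (seeded, without
      replacement) to the smaller cell count and the equal-length vectors
      compared; deterministic per seed.
    * ``pseudobulk`` — per-sample mean vectors over the sample ids shared
      by both types (requires >= 2 shared samples).
    """
    for gene in (ligand, receptor):
        if gene not in norm.index:
            raise KeyError(f"gene {gene!r} absent from expression matrix")
    cells_i = expr.cells_of_type(type_i)
    cells_j = expr.cells_of_type(type_j)

    if mode == "subsample":
        m = min(len(cells_i), len(cells_j))
        rng = np.random.default_rng(seed)
        if len(cells_i) > m:
            cells_i = np.sort(rng.choice(cells_i, size=m, replace=False))
        if len(cells_j) > m:
            cells_j = np.sort(rng.choice(cells_j, size=m, replace=False))
        u = norm.loc[ligand].to_numpy()[cells_i]
        v = norm.loc[receptor].to_numpy()[cells_j]
        return cosine(u, v)

    if mode == "pseudobulk":
        if expr.sample_id is None:
            raise ValueError("pseudobulk mode requires per-cell sample_id labels")
        sid = expr.sample_id.to_numpy()
        shared = sorted(set(sid[cells_i]) & set(sid[cells_j]))
        if len(shared) < 2:
            raise ValueError(
                "pseudobulk mode needs >= 2 samples shared by both cell types "
                f"(got {len(shared)}); consider mode='subsample'"
            )
        lig = norm.loc[ligand].to_numpy()
        rec = norm.loc[receptor].to_numpy()
        u = np.array([lig[cells_i[sid[cells_i] == s]].mean() for s in shared])
        v = np.array([rec[cells_j[sid[cells_j] == s]].mean() for s in shared])
        return cosine(u, v)

    raise ValueError(f"unknown mode {mode!r}; expected 'subsample' or 'pseudobulk'")


def score_interactions(
    lr: LigandReceptorTable,
    results: dict,
    expr: LabeledExpression,
    norm: pd.DataFrame,
    mode: str = "subsample",
    seed: int = 0,
) -> InteractionScores:
    """CGscores for every ordered cell-type pair and qualifying L/R pair,
    plus the CTscore ranking.

    ``results`` maps cell type -> BeliefResult (trimmed).  A pair qualifies
    for (sender i, receiver j) when the ligand is in i's trimmed network and
    the receptor in j's.
    """
    types = list(results)
    rows = []
    for ti in types:
        trimmed_i = set(results[ti].trimmed_nodes)
        bel_i = results[ti].beliefs
        for tj in types:
            if ti == tj:
                continue
            trimmed_j = set(results[tj].trimmed_nodes)
            bel_j = results[tj].beliefs
            for _, pair in lr.pairs.iterrows():
                lig, rec = pair["ligand"], pair["receptor"]
                if lig not in trimmed_i or rec not in trimmed_j:
                    continue
                cc = cross_type_cosine(
                    expr, norm, lig, ti, rec, tj, mode=mode, seed=seed
                )
                rows.append(
                    (ti, tj, lig, rec,
                     cg_score(float(bel_i[lig]), float(bel_j[rec]), max(cc, 0.0)))
                )
    cg = pd.DataFrame(
        rows, columns=["type_i", "type_j", "ligand", "receptor", "cg_score"]
    )
    if cg.empty:
        ct = pd.DataFrame(columns=["type_i", "type_j", "ct_score", "n_pairs"])
    else:
        ct = (
            cg.groupby(["type_i", "type_j"], as_index=False)
            .agg(ct_score=("cg_score", "mean"), n_pairs=("cg_score", "size"))
            .sort_values("ct_score", ascending=False)
            .reset_index(drop=True)
        )
    return InteractionScores(cg=cg, ct=ct)


# ---------------------------------------------------------------------------
# TF regulon enrichment and scoring
# ---------------------------------------------------------------------------

def tf_enrichment(
    tf_targets: dict,
    trimmed_genes,
    universe,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Hypergeometric over-representation of each TF's targets in the
    trimmed network, per source database.

    ``tf_targets`` maps database name -> GeneSetCollection (one set per
    TF).  TFs are kept at raw p < ``alpha`` (BH-adjusted values are also
    reported); ``multi_db`` flags TFs significant in >= 2 databases.
    """
    trimmed = set(trimmed_genes)
    universe = set(universe)
    if not trimmed <= universe:
        raise ValueError("tf_enrichment: trimmed genes outside universe")
    if not trimmed:
        return pd.DataFrame(
            columns=["tf", "db", "n_targets", "overlap", "p", "p_adj", "multi_db"]
        )
    M, N = len(universe), len(trimmed)
    rows = []
    for db, coll in tf_targets.items():
        for tf, targets in coll.sets.items():
            t_in = targets & universe
            k = len(t_in & trimmed)
            n = len(t_in)
            p = float(scipy.stats.hypergeom.sf(k - 1, M, n, N)) if n else 1.0
            rows.append((tf, db, n, sorted(t_in & trimmed), min(p, 1.0)))
    df = pd.DataFrame(rows, columns=["tf", "db", "n_targets", "overlap", "p"])
    if df.empty:
        df["p_adj"] = []
        df["multi_db"] = []
        return df
    df["p_adj"] = multipletests(df["p"].to_numpy(), method="fdr_bh")[1]
    df = df[df["p"] < alpha].reset_index(drop=True)
    n_dbs = df.groupby("tf")["db"].nunique()
    df["multi_db"] = df["tf"].map(n_dbs >= 2)
    return df.sort_values(["p", "tf", "db"]).reset_index(drop=True)


def tf_score(
    tf: str,
    regulon_genes,
    beliefs: pd.Series,
    expr: LabeledExpression,
    norm: pd.DataFrame,
    cell_type,
) -> float:
    """Mean over regulon genes of belief × cosine(gene, TF) within the type."""
    if tf not in norm.index:
        raise KeyError(f"TF gene {tf!r} absent from expression matrix")
    regulon_genes = sorted(regulon_genes)
    if not regulon_genes:
        raise ValueError(f"tf_score: empty regulon for {tf!r}")
    cols = expr.cells_of_type(cell_type)
    tf_vec = norm.loc[tf].to_numpy()[cols]
    vals = []
    for gene in regulon_genes:
        vals.append(
            float(beliefs[gene]) * cosine(norm.loc[gene].to_numpy()[cols], tf_vec)
        )
    return float(np.mean(vals))


def score_tfs(
    tf_targets: dict,
    result: BeliefResult,
    expr: LabeledExpression,
    norm: pd.DataFrame,
    universe,
    alpha: float = 0.05,
) -> TFRegulonScores:
    """Enrichment + TFscore for one cell type's trimmed network.

    TFs absent from the expression matrix, or whose regulon (targets ∩
    trimmed network) is empty, are skipped with a log line.
    """
    enr = tf_enrichment(tf_targets, result.trimmed_nodes, universe, alpha=alpha)
    trimmed = set(result.trimmed_nodes)
    rows, regulons = [], {}
    for _, r in enr.iterrows():
        tf = r["tf"]
        regulon = sorted(set(r["overlap"]) & trimmed)
        if not regulon:
            logger.info("score_tfs: TF %r has empty regulon; skipped", tf)
            continue
        if tf not in norm.index:
            logger.info("score_tfs: TF %r absent from matrix; skipped", tf)
            continue
        score = tf_score(tf, regulon, result.beliefs, expr, norm, result.cell_type)
        rows.append(
            (tf, result.cell_type, r["db"], len(regulon), r["p"], r["p_adj"],
             bool(r["multi_db"]), score)
        )
        regulons[(result.cell_type, tf)] = regulon
    scores = pd.DataFrame(
        rows,
        columns=["tf", "cell_type", "db", "regulon_size", "p", "p_adj",
                 "multi_db", "tf_score"],
    ).sort_values("tf_score", ascending=False).reset_index(drop=True)
    return TFRegulonScores(scores=scores, regulons=regulons)


# ---------------------------------------------------------------------------
# gene panel
# ---------------------------------------------------------------------------

def extract_panel(
    tf_scores: TFRegulonScores,
    result: BeliefResult,
    cell_type,
    pathway_membership: dict | None = None,
) -> pd.DataFrame:
    """Overlap of TF regulon genes with the trimmed network of ``cell_type``.

    Returns (gene, tf_support, pathway_support) sorted by gene; empty with a
    warning when the inputs are disjoint.  ``pathway_membership`` optionally
    maps pathway name -> member genes for provenance.
    """
    regulon_union: dict[str, set] = {}
    for (ct, tf), genes in tf_scores.regulons.items():
        if ct != cell_type:
            continue
        for g in genes:
            regulon_union.setdefault(g, set()).add(tf)
    trimmed = set(result.trimmed_nodes)
    panel_genes = sorted(set(regulon_union) & trimmed)
    if not panel_genes:
        logger.warning("extract_panel: no overlap between regulons and the "
                       "trimmed network of %r", cell_type)
    rows = []
    for g in panel_genes:
        pws = (
            sorted(n for n, m in pathway_membership.items() if g in m)
            if pathway_membership
            else []
        )
        rows.append((g, ",".join(sorted(regulon_union[g])), ",".join(pws)))
    return pd.DataFrame(rows, columns=["gene", "tf_support", "pathway_support"])
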