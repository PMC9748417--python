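"""Seeded synthetic datasets with the statistical structure the pipeline
assumes, plus ground truth for recovery evaluation.

Counts follow the Gamma-Poisson model the empirical-Bayes stage fits: for
gene g in cell c, a rate θ ~ Gamma(shape a, scale μ/a) is drawn around the
gene's cell-type mean μ and the count is Poisson(θ), so marginal moments are
E = μ and Var = μ + μ²/a.

Planted structure
-----------------
* Each cell type owns a block of marker genes (upregulated there), collected
  into one pathway per type; marker blocks include, for every ordered type
  pair, one decoy ligand (in the sender block) and one decoy receptor (in
  the receiver block) so that every ordered pair carries exactly one
  ligand-receptor pair at the same baseline strength — under the null the
  pairs are exchangeable.
* The planted pair (sender T0 -> receiver T1) gets an extra expression boost
  of factor (1 + boost·ρ) on its ligand and receptor, so ρ = 0 reduces the
  planted pair to a decoy and recovery must be at chance.
* Every marker and TF gene carries an independent per-cell "activity"
  factor f ~ Gamma(a₀, 1/a₀) (mean 1) scaling its Poisson rate in its home
  type, which sets a common baseline level of co-expression noise.  The
  planted TF (expressed in T0) is co-expressed with its target genes by
  mixing their activity factors toward one shared latent factor s:
  f = (1−ρ)·e + ρ·s with e gene-specific and s common, so at ρ = 0 the
  planted TF is statistically exchangeable with the decoys and at ρ → 1 the
  TF and its targets fluctuate together.  Everything stays inside the
  Gamma-mixture-Poisson family.  Decoy TFs have random marker-gene targets
  and purely gene-specific factors.
* TF target sets are emitted for three synthetic source databases with
  jittered memberships, so the multi-database significance flag is
  exercised.

Not emulated: doublets, ambient RNA, batch effects, gene-length or capture
biases — recovery here shows the inference chain works under its own model,
not that it is robust to real-data artifacts.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse

from .resources_io import (
    GeneSetCollection,
    LabeledExpression,
    LigandReceptorTable,
    PPIEdgeList,
)

TF_DBS = ("db1", "db2", "db3")


@dataclass
class SyntheticConfig:
    """Generator defaults; sizes keep a full pipeline run to ~1 s."""

    n_types: int = 3
    cells_per_type: int = 200
    n_genes: int = 300
    n_markers_per_type: int = 15
    background_mean: float = 1.0
    marker_mean: float = 4.0
    #: planted ligand/receptor mean = marker_mean · (1 + planted_boost · rho)
    planted_boost: float = 4.0
    #: co-expression / planted-signal strength in [0, 1]
    rho: float = 0.9
    #: per-gene Gamma shape (dispersion); Var = μ + μ²/gamma_shape
    gamma_shape: float = 4.0
    #: shape of the per-gene / shared activity factors f ~ Gamma(a0, 1/a0)
    latent_shape: float = 2.0
    n_noise_pathways: int = 5
    noise_pathway_size: int = 10
    n_decoy_tfs_per_type: int = 3
    tf_targets_size: int = 8
    n_samples: int = 4

    def validate(self) -> None:
        if self.n_types < 2:
            raise ValueError("need at least 2 cell types")
        if self.n_genes < 20:
            raise ValueError("need at least 20 genes")
        if not 0.0 <= self.rho <= 1.0:
            raise ValueError("rho must lie in [0, 1]")
        if self.n_markers_per_type < 2 * (self.n_types - 1) + 2:
            raise ValueError("marker block too small to host ligand/receptor roles")
        n_tfs = self.n_types * self.n_decoy_tfs_per_type + 1
        if self.n_types * self.n_markers_per_type + n_tfs > self.n_genes:
            raise ValueError("more planted genes than genes; increase n_genes")
        if self.tf_targets_size > self.n_markers_per_type:
            raise ValueError("tf_targets_size exceeds the marker block size")


@dataclass
class SyntheticTruth:
    """What was planted, for recovery scoring."""

    planted_pair: tuple  # (sender type, receiver type, ligand, receptor)
    planted_tf: tuple  # (tf gene, tuple of target genes)
    config: SyntheticConfig
    seed: int
    marker_blocks: dict = field(default_factory=dict)  # type -> genes
    decoy_pairs: list = field(default_factory=list)


@dataclass
class SyntheticBundle:
    expr: LabeledExpression
    gene_sets: GeneSetCollection
    lr: LigandReceptorTable
    ppi: PPIEdgeList
    tf_targets: dict  # db name -> GeneSetCollection
    truth: SyntheticTruth


def generate(config: SyntheticConfig | None = None, seed: int = 0) -> SyntheticBundle:
    """Build the full input bundle; byte-identical per (config, seed)."""
    cfg = config or SyntheticConfig()
    cfg.validate()
    rng = np.random.default_rng(seed)

    types = [f"T{k}" for k in range(cfg.n_types)]
    n_cells = cfg.n_types * cfg.cells_per_type
    genes = [f"G{i:04d}" for i in range(cfg.n_genes)]

    # --- gene roles -------------------------------------------------------
    idx = 0
    marker_blocks: dict[str, list[str]] = {}
    for t in types:
        marker_blocks[t] = genes[idx : idx + cfg.n_markers_per_type]
        idx += cfg.n_markers_per_type
    # within each block: first (n_types-1) genes are ligand slots, the next
    # (n_types-1) are receptor slots
    others = {t: [u for u in types if u != t] for t in types}
    ligand_of = {}   # (sender, receiver) -> ligand gene
    receptor_of = {}  # (sender, receiver) -> receptor gene
    for t in types:
        block = marker_blocks[t]
        for j, u in enumerate(others[t]):
            ligand_of[(t, u)] = block[j]
            receptor_of[(u, t)] = block[cfg.n_types - 1 + j]

    tf_genes: dict[str, list[str]] = {}
    planted_tf = genes[idx]
    tf_genes[types[0]] = [planted_tf]
    idx += 1
    for t in types:
        tf_genes.setdefault(t, [])
        for _ in range(cfg.n_decoy_tfs_per_type):
            tf_genes[t].append(genes[idx])
            idx += 1
    background = genes[idx:]

    sender, receiver = types[0], types[1]
    planted_ligand = ligand_of[(sender, receiver)]
    planted_receptor = receptor_of[(sender, receiver)]

    # planted TF targets: the ligand plus other sender markers
    pool = [g for g in marker_blocks[sender] if g != planted_ligand]
    planted_targets = [planted_ligand] + sorted(
        rng.choice(pool, size=cfg.tf_targets_size - 1, replace=False).tolist()
    )

    # --- mean matrix ------------------------------------------------------
    cell_type = np.repeat(types, cfg.cells_per_type)
    mu = np.full((cfg.n_genes, n_cells), cfg.background_mean, dtype=float)
    gene_pos = {g: i for i, g in enumerate(genes)}
    for t in types:
        cols = np.flatnonzero(cell_type == t)
        for g in marker_blocks[t] + tf_genes[t]:
            mu[gene_pos[g], cols] = cfg.marker_mean
    boost = 1.0 + cfg.planted_boost * cfg.rho
    mu[gene_pos[planted_ligand], cell_type == sender] = cfg.marker_mean * boost
    mu[gene_pos[planted_receptor], cell_type == receiver] = cfg.marker_mean * boost

    # --- rates and counts -------------------------------------------------
    theta = rng.gamma(shape=cfg.gamma_shape, scale=mu / cfg.gamma_shape)
    sender_cols = np.flatnonzero(cell_type == sender)
    shared = rng.gamma(shape=cfg.latent_shape, scale=1.0 / cfg.latent_shape,
                       size=len(sender_cols))
    coexpressed = {planted_tf, *planted_targets}
    for t in types:
        cols = np.flatnonzero(cell_type == t)
        for g in marker_blocks[t] + tf_genes[t]:
            own = rng.gamma(shape=cfg.latent_shape, scale=1.0 / cfg.latent_shape,
                            size=len(cols))
            if t == sender and g in coexpressed:
                factor = (1.0 - cfg.rho) * own + cfg.rho * shared
            else:
                factor = own
            theta[gene_pos[g], cols] *= factor
    counts = rng.poisson(theta).astype(np.int64)

    expr = LabeledExpression(
        counts=counts,
        gene_ids=pd.Index(genes),
        cell_ids=pd.Index([f"C{c:04d}" for c in range(n_cells)]),
        cell_type=pd.Series(cell_type, index=[f"C{c:04d}" for c in range(n_cells)]),
        sample_id=pd.Series(
            [f"s{c % cfg.n_samples}" for c in range(n_cells)],
            index=[f"C{c:04d}" for c in range(n_cells)],
        ),
    )

    # --- resources --------------------------------------------------------
    gene_sets = GeneSetCollection()
    for t in types:
        gene_sets.sets[f"PW_{t}"] = set(marker_blocks[t])
        gene_sets.descriptions[f"PW_{t}"] = f"marker pathway of {t}"
    for m in range(cfg.n_noise_pathways):
        members = rng.choice(background, size=min(cfg.noise_pathway_size,
                                                  len(background)), replace=False)
        gene_sets.sets[f"NOISE{m}"] = set(members.tolist())
        gene_sets.descriptions[f"NOISE{m}"] = "random background set"

    lr_rows = [
        {"ligand": ligand_of[(t, u)], "receptor": receptor_of[(t, u)],
         "pathway": f"PW_{t}"}
        for t in types
        for u in others[t]
    ]
    lr = LigandReceptorTable(pairs=pd.DataFrame(lr_rows))

    ppi_edges: set = set()
    for t in types:
        block = marker_blocks[t]
        for i in range(len(block)):  # ring
            ppi_edges.add(tuple(sorted((block[i], block[(i + 1) % len(block)]))))
        lr_genes = [ligand_of[(t, u)] for u in others[t]] + [
            receptor_of[(u, t)] for u in others[t]
        ]
        for g in lr_genes:  # extra spokes around ligand/receptor genes
            for nb in rng.choice([b for b in block if b != g], size=3, replace=False):
                ppi_edges.add(tuple(sorted((g, nb))))
    for _ in range(20):  # background noise edges, never in any graph
        a, b = rng.choice(background, size=2, replace=False)
        ppi_edges.add(tuple(sorted((a, b))))
    ppi = PPIEdgeList(
        edges=pd.DataFrame(sorted(ppi_edges), columns=["gene_a", "gene_b"])
    )

    tf_targets: dict[str, GeneSetCollection] = {}
    base_targets = {planted_tf: planted_targets}
    for t in types:
        for tf in tf_genes[t]:
            if tf == planted_tf:
                continue
            base_targets[tf] = sorted(
                rng.choice(marker_blocks[t], size=cfg.tf_targets_size,
                           replace=False).tolist()
            )
    for db in TF_DBS:
        coll = GeneSetCollection()
        for tf, targets in base_targets.items():
            jitter_n = max(2, int(round(0.8 * len(targets))))
            kept = sorted(rng.choice(targets, size=jitter_n, replace=False).tolist())
            if tf == planted_tf and planted_ligand not in kept:
                kept = sorted(kept[:-1] + [planted_ligand])
            coll.sets[tf] = set(kept)
            coll.descriptions[tf] = f"synthetic {db} targets of {tf}"
        tf_targets[db] = coll

    truth = SyntheticTruth(
        planted_pair=(sender, receiver, planted_ligand, planted_receptor),
        planted_tf=(planted_tf, tuple(planted_targets)),
        config=cfg,
        seed=seed,
        marker_blocks={t: list(b) for t, b in marker_blocks.items()},
        decoy_pairs=[
            (t, u, ligand_of[(t, u)], receptor_of[(t, u)])
            for t in types
            for u in others[t]
            if (t, u) != (sender, receiver)
        ],
    )
    return SyntheticBundle(
        expr=expr, gene_sets=gene_sets, lr=lr, ppi=ppi,
        tf_targets=tf_targets, truth=truth,
    )


# ---------------------------------------------------------------------------
# recovery evaluation
# ---------------------------------------------------------------------------

def truth_eval(result, truth: SyntheticTruth) -> dict:
    """Score a pipeline run against the planted structure.

    ``result`` is a PipelineResult (duck-typed: needs ``interactions``,
    ``tf_scores`` and ``panels``).  Reports the rank of the planted ordered
    cell-type pair by CTscore (1 = best; None if unscored), the rank of the
    planted TF by TFscore within the sender type, and the recall of the
    planted TF's targets in the sender panel.  Never raises on an empty run.
    """
    sender, receiver, _, _ = truth.planted_pair
    tf, targets = truth.planted_tf

    report: dict = {"recovered": False}

    ct = result.interactions.ct
    if ct.empty:
        report["pair_rank"] = None
        report["n_pairs_scored"] = 0
    else:
        ranked = ct.sort_values("ct_score", ascending=False).reset_index(drop=True)
        hit = ranked[(ranked["type_i"] == sender) & (ranked["type_j"] == receiver)]
        report["pair_rank"] = None if hit.empty else int(hit.index[0]) + 1
        report["n_pairs_scored"] = int(len(ranked))

    tfs = result.tf_scores.get(sender)
    if tfs is None or tfs.scores.empty:
        report["tf_rank"] = None
        report["n_tfs_scored"] = 0
    else:
        per_tf = (
            tfs.scores.groupby("tf")["tf_score"].max().sort_values(ascending=False)
        )
        report["n_tfs_scored"] = int(len(per_tf))
        report["tf_rank"] = (
            int(per_tf.index.get_loc(tf)) + 1 if tf in per_tf.index else None
        )

    panel = result.panels.get(sender)
    if panel is None or panel.empty:
        report["panel_recall"] = 0.0
    else:
        got = set(panel["gene"]) & set(targets)
        report["panel_recall"] = len(got) / len(targets)

    report["recovered"] = report.get("pair_rank") == 1 and report.get("tf_rank") == 1
    return report


# ---------------------------------------------------------------------------
# on-disk bundle (CLI `simulate`)
# ---------------------------------------------------------------------------

def write_bundle(bundle: SyntheticBundle, outdir) -> None:
    """Write the bundle as the plain-text files the readers consume."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    expr = bundle.expr
    scipy.io.mmwrite(
        out / "matrix.mtx", scipy.sparse.coo_matrix(expr.counts), field="integer"
    )
    (out / "features.tsv").write_text("\n".join(expr.gene_ids) + "\n")
    (out / "barcodes.tsv").write_text("\n".join(expr.cell_ids) + "\n")
    labels = pd.DataFrame(
        {
            "cell_id": expr.cell_ids,
            "cell_type": expr.cell_type.to_numpy(),
            "sample_id": expr.sample_id.to_numpy(),
        }
    )
    labels.to_csv(out / "labels.tsv", sep="\t", index=False)

    from .resources_io import write_gmt

    write_gmt(bundle.gene_sets, out / "pathways.gmt")
    bundle.lr.pairs.to_csv(out / "lr_pairs.tsv", sep="\t", index=False)
    bundle.ppi.edges.to_csv(out / "ppi.tsv", sep="\t", index=False)
    for db, coll in bundle.tf_targets.items():
        write_gmt(coll, out / f"tf_{db}.gmt")

    truth = bundle.truth
    payload = {
        "planted_pair": list(truth.planted_pair),
        "planted_tf": [truth.planted_tf[0], list(truth.planted_tf[1])],
        "seed": truth.seed,
        "config": dataclasses.asdict(truth.config),
        "decoy_pairs": [list(p) for p in truth.decoy_pairs],
    }
    (out / "truth.json").write_text(json.dumps(payload, indent=2) + "\n")
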