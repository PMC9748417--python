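"""Readers and writers for the standard input resources.

All science lives elsewhere; this module only parses, validates and writes
the plain-text formats the pipeline consumes:

* expression matrices (MatrixMarket triplet + barcodes/features, or dense TSV)
  with a per-cell label table,
* GMT gene-set collections (pathways, TF target sets),
* ligand-receptor pair tables and PPI edge lists (TSV),
* score tables (TSV, loss-free round-trip at fixed precision).

Gene identity is by symbol string, case-sensitive, with no aliasing: every
curated resource the pipeline uses (ligand-receptor databases, GMT files,
PPI lists) is symbol-keyed. Matrices are genes x cells (10x convention).
"""

from __future__ import annotations

import logging
import os
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse

logger = logging.getLogger("elbp")

#: decimal places used by every table writer; round-trips exactly through
#: pandas' float parser.
FLOAT_PRECISION = 6


# ---------------------------------------------------------------------------
# domain containers
# ---------------------------------------------------------------------------

@dataclass
class LabeledExpression:
    """A genes x cells count matrix with per-cell cluster (cell type) labels.

    Parameters
    ----------
    counts
        Dense nonnegative integer matrix, genes in rows, cells in columns.
    gene_ids, cell_ids
        Unique row / column identifiers.
    cell_type
        One cluster label per cell, aligned with ``cell_ids``.
    sample_id
        Optional per-cell sample-of-origin label (needed for pseudobulk
        cross-type cosines).
    mito_fraction
        Optional per-cell mitochondrial read fraction in [0, 1].
    """

    counts: np.ndarray
    gene_ids: pd.Index
    cell_ids: pd.Index
    cell_type: pd.Series
    sample_id: pd.Series | None = None
    mito_fraction: pd.Series | None = None

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        self.gene_ids = pd.Index(self.gene_ids)
        self.cell_ids = pd.Index(self.cell_ids)
        if self.counts.shape != (len(self.gene_ids), len(self.cell_ids)):
            raise ValueError(
                f"counts shape {self.counts.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.cell_ids)} cells"
            )
        if self.gene_ids.has_duplicates:
            dups = self.gene_ids[self.gene_ids.duplicated()].unique().tolist()
            raise ValueError(f"duplicate gene ids: {dups[:5]}")
        if self.cell_ids.has_duplicates:
            dups = self.cell_ids[self.cell_ids.duplicated()].unique().tolist()
            raise ValueError(f"duplicate cell ids: {dups[:5]}")
        if not np.isfinite(self.counts).all():
            raise ValueError("counts contain non-finite values")
        if (self.counts < 0).any():
            raise ValueError("counts contain negative values")
        self.cell_type = pd.Series(self.cell_type)
        missing = self.cell_ids.difference(self.cell_type.index)
        if len(missing) > 0:
            raise ValueError(f"missing cell_type label for cell {missing[0]!r}")
        self.cell_type = self.cell_type.reindex(self.cell_ids)
        if self.sample_id is not None:
            self.sample_id = pd.Series(self.sample_id).reindex(self.cell_ids)
        if self.mito_fraction is not None:
            mf = pd.Series(self.mito_fraction).reindex(self.cell_ids).astype(float)
            if ((mf < 0) | (mf > 1)).any():
                raise ValueError("mito_fraction outside [0, 1]")
            self.mito_fraction = mf

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_cells(self) -> int:
        return len(self.cell_ids)

    @property
    def cell_types(self) -> list:
        """Distinct cell-type labels in first-appearance order."""
        return list(dict.fromkeys(self.cell_type.tolist()))

    def cells_of_type(self, cell_type) -> np.ndarray:
        """Column indices of the cells carrying ``cell_type``."""
        mask = (self.cell_type == cell_type).to_numpy()
        if not mask.any():
            raise KeyError(f"cell type {cell_type!r} not present")
        return np.flatnonzero(mask)

    def subset_cells(self, keep: np.ndarray) -> "LabeledExpression":
        """New object restricted to the given cell column indices."""
        cells = self.cell_ids[keep]
        return LabeledExpression(
            counts=self.counts[:, keep],
            gene_ids=self.gene_ids,
            cell_ids=cells,
            cell_type=self.cell_type.iloc[keep],
            sample_id=None if self.sample_id is None else self.sample_id.iloc[keep],
            mito_fraction=None
            if self.mito_fraction is None
            else self.mito_fraction.iloc[keep],
        )


@dataclass
class GeneSetCollection:
    """Named gene sets (pathways or TF target sets) with descriptions."""

    sets: dict[str, set] = field(default_factory=dict)
    descriptions: dict[str, str] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.sets)

    def __getitem__(self, name: str) -> set:
        return self.sets[name]

    def names(self) -> list[str]:
        return list(self.sets)


@dataclass
class LigandReceptorTable:
    """Curated ligand-receptor gene pairs, optionally tagged by pathway."""

    pairs: pd.DataFrame  # columns ligand, receptor[, pathway]

    def __post_init__(self) -> None:
        if self.pairs.duplicated(subset=["ligand", "receptor"]).any():
            raise ValueError("duplicate (ligand, receptor) rows")

    @property
    def ligands(self) -> set:
        return set(self.pairs["ligand"])

    @property
    def receptors(self) -> set:
        return set(self.pairs["receptor"])

    @property
    def genes(self) -> set:
        return self.ligands | self.receptors

    def __len__(self) -> int:
        return len(self.pairs)


@dataclass
class PPIEdgeList:
    """Undirected protein-protein interaction edges.

    Confidence weights are carried through but not used by the potentials.
    """

    edges: pd.DataFrame  # columns gene_a, gene_b[, weight]

    def __post_init__(self) -> None:
        if (self.edges["gene_a"] == self.edges["gene_b"]).any():
            raise ValueError("self-loop edges present")
        key = self.edges.apply(
            lambda r: tuple(sorted((r["gene_a"], r["gene_b"]))), axis=1
        )
        if key.duplicated().any():
            raise ValueError("duplicate unordered edges present")

    def edge_set(self) -> set:
        return {
            tuple(sorted(t))
            for t in zip(self.edges["gene_a"], self.edges["gene_b"])
        }

    def __len__(self) -> int:
        return len(self.edges)


# ---------------------------------------------------------------------------
# expression readers
# ---------------------------------------------------------------------------

def _read_labels(labels_path, cell_ids: pd.Index):
    labels = pd.read_csv(labels_path, sep="\t", dtype={"cell_id": str})
    if "cell_id" not in labels.columns or "cell_type" not in labels.columns:
        raise ValueError(
            "label file must have columns 'cell_id' and 'cell_type' "
            f"(optional: sample_id, mito_fraction); got {list(labels.columns)}"
        )
    labels = labels.set_index("cell_id")
    missing = cell_ids.difference(labels.index)
    if len(missing) > 0:
        raise ValueError(f"missing cell_type label for cell {missing[0]!r}")
    cell_type = labels["cell_type"].reindex(cell_ids)
    sample_id = labels["sample_id"].reindex(cell_ids) if "sample_id" in labels else None
    mito = (
        labels["mito_fraction"].reindex(cell_ids).astype(float)
        if "mito_fraction" in labels
        else None
    )
    return cell_type, sample_id, mito


def read_expression(path, format: str = "mtx", labels_path=None) -> LabeledExpression:
    """Read a genes x cells count matrix plus its per-cell label table.

    ``format='mtx'``: ``path`` is a directory holding ``matrix.mtx``,
    ``features.tsv`` (gene ids, first column) and ``barcodes.tsv`` (cell
    ids).  ``format='dense'``: ``path`` is a TSV with gene ids in the first
    column and cell ids as header.

    ``labels_path`` is a TSV with columns ``cell_id``, ``cell_type`` and
    optional ``sample_id`` / ``mito_fraction``; it must cover every cell.
    """
    if format == "mtx":
        path = Path(path)
        mat = scipy.io.mmread(os.fspath(path / "matrix.mtx"))
        counts = np.asarray(
            mat.toarray() if scipy.sparse.issparse(mat) else mat
        )
        gene_ids = pd.Index(
            pd.read_csv(path / "features.tsv", sep="\t", header=None)[0].astype(str)
        )
        cell_ids = pd.Index(
            pd.read_csv(path / "barcodes.tsv", sep="\t", header=None)[0].astype(str)
        )
    elif format == "dense":
        df = pd.read_csv(path, sep="\t", index_col=0)
        counts = df.to_numpy()
        gene_ids = pd.Index(df.index.astype(str))
        cell_ids = pd.Index(df.columns.astype(str))
    else:
        raise ValueError(f"unknown format {format!r}; expected 'mtx' or 'dense'")

    if not np.issubdtype(np.asarray(counts).dtype, np.number):
        raise ValueError("expression matrix contains non-numeric entries")
    if (counts < 0).any():
        raise ValueError("expression matrix contains negative counts")
    counts = np.asarray(counts)
    if not np.allclose(counts, np.round(counts)):
        raise ValueError("expression matrix contains non-integer counts")
    counts = np.round(counts).astype(np.int64)

    if labels_path is None:
        raise ValueError("labels_path is required (per-cell cluster labels)")
    cell_type, sample_id, mito = _read_labels(labels_path, cell_ids)
    return LabeledExpression(
        counts=counts,
        gene_ids=gene_ids,
        cell_ids=cell_ids,
        cell_type=cell_type,
        sample_id=sample_id,
        mito_fraction=mito,
    )


# ---------------------------------------------------------------------------
# GMT / pair-table readers
# ---------------------------------------------------------------------------

def read_gmt(path) -> GeneSetCollection:
    """Parse a standard GMT file: name TAB description TAB gene [TAB gene ...].

    Duplicate member genes within a line are deduplicated; a duplicated set
    name across lines is an error.
    """
    coll = GeneSetCollection()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(
                    f"{path}: line {lineno}: expected >=3 tab-separated fields "
                    f"(name, description, genes...), got {len(fields)}"
                )
            name, desc, *genes = fields
            genes = [g for g in genes if g]
            if not genes:
                raise ValueError(f"{path}: line {lineno}: set {name!r} has no members")
            if name in coll.sets:
                raise ValueError(f"{path}: line {lineno}: duplicate set name {name!r}")
            coll.sets[name] = set(genes)
            coll.descriptions[name] = desc
    return coll


def write_gmt(coll: GeneSetCollection, path) -> None:
    with open(path, "w") as fh:
        for name, members in coll.sets.items():
            desc = coll.descriptions.get(name, "")
            fh.write("\t".join([name, desc, *sorted(members)]) + "\n")


def read_lr_pairs(path) -> LigandReceptorTable:
    """Read a ligand-receptor TSV (columns: ligand, receptor[, pathway]).

    Duplicated (ligand, receptor) rows are collapsed to one, with a logged
    count.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    expected = {"ligand", "receptor"}
    if not expected.issubset(df.columns):
        raise ValueError(
            f"{path}: expected header with columns ligand, receptor[, pathway]; "
            f"got {list(df.columns)}"
        )
    before = len(df)
    df = df.drop_duplicates(subset=["ligand", "receptor"]).reset_index(drop=True)
    if len(df) < before:
        logger.warning(
            "read_lr_pairs: dropped %d duplicate ligand-receptor rows", before - len(df)
        )
    return LigandReceptorTable(pairs=df)


def read_ppi(path) -> PPIEdgeList:
    """Read a PPI TSV (columns: gene_a, gene_b[, weight]).

    Self-loop rows and duplicate unordered pairs are dropped with logged
    counts; weights, when present, must lie in [0, 1].
    """
    df = pd.read_csv(path, sep="\t", dtype={"gene_a": str, "gene_b": str})
    expected = {"gene_a", "gene_b"}
    if not expected.issubset(df.columns):
        raise ValueError(
            f"{path}: expected header with columns gene_a, gene_b[, weight]; "
            f"got {list(df.columns)}"
        )
    loops = df["gene_a"] == df["gene_b"]
    if loops.any():
        logger.warning("read_ppi: dropped %d self-loop rows", int(loops.sum()))
        df = df[~loops]
    key = [tuple(sorted(t)) for t in zip(df["gene_a"], df["gene_b"])]
    dup = pd.Series(key).duplicated().to_numpy()
    if dup.any():
        logger.warning("read_ppi: dropped %d duplicate unordered edges", int(dup.sum()))
        df = df[~dup]
    df = df.reset_index(drop=True)
    if "weight" in df.columns:
        w = df["weight"].astype(float)
        if ((w < 0) | (w > 1)).any():
            raise ValueError(f"{path}: weight outside [0, 1]")
    return PPIEdgeList(edges=df)


# ---------------------------------------------------------------------------
# score table writer / reader (loss-free round trip at fixed precision)
# ---------------------------------------------------------------------------

def write_scores(scores: pd.DataFrame, path) -> None:
    """Write a score table as TSV with floats at %.6f (round-trip exact)."""
    scores.to_csv(path, sep="\t", index=False, float_format=f"%.{FLOAT_PRECISION}f")


def read_scores(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
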