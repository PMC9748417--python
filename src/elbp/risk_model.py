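"""Tumor-microenvironment risk score (TMRS): a signed linear combination of
gene expression values,

    TMRS(sample) = Σ_i β_i · EXP_i ,

with a cohort-median split into high/low risk groups (ties go to low).  The
published nine-gene coefficient vector (IRF1, RHOA, PLAUR, NCF2, CXCR4,
HCK, LYZ, RGS1, VCAN) ships as the default model; fitting (LASSO-Cox) is
out of scope — any coefficient table can be supplied.

The expression scale (log vs. linear) is the caller's responsibility: the
coefficients are applied to the values as given.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd

DEFAULT_MODEL_NAME = "tmrs9"


@dataclass
class RiskModel:
    """Gene -> signed coefficient β_i."""

    coefficients: pd.Series
    name: str = "custom"

    def __post_init__(self) -> None:
        self.coefficients = pd.Series(self.coefficients, dtype=float)
        if len(self.coefficients) == 0:
            raise ValueError("RiskModel needs at least one coefficient")
        if self.coefficients.index.has_duplicates:
            raise ValueError("duplicate gene names in RiskModel")

    @property
    def genes(self) -> list[str]:
        return self.coefficients.index.tolist()


@dataclass
class RiskScores:
    """Per-sample TMRS and the median-split risk group."""

    tmrs: pd.Series
    group: pd.Series  # "high" | "low"


def load_model(path) -> RiskModel:
    """Read a model TSV (columns: gene, beta)."""
    df = pd.read_csv(path, sep="\t")
    if not {"gene", "beta"}.issubset(df.columns):
        raise ValueError(
            f"model file needs columns gene, beta; got {list(df.columns)}"
        )
    return RiskModel(
        coefficients=pd.Series(df["beta"].to_numpy(), index=df["gene"]),
        name=str(path),
    )


def default_model() -> RiskModel:
    """The packaged nine-gene TMRS coefficient vector."""
    ref = resources.files("elbp").joinpath("data/tmrs9.tsv")
    with resources.as_file(ref) as path:
        model = load_model(path)
    model.name = DEFAULT_MODEL_NAME
    return model


def tmrs_evaluate(model: RiskModel, expression: pd.DataFrame) -> RiskScores:
    """Score a samples x genes expression table with a coefficient vector.

    Every model gene must be a column of ``expression``; missing genes are a
    hard error listing them.  Samples with TMRS <= cohort median go to the
    "low" group.
    """
    missing = [g for g in model.genes if g not in expression.columns]
    if missing:
        raise KeyError(f"expression table missing model genes: {missing}")
    sub = expression[model.genes]
    values = sub.to_numpy()
    if not np.issubdtype(values.dtype, np.number):
        raise ValueError("expression table contains non-numeric values")
    if not np.isfinite(values).all():
        raise ValueError("expression table contains non-finite values")
    tmrs = pd.Series(
        values @ model.coefficients.to_numpy(), index=expression.index, name="tmrs"
    )
    median = float(tmrs.median())
    group = pd.Series(
        np.where(tmrs > median, "high", "low"), index=tmrs.index, name="group"
    )
    return RiskScores(tmrs=tmrs, group=group)
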