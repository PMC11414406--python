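"""Count preprocessing: TPM normalization, gene-set filtering, batch correction.

Raw gene-level read counts enter the pipeline here.  Counts are converted to
transcripts per million (TPM), lowly expressed genes are removed based on
their wild-type expression, and additive batch effects are regressed out of
log2-scale values gene by gene while preserving the biological group
structure.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from importlib import resources
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

logger = logging.getLogger(__name__)

#: column names required in the sample metadata table
SAMPLE_COLUMNS = ("background", "genotype", "replicate", "batch")


@dataclass
class CountStudy:
    """A gene x sample integer count matrix with per-sample metadata.

    Attributes
    ----------
    counts:
        DataFrame of nonnegative integers, genes as rows, samples as columns.
    gene_lengths:
        Series mapping gene id -> length in bp (positive).
    samples:
        DataFrame indexed by sample id with columns
        ``background`` (``BY``/``RM``), ``genotype`` (TF id or ``WT``),
        ``replicate`` and ``batch``.
    """

    counts: pd.DataFrame
    gene_lengths: pd.Series
    samples: pd.DataFrame

    def __post_init__(self) -> None:
        if self.counts.index.has_duplicates:
            raise ValueError("duplicate gene ids in count matrix")
        missing = self.counts.index.difference(self.gene_lengths.index)
        if len(missing):
            raise ValueError(f"genes without a length: {list(missing[:5])}")
        missing_meta = self.counts.columns.difference(self.samples.index)
        if len(missing_meta):
            raise ValueError(f"samples without metadata: {list(missing_meta[:5])}")
        for col in SAMPLE_COLUMNS:
            if col not in self.samples.columns:
                raise ValueError(f"sample metadata lacks column {col!r}")

    def wildtype_samples(self, background: str | None = None) -> list[str]:
        """Sample ids whose genotype is ``WT``, optionally per background."""
        meta = self.samples.loc[self.counts.columns]
        mask = meta["genotype"] == "WT"
        if background is not None:
            mask &= meta["background"] == background
        return list(meta.index[mask])


@dataclass
class ExpressionMatrix:
    """Gene x sample expression values on a declared scale.

    ``scale`` is ``"tpm"`` (columns sum to 1e6) or ``"log2tpm"``.
    """

    values: pd.DataFrame
    scale: str

    def __post_init__(self) -> None:
        if self.scale not in ("tpm", "log2tpm"):
            raise ValueError(f"unknown scale {self.scale!r}")


def compute_tpm(study: CountStudy) -> ExpressionMatrix:
    """Length-normalize counts to transcripts per million.

    For gene g in sample j: ``tpm = 1e6 * (c_gj/l_g) / sum_h(c_hj/l_h)``.
    Every output column sums to 1e6.

    Raises
    ------
    ValueError
        If a sample has zero total counts (the normalization is undefined);
        the error names the sample.
    """
    lengths = study.gene_lengths.loc[study.counts.index].to_numpy(float)
    if np.any(lengths <= 0):
        raise ValueError("all gene lengths must be positive")
    rate = study.counts.to_numpy(float) / lengths[:, None]
    colsum = rate.sum(axis=0)
    zero = np.flatnonzero(colsum == 0)
    if zero.size:
        raise ValueError(
            f"sample {study.counts.columns[zero[0]]!r} has no mapped reads; TPM undefined"
        )
    tpm = 1e6 * rate / colsum
    return ExpressionMatrix(
        pd.DataFrame(tpm, index=study.counts.index, columns=study.counts.columns),
        scale="tpm",
    )


def log2_transform(expr: ExpressionMatrix, pseudocount: float = 1.0) -> ExpressionMatrix:
    """log2(TPM + pseudocount); pseudocount defaults to 1 and is configurable."""
    if expr.scale != "tpm":
        raise ValueError("log2_transform expects a TPM-scale matrix")
    return ExpressionMatrix(np.log2(expr.values + pseudocount), scale="log2tpm")


def default_excluded_genes() -> list[str]:
    """The shipped default exclusion list (uracil-biosynthesis pathway genes).

    Stored as an editable YAML config inside the package so the annotation is
    a user-replaceable input rather than hard-coded logic.
    """
    text = resources.files("pleiokit.data").joinpath("excluded_genes.yaml").read_text()
    return list(yaml.safe_load(text)["excluded_genes"])


def define_gene_set(
    expr: ExpressionMatrix,
    wildtype_samples: Sequence[str] | Mapping[str, Sequence[str]],
    exclude_ids: Iterable[str] = (),
) -> pd.Index:
    """Select analyzable genes: mean wild-type TPM >= 1, minus an exclusion list.

    ``wildtype_samples`` is either a flat list of wild-type sample ids or a
    mapping background -> wild-type sample ids.  With a mapping, a gene must
    pass the threshold in every background's own wild type (the joint gene
    set used when both backgrounds are analyzed together).

    The boundary is inclusive: mean TPM exactly 1.0 is retained.
    """
    if expr.scale != "tpm":
        raise ValueError("define_gene_set expects a TPM-scale matrix")
    if isinstance(wildtype_samples, Mapping):
        groups = {k: list(v) for k, v in wildtype_samples.items()}
    else:
        groups = {"all": list(wildtype_samples)}
    if not groups or any(len(v) == 0 for v in groups.values()):
        raise ValueError("wildtype_samples must be nonempty")
    keep = pd.Series(True, index=expr.values.index)
    for _, samples in groups.items():
        keep &= expr.values[samples].mean(axis=1) >= 1.0
    keep &= ~expr.values.index.isin(set(exclude_ids))
    selected = expr.values.index[keep]
    if len(selected) == 0:
        raise ValueError("no genes survive the expression filter")
    return selected


def remove_batch_effects(
    expr: ExpressionMatrix,
    batches: Sequence[str] | pd.Series,
    groups: Sequence[str] | pd.Series | None = None,
) -> ExpressionMatrix:
    """Regress additive batch terms out of a log2-scale matrix.

    Per gene, an ordinary least squares model ``value ~ 1 + batch [+ group]``
    is fit across samples; the estimated batch contribution, recentred to
    mean zero over samples, is subtracted.  Biological structure passed via
    ``groups`` is protected by including it as covariates so the batch
    coefficients only absorb variation orthogonal to it.

    With a single batch the input is returned unchanged.  A batch that is
    confounded 1:1 with a biological group makes the design rank-deficient
    and raises a descriptive error.
    """
    if expr.scale != "log2tpm":
        raise ValueError("remove_batch_effects expects log2-scale values")
    y = expr.values
    batches = pd.Series(np.asarray(batches, dtype=object), index=y.columns)
    if batches.nunique() < 2:
        return ExpressionMatrix(y.copy(), scale=expr.scale)

    batch_dummies = pd.get_dummies(batches, drop_first=True).astype(float)
    parts = [pd.Series(1.0, index=y.columns, name="intercept"), batch_dummies]
    if groups is not None:
        groups = pd.Series(np.asarray(groups, dtype=object), index=y.columns)
        parts.insert(1, pd.get_dummies(groups, drop_first=True).astype(float))
    X = pd.concat(parts, axis=1)
    Xm = X.to_numpy(float)
    if np.linalg.matrix_rank(Xm) < Xm.shape[1]:
        raise ValueError(
            "batch is confounded with the biological grouping (design matrix "
            "rank-deficient); batch effects cannot be separated from group effects"
        )
    beta, *_ = np.linalg.lstsq(Xm, y.to_numpy(float).T, rcond=None)
    batch_cols = [X.columns.get_loc(c) for c in batch_dummies.columns]
    batch_term = batch_dummies.to_numpy(float) @ beta[batch_cols, :]  # samples x genes
    batch_term -= batch_term.mean(axis=0, keepdims=True)
    corrected = y - batch_term.T
    return ExpressionMatrix(corrected, scale=expr.scale)


def strain_means(expr: ExpressionMatrix, samples: pd.DataFrame) -> pd.DataFrame:
    """Mean expression per strain (background, genotype) over replicates.

    The replicate-averaged log2TPM profile is the expression level fed to
    coexpression-module detection.  Columns are named ``background:genotype``.
    """
    meta = samples.loc[expr.values.columns]
    key = meta["background"].astype(str) + ":" + meta["genotype"].astype(str)
    return expr.values.T.groupby(key.to_numpy()).mean().T
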