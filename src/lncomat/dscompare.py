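"""Cross-dataset concordance: common genes, relative sample distances, and
pairwise log2 fold-change correlations between independent expression studies.

Datasets from different platforms are compared only on their exactly matching
gene ids (after case/whitespace canonicalization; no symbol aliasing), via
(a) the sample-by-sample Euclidean distance matrix rescaled by its maximum
entry so values lie in [0, 1], and (b) the Pearson correlation of per-gene
log2 fold changes over the common gene set.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform

from .formats import ContractError, ExpressionMatrix
from .coexpr import pearson


@dataclass
class DatasetBundle:
    """One study's per-gene log2 fold changes (tumor vs normal)."""

    name: str
    log2fc: pd.Series

    def __post_init__(self) -> None:
        if self.log2fc.index.has_duplicates:
            dups = self.log2fc.index[self.log2fc.index.duplicated()].unique()
            raise ContractError(
                f"dataset {self.name!r} has duplicate gene ids: {list(dups)[:5]}")


def _canon(gene_id: str) -> str:
    return str(gene_id).strip().upper()


def common_genes(bundles: list[DatasetBundle]) -> set[str]:
    """Exact intersection of gene ids across datasets after canonicalization."""
    if len(bundles) < 2:
        raise ContractError("need >= 2 datasets to intersect")
    sets = []
    for b in bundles:
        ids = [_canon(g) for g in b.log2fc.index]
        if len(set(ids)) != len(ids):
            raise ContractError(
                f"dataset {b.name!r} has ids that collide after canonicalization")
        sets.append(set(ids))
    out = set.intersection(*sets)
    if not out:
        import warnings
        warnings.warn("datasets share no genes", stacklevel=2)
    return out


def relative_euclidean_matrix(matrix: ExpressionMatrix) -> pd.DataFrame:
    """Sample x sample Euclidean distances divided by the maximum distance.

    Symmetric, zero diagonal, maximum entry exactly 1. All-identical samples
    (zero maximum distance) are a degenerate input and raise.
    """
    v = matrix.values.to_numpy(dtype=float).T  # samples x genes
    if v.shape[0] < 2:
        raise ContractError("need >= 2 samples")
    d = pdist(v, metric="euclidean")
    dmax = d.max()
    if dmax == 0:
        raise ContractError("all samples identical: maximum distance is zero")
    rel = squareform(d / dmax)
    return pd.DataFrame(rel, index=matrix.sample_ids, columns=matrix.sample_ids)


def crossdataset_fc_correlation(
    a: DatasetBundle,
    b: DatasetBundle,
    genes: set[str] | list[str] | None = None,
) -> tuple[float, int]:
    """Pearson r of the two datasets' log2FC over the common genes, with n.

    ``genes`` defaults to the pairwise intersection; ids are canonicalized
    the same way as :func:`common_genes`.
    """
    fa = a.log2fc.rename(index=_canon)
    fb = b.log2fc.rename(index=_canon)
    if genes is None:
        genes = common_genes([a, b])
    genes = sorted(_canon(g) for g in genes)
    missing = [g for g in genes if g not in fa.index or g not in fb.index]
    if missing:
        raise ContractError(f"genes absent from a bundle: {missing[:5]}")
    if len(genes) < 3:
        raise ContractError("need >= 3 common genes for a correlation")
    r = pearson(fa.loc[genes].to_numpy(), fb.loc[genes].to_numpy())
    return r, len(genes)
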