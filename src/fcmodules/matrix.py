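"""Expression-matrix container and shared preprocessing primitives.

A gene-expression study is held as a genes x samples matrix with unique
gene and sample identifiers.  The preprocessing pipeline applied before
component discovery is fixed: quantile normalization between arrays,
gene (row) centering, then per-array (column) scaling and centering.
Sample standard deviations use the unbiased n-1 denominator throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats


@dataclass
class ExpressionMatrix:
    """Genes x samples matrix with row (gene) and column (sample) labels.

    Parameters
    ----------
    values
        Real matrix, rows = genes, columns = samples.  Must be free of
        missing values.
    gene_ids, sample_ids
        Unique ordered identifiers matching the matrix dimensions.
    """

    values: np.ndarray
    gene_ids: list[str] = field(default_factory=list)
    sample_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("expression values must be a 2-D matrix")
        g, s = self.values.shape
        if not self.gene_ids:
            self.gene_ids = [f"g{i}" for i in range(g)]
        if not self.sample_ids:
            self.sample_ids = [f"s{j}" for j in range(s)]
        self.gene_ids = [str(x) for x in self.gene_ids]
        self.sample_ids = [str(x) for x in self.sample_ids]
        if len(self.gene_ids) != g:
            raise ValueError("gene_ids length does not match row count")
        if len(self.sample_ids) != s:
            raise ValueError("sample_ids length does not match column count")
        if len(set(self.gene_ids)) != g:
            raise ValueError("duplicate gene identifiers")
        if len(set(self.sample_ids)) != s:
            raise ValueError("duplicate sample identifiers")
        if np.isnan(self.values).any():
            raise ValueError("missing values are not allowed")

    @property
    def g(self) -> int:
        """Number of genes (rows)."""
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def copy_with(self, values: np.ndarray) -> "ExpressionMatrix":
        return ExpressionMatrix(values, list(self.gene_ids), list(self.sample_ids))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.gene_ids, columns=self.sample_ids)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "ExpressionMatrix":
        return cls(df.to_numpy(dtype=float), [str(i) for i in df.index],
                   [str(c) for c in df.columns])

    def subset_samples(self, sample_ids: Sequence[str]) -> "ExpressionMatrix":
        idx = [self.sample_ids.index(s) for s in sample_ids]
        return ExpressionMatrix(self.values[:, idx], list(self.gene_ids),
                                [self.sample_ids[i] for i in idx])


@dataclass
class DistanceMatrix:
    """Symmetric samples x samples correlation-distance matrix, D = 1 - cor."""

    values: np.ndarray
    sample_ids: list[str]
    metric: str

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = self.values.shape[0]
        if self.values.shape != (n, n):
            raise ValueError("distance matrix must be square")
        if not np.allclose(self.values, self.values.T, atol=1e-10):
            raise ValueError("distance matrix must be symmetric")
        if not np.allclose(np.diag(self.values), 0.0, atol=1e-10):
            raise ValueError("distance matrix must have a zero diagonal")

    @property
    def n(self) -> int:
        return self.values.shape[0]


def read_matrix_tsv(path) -> ExpressionMatrix:
    """Read a tab-separated genes x samples matrix (first column = gene ID)."""
    df = pd.read_csv(path, sep="\t", index_col=0, float_precision="round_trip")
    return ExpressionMatrix.from_frame(df)


def write_matrix_tsv(m: ExpressionMatrix, path) -> None:
    df = m.to_frame()
    df.index.name = "gene_id"
    df.to_csv(path, sep="\t")


def read_matrix_hdf5(path) -> ExpressionMatrix:
    import h5py

    with h5py.File(path, "r") as f:
        values = f["values"][...]
        genes = [x.decode() for x in f["gene_ids"][...]]
        samples = [x.decode() for x in f["sample_ids"][...]]
    return ExpressionMatrix(values, genes, samples)


def write_matrix_hdf5(m: ExpressionMatrix, path) -> None:
    import h5py

    with h5py.File(path, "w") as f:
        f.create_dataset("values", data=m.values)
        f.create_dataset("gene_ids", data=np.array(m.gene_ids, dtype="S"))
        f.create_dataset("sample_ids", data=np.array(m.sample_ids, dtype="S"))


def quantile_normalize(m: ExpressionMatrix,
                       reference: np.ndarray | None = None) -> ExpressionMatrix:
    """Quantile-normalize columns to a common distribution.

    The reference distribution is the vector of row means of the
    column-sorted matrix (the standard between-array procedure).  Ties
    within a column receive the average of the reference values at the
    tied sorted positions, so the map is rank-based and idempotent.

    Parameters
    ----------
    reference
        Optional stored reference distribution (sorted ascending, length =
        number of genes).  By default a fresh reference is computed from
        the matrix itself.
    """
    X = m.values
    if np.isnan(X).any():
        raise ValueError("missing values are not allowed")
    g = X.shape[0]
    if reference is None:
        reference = np.sort(X, axis=0).mean(axis=1)
    else:
        reference = np.asarray(reference, dtype=float)
        if reference.shape != (g,):
            raise ValueError("reference length must equal the gene count")
    out = np.empty_like(X)
    for j in range(X.shape[1]):
        col = X[:, j]
        order = np.argsort(col, kind="mergesort")
        svals = col[order]
        # group boundaries of tied runs in sorted order
        starts = np.flatnonzero(np.r_[True, svals[1:] != svals[:-1]])
        ends = np.r_[starts[1:], g]
        csum = np.r_[0.0, np.cumsum(reference)]
        group_mean = (csum[ends] - csum[starts]) / (ends - starts)
        per_pos = np.repeat(group_mean, ends - starts)
        out[order, j] = per_pos
    return m.copy_with(out)


def center_genes(m: ExpressionMatrix) -> ExpressionMatrix:
    """Subtract each gene's (row) mean."""
    return m.copy_with(m.values - m.values.mean(axis=1, keepdims=True))


def scale_center_arrays(m: ExpressionMatrix) -> ExpressionMatrix:
    """Center each array (column) to mean 0 and scale to sample SD 1."""
    X = m.values
    sd = X.std(axis=0, ddof=1)
    bad = np.flatnonzero(sd == 0)
    if bad.size:
        raise ValueError(
            f"zero-variance column(s): {[m.sample_ids[i] for i in bad]}")
    return m.copy_with((X - X.mean(axis=0)) / sd)


def preprocess(m: ExpressionMatrix) -> ExpressionMatrix:
    """Full preprocessing: quantile normalize, gene-center, array scale/center."""
    return scale_center_arrays(center_genes(quantile_normalize(m)))


def correlation_distance(m: ExpressionMatrix, metric: str = "spearman") -> DistanceMatrix:
    """Pairwise sample distance D_ij = 1 - cor(col_i, col_j).

    metric "spearman" uses rank correlation with average ranks for ties,
    "pearson" the plain product-moment correlation.  Entries lie in
    [0, 2]; 0 means identical ranking/profile, 2 perfect anticorrelation.
    """
    X = m.values
    if X.shape[0] < 2:
        raise ValueError("need at least 2 genes to correlate samples")
    if (X.std(axis=0) == 0).any():
        raise ValueError("constant column: correlation undefined")
    if metric == "spearman":
        R = np.apply_along_axis(stats.rankdata, 0, X)
        C = np.corrcoef(R, rowvar=False)
    elif metric == "pearson":
        C = np.corrcoef(X, rowvar=False)
    else:
        raise ValueError(f"unknown metric {metric!r}")
    C = np.atleast_2d(C)
    D = 1.0 - C
    np.fill_diagonal(D, 0.0)
    D = 0.5 * (D + D.T)
    return DistanceMatrix(D, list(m.sample_ids), metric)
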