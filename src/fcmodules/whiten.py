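"""SVD whitening and parallel-analysis selection of the component count.

The preprocessed compendium X (genes x samples, columns centered and
scaled) is factored as X = U D V^T.  Covariance eigenvalues are
e_i = d_ii^2 / (g - 1), the g - 1 divisor matching the unbiased
variance estimate.  The whitened matrix handed to ICA is
Y = sqrt(g - 1) * U restricted to the leading n columns, so that
Y^T Y = (g - 1) I_n.

The number of components n is chosen by parallel analysis: the observed
eigenvalues are compared with a quantile (Horn: median, Glorfeld: 95th
percentile) of eigenvalues from i.i.d. standard-normal matrices of the
same shape, and a component is retained when its bias-corrected
eigenvalue e_i - bias_i exceeds 1.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .matrix import ExpressionMatrix


@dataclass
class WhitenedData:
    U: np.ndarray          # genes x r, orthonormal columns
    d: np.ndarray          # singular values, length r
    V: np.ndarray          # samples x r
    e: np.ndarray          # covariance eigenvalues d^2/(g-1)
    n: int                 # retained component count
    g: int                 # gene count
    gene_ids: list[str]

    @property
    def Y(self) -> np.ndarray:
        """Whitened matrix sqrt(g-1) * U[:, :n]; satisfies Y'Y = (g-1) I."""
        return np.sqrt(self.g - 1) * self.U[:, : self.n]

    def with_n(self, n: int) -> "WhitenedData":
        if n < 0 or n > self.d.size:
            raise ValueError("n out of range")
        return WhitenedData(self.U, self.d, self.V, self.e, n, self.g, self.gene_ids)


def svd_whiten(x: ExpressionMatrix, n: int | None = None) -> WhitenedData:
    """Whiten a preprocessed matrix via SVD.

    Trailing zero singular values of a rank-deficient input are kept.
    `n` defaults to the full factor rank; parallel analysis normally
    overrides it.
    """
    X = x.values
    if X.size == 0:
        raise ValueError("empty matrix")
    U, d, Vt = np.linalg.svd(X, full_matrices=False)
    g = x.g
    e = d ** 2 / (g - 1)
    r = d.size
    return WhitenedData(U, d, Vt.T, e, r if n is None else n, g, list(x.gene_ids))


def _sim_eigenvalues(g: int, s: int, n_sim: int, rng: np.random.Generator) -> np.ndarray:
    """Eigenvalues (d^2/(g-1)) of n_sim random N(0,1) matrices, shape (n_sim, s)."""
    out = np.empty((n_sim, min(g, s)))
    for i in range(n_sim):
        R = rng.standard_normal((g, s))
        sv = np.linalg.svd(R, compute_uv=False)
        out[i] = sv ** 2 / (g - 1)
    return out


def parallel_analysis(x_or_whitened, n_sim: int = 5000, quantile: float = 0.50,
                      seed: int = 0, rule: str = "corrected_gt_1") -> int:
    """Parallel-analysis component count.

    Parameters
    ----------
    x_or_whitened
        ExpressionMatrix (whitened internally) or a WhitenedData.
    n_sim
        Number of random-matrix simulations.
    quantile
        0.50 for Horn's method (median bias), 0.95 for Glorfeld's.
    rule
        "corrected_gt_1": retain components with e_i - bias_i > 1.
        "above_bias": the conventional e_i > bias_i variant.
    """
    if n_sim < 1:
        raise ValueError("n_sim must be >= 1")
    if isinstance(x_or_whitened, WhitenedData):
        w = x_or_whitened
        g = w.g
        s = w.V.shape[0]
        e = w.e
    else:
        w = svd_whiten(x_or_whitened)
        g, s, e = w.g, x_or_whitened.n_samples, w.e
    rng = np.random.default_rng(seed)
    sims = _sim_eigenvalues(g, s, n_sim, rng)
    bias = np.quantile(sims, quantile, axis=0)[: e.size]
    if rule == "corrected_gt_1":
        keep = (e - bias) > 1.0
    elif rule == "above_bias":
        keep = e > bias
    else:
        raise ValueError(f"unknown rule {rule!r}")
    return int(np.count_nonzero(keep))


def variance_explained(e: np.ndarray, n: int) -> float:
    """Fraction of total covariance eigenvalue mass in the leading n."""
    e = np.asarray(e, dtype=float)
    if np.any(e < 0):
        raise ValueError("eigenvalues must be nonnegative")
    total = e.sum()
    if total == 0:
        raise ValueError("all-zero eigenvalues")
    return float(e[:n].sum() / total)
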