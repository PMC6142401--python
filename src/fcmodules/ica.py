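"""Multi-run ICA on the whitened matrix.

The whitened matrix Y (genes x n, Y'Y = (g-1) I) is decomposed as
Y = S A, with the source matrix S (genes x n) holding one functional
component per column and A the n x n mixing matrix.  Sources are
recovered by maximizing non-Gaussianity (negentropy); because ICA is
only identifiable up to sign and permutation, every solution is brought
to a canonical form (columns sign-flipped to nonnegative skewness, then
ordered by decreasing skewness), and among repeated runs the solution
with the highest total negentropy is kept as the reference.

Two backends are provided:

``logcosh``
    Symmetric fixed-point negentropy maximization with the log cosh
    contrast (the classic FastICA update), fast and deterministic for a
    given seed.
``proden``
    A tilted-Gaussian contrast: each source's log-density is estimated
    nonparametrically on a grid (kernel-smoothed histogram), and the
    fixed-point update uses the estimated score of the tilt
    g(s) = log f(s) - log phi(s).  Slower, but sensitive to a wider
    range of source densities.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import integrate, stats
from scipy.ndimage import gaussian_filter1d

from .whiten import WhitenedData

_E_LOGCOSH_GAUSS: float | None = None


def _e_logcosh_gauss() -> float:
    """E[log cosh nu] for nu ~ N(0,1) (negentropy baseline), cached."""
    global _E_LOGCOSH_GAUSS
    if _E_LOGCOSH_GAUSS is None:
        val, _ = integrate.quad(
            lambda t: np.log(np.cosh(t)) * stats.norm.pdf(t), -12, 12)
        _E_LOGCOSH_GAUSS = val
    return _E_LOGCOSH_GAUSS


@dataclass
class ICASolution:
    """One ICA decomposition Y = S A.

    S columns are standardized (mean 0, sample SD 1).  W is the
    effective unmixing, S = Y W'.
    """

    S: np.ndarray
    A: np.ndarray
    W: np.ndarray
    per_component_negentropy: np.ndarray
    iterations: int
    converged: bool
    seed: int
    backend: str
    gene_ids: list[str] | None = None

    @property
    def n(self) -> int:
        return self.S.shape[1]

    @property
    def total_negentropy(self) -> float:
        return float(self.per_component_negentropy.sum())


def _sym_decorrelate(W: np.ndarray) -> np.ndarray:
    u, _, vt = np.linalg.svd(W)
    return u @ vt


def _logcosh_update(Z: np.ndarray, W: np.ndarray) -> np.ndarray:
    g = Z.shape[0]
    S = Z @ W.T
    G = np.tanh(S)
    Gp = 1.0 - G ** 2
    return (G.T @ Z) / g - np.diag(Gp.mean(axis=0)) @ W


def _tilt_on_grid(s: np.ndarray, grid_points: int, order: float):
    """Estimate the log-density tilt g(s) = log f(s) - log phi(s) on a grid.

    The density is a kernel-smoothed histogram on `grid_points` bins;
    `order` controls the robustness of the smoother (larger = smoother),
    applied as the kernel width in bins.
    """
    lo, hi = s.min() - 0.5, s.max() + 0.5
    grid = np.linspace(lo, hi, grid_points)
    h = grid[1] - grid[0]
    counts, _ = np.histogram(s, bins=grid_points, range=(lo, hi))
    sigma_bins = max(order, 1.06 * s.std() * s.size ** (-0.2) / h)
    dens = gaussian_filter1d(counts.astype(float), sigma_bins, mode="constant")
    dens = dens / (dens.sum() * h)
    dens = np.maximum(dens, 1e-12)
    tilt = np.log(dens) - stats.norm.logpdf(grid)
    d1 = np.gradient(tilt, h)
    d2 = np.gradient(d1, h)
    return grid, tilt, d1, d2


def _proden_update(Z: np.ndarray, W: np.ndarray, grid_points: int,
                   order: float) -> tuple[np.ndarray, np.ndarray]:
    g = Z.shape[0]
    S = Z @ W.T
    W1 = np.empty_like(W)
    negent = np.empty(W.shape[0])
    for j in range(W.shape[0]):
        s = S[:, j]
        grid, tilt, d1, d2 = _tilt_on_grid(s, grid_points, order)
        g1 = np.interp(s, grid, d1)
        g2 = np.interp(s, grid, d2)
        W1[j] = (Z.T @ g1) / g - g2.mean() * W[j]
        negent[j] = np.interp(s, grid, tilt).mean()
    return W1, negent


def run_ica(y, backend: str = "logcosh", tol: float = 1e-6,
            max_iter: int = 8000, grid_points: int = 2000, seed: int = 0,
            order: float = 11.0, n_components: int | None = None) -> ICASolution:
    """Unmix a whitened matrix into independent source columns.

    Parameters
    ----------
    y
        WhitenedData or a genes x n array with orthogonal equal-norm
        columns (output of svd_whiten).
    backend
        "logcosh" or "proden" (see module docstring).
    tol, max_iter
        Convergence is declared when the maximum change in unmixing
        directions falls below `tol`; a non-converged run is returned
        with ``converged=False`` and a warning.
    grid_points, order
        Density-estimation grid size and robustness parameter of the
        proden backend; ignored by logcosh.
    seed
        Seeds the random orthogonal initialization.
    """
    gene_ids = None
    if isinstance(y, WhitenedData):
        gene_ids = y.gene_ids
        Y = y.Y
    else:
        Y = np.asarray(y, dtype=float)
    if Y.ndim != 2 or Y.shape[1] < 1:
        raise ValueError("Y must be a 2-D matrix with at least one column")
    n = Y.shape[1]
    if n_components is not None:
        if n_components > n:
            raise ValueError("n_components exceeds the number of whitened columns")
        Y = Y[:, :n_components]
        n = n_components
    g = Y.shape[0]
    # rescale to unit sample SD columns (whitened convention)
    Z = Y / Y.std(axis=0, ddof=1)

    rng = np.random.default_rng(seed)
    W = _sym_decorrelate(rng.standard_normal((n, n)))

    converged = False
    negent_pd = None
    it = 0
    for it in range(1, max_iter + 1):
        if backend == "logcosh":
            W1 = _logcosh_update(Z, W)
        elif backend == "proden":
            W1, negent_pd = _proden_update(Z, W, grid_points, order)
        else:
            raise ValueError(f"unknown backend {backend!r}")
        W1 = _sym_decorrelate(W1)
        lim = np.max(np.abs(np.abs(np.diag(W1 @ W.T)) - 1.0))
        W = W1
        if lim < tol:
            converged = True
            break
    if not converged:
        warnings.warn(
            f"ICA did not converge within {max_iter} iterations (backend={backend})",
            stacklevel=2)

    S = Z @ W.T
    sd = S.std(axis=0, ddof=1)
    S = (S - S.mean(axis=0)) / sd
    W_eff = (W / Y.std(axis=0, ddof=1)) / sd[:, None]
    # exact mixing for the standardized sources: Y = S A
    A, *_ = np.linalg.lstsq(S, Y, rcond=None)

    if backend == "logcosh":
        negent = (np.log(np.cosh(S)).mean(axis=0) - _e_logcosh_gauss()) ** 2
    else:
        negent = negent_pd if negent_pd is not None else np.zeros(n)

    return ICASolution(S, A, W_eff, np.asarray(negent, dtype=float), it,
                       converged, seed, backend, gene_ids)


def canonicalize(sol: ICASolution) -> ICASolution:
    """Canonical form: flip columns to nonnegative skewness, sort by skewness.

    Sign flips propagate to the corresponding rows of A (and W) so
    Y = S A is preserved exactly; ties in skewness keep original order.
    """
    skew = stats.skew(sol.S, axis=0)
    signs = np.where(skew < 0, -1.0, 1.0)
    S = sol.S * signs
    A = sol.A * signs[:, None]
    W = sol.W * signs[:, None]
    skew = skew * signs
    order = np.argsort(-skew, kind="stable")
    return ICASolution(S[:, order], A[order], W[order],
                       sol.per_component_negentropy[order], sol.iterations,
                       sol.converged, sol.seed, sol.backend, sol.gene_ids)


def select_best(solutions: list[ICASolution]) -> ICASolution:
    """Highest-total-negentropy solution; ties break to the lowest seed."""
    if not solutions:
        raise ValueError("no solutions given")
    backends = {s.backend for s in solutions}
    if len(backends) > 1:
        raise ValueError("negentropy scores are not comparable across backends")
    return min(solutions, key=lambda s: (-s.total_negentropy, s.seed))


def run_ica_batch(y, n_runs: int, base_seed: int = 0, **kwargs) -> list[ICASolution]:
    """Run ICA `n_runs` times with seeds base_seed + i; canonicalize each."""
    return [canonicalize(run_ica(y, seed=base_seed + i, **kwargs))
            for i in range(n_runs)]


def input_space_unmixing(w: WhitenedData, sol: ICASolution) -> np.ndarray:
    """Unmixing T (n x samples) acting on the pre-whitening matrix.

    Satisfies S ~= X @ T.T for the matrix X that was whitened, composing
    the whitening transform with the ICA unmixing; useful for comparing
    against a known mixing matrix on square synthetic problems.
    """
    n = sol.n
    d = w.d[:n]
    if np.any(d == 0):
        raise ValueError("zero singular value inside the retained components")
    V = w.V[:, :n]
    scale = np.sqrt(w.g - 1)
    Winv = sol.W @ np.diag(scale / d)  # acts on U-coordinates
    return Winv @ V.T
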