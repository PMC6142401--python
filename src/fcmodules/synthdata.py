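"""Ground-truth synthetic data generators and the Amari recovery oracle.

Expression-like mixtures are built from standardized super-Gaussian
sources (Laplace by default, matching the heavy-tailed loading
distributions seen in real compendia), mixed by a known matrix and
optionally perturbed with Gaussian noise, so every pipeline stage can
be tested against a planted truth.  The Amari index quantifies how far
a recovered unmixing is from the planted mixing up to scaled signed
permutation — the natural ambiguity of ICA.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .matrix import ExpressionMatrix


@dataclass
class SyntheticMixture:
    S_true: np.ndarray       # genes x n, standardized sources
    A_true: np.ndarray       # n x n invertible mixing
    X: np.ndarray            # observed genes x n matrix
    noise_sd: float
    seed: int
    source_family: str

    @property
    def condition_number(self) -> float:
        return float(np.linalg.cond(self.A_true))

    def as_expression_matrix(self) -> ExpressionMatrix:
        return ExpressionMatrix(self.X)


def _draw_sources(g: int, n: int, family: str, rng: np.random.Generator
                  ) -> np.ndarray:
    if family == "laplace":
        S = rng.laplace(size=(g, n))
    elif family == "exponential":
        S = rng.exponential(size=(g, n))
    elif family == "gaussian_mixture":
        # sparse-activation mixture: mostly near zero, occasional large values
        comp = rng.random((g, n)) < 0.1
        S = np.where(comp, rng.normal(0.0, 3.0, size=(g, n)),
                     rng.normal(0.0, 0.5, size=(g, n)))
    elif family == "gaussian":
        S = rng.standard_normal((g, n))
    else:
        raise ValueError(f"unknown source family {family!r}")
    S = S - S.mean(axis=0)
    return S / S.std(axis=0, ddof=1)


def gen_mixture(g: int, n: int, source_family: str = "laplace",
                mixing: str = "orthogonal", noise_sd: float = 0.0,
                seed: int = 0) -> SyntheticMixture:
    """Independent standardized sources mixed by a known n x n matrix.

    `mixing` "orthogonal" draws a Haar-distributed orthogonal matrix
    (perfectly conditioned); "random" a standard-normal matrix
    (invertible with probability one, condition number reported).
    Deterministic given `seed`.
    """
    if g < n:
        raise ValueError("need at least as many genes as components")
    if n < 1:
        raise ValueError("need at least one component")
    rng = np.random.default_rng(seed)
    S = _draw_sources(g, n, source_family, rng)
    M = rng.standard_normal((n, n))
    if mixing == "orthogonal":
        A, _ = np.linalg.qr(M)
    elif mixing == "random":
        A = M
    else:
        raise ValueError(f"unknown mixing {mixing!r}")
    X = S @ A
    if noise_sd > 0:
        X = X + rng.normal(0.0, noise_sd, size=X.shape)
    return SyntheticMixture(S, A, X, noise_sd, seed, source_family)


def gen_two_class_study(n_genes: int = 2000, n_per_group: int = 20,
                        n_fcs: int = 5, shifted_fcs=(1,),
                        effect_size: float = 2.0, noise_sd: float = 1.0,
                        batch: str = "none", n_batches: int = 2,
                        batch_sd: float = 2.0, seed: int = 0):
    """Two-class expression study with a planted low-rank group signal.

    Samples are linear combinations of `n_fcs` planted Laplace sources
    plus i.i.d. Gaussian gene noise; group 2's mean weight on each
    component listed in `shifted_fcs` (1-based) is shifted by
    `effect_size`.  With batch="shift", samples are split across
    `n_batches` batches that each receive their own random gene-space
    intercept of scale `batch_sd` — a batch artifact orthogonal to the
    planted class signal.

    Returns (ExpressionMatrix, labels array, truth dict).
    """
    shifted = sorted(set(int(f) for f in shifted_fcs))
    if any(f < 1 or f > n_fcs for f in shifted):
        raise ValueError("shifted_fcs must be within 1..n_fcs")
    rng = np.random.default_rng(seed)
    S = _draw_sources(n_genes, n_fcs, "laplace", rng)
    n_samples = 2 * n_per_group
    labels = np.array(["A"] * n_per_group + ["B"] * n_per_group)
    W = rng.standard_normal((n_fcs, n_samples))
    for f in shifted:
        W[f - 1, n_per_group:] += effect_size
    X = S @ W + rng.normal(0.0, noise_sd, size=(n_genes, n_samples))
    batches = np.zeros(n_samples, dtype=int)
    if batch == "shift":
        batches = np.tile(np.arange(n_batches), n_samples // n_batches + 1)[:n_samples]
        for b in range(n_batches):
            X[:, batches == b] += rng.normal(
                0.0, batch_sd, size=(n_genes, 1))
    elif batch != "none":
        raise ValueError(f"unknown batch mode {batch!r}")
    m = ExpressionMatrix(X)
    truth = {"S_true": S, "W_true": W, "shifted_fcs": shifted,
             "labels": labels, "batches": batches, "effect_size": effect_size,
             "seed": seed}
    return m, labels, truth


def amari_error(W: np.ndarray, A_true: np.ndarray) -> float:
    """Normalized Amari index of G = W @ A_true, in [0, 1].

    Zero exactly when G is a scaled signed permutation, i.e. the
    unmixing W inverts A_true up to the inherent ICA ambiguities.
    """
    W = np.asarray(W, dtype=float)
    A = np.asarray(A_true, dtype=float)
    if W.shape != A.shape or W.shape[0] != W.shape[1]:
        raise ValueError("W and A_true must be square with equal shapes")
    if abs(np.linalg.det(A)) < 1e-12:
        raise ValueError("A_true is singular")
    G = np.abs(W @ A)
    n = G.shape[0]
    row = (G.sum(axis=1) / G.max(axis=1) - 1.0).sum()
    col = (G.sum(axis=0) / G.max(axis=0) - 1.0).sum()
    return float((row + col) / (2 * n * (n - 1)))
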