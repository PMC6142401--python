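"""Cross-run component alignment and reproducibility summaries.

ICA recovers sources only up to sign and order, so solutions from
repeated runs (or data resamples) are aligned to a reference before
they can be compared.  For source matrices S0 (reference) and Sk, the
pairwise Pearson correlation matrix rho defines costs

    r- = (1 - rho) / 2,   r+ = (1 + rho) / 2,   C = min(r+, r-)

so that a perfectly (anti)correlated pair costs 0 and an uncorrelated
pair costs 0.5.  The assignment B minimizing total cost is found with
the Hungarian algorithm, and the signed permutation P carries +1 on an
assigned cell where r- < r+ and -1 where r- >= r+, so that the aligned
correlations c_i = cor(S0_i, [Sk P]_i) are nonnegative.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import linear_sum_assignment

from .ica import ICASolution, canonicalize, run_ica, select_best
from .matrix import ExpressionMatrix
from .whiten import svd_whiten


@dataclass
class MatchResult:
    rho: np.ndarray
    r_plus: np.ndarray
    r_minus: np.ndarray
    cost: np.ndarray
    B: np.ndarray        # 0/1 assignment, B[i, j] = 1 iff S0 comp i <- Sk comp j
    P: np.ndarray        # signed permutation, Sk @ P aligns to S0
    c: np.ndarray        # aligned correlations, all >= 0

    @property
    def total_cost(self) -> float:
        return float((self.cost * self.B).sum())


@dataclass
class StabilityReport:
    """Per-component mean, SEM and max of aligned correlations."""

    mean: np.ndarray
    sem: np.ndarray
    max: np.ndarray
    n_runs: int

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame({
            "fc": [f"FC{i + 1}" for i in range(self.mean.size)],
            "mean": self.mean, "sem": self.sem, "max": self.max,
        })


def _as_source_matrix(s) -> np.ndarray:
    if isinstance(s, ICASolution):
        return s.S
    return np.asarray(s, dtype=float)


def correlation_cost(s0, sk):
    """Pairwise correlations and the sign-invariant cost matrix."""
    S0 = _as_source_matrix(s0)
    Sk = _as_source_matrix(sk)
    if S0.shape != Sk.shape:
        raise ValueError("source matrices must have identical shapes")
    if (S0.std(axis=0) == 0).any() or (Sk.std(axis=0) == 0).any():
        raise ValueError("constant component column")
    n = S0.shape[1]
    C = np.corrcoef(S0, Sk, rowvar=False)
    rho = C[:n, n:]
    r_plus = 0.5 * (1.0 + rho)
    r_minus = 0.5 * (1.0 - rho)
    cost = np.minimum(r_plus, r_minus)
    return rho, r_plus, r_minus, cost


def match_components(s0, sk) -> MatchResult:
    """Optimal signed matching of Sk's components onto S0's."""
    S0 = _as_source_matrix(s0)
    Sk = _as_source_matrix(sk)
    rho, r_plus, r_minus, cost = correlation_cost(S0, Sk)
    n = rho.shape[0]
    rows, cols = linear_sum_assignment(cost)
    B = np.zeros((n, n))
    B[rows, cols] = 1.0
    P = np.zeros((n, n))
    for i, j in zip(rows, cols):
        P[j, i] = 1.0 if r_minus[i, j] < r_plus[i, j] else -1.0
    aligned = Sk @ P
    c = np.array([np.corrcoef(S0[:, i], aligned[:, i])[0, 1] for i in range(n)])
    return MatchResult(rho, r_plus, r_minus, cost, B, P, c)


def stability_summary(best: ICASolution, others: list[ICASolution]) -> StabilityReport:
    """Align each run to the best solution; aggregate c per component."""
    if not others:
        raise ValueError("no other solutions to compare against")
    cs = np.vstack([match_components(best, o).c for o in others])
    mean = cs.mean(axis=0)
    sem = cs.std(axis=0, ddof=1) / np.sqrt(cs.shape[0]) if cs.shape[0] > 1 \
        else np.zeros(cs.shape[1])
    return StabilityReport(mean, sem, cs.max(axis=0), len(others))


def subsample_stability(full: ExpressionMatrix, reference: ICASolution,
                        size: int | None = None, n_resamples: int = 50,
                        runs_each: int = 10, n_components: int | None = None,
                        seed: int = 0, backend: str = "logcosh",
                        **ica_kwargs) -> StabilityReport:
    """Component stability under column resampling of the compendium.

    Each resample draws `size` samples without replacement, whitens with
    the reference component count, runs ICA `runs_each` times, keeps the
    highest-negentropy solution, and aligns it to `reference`.  Aligned
    correlations are aggregated per component across resamples.
    """
    total = full.n_samples
    if size is None:
        size = total
    if size > total:
        raise ValueError("resample size exceeds available samples")
    if n_components is None:
        n_components = reference.n
    rng = np.random.default_rng(seed)
    chosen: list[ICASolution] = []
    for r in range(n_resamples):
        cols = rng.choice(total, size=size, replace=False)
        sub = ExpressionMatrix(full.values[:, cols], list(full.gene_ids),
                               [full.sample_ids[i] for i in cols])
        w = svd_whiten(sub, n=n_components)
        runs = [canonicalize(run_ica(w, backend=backend,
                                     seed=seed + 1000 * (r + 1) + i, **ica_kwargs))
                for i in range(runs_each)]
        chosen.append(select_best(runs))
    return stability_summary(reference, chosen)
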