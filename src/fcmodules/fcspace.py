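"""Projection of expression data into component space and FC-space search.

A query study Q_gene (genes x samples) is projected onto the component
loadings S by Q_FC = S' Q_gene, after aligning the two gene universes
by identifier.  Downstream analyses (neighbor search, tissue
fingerprinting) operate on the resulting n x samples score matrix with
Pearson correlation between score vectors.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .matrix import ExpressionMatrix


@dataclass
class FCProjection:
    """Component-score matrix: rows = components, columns = samples."""

    scores: np.ndarray
    fc_ids: list[str]
    sample_ids: list[str]
    unit_norm: bool = False
    coverage: float = 1.0   # fraction of loading genes found in the query

    @property
    def n(self) -> int:
        return self.scores.shape[0]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.scores, index=self.fc_ids, columns=self.sample_ids)

    def subset_samples(self, sample_ids) -> "FCProjection":
        idx = [self.sample_ids.index(s) for s in sample_ids]
        return FCProjection(self.scores[:, idx], list(self.fc_ids),
                            [self.sample_ids[i] for i in idx],
                            self.unit_norm, self.coverage)


@dataclass
class NeighborSet:
    group_label: str
    retained: list[str]                  # reference sample ids kept
    frequency: dict[str, int]            # neighbor -> number of group members
    min_correlation: dict[str, float]    # neighbor -> min cor over those members


def project(q: ExpressionMatrix, S: np.ndarray, loading_gene_ids: list[str],
            fc_ids: list[str] | None = None, unit_norm: bool = False,
            min_coverage: float = 0.9) -> FCProjection:
    """Project a study into component space on the gene-ID intersection.

    Loading genes missing from the query are dropped (not zero-imputed);
    the retained fraction is reported as coverage and must exceed
    `min_coverage`.
    """
    S = np.asarray(S, dtype=float)
    if fc_ids is None:
        fc_ids = [f"FC{i + 1}" for i in range(S.shape[1])]
    pos = {g: i for i, g in enumerate(q.gene_ids)}
    keep = [i for i, g in enumerate(loading_gene_ids) if g in pos]
    if not keep:
        raise ValueError("no genes shared between loadings and query")
    coverage = len(keep) / len(loading_gene_ids)
    if coverage < min_coverage:
        raise ValueError(
            f"gene coverage {coverage:.3f} below the floor {min_coverage}")
    S_sub = S[keep]
    q_rows = [pos[loading_gene_ids[i]] for i in keep]
    Q = q.values[q_rows]
    if unit_norm:
        norms = np.linalg.norm(S_sub, axis=0)
        if (norms == 0).any():
            raise ValueError("zero-norm loading column")
        S_sub = S_sub / norms
    return FCProjection(S_sub.T @ Q, list(fc_ids), list(q.sample_ids),
                        unit_norm, coverage)


def _cor_columns(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Pearson correlation between every column of a and every column of b."""
    na = a.shape[1]
    C = np.corrcoef(a, b, rowvar=False)
    return C[:na, na:]


def find_neighbors(group: FCProjection, reference: FCProjection,
                   min_cor: float = 0.95, min_frac: float = 0.5) -> NeighborSet:
    """Reference samples correlating > min_cor with enough group members.

    A reference sample is a neighbor of a group member when their
    FC-score Pearson correlation exceeds `min_cor`; neighbors of fewer
    than ceil(min_frac * group size) members are dropped.
    """
    if group.scores.shape[1] == 0:
        raise ValueError("empty group")
    if group.n != reference.n:
        raise ValueError("projections use different component bases")
    C = _cor_columns(group.scores, reference.scores)
    hits = C > min_cor
    freq = hits.sum(axis=0)
    threshold = math.ceil(min_frac * group.scores.shape[1])
    retained, frequency, min_correlation = [], {}, {}
    for j, rid in enumerate(reference.sample_ids):
        if freq[j] >= threshold and freq[j] > 0:
            retained.append(rid)
            frequency[rid] = int(freq[j])
            min_correlation[rid] = float(C[hits[:, j], j].min())
    return NeighborSet("group", retained, frequency, min_correlation)


def unique_neighbors(a: NeighborSet, b: NeighborSet) -> tuple[set[str], set[str]]:
    """Set-differences of two groups' retained neighbor sets."""
    sa, sb = set(a.retained), set(b.retained)
    return sa - sb, sb - sa


@dataclass
class FingerprintLibrary:
    """Per-tissue medoid representatives in FC space."""

    reference: FCProjection
    labels: dict[str, str]                       # sample id -> tissue label
    medoids: dict[str, str] = field(default_factory=dict)  # label -> sample id

    def label_samples(self, label: str) -> list[str]:
        return [s for s in self.reference.sample_ids if self.labels[s] == label]


def tissue_fingerprint(reference: FCProjection, labels: dict[str, str]
                       ) -> FingerprintLibrary:
    """Build a fingerprint library: per-label medoid under 1 - Pearson."""
    lib = FingerprintLibrary(reference, dict(labels))
    by_label: dict[str, list[int]] = {}
    for i, sid in enumerate(reference.sample_ids):
        by_label.setdefault(labels[sid], []).append(i)
    for label, idx in by_label.items():
        sub = reference.scores[:, idx]
        D = 1.0 - _cor_columns(sub, sub)
        totals = D.sum(axis=1)
        lib.medoids[label] = reference.sample_ids[idx[int(np.argmin(totals))]]
    return lib


def fingerprint_pair_summary(lib_a: FingerprintLibrary, lib_b: FingerprintLibrary
                             ) -> pd.DataFrame:
    """Median and SD of cross-sample correlations per label-label pair."""
    rows = []
    for la in sorted(set(lib_a.labels.values())):
        ia = [lib_a.reference.sample_ids.index(s) for s in lib_a.label_samples(la)]
        for lb in sorted(set(lib_b.labels.values())):
            ib = [lib_b.reference.sample_ids.index(s) for s in lib_b.label_samples(lb)]
            C = _cor_columns(lib_a.reference.scores[:, ia],
                             lib_b.reference.scores[:, ib]).ravel()
            rows.append({"label_a": la, "label_b": lb,
                         "median_cor": float(np.median(C)),
                         "sd_cor": float(np.std(C, ddof=1)) if C.size > 1 else 0.0})
    return pd.DataFrame(rows)


def annotate_query(lib: FingerprintLibrary, query_scores: np.ndarray
                   ) -> tuple[str, str, float]:
    """Most similar tissue for one query score vector.

    Returns (label with highest median correlation, single best-correlated
    sample id, that sample's correlation).
    """
    q = np.asarray(query_scores, dtype=float).reshape(-1, 1)
    C = _cor_columns(q, lib.reference.scores).ravel()
    by_label: dict[str, list[float]] = {}
    for c, sid in zip(C, lib.reference.sample_ids):
        by_label.setdefault(lib.labels[sid], []).append(c)
    best_label = max(by_label, key=lambda k: np.median(by_label[k]))
    j = int(np.argmax(C))
    return best_label, lib.reference.sample_ids[j], float(C[j])
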