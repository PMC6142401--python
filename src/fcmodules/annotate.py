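"""Active-gene modules per component and gene-set over-representation.

For each functional component the genes whose loadings lie more than
z standard deviations above (up module) or below (down module) the
loading mean are the component's active genes.  Active sets are tested
against gene-set collections (GMT format) with a hypergeometric
upper-tail test and Benjamini-Hochberg correction; overlaps are also
reported as a percentage of the signature size.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats


@dataclass
class GeneModule:
    fc_id: str
    up_genes: set[str]
    down_genes: set[str]
    z: float = 3.0

    @property
    def active(self) -> set[str]:
        return self.up_genes | self.down_genes


@dataclass
class EnrichmentRecord:
    fc_id: str
    set_name: str
    overlap_count: int
    overlap_pct: float    # of signature size, in percent
    p_value: float
    p_adjusted: float


def active_genes(loadings: np.ndarray, gene_ids: list[str], fc_id: str = "FC",
                 z: float = 3.0) -> GeneModule:
    """Genes with loading strictly beyond mean +/- z * SD of the column."""
    x = np.asarray(loadings, dtype=float)
    sd = x.std(ddof=1)
    if sd == 0:
        raise ValueError("constant loading column")
    mu = x.mean()
    up = {g for g, v in zip(gene_ids, x) if v > mu + z * sd}
    down = {g for g, v in zip(gene_ids, x) if v < mu - z * sd}
    return GeneModule(fc_id, up, down, z)


def modules_from_sources(S: np.ndarray, gene_ids: list[str],
                         z: float = 3.0) -> list[GeneModule]:
    return [active_genes(S[:, j], gene_ids, f"FC{j + 1}", z)
            for j in range(S.shape[1])]


def overlap_pct(module: GeneModule, signature: set[str]) -> tuple[int, float]:
    """Overlap count and percentage of the signature covered by the module."""
    if not signature:
        raise ValueError("empty signature")
    count = len(module.active & set(signature))
    return count, 100.0 * count / len(signature)


def hypergeom_enrich(overlap: int, n_active: int, n_signature: int,
                     n_universe: int) -> float:
    """Upper-tail hypergeometric probability P(X >= overlap).

    X counts signature genes in a draw of `n_active` genes from a
    universe of `n_universe` containing `n_signature` signature genes.
    """
    if overlap > min(n_active, n_signature):
        raise ValueError("overlap exceeds the smaller set")
    if max(n_active, n_signature) > n_universe:
        raise ValueError("set larger than the universe")
    if min(overlap, n_active, n_signature) < 0:
        raise ValueError("negative count")
    return float(stats.hypergeom.sf(overlap - 1, n_universe, n_signature, n_active))


def bh_adjust(p_values, family_size: int | None = None) -> np.ndarray:
    """Benjamini-Hochberg step-up adjustment with an explicit family size.

    `family_size` (N) may exceed the number of p-values supplied, e.g.
    when only a subset of all tests performed is being adjusted; it
    defaults to the number of p-values.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    N = p.size if family_size is None else int(family_size)
    if N < p.size:
        raise ValueError("family size smaller than the number of p-values")
    order = np.argsort(p, kind="stable")
    ranked = p[order] * N / np.arange(1, p.size + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty_like(p)
    out[order] = np.minimum(adj, 1.0)
    return out


def promiscuity(modules: list[GeneModule]) -> pd.Series:
    """Per-gene count of components in which the gene is active.

    Genes active in no component are absent from the table.
    """
    counts: dict[str, int] = {}
    for mod in modules:
        for g in mod.active:
            counts[g] = counts.get(g, 0) + 1
    return pd.Series(counts, dtype=int).sort_values(ascending=False)


def read_gmt(path) -> dict[str, set[str]]:
    """Read a GMT gene-set file: name, description, member genes (tab-sep)."""
    sets: dict[str, set[str]] = {}
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"malformed GMT line: {line[:50]!r}")
            sets[parts[0]] = {g for g in parts[2:] if g}
    return sets


def write_gmt(sets: dict[str, set[str]], path, description: str = "na") -> None:
    with open(path, "w") as fh:
        for name, members in sets.items():
            fh.write("\t".join([name, description, *sorted(members)]) + "\n")


def enrich_modules(modules: list[GeneModule], gene_sets: dict[str, set[str]],
                   universe: set[str] | None = None, alpha: float = 0.01,
                   ) -> list[EnrichmentRecord]:
    """Test every module-signature pair; keep pairs with BH-adjusted p < alpha.

    The universe defaults to the union of all module gene universes'
    active calls being drawn from, i.e. it must normally be supplied as
    the full gene list of the loading matrix.  Signatures are first
    intersected with the universe.
    """
    if universe is None:
        raise ValueError("an explicit gene universe is required")
    records = []
    for mod in modules:
        active = mod.active & universe
        for name, sig in gene_sets.items():
            sig_u = sig & universe
            if not sig_u:
                continue
            count = len(active & sig_u)
            pct = 100.0 * count / len(sig_u)
            p = hypergeom_enrich(count, len(active), len(sig_u), len(universe))
            records.append(EnrichmentRecord(mod.fc_id, name, count, pct, p, np.nan))
    padj = bh_adjust([r.p_value for r in records])
    for r, a in zip(records, padj):
        r.p_adjusted = float(a)
    return [r for r in records if r.p_adjusted < alpha]


def enrichment_table(records: list[EnrichmentRecord]) -> pd.DataFrame:
    return pd.DataFrame([{
        "fc_id": r.fc_id, "set": r.set_name, "count": r.overlap_count,
        "pct": r.overlap_pct, "p": r.p_value, "p_adj": r.p_adjusted,
    } for r in records])
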