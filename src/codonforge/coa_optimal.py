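"""Correspondence analysis of RSCU, optimal-codon determination, and
RSCU-based hierarchical clustering of species.

The correspondence analysis is the standard chi-square-residual SVD: with
relative matrix P, row masses r and column masses c,

    S = D_r^{-1/2} (P - r c^T) D_c^{-1/2} = U Sigma V^T,

principal inertias are the squared singular values and row/column principal
coordinates are D^{-1/2} U Sigma / D^{-1/2} V Sigma. Axis signs are fixed
by forcing the codon with the largest absolute loading on each axis to be
positive, so outputs are reproducible.

Optimal codons follow the ΔRSCU procedure: genes ranked by CAI, the top and
bottom 10% pooled into high- and low-expression sets, and a codon is
optimal when ΔRSCU = RSCU_high - RSCU_low exceeds 0.08 while its RSCU on
the full pooled set exceeds 1.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import cophenet, linkage, to_tree
from scipy.spatial.distance import pdist

from .codon_statistics import CodonCountTable, count_codons, pooled_counts, rscu
from .expression_indices import UsageIndexRecord
from .genetic_code import GeneticCode, STANDARD_CODE
from .sequence_io import GeneSet

DELTA_RSCU_THRESHOLD = 0.08
HIGH_LOW_FRACTION = 0.10


@dataclass
class COAResult:
    row_coords: pd.DataFrame  # genes x axes
    col_coords: pd.DataFrame  # codons x axes
    inertias: np.ndarray
    n_axes: int
    dropped_rows: tuple[str, ...] = ()
    dropped_cols: tuple[str, ...] = ()

    @property
    def contribution_pct(self) -> np.ndarray:
        total = self.inertias.sum()
        if total < 1e-14:  # no variance: contributions undefined
            return np.full_like(self.inertias, np.nan)
        return 100.0 * self.inertias / total

    @property
    def total_inertia(self) -> float:
        return float(self.inertias.sum())


@dataclass(frozen=True)
class OptimalCodonReport:
    high_frequency: frozenset[str]
    high_expression: frozenset[str]
    optimal: frozenset[str]
    delta_rscu: dict[str, float]
    rscu_full: dict[str, float]
    rscu_high: dict[str, float]
    rscu_low: dict[str, float]
    high_genes: tuple[str, ...]
    low_genes: tuple[str, ...]

    def as_frame(self, code: GeneticCode = STANDARD_CODE) -> pd.DataFrame:
        rows = []
        for c in sorted(self.rscu_full):
            rows.append(
                dict(
                    codon=c,
                    aa=code.codon_to_aa[c],
                    rscu_full=self.rscu_full[c],
                    rscu_high=self.rscu_high[c],
                    rscu_low=self.rscu_low[c],
                    delta_rscu=self.delta_rscu[c],
                    high_frequency=c in self.high_frequency,
                    high_expression=c in self.high_expression,
                    optimal=c in self.optimal,
                )
            )
        return pd.DataFrame(rows)


@dataclass
class SpeciesTree:
    labels: tuple[str, ...]
    linkage_matrix: np.ndarray
    newick: str
    method: str = "average"
    metric: str = "euclidean"

    def cophenetic_distances(self) -> pd.DataFrame:
        d = cophenet(self.linkage_matrix)
        n = len(self.labels)
        mat = np.zeros((n, n))
        mat[np.triu_indices(n, 1)] = d
        mat += mat.T
        return pd.DataFrame(mat, index=list(self.labels), columns=list(self.labels))


def coa_on_rscu(rscu_matrix: pd.DataFrame, n_axes: int | None = None) -> COAResult:
    """Correspondence analysis of a genes x codons RSCU table."""
    if rscu_matrix.shape[0] < 2:
        raise ValueError("correspondence analysis needs at least 2 rows")
    if (rscu_matrix.values < 0).any():
        raise ValueError("negative entries in RSCU matrix")
    m = rscu_matrix.copy()
    zero_rows = tuple(m.index[m.sum(axis=1) == 0])
    zero_cols = tuple(m.columns[m.sum(axis=0) == 0])
    if zero_rows or zero_cols:
        warnings.warn(
            f"dropping zero-sum rows {list(zero_rows)} / columns {list(zero_cols)}"
        )
        m = m.drop(index=list(zero_rows), columns=list(zero_cols))
    n = m.values.astype(float)
    p = n / n.sum()
    r = p.sum(axis=1)
    c = p.sum(axis=0)
    s = (p - np.outer(r, c)) / np.sqrt(np.outer(r, c))
    u, sig, vt = np.linalg.svd(s, full_matrices=False)
    rank = min(m.shape) - 1
    tol = max(sig.max() * 1e-12, 1e-14) if sig.size else 0.0
    rank = min(rank, int((sig > tol).sum()))
    if rank < 2:
        warnings.warn(f"RSCU matrix has rank {rank}: fewer than 2 axes")
    keep = rank if n_axes is None else min(n_axes, rank)
    u, sig, vt = u[:, :keep], sig[:keep], vt[:keep, :]
    with np.errstate(invalid="ignore", divide="ignore"):
        f = (u * sig) / np.sqrt(r)[:, None]
        g = (vt.T * sig) / np.sqrt(c)[:, None]
    # fix arbitrary axis signs: largest-|loading| codon positive on each axis
    for k in range(keep):
        if g.shape[0] and g[np.argmax(np.abs(g[:, k])), k] < 0:
            f[:, k] *= -1
            g[:, k] *= -1
    axes = [f"Axis{k + 1}" for k in range(keep)]
    return COAResult(
        row_coords=pd.DataFrame(f, index=m.index, columns=axes),
        col_coords=pd.DataFrame(g, index=m.columns, columns=axes),
        inertias=sig**2,
        n_axes=keep,
        dropped_rows=zero_rows,
        dropped_cols=zero_cols,
    )


def rscu_matrix_from_genes(gs: GeneSet) -> pd.DataFrame:
    """Per-gene RSCU rows over the code's synonymous codons (59 standard)."""
    cols = list(gs.code.synonymous_codons)
    rows = {
        g.gene: [rscu(count_codons(g, gs.code), gs.code).rscu.get(c, 0.0) for c in cols]
        for g in gs
    }
    return pd.DataFrame.from_dict(rows, orient="index", columns=cols)


def axis_correlations(
    coa: COAResult,
    records: list[UsageIndexRecord],
    indicators: list[str],
    axis: str = "Axis1",
) -> pd.DataFrame:
    """Pearson r/p between an ordination axis and each scalar indicator."""
    by_gene = {r.gene: r for r in records}
    missing = [g for g in coa.row_coords.index if g not in by_gene]
    if missing:
        raise ValueError(f"gene labels missing from records: {missing}")
    coords = coa.row_coords[axis]
    rows = []
    for ind in indicators:
        vals = np.array(
            [np.nan if by_gene[g][ind] is None else float(by_gene[g][ind]) for g in coa.row_coords.index]
        )
        mask = ~np.isnan(vals)
        if mask.sum() < 3 or np.allclose(vals[mask], vals[mask][0]):
            rows.append((axis, ind, np.nan, np.nan))
            continue
        r, p = stats.pearsonr(coords[mask], vals[mask])
        rows.append((axis, ind, float(r), float(p)))
    return pd.DataFrame(rows, columns=["axis", "indicator", "r", "p"])


def high_frequency_codons(rscu_full) -> frozenset[str]:
    """Codons with RSCU strictly greater than 1 on the full pooled set."""
    table = rscu_full.rscu if hasattr(rscu_full, "rscu") else rscu_full
    return frozenset(c for c, v in table.items() if v > 1.0)


def select_extreme_genes(
    gene_labels: list[str], cai_values: dict[str, float], frac: float = HIGH_LOW_FRACTION
) -> tuple[list[str], list[str]]:
    """Top/bottom ``ceil(frac * n)`` genes by CAI (ties by label, logged)."""
    n_sel = max(1, math.ceil(frac * len(gene_labels)))
    ranked = sorted(gene_labels, key=lambda g: (-cai_values[g], g))
    return ranked[:n_sel], ranked[-n_sel:]


def optimal_codons(
    gs: GeneSet,
    cai_values: dict[str, float],
    frac: float = HIGH_LOW_FRACTION,
    delta_threshold: float = DELTA_RSCU_THRESHOLD,
) -> OptimalCodonReport:
    """ΔRSCU optimal-codon determination.

    Genes are ranked by CAI; the top and bottom ``frac`` (default 10%,
    rounded up, at least one gene) form the high- and low-expression
    subsets, whose pooled RSCU difference is ΔRSCU. A codon is optimal when
    ΔRSCU > ``delta_threshold`` and its full-set RSCU > 1.
    """
    labels = gs.gene_labels()
    if len(set(labels)) < 2:
        raise ValueError("optimal-codon determination needs >= 2 genes")
    high_genes, low_genes = select_extreme_genes(labels, cai_values, frac)
    if set(high_genes) & set(low_genes):
        raise ValueError(
            f"high/low expression subsets overlap (n={len(labels)}, frac={frac})"
        )

    def pooled_rscu(names: list[str]) -> dict[str, float]:
        sub = GeneSet(species=gs.species, genes=[gs.get(n) for n in names], code=gs.code)
        return rscu(pooled_counts(sub), gs.code).rscu

    r_full = rscu(pooled_counts(gs), gs.code).rscu
    r_high = pooled_rscu(high_genes)
    r_low = pooled_rscu(low_genes)
    delta = {c: r_high[c] - r_low[c] for c in r_full}
    high_freq = high_frequency_codons(r_full)
    high_expr = frozenset(c for c, d in delta.items() if d > delta_threshold)
    return OptimalCodonReport(
        high_frequency=high_freq,
        high_expression=high_expr,
        optimal=high_freq & high_expr,
        delta_rscu=delta,
        rscu_full=r_full,
        rscu_high=r_high,
        rscu_low=r_low,
        high_genes=tuple(high_genes),
        low_genes=tuple(low_genes),
    )


def _tree_to_newick(node, labels: tuple[str, ...]) -> str:
    if node.is_leaf():
        return labels[node.id]
    left = _tree_to_newick(node.get_left(), labels)
    right = _tree_to_newick(node.get_right(), labels)
    dl = node.dist - node.get_left().dist
    dr = node.dist - node.get_right().dist
    return f"({left}:{dl:.6g},{right}:{dr:.6g})"


def rscu_cluster(
    per_species_rscu: pd.DataFrame,
    method: str = "average",
    metric: str = "euclidean",
) -> SpeciesTree:
    """Agglomerative clustering of species on their pooled RSCU profiles.

    Default: average linkage (UPGMA) on Euclidean distance over the
    species x synonymous-codon matrix. The dendrogram is serialized as a
    Newick string with ultrametric branch lengths.
    """
    if per_species_rscu.shape[0] < 2:
        raise ValueError("clustering needs at least 2 species")
    labels = tuple(per_species_rscu.index)
    z = linkage(pdist(per_species_rscu.values, metric=metric), method=method)
    newick = _tree_to_newick(to_tree(z), labels) + ";"
    return SpeciesTree(labels=labels, linkage_matrix=z, newick=newick, method=method, metric=metric)
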