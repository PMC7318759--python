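"""Genome-wide population relationships among pools.

Pairwise genetic distances are genome-wide means of the Karlsson per-SNP
F_ST (no windowing), assembled into a symmetric matrix; the matrix feeds a
neighbour-joining tree (with SNP-bootstrap branch supports) and a Mantel
permutation test of the correlation between genetic and geographic
(great-circle) distances.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
import skbio

from .variants import PoolPanel, VariantTable
from .windows import fst_snp_karlsson

__all__ = [
    "DistanceMatrix",
    "NJTree",
    "MantelResult",
    "pairwise_fst_matrix",
    "nj_tree",
    "bootstrap_support",
    "mantel_test",
    "geographic_distances",
]

EARTH_RADIUS_KM = 6371.0


@dataclass
class DistanceMatrix:
    """Symmetric labelled distance matrix (zero diagonal)."""

    labels: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        n = len(self.labels)
        if v.shape != (n, n):
            raise ValueError("matrix shape must match label count")
        if not np.allclose(v, v.T, equal_nan=True):
            raise ValueError("matrix must be symmetric")
        if not np.allclose(np.diag(v), 0.0):
            raise ValueError("diagonal must be zero")
        self.values = v

    def __len__(self) -> int:
        return len(self.labels)

    def submatrix(self, labels: Sequence[str]) -> "DistanceMatrix":
        idx = [self.labels.index(l) for l in labels]
        return DistanceMatrix(list(labels), self.values[np.ix_(idx, idx)])

    def to_skbio(self) -> skbio.DistanceMatrix:
        # exact symmetrization: skbio rejects float-roundoff asymmetry
        v = (self.values + self.values.T) / 2.0
        return skbio.DistanceMatrix(v, ids=self.labels)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.labels, columns=self.labels)

    def to_long_frame(self) -> pd.DataFrame:
        """Heatmap-ready long format (pool_a, pool_b, value), upper triangle."""
        rows = [
            (self.labels[i], self.labels[j], self.values[i, j])
            for i in range(len(self)) for j in range(i + 1, len(self))
        ]
        return pd.DataFrame(rows, columns=["pool_a", "pool_b", "value"])

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "DistanceMatrix":
        return cls(list(df.index), df.to_numpy(dtype=float))


def _per_site_pair_fst(table: VariantTable) -> tuple[np.ndarray, list[tuple[int, int]]]:
    """(n_pairs, n_sites) per-SNP F matrix (NaN = undefined) and pair index."""
    depth = table.depth().astype(float)
    alt = table.alt_reads.astype(float)
    n_pools = len(table.panel)
    pairs = list(itertools.combinations(range(n_pools), 2))
    F = np.empty((len(pairs), len(table)))
    for k, (i, j) in enumerate(pairs):
        _, _, F[k] = fst_snp_karlsson(alt[:, i], depth[:, i], alt[:, j], depth[:, j])
    return F, pairs


def pairwise_fst_matrix(table: VariantTable, panel: PoolPanel | None = None
                        ) -> DistanceMatrix:
    """Genome-wide mean per-SNP F_ST for every unordered pool pair.

    For n pools this fills C(n, 2) entries (253 for 23 pools); SNPs with
    undefined F (both pools fixed for the same allele, or depth < 2) are
    skipped.  Raises ``ValueError`` for a pair with no defined SNP.
    """
    panel = panel or table.panel
    F, pairs = _per_site_pair_fst(table)
    n = len(panel)
    out = np.zeros((n, n))
    for k, (i, j) in enumerate(pairs):
        ok = ~np.isnan(F[k])
        if not ok.any():
            raise ValueError(
                f"no defined F_ST SNP for pair ({panel.names[i]}, {panel.names[j]})"
            )
        out[i, j] = out[j, i] = F[k, ok].mean()
    return DistanceMatrix(list(panel.names), out)


# ---------------------------------------------------------------------------
# Neighbour joining
# ---------------------------------------------------------------------------

@dataclass
class NJTree:
    """Unrooted NJ tree over the matrix labels, optional bootstrap supports.

    ``supports`` maps canonical bipartitions (frozenset of the smaller
    side's labels) to percentages in [0, 100].  Negative branch lengths
    are kept internally and clamped to zero only at Newick export.
    """

    tree: skbio.TreeNode
    labels: list[str]
    supports: dict[frozenset, float] | None = None

    def bipartitions(self) -> set[frozenset]:
        return _bipartitions(self.tree, self.labels)

    def to_newick(self, clamp_negative: bool = True) -> str:
        t = self.tree.copy()
        for node in t.traverse():
            if clamp_negative and node.length is not None and node.length < 0:
                node.length = 0.0
            if self.supports is not None and not node.is_tip() and node.parent is not None:
                side = frozenset(l.name for l in node.tips())
                key = _canonical(side, set(self.labels))
                if key in self.supports:
                    node.name = f"{self.supports[key]:.0f}"
        return str(t).strip()


def _canonical(side: frozenset, all_labels: set) -> frozenset:
    comp = frozenset(all_labels - side)
    # canonical representative: smaller side, ties by sorted labels
    return min(side, comp, key=lambda s: (len(s), tuple(sorted(s))))


def _bipartitions(tree: skbio.TreeNode, labels: Sequence[str]) -> set[frozenset]:
    """Non-trivial bipartitions induced by the internal edges of a tree."""
    all_labels = set(labels)
    out = set()
    for subset in tree.subsets():
        side = frozenset(subset)
        if 1 < len(side) < len(all_labels) - 1:
            out.add(_canonical(side, all_labels))
    return out


def nj_tree(dist: DistanceMatrix) -> NJTree:
    """Saitou-Nei neighbour joining; exact on additive matrices."""
    if len(dist) < 3:
        raise ValueError("NJ needs at least 3 taxa")
    tree = skbio.tree.nj(dist.to_skbio())
    return NJTree(tree=tree, labels=list(dist.labels))


def bootstrap_support(
    table: VariantTable,
    panel: PoolPanel | None = None,
    n_reps: int = 10_000,
    seed: int | None = None,
) -> NJTree:
    """NJ tree with SNP-bootstrap branch supports.

    SNP loci are resampled with replacement ``n_reps`` times; the
    F_ST matrix and NJ tree are rebuilt per replicate and each internal
    edge of the point-estimate tree is annotated with the percentage of
    replicates whose tree contains the same bipartition.
    """
    panel = panel or table.panel
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    rng = np.random.default_rng(seed)
    F, pairs = _per_site_pair_fst(table)
    Fz = np.nan_to_num(F)
    M = (~np.isnan(F)).astype(float)
    n = len(panel)

    def matrix_from_weights(w: np.ndarray) -> DistanceMatrix:
        num = Fz @ w
        den = M @ w
        vals = np.zeros((n, n))
        for k, (i, j) in enumerate(pairs):
            if den[k] == 0:
                raise ValueError("bootstrap replicate with no defined SNP for a pair")
            vals[i, j] = vals[j, i] = num[k] / den[k]
        return DistanceMatrix(list(panel.names), vals)

    point = nj_tree(matrix_from_weights(np.ones(len(table))))
    target = point.bipartitions()
    hits = {b: 0 for b in target}
    n_sites = len(table)
    for _ in range(n_reps):
        w = np.bincount(rng.integers(0, n_sites, size=n_sites),
                        minlength=n_sites).astype(float)
        rep = nj_tree(matrix_from_weights(w))
        found = rep.bipartitions()
        for b in target:
            if b in found:
                hits[b] += 1
    point.supports = {b: 100.0 * c / n_reps for b, c in hits.items()}
    return point


# ---------------------------------------------------------------------------
# Mantel test
# ---------------------------------------------------------------------------

@dataclass
class MantelResult:
    """Mantel correlation with one-sided permutation p-value."""

    r: float
    p: float
    n_perm: int


def _upper(values: np.ndarray) -> np.ndarray:
    iu = np.triu_indices(values.shape[0], k=1)
    return values[iu]


def mantel_test(
    d_genetic: DistanceMatrix,
    d_geographic: DistanceMatrix,
    n_perm: int = 9_999,
    seed: int | None = None,
    exact: bool = False,
) -> MantelResult:
    """Mantel test of matrix correlation under joint row/column permutation.

    r is the Pearson correlation of the off-diagonal upper triangles;
    p is one-sided, ``(1 + #{permuted r >= observed r}) / (n_perm + 1)``,
    permuting the row/column order of the second matrix jointly.  With
    ``exact=True`` all n! label permutations are enumerated instead
    (feasible for <= 8 labels) and p is the exact fraction of
    permutations (identity included) with r >= observed.
    """
    if set(d_genetic.labels) != set(d_geographic.labels):
        raise ValueError("matrices must share the same labels")
    d_geographic = d_geographic.submatrix(d_genetic.labels)
    A = d_genetic.values
    B = d_geographic.values
    n = A.shape[0]
    iu = np.triu_indices(n, k=1)
    x = A[iu]
    x = x - x.mean()
    sx = math.sqrt((x**2).sum())

    def corr_with(perm_rows: np.ndarray) -> np.ndarray:
        """Pearson r of x vs B permuted by each row of perm_rows."""
        rows = perm_rows[:, iu[0]]
        cols = perm_rows[:, iu[1]]
        y = B[rows, cols]
        y = y - y.mean(axis=1, keepdims=True)
        sy = np.sqrt((y**2).sum(axis=1))
        return (y @ x) / (sx * sy)

    r_obs = float(corr_with(np.arange(n)[None, :])[0])
    if exact:
        perms = np.array(list(itertools.permutations(range(n))))
        rs = corr_with(perms)
        p = float(np.mean(rs >= r_obs - 1e-12))
        return MantelResult(r=r_obs, p=p, n_perm=len(perms))
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    rng = np.random.default_rng(seed)
    perms = np.array([rng.permutation(n) for _ in range(n_perm)])
    rs = corr_with(perms)
    p = (1.0 + int(np.sum(rs >= r_obs - 1e-12))) / (n_perm + 1.0)
    return MantelResult(r=r_obs, p=float(p), n_perm=n_perm)


# ---------------------------------------------------------------------------
# Geographic distances
# ---------------------------------------------------------------------------

def geographic_distances(panel: PoolPanel,
                         pools: Sequence[str] | None = None) -> DistanceMatrix:
    """Great-circle (haversine) distances in km between pool coordinates."""
    names = list(pools) if pools is not None else list(panel.names)
    coords = []
    for name in names:
        p = panel[name]
        if p.longitude is None or p.latitude is None:
            raise ValueError(f"pool {name!r} has no coordinates")
        coords.append((math.radians(p.latitude), math.radians(p.longitude)))
    n = len(names)
    out = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            lat1, lon1 = coords[i]
            lat2, lon2 = coords[j]
            a = (math.sin((lat2 - lat1) / 2) ** 2
                 + math.cos(lat1) * math.cos(lat2)
                 * math.sin((lon2 - lon1) / 2) ** 2)
            d = 2.0 * EARTH_RADIUS_KM * math.asin(min(1.0, math.sqrt(a)))
            out[i, j] = out[j, i] = d
    return DistanceMatrix(names, out)
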