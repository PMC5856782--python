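"""Population structure: allele-sharing distances, NJ tree, PCA, permutation test.

Neighbor joining follows Saitou–Nei agglomeration with the Studier–Keppler
criterion Q(i,j) = (r-2)·d(i,j) - Σ_k d(i,k) - Σ_k d(j,k); ties are broken
by lexicographic order of the joined nodes' labels, so reconstruction is
fully deterministic.  On additive matrices the true topology and branch
lengths are recovered exactly.

The PCA operates on the dosage matrix with per-site centering by twice the
alt-allele frequency and (by default) Patterson scaling by sqrt(2p̂(1-p̂)).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from ._rng import stage_rng
from .variants import MISSING, PopulationDesign, VariantTable

__all__ = [
    "DistanceMatrix",
    "allele_sharing_distance",
    "distance_matrix",
    "TreeNode",
    "neighbor_joining",
    "PCAResult",
    "genotype_pca",
    "permutation_test_separation",
]


@dataclass
class DistanceMatrix:
    """Symmetric non-negative distances with zero diagonal."""

    ids: List[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.ids)
        if self.values.shape != (n, n):
            raise ValueError("matrix shape does not match ids")
        if not np.allclose(self.values, self.values.T, atol=0.0):
            raise ValueError("distance matrix is not symmetric")
        if np.any(np.diag(self.values) != 0.0):
            raise ValueError("nonzero diagonal")

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.ids, columns=self.ids)


def allele_sharing_distance(table: VariantTable, sample_i: str, sample_j: str) -> float:
    """1 - mean per-site shared-allele score between two samples.

    Per shared called site the score is 2 - |dosage_i - dosage_j| (two
    shared alleles for identical genotypes, none for opposite homozygotes);
    d = 1 - Σscore / (2·n_sites) lies in [0, 1].
    """
    gi = table.genotypes[:, table.sample_index([sample_i])[0]].astype(float)
    gj = table.genotypes[:, table.sample_index([sample_j])[0]].astype(float)
    ok = (gi != MISSING) & (gj != MISSING)
    if not np.any(ok):
        raise ValueError(f"no overlapping called sites for {sample_i}, {sample_j}")
    score = 2.0 - np.abs(gi[ok] - gj[ok])
    return float(1.0 - score.sum() / (2.0 * ok.sum()))


def distance_matrix(table: VariantTable) -> DistanceMatrix:
    """Full allele-sharing distance matrix over the table's samples."""
    n = table.n_samples
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d[i, j] = d[j, i] = allele_sharing_distance(table, table.samples[i], table.samples[j])
    return DistanceMatrix(list(table.samples), d)


# ---------------------------------------------------------------------------
# neighbor joining


@dataclass
class TreeNode:
    """Unrooted tree node (represented with an arbitrary internal root)."""

    label: Optional[str] = None
    children: List[Tuple["TreeNode", float]] = field(default_factory=list)

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def leaves(self) -> List[str]:
        if self.is_leaf:
            return [self.label]
        out: List[str] = []
        for child, _ in self.children:
            out.extend(child.leaves())
        return out

    def sort_key(self) -> str:
        return self.label if self.is_leaf else min(c.sort_key() for c, _ in self.children)

    def to_newick(self, clamp_negative: bool = True) -> str:
        def fmt(node: "TreeNode", length: Optional[float]) -> str:
            if node.is_leaf:
                core = node.label
            else:
                parts = [fmt(c, l) for c, l in node.children]
                core = "(" + ",".join(parts) + ")"
            if length is None:
                return core
            bl = max(length, 0.0) if clamp_negative else length
            return f"{core}:{bl:.10g}"

        return fmt(self, None) + ";"

    def clades(self) -> List[frozenset]:
        """Leaf sets of every subtree (for monophyly checks)."""
        out = []

        def walk(node: "TreeNode") -> frozenset:
            if node.is_leaf:
                s = frozenset([node.label])
            else:
                s = frozenset().union(*(walk(c) for c, _ in node.children))
            out.append(s)
            return s

        walk(self)
        return out


def neighbor_joining(dm: DistanceMatrix) -> Tuple[TreeNode, pd.DataFrame]:
    """Saitou–Nei neighbor joining; returns (tree, raw branch-length table).

    The tree keeps raw (possibly negative) branch lengths; Newick export
    clamps them at 0 by default.  The sidecar table records every edge's
    raw length.
    """
    r = len(dm.ids)
    if r < 3:
        raise ValueError("neighbor joining needs >= 3 taxa")
    order = np.argsort(np.asarray(dm.ids, dtype=object))
    nodes: List[TreeNode] = [TreeNode(label=dm.ids[i]) for i in order]
    d = dm.values[np.ix_(order, order)].astype(float).copy()
    edges: List[dict] = []

    def record(parent_key: str, child: TreeNode, length: float) -> None:
        edges.append(dict(parent=parent_key, child=child.sort_key(), raw_length=float(length)))

    while len(nodes) > 2:
        n = len(nodes)
        rowsum = d.sum(axis=1)
        q = (n - 2) * d - rowsum[:, None] - rowsum[None, :]
        np.fill_diagonal(q, np.inf)
        # deterministic tie-break: smallest Q, then lexicographic label pair
        best: Optional[Tuple[str, str]] = None
        bi = bj = -1
        qmin = np.inf
        for i in range(n):
            for j in range(i + 1, n):
                tol = 1e-12 * (1.0 + abs(qmin)) if np.isfinite(qmin) else 0.0
                key = tuple(sorted((nodes[i].sort_key(), nodes[j].sort_key())))
                if q[i, j] < qmin - tol or (q[i, j] <= qmin + tol and (best is None or key < best)):
                    qmin = min(qmin, q[i, j])
                    best = key
                    bi, bj = i, j
        i, j = bi, bj
        vi = d[i, j] / 2.0 + (rowsum[i] - rowsum[j]) / (2.0 * (n - 2))
        vj = d[i, j] - vi
        parent = TreeNode(children=[(nodes[i], vi), (nodes[j], vj)])
        record(parent.sort_key(), nodes[i], vi)
        record(parent.sort_key(), nodes[j], vj)
        new_d = (d[i, :] + d[j, :] - d[i, j]) / 2.0
        keep = [k for k in range(n) if k not in (i, j)]
        d = np.vstack([d[keep][:, keep], new_d[keep][None, :]])
        d = np.hstack([d, np.append(new_d[keep], 0.0)[:, None]])
        nodes = [nodes[k] for k in keep] + [parent]

    # join the last two nodes with the remaining distance on one edge
    a, b = nodes
    length = float(d[0, 1])
    root, other = (a, b) if not a.is_leaf else (b, a)
    record(root.sort_key(), other, length)
    root.children.append((other, length))
    return root, pd.DataFrame(edges)


# ---------------------------------------------------------------------------
# PCA


@dataclass
class PCAResult:
    """Scores (samples x components), variance-explained fractions, loadings."""

    samples: List[str]
    scores: np.ndarray
    variance_fractions: np.ndarray
    loadings: Optional[np.ndarray] = None

    def scores_frame(self) -> pd.DataFrame:
        cols = [f"PC{i + 1}" for i in range(self.scores.shape[1])]
        return pd.DataFrame(self.scores, index=self.samples, columns=cols)


def genotype_pca(
    table: VariantTable,
    patterson_scale: bool = True,
    n_components: Optional[int] = None,
) -> PCAResult:
    """PCA of the dosage matrix via SVD.

    Sites are centered by 2p̂ and, with Patterson scaling, divided by
    sqrt(2p̂(1-p̂)); missing dosages contribute 0 after centering.
    Monomorphic sites are dropped; an input with no polymorphic site is an
    error.  Component signs are fixed by forcing each component's largest-
    magnitude loading positive.
    """
    if table.n_samples < 2:
        raise ValueError("PCA needs >= 2 samples")
    g = table.genotypes.astype(float).T  # samples x sites
    miss = g == MISSING
    g[miss] = np.nan
    p = np.nanmean(g, axis=0) / 2.0
    poly = (p > 0) & (p < 1) & ~np.isnan(p)
    if poly.sum() < 2:
        raise ValueError("PCA needs >= 2 polymorphic sites")
    g = g[:, poly]
    p = p[poly]
    x = g - 2.0 * p[None, :]
    if patterson_scale:
        x = x / np.sqrt(2.0 * p * (1.0 - p))[None, :]
    x[np.isnan(x)] = 0.0
    u, s, vt = np.linalg.svd(x, full_matrices=False)
    var = s**2
    frac = var / var.sum()
    # sign convention: largest-|.| loading of each component positive
    for k in range(vt.shape[0]):
        imax = int(np.argmax(np.abs(vt[k])))
        if vt[k, imax] < 0:
            vt[k] *= -1.0
            u[:, k] *= -1.0
    scores = u * s[None, :]
    if n_components is not None:
        scores = scores[:, :n_components]
        frac = frac[:n_components]
        vt = vt[:n_components]
    return PCAResult(list(table.samples), scores, frac, loadings=vt.T)


# ---------------------------------------------------------------------------
# permutation test


def _separation_statistic(points: np.ndarray, groups: np.ndarray) -> float:
    """Mean between-group distance minus mean within-group distance."""
    from scipy.spatial.distance import pdist, squareform

    d = squareform(pdist(points))
    between, within = [], []
    n = len(groups)
    for i in range(n):
        for j in range(i + 1, n):
            (between if groups[i] != groups[j] else within).append(d[i, j])
    b = float(np.mean(between)) if between else 0.0
    w = float(np.mean(within)) if within else 0.0
    return b - w


def permutation_test_separation(
    scores: np.ndarray,
    labels: Sequence[str],
    grouping: Dict[str, str],
    n_perm: int = 999,
    seed: int = 0,
    n_components: int = 2,
) -> Tuple[float, float]:
    """Permutation p-value for group separation in score space.

    *grouping* maps each label to a group (e.g. {'H': 'high', 'L': 'low',
    'M': 'low'} for the H vs L∪M contrast).  The statistic is the mean
    between-group minus mean within-group Euclidean distance on the first
    ``n_components`` score columns; p = (1 + #{perm >= obs}) / (1 + n_perm).
    """
    if n_perm < 99:
        raise ValueError("n_perm >= 99 required")
    pts = np.asarray(scores, dtype=float)[:, :n_components]
    groups = np.asarray([grouping[l] for l in labels], dtype=object)
    if len(set(groups)) < 2:
        raise ValueError("need >= 2 groups")
    obs = _separation_statistic(pts, groups)
    rng = stage_rng(seed, "permutation_test")
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(groups)
        if _separation_statistic(pts, perm) >= obs:
            count += 1
    p = (1 + count) / (1 + n_perm)
    return float(obs), float(p)
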