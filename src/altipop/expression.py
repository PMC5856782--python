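"""RPKM quantification, ANOVA+FDR differential expression, sample clustering.

The DE rule is the classical transcriptome screen: a per-gene one-way ANOVA
(F-test) on log2(RPKM + pseudocount) across groups, Benjamini–Hochberg
adjustment, and a call only when both p_adj < alpha and |log2FC| exceeds a
magnitude threshold.  The pairwise (two-group) case reduces to the
equal-variance t-test.  Direction is defined from the lower- to the
higher-altitude group of a pair: positive log2FC means higher expression at
higher altitude.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import linkage, to_tree
from scipy.spatial.distance import squareform

from .variants import PopulationDesign

__all__ = [
    "ExpressionMatrix",
    "rpkm",
    "de_test",
    "bh_fdr",
    "call_degs",
    "pairwise_de",
    "cluster_samples",
    "volcano_table",
]


@dataclass
class ExpressionMatrix:
    """Integer read counts per gene x sample with gene lengths.

    ``library_sizes`` defaults to column sums; ``rpkm`` is derived as
    1e9 * count / (library_size * length).
    """

    counts: pd.DataFrame
    lengths: pd.Series
    library_sizes: Optional[pd.Series] = None

    def __post_init__(self) -> None:
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("negative counts")
        self.lengths = self.lengths.reindex(self.counts.index)
        if self.lengths.isna().any():
            raise ValueError("missing gene lengths")
        if (self.lengths <= 0).any():
            raise ValueError("non-positive gene length")
        if self.library_sizes is None:
            self.library_sizes = self.counts.sum(axis=0)
        if (self.library_sizes <= 0).any():
            raise ValueError("non-positive library size")

    @property
    def samples(self) -> List[str]:
        return list(self.counts.columns)

    def rpkm(self) -> pd.DataFrame:
        return rpkm(self.counts, self.lengths, self.library_sizes)

    @classmethod
    def from_tsv(cls, path: str) -> "ExpressionMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0)
        if "length" not in df.columns:
            raise ValueError("counts TSV must carry a 'length' column")
        lengths = df.pop("length")
        return cls(df.astype(np.int64), lengths)

    def to_tsv(self, path: str) -> None:
        out = self.counts.copy()
        out.insert(0, "length", self.lengths)
        out.to_csv(path, sep="\t")


def rpkm(counts: pd.DataFrame, lengths: pd.Series, library_sizes: Optional[pd.Series] = None) -> pd.DataFrame:
    """Reads per kilobase of transcript per million mapped reads."""
    if library_sizes is None:
        library_sizes = counts.sum(axis=0)
    if (np.asarray(library_sizes) <= 0).any():
        raise ValueError("library sizes must be positive")
    if (np.asarray(lengths) <= 0).any():
        raise ValueError("gene lengths must be positive")
    L = lengths.reindex(counts.index).to_numpy(dtype=float)
    lib = np.asarray(library_sizes, dtype=float)
    return pd.DataFrame(
        1e9 * counts.to_numpy(dtype=float) / (lib[None, :] * L[:, None]),
        index=counts.index,
        columns=counts.columns,
    )


def de_test(
    log_expr: pd.DataFrame, groups: Dict[str, Sequence[str]]
) -> pd.Series:
    """Per-gene one-way ANOVA p-values on (already log-transformed) expression.

    Groups with zero within-group variance everywhere and equal means give
    p = 1 (no evidence convention).  Two groups reduce to the pooled t-test.
    """
    if len(groups) < 2:
        raise ValueError("need >= 2 groups")
    for lab, cols in groups.items():
        if len(cols) < 2:
            raise ValueError(f"group {lab} has < 2 samples")
    blocks = [log_expr[list(cols)].to_numpy(dtype=float) for cols in groups.values()]
    pvals = np.ones(len(log_expr))
    for i in range(len(log_expr)):
        vals = [b[i] for b in blocks]
        if all(np.ptp(v) == 0 for v in vals):
            means = [v[0] for v in vals]
            pvals[i] = 1.0 if np.ptp(means) == 0 else 0.0
            continue
        f, p = stats.f_oneway(*vals)
        pvals[i] = p
    return pd.Series(pvals, index=log_expr.index, name="pvalue")


def bh_fdr(pvalues: Iterable[float]) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values."""
    from statsmodels.stats.multitest import multipletests

    p = np.asarray(list(pvalues), dtype=float)
    if len(p) == 0:
        return p
    return multipletests(p, method="fdr_bh")[1]


def call_degs(
    p_adj: pd.Series, log2fc: pd.Series, alpha: float = 0.05, fc_min: float = 1.0
) -> pd.Series:
    """'up' / 'down' / 'ns' per gene: p_adj < alpha AND |log2FC| > fc_min."""
    sig = (p_adj < alpha) & (log2fc.abs() > fc_min)
    calls = np.where(~sig, "ns", np.where(log2fc > 0, "up", "down"))
    return pd.Series(calls, index=p_adj.index, name="call")


def pairwise_de(
    expr: ExpressionMatrix,
    design: PopulationDesign,
    pair: Tuple[str, str],
    pseudocount: float = 1.0,
    alpha: float = 0.05,
    fc_min: float = 1.0,
) -> pd.DataFrame:
    """DE table for one population pair, ordered (lower, higher) altitude.

    Columns: log2fc (higher minus lower group mean of log2(RPKM+pc)),
    pvalue, p_adj, call.
    """
    lo, hi = pair
    order = {lab: i for i, lab in enumerate(design.labels)}
    if order[lo] > order[hi]:
        lo, hi = hi, lo
    logr = np.log2(expr.rpkm() + pseudocount)
    cols_lo = design.samples_for(lo)
    cols_hi = design.samples_for(hi)
    p = de_test(logr, {lo: cols_lo, hi: cols_hi})
    lfc = logr[cols_hi].mean(axis=1) - logr[cols_lo].mean(axis=1)
    p_adj = pd.Series(bh_fdr(p), index=p.index, name="p_adj")
    return pd.DataFrame(
        {"log2fc": lfc, "pvalue": p, "p_adj": p_adj, "call": call_degs(p_adj, lfc, alpha, fc_min)}
    )


def cluster_samples(
    rpkm_matrix: pd.DataFrame, genes: Optional[Sequence[str]] = None
) -> Tuple[np.ndarray, List[str], str]:
    """Average-linkage clustering of samples on 1 - Pearson r of log2(RPKM+1).

    Returns (scipy linkage matrix, retained sample names, Newick string).
    Constant-expression samples (undefined correlation) are dropped with a
    warning.
    """
    import logging

    x = np.log2(rpkm_matrix + 1.0)
    if genes is not None:
        x = x.loc[list(genes)]
    if x.shape[1] < 3:
        raise ValueError("clustering needs >= 3 samples")
    sd = x.std(axis=0, ddof=0)
    keep = sd > 0
    if not keep.all():
        logging.getLogger(__name__).warning(
            "dropping constant-expression samples: %s", list(x.columns[~keep])
        )
    x = x.loc[:, keep]
    corr = np.corrcoef(x.to_numpy().T)
    dist = 1.0 - corr
    np.fill_diagonal(dist, 0.0)
    dist = np.maximum((dist + dist.T) / 2.0, 0.0)
    z = linkage(squareform(dist, checks=False), method="average")
    names = list(x.columns)

    def newick(node) -> str:
        if node.is_leaf():
            return names[node.id]
        left = newick(node.get_left())
        right = newick(node.get_right())
        dl = node.dist - node.get_left().dist
        dr = node.dist - node.get_right().dist
        return f"({left}:{dl:.10g},{right}:{dr:.10g})"

    tree = to_tree(z)
    return z, names, newick(tree) + ";"


def volcano_table(de_table: pd.DataFrame) -> pd.DataFrame:
    """(log2FC, -log10 p_adj) projection of a pairwise DE table."""
    with np.errstate(divide="ignore"):
        neglog = -np.log10(de_table["p_adj"].to_numpy(dtype=float))
    return pd.DataFrame(
        {"log2fc": de_table["log2fc"], "neg_log10_p_adj": neglog, "call": de_table["call"]},
        index=de_table.index,
    )
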