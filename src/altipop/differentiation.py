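"""Pairwise FST / GST, locus-specific branch lengths and outlier scans.

FST uses Hudson's estimator aggregated as a ratio of averages (robust for
the small per-population sample sizes of a transcriptome survey); Nei's GST
partitions heterozygosity across all populations at once.  Raw per-site and
per-gene values may be negative and are preserved in diagnostic columns;
aggregated values are clamped to [0, 1] before the LSBL decomposition,
which assumes metric-like distances.

LSBL splits the three pairwise distances among populations A, B, C into
per-population branch lengths:

    lsbl_A = (d_AB + d_AC - d_BC) / 2   (cyclically for B and C)

so lineage-specific divergence of one population is isolated from shared
drift of the other two.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Set, Tuple

import numpy as np
import pandas as pd

from .variants import PopulationDesign, VariantTable

__all__ = [
    "hudson_fst_sites",
    "hudson_fst",
    "weir_cockerham_fst",
    "nei_gst",
    "lsbl",
    "lsbl_table",
    "select_by_lsbl",
    "outlier_genes",
    "pairwise_fst_table",
    "differentiation_table",
]


def _check_freqs(p: np.ndarray, n: np.ndarray, name: str) -> None:
    if np.any((p < 0) | (p > 1)):
        raise ValueError(f"{name}: allele frequencies outside [0, 1]")
    if np.any(n < 2):
        raise ValueError(f"{name}: need >= 2 chromosomes per site")


def hudson_fst_sites(
    p1: np.ndarray, p2: np.ndarray, n1: np.ndarray, n2: np.ndarray
) -> Tuple[np.ndarray, np.ndarray]:
    """Per-site Hudson numerator and denominator.

    N = (p1-p2)^2 - p1(1-p1)/(n1-1) - p2(1-p2)/(n2-1)
    D = p1(1-p2) + p2(1-p1)
    """
    p1 = np.atleast_1d(np.asarray(p1, dtype=float))
    p2 = np.atleast_1d(np.asarray(p2, dtype=float))
    n1 = np.broadcast_to(np.atleast_1d(np.asarray(n1, dtype=float)), p1.shape)
    n2 = np.broadcast_to(np.atleast_1d(np.asarray(n2, dtype=float)), p2.shape)
    _check_freqs(p1, n1, "pop1")
    _check_freqs(p2, n2, "pop2")
    num = (p1 - p2) ** 2 - p1 * (1 - p1) / (n1 - 1) - p2 * (1 - p2) / (n2 - 1)
    den = p1 * (1 - p2) + p2 * (1 - p1)
    return num, den


def hudson_fst(
    p1: np.ndarray, p2: np.ndarray, n1: np.ndarray, n2: np.ndarray, clamp: bool = True
) -> float:
    """Multi-site Hudson FST as ratio of averages ΣN/ΣD.

    Sites monomorphic in both populations (D = 0) are excluded; if every
    site is excluded the estimate is undefined (NaN).  The raw ratio may be
    slightly negative; by default it is clamped to [0, 1].
    """
    num, den = hudson_fst_sites(p1, p2, n1, n2)
    use = den > 0
    if not np.any(use):
        return float("nan")
    raw = float(num[use].sum() / den[use].sum())
    return float(min(max(raw, 0.0), 1.0)) if clamp else raw


def weir_cockerham_fst(
    p1: np.ndarray, p2: np.ndarray, n1: np.ndarray, n2: np.ndarray, clamp: bool = True
) -> float:
    """Two-population Weir–Cockerham θ̂ (ratio of averages), for sensitivity checks.

    Allele-frequency-only form (no inbreeding / heterozygosity term beyond
    the binomial expectation), r = 2 populations.
    """
    p1 = np.atleast_1d(np.asarray(p1, dtype=float))
    p2 = np.atleast_1d(np.asarray(p2, dtype=float))
    c1 = np.broadcast_to(np.atleast_1d(np.asarray(n1, dtype=float)), p1.shape) / 2.0
    c2 = np.broadcast_to(np.atleast_1d(np.asarray(n2, dtype=float)), p2.shape) / 2.0
    r = 2.0
    n_bar = (c1 + c2) / r
    nc = (r * n_bar - (c1**2 + c2**2) / (r * n_bar)) / (r - 1.0)
    p_bar = (c1 * p1 + c2 * p2) / (r * n_bar)
    s2 = (c1 * (p1 - p_bar) ** 2 + c2 * (p2 - p_bar) ** 2) / ((r - 1.0) * n_bar)
    h_bar = (c1 * 2 * p1 * (1 - p1) + c2 * 2 * p2 * (1 - p2)) / (r * n_bar)
    a = n_bar / nc * (s2 - 1.0 / (n_bar - 1.0) * (p_bar * (1 - p_bar) - (r - 1.0) / r * s2 - h_bar / 4.0))
    b = n_bar / (n_bar - 1.0) * (p_bar * (1 - p_bar) - (r - 1.0) / r * s2 - (2.0 * n_bar - 1.0) / (4.0 * n_bar) * h_bar)
    c = h_bar / 2.0
    den = a + b + c
    use = den > 0
    if not np.any(use):
        return float("nan")
    raw = float(a[use].sum() / den[use].sum())
    return float(min(max(raw, 0.0), 1.0)) if clamp else raw


def nei_gst(
    freqs: Sequence[np.ndarray], clamp: bool = True
) -> float:
    """Nei's GST over >= 2 populations and a set of sites.

    H_S = mean over populations of 2p̂q̂, H_T = 2p̄q̄ with p̄ the across-
    population mean frequency; GST = 1 - ΣH_S / ΣH_T over sites.  Undefined
    (NaN) when ΣH_T = 0.
    """
    if len(freqs) < 2:
        raise ValueError("GST needs >= 2 populations")
    P = np.vstack([np.atleast_1d(np.asarray(p, dtype=float)) for p in freqs])
    if np.any((P < 0) | (P > 1)):
        raise ValueError("allele frequencies outside [0, 1]")
    hs = np.mean(2.0 * P * (1.0 - P), axis=0)
    p_bar = P.mean(axis=0)
    ht = 2.0 * p_bar * (1.0 - p_bar)
    use = ht > 0
    if not np.any(use):
        return float("nan")
    raw = 1.0 - float(hs[use].sum() / ht[use].sum())
    return float(min(max(raw, 0.0), 1.0)) if clamp else raw


def lsbl(d_ab: float, d_ac: float, d_bc: float) -> Tuple[float, float, float]:
    """Locus-specific branch lengths (A, B, C) from pairwise distances.

    Negative input distances are clamped to 0 before decomposition; NaN in
    any input propagates to all three outputs.  Branch lengths below 0 are
    reported as 0 (the raw values are recoverable from the inputs).
    """
    if any(np.isnan(x) for x in (d_ab, d_ac, d_bc)):
        return (float("nan"),) * 3
    d_ab, d_ac, d_bc = (max(d, 0.0) for d in (d_ab, d_ac, d_bc))
    raw = (
        (d_ab + d_ac - d_bc) / 2.0,
        (d_ab + d_bc - d_ac) / 2.0,
        (d_ac + d_bc - d_ab) / 2.0,
    )
    return tuple(max(x, 0.0) for x in raw)


def _pop_freqs(table: VariantTable, design: PopulationDesign) -> Dict[str, Tuple[np.ndarray, np.ndarray]]:
    out = {}
    for lab, cols in design.indices(table).items():
        alt, n_chr = table.alt_counts(cols)
        with np.errstate(invalid="ignore"):
            p = np.where(n_chr > 0, alt / np.maximum(n_chr, 1), np.nan)
        out[lab] = (p, n_chr)
    return out


def _gene_groups(table: VariantTable) -> Dict[str, np.ndarray]:
    groups: Dict[str, list] = {}
    for i, tid in enumerate(table.transcript_id):
        groups.setdefault(str(tid), []).append(i)
    return {k: np.asarray(v, dtype=np.intp) for k, v in groups.items()}


def pairwise_fst_table(
    table: VariantTable,
    design: PopulationDesign,
    estimator: str = "hudson",
) -> pd.DataFrame:
    """Per-gene (and genome-wide) pairwise FST for every population pair.

    Only sites with >= 1 called genotype (2 chromosomes) in both populations
    of a pair contribute.  Columns: unit_id, pair, fst, fst_raw, n_sites.
    """
    est = {"hudson": hudson_fst, "weir-cockerham": weir_cockerham_fst}[estimator]
    freqs = _pop_freqs(table, design)
    groups = _gene_groups(table)
    rows = []
    units = list(groups.items()) + [("genome", np.arange(table.n_sites, dtype=np.intp))]
    for tid, sites in units:
        for a, b in combinations(design.labels, 2):
            pa, na = freqs[a]
            pb, nb = freqs[b]
            ok = sites[(na[sites] >= 2) & (nb[sites] >= 2)]
            if len(ok) == 0:
                fst_v, raw = float("nan"), float("nan")
            else:
                fst_v = est(pa[ok], pb[ok], na[ok], nb[ok], clamp=True)
                raw = est(pa[ok], pb[ok], na[ok], nb[ok], clamp=False)
            rows.append(dict(unit_id=tid, pair=f"{a}-{b}", fst=fst_v, fst_raw=raw, n_sites=len(ok)))
    return pd.DataFrame(rows)


def gst_table(table: VariantTable, design: PopulationDesign) -> pd.DataFrame:
    """Per-gene (and genome-wide) Nei GST over all populations."""
    freqs = _pop_freqs(table, design)
    groups = _gene_groups(table)
    rows = []
    units = list(groups.items()) + [("genome", np.arange(table.n_sites, dtype=np.intp))]
    for tid, sites in units:
        ok = sites
        for lab in design.labels:
            ok = ok[freqs[lab][1][ok] >= 2]
        if len(ok) == 0:
            g, raw = float("nan"), float("nan")
        else:
            plist = [freqs[lab][0][ok] for lab in design.labels]
            g = nei_gst(plist, clamp=True)
            raw = nei_gst(plist, clamp=False)
        rows.append(dict(unit_id=tid, gst=g, gst_raw=raw, n_sites=len(ok)))
    return pd.DataFrame(rows)


def lsbl_table(fst_table: pd.DataFrame, labels: Sequence[str]) -> pd.DataFrame:
    """Per-gene LSBL from a pairwise FST table (three populations).

    Columns: unit_id, lsbl_<A>, lsbl_<B>, lsbl_<C>.
    """
    if len(labels) != 3:
        raise ValueError("LSBL is defined for exactly three populations")
    a, b, c = labels
    wide = fst_table.pivot(index="unit_id", columns="pair", values="fst")

    def pair_col(x: str, y: str) -> str:
        return f"{x}-{y}" if f"{x}-{y}" in wide.columns else f"{y}-{x}"

    d_ab = wide[pair_col(a, b)]
    d_ac = wide[pair_col(a, c)]
    d_bc = wide[pair_col(b, c)]
    vals = [lsbl(*t) for t in zip(d_ab, d_ac, d_bc)]
    out = pd.DataFrame(vals, columns=[f"lsbl_{a}", f"lsbl_{b}", f"lsbl_{c}"], index=wide.index)
    return out.reset_index()


def select_by_lsbl(
    lsbl_tab: pd.DataFrame, population: str, threshold: float = 0.5
) -> Tuple[Set[str], int]:
    """Candidate genes with lsbl_<population> strictly above *threshold*.

    Also returns the count of genes with LSBL exactly 1 (maximal branch).
    The 'genome' aggregate row, if present, is excluded.
    """
    col = f"lsbl_{population}"
    tab = lsbl_tab[lsbl_tab.unit_id != "genome"]
    vals = tab[col]
    selected = set(tab.unit_id[vals > threshold])
    n_max = int(np.sum(vals == 1.0))
    return selected, n_max


def outlier_genes(
    stat_table: pd.DataFrame, stat_col: str, q: float = 0.99
) -> Set[str]:
    """Genes above the empirical q-quantile of a statistic (ties included).

    Requires >= 20 genes with a defined statistic for a meaningful quantile.
    """
    if not (0.0 < q < 1.0):
        raise ValueError("quantile must lie in (0, 1)")
    tab = stat_table[stat_table.unit_id != "genome"].dropna(subset=[stat_col])
    if len(tab) < 20:
        raise ValueError(f"only {len(tab)} genes with defined {stat_col}; >= 20 required")
    cutoff = float(np.quantile(tab[stat_col].to_numpy(), q))
    return set(tab.unit_id[tab[stat_col] >= cutoff])


def differentiation_table(
    table: VariantTable, design: PopulationDesign, estimator: str = "hudson"
) -> pd.DataFrame:
    """Joined per-gene FST (wide), GST and LSBL table."""
    fst_tab = pairwise_fst_table(table, design, estimator=estimator)
    wide = fst_tab.pivot(index="unit_id", columns="pair", values="fst")
    wide.columns = [f"fst_{c}" for c in wide.columns]
    g = gst_table(table, design).set_index("unit_id")
    out = wide.join(g[["gst", "gst_raw", "n_sites"]])
    if len(design.labels) == 3:
        ls = lsbl_table(fst_tab, design.labels).set_index("unit_id")
        out = out.join(ls)
    return out.reset_index()
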