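"""Nucleotide diversity, Watterson's theta, Tajima's D and density t-tests.

π is computed from unphased genotype dosages with the unbiased per-site
heterozygosity estimator 2·p̂·(1−p̂)·n/(n−1), which equals the mean pairwise
difference among the sampled chromosomes at that site.  Sites with missing
calls contribute with their own called chromosome count; an all-missing
site is skipped.

Tajima's D follows the classical constants cascade (a1, a2, b1, b2, c1, c2,
e1, e2) and is undefined — flagged, not zero — when S = 0.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Dict, Iterable, List, Optional, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .variants import MISSING, PopulationDesign, TranscriptAnnotation, VariantTable

__all__ = [
    "watterson_theta",
    "nucleotide_diversity",
    "tajima_constants",
    "tajimas_d",
    "d_threshold_bins",
    "pooled_t_test",
    "diversity_table",
]


def _harmonic(n: int, power: int = 1) -> float:
    return sum(1.0 / i**power for i in range(1, n))


def watterson_theta(S: int, n: int, L: float) -> float:
    """Per-site Watterson estimator θ̂_W = S / (a1 · L), a1 = Σ_{i<n} 1/i."""
    if n < 2:
        raise ValueError("Watterson's theta requires n >= 2 chromosomes")
    if L <= 0:
        raise ValueError("covered length must be positive")
    if S < 0:
        raise ValueError("segregating-site count must be >= 0")
    return S / (_harmonic(n) * L)


def _site_pi_terms(dosages: np.ndarray) -> Tuple[np.ndarray, int]:
    """Per-site unbiased heterozygosity 2p̂q̂·n/(n−1); returns (terms, skipped)."""
    dosages = np.asarray(dosages)
    if dosages.ndim == 1:
        dosages = dosages[None, :]
    called = dosages != MISSING
    n_chr = 2 * called.sum(axis=1)
    alt = np.where(called, dosages, 0).sum(axis=1)
    usable = n_chr >= 2
    skipped = int(np.sum(~usable))
    n = n_chr[usable].astype(float)
    p = alt[usable] / n
    terms = 2.0 * p * (1.0 - p) * n / (n - 1.0)
    return terms, skipped


def nucleotide_diversity(dosages: np.ndarray, L: float) -> float:
    """Per-site π over a unit: Σ_sites 2p̂q̂·n/(n−1) / L.

    *dosages* is (n_sites, n_samples) with -1 for missing; sites with fewer
    than two called chromosomes are skipped.
    """
    if L <= 0:
        raise ValueError("covered length must be positive")
    terms, _ = _site_pi_terms(dosages)
    return float(terms.sum()) / L


def tajima_constants(n: int) -> Dict[str, float]:
    """Tajima's variance constants for n sampled chromosomes."""
    if n < 2:
        raise ValueError("n >= 2 required")
    a1 = _harmonic(n)
    a2 = _harmonic(n, 2)
    b1 = (n + 1.0) / (3.0 * (n - 1.0))
    b2 = 2.0 * (n**2 + n + 3.0) / (9.0 * n * (n - 1.0))
    c1 = b1 - 1.0 / a1
    c2 = b2 - (n + 2.0) / (a1 * n) + a2 / a1**2
    e1 = c1 / a1
    e2 = c2 / (a1**2 + a2)
    return dict(a1=a1, a2=a2, b1=b1, b2=b2, c1=c1, c2=c2, e1=e1, e2=e2)


def tajimas_d(S: int, k_bar: float, n: int) -> float:
    """Tajima's D from S segregating sites and mean pairwise differences k̄.

    k̄ is π summed over the unit's sites (not per site).  Returns NaN when
    S = 0 (the statistic is undefined, not zero).
    """
    if S < 0:
        raise ValueError("S must be >= 0")
    if S == 0:
        return float("nan")
    c = tajima_constants(n)
    var = c["e1"] * S + c["e2"] * S * (S - 1.0)
    if var <= 0:
        return float("nan")
    return (k_bar - S / c["a1"]) / math.sqrt(var)


def d_threshold_bins(
    d_values: Iterable[float], upper: float = 1.5, lower: float = -1.0
) -> Dict[str, float]:
    """Proportions of defined D values above *upper* and below *lower*.

    Undefined (NaN) values are excluded from the denominator and their
    count reported.
    """
    arr = np.asarray(list(d_values), dtype=float)
    defined = arr[~np.isnan(arr)]
    n_undef = int(len(arr) - len(defined))
    if len(defined) == 0:
        raise ValueError("no defined Tajima's D values to bin")
    return {
        "prop_above": float(np.mean(defined > upper)),
        "prop_below": float(np.mean(defined < lower)),
        "n_defined": int(len(defined)),
        "n_undefined": n_undef,
    }


def pooled_t_test(group_a: Iterable[float], group_b: Iterable[float]) -> Tuple[float, int, float]:
    """Two-sample pooled (equal-variance) t-test; returns (t, df, two-sided p).

    Degenerate zero-variance inputs use the documented conventions:
    equal means -> (0, df, 1); unequal means -> (±inf, df, 0).
    """
    a = np.asarray(list(group_a), dtype=float)
    b = np.asarray(list(group_b), dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs >= 2 values")
    df = len(a) + len(b) - 2
    sp2 = ((len(a) - 1) * a.var(ddof=1) + (len(b) - 1) * b.var(ddof=1)) / df
    if sp2 == 0.0:
        if a.mean() == b.mean():
            return 0.0, df, 1.0
        return math.copysign(float("inf"), a.mean() - b.mean()), df, 0.0
    t = (a.mean() - b.mean()) / math.sqrt(sp2 * (1.0 / len(a) + 1.0 / len(b)))
    p = 2.0 * stats.t.sf(abs(t), df)
    return float(t), df, float(p)


# ---------------------------------------------------------------------------
# per-gene / genome-wide table


def diversity_table(
    table: VariantTable,
    annotation: TranscriptAnnotation,
    design: PopulationDesign,
    low_call_fraction: float = 0.5,
) -> pd.DataFrame:
    """π, θ_W and Tajima's D per (gene, population) plus genome-wide rows.

    Columns: unit_id, population, S, n, L, theta_w, pi, tajima_d,
    low_confidence.  n is 2 x the population's sample count; sites with
    missing calls use their own n inside π.  Genes where fewer than
    ``low_call_fraction`` of site-calls are present are flagged.
    """
    design.require_min_samples(2)
    idx = design.indices(table)
    lengths = annotation.table.set_index("transcript_id").covered_bp
    rows: List[dict] = []
    seg_masks = {lab: table.segregating_mask(idx[lab]) for lab in design.labels}
    by_tid: Dict[str, np.ndarray] = {}
    for i, tid in enumerate(table.transcript_id):
        by_tid.setdefault(str(tid), []).append(i)
    by_tid = {k: np.asarray(v, dtype=np.intp) for k, v in by_tid.items()}
    empty = np.asarray([], dtype=np.intp)
    genome_acc = {lab: dict(S=0, k=0.0, L=0.0) for lab in design.labels}
    for tid in annotation.transcript_ids:
        L = float(lengths.loc[tid])
        sites = by_tid.get(tid, empty)
        for lab in design.labels:
            cols = idx[lab]
            n = 2 * len(cols)
            g = table.genotypes[np.ix_(sites, cols)] if len(sites) else np.zeros((0, len(cols)), np.int8)
            S = int(seg_masks[lab][sites].sum()) if len(sites) else 0
            terms, _ = _site_pi_terms(g) if g.size else (np.zeros(0), 0)
            k_sum = float(terms.sum())
            pi = k_sum / L
            theta = watterson_theta(S, n, L)
            d = tajimas_d(S, k_sum, n)
            called_frac = float(np.mean(g != MISSING)) if g.size else 1.0
            rows.append(
                dict(unit_id=tid, population=lab, S=S, n=n, L=L, theta_w=theta,
                     pi=pi, tajima_d=d, low_confidence=called_frac < low_call_fraction)
            )
            acc = genome_acc[lab]
            acc["S"] += S
            acc["k"] += k_sum
            acc["L"] += L
    for lab in design.labels:
        acc = genome_acc[lab]
        n = 2 * len(idx[lab])
        rows.append(
            dict(unit_id="genome", population=lab, S=acc["S"], n=n, L=acc["L"],
                 theta_w=watterson_theta(int(acc["S"]), n, acc["L"]),
                 pi=acc["k"] / acc["L"],
                 tajima_d=tajimas_d(int(acc["S"]), acc["k"], n),
                 low_confidence=False)
        )
    return pd.DataFrame(rows)
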