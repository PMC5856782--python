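"""Hedges' g effect sizes, DerSimonian–Laird random-effects pooling,
meta-regression on a moderator, and randomization of samples into
pseudo-studies.

Hedges' g is the small-sample bias-corrected standardized mean difference

    d = (m1 - m2) / s_pooled,   J = 1 - 3 / (4(n1+n2-2) - 1),   g = J d
    var_g = J^2 [ (n1+n2)/(n1 n2) + d^2 / (2(n1+n2-2)) ]

Pooling uses the DerSimonian–Laird method-of-moments tau^2 with
inverse-variance weights 1/(var_g + tau^2); meta-regression is weighted
least squares with the same weights (tau^2 from the intercept-only fit)
and normal-theory inference.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from ._rng import stage_rng

Z95 = 1.959963984540054

__all__ = [
    "hedges_g",
    "StudyEffect",
    "RandomEffectsMeta",
    "MetaResults",
    "MetaRegressionResults",
    "effects_from_summaries",
    "randomize_studies",
    "pseudo_study_effects",
]


def hedges_g(
    mean1: float, sd1: float, n1: int, mean2: float, sd2: float, n2: int
) -> Tuple[float, float]:
    """Bias-corrected standardized mean difference g and its sampling variance."""
    if n1 < 2 or n2 < 2:
        raise ValueError("group sizes must be >= 2")
    df = n1 + n2 - 2
    sp2 = ((n1 - 1) * sd1**2 + (n2 - 1) * sd2**2) / df
    if sp2 <= 0:
        raise ValueError("pooled sd is zero; standardization undefined")
    d = (mean1 - mean2) / math.sqrt(sp2)
    J = 1.0 - 3.0 / (4.0 * df - 1.0)
    g = J * d
    var_g = J**2 * ((n1 + n2) / (n1 * n2) + d**2 / (2.0 * df))
    return g, var_g


@dataclass
class StudyEffect:
    """One study's effect size, variance, group sizes and optional moderator."""

    study: str
    g: float
    var_g: float
    n1: int
    n2: int
    moderator: Optional[float] = None

    def __post_init__(self) -> None:
        if not (self.var_g > 0):
            raise ValueError("var_g must be positive")
        if not np.isfinite(self.g):
            raise ValueError("g must be finite")


def effects_from_summaries(studies: pd.DataFrame, moderator: Optional[str] = None) -> List[StudyEffect]:
    """StudyEffect list from a (study, mean1, sd1, n1, mean2, sd2, n2[, moderator]) table."""
    out = []
    for _, r in studies.iterrows():
        g, v = hedges_g(r.mean1, r.sd1, int(r.n1), r.mean2, r.sd2, int(r.n2))
        out.append(
            StudyEffect(str(r.study), g, v, int(r.n1), int(r.n2),
                        float(r[moderator]) if moderator else None)
        )
    return out


class RandomEffectsMeta:
    """DerSimonian–Laird random-effects model over study effects.

    With ``moderator=True`` the fit is a random-effects meta-regression of
    g on each study's moderator covariate (tau^2 from the intercept-only
    DL fit).
    """

    def __init__(self, effects: Sequence[StudyEffect], moderator: bool = False) -> None:
        if len(effects) < 1:
            raise ValueError("no studies")
        self.effects = list(effects)
        self.moderator = moderator
        if moderator:
            xs = [e.moderator for e in effects]
            if any(x is None for x in xs):
                raise ValueError("moderator requested but some studies lack one")
            if len(effects) < 3:
                raise ValueError("meta-regression needs >= 3 studies")
            if np.ptp(xs) == 0:
                raise ValueError("moderator is constant")

    @staticmethod
    def _dl_tau2(g: np.ndarray, v: np.ndarray) -> Tuple[float, float]:
        """(tau2, Q) by the DerSimonian–Laird method of moments."""
        w = 1.0 / v
        g_fe = float((w * g).sum() / w.sum())
        Q = float((w * (g - g_fe) ** 2).sum())
        k = len(g)
        denom = w.sum() - (w**2).sum() / w.sum()
        tau2 = max(0.0, (Q - (k - 1)) / denom) if denom > 0 else 0.0
        return tau2, Q

    def fit(self) -> "MetaResults | MetaRegressionResults":
        g = np.array([e.g for e in self.effects])
        v = np.array([e.var_g for e in self.effects])
        k = len(g)
        if k == 1:
            return MetaResults(
                pooled=float(g[0]), se=float(math.sqrt(v[0])), tau2=float("nan"),
                q=0.0, z=float(g[0] / math.sqrt(v[0])),
                p=float(2 * stats.norm.sf(abs(g[0]) / math.sqrt(v[0]))),
                ci_low=float(g[0] - Z95 * math.sqrt(v[0])),
                ci_high=float(g[0] + Z95 * math.sqrt(v[0])),
                weights=np.array([1.0]), k=1,
            )
        tau2, Q = self._dl_tau2(g, v)
        w = 1.0 / (v + tau2)
        if not self.moderator:
            pooled = float((w * g).sum() / w.sum())
            se = float(math.sqrt(1.0 / w.sum()))
            z = pooled / se
            return MetaResults(
                pooled=pooled, se=se, tau2=tau2, q=Q, z=z,
                p=float(2 * stats.norm.sf(abs(z))),
                ci_low=pooled - Z95 * se, ci_high=pooled + Z95 * se,
                weights=w / w.sum(), k=k,
            )
        x = np.array([e.moderator for e in self.effects], dtype=float)
        X = np.column_stack([np.ones(k), x])
        W = np.diag(w)
        xtwx = X.T @ W @ X
        cov = np.linalg.inv(xtwx)
        beta = cov @ X.T @ W @ g
        se = np.sqrt(np.diag(cov))
        z = beta / se
        p = 2 * stats.norm.sf(np.abs(z))
        return MetaRegressionResults(
            intercept=float(beta[0]), slope=float(beta[1]),
            se_intercept=float(se[0]), se_slope=float(se[1]),
            z_slope=float(z[1]), p_slope=float(p[1]),
            z_intercept=float(z[0]), p_intercept=float(p[0]),
            tau2=tau2, k=k,
        )


@dataclass
class MetaResults:
    """Pooled random-effects estimate with heterogeneity diagnostics."""

    pooled: float
    se: float
    tau2: float
    q: float
    z: float
    p: float
    ci_low: float
    ci_high: float
    weights: np.ndarray
    k: int

    def summary(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "estimate": [self.pooled], "se": [self.se], "z": [self.z], "p": [self.p],
                "ci95_low": [self.ci_low], "ci95_high": [self.ci_high],
                "tau2": [self.tau2], "Q": [self.q], "k": [self.k],
            },
            index=["pooled_g"],
        )


@dataclass
class MetaRegressionResults:
    """Random-effects meta-regression (WLS with DL tau^2) results."""

    intercept: float
    slope: float
    se_intercept: float
    se_slope: float
    z_slope: float
    p_slope: float
    z_intercept: float
    p_intercept: float
    tau2: float
    k: int

    def summary(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "estimate": [self.intercept, self.slope],
                "se": [self.se_intercept, self.se_slope],
                "z": [self.z_intercept, self.z_slope],
                "p": [self.p_intercept, self.p_slope],
            },
            index=["intercept", "moderator"],
        )


# ---------------------------------------------------------------------------
# pseudo-study randomization


def randomize_studies(
    site_measurements: Mapping[str, Sequence[Sequence[float]]],
    n_per_site: int = 9,
    seed: int = 0,
    with_replacement: bool = True,
) -> Dict[str, List[Dict[str, float]]]:
    """Randomize per-sample measurement vectors into pseudo-studies.

    *site_measurements* maps each site label to its samples' measurement
    vectors (e.g. per-gene SNP densities per individual).  For each site,
    ``n_per_site`` pseudo-studies are formed by resampling that site's
    sample vectors (with replacement by default; without replacement cycles
    through seeded permutations of the samples) and pooling their
    measurements.  Each pseudo-study is summarized as mean, sd and n.
    """
    rng = stage_rng(seed, "randomize_studies")
    out: Dict[str, List[Dict[str, float]]] = {}
    for site in site_measurements:
        vectors = [np.asarray(v, dtype=float) for v in site_measurements[site]]
        if not vectors:
            raise ValueError(f"site {site} has no samples")
        studies = []
        for s in range(n_per_site):
            if with_replacement:
                picks = rng.integers(0, len(vectors), size=len(vectors))
            else:
                picks = rng.permutation(len(vectors))
            pooled = np.concatenate([vectors[i] for i in picks])
            if len(pooled) < 2:
                raise ValueError("pseudo-study with < 2 measurements")
            studies.append(
                dict(mean=float(pooled.mean()), sd=float(pooled.std(ddof=1)), n=int(len(pooled)))
            )
        out[site] = studies
    return out


def pseudo_study_effects(
    partition: Mapping[str, List[Dict[str, float]]],
    site: str,
    reference: str,
    moderator: Optional[Mapping[str, float]] = None,
) -> List[StudyEffect]:
    """Pair pseudo-studies of *site* against *reference* into Hedges' g effects."""
    studies_a = partition[site]
    studies_b = partition[reference]
    if len(studies_a) != len(studies_b):
        raise ValueError("sites have different pseudo-study counts")
    out = []
    for i, (a, b) in enumerate(zip(studies_a, studies_b)):
        g, v = hedges_g(a["mean"], a["sd"], a["n"], b["mean"], b["sd"], b["n"])
        out.append(
            StudyEffect(
                f"{site}-vs-{reference}-{i + 1}", g, v, a["n"], b["n"],
                moderator.get(site) if moderator else None,
            )
        )
    return out
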