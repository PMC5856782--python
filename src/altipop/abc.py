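"""Rejection ABC for per-transcript SNP density across populations.

The generative model couples the three components a transcriptome SNP
density depends on: a per-bp SNP rate ``mu_p`` per population, read/
detection saturation governed by ``kappa`` (a transcript's variants are
detected with probability E/(E+kappa) at expression level E), and lognormal
expression fluctuation with sd ``sigma_rpkm``.  Per transcript i in
population p the SNP count is

    c_i = E_i / (E_i + kappa),  E_i = expression_i * LogNormal(0, sigma)
    count_i ~ Poisson(mu_p * L_i * c_i)

and the summary statistics are the mean and sd over transcripts of the
per-transcript density (count / L_i, scaled to SNPs/Mb) in each population.

Rejection sampling draws parameter vectors from independent uniform priors,
simulates summaries, standardizes each summary by its across-simulation sd,
and accepts the ``tolerance_quantile`` fraction closest (Euclidean) to the
observed summaries.  The "bifurcation" decision asks what fraction of the
posterior has mu_H above a ratio threshold times the mean of mu_L and mu_M.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from ._rng import stage_rng

__all__ = [
    "ABCModelParams",
    "ABCConfig",
    "simulate_density_model",
    "SnpDensityAbcModel",
    "AbcResults",
    "observed_density_summaries",
]


@dataclass
class ABCModelParams:
    """One parameter vector of the density model."""

    mu_pop: Tuple[float, ...]  # per-bp SNP rate per population
    kappa: float  # detection saturation constant (expression units)
    sigma_rpkm: float  # lognormal sd of expression fluctuation

    def __post_init__(self) -> None:
        if any(m <= 0 for m in self.mu_pop):
            raise ValueError("mu_pop must be positive")
        if self.kappa <= 0:
            raise ValueError("kappa must be positive")
        if self.sigma_rpkm < 0:
            raise ValueError("sigma_rpkm must be >= 0")


@dataclass
class ABCConfig:
    """Rejection-sampler settings: priors, budget, tolerance, seed.

    ``priors`` maps parameter names (``mu_<label>``, ``kappa``,
    ``sigma_rpkm``) to uniform (low, high) ranges.
    """

    priors: Mapping[str, Tuple[float, float]]
    n_sims: int = 20_000
    tolerance_quantile: float = 0.01
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_sims < 100:
            raise ValueError("n_sims >= 100 required")
        if not (0.0 < self.tolerance_quantile <= 1.0):
            raise ValueError("tolerance_quantile must lie in (0, 1]")
        for name, (lo, hi) in self.priors.items():
            if not (hi > lo):
                raise ValueError(f"prior for {name} has empty range")


def simulate_density_model(
    mu: np.ndarray,
    kappa: np.ndarray,
    sigma: np.ndarray,
    lengths: np.ndarray,
    expression: np.ndarray,
    rng: np.random.Generator,
) -> np.ndarray:
    """Summaries for a batch of parameter vectors.

    mu: (n_sims, n_pops); kappa, sigma: (n_sims,).  Returns an array of
    shape (n_sims, 2 * n_pops): per population the mean then sd of the
    per-transcript density in SNPs/Mb.
    """
    mu = np.atleast_2d(np.asarray(mu, dtype=float))
    kappa = np.atleast_1d(np.asarray(kappa, dtype=float))
    sigma = np.atleast_1d(np.asarray(sigma, dtype=float))
    lengths = np.asarray(lengths, dtype=float)
    expression = np.asarray(expression, dtype=float)
    if len(lengths) == 0:
        raise ValueError("no transcripts")
    n_sims, n_pops = mu.shape
    n_t = len(lengths)
    out = np.empty((n_sims, 2 * n_pops))
    noise = rng.lognormal(0.0, 1.0, size=(n_sims, n_t)) ** sigma[:, None]
    e = expression[None, :] * noise
    c = e / (e + kappa[:, None])
    for p in range(n_pops):
        lam = mu[:, p : p + 1] * lengths[None, :] * c
        counts = rng.poisson(lam)
        dens = counts / lengths[None, :] * 1e6
        out[:, 2 * p] = dens.mean(axis=1)
        out[:, 2 * p + 1] = dens.std(axis=1, ddof=1)
    return out


def observed_density_summaries(
    per_transcript_counts: pd.DataFrame, lengths: pd.Series
) -> Tuple[np.ndarray, List[str]]:
    """(mean, sd) per population of per-transcript SNP density (SNPs/Mb).

    *per_transcript_counts*: genes x populations table of within-population
    segregating-site counts.
    """
    L = lengths.reindex(per_transcript_counts.index).to_numpy(dtype=float)
    names: List[str] = []
    vals: List[float] = []
    for pop in per_transcript_counts.columns:
        dens = per_transcript_counts[pop].to_numpy(dtype=float) / L * 1e6
        vals += [float(dens.mean()), float(dens.std(ddof=1))]
        names += [f"mean_density_{pop}", f"sd_density_{pop}"]
    return np.asarray(vals), names


class SnpDensityAbcModel:
    """Rejection-ABC model of per-transcript SNP density.

    Parameters
    ----------
    observed : array of summary statistics (mean, sd per population)
    lengths, expression : per-transcript covariates fed to the simulator
    pop_labels : population labels, defining mu_<label> parameters
    config : ABCConfig; if priors are empty, default uniform ranges are
        derived from the observed mean densities (x10 either side).
    """

    def __init__(
        self,
        observed: np.ndarray,
        lengths: np.ndarray,
        expression: np.ndarray,
        pop_labels: Sequence[str] = ("L", "M", "H"),
        config: Optional[ABCConfig] = None,
    ) -> None:
        self.observed = np.asarray(observed, dtype=float)
        if not np.all(np.isfinite(self.observed)):
            raise ValueError("observed summaries must be finite")
        self.lengths = np.asarray(lengths, dtype=float)
        self.expression = np.asarray(expression, dtype=float)
        self.pop_labels = tuple(pop_labels)
        if len(self.observed) != 2 * len(self.pop_labels):
            raise ValueError("observed must hold (mean, sd) per population")
        if config is None or not config.priors:
            priors = self.default_priors()
            config = ABCConfig(
                priors=priors,
                n_sims=config.n_sims if config else 20_000,
                tolerance_quantile=config.tolerance_quantile if config else 0.01,
                seed=config.seed if config else 0,
            )
        self.config = config
        self.param_names = [f"mu_{lab}" for lab in self.pop_labels] + ["kappa", "sigma_rpkm"]

    def default_priors(self) -> Dict[str, Tuple[float, float]]:
        """Uniform priors bracketing the observed density scale by x10."""
        priors: Dict[str, Tuple[float, float]] = {}
        for i, lab in enumerate(self.pop_labels):
            mu_obs = max(self.observed[2 * i] / 1e6, 1e-9)  # per bp
            priors[f"mu_{lab}"] = (mu_obs / 10.0, mu_obs * 10.0)
        med_expr = float(np.median(self.expression))
        priors["kappa"] = (med_expr / 100.0, med_expr * 2.0)
        priors["sigma_rpkm"] = (0.0, 1.5)
        return priors

    def fit(self, batch_size: int = 5000) -> "AbcResults":
        cfg = self.config
        rng = stage_rng(cfg.seed, "abc_rejection")
        n = cfg.n_sims
        draws = np.column_stack(
            [rng.uniform(*cfg.priors[name], size=n) for name in self.param_names]
        )
        n_pops = len(self.pop_labels)
        sims = np.empty((n, 2 * n_pops))
        for start in range(0, n, batch_size):
            sl = slice(start, min(start + batch_size, n))
            sims[sl] = simulate_density_model(
                draws[sl, :n_pops], draws[sl, n_pops], draws[sl, n_pops + 1],
                self.lengths, self.expression, rng,
            )
        sd = sims.std(axis=0, ddof=1)
        usable = sd > 0
        if not usable.all():
            warnings.warn("summary with zero variance across simulations dropped from distance")
        z_sims = (sims[:, usable] - self.observed[None, usable]) / sd[None, usable]
        dist = np.sqrt((z_sims**2).sum(axis=1))
        n_accept = max(int(round(n * cfg.tolerance_quantile)), 1)
        order = np.argsort(dist, kind="stable")
        accepted = order[:n_accept]
        return AbcResults(
            model=self,
            params=pd.DataFrame(draws[accepted], columns=self.param_names),
            distances=dist[accepted],
            all_distances=dist,
            prior_draws=pd.DataFrame(draws, columns=self.param_names),
        )


@dataclass
class AbcResults:
    """Accepted posterior sample with summaries and the bifurcation decision."""

    model: SnpDensityAbcModel
    params: pd.DataFrame
    distances: np.ndarray
    all_distances: np.ndarray
    prior_draws: pd.DataFrame

    def summary(self) -> pd.DataFrame:
        """Per-parameter posterior mean, median and central 95% interval."""
        q = self.params.quantile([0.025, 0.5, 0.975])
        return pd.DataFrame(
            {
                "mean": self.params.mean(),
                "median": q.loc[0.5],
                "ci95_low": q.loc[0.025],
                "ci95_high": q.loc[0.975],
            }
        )

    def posterior_ratio(self, num_pop: str, den_pops: Sequence[str]) -> pd.Series:
        """Posterior draws of mu_<num> / mean(mu_<den> ...)."""
        num = self.params[f"mu_{num_pop}"]
        den = self.params[[f"mu_{p}" for p in den_pops]].mean(axis=1)
        return num / den

    def bifurcation_test(
        self,
        ratio_threshold: float = 1.5,
        prob_cutoff: float = 0.95,
        high_pop: Optional[str] = None,
    ) -> Tuple[float, bool]:
        """P(mu_H > threshold x mean(mu of the other populations)) and flag."""
        labs = list(self.model.pop_labels)
        hp = high_pop or labs[-1]
        others = [l for l in labs if l != hp]
        ratio = self.posterior_ratio(hp, others)
        prob = float(np.mean(ratio > ratio_threshold))
        return prob, prob > prob_cutoff

    def to_tsv(self, path: str) -> None:
        out = self.params.copy()
        out["distance"] = self.distances
        out.to_csv(path, sep="\t", index=False)
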