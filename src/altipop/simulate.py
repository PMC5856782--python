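"""Synthetic three-population transcriptome SNP and expression data.

The generator emulates the statistical structure of a transcriptome SNP
survey of three altitudinal populations (low L, middle M, high H; three
diploid individuals each):

* allele frequencies follow a hierarchical Balding–Nichols model — an
  ancestral frequency per site, a shared "lowland" drift step for L and M,
  then independent per-population drift — so the pairwise FST between L and
  M is much smaller than between either and H;
* the high-altitude population carries an elevated segregating-site density
  (population-private extra sites) and an excess of private SNPs;
* read counts per gene are negative-binomial, with a configurable fraction
  of genes differentially expressed between M and H.

All draws go through a single seeded Generator; identical config + seed
gives bit-identical tables.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from ._rng import stage_rng
from .variants import BASES, MISSING, PopulationDesign, TranscriptAnnotation, VariantTable

__all__ = [
    "SimulationConfig",
    "simulate_allele_frequencies",
    "simulate_variant_table",
    "simulate_expression",
    "simulate_meta_studies",
    "simulate_dataset",
]

_TRANSITION = {"A": "G", "G": "A", "C": "T", "T": "C"}
_TRANSVERSIONS = {b: tuple(x for x in BASES if x != b and x != _TRANSITION[b]) for b in BASES}


@dataclass
class SimulationConfig:
    """Parameters of the synthetic three-population dataset.

    divergence_F are Balding–Nichols drift coefficients per population;
    L and M drift from a shared lowland ancestor (itself drifted from the
    root by ``lowland_F``), H drifts directly from the root.  With the
    defaults the expected Hudson FST is ~0.07 for (L,M) and ~0.45 for
    (L,H)/(M,H), and H carries ~1.8x the segregating-site density of L/M.
    """

    n_transcripts: int = 500
    transcript_length_mean: float = 1500.0
    transcript_length_dispersion: float = 0.35  # lognormal sigma of length
    samples_per_pop: int = 3
    pop_labels: Tuple[str, ...] = ("L", "M", "H")
    ancestral_beta: Tuple[float, float] = (0.8, 0.8)
    divergence_F: Tuple[float, ...] = (0.07, 0.07, 0.62)
    lowland_F: float = 0.42
    snp_rate: float = 0.01  # candidate segregating sites per bp
    density_multiplier: Tuple[float, ...] = (1.0, 1.0, 1.8)
    private_snp_rate: Tuple[float, ...] = (4e-4, 4e-4, 4e-4)  # extra private sites per bp
    missing_rate: float = 0.0
    ts_tv_ratio: float = 2.7
    de_fraction: float = 0.1
    de_log2fc: float = 2.0
    nb_dispersion: float = 0.02
    expression_log_mean: float = 6.0  # natural-log scale of baseline counts/kb
    expression_log_sd: float = 1.2
    library_size_cv: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        npop = len(self.pop_labels)
        if len(self.divergence_F) != npop or len(self.density_multiplier) != npop or len(self.private_snp_rate) != npop:
            raise ValueError("per-population parameter tuples must match pop_labels")
        for F in (*self.divergence_F, self.lowland_F):
            if not (0.0 <= F < 1.0):
                raise ValueError(f"drift coefficient F={F} outside [0, 1)")
        if not (0.0 <= self.de_fraction <= 1.0):
            raise ValueError("de_fraction must lie in [0, 1]")
        for name in ("n_transcripts", "samples_per_pop"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        for name in ("transcript_length_mean", "snp_rate", "ts_tv_ratio"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.nb_dispersion < 0:
            raise ValueError("nb_dispersion must be >= 0")
        if any(m <= 0 for m in self.density_multiplier) or any(r < 0 for r in self.private_snp_rate):
            raise ValueError("density multipliers must be positive, private rates non-negative")

    @property
    def sample_names(self) -> List[str]:
        return [f"{lab}{i + 1}" for lab in self.pop_labels for i in range(self.samples_per_pop)]

    def design(self) -> PopulationDesign:
        assignment = {
            f"{lab}{i + 1}": lab for lab in self.pop_labels for i in range(self.samples_per_pop)
        }
        return PopulationDesign(self.pop_labels, assignment)


def _balding_nichols(rng: np.random.Generator, p: np.ndarray, F: float) -> np.ndarray:
    """Draw daughter frequencies around p with drift F (F=0: no drift)."""
    if F == 0.0:
        return p.copy()
    out = p.copy()
    interior = (p > 0.0) & (p < 1.0)
    shape = (1.0 - F) / F
    pi = p[interior]
    out[interior] = rng.beta(pi * shape, (1.0 - pi) * shape)
    return out


def simulate_allele_frequencies(
    config: SimulationConfig, n_sites: Optional[int] = None
) -> pd.DataFrame:
    """Per-site ancestral and per-population allele frequencies.

    Sites are the 'core' (non-private) segregating candidates; their number
    defaults to Poisson(snp_rate x expected transcriptome length).
    """
    rng = stage_rng(config.seed, "allele_frequencies")
    if n_sites is None:
        expected_bp = config.n_transcripts * config.transcript_length_mean
        n_sites = int(rng.poisson(config.snp_rate * expected_bp))
    a, b = config.ancestral_beta
    p0 = rng.beta(a, b, size=n_sites)
    p_low = _balding_nichols(rng, p0, config.lowland_F)
    freqs = {"p0": p0}
    for lab, F in zip(config.pop_labels, config.divergence_F):
        parent = p0 if lab == config.pop_labels[-1] else p_low
        freqs[lab] = _balding_nichols(rng, parent, F)
    return pd.DataFrame(freqs)


def _draw_lengths(rng: np.random.Generator, config: SimulationConfig) -> np.ndarray:
    sigma = config.transcript_length_dispersion
    mu = np.log(config.transcript_length_mean) - sigma**2 / 2.0
    lengths = np.maximum(np.round(rng.lognormal(mu, sigma, config.n_transcripts)), 300)
    return lengths.astype(np.int64)


def _make_annotation(rng: np.random.Generator, config: SimulationConfig) -> TranscriptAnnotation:
    lengths = _draw_lengths(rng, config)
    rows = []
    sequences: Dict[str, str] = {}
    base_arr = np.array(list(BASES))
    for i, L in enumerate(lengths):
        tid = f"T{i + 1:05d}"
        utr5_len = max(int(round(0.1 * L)), 1)
        cds_len = 3 * (int(round(0.6 * L)) // 3)
        cds_len = max(cds_len, 3)
        if utr5_len + cds_len >= L:
            cds_len = 3 * ((int(L) - utr5_len - 1) // 3)
        utr3_start = utr5_len + cds_len + 1
        rows.append(
            dict(
                transcript_id=tid, length=int(L),
                cds_start=utr5_len + 1, cds_end=utr5_len + cds_len, frame=0,
                utr5_start=1, utr5_end=utr5_len,
                utr3_start=utr3_start if utr3_start <= L else 0,
                utr3_end=int(L) if utr3_start <= L else 0,
                covered_bp=int(L),
            )
        )
        sequences[tid] = "".join(rng.choice(base_arr, size=int(L)))
    return TranscriptAnnotation(pd.DataFrame(rows), sequences)


def _assign_positions(
    rng: np.random.Generator,
    n_sites: int,
    annotation: TranscriptAnnotation,
    occupied: Dict[str, set],
) -> Tuple[List[str], List[int]]:
    lengths = annotation.table.length.to_numpy(dtype=float)
    tids = annotation.table.transcript_id.to_numpy()
    weights = lengths / lengths.sum()
    t_idx = rng.choice(len(tids), size=n_sites, p=weights)
    out_t: List[str] = []
    out_p: List[int] = []
    for ti in t_idx:
        tid = tids[ti]
        occ = occupied.setdefault(tid, set())
        L = int(lengths[ti])
        for _ in range(1000):  # collision -> resample
            pos = int(rng.integers(1, L + 1))
            if pos not in occ:
                occ.add(pos)
                out_t.append(tid)
                out_p.append(pos)
                break
        else:
            raise RuntimeError(f"transcript {tid} saturated with SNPs")
    return out_t, out_p


def _draw_alleles(
    rng: np.random.Generator, config: SimulationConfig, tids: Sequence[str], poss: Sequence[int],
    sequences: Dict[str, str],
) -> Tuple[List[str], List[str]]:
    """Ref = the reference base at the position; alt by Ts:Tv weighting."""
    r = config.ts_tv_ratio
    p_ts = r / (r + 1.0)
    refs, alts = [], []
    for tid, pos in zip(tids, poss):
        ref = sequences[tid][pos - 1]
        if rng.random() < p_ts:
            alt = _TRANSITION[ref]
        else:
            alt = _TRANSVERSIONS[ref][int(rng.integers(2))]
        refs.append(ref)
        alts.append(alt)
    return refs, alts


def _private_dosages(
    rng: np.random.Generator, n_ind: int, n_sites: int
) -> np.ndarray:
    """Low-frequency dosage rows segregating in a population of n_ind diploids."""
    n_chr = 2 * n_ind
    # alt-allele counts concentrated at 1-3 copies (private SNPs are rare)
    counts = rng.choice([1, 2, 3], size=n_sites, p=[0.7, 0.2, 0.1])
    counts = np.minimum(counts, n_chr - 1)
    out = np.zeros((n_sites, n_ind), dtype=np.int8)
    for i, c in enumerate(counts):
        chroms = rng.choice(n_chr, size=int(c), replace=False)
        for ch in chroms:
            out[i, ch // 2] += 1
    return out


def simulate_variant_table(
    config: SimulationConfig, freqs: pd.DataFrame
) -> Tuple[VariantTable, TranscriptAnnotation]:
    """Genotypes + annotation from a per-site frequency table.

    Core sites get Binomial(2, p_pop) dosages per individual.  Extra
    population-private sites are then injected: (i) enough H-private (in
    general, multiplier-driven) sites that each population's within-
    population segregating-site count targets ``multiplier_p x`` a common
    baseline, and (ii) ``private_snp_rate`` per bp of low-frequency private
    sites per population.
    """
    rng = stage_rng(config.seed, "variant_table")
    annotation = _make_annotation(rng, config)
    npop = len(config.pop_labels)
    n_ind = config.samples_per_pop
    n_core = len(freqs)

    geno_blocks = []
    for lab in config.pop_labels:
        p = freqs[lab].to_numpy()
        geno_blocks.append(rng.binomial(2, p[:, None], size=(n_core, n_ind)).astype(np.int8))
    genotypes = np.concatenate(geno_blocks, axis=1)

    # per-population segregating counts on core sites
    seg_counts = []
    for k in range(npop):
        g = genotypes[:, k * n_ind : (k + 1) * n_ind]
        s = g.sum(axis=1)
        seg_counts.append(int(np.sum((s > 0) & (s < 2 * n_ind))))
    # reference count = mean over the least-inflated populations, so the
    # realized within-population density ratio tracks the multipliers
    mult = np.asarray(config.density_multiplier, dtype=float)
    ref_pops = mult == mult.min()
    baseline = float(np.mean(np.asarray(seg_counts)[ref_pops] / mult[ref_pops]))
    total_bp = annotation.total_covered_bp()

    extra_blocks: List[np.ndarray] = []
    extra_pop: List[int] = []
    for k, lab in enumerate(config.pop_labels):
        target = baseline * mult[k] - seg_counts[k]
        lam = max(target, 0.0) + config.private_snp_rate[k] * total_bp
        n_extra = int(rng.poisson(lam))
        if n_extra:
            block = np.zeros((n_extra, npop * n_ind), dtype=np.int8)
            block[:, k * n_ind : (k + 1) * n_ind] = _private_dosages(rng, n_ind, n_extra)
            extra_blocks.append(block)
            extra_pop.extend([k] * n_extra)
    if extra_blocks:
        genotypes = np.concatenate([genotypes] + extra_blocks, axis=0)

    n_total = genotypes.shape[0]
    occupied: Dict[str, set] = {}
    tids, poss = _assign_positions(rng, n_total, annotation, occupied)
    refs, alts = _draw_alleles(rng, config, tids, poss, annotation.sequences)

    if config.missing_rate > 0.0:
        mask = rng.random(genotypes.shape) < config.missing_rate
        genotypes = genotypes.copy()
        genotypes[mask] = MISSING

    order = np.lexsort((np.asarray(poss), np.asarray(tids, dtype=object)))
    table = VariantTable(
        np.asarray(tids, dtype=object)[order],
        np.asarray(poss)[order],
        np.asarray(refs, dtype=object)[order],
        np.asarray(alts, dtype=object)[order],
        genotypes[order],
        config.sample_names,
    )
    return table, annotation


def simulate_expression(
    config: SimulationConfig, annotation: TranscriptAnnotation
) -> Tuple[pd.DataFrame, pd.Series, pd.DataFrame]:
    """Negative-binomial read counts per gene x sample, plus the DE truth table.

    Returns (counts, gene_lengths, truth).  DE genes (a ``de_fraction`` of
    all genes, random sign) have their mean shifted by 2**de_log2fc in the
    highest-altitude population's samples, so they are differential between
    M and H (and between L and H).
    """
    rng = stage_rng(config.seed, "expression")
    tids = annotation.table.transcript_id.to_numpy()
    lengths = annotation.table.length.to_numpy(dtype=float)
    n_genes = len(tids)
    samples = config.sample_names
    n_samp = len(samples)

    baseline = rng.lognormal(config.expression_log_mean, config.expression_log_sd, n_genes)
    lib = np.ones(n_samp)
    if config.library_size_cv > 0:
        sigma = np.sqrt(np.log1p(config.library_size_cv**2))
        lib = rng.lognormal(-sigma**2 / 2.0, sigma, n_samp)

    n_de = int(round(config.de_fraction * n_genes))
    de_idx = rng.choice(n_genes, size=n_de, replace=False) if n_de else np.array([], dtype=int)
    signs = rng.choice([-1.0, 1.0], size=n_de)
    log2fc = np.zeros(n_genes)
    log2fc[de_idx] = signs * config.de_log2fc

    high = config.pop_labels[-1]
    is_high = np.array([s.rstrip("0123456789") == high for s in samples])
    mean = baseline[:, None] * (lengths[:, None] / 1e3) * lib[None, :]
    mean = mean * np.where(is_high[None, :], 2.0 ** log2fc[:, None], 1.0)

    if config.nb_dispersion > 0:
        shape = 1.0 / config.nb_dispersion
        lam = rng.gamma(shape, mean / shape)
    else:
        lam = mean
    counts = rng.poisson(lam).astype(np.int64)

    counts_df = pd.DataFrame(counts, index=pd.Index(tids, name="gene_id"), columns=samples)
    lengths_s = pd.Series(lengths.astype(int), index=counts_df.index, name="length")
    truth = pd.DataFrame(
        {"gene_id": tids[de_idx], "log2fc": log2fc[de_idx]}
    ).sort_values("gene_id").reset_index(drop=True)
    return counts_df, lengths_s, truth


def simulate_meta_studies(
    true_effect: float,
    tau2: float,
    n_studies: int,
    group_n: int,
    seed: int = 0,
) -> pd.DataFrame:
    """Per-study raw summary statistics for a standardized-mean-difference meta-analysis.

    Study-level true effects are Normal(true_effect, tau2); both groups are
    unit-variance Normal with the treatment group shifted by the study
    effect.  Returns columns study, mean1, sd1, n1, mean2, sd2, n2.
    """
    if tau2 < 0:
        raise ValueError("tau2 must be >= 0")
    if group_n < 2:
        raise ValueError("group_n must be >= 2 (sd undefined otherwise)")
    rng = stage_rng(seed, "meta_studies")
    rows = []
    thetas = rng.normal(true_effect, np.sqrt(tau2), n_studies)
    for i, theta in enumerate(thetas):
        g1 = rng.normal(theta, 1.0, group_n)
        g2 = rng.normal(0.0, 1.0, group_n)
        rows.append(
            dict(
                study=f"S{i + 1:02d}",
                mean1=g1.mean(), sd1=g1.std(ddof=1), n1=group_n,
                mean2=g2.mean(), sd2=g2.std(ddof=1), n2=group_n,
            )
        )
    return pd.DataFrame(rows)


def simulate_dataset(config: SimulationConfig):
    """Full synthetic dataset: (table, annotation, design, counts, lengths, truth)."""
    freqs = simulate_allele_frequencies(config)
    table, annotation = simulate_variant_table(config, freqs)
    counts, lengths, truth = simulate_expression(config, annotation)
    return table, annotation, config.design(), counts, lengths, truth
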