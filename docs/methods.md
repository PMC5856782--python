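# Methods

This note records the statistical models implemented in `altipop`, the
choices made where several defensible definitions exist, and what the
synthetic data generator does and does not emulate.

## The synthetic three-population model

The generator stands in for an RNA-seq study of three altitudinal
populations (L, M, H; three diploid individuals each) whose raw data are
not available. It is first-class, tested code: its outputs define the
conditions under which every downstream method is exercised.

**Allele frequencies.** Each segregating site has an ancestral frequency
p₀ ~ Beta(0.8, 0.8). Population frequencies follow the Balding–Nichols
model: a daughter population with drift coefficient F draws its frequency
from Beta(p(1−F)/F, (1−p)(1−F)/F) around its parent's p, which has mean p
and variance F·p(1−p). The topology is hierarchical: a shared "lowland"
ancestor drifts from the root with F = 0.42, L and M drift independently
from it with F = 0.07 each, and H drifts directly from the root with
F = 0.62. For two populations with total drift F₁, F₂ from their common
ancestor, Hudson's FST has expectation ≈ (F₁+F₂)/2, so these defaults give
pairwise FST ≈ 0.07 for (L,M) and ≈ 0.44 for (L,H) and (M,H) after the
dilution introduced by low-frequency private sites (measured on the default
configuration: 0.075–0.080, 0.43–0.44). F = 0 is accepted as the exact
no-drift limit.

**Site counts and private SNPs.** Core sites arrive at `snp_rate` = 0.01
per bp (positions uniform within transcripts, collisions resampled).
Because strong drift pushes H's frequencies toward fixation, H would
otherwise segregate *fewer* sites than L/M; the elevated SNP density of the
high-altitude population is therefore produced by injecting H-private,
low-frequency sites (1–3 alt copies) until each population's
within-population segregating count targets `density_multiplier`
(default 1.0/1.0/1.8) times a reference count taken from the
least-inflated populations. The realized H:L density ratio under the
defaults is ≈ 1.7. An additional `private_snp_rate` (4×10⁻⁴/bp per
population) supplies baseline private sites for L and M. Ref/alt bases are
drawn with a transition:transversion count ratio of 2.7.

**Expression.** Counts are Gamma–Poisson (negative binomial) with mean
baseline × length(kb) × library factor, baseline lognormal
(ln-mean 6.0, ln-sd 1.2). A `de_fraction` (default 0.1) of genes receives a
±`de_log2fc` (default 2.0) shift in the H samples, making them
differential between M and H and between L and H. `nb_dispersion`
defaults to 0.02: combined with the depth default this keeps the total
per-gene CV² ≈ dispersion (shot noise ≲ 0.01), i.e. the low-dispersion
regime in which a 3-vs-3 ANOVA screen at |log₂FC| > 1 has high power.
These two defaults were set together so that the generator realizes a
genuinely low-dispersion study; at dispersion ≈ 0.05 or shallow depth the
small-sample F-test loses roughly a quarter of the true positives to the
FDR correction, which is a property of 3-vs-3 designs, not of the
implementation.

**What the generator does not emulate.** No linkage (sites are
independent), no coalescent genealogies or recombination, no indels or
multi-allelic sites, no mapping/calling artifacts, no expression–genotype
correlation, no library-size trends unless enabled. Passing recovery tests
on these data therefore demonstrates correctness of the estimators and
pipelines under the intended statistical structure, not robustness to the
artifacts of real RNA-seq SNP calling.

## Estimators and conventions

* **π** uses the unbiased per-site form 2p̂q̂·n/(n−1) on unphased dosages
  (equal to the mean pairwise difference among the site's called
  chromosomes), summed over sites and divided by covered length. Sites use
  their own called-chromosome n; genes with <50% called site-cells are
  flagged low-confidence. Per-gene values aggregate exactly to the
  genome-wide value under length weighting.
* **Tajima's D** is computed per gene from (S, k̄, n) with the classical
  constants; it is undefined (NaN, excluded from threshold bins) when
  S = 0.
* **FST** is Hudson's estimator with ratio-of-averages aggregation,
  chosen for small-sample robustness; per-site and per-gene raw values may
  be negative and are preserved in `*_raw` columns, with clamping to [0,1]
  only at aggregation so the LSBL decomposition sees metric-like inputs.
  A two-population Weir–Cockerham variant is available via
  `estimator="weir-cockerham"` for sensitivity analysis. **GST** is Nei's
  heterozygosity partition 1 − ΣH_S/ΣH_T.
* **LSBL** decomposes the three pairwise per-gene FST values;
  lsbl_A + lsbl_B recovers d_AB exactly. Candidate selection uses a strict
  `lsbl > 0.5`; the count of genes at exactly 1 (fixed H-specific
  differences at every informative site) is reported separately.
* **Outlier scans** flag genes at or above the empirical q-quantile
  (default 0.99, ties included); "shared" outliers are the FST∩GST
  intersection.
* **NJ** follows Saitou–Nei with the Studier–Keppler Q criterion; ties are
  broken by lexicographic order of the candidate pair's smallest leaf
  labels, making reconstruction deterministic. Negative branch lengths are
  kept internally and in a sidecar table and clamped to 0 only in Newick
  output. On additive matrices topology and lengths are exact.
* **PCA** centers dosages by 2p̂ and scales by √(2p̂(1−p̂)) (Patterson)
  by default; missing dosages contribute 0 after centering; component
  signs are fixed by forcing each component's largest-magnitude loading
  positive.
* **Permutation test**: statistic = mean between-group minus mean
  within-group Euclidean distance on the first two PC scores;
  p = (1 + #{perm ≥ obs})/(1 + n_perm). With 9 samples the label-permutation
  space has only 84 distinct 3/6 splits, so the attainable minimum p is
  ≈ 0.01 rather than 1/(n_perm+1).
* **DEG rule**: one-way ANOVA on log₂(RPKM + 1) (pseudocount configurable),
  Benjamini–Hochberg adjustment, call iff p_adj < 0.05 and |log₂FC| > 1.
  Positive log₂FC means higher expression in the higher-altitude group of
  the pair. Zero-variance degenerate genes use the p = 1 (equal means) /
  p = 0 (unequal means) convention. Library size is the column sum (no
  TMM); a count-model DE framework is deliberately out of scope.
* **Meta-analysis**: Hedges' g with J = 1 − 3/(4df−1) bias correction and
  var(g) = J²[(n₁+n₂)/(n₁n₂) + d²/(2df)]; DerSimonian–Laird
  method-of-moments τ² truncated at 0; meta-regression is WLS with weights
  1/(var+τ²) using the intercept-only τ², normal-theory inference.
  Pseudo-studies resample each site's per-sample measurement vectors with
  replacement (a without-replacement mode exists); effects contrast a site
  against a reference site (L by default) study-by-study.

## Rejection ABC over SNP density

The generative model makes per-transcript SNP counts depend on the three
components a transcriptome density measurement confounds: mutation rate,
read-occurrence saturation, and expression fluctuation —
count_i ~ Poisson(μ_p · L_i · c_i) with c_i = E_i/(E_i + κ) and
E_i = expression_i × LogNormal(0, σ). Summaries are the mean and sd of
per-transcript density per population; the distance is Euclidean on
summaries standardized by their across-simulation sd; the accepted set is
the `tolerance_quantile` closest of `n_sims` uniform prior draws. Default
priors bracket the observed density scale by ×10 either side (μ's), span
(median expression)/100 to ×2 for κ, and (0, 1.5) for σ.

The "bifurcation" decision reports the posterior probability that
μ_H > 1.5 × mean(μ_L, μ_M), flagged at 0.95. A known property of plain
rejection sampling at desk-scale budgets: with priors spanning two orders
of magnitude, the accepted fraction α pins each of the three constrained
parameter directions only to ~α^(1/3) of its prior range (≈ ×2.7
multiplicative windows at α = 1%), so the ratio posterior keeps an sd of
~0.4–0.7 however informative the data are, and the 0.95-probability flag
does not certify a true 1.8× elevation at 2×10⁴–2×10⁵ simulations. The
posterior *mean* ratio is nevertheless accurate (≈ 1.8 under the default
conditions), the credible interval shrinks monotonically with tolerance,
and the flag stays quiet under an all-equal-μ truth. Certifying at 0.95
would require ~10⁶–10⁷ simulations or a regression-adjusted/SMC sampler,
both outside this package's scope.

## Reproducibility and problem sizes

All randomness flows from one integer seed split into independent
per-stage streams keyed by stable stage names (CRC32 of the stage name as
a spawn key), so toggling one pipeline stage never changes another's
draws. The pipeline writes a manifest of SHA-256 content hashes; identical
config + seed reproduces identical hashes.

Simulation-based checks run at sizes chosen to keep the full test suite
fast while leaving ample statistical resolution: 300–500 transcripts
(≈ 6,000–11,000 SNPs) for structure/selection recovery, 20 seeded
replicates for structure and ABC null calibration, 20,000 simulations at
1% tolerance for ABC recovery, 500 replicates for meta-analysis CI
coverage, and a 2,000-gene bundled demo config. The ABC recovery check
uses ~0.6 expected SNPs per transcript over 1,000 transcripts so that the
Monte-Carlo noise of the mean-density summary is a few percent of its
value.

## Known limitations

* Coding-effect classification needs the reference transcript sequence
  (FASTA); without it only region-level (UTR/CDS) classes are available.
  Each SNP is evaluated independently against the reference codon
  (multi-hit codons are not compounded), transcripts are treated as
  plus-strand, and CDS tails shorter than a codon are treated as
  noncoding with a warning.
* The per-Mb density denominator is the annotation's covered length;
  with real capture data an effective covered length should be supplied.
* "Present in a population" for Venn partitions means ≥1 alt allele; a
  frequency threshold is available but changes private/shared counts.
* The permutation statistic, the allele-sharing distance behind the NJ
  tree, and the pseudo-study measurement (per-sample per-gene SNP density)
  are documented choices where the underlying study procedure is
  underdetermined; all are swappable at the API level.
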