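# Methods

## The analysis model

Records are binary disease outcomes on daughters; genetic evaluation is on
their sires. On the liability scale, record *i* follows

    lambda_i = x_i' beta + h_{hy(i)} + s_{sire(i)} + e_i,
    y_i = 1  iff  lambda_i > 0

with fixed year-season effects `beta` (intercept plus contrasts, reference
level absorbed), herd-year effects `h ~ N(0, I sigma2_h)`, sire effects
`s ~ N(0, H sigma2_s)` and residual `e ~ N(0, I)`. The threshold is fixed
at 0 and the residual variance at 1: these are the standard identification
constraints of the probit/threshold model, and every retained posterior
sample carries `sigma2_e = 1` by construction.

`H` combines pedigree and genomic relationships. Its inverse is assembled
directly as

    H^-1 = A^-1 + [0 0; 0 G*^-1 - A22^-1]

over the *sire pedigree* — the sires of recorded daughters plus all their
ancestors. Daughters and their dams carry no model effect (a sire model),
so they are excluded from the relationship structure; this keeps the mixed
model equations small enough to factor densely inside the sampler.

Because the sire effect is the transmitted half of the breeding value,
`sigma2_s = sigma2_a / 4` and the liability-scale heritability is

    h2 = 4 sigma2_s / (sigma2_s + sigma2_h + sigma2_e),

computed per retained sample so the posterior mean of the ratio — not the
ratio of posterior means — is reported. At variance components
(0.037, 0.496, 1) the closed form gives 0.0966.

## Relationship matrices

* `A` by the tabular method, inbreeding included; `A^-1` by Henderson's
  rules with Meuwissen–Luo inbreeding coefficients, stored sparse.
* `G = Z D Z'` with `z_ij = g_ij - 2 p_j` (0/1/2 coding centred at the
  allele frequency) and first-round weights
  `D_ii = 1 / (m * 2 p_i (1 - p_i))`, the inverse expected marker
  variance. This normalization keeps `sum_i d_i 2 p_i (1 - p_i) = 1`
  (enforced at 1e-10 on every weight vector) and `mean(diag G)` near 1 for
  an outbred genotyped set.
* Allele frequencies default to the analyzed genotyped set; a frequency
  override is accepted (`--freq-file`). Note that sample-frequency
  centering makes every column of `Z` sum to zero, so unblended `G` always
  has the all-ones null vector — one reason blending is on by default.
* `G* = (1 - alpha) G + alpha A22` with `alpha = 0.05`, the customary
  positive-definiteness repair; configurable. No extra scaling of the
  `G*^-1 - A22^-1` correction block is applied (tau = omega = 1).

## Gibbs sampler

Per sweep: (1) latent liabilities from unit-variance truncated normals
(inverse-CDF, vectorized); (2) one joint draw of `(beta, h, s)` from the
Gaussian full conditional `N(C^-1 W' lambda, C^-1)` via a dense Cholesky
of the MME coefficient matrix `C` — exact blocking, no single-site
sweeps; (3) variances from scaled-inverse-chi-square full conditionals
using `h'h` and `s' H^-1 s`. Default priors are flat on `beta` and
scaled-inverse-chi-square with `nu = -2, S2 = 0` (flat on the variance)
for both variance components; the hyperparameters are exposed because the
flat prior misbehaves when a factor has only a handful of levels (the
posterior chi-square needs more than 2 degrees of freedom, and with few
levels occasional enormous variance draws make the MME numerically
singular — unit tests on toy data therefore pass weakly proper priors).

Run length defaults to 120,000 sweeps, 20,000 burn-in, thinning 10.
Summaries report posterior mean, SD, shortest 95% HPD interval, effective
sample size (arviz) and a Geweke z-score.

The sampler has two testing hooks that do not alter the default path:
an observed-liability (Gaussian) mode, which reduces the model to a
linear mixed model whose posterior means must match the direct MME
solution, and fixed-variance mode.

## SNP effects and windows

Marker effects are back-solved as `u = D Z' G*^-1 a_g`, where `a_g` are
the posterior means of the genotyped sires' effects (a configurable scale
factor, e.g. x2 for transmitting ability to EBV, is exposed; all variance
*shares* are invariant to it). Re-weighting replaces expected marker
contributions with realized variances: `d_i` proportional to `u_i^2`,
floored at 1e-8 times the mean squared effect (so markers shrunk to ~0
cannot make the re-weighted `G` singular), then rescaled to the
normalization above so `G` keeps its scale across rounds. Four rounds are
run by default with `a_g` held fixed; a full re-fit per round is possible
by re-running the pipeline on the updated weights but is not the default
path. Window variance is the sum of `2 p_i (1 - p_i) u_i^2` over blocks
of 10 adjacent SNPs tiled per chromosome (final partial block kept),
normalized genome-wide to sum to 1; an overlapping step-1 sliding mode
exists behind a flag for comparison but the tiled mode is the default and
the one whose shares are normalized. Top windows are ranked by share with
ties broken by (chromosome, start bp).

## Synthetic data generator

The generator emulates a progeny-test structure: founder sires, each line
continued by one son per generation, with `daughters_per_sire` recorded
daughters per sire per generation, every daughter out of a unique founder
dam. Defaults: 150 founder sires, 2 generations, 10 daughters/sire,
29 chromosomes x 100 SNPs, 1 Morgan per chromosome, sire variance 0.037,
herd-year variance 0.496, residual 1, incidence 10.91% — the data shape
and variance structure of a first-lactation clinical-mastitis evaluation,
scaled down in animal and marker counts so that a full run is interactive.

Choices worth noting:

* **Recombination.** Gametes follow a two-state Markov switch along each
  chromosome with Haldane interval probabilities
  `r = (1 - exp(-2d)) / 2`; under no interference this is exactly the
  Poisson-crossover process observed at the marker loci, and it vectorizes
  over whole cohorts.
* **Breeding values.** A QTL part (markers sampled from the panel, effects
  scaled so their expected Hardy–Weinberg variance is
  `qtl_variance_fraction * 4 sigma2_s`) plus a pedigree-transmitted
  polygenic remainder. The sire effect entering a daughter's liability is
  half her sire's breeding value; the daughter's own Mendelian deviation
  is part of the unit residual, as the sire model assumes.
* **Exact-moment standardization.** Herd-year effects, year-season effects
  and founder polygenic values are rescaled to exact sample mean 0 and
  sample variance sigma2. Without this, the finite number of herd-year
  levels adds level-sampling noise that would make the realized incidence
  and variances artifacts of the draw rather than parameters; with it, the
  analytic threshold `t = Phi^-1(1 - incidence) * sqrt(sigma2_ys +
  sigma2_h + sigma2_s + 1)` reproduces the configured incidence to
  binomial accuracy (single-level factors contribute no variance and are
  excluded from the marginal).
* **What is not emulated.** Real-chip LD patterns and allele-frequency
  spectra, selection and assortative mating, non-random herd assignment,
  and informative missingness (only uniform dropout is available to
  exercise QC). Passing tests therefore validate the estimation machinery
  under the model's own assumptions, not robustness to violations of them.

## Problem sizes used in the checks

The recovery study uses 3,000 daughters of 300 unrelated sires
(30 herd-years, 4 year-seasons) with 12,000 sweeps / 2,000 burn-in / thin
10 per replicate, 20 replicates — sizes at which a full suite run stays
interactive while the 95% HPD coverage of the true variance components is
still a sharp test. Incidence calibration uses 200,000 records (5,000
sires x 40 daughters, 3,000 herd-years, 58 year-seasons). The
re-weighting enrichment study uses 500 genotyped sires x 1,000 linked
SNPs with one 10-SNP window carrying 20% of the genic variance and
breeding values observed with 80% reliability.

## Known limitations

* Dense Cholesky of the MME per sweep bounds the practical sire-pedigree
  size to a few thousand; a sparse-factorization update path would be the
  natural extension.
* `a_g` is taken from a single converged chain; re-weighting rounds do not
  propagate posterior uncertainty in `a_g`.
* Window variance is the additive per-SNP sum; no LD-aware `var(Z_w u_w)`
  variant, and no significance testing of windows — shares are descriptive.
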