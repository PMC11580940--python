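# Methods

## Rate decomposition and standardization

The per-generation germline mutation rate is modeled as the sum of an
embryonic load μ_E (mutations/site/generation, fixed per conception) and a
post-puberty gamete accrual at rate μ_gam = μ_O + μ_S (mutations/site/year),
so that at parental ages (A_P, A_M) the expected rate is
μ_E + (A_P − P)·μ_S + (A_M − P)·μ_O with P the age of puberty. Individual
studies rarely resolve μ_O from μ_S; everything downstream uses their sum.

Published studies report the parental-age effect in four shapes, each with
its own standardizer:

* **Sex-specific slopes/intercepts** (`standardize_sex_specific`). μ_gam is
  the summed slopes; μ_E is the summed intercepts advanced from each
  intercept's reference age to puberty along its own slope:
  μ_E = [m_i + p_i + (P − a_m)·m_s + (P − a_p)·p_s] / D. Counts reported per
  diploid genome are divided by D = 2A (A = accessible haploid size); per-site
  inputs use D = 1. Confidence bounds, when the source provides bound values
  for its parameters, are propagated by re-applying the same formula to the
  bound values — deliberately not a delta method, because the source CIs are
  themselves regression bounds of unknown correlation structure.
* **Combined per-site slope + intercept** (`standardize_slope_intercept`),
  with an optional `intercept_offset_years` adding years of gamete accrual
  when the reported intercept predates the study's definition of puberty.
* **Rate at puberty + mean rate over a span** (`standardize_mean_rate`):
  μ_gam = (mean − at_puberty) / (mean_reproductive_age − P).
* **Trio tables** (`TrioRegressionModel`): OLS of per-trio rate
  (count / callable diploid sites) on mean parental age; slope = μ_gam,
  μ_E = intercept + P·slope, with t-based CIs from the coefficient
  covariance. OLS on rates is the simplest faithful model of a published
  "regression of mutation rate against parental age"; the Poisson count
  noise makes residuals mildly heteroskedastic, which measured joint CI
  coverage at ~94% rather than the nominal ~95% in simulation — adequate for
  the recovery guarantees stated in the tests.

Eight study specs ship with the package. Two caveats are embedded in the
fixtures themselves: the chimpanzee paternal slope is treated as per diploid
genome (the source's "per site" wording contradicts its own arithmetic), and
the olive baboon's published summary rates (5.0×10⁻⁹, 1.4×10⁻¹⁰) are not
exactly reproducible from its published inputs — our general reference-age
formula gives 5.10×10⁻⁹ and 1.55×10⁻¹⁰ — so the baboon is treated as
approximate and excluded from exact-agreement checks. The mouse entry stores
the published decomposition directly (with its CIs) because the underlying
per-offspring data are not redistributable; the trio-regression code path is
exercised on simulated pedigrees instead.

The per-generation total is μ = μ_E + (g − P)·μ_gam: gamete mutations accrue
only over the g − P post-puberty years. This reproduces all eight published
per-generation totals at printed precision.

## Clock models

Fixed-rate model: u(g) = μ_E + g·(1 − p)·μ_gam with p = P/g held at the
cross-species constant 0.42 (see below). Relaxed clock:
u(g) = μ_E(1)·g^α + (1 − p)·μ_gam(1)·g^(β+1), with α, β estimated by
unweighted OLS of log μ_E and log μ_gam on log g (natural logs; slopes are
base-invariant and intercepts are exponentiated back). Log-log regression is
used because generation times and rate estimates are closer to lognormal
than normal across species. Species with non-positive rates are excluded
with a logged warning; fewer than three usable species is an error. p is a
configuration parameter, never refit inside the clock fit. Fitting is
unweighted: per-species estimate precisions are not comparable across the
heterogeneous source studies.

The puberty fraction is estimated by a through-origin regression of age at
first reproduction on generation time (`PubertyFractionModel`), reporting
the slope and the Pearson correlation of the pairs.

## Phylogenetic regression

`brownian_vcv` builds the Brownian covariance of tip traits (entry (i,j) =
root-to-MRCA path length) by a single postorder traversal. Pagel's λ scales
the off-diagonal entries only. GLS solves the generalized normal equations
through a Cholesky whitening; the reported log-likelihood is the profile
Gaussian ML value (σ² profiled out), and coefficient covariance uses the
degrees-of-freedom-corrected residual variance. `PGLSModel` profiles the
likelihood over λ on a 21-point grid on [0, 1] and refines the best cell
with bounded 1-D minimization (xatol 10⁻⁶); the grid pass guards against
flat or multimodal profiles on small trees. ML rather than REML is used.
The model carries no within-species measurement-error term. Tip names are
matched by exact string after whitespace trimming.

Degenerate inputs: an exactly singular covariance (e.g. duplicated tips with
perfect shared history) fails at the Cholesky factorization; a design with
zero predictor spread is rejected before factorization. Near-singular
covariances at λ ≈ 1 on trees with very short sister branches are solved as
given — the whitened system remains well-posed even when individual entries
are nearly collinear.

## Selection theory and Wright–Fisher verification

Costs are normalized to negative selection coefficients in both mutator
modes so magnitudes compare directly with the drift barrier 1/(2N_e):
S = −2uLE[s] for a per-generation mutator (u per site, L the diploid genome
length, so uL is the per-genome load per generation) and
S = −k·g·(1 − p)·E[s] for a clocklike mutator (k per year). An alternative
reading in which u is already a per-genome load (cost −uE[s], threshold
1/(2N_e·E[s])) is exposed via the `per_genome_u` flag; the two readings
coexist in the theory literature and neither is treated as uniquely correct.
The factor 2 in the per-site form is implemented as stated in the source
theory. Thresholds are the effect sizes at which |S| = 1/(2N_e) exactly:
u* = 1/(4N_e·L·E[s]) and k* = 1/(2·gN_e·(1 − p)·E[s]) — the clocklike
barrier depends on N_e and g only through the product gN_e. N_e is estimated
from diversity as π/(4μ), and its allometry is modeled as N_e = C·g^γ, so
gN_e = C·g^(1+γ) increases with g whenever γ > −1.

The Wright–Fisher simulator is diploid with genic (additive) selection:
genotype fitnesses 1, 1 + S/2, 1 + S, deterministic update
p* = p(1 + S/2 + pS/2)/(1 + pS), binomial resampling of 2N copies, one
initial copy. The matching diffusion prediction is
P_fix(1/(2N)) = (1 − e^(−S))/(1 − e^(−2NS)), the standard Kimura result for
a per-copy coefficient S/2; simulator and formula are verified against each
other in the tests (the simulator is the implementation, the closed form the
oracle). Trajectories still segregating after 100·2N generations are counted
as losses and logged; at the parameter ranges exercised this cap is never
reached in practice. The Monte Carlo standard error uses a floor of
√(1/reps²) so that zero-fixation outcomes under strong selection still carry
a usable uncertainty.

## Synthetic data

The generators emulate the study conditions the fitted quantities were
derived under:

* **Trios**: parental ages uniform on a configured range above puberty;
  expected count = sites·[μ_E + (mean age − P)·μ_gam] (the gamete rate split
  equally between parents, since only the sum is identifiable); counts are
  Poisson. Defaults used in the recovery studies are human-like: 200 trios,
  ages 15–45 y, P = 13 y, 5.4×10⁹ callable diploid sites, truth
  μ_E = 5×10⁻⁹, μ_gam = 5×10⁻¹⁰. A gamma-mixture overdispersion switch
  exists but defaults to off (pure Poisson).
* **Species panels**: g log-uniform on [0.5, 40] y; rates follow the
  relaxed-clock power laws times lognormal noise (sd 0.3 on the log scale by
  default); the log-noise is drawn from a λ-scaled Brownian motion on a
  supplied tree, with `lambda_signal` interpolating between independent
  (0) and fully phylogenetic (1) noise; the correlation matrix is normalized
  to unit diagonal so marginal noise variance is λ-independent. π = 4·N_e·μ
  holds exactly with N_e = C·g^γ (defaults C = 10⁵, γ = −0.487), so Ne
  recovery from diversity is an exact construction identity, and the
  γ-recovery checks are exact when no noise is placed on N_e itself.
* **Puberty tables**: g log-uniform on [2, 52] y, P = 0.42·g times mean-one
  lognormal noise with log-sd 0.36. The sd was derived in closed form so the
  induced Pearson correlation between P and g is ≈ 0.87 at n = 230
  (r = 13.37/√(414.4t − 235.6) with t = e^(σ²), from the moments of the
  log-uniform g); mean-one (rather than median-one) noise keeps the
  through-origin slope estimator unbiased.
* **Trees**: Yule (pure-birth) trees via dendropy, rescaled to unit
  root-to-tip depth, tips labeled sp001…; byte-identical newick per seed.

What the generators do *not* emulate: mutation spectra or genomic placement,
per-species differences in callable regions, correlated parental ages,
measurement error on published generation times, or selection of species
into the literature. Passing recovery tests therefore demonstrates that the
estimators are correct and calibrated under the stated noise models, not
that any particular biological dataset satisfies those models.

## Problem sizes and numerical choices

Simulation studies use 50-species panels, 200-trio pedigrees (300 replicate
seeds for coverage estimates), 230-pair puberty tables, 20 replicate
50-tip trees for λ recovery, and 5×10⁴ Wright–Fisher replicates at
N = 100–1000 — sizes at which every Monte Carlo check has small error
relative to its acceptance margin while the full suite runs in seconds.
Statistical checks against a truth use 2-SE or 3-MC-SE bands; exact
arithmetic is checked to 10⁻⁹–10⁻¹² relative. Where a single-seed 2-SE
check would fail for ~5% of seeds even under perfect calibration, the tests
aggregate over a contiguous block of seeds at the same per-fit tolerance.

## Known limitations

* Only the sum μ_O + μ_S is modeled; sex-specific gamete rates are out of
  scope.
* The relaxed-clock fit treats the eight standardized decompositions as
  exchangeable points; no weighting by study precision, no phylogenetic
  correction (Pagel's λ estimated on this small panel is 0).
* PGLS is univariate with a single predictor; no OU/κ/δ transforms.
* The drift-barrier theory uses a scalar E[s]; distributions of fitness
  effects, linkage, and mutator hitchhiking are not modeled.
* Model comparison between fixed and relaxed clocks is by curve evaluation,
  not formal model selection.
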