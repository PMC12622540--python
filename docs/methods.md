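# Methods

`plastmap` analyses the trade-off between the mean and the plasticity of a
quantitative trait scored on a diversity panel across several environments
(the motivating system is grain chalkiness in a rice mini-core collection
grown over five site-years). This note documents the models, the defaults
and why they were chosen, what the synthetic generator does and does not
emulate, and the numerical conventions.

## Reaction-norm model

The core decomposition is the genotype-specific Finlay–Wilkinson regression

    y_ij = mu + g_i + (1 + b_i) · h_j + eps_ij,

with accession main effect `g_i` (the *phenotypic mean* sub-phenotype),
environment effect `h_j` (sum constrained to zero), slope `1 + b_i`
(*linear plasticity*, mean slope constrained to 1), and residual
`eps_ij ~ N(0, sigma²_i)` with accession-specific variance. The natural
log of the accession's residual variance is the *nonlinear plasticity*:
departure from a straight-line environmental response. Accessions with
fewer than three observed environments have no defined residual variance
and carry NaN there; accessions observed once (or whose environments all
share one `h` value) get NaN slopes and are listed in `flagged` rather
than dropped silently.

Two estimators:

- **Least squares** (`fit_fw_ls`): `h_j` is the environment mean minus the
  grand mean; each accession is then an ordinary regression of `y_ij` on
  `h_j`. Exact on interpolable data, idempotent on its own fitted values.
- **Gibbs sampler** (`fit_fw_gibbs`): the Bayesian model with independent
  (identity-covariance) normal priors on `g`, `b` and `h` — no kinship or
  pedigree in the priors. The multiplicative `(1 + b_i)·h_j` term has a
  soft scale ridge (inflate the slopes, deflate `h`) that vague priors
  cannot pin down on small tables, so the inverse-gamma variance priors
  are anchored empirically: effect-variance rates at the LS-fit variances
  (shape 2), residual-variance rate at the pooled LS residual variance
  (which is zero for interpolable data, concentrating the posterior on
  the exact solution). Posterior means are reported, with a split-chain
  scale-reduction diagnostic on the residual variance; `R-hat > 1.1`
  records a convergence warning in the output.

Dispersion summaries: `CV = sd/mean × 100` with the sample (n−1) standard
deviation, and the quartile coefficient of dispersion
`QCD = (Q3−Q1)/(Q3+Q1)` with linear-interpolation quantiles. Both are
invariant under positive rescaling; CV is translation-sensitive by design.

## Variance components and heritability

`fit_gxe_variance_components` fits

    y ~ mu + (1|Line) + (1|Env) + (1|Line:Env) + e

by EM-REML on Henderson's mixed-model equations (variance floor at 1e-8 of
the phenotype variance, Aitken-accelerated updates kept only when they
raise the REML log-likelihood, convergence at 1e-8 relative change, max
5000 sweeps). On balanced complete designs EM is seeded at the closed-form
ANOVA (expected-mean-squares) estimates, which are the REML optimum when
interior, so the fixed-point agreement with `anova_moments` is a genuine
property of the update formulas.

With one observation per Line×Env cell the interaction and residual
variances are not separately identifiable; the model then drops the
explicit interaction term and reports the residual as `VGE` with `Ve = 0`
and `confounded=True`. A likelihood-ratio test of `Line:Env` on such data
raises rather than reporting an arbitrary split.

Random terms are tested by REML LRT against the boundary-corrected null:
a 50:50 mixture of a point mass at zero and chi-square(1) (plain
chi-square(1) behind `boundary_mixture=False`).

Broad-sense heritability is

    H² = Vg / (Vg + VE + VGE/m + Ve/(n·m)),

with `m` environments and `n` individuals. The printed residual term is
typographically ambiguous between `Ve/(n·m)` and `(Ve/n)·m`; the default
reading divides by `n·m` — the only one under which the contribution of
measurement error shrinks as data accumulate — with the other reading
available via `ve_reading="n_times_m"`. Including `VE` in the denominator
is unusual for line-mean heritability but is implemented as stated.

BLUPs of the Line effects solve the mixed-model equations at the supplied
variance components; on balanced single-factor data they reduce to the
textbook shrinkage `Vg/(Vg + s²/m) · (accession mean − grand mean)`.

## Association scans

`lmm_scan` is the standard two-stage approximation used by the fast LMM
family: eigendecompose the kinship `K`, estimate the residual-to-genetic
variance ratio `delta` once by null-model REML (grid plus Brent on
log-delta), then test each SNP by weighted least squares in the rotated
basis with a Wald t-test (df = n − covariates − 2). `exact_delta=True`
re-profiles delta per SNP. With `K = I` the procedure reduces exactly to
ordinary regression. Kinship is the standardized genotype cross-product
(each SNP scaled to unit variance; `method="centered"` gives the
VanRaden-style numerator matrix); missing dosages are mean-imputed per
SNP before kinship and testing. Power analyses use leave-one-chromosome-
out kinship, since a GRM containing the causal SNP's own LD block absorbs
part of its signal (proximal contamination).

The genome-wide threshold is `alpha / n_indep` where `n_indep` counts
SNPs surviving greedy windowed pairwise-r² pruning (window in kb, step in
SNPs, r² cutoff; within a violating pair the lower-MAF SNP is removed,
ties dropping the later position). With the published inputs — 36,508
independent SNPs at alpha = 0.05 — this reproduces the 1.37e-6 threshold.

Per-SNP variance explained uses the standardized form

    PVE = [2f(1−f)β²] / [2f(1−f)β² + 2f(1−f)N·se²] = β² / (β² + N·se²),

with `N = N_total − N_missing`. Both forms are implemented and agree to
machine precision.

Population differentiation uses the Weir–Cockerham (1984) two-deme
estimator with the full heterozygosity correction; fixed differences give
exactly 1, and slightly negative estimates are reported as computed.

## QTL atlas

Significant SNPs are clustered into QTL when within `merge_kb` (default
200 kb) of each other; a cluster spans its min/max SNP positions padded by
`merge_kb/2` per side (a lone SNP becomes a closed interval of exactly
2·pad bp). The peak-to-interval rule is configuration because published
hotspot counts depend on it. Overlapping QTL across scans condense into
hotspot H-QTL as connected components of the interval-overlap graph
(closed intervals, ≥1 bp, chained transitively; `pairwise=True` restricts
membership to QTL overlapping every current member). Hotspots need ≥2
members; more than 3 sets the key flag. Candidate genes are genes whose
span intersects a 20-kb window centred on any significant SNP (closed-
interval intersection, so a gene ending exactly on the window edge
counts). Haplotype groups (exact dosage strings over a SNP set, minimum
group size 10) are compared by one-way ANOVA with Tukey–Kramer adjusted
pairwise contrasts; effect-sign profiles flag SNPs as antagonistic
(opposite mean/plasticity effect signs beyond an epsilon of 1e-6),
concordant, or neutral.

## Environment models

DIFF scores are signed per-accession differences, reference environment
minus comparison (bounded in [−100, 100] for percent traits). The
per-genotype environment-response regression fits each accession's
phenotypes on an environmental index (any temperature column or derived
covariate); a zero-variance response gets slope 0 and, by convention,
R² = 0; the mean per-accession R² summarises the index's contribution to
plasticity. Temperature correlations are Pearson across environments
(≥3 required). The bootstrap resamples with replacement at the original
size, deterministically under a named substream of the seed. The
grain-width pleiotropy regression reports the simple-model R² as percent
PVE.

## Marker selection

LASSO (scikit-learn coordinate descent) on internally standardized
dosages, penalty chosen at the minimum mean cross-validated error over a
100-point path down to `lambda_max/100` (the glmnet small-sample path),
with seeded fold assignment; the 1-SE rule is available behind a flag.
SNP pairs with r² > 0.95 are pre-filtered, keeping the higher-MAF member.
Backward stepwise elimination accepts a drop only when
`AIC = n·ln(RSS/n) + 2k` decreases (k counts all coefficients including
the intercept), so the final AIC never exceeds the starting one. Model
PVE is the in-sample R² × 100 of the unpenalized refit on the selected
SNPs (the cross-validated error used for the penalty choice is a
selection criterion, not the reported PVE). Combined models refit on the
union of mean-effect and plasticity-effect panels against raw phenotypes
or multi-environment BLUPs.

## Synthetic data

The generator produces the study conditions at desk scale: by default 500
accessions × 2000 SNPs × 5 environments, one chalkiness-like percent
trait with grand mean 32, environment effects of SD 8 correlated 0.9 with
grain-filling mean temperature, accession main-effect variance ≈190
(30% from five planted QTL, the rest polygenic), slope variance 0.15
(30% from five planted plasticity QTL), and accession-specific residual
variances lognormal around 4. These defaults put broad-sense heritability
near 0.7 (the 0.64–0.85 regime) and make temperature–trait correlations,
temperature–CV anti-correlations and the environment-index regression
meaningful on synthetic data. Genotypes come from a latent Gaussian
copula thresholded to Hardy–Weinberg dosages — equicorrelated blocks give
a closed-form LD target — with optional Balding–Nichols two-subpopulation
differentiation (per-SNP Fst centred on the divergence parameter) and a
configurable missing-call rate. Environment effects are rescaled to the
configured SD exactly, so the environment variance is a set condition
rather than a chi-square draw; identifiability conventions (Σh = 0,
mean b = 0, centred g) are imposed at generation so recovery tests are
well-posed. All draws come from named substreams of one master seed, so
each stage is independently reproducible.

The recorded truth (`vc_true`) stores the *realised* (ddof-1) variances
of the drawn effects rather than the generative values: with five
environment levels the generative environment variance carries ~70%
sampling error that no estimator can beat, so realised variances are the
estimable targets that recovery tests should (and do) use.

What the generator does not emulate: real LD decay (block-equicorrelation
only), selection or demography beyond Balding–Nichols, trait skewness
and zero-inflation of real chalkiness distributions, spatial field
effects, and year-to-year covariate structure beyond the single
temperature coupling. Percent traits are generated on the unbounded model
scale and optionally clipped to [0, 100] (fraction logged). Clipping
censors low-mean accessions and corrupts their slope estimates, so
parameter-recovery fixtures disable it — recovery is only well-posed
under the exact generating model — and passing recovery tests therefore
certify estimator correctness, not robustness to boundary censoring in
real percent data.

## Problem sizes and tolerances

Tests and the acceptance script run at desk scale: recovery fixtures of
300 accessions × 6 environments; null-calibration scans of 5000 SNPs at
n = 300; power and marker-selection replicates of 20 seeds at n = 400–500.
EM-REML converges at 1e-8 relative log-likelihood change; the Gibbs
sampler defaults to 2000 iterations with 500 burn-in; LASSO paths use 100
penalties to `lambda_max/100`. Degenerate inputs (single environment,
constant phenotype or index, monomorphic SNP sets, zero-mean CV inputs)
raise informative errors rather than returning silent NaNs.
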