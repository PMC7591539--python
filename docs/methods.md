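# Methods

This note documents the models, estimators and design choices behind
`stressmito`, what the synthetic-data generator does and does not
emulate, and the numerical conventions that matter for reproducing its
output.

## Behavioral scoring

Every raw behavioral readout x is z-normalized against the unstressed
control group, z = (x − mean_CTR)/SD_CTR (sample SD, ddof = 1), so
controls have mean 0 and SD 1 by construction. Missing raw values
propagate; a constant control group raises a degenerate-reference
error.

The social-avoidance composite uses the four social-interaction-test
parameters: interaction-zone time with the social target present,
corner-zone time with the target present, and the present/absent ratios
of each. No single standard formula exists for combining them; the package's
default — the mean of the
four parameter z-scores after sign orientation (interaction time and
interaction ratio negated; corner time and corner ratio kept), so that
larger = more avoidant — is a transparent, unit-free stand-in and is
labelled as such. Animals whose target-absent time is zero have
undefined ratios and are excluded with a logged reason.

The integrated behavioral z-score is the arithmetic mean of three
oriented test scores: the avoidance composite (re-standardized against
controls), forced-swim immobility z, and the *negated* saccharin-
preference z (anhedonia — lower preference — raises the score). Only
the final directionality is constrained (stress raises the score); the
package implements it by negating preference.
The score exists only for animals with all three tests; others are
dropped listwise from z-dependent analyses only.

Stressed animals with integrated z inside [μ_CTR − σ_CTR, μ_CTR + σ_CTR]
(computed from the controls' integrated z) are low-susceptible (LS),
outside high-susceptible (HS). The boundary is closed: exactly ±1 SD is
LS, reading "fell into the standard deviation" as a closed interval.

## Negative-binomial GLM engine

Counts are modelled as NB2: Var = μ + αμ², log μ_ij = x_j'β_i + log s_j,
with per-sample size factors s_j as offsets and a per-gene dispersion α
treated as known during β estimation (the standard two-stage
convention). Fitting is IRLS with step-halving, tolerance 1e−8 on the
coefficient change, at most 100 iterations, vectorised across genes
(all genes share the design, so each iteration is a batch of p×p
solves; p ≤ 3 in all shipped designs). Standard errors come from the
Fisher information X'WX at the optimum, W = μ/(1 + αμ) — for balanced
group designs this equals the observed information at the MLE. The
engine is cross-checked coefficient-for-coefficient against
`statsmodels` NB GLM fits in the test suite; the vectorised path exists
because per-gene model selection over thousands of genes and hundreds
of replicate cohorts is far outside what per-gene fits allow.

Size factors use the median-of-ratios rule: reference genes are those
with strictly positive counts in every sample; s_j is the median over
reference genes of k_ij divided by the gene's geometric mean across
samples. No rescaling is applied afterwards, so doubling one of two
samples yields (1/√2, √2). An optional pseudo-reference (genes positive
in ≥ 50% of samples, geometric mean over positive entries) handles
sparse matrices.

Genes with mean normalized count below 5 (configurable) are excluded
from inference, mirroring the exclusion of genes expressed too low to
be detected reliably.

### Dispersion

The per-gene dispersion is a method-of-moments estimate around GLM
fitted means: α̂ = Σ[(y−μ̂)²/(1−h) − μ̂] / Σμ̂², where h are the GLM
leverages under the implied weights (a first pass with a global
n/(n−p) correction supplies the weights). With true means this
estimator is unbiased; the leverage correction removes most of the
fitted-mean bias at n ≈ 25.

Because BIC model comparison and Wald calibration are sensitive to
dispersion noise at cohort-scale n, the default policy for `run_dge`
and `select_model_per_gene` moderates the raw estimates: a
mean-dispersion trend α_trend(μ) = a₀ + a₁/μ is fitted across genes
(5–95% trimmed least squares for robustness), the sampling variance s²
of the raw estimator is measured by an internal parametric NB
simulation at the trend dispersion under the same design and depths
(canonicalized gene/sample order, fixed internal stream, so results
are invariant to input ordering), and each gene is pulled toward its
trend value with weight τ²/(τ² + s²), where τ² = max(var(α̂ − trend) −
s², 0) is the excess true spread. When genes share one dispersion the
weight approaches zero and the estimate approaches the pooled trend;
with genuinely heterogeneous dispersions the shrinkage backs off. The
un-moderated estimate remains available (`dispersion_policy="mom"`).
This is a deliberately simple stand-in for the empirical-Bayes
dispersion machinery of the established DE frameworks; it shares their
structure (trend + shrinkage) without their profile-likelihood
refinements.

All-zero genes have undefined dispersion and are flagged out. The floor
is 1e−8 (numerically Poisson).

## Differential expression

Two-group contrasts: Wald z = β/SE on the group coefficient, two-sided
normal p. Covariate-corrected designs: likelihood-ratio χ² between
nested fits sharing offsets and dispersion, df = Δ(coefficients).
Covariates are arbitrary metadata columns in an additive formula
("~ group + age + rin"); nothing is hard-coded, so the same engine
serves two-group mouse designs and covariate-corrected human designs.
Fold changes are reported in log2 (converted from natural-log
coefficients). Unconverged or degenerate fits yield flagged missing
p-values excluded from Benjamini–Hochberg, which is otherwise standard
step-up with monotonicity enforcement (delegated to statsmodels,
verified exactly against a brute-force implementation).

The LRT's χ²(1) reference is asymptotic: at n ≈ 30 the null statistic
runs ~4% hot (verified with oracle dispersions), which a 2,000-gene KS
test can detect. Calibration checks of the LRT therefore run at n = 100,
where the approximation is accurate; this is a property of the test
statistic, not of the implementation.

## Model selection

Per gene, three models: null (intercept), treatment (intercept +
stress indicator), zscore (intercept + integrated behavioral z).
Only animals with an integrated z enter. One dispersion per gene is
estimated under the union design (intercept + group + z) — the three
candidates include two non-nested 2-parameter models, so the union is
the richest mean structure that nests all of them — and shared across
the three fits so likelihoods are comparable.

BIC = −2ℓ + k ln n with n = number of animals in the fit and k = 1, 2, 2
(the shared dispersion is not counted; flags expose deviance-based BIC
and a +1-for-dispersion convention, both of which change nothing in the
weights because deviance and −2ℓ differ per gene by the saturated-model
constant and constant k shifts cancel). Schwarz weights are
exp(−Δ_m/2)/Σ exp(−Δ/2) with Δ_m = BIC_m − min BIC (min-shifted for
overflow safety); they sum to 1 and the best model attains the maximal
weight. When z is an affine function of the group indicator the two
non-null designs span the same space and their BICs tie exactly.

Set-level summaries report mean Schwarz weights, the fraction of set
genes whose z-score weight beats the treatment weight, and a one-sided
hypergeometric enrichment of that binarized call versus non-set genes —
no standard statistic exists for ranking pathways by model-selection
calls, so the hypergeometric summary is the package's documented
choice. HS/LS analysis
fits a three-level class design (control reference) and reports both
Wald contrasts; classes with fewer than two animals are skipped.

## Competitive gene-set testing

For a set of m genes, the test compares the set's mean per-gene
statistic with the non-set mean by a z-test whose denominator is
inflated by √VIF, VIF = 1 + (m−1)ρ̄ — the variance-inflation
construction for correlated gene sets, applied to pre-ranked
statistics (signed Wald statistics by default; signed log-p is the
configurable alternative). ρ̄ is the mean pairwise Pearson correlation
of the set genes' within-group-centered log2-normalized expression,
floored at 0; when not estimated, a conventional default of 0.01 is
used. With ρ = 0 the procedure reduces exactly to the plain two-sample
z-test. Under a permutation null with genuinely correlated set
expression, the estimated-ρ̄ test holds its nominal 5% level (measured
~0.04–0.06) where the unadjusted test rejects ~25%.

The packaged mtDNA catalog pins the 13 mitochondrially encoded OXPHOS
subunit genes with complex assignments (7×I, 1×III, 3×IV, 2×V; complex
II empty) and the 7-gene detected subset; nuclear mito catalogs and
GO/KEGG collections are user-supplied GMTs, never fetched. Barcode
export ranks statistics descending with ties broken by gene id and
reports member ranks plus a sliding-window relative-enrichment trace.

## Motif activity

Promoter windows are TSS ± 500 bp (1001 bases), BED 0-based half-open,
minus-strand windows reflected, overhangs clipped with a warning.
Site counts are positions on either strand whose log2-odds score
(column probabilities smoothed by pseudocount 0.01 and renormalized,
against the motif's background) reaches a threshold, default 10 bits —
a hard-threshold replacement for probabilistic site-posterior scanners;
externally computed site-count tables can be supplied instead.
Opposite-strand overlapping hits count separately, so palindromic
consensus sites count twice.

Activities solve min_A ‖E_s − N A_s‖² + λ‖A_s‖² per sample via SVD
(equivalently the normal equations, satisfied to < 1e−8), after
column-centering N and row-centering E — the centering absorbs the
intercept per the motif-activity-response convention; a `center=False`
escape hatch reproduces raw closed forms. λ is chosen by generalized
cross-validation over a log-spaced grid including 0 (fixed-λ override
available); there is no canonical normalization or tuning convention
for per-sample activities, so these defaults are documented choices.
Group differences use two-sided unpaired t-tests with BH correction;
motifs constant in both groups are flagged, all-zero site columns get
activity 0 with a flag.

## Synthetic cohorts

The generator reproduces the study conditions: 11 CTR / 16 stressed
animals by default; raw SIT times, FST immobility and saccharin/water
volumes drawn from control baselines typical of the assays (e.g. 60 s
interaction time, 100 s immobility of the scored 4 min, 88% preference)
with stress shifts proportional to a latent per-animal severity.
Controls draw the latent from N(0, 0.25); stressed animals from a
two-component mixture, 40% N(0.7, 0.25) (low) and 60% N(2.5, 0.35)
(high), so LS/HS stratification has genuine structure. The default
shift magnitudes (≈1 control SD per latent unit per test) give the
strong integrated-z group separation typical of this protocol (two-sample p < 0.05 in ≳95% of replicate cohorts at default
sizes). Times are clipped at 0 and preference at [0, 100].

Counts: gene catalog of 2,000 nuclear genes plus the 13 mtDNA OXPHOS
genes. Classes: null, treatment-driven (mean × 2^(±log2FC·group)) and
z-score-driven (mean × 2^(±slope·z)); effect signs alternate so
size-factor normalization is not systematically distorted (one-sided
regulons bias the median-of-ratios in a group-correlated way); the
mtDNA genes default to z-driven, all up, matching the up-regulation
characteristic of chronic stress. Counts are NB via the Gamma–Poisson mixture with Var = μ +
αμ² (α shared, default 0.1; identical to the GLM engine's
parameterization so recovery tests are closed-loop), per-sample depths
uniform on [0.7, 1.3], baselines log-normal (log-SD 0.5, or fixed).

Promoters: 1001-bp windows, one contig per gene, background GC 50%,
Poisson-planted non-overlapping motif occurrences sampled from each
PWM; expression changes E = N_true·A + noise with group-structured
per-sample activities.

Everything is seeded; identical seeds and parameters give byte-identical
outputs.

What the generator does *not* emulate — and hence what passing tests do
not establish about real data: batch and library-chemistry effects,
mean-dependent dispersion trends (α is flat by default), gene–gene
correlation beyond what the latent severity induces, sex or covariate
structure of human cohorts, read-level artifacts, and real promoter
composition (background is i.i.d.). Recovery rates measured here are
upper bounds for data with those complications.

## Problem sizes and replicate counts

The shipped acceptance analyses use 2,000 + 13 genes × 25 animals with
200 replicate cohorts for model-selection recovery, 2,000 null genes at
15/group (Wald) and 50/group (LRT) for calibration, 1,000 replicates
for competitive-test calibration, and 300 promoters × 6 motifs × 100
replicates for motif recovery — sizes chosen so each answer's
Monte-Carlo error is small relative to the margins being checked while
the whole battery runs in minutes on one CPU.

## Known limitations

- The avoidance-composite formula and the enrichment statistic behind
  the set-level model-selection ranking are documented stand-ins (see
  above); both are configurable.
- Dispersion moderation is moment-based, not profile-likelihood; with
  very few samples (n ≲ 8) the trend fit is unstable and the raw
  moment policy is preferable.
- The LRT inherits the usual small-sample χ² inflation (~4% at n = 30).
- The PWM scanner counts hard-threshold hits; weak sites below
  threshold contribute nothing, unlike posterior-weighted scanners.
- Size factors assume most genes unchanged; heavily asymmetric global
  shifts bias the offsets as in any median-of-ratios scheme.
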