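# Methods

This note records the statistical models implemented in `leptomet`, the
assumptions behind them, the defaults and why they were chosen, what the
synthetic-data generator does and does not emulate, and the numerical
corner-case conventions. Everything quantitative stated here is computed by
the test suite or by `scripts/acceptance.py`; nothing is quoted from
elsewhere.

## Study setting and pre-processing

The target design is a paired intervention in a very small cohort: each of
n individuals (default 6) contributes one pre- and one post-treatment serum
sample, profiled on a semi-quantitative UPLC-MS/MS panel of several hundred
metabolites annotated into super-pathways and sub-pathways. Intensities are
positive, missingness is left-censoring at the detection limit.

Pre-processing (`dataio`): per-metabolite minimum imputation (half-minimum
available) of censored entries, then log10. Minimum imputation matches the
left-censoring mechanism — the unrecorded values are the smallest — but it
does shrink the variance of heavily censored metabolites; the null
calibration suite therefore runs on uncensored simulations so that it
measures the calibration of the tests themselves rather than the (known,
documented) imputation bias.

`adjust_covariates` residualizes nuisance covariates by per-metabolite
least squares (indicator contrasts for categoricals, grand mean re-added)
and refuses `condition`/`individual_id`. It is the right tool for
cross-sectional analyses such as the BMI score cohorts (hundreds of
samples). It is deliberately NOT used before the paired stage: with 12
samples and ~7 covariate parameters, residualization projects out roughly
half the sample space; individual-constant covariates span nearly the whole
between-individual space at n = 6, so the projection acts like
within-individual centering, which (a) inflates paired type I error
(measured: 0.09 at nominal 0.05) and (b) smears any condition-specific
latent structure into the other condition, erasing exactly the differential
correlation signal the module stage looks for.

## Paired differential analysis

The paired design collapses to within-individual differences
d_i = x_post − x_pre. Individual-constant covariates (sex, age, ethnicity)
cancel exactly in d and need no correction. Sample-level covariates do not:
run day differs between an individual's two samples, and a random
assignment can leave the run-day contrast partially aligned with the
condition contrast, creating spurious "effects" in some studies (observed
per-study null rates up to 0.14 when ignored). The difference regression
therefore includes the within-individual contrasts of the configured
sample-level covariates (default: run day):

    d_i = β0 + w_i' γ + ε_i ,   effect = β0 ,   df_g = n − rank([1 W])

Columns that difference to zero are dropped automatically, so the model
degrades gracefully to the one-sample t when run day is constant or
per-individual.

Variance moderation: s²_g is shrunk toward a scaled-inverse-chi-square
prior whose hyperparameters (d₀, s₀²) are estimated by matching the mean
and excess variance of log s²_g to the digamma/trigamma moments of the
scaled-F law; the trigamma equation is inverted by Newton iteration. If the
empirical spread of log s²_g does not exceed the sampling spread the prior
is a point mass (d₀ = ∞, normal reference). The degenerate case of exactly
equal variances returns that common value as s₀². With d₀ = 0 the pipeline
reproduces the textbook paired t-test to 1e-12 (oracle test).

Calibration, measured on pure-null simulated studies (m = 500, n = 6, four
studies → 2000 tests, no censoring): p < 0.05 rate 0.045–0.054 across seed
blocks, inside the exact binomial band around 0.05. Dual significance
tiers are reported: nominal p < 0.05 and BH FDR < 0.2 (the liberal
threshold appropriate to an n = 6 discovery study).

## Preranked enrichment

Classic running-sum enrichment on the t̃-ranked metabolome over sub-pathway
sets (min size 3 — metabolite sub-pathways are small). Weight exponent
defaults to 1; 0 is supported. Because ranking happens after the paired
collapse, sample permutation is not available; the null randomizes set
membership: ES of uniformly random same-size member sets of the fixed
ranking (default 1000 draws, seeded). NES divides ES by the mean |null ES|
of matching sign; p is the add-one-corrected same-sign exceedance; FDR q
compares the pooled null NES tail with the observed NES tail, capped at 1.
Ties in the ranking are broken by metabolite id for determinism. A set is
flagged when q < 0.2 and p < 0.05.

## Differential correlation modules

Goal: groups of metabolites whose mutual correlation across individuals
changes between conditions — the signature of a coordinated response whose
direction may differ between individuals. Per-condition correlation
matrices (Pearson default; Spearman available but at n = 6 the rank
transform discards too much of the signal) are soft-thresholded with signed
power β and differenced:

    D_ij = sqrt( 0.5 | sign(c_pre)|c_pre|^β − sign(c_post)|c_post|^β | )

D is a change adjacency: high where the pair's correlation changed. β
defaults to 10. The choice is driven by the null distribution of a
correlation coefficient at n = 6 per condition (SD ≈ 0.45, P(|r| > 0.7) ≈
0.12): a power this high maps the null tail to ≈ 0.7^10 ≈ 0.03 while a
genuine module correlation of ~0.97 keeps 0.74, and the planted-module
benchmark (below) confirms that lower powers (2–6) lose most of the
recovery rate.

Clustering: average linkage on the dissimilarity 1 − D. Candidate clusters
are read off the dendrogram at several relative cut heights (0.3–0.6 of the
merge-height range); a candidate survives if its mean within dissimilarity
is below 0.9× its mean dissimilarity to the rest; weakly connected members
(connectivity < 0.8× cluster median) are shed. Candidates are scored by
(between − within contrast) × √size — coherent AND substantial — and
resolved greedily into disjoint modules; accepted modules then recapture
stragglers whose mean change-adjacency to the module reaches 0.7× the
member median. Metabolites in no module form the explicit pseudo-module 0.
All knobs live in `DiffCoExParams`.

Sub-modules: sign of the leading eigenvector of the module's post-treatment
correlation matrix (post, not pooled: modules are detected for their
post-treatment coherence); an all-one-sign module is a single sub-module.
The larger sub-module is oriented +1.

Significance: dispersion statistic mean D²_ij over member pairs (computed
at β = 2 — at the discovery power 10 the statistic is dominated by a few
near-unit correlations and partial relabelings can overshoot the observed
value), null by flipping pre/post within individuals, exhaustive over the
63 non-identity flips at n ≤ 10, sampled otherwise. p counts ties. Two
structural facts about this null: every flip ties its complement, and the
all-individual flip always ties the observed statistic exactly (the
statistic is symmetric in the two conditions). Hence 32 exchangeable
levels, a p floor of 2/64, and an exact null level P(p < 0.05) = 1/32 —
the calibration test checks the rate against that discrete level, and that
it never exceeds the binomial band around 0.05. "Gain of correlation" is
reported as mean|c_post| − mean|c_pre| over member pairs.

Sub-module annotation: one-sided Fisher exact tests of each sub-pathway in
each sub-module against the discovery universe, BH across all
sub-module × sub-pathway tests.

## Lipid structure tests

The `(C:D)` token grammar covers the vendor naming convention; explicit
`chain_length`/`double_bonds` annotation columns take precedence. Length
classes: medium 6–12 carbons, long 13–21, very long ≥ 22; shorter chains
are labeled "short" and excluded from the three classes. Saturation:
0/1/≥2 double bonds. Association tests consume log10 effects (not raw
ratios) for up/down symmetry: Pearson chain-length correlation per length
class (Fisher-z CI), Kruskal–Wallis across saturation classes with tie
correction (all-identical inputs return H = 0, p = 1 by convention), and a
two-sided Fisher exact test of 12α-hydroxylation vs leading-edge presence
with conditional-MLE odds ratio and exact CI.

## BMI metabolomic score

Only the direction (±1) of the reference signature is used. Matching is by
normalized biochemical name with parentheticals KEPT (lipid names are
distinguished by their `(C:D)` token). Matched metabolites are z-scored
(ddof 1) across an explicitly supplied cohort — children and adults are
scored separately, cohort membership is never inferred — and summed with
their signs; zero-variance metabolites are dropped with a log message.
Associations: Pearson r, CI = tanh(atanh r ± 1.96/√(n−3)), two-sided p from
t(n−2); |r| = 1 short-circuits to a degenerate interval without overflow.

Of the five published worked-example intervals recomputed from the printed
(r, n) pairs, three reproduce exactly at two decimals and two differ in the
last digit of one bound — the pattern expected when the original intervals
were computed from unrounded r (e.g. r ≈ 0.825 reproduces the printed
(0.19, 0.97) where the rounded 0.82 gives 0.175). The acceptance tests
assert 0.01 tolerance on four intervals and 0.02 on the small-n fifth.

## Cross-study matching and concordance

Tier 1 exact name; tier 2 normalized name (lowercase, asterisks out,
parenthetical qualifiers out, punctuation collapsed), unique on both sides;
tier 3 normalized name + sub-pathway agreement. Many-to-many candidates are
left unmatched and logged — no fuzzy distance matching, because a silent
mismatch is worse than an unmatched metabolite at panel scale. Concordance
per sub-pathway: sign agreement over shared metabolites and Pearson r of
log10 fold changes (groups under 3 shared members report n only).

## Synthetic-data generator

Log10 model: x = μ_g + b_ig + covariate effects + ε, with metabolite
baselines μ_g ~ N(6, 1), individual offsets b ~ N(0, 0.3) shared between an
individual's samples (the dominant inter-individual variation such cohorts
show), noise SD 0.15 (realistic residual noise for semi-quantitative MS),
sex/age/run-day effects with per-metabolite coefficients (SD 0.1 / 0.01 per
year / 0.1). Post-treatment adds: δ = 0.3 to one lipid sub-pathway
(class-wide shift), and for the 15 module members a latent factor
loading·sign_g·f_i (loading 0.9, split 8/−7) that REPLACES the member's
individual offset — the treatment reorganizes inter-individual variation
into a coordinated axis, giving within-module post correlation
loading²/(loading² + noise²) ≈ 0.97 and null pre correlation. BMI is
generated at the individual level from the signature metabolites' offsets
(signature of 49, directions alternating), with effect and noise chosen so
the population composite-BMI correlation is 0.60; the population
score-BMI correlation for a fully matched score is that times the
measurement attenuation σ_b/√(σ_b² + σ_ε²) ≈ 0.894, i.e. 0.537 — the
yardstick the score-recovery tests use. Censoring is a single global
detection limit placed at the `missing_rate` quantile of all intensities,
so missingness concentrates in low-abundance metabolites as in real
panels; planted module and signature members are drawn from above-median
abundance metabolites, because real panels only deliver (and real analyses
only see) well-quantified metabolites.

What the generator does not emulate: realistic MS noise spectra,
inter-metabolite baseline correlation outside the planted module,
non-Gaussian intensity distributions, and annotation errors. Passing
recovery tests therefore demonstrate the statistics work under the stated
generative model at the stated sizes, not that any particular real dataset
would yield the same discoveries.

## Benchmark problem sizes

The suites run at deliberately scaled sizes: null calibration at m = 500 ×
4 studies (differential), 50 studies × 6 random 10-member sets (module
significance), 45 random sub-modules of 120 in a universe of 480 (Fisher
stage); prior recovery at m = 2000, df = 5; enrichment recovery on 25
full-size (661-metabolite) studies; module recovery on 50 studies at
m = 120 with censoring and nuisance covariates disabled — the generator's
own invariant for the module factor is stated under exactly those
conditions, and at n = 6 the impostor rate of background metabolites
against the latent factor is what limits recovery under the fully loaded
configuration (measured ~0.72 recovery rate there, reported as a
diagnostic); score recovery on cohorts of 200 individuals. Measured
headline results (seed 1): prior (3.94, 0.500); differential null rate
0.053; enrichment top-ranked-and-significant 25/25; module Jaccard ≥ 0.8
in 48/50 with sign accuracy 1.0; score gap 0.066.

## Known limitations

- All inference is conditional on the imputation scheme; heavily censored
  metabolites carry deflated variances and their correlations are not
  meaningful (the module stage is run on unresidualized log data and module
  membership of heavily censored metabolites should be read skeptically).
- The flip-permutation p has resolution 2/64 at n = 6; "significant at
  0.05" means "at the floor or one level above", and many noise-driven
  candidate clusters reach the floor in full-size studies — module calls
  should be read together with their gain and sub-pathway coherence.
- The moderated t assumes exchangeable variances across the metabolome;
  planted heteroscedasticity (e.g. module members) is absorbed by the
  finite-d₀ prior but extreme variance structure would miscalibrate it.
- Name-based cross-study matching is deliberately conservative; panels with
  systematically different naming conventions will simply match less.
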