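# leptomet

Analysis toolkit for small paired-intervention metabolomics studies — the
setting where a handful of individuals are profiled on a semi-quantitative
UPLC-MS/MS metabolite panel before and after a treatment (the motivating
case: six children with congenital leptin deficiency, 661 serum metabolites,
sampled before and shortly after leptin replacement). At that sample size
nothing survives metabolome-wide correction, so the toolkit is built around
the statistics that do carry information at n = 6: variance moderation
across the metabolome, class-level enrichment, correlation-structure change,
and transferred phenotype signatures.

## What it computes

**Paired differential analysis** (`leptomet.differential`). Within-individual
log10 differences d_i = x_post − x_pre; sample-level batch covariates (run
day) enter as within-individual contrasts in the difference regression,
while individual-constant covariates cancel exactly. Per metabolite g the
residual variance s²_g (df_g) is shrunk toward an empirical-Bayes prior
(d₀, s₀²) fitted by digamma/trigamma moment matching on log s²_g, and

    t̃_g = β̂_g / ( s̃_g √v ),   s̃²_g = (d₀ s₀² + df_g s²_g) / (d₀ + df_g)

is referred to t(d₀ + df_g), two-sided, with Benjamini–Hochberg control and
the dual reporting tiers nominal p < 0.05 / FDR < 0.2.

**Preranked metabolite-set enrichment** (`leptomet.enrichment`). Running-sum
enrichment score over sub-pathway sets on the t̃-ranked metabolome, null by
random same-size member sets, NES normalization, pooled-null FDR q, and
leading-edge extraction.

**Differential correlation modules** (`leptomet.network`). Per-condition
correlation matrices are soft-thresholded (signed power β, default 10 — at
n = 6 the null |r| tail is heavy and a high power suppresses it) and the
change adjacency D_ij = √(½|a_pre − a_post|) is clustered (average linkage
on 1 − D, multi-height candidate harvest, contrast filtering, pruning).
Modules are split into anti-correlated sub-modules by the leading
eigenvector of the post-treatment correlation matrix, tested by exhaustive
within-individual condition flips (63 flips at n = 6), and annotated by
one-sided Fisher sub-pathway enrichment.

**Lipid structure tests** (`leptomet.lipids`). Parses `(C:D)` tokens from
vendor names, classifies chain length (medium C6-12, long C13-21, very long
≥C22) and saturation, and runs chain-length/response Pearson correlations,
a Kruskal–Wallis saturation-class test and the 12α-hydroxylation ×
leading-edge Fisher exact test.

**BMI metabolomic score** (`leptomet.scores`). A reference signature
(metabolite, direction ±1) is matched by normalized name; matched
metabolites are z-scored over an explicit cohort and summed with their
signs. Associations are reported as Pearson r with Fisher-z 95% intervals,
tanh(atanh r ± 1.96/√(n−3)).

**Cross-study concordance** (`leptomet.crossstudy`). Three-tier biochemical
name matching between panels and per-sub-pathway sign agreement / fold-change
correlation.

**Synthetic studies** (`leptomet.synthetic`). A generator that emulates the
study shape — 6 individuals × 2 conditions, 661 metabolites in the 7
platform super-pathways (368 lipids, 170 amino acids, …) — with planted
ground truth: a class-wide shift on one sub-pathway, a post-only correlation
module with anti-correlated halves, a BMI signature, nuisance covariates and
detection-limit censoring. Every pipeline stage has a recovery test against
this truth.

## Worked example

```python
import leptomet as lm

matrix, annotations, metadata, truth = lm.simulate_study(lm.SimulationConfig(seed=17))
diff = lm.run_differential(lm.impute_and_log(matrix), metadata)
print(diff[["metabolite_id", "effect", "t_mod", "p_raw", "p_adj"]].head(3).to_string(index=False))
print(f"{int(diff['significant_nominal'].sum())} metabolites at nominal p < 0.05")

enr = lm.run_enrichment(diff, annotations, seed=17)
print(enr[["set_id", "size", "nes", "p_raw", "fdr_q"]].head(2).to_string(index=False))

modules, _ = lm.discover_modules(lm.impute_and_log(matrix), metadata)
report = lm.recovery_report({"modules": modules}, truth)
print("Jaccard vs planted module:", round(report["module_jaccard"], 2))
```

prints

```
metabolite_id    effect     t_mod    p_raw   p_adj
        M0004 -0.207165 -7.041284 0.005616 0.97992
        M0654  0.124722  6.928247 0.005885 0.97992
        M0339  0.450233  6.806908 0.006194 0.97992
28 metabolites at nominal p < 0.05
               set_id  size      nes    p_raw    fdr_q
long chain fatty acid    14 2.130383 0.001805 0.000000
      energy class 01    10 1.633965 0.017274 0.221392
Jaccard vs planted module: 0.83
```

Read: no single metabolite survives FDR correction (p_adj ≈ 0.98
throughout, exactly the small-n regime), yet the planted class-wide shift on
the long-chain fatty acids is the top-ranked enrichment set with q ≈ 0, and
the planted 15-member post-only correlation module is recovered with
Jaccard 0.83.

The same stages are exposed as a CLI (`leptomet preprocess / differential /
enrich / modules / lipidstats / bmiscore / compare / simulate`); each
subcommand reads and writes plain TSV/JSON.

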