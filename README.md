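# pdxmatch

Bulk-tumour deconvolution, hot/cold immune stratification, and
patient-derived xenograft (PDX) cancer-cell archetype matching.

## The problem

Triple-negative breast cancers (TNBC) differ widely in immune cell
infiltration: "hot" tumours (top quartile of immune fraction) carry a
large immune compartment, "cold" tumours (bottom quartile) little.
Because PDX models grow in immunodeficient hosts, the immune state of a
patient tumour may bias which tumours engraft. Testing that requires a
chain of inferences from bulk expression data:

1. **Deconvolution.** Bulk expression is a convex mixture of cell-type
   intrinsic profiles: `b_s = Σ_k π_sk f_k` with `π_sk ≥ 0`,
   `Σ_k π_sk = 1`. Stage 1 estimates the per-sample proportions `π` by
   exact simplex-constrained least squares against reference profiles;
   Stage 2 estimates per-gene intrinsic profiles `f` (with standard
   errors) by non-negative least squares across samples; the two stages
   alternate to convergence.
2. **Stratification.** Tumours are ranked by immune fraction and the
   bottom/top quartiles labelled cold/hot; Stage 2 is re-run per group
   to get the cold and hot **cancer-cell** profiles.
3. **Differential expression and enrichment.** Genes with
   `(hot+1)/(cold+1) ≥ 5` (either direction) and Welch-t p < 0.05
   separate the archetypes; gene-set over-representation uses the
   upper-tail hypergeometric test.
4. **Matching.** Each PDX cancer-cell profile (host reads already
   removed) is Pearson-correlated on log2(x+1) values against both
   archetypes; the ratio `r_cold / r_hot > 1` labels the model cold.
5. **Bias test.** With `k` of `n` models matching cold, the exact
   binomial tail `P(X ≥ k | n, p0)` (default null `p0 = 0.64`, the
   cold/basal share expected without engraftment bias) is computed by
   direct pmf summation — no normal approximation.

A synthetic-data module generates ground-truth cohorts with exactly
this structure (Dirichlet mixing proportions, planted ≥5-fold archetype
genes, an immune gradient separating hot from cold, PDX-like noisy
archetype copies), so every stage is verifiable without downloading
anything. See `docs/methods.md` for models, assumptions, and numerical
choices.

## Worked example

```python
import pdxmatch as pm

cfg = pm.SimulationConfig(seed=1, noise_cv=0.1, archetype_fold_max=20.0)
bulk, truth = pm.generate_cohort(cfg)                      # 100 tumours
pdx, pdx_truth = pm.generate_pdx_profiles(cfg, truth.archetypes)

fit = pm.deconvolve(bulk, truth.reference_profiles)
print(f"converged: {fit.converged} after {fit.n_iterations} iterations")

partition = pm.partition_hot_cold(fit.proportions.data["immune"])
print(f"partition: {partition.labels.value_counts().to_dict()}")

hot, cold = pm.groupwise_cancer_profiles(bulk, fit.proportions, partition)
de = pm.differential_expression(hot, cold)
print(f"differentially expressed genes: {int(de['passes'].sum())}")

matches = pm.classify_pdx(pm.correlate_to_archetypes(pdx, hot, cold))
hist = pm.match_histogram(matches)
print(f"cold matches: {hist.n_cold}/{hist.n} ({hist.cold_share_percent}%)")

bias = pm.engraftment_bias_test(hist.n_cold, hist.n, p0=0.64)
print(f"engraftment bias p-value: {bias.p_value:.3g}")
```

prints

```
converged: True after 109 iterations
partition: {'intermediate': 50, 'hot': 25, 'cold': 25}
differentially expressed genes: 402
cold matches: 156/166 (94%)
engraftment bias p-value: 7.94e-20
```

Reading it: the alternating fit converged; the quartile rule labelled
25 tumours cold and 25 hot; 402 of the 438 planted archetype genes were
recovered at the 5-fold/p<0.05 thresholds; 156 of 166 simulated PDX
models (94%, matching their generating share) correlate better with the
cold cancer-cell profile; and that count is wildly inconsistent with
the 64% null — strong evidence of a cold engraftment bias.

The same chain runs from the shell on TSV/GMT/YAML inputs:

```sh
pdxmatch simulate --outdir data --seed 1
pdxmatch run-all --outdir run --seed 1          # synthetic end-to-end
pdxmatch bias-test --k-cold 156 --n 166 --p0 0.64
```

`run-all` executes all eight stages (deconvolve, immune, partition,
profiles, de, enrich, match, bias-test) and writes a manifest with
per-file checksums; reruns with the same seed reproduce identical
checksums.

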