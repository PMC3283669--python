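# regulon-shift

Tools for analysing growth-phase-dependent gene regulation by a pair of
paralogous zinc-finger transcription factors (the budding-yeast Gis1/Rph1
pair is the motivating system). The package covers the full chain from
promoter sequence to regulatory model:

- **Promoter motif statistics.** Extraction of ≤800-bp upstream regions from
  a genome FASTA + GFF3 (truncated at neighbouring genes), and
  orientation-resolved exact-word scanning for the stress response element
  (STRE, `AGGGG`/`CCCCT`) and the post-diauxic shift element (PDS,
  `AGGGAT`/`ATCCCT`), counting overlapping matches.
- **Genotype contrasts.** For a 4-genotype (wt, two single deletions, the
  double deletion) × 3-phase (log, post-diauxic shift, early stationary)
  design, per-gene contrast log2 ratios with an empirical-Bayes moderated
  *t*: the statistic is Δ / (s̃ · √(1/n_A + 1/n_B)) with posterior variance
  s̃² = (d₀s₀² + d·s²)/(d₀ + d), the prior (d₀, s₀²) estimated from all gene
  variances by digamma/trigamma moment matching, and Benjamini–Hochberg FDR
  control. A gene is called differentially expressed at ≥2-fold and FDR
  p < 0.01.
- **Regulon statistics.** The influence ratio |g| − |r| (which paralog
  dominates), the redundancy coefficient (d − (g + r))/d (1 = effect only in
  the double mutant, 0 = additive, negative = singles exceed the double),
  regulation-mode classification, average-linkage clustering on 1 − Pearson
  distance, hypergeometric set-overlap tests, Wilcoxon rank-sum group
  responses, Welch-*t* motif enrichment, and a one-sided hypergeometric
  orientation-bias test over motif occurrences.
- **Motif-activity model.** Per contrast, weighted least squares of gene
  log2 ratios on oriented motif counts, y_g = β₀ + Σ β_m·x_{gm} + ε, with
  gene weights |y_g|; each β_m is the activity of one oriented motif in that
  contrast, with a partial-F (squared-*t*) p-value.
- **Synthetic studies.** A generator that plants Poisson-distributed motif
  insertions in background promoters and builds genotype effects from a known
  activity model, so every stage can be validated against ground truth.

## Worked example

```python
from regulon_shift import (SimulationConfig, simulate_study, summarize_density,
                           compute_contrast, fit_eb_prior, moderated_t_test,
                           call_differential, build_design, fit_motif_activity)

study = simulate_study(SimulationConfig(n_genes=1000, seed=42))
print(summarize_density(study.true_counts).round(3))

m = study.expression
base = compute_contrast(m, "log", "gis1", "wt")
prior = fit_eb_prior(base.table["s2"].to_numpy(), float(base.table["df"].iloc[0]))
res = moderated_t_test(compute_contrast(m, "log", "gis1rph1", "wt"), prior)
de = call_differential(res)
print(f"prior: d0={prior.d0:.2f}, s0^2={prior.s0_sq:.4f}")
print(f"differentially expressed (|log2| >= 1, FDR < 0.01): {len(de)} genes")

design = build_design(study.true_counts, motifs=["STRE", "PDS"])
fit = fit_motif_activity(design, res.log2_ratio, weighting="abs_response")
print(fit.to_frame().round(4))
```

prints

```
       fwd_per_promoter  rev_per_promoter  ...  fwd_rev_ratio  n_promoters
motif
STRE              0.532             0.479  ...          1.111         1000
PDS               0.254             0.251  ...          1.012         1000

prior: d0=93.44, s0^2=0.0395
differentially expressed (|log2| >= 1, FDR < 0.01): 230 genes

           coefficient  stderr  p_value
intercept       0.0482  0.0112      0.0
fwd_STRE        0.6751  0.0060      0.0
rev_STRE        0.3621  0.0064      0.0
fwd_PDS         0.2494  0.0094      0.0
rev_PDS         0.0503  0.0098      0.0
```

The density table shows STRE and PDS occurrences per promoter by
orientation. The synthetic study plants a log-phase *repression* program
(deleting both factors raises expression of motif-bearing genes), so the
double-vs-wt contrast recovers strongly positive activities for the forward
STRE (planted 0.70, fitted 0.675) and forward PDS (planted 0.25, fitted
0.249); 230 genes pass the 2-fold / FDR 0.01 rule.

## Command line

```sh
regulon-shift simulate --n-genes 2000 --seed 1 --out study/
regulon-shift scan --genome ref.fa --gff genes.gff3 --max-len 800 --out counts.tsv
regulon-shift contrasts --matrix expr.tsv --phase log --out contrasts_log.tsv
regulon-shift cluster --contrasts contrasts_log.tsv --k 6 --out clusters.tsv
regulon-shift activity --counts counts.tsv --contrasts contrasts_log.tsv --out activity.tsv
regulon-shift run --matrix expr.tsv --promoters promoters.fa --out results/
```

`regulon-shift run` executes every stage and writes per-phase contrast
tables, cluster assignments, influence/redundancy profiles, DE-set overlap
matrices, gene-set group responses, motif enrichment/density/orientation
tables, the fitted activity table, and a manifest (config hash + seed) that
suffices to reproduce the bundle byte-for-byte.

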