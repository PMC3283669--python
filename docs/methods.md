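# Methods

## Design and scope

The package analyses a 4-genotype × 3-phase expression design — wild type,
two single deletions of paralogous transcription factors, and the double
deletion, sampled in logarithmic growth (`log`), just after the diauxic
shift (`PDS`), and in early stationary phase (`stat`) — together with the
genes' promoter sequences. It starts from a log2 expression matrix;
probe-level normalisation of raw arrays is out of scope. Each phase is
normalised and analysed separately: no variance or prior information is
shared across phases.

## Promoters and motif counting

A promoter is the region from the start codon to 800 bp upstream, truncated
at the nearest boundary of any other annotated gene regardless of strand;
minus-strand promoters are reverse-complemented so every sequence reads
5'→3' toward the start codon. Coordinates are 0-based half-open internally;
GFF3 (1-based closed) is converted on read. Genes whose upstream neighbour
abuts or overlaps the start get an empty promoter, which is flagged and
excluded from density denominators.

Motifs are exact DNA words: STRE `AGGGG` and PDS `AGGGAT`, with "forward"
meaning the word as written on the promoter strand and "reverse" its reverse
complement. Overlapping matches are all counted (a step-1 sliding window):
G-run words can overlap themselves, and greedy counting would undercount.
`N` never matches. The PDS element is deliberately the 6-mer used in the
quantitative analyses rather than the longer degenerate consensus
`T(A/T)AGGGAT`; one degenerate IUPAC position per word is supported so the
long form can be scanned in sensitivity analyses, but it is not the default.

## Contrast statistics

Per phase, a one-way per-gene layout over all strains present gives strain
means and a pooled residual variance s² with d = (samples) − (strains)
degrees of freedom; pooling across all four strains (not just the contrasted
pair) is a deliberate choice — the design is balanced and the extra degrees
of freedom stabilise the denominator. A contrast is a difference of two
strain means, with scale factor √(1/n_A + 1/n_B).

The moderated t shrinks s² toward a prior: s̃² = (d₀s₀² + d·s²)/(d₀ + d),
t = Δ/(s̃·scale), p two-sided from t with d₀ + d df. The hyperparameters are
estimated by moment matching on z = log s²: under the scaled-F model,
Var(z) = ψ′(d/2) + ψ′(d₀/2), so d₀ comes from inverting the trigamma
function on the excess spread of z (Newton iteration) and s₀² from the mean
of z corrected by digamma terms. When the observed spread does not exceed
the sampling component ψ′(d/2), d₀ is flagged infinite and the statistic
becomes a z-score with fixed s₀²; d₀ = 0 reproduces the ordinary t exactly.
Zero variances are excluded from prior estimation; an all-zero ensemble is
rejected as degenerate. A test cross-checks the statistic against the
reference R implementation of the moderated t (limma) on a two-group layout
where the two models coincide.

Differential expression requires |log2 ratio| ≥ 1 (inclusive) and BH-adjusted
p < 0.01 (strict). BH adjustment is delegated to statsmodels.

qPCR fold changes use the delta–delta Ct identity, fold = 2^−ΔΔCt.

## Regulon statistics

With g, r, d the single- and double-mutant log2 ratios versus wild type:
influence = |g| − |r|; redundancy = (d − (g + r))/d, returned as NaN when
d = 0 (undefined, never an exception). Mode classification uses only the
*significant* contrasts' signs (positive ratio ⇒ the factor represses):
opposite-signed significant singles → `opposite`; a single significant
single-mutant effect → factor-specific activation/repression; anything
implicating both factors is split at redundancy ≥ 0.5 into redundant versus
synergistic regulation. The 0.5 cutoff is the conventional midpoint between
the additive (0) and double-only (1) regimes.

Clustering of per-gene contrast profiles uses average linkage on
1 − Pearson distance (scipy), cut to k clusters (default 6 per phase).
Zero-variance profiles have no defined correlation and are rejected by name.
Ties in agglomeration follow scipy's deterministic input-order rule; the
test oracle uses continuous random data where ties have probability zero.

Set-overlap significance is the upper-tail hypergeometric
P(X ≥ overlap | N, |a|, |b|). The universe N defaults to all genes on the
expression matrix but is an explicit parameter — the appropriate universe
depends on how the compared sets were derived, and silently guessing it
changes p-values by orders of magnitude.

Group response is a two-sample Wilcoxon rank-sum of a gene set's log2 ratios
against all other genes (two-sided; exact when the smaller side has ≤10
values, otherwise normal approximation with tie correction), with direction
from the median difference. Motif enrichment is a Welch two-sample t on
per-promoter total counts, set versus complement, reported one-sided toward
enrichment with the depletion side alongside (the variance structure of
count data is unequal between small DE sets and the genome background, hence
Welch).

Orientation bias treats motif *occurrences*, not promoters, as sampled
units: with K forward among M total occurrences genome-wide and n
occurrences in the set, the p-value is the one-sided hypergeometric tail in
the observed direction. Occurrence-level sampling matches how
forward/reverse totals and their ratios are tabulated.

## Motif-activity model

For one contrast, y_g = β₀ + Σ_m β_m x_{gm} + ε_g over genes, where x_{gm}
is the promoter's count of oriented motif m (columns: intercept, fwd STRE,
rev STRE, fwd PDS, rev PDS). The fit is weighted least squares with
w_g = |y_g| taken literally: genes with larger expression changes dominate,
and zero-response genes drop out (the degenerate case resolved explicitly).
Each coefficient's "ANOVA p-value" is the partial F-test of that column
within the joint model, identical to the squared-t test reported by WLS.
Counts are the default predictor encoding; a presence/absence indicator mode
is provided because multiple copies per promoter make the two encodings
genuinely different models.

**Known property of the |y| weighting:** the weights depend on the noisy
response, so they are endogenous; measured on synthetic data the weighted
estimates are biased by several standard errors (worst on the intercept,
through the sign-dependent weighting of noise and the drop-out of near-zero
responses). Parameter-recovery validation therefore uses the unweighted
mode, where OLS sampling theory applies and all planted coefficients are
recovered within 3 SE; noise-free responses are recovered exactly by both
modes. The weighted mode remains the default for data analysis, where the
aim is to let strongly responding genes determine the activity estimates.

## Synthetic-data generator

The generator defines the package's ground truth. Promoters are i.i.d.
per-base background at 38% GC (yeast-like) with Poisson(λ) insertions per
(motif, orientation) — defaults λ = 0.2 per STRE orientation, 0.1 per PDS
orientation — placed uniformly without overlapping each other (overlap with
incidental background matches is allowed). True counts are defined by
re-scanning the emitted sequence: background creates incidental matches and
insertions can abut, so insertion bookkeeping is not a verifiable truth. An
optional clean-background mode rejection-samples promoters containing any
motif word, for exact-null tests; it is off by default because realistic
background densities matter for the activity model.

Expression is built per phase from the counts: the three mutant effect
vectors (relative to wild type) are solved from the configured
contrast-level activities by linearity — the five genotype contrasts are
linear in three strain effects, so an inconsistent over-specification is an
error — and each gene's strain mean is baseline + X_g·β(strain), baseline ~
N(8, 2²) per gene, with N(0, noise_sd²) replicate noise (default 0.2,
3 replicates per strain × phase). With zero noise every configured
contrast's realised log2 ratio equals X·β exactly, and the activity fit
recovers β to machine precision.

The default planted activities encode the growth-phase switch the analysis
is designed to detect: positive STRE/PDS coefficients in `log` (both factors
repress motif-bearing genes; deletion derepresses), negative after the shift
(activation), with the PDS element tied to factor 1 and the reverse STRE
mainly to factor 2. The numerical values are the fitted magnitudes such an
analysis produces on real data of this design (e.g. fwd STRE +0.70 in the
double-vs-wt log contrast, −0.32 for rev STRE post-shift).

What the simulator does *not* emulate: probe-level array artifacts,
cross-hybridisation, nucleotide composition heterogeneity along real
promoters, chromatin context, correlated replicate noise, and indirect
regulation cascades. Passing tests therefore demonstrate the statistical
machinery is correct and calibrated under the stated model, not that the
biological conclusions transfer to any particular dataset.

## Problem sizes and numerical choices

Unit and acceptance tests use 300–2000 genes, 10 calibration runs of 2000
genes for the moderated t (20,000 null tests), 4000 Wilcoxon null draws,
500 × 4 null activity coefficients, and 100 seeds for the sign-pattern
experiment; the full suite runs in about a minute. Calibration asserts
rejection rates in [0.04, 0.06] at α = 0.05. Trigamma inversion runs Newton
to 1e-10 relative tolerance with closed-form endpoints for extreme
arguments. TSVs are written with `%.17g` floats and read with round-trip
parsing so write→read is exact and repeated runs are byte-identical.
Hypergeometric, Wilcoxon, t and F machinery comes from scipy/statsmodels;
the bespoke statistics (influence, redundancy, mode classification,
occurrence-level orientation test, variance-prior estimation) are
implemented here and tested against enumeration or simulation oracles.

## Limitations

- Genome-scale density expectations (≈0.47 STRE per promoter in yeast) are
  validated by a test that downloads the genome; it cannot run offline.
- The orientation-bias test conditions on total occurrence counts and
  ignores promoter-level clustering of occurrences; a gene with many sites
  contributes each site independently.
- The universe behind overlap tests materially affects p-values and must be
  chosen by the analyst.
- Exact Wilcoxon p-values are only used for small groups; large-group
  p-values rely on the normal approximation.
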