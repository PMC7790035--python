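# Methods

This note records the models implemented in `crosstrait`, the defaults and
why they were chosen, what the synthetic generator does and does not
emulate, and the numerical choices that matter for reproducing results.

## Summary-statistic model and harmonization

A trait's summary statistics are per-SNP records (id, chromosome, 1-based
position, effect/other allele, z, N, p) with p ∈ (0, 1] and p consistent
with z (|p − 2Φ(−|z|)| ≤ 1e-4 when both are given; inconsistent rows are
dropped and counted). p-values are floored at 1e-300 and z capped at the
matching quantile (≈ ±37.0), both configurable. Pairs are merged on SNP id
(chromosome:position fallback is opt-in), trait B's z negated on allele
swaps, strand complements mapped before matching, and strand-ambiguous SNPs
(A/T, C/G) dropped by default — without allele frequencies they cannot be
oriented. Long-range-LD regions are excluded before any FDR computation;
the default mask is the MHC (chr6:26–34 Mb) and the 8p23.1 inversion
(chr8:7–13 Mb), both 1-based inclusive, because their extreme LD violates
the pruning model underlying the lookup tables. BED input is converted
from 0-based half-open.

## Synthetic GWAS generator

Genotypes are never materialized. Per-SNP causal effects are drawn from the
four-component point-normal mixture (null / A-only / B-only / shared,
weights π₀, π_A, π_B, π₁₂; shared effects bivariate normal with correlation
ρ₁₂), and z-scores follow

    z_j = √N · Σ_k r_jk β_k + ε_j,   ε_j ~ N(0, σ₀²),  corr(ε_A, ε_B) = ρ₀,

which is the standard marginal model for association z-scores with
standardized genotypes. LD is block-exchangeable: 1,000 blocks of 50 SNPs
spaced 5 kb apart (so ~50 SNPs fall within the 250 kb locus-merge window),
with within-block correlation cycled over (0.2, 0.4, 0.6, 0.8) across
blocks. The cycling serves two purposes: real LD is heterogeneous, and a
varying LD score is what identifies the slope of LD-score regression — with
a single block correlation every SNP has the same ℓ and slope/intercept are
not separable (the regression then reports rg as undefined rather than
guessing).

Default scale: m = 50,000 SNPs, π_A = π_B = 1e-3, π₁₂ = 2e-3, per-causal
effect variance σ_b² = 2e-4, N = 1e5, σ₀ = 1, ρ₀ = 0 (disjoint cohorts).
These give a per-causal-SNP noncentrality N·σ_b² = 20 — a desk-scale
miniature of a well-powered GWAS of a polygenic trait, with heritability
h² = m·π·σ_b² ≈ 0.02–0.03 concentrated in few hundred variants rather than
the genome-wide 1e7-SNP scale. What the generator does **not** emulate:
realistic MAF spectra and MAF-dependent effect sizes, imputation error,
population stratification, long-range LD, and LD-correlated residuals
(ε is independent across SNPs, so null z-scores are exchangeable within a
block rather than correlated). Conclusions from passing tests therefore
speak to the correctness and calibration of the estimators under the stated
model, not to robustness against those real-data complications.

One global seed drives documented per-stage substreams (`derive_seed`), so
any stage can be re-run independently and a full pipeline re-run is
bit-identical.

## Conditional Q–Q

For each secondary threshold t ∈ {1, 0.1, 0.01, 0.001} the primary trait's
−log₁₀ p is evaluated at 1,000 evenly spaced empirical quantile levels
against −log₁₀ of those levels; curves are capped at 20 for display tables,
and strata under 100 SNPs are flagged rather than dropped. LD-aware
weighting of the curves (used in some condFDR implementations) is not
applied. Null calibration is assessed with Dvoretzky–Kiefer–Wolfowitz bands;
when several strata are checked simultaneously the band level is split
across strata (Bonferroni) so that "all strata inside" is itself a 95%
statement.

## Bivariate causal mixture

The likelihood treats LD-pruned SNPs (greedy random pruning at r² < 0.1) as
independent draws from the four-component bivariate normal mixture described
in the README. This replaces the full LD-convolution likelihood of the
architecture-level literature — a deliberate trade of some realism for a
fit that takes seconds at desk scale; consequently the per-trait
polygenicities it reports refer to the pruned-SNP universe and are not
comparable to genome-scale estimates from convolution-based tools.

Fitting: weights are optimized through a softmax (reference category π₀),
variances through log, correlations through atanh. Univariate two-component
margins are fitted first and seed 8 multi-start Nelder–Mead searches
(fractions of the smaller total polygenicity assigned to π₁₂, jittered);
each start gets a short coarse pass (maxfev 200) and the two best are
polished (maxfev 2,000, xatol 1e-5). ρ₀ is fixed at 0 by default (disjoint
cohorts) and freed by flag. k in AIC = 2k + 2·NLL counts the free
transformed parameters. Fits are deterministic given data and seed.

Overlap diagnostics refit with π₁₂ pinned to 0 (minimum overlap; ρ₁₂ is
then unidentified and removed, k drops by 2) and with the smaller trait's
unique weight pinned to 0 (maximum overlap, k drops by 1). Positive
ΔAIC = AIC_constrained − AIC_best means the data distinguish the best fit
from that scenario; the `distinguishable` flag requires both deltas
positive. The 90%-heritability Venn transform (q* ≈ 0.445) is applied per
component, so unique + shared counts add up to each trait's total by
construction.

## cond/conjFDR lookup

Grid: −log₁₀ p from 0 to 20 in steps of 0.1 on both axes. Counts C₂ and
C₁₂ are averaged as real numbers over 100 random greedy LD prunings at
r² < 0.1 (defaults; all exposed) before the ratio p₁·C₂/C₁₂ is formed and
capped at 1; the null proportion is conservatively fixed at 1. Cells whose
averaged joint count falls below 1 inherit the nearest less-stringent
defined cell (toward smaller −log₁₀ p₁, whole columns toward smaller
−log₁₀ p₂), then monotonicity in p₁ is enforced by a running maximum toward
less-significant p₁. Every SNP — pruned or not — receives a value by
bilinear interpolation in −log₁₀ space, with out-of-grid points clamped to
the edge. Interpolating in −log₁₀ space keeps resolution where discoveries
happen. The trio statistic is the maximum of the three pairwise conjFDR
values — conservative by construction: trio significance at τ implies
significance in all three pairs at τ.

A property worth knowing when reading locus tables: tail-area FDR controls
the false fraction among *SNPs* called jointly significant, not among
*loci*. True joint signals cluster (many significant SNPs per causal
block) while boundary false positives tend to found singleton loci, so the
locus-level false fraction can exceed the SNP-level FDR, and in
architectures with substantial trait-specific components this dilutes
effect-direction concordance at shared loci. In replicate simulations at
the default scale, SNP-level conjunction FDP at conjFDR < 0.05 is ~3%
while locus-level impurity under a mixed architecture reaches ~20%;
direction-recovery checks therefore use a pure-shared architecture, which
isolates the quantity being tested.

## Locus definition and concordance

FUMA defaults, all configurable: independent significant SNPs at
conjFDR < 0.05 mutually r² < 0.6 (greedy by ascending conjFDR, ties broken
by chromosome and position, making the result deterministic and row-order
independent); lead SNPs a subset mutually r² < 0.1; candidate SNPs at
conjFDR < 0.10 with r² ≥ 0.6 to an independent significant SNP; candidate
envelopes within 250 kb merge, and the merged locus' lead is its smallest
conjFDR. r² comes from the provided block LD; cross-block r² is 0.
Concordance compares sign(z_A)·sign(z_B) at lead SNPs only (a
candidate-majority variant exists behind a flag); loci with a zero or
missing z are excluded from the percentage and reported as "na".

## LD-score regression

Both regressions weight by 1/ℓ as a heteroskedasticity proxy; no two-step
intercept constraint is applied — the simplest defensible variant. rg is
clamped to [−1, 1]; non-positive heritability slopes make rg undefined and
are reported with a reason rather than truncated. SE and p come from a
delete-one jackknife over 200 contiguous SNP blocks (contiguity preserves
any residual local dependence inside a block). The Bonferroni flag marks
p < 0.05/n_tests for a declared family of tests.

## Problem sizes in the test suite

Replicate studies run at m = 5e4 (FDR calibration, concordance, rg,
Q–Q bands; 10–20 replicates, 20 pruning iterations per grid) and m = 1e5
with no LD for mixture recovery (10 replicates); these sizes give
Monte-Carlo error comfortably inside the asserted tolerances while keeping
the full suite fast. The acceptance script reports each quantity together
with the problem size n used to compute it.

## Known limitations

- The pruned-SNP independence approximation biases mixture polygenicity
  toward the pruned universe; only ratios and the shared-count scale are
  comparable across analyses with the same pruning.
- condFDR lookup tables assume the exclusion mask has removed regions whose
  LD is grossly non-block-like; applying the pipeline with no mask to real
  data including the MHC will miscalibrate the grids.
- The trio combination rule (max of pairwise conjFDRs) is conservative; it
  does not model three-way dependence beyond the pairwise grids.
- Effect-direction concordance is a lead-SNP statement; under strong allelic
  heterogeneity within a locus a single sign need not summarize the locus.
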