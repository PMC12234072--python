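# Methods

This note documents the statistical models, the synthetic-data design,
and the numerical choices behind pacmeth, in the spirit of the model
documentation shipped by packages like statsmodels or msprime.

## Study design the package models

Four seabird colonies: a REFERENCE site and three PAC-exposed sites
(SPILL: acute oil spill; SHIP: chronic shipping traffic; SEEP: natural
hydrocarbon seeps). WGBS on liver DNA at ~15× target coverage across
three sequencing lanes; each exposed colony is compared with the
reference. Sample sizes in the source study were 21/14/16/28
(REFERENCE/SPILL/SHIP/SEEP). Alongside methylation, each bird carries a
liver PAC concentration profile; the ratio of low-molecular-weight (2–3
aromatic rings) to high-molecular-weight (4–6 rings) PACs distinguishes
petrogenic/anthropogenic signatures (LMW-dominated) from natural seep
exposure (HMW-dominated).

## Preprocessing

- **Destranding.** A CpG dyad is covered on both strands; the minus-strand
  record at position p+1 is merged into the plus-strand record at p by
  summing counts. Orphan minus-strand records are re-anchored to p−1.
  Totals are conserved exactly.
- **Coverage filter.** Keep loci with 5 ≤ N ≤ min(100, c), where c is the
  per-sample nearest-rank 99.9th percentile of pre-filter totals
  (PCR-duplicate guard). Idempotent by construction.
- **Normalization.** Per-sample scaling factor f_s = (median of
  per-sample median coverages) / (sample median coverage); totals are
  rescaled and rounded half-up, methylated counts proportionally, so each
  locus's methylation proportion moves by at most one read.
- **Uniting.** A locus enters the matrix when it is non-missing in at
  least ceil(0.8 × group size) samples of *every* group ("at least 80%"
  read literally: 4 of 5 passes).
- **Lane overdispersion λ.** For each locus, lane levels are pooled
  proportions per sequencing lane; λ is the mean over loci of
  (variance of lane levels) / (their binomial sampling variance). λ ≈ 1
  means no lane batch effect. Note that λ as defined absorbs *biological*
  replicate dispersion too: with beta-binomial dispersion φ the
  expectation is roughly 1 + (N̄−1)φ even without any lane effect, so the
  diagnostic is informative for comparing lanes under a common biology,
  and its null calibration is tested at φ = 0.

## Per-CpG differential methylation

Counts X_ij ~ BetaBin(N_ij, p_g, φ_i): Var(X) = Np(1−p)[1+(N−1)φ].

1. **Raw dispersion** by Williams-type method of moments (README formula).
   Group proportions inside χ² are continuity-stabilised,
   p̂ = (ΣX+0.5)/(ΣN+1), so boundary loci do not produce zero
   denominators. Loci with no replication (≤ 1 sample per group) or zero
   Σ(N−1) are clamped to φ = 0; the estimate is clipped to [0, 0.99].
2. **Shrinkage.** log(φ+ε), ε = 10⁻⁴, is moderated toward a prior mean
   with weight d₀ = 20 against df_i = m_i − K:
   log φ̃_i = (d₀μ + df_i·log(φ̂_i+ε))/(d₀+df_i). The prior center is
   μ = log(mean(φ̂)+ε) — the *arithmetic* mean, because a large fraction
   of loci clamp at φ̂ = 0 (boundary proportions carry no dispersion
   information) and a geometric-mean center would collapse toward zero,
   understating replicate variance and inflating type-I error (measured:
   ~0.085 with a geometric center vs 0.05–0.06 with the arithmetic one,
   at nominal 0.05). With fewer than 100 loci the prior falls back to
   μ = log(0.05), the package's default biological dispersion scale.
3. **Wald test.** Pooled group proportions compared with variance
   V̂_g = p̃(1−p̃)Σ N[1+(N−1)φ̃]/(ΣN)²; two-sided normal p; BH-FDR.
   Reported `diff` is always exposed − reference.
4. **Lane covariate (optional).** Response arcsin(2p̃_ij−1) with weights
   4N/(1+(N−1)φ̃) in a linear model [intercept, group, lane dummies];
   Wald on the group coefficient with the known arcsine-stabilised
   variance rather than a residual estimate (residual σ̂² is too noisy at
   m = 14–28). Whether the original analysis put the lane inside the
   beta-binomial fit or a transformation is not recoverable; both code
   paths exist and agree in rank on balanced designs away from boundary
   proportions.

On tiny instances the Wald p-values rank loci the same way as an exact
beta-binomial likelihood-ratio test (Spearman ρ ≥ 0.9 in the suite).

## DMR calling

Seeds are maximal runs of CpGs with p ≤ 0.01 whose consecutive
significant members are ≤ 100 bp apart (intervening non-significant CpGs
included). Region boundaries are the half-open interval
[first_pos − 1, last_pos). Candidates closer than 100 bp merge, after
which the filters — length ≥ 50 bp, ≥ 3 CpGs, ≥ 50% significant — and the
statistics (mean diff, Σ Wald area) are recomputed. Direction is hyper
iff mean diff > 0; exact zeros (a measure-zero event) are classified hypo
and logged. The 100 bp merge distance is the cited caller's documented
default; all thresholds are arguments. No effect-size floor is applied,
matching the source parameter list.

## Overlap statistics and the slot null

Intersections use half-open ≥ 1 bp semantics (abutting regions do not
overlap). The permutation null treats the genome as M = round(G/L̄)
interchangeable region slots (defaults G = 1.3×10⁹, L̄ = 400 →
M = 3,250,000; the coarser "~3×10⁶" rounding is a config change and
indistinguishable in practice). Each DMR set is a uniform
without-replacement draw of slots; two sets overlap where they share a
slot. The intersection size of independent uniform subsets of sizes a and
b is exactly Hypergeometric(M, a, b), and the triple intersection follows
a nested conditional hypergeometric, so the null is sampled from those
distributions directly — distributionally identical to materialising the
slot draws, O(rounds) instead of O(rounds·M). Empirical p-values use the
add-one convention (1 + #{null ≥ obs})/(1 + R), bounded below by
1/(R+1). The overlap-difference test uses D = |A∩B| − |A∩C|, two-sided
on |D|; conditional on A the two overlaps are independent, and their
laws depend on A only through its size, so the null D is a difference of
independent hypergeometrics.

Shared-DMR percentages use the asymmetric first-set count and the summed
set sizes (112/(770+435) = 9.29%), matching the printed arithmetic.

## Site statistics

- **Two-proportion χ²** (df = 1, no continuity correction — the printed
  93.14 is only reproduced without Yates; a `correction` flag exists).
  As the slot denominator grows the statistic converges to
  (x₁−x₂)²/(x₁+x₂).
- **Fisher exact 2×2** sums hypergeometric probabilities ≤ that of the
  observed table, in exact integer arithmetic (math.comb), so probability
  ties are handled without floating-point tolerance; the suite checks
  exact equality with an independent factorial/Fraction enumeration for
  every table with margins ≤ 30, and agreement with scipy. The 2×K
  Monte-Carlo variant holds margins fixed via multivariate hypergeometric
  draws with an add-one p. The direction table defaults to pooled
  anthropogenic (SPILL+SHIP) vs SEEP; per-site 2×3 is available.
- **LMW:HMW ratios** are per-bird (parent+alkylated, heterocyclics
  excluded as tabulated separately); the site ratio is the mean of bird
  ratios; birds with zero HMW are excluded and logged. Kruskal–Wallis is
  tie-corrected; pairwise tests are two-sided Wilcoxon rank-sum with BH
  adjustment. The source's "KW-H₃" subscript implies four groups while
  its text names three exposed sites; the package reports H with the
  group count actually supplied and forces neither reading.
- **PCA** on the samples × loci percent-methylation matrix
  (complete loci only), column-centered, unscaled, via SVD; component
  variance shares sum to 100.
- **ward.D clustering** on 1 − Pearson correlation between sample
  profiles, with the Lance–Williams Ward update applied to *unsquared*
  distances (the ward.D convention; scipy's 'ward' linkage implements
  ward.D2, hence the hand-rolled agglomeration). Ties break by smallest
  cluster index; Ward's coefficients satisfy reducibility, so linkage
  heights are monotone.

## Synthetic data generator

The generator produces the statistical structure the analysis assumes,
not sequence-level realism:

- **Genome.** Default desk scale: toy chromosomes with CpG dyads placed
  in clusters of ~5 (within-cluster gaps 2–50 bp) so runs of ≥ 3 CpGs
  within 100 bp — DMR-callable territory — always exist. Positions are
  1-based plus-strand Cs, ≥ 2 bp apart.
- **Baselines.** Per-locus methylation is drawn from the bimodal mixture
  w·Beta(5, 0.5) + (1−w)·Beta(0.5, 5), with w solved so the global
  coverage-weighted methylation fraction hits the configured target
  (default 0.67, the vertebrate-liver scale). Inside planted DMRs the
  baseline is drawn from an intermediate band (~0.3–0.7) instead:
  differential regions arise at partially methylated regulatory loci, and
  a ±0.25 shift must be realizable after clipping to [0, 1].
- **Counts.** Coverage ~ NegBin(mean 15, size 10); methylated counts are
  beta-binomial with dispersion φ (default 0.05) around the baseline
  (+δ inside planted DMRs for exposed samples). Zero-coverage records are
  dropped, which is what creates realistic missingness for the 80%
  uniting rule. Lanes are assigned round-robin; an optional lane offset
  exists only to exercise the λ diagnostic and covariate path (default 0,
  matching the reported λ < 1).
- **Planted DMRs.** Gamma(shape 4) lengths with configurable mean
  (default 400 bp, truncated at 50), ≥ 3 CpGs, mutually non-overlapping,
  hyper with configurable probability, placed by rejection sampling with
  an explicit error when the genome cannot host the request.
- **PAC tables.** ~27 compounds (parent/alkylated × LMW/HMW plus
  heterocyclics, USEPA16 flags) with lognormal per-compound noise
  (σ = 0.4) and lognormal bird-level LMW and HMW burden effects
  (σ = 0.15). Site mean composition is treated as a fixed site-level
  property: after sampling, the parent-compound mass is scaled so the
  mean ΣUSEPA16 equals the profile target, and the HMW mass so the mean
  bird LMW:HMW ratio equals the target ratio — the study reports these
  site means as fixed observed quantities, and the generator reproduces
  them by construction while bird-level variation stays random.
  Oil-spill-like profiles add a heavy-tail mixture (default 30% of birds
  with a 10× LMW burden) modelling episodic acute exposure; this is what
  makes the rank-based site comparisons behave like the observed pattern
  (SEEP sharply below both anthropogenic sites, SPILL vs SHIP usually
  indistinguishable) while the means stay calibrated.

**What passing tests do and do not show.** The generator emulates count
statistics, missingness, lane structure and composition targets. It does
not emulate sequence context, bisulfite conversion error, SNP
interference, correlated methylation beyond planted regions, or
chromosome-scale coverage waves — so green tests certify the *inference
machinery* (calibration, recovery, determinism), not performance on any
particular real dataset.

## Problem sizes and numerical choices

Default test/pipeline scale is 1–2 chromosomes of 150–600 kb with
700–3,000 CpGs and 6–8 samples per group; at this scale the full pipeline
runs in ~1 s and the entire suite in well under a minute, while keeping
every geometric property of the full-size problem (the slot null is always
run at the real M = 3.25×10⁶). Full-size runs are a config change.

- Seeds: every stochastic routine takes an explicit seed; the pipeline
  fans one seed into fixed per-stage offsets so stages rerun alone
  reproduce themselves; manifests carry sha256 checksums.
- Continuity constants: +0.5/+1 proportion stabilisation; ε = 10⁻⁴ on
  the log-dispersion scale; dispersion clipped to [0, 0.99].
- Rounding: half-up (not banker's) for normalized counts; percentages
  reported to 2 decimals; nearest-rank percentiles with an epsilon guard
  against binary rounding of q/100·n.
- Degenerate inputs: empty tables and empty region sets flow through;
  all-zero-coverage loci are skipped and counted; fixed-methylation loci
  are excluded from λ; empty margins give Fisher p = 1.

## Known limitations

- The Wald test is asymptotic; at very low coverage (< 5×) or extreme
  proportions its calibration degrades (the suite demonstrates rank
  agreement with an exact likelihood-ratio oracle on tiny instances, not
  exact p-value agreement).
- No smoothing across neighbouring CpGs; each locus is tested
  independently, as in the non-smoothed path of the modelled analysis.
- The slot null ignores genomic adjacency (slots are interchangeable);
  whether the original analysis permuted real coordinates is not
  documented, and clustered genomes would make the null conservative or
  liberal depending on DMR clustering.
- The source study's Results and Discussion disagree on the
  direction labels (hyper vs hypo) and on two DMR totals (770/435 vs
  878/539); the package fixes the sign convention exposed − reference and
  reproduces the Results-section numbers.
- PAC class summaries reproduce the reference-site table's scale, not any
  compound-level truth; compound identities are a representative subset
  of the 52 measured.
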