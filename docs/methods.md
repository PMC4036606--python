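# Methods

## Model and sampling scheme

The genomic model is `y = 1μ + Xα + e` with `e ~ N(0, σ²_e I)`, where X
holds the coded genotypes of m training individuals at n SNPs and α the
allele-substitution effects. The SSVS prior is a two-component normal
mixture per locus: with prior probability 1 − π the locus is "in" (QTL
indicator I_j = 1, variance σ²_α), otherwise it is shrunk a hundredfold
(variance σ²_α/100). The divisor 100 and π are fixed hyperparameters; π
is not estimated. Conditional posteriors:

- μ | · ~ N(mean of (e + μ), σ²_e/m) (constant prior);
- I_j | · : Pr(I_j = 1) = f₁(1−π) / (f₀π + f₁(1−π)) where
  f_δ ∝ v_δ^{−1/2} exp(−r_j²/(2v_δ)), v_δ = (x_j'x_j)² σ²_α/ω_δ + x_j'x_j σ²_e,
  ω₁ = 1, ω₀ = 100, and r_j = x_j'e + x_j'x_j α_j is the locus statistic
  (equal to x_j'y* with y* the phenotypes corrected for all other loci).
  The densities are compared in log space, so simultaneous underflow of
  both likelihoods cannot corrupt the probability;
- α_j | · ~ N((r_j)/(x_j'x_j + λ_j), σ²_e/(x_j'x_j + λ_j)) with
  λ_j = ω_j σ²_e/σ²_α recomputed per locus per iteration;
- σ²_α | · ~ (S²_α + Σ_j ω_j α_j²)/χ²_{ν_α+n};
- σ²_e | · ~ e'e/χ²_{m−2}.

Scaled-inverse-χ² draws use the scale/χ²_df convention throughout (the
standard in this literature). The residual-variance degrees of freedom
m − 2 (rather than the more common m) are retained deliberately; for any
realistic m the difference is negligible. The prior scale for the effect
variance comes from partitioning an assumed total additive-genetic
variance σ²_a over n loci, a fraction 1 − π of which carry weight 1 and a
fraction π weight 1/100:

    σ²_a = n σ̃²_α ((1 − π) + π/100)  ⇒  σ̃²_α = 100 σ²_a / (n (100 − 99π)),
    S²_α = σ̃²_α (ν_α − 2)/ν_α.

Two quantities in this derivation are design choices rather than
transcriptions: the locus statistic r_j is formed as x_j'e + x_j'x_j α_j
(forming it as x_j'y* *plus* another x_j'x_j α_j term would double-count
the add-back, since x_j'y* already contains it), and the σ̃²_α formula is
the variance-partition reconstruction above. Both are exercised by the
unit tests (the prior-scale formula against the hand-evaluated value
100/(1.099·1000) at π = 0.999, n = 1000).

Initialization: μ = ȳ, α = 0, I = 0 (ω = 100), σ²_e = var(y)/2,
σ²_α = σ̃²_α, and σ²_a defaults to var(y)/2 when not supplied. Default
chain: 2000 iterations, 500 burn-in, thin 10. Posterior means are
accumulated over every post-burn-in iteration; traces keep every thinned
iteration from the start of the chain. GEBVs are the coded training
matrix times the posterior-mean effects (an exact identity, tested to
1e-10). A divergence guard aborts with the iteration index if any state
variable becomes non-finite.

## Genotype coding

Three schemes map genotypes 0/1/2 to predictor values γ: raw (0,1,2),
centered (g − 2p_j), and centered-and-scaled ((g − 2p_j)/√(2p_j(1−p_j))),
the default because unit-variance predictors behave better numerically in
MCMC. p_j is the frequency of the allele whose homozygote is coded 2,
estimated as the column mean over 2. Monomorphic loci make the scaled
coding undefined; they are dropped with a warning under both centered
schemes (kept under raw) so that real panels run unattended; an all-
monomorphic panel is a fatal error. The coding is linear in the allele
count, so selection candidates with real-valued dosages are coded with
the *training* offset and scale — no rounding is needed at prediction
time. Training individuals, whose genotypes feed the 3-group
bookkeeping, must be integers; externally imputed training dosages are
rounded by `round_dosages` (≤ 0.5 → 0, ≥ 1.5 → 2, else 1, boundaries
inclusive).

## Update kernels and RHS-blocks

The three kernels form the same conditional mean:

- original: numerator x_j'e + x_j'x_j α_j, m+1 multiplications;
- improved: residuals summed per genotype class in one additive pass
  (ascending individual order, which fixes the floating-point
  accumulation order for cross-kernel comparisons); numerator
  γ_j'f_j + n_j'γ_j² α_j with exactly 4 scalar multiplications;
- RHS-block: loci are partitioned into blocks of s SNPs (consecutive by
  default, or a seeded random permutation chunked). Within a block the
  group code of an individual is `1 + Σ_t g_t 3^(t−1)` over within-block
  positions t = 1..s — positional base-3, which at s = 2 reproduces the
  published two-SNP layout (at the second locus groups 1–3 carry
  genotype 0, 4–6 genotype 1, 7–9 genotype 2). For s > 2 the
  most-significant position is a convention of this package (the
  two-SNP layout does not pin it down); any fixed convention yields the
  same chain because the code is only ever decoded through
  `geno_of_group`. At block start the residual sums F_g of all 3^s
  groups are computed in one O(m) pass; locus t inside the block reads
  the class sums h_k = Σ_{g: geno(g,t)=k} (F_g − n_g ΔE_g) in O(3^s);
  the per-group running change ΔE_g accumulates γ_t(g)·Δα_t (3 distinct
  products per locus); block end writes e_i ← e_i − ΔE_{g(i)} in one
  O(m) pass. Keeping running (F, ΔE) pairs instead of materializing
  per-locus-pair cross-count matrices is algebraically identical for
  s = 2 (verified by expansion in the tests) and keeps the inner-locus
  cost at O(3^s) for any s. Zero-count groups are retained; their
  contributions are zero and need no special casing.

The within-block locus order is frozen at block construction and reused
every iteration (required for the group coding to stay valid); block-level
evaluation order can optionally be permuted per iteration
(`permute_block_order`), which consumes one extra permutation draw per
iteration and therefore breaks random-stream alignment with the other two
kernels — it is off by default.

RNG discipline: every iteration consumes one standard normal for μ, one
uniform plus one standard normal per locus, and two χ² draws, in the same
order under all three kernels, so equal-seed chains are comparable across
algorithms to floating-point accuracy (observed agreement of thinned
effect traces is ~1e-10 relative over 500 iterations).

Operation counters instrument the kernel arithmetic (multiplications,
additions/subtractions, divisions). Convention: the division by the
denominator and the formation of Δα are not multiplications, so the
original numerator counts m+1 and the improved numerator exactly 4. The
counters are the portable proxy for CPU-time comparisons; wall time and a
peak-RSS probe (`resource.getrusage`) are reported by the benchmark sweep
but never asserted, being hardware-dependent.

## Resource model

The dominant array is the 1-byte m×n genotype store (residual updating)
or the 2-byte m×(n/s) group-code store (RHS-updating), giving the
closed-form predictions n·m·10⁻⁹ Gb and 2·n·m·10⁻⁹/s Gb. The CPU-optimal
block size is a step function of m: 2 below 1000 individuals, 3 to 2500,
4 to 11000, 5 to 50000, 6 to 100000; beyond that range s = 6 is
extrapolated with a warning. `block_size="auto"` applies this rule.

## Synthetic data

The generator draws, per locus, an allele frequency uniformly from the
MAF range (default 0.05–0.5) and genotypes Binomial(2, p) i.i.d. across
individuals — unlinked loci in Hardy–Weinberg proportions. A chosen
number of loci act as QTL with standard-normal effects; the residual
variance is set from the realized genetic variance so that
var(TBV)/var(y) matches the requested h² up to residual sampling noise.
All draws come from seeded numpy PCG64 streams (one per stage), so
datasets are reproducible across platforms.

What this emulates — and what it does not: real SNP panels have linkage
disequilibrium, minor-allele-frequency spectra shaped by demography,
pedigree structure and selection, none of which are modelled. Passing
tests on these data therefore demonstrate algorithmic correctness
(kernel equivalence, residual bookkeeping, calibration of the indicator
under the null, recovery of variance components when the model is true),
not predictive accuracy on real populations.

## Problem sizes and tolerances

- Kernel-equivalence checks compare thinned effect traces at m = 200,
  n = 50, 500 iterations (tolerance 1e-8 relative); cross-seed,
  cross-algorithm GEBV stability uses m = 1000, n = 500, 20 QTL,
  h² = 0.5, 4000 iterations.
- Parameter recovery runs m = 2000, n = 1000, 50 QTL, h² = 0.5 for 1200
  iterations (300 burn-in) with the RHS kernel; the per-iteration
  genetic-variance summary is Σ_j x_j'x_j α_j²/m, which for unlinked
  loci estimates var(Xα).
- Residual consistency is enforced at ≤ 1e-8·(1 + max|y|) after every
  iteration when `check_residuals` is on.
- Monte-Carlo oracles for the variance samplers use 1e5 draws and 3-SE
  bands; the null-calibration band for the mean inclusion probability is
  a factor of 3 around 1 − π.

## Limitations

- Single-trait, complete data, no fixed effects beyond the mean, no
  BayesA/B/C variants, no estimation of π, no convergence diagnostics
  beyond trace export.
- Loci with more than three observed values are not supported (they
  would erode the 3-group advantage); no imputation, no linkage maps.
- The RHS kernel assumes all 3^s groups may be present and does not
  exploit absent groups or clever SNP-to-block grouping.
- Pure-Python per-locus loops carry interpreter overhead, so measured
  wall time does not reflect the kernels' operation-count ratios as
  sharply as a compiled implementation would; operation counts are the
  meaningful comparison.
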