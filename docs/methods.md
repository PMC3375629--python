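# Methods

## Model and procedure

The package aggregates per-SNP association p-values from K GWA studies of
related phenotypes. After an inner join by SNP identifier (a SNP is kept
only if present in every study and in the annotation — no imputation
scheme is defensible at the summary-statistic level), each study column
is ranked by ascending p-value. Ranks are **ordinal** with a
deterministic (p, snp_id) tie-break, never midranks: the permutation null
samples from the observed ranks and requires each column to be exactly a
permutation of 1..N. The per-SNP statistic is kept in log space,
log RP = Σ_k ln r_k, which orders SNPs identically to the integer rank
product and cannot overflow (at N = 10⁶, K = 4 the integer product
reaches 10²⁴; the log form is ≈ 55.26).

The null distribution of log RP is Monte-Carlo: each iteration samples
one SNP per study column, uniformly with replacement and independently
per column, and its statistic is the sum of the sampled column ranks'
logs. Two constraints make this null appropriate for GWA data:

* **MAF stratification.** SNPs are grouped into MAF bins (default
  boundaries 0.10, 0.25, 0.50; configurable). One null is built per bin
  from that bin's members only, and shared by all SNPs of the bin. The
  bin's null therefore inherits the rank distribution its power level
  actually produces, which is the mechanism that restores per-bin
  calibration. Per-bin rather than per-SNP nulls keep the cost O(bins)
  and are the interpretation consistent with controlling power
  differences between MAF groups. Boundary membership is half-open
  lower-inclusive ([0.10, 0.25) etc.), with 0.50 closed into the top bin.
* **LD exclusion.** An iteration is valid only if every *pair* of its K
  sampled SNPs is "outside LD range": different chromosomes, or more
  than `ld_distance` bp apart (default 1 Mb, configurable — a pragmatic
  upper bound on the physical reach of LD in outbred human populations,
  not an r² estimate). A SNP sampled twice in one iteration has distance
  0 and is invalid. Pairwise independence of the sampled ranks is exactly
  what the RP null assumes, hence the pairwise formulation. Rejection
  sampling (draw, test, redraw) keeps accepted draws exactly uniform over
  the valid tuples; per-bin rejection rates are logged so pathological
  bins (small, physically clustered) are visible, and a bin that cannot
  produce a valid draw within `max_rejections_per_draw` (default 10⁴)
  consecutive rejections raises an error naming the bin and its size.

Empirical p-values use the permutation estimator p = (r + 1)/(B + 1)
with ties counted as ≤ (lower tail for RP); it never returns 0 and its
minimum is 1/(B + 1), which the run manifest compares against the
Bonferroni threshold α/N so an under-iterated run warns rather than
silently reporting no significance.

**Paired-run protocol.** The full null construction is executed twice
with two seeds derived from one user seed (SeedSequence expansion, masked
to 31 bits; per-bin, per-attempt generators are spawned from
SeedSequence([run_seed, attempt, bin])). SNPs with min(p₁, p₂) ≤ 100/B
are screened: if any such pair disagrees by more than `rel_tolerance`
(default 0.2) relative, B is doubled and both runs redrawn with fresh
derived seeds, up to `max_doublings` (default 6) times; SNPs still
disagreeing after the last doubling are flagged but reported. The
reported p-value is the **higher** of the final pair — a deliberately
conservative choice. The 100/B screen focuses the convergence test where
Monte-Carlo noise matters (counts ≤ 100) instead of on the bulk of
clearly null SNPs; the 0.2 tolerance is this package's quantification of
"the two runs agree".

## Comparator methods

* **Fisher**: X² = −2 Σ ln p_k against the χ²(2K) upper tail. p = 0
  inputs are rejected (infinite statistic); at ingestion such rows are
  dropped and tallied rather than clamped.
* **Empirical (modified) Fisher**: the same X² statistic, but referred to
  the *same constrained resampling null* as modRP (per-bin, LD-excluded,
  paired runs, upper-tail counting). Mirroring modRP's null is a design
  choice: it makes the four-way comparison isolate the statistic rather
  than the null construction.
* **Standard RP**: definitionally modRP with both constraints disabled —
  a single global null of the observed ranks. With equal seeds it is
  bit-identical to that configuration, which the tests assert.

All selected methods share one merged dataset, one binning and one
seed-derived pair, so their p-values are directly comparable per SNP.
Significance is Bonferroni at α/N (inclusive comparison p ≤ threshold);
no FDR control is offered.

## Diagnostics

The correlation report computes Spearman correlation between study
p-value columns over all SNPs and over the top ⌈fraction·N⌉ SNPs by
ascending log RP (default fraction 0.001; at least 3 SNPs required).
Spearman rather than Pearson because the method itself is rank-based and
the result is then invariant under each study's monotone p-value
transformations.

## Synthetic data generator

The generator emulates the statistical structure the constraints exist to
handle, not genotypes:

* Null p-values arise as upper-tail probabilities of standard Gaussian
  z-scores with **equicorrelation ρ within positional blocks** (Gaussian
  copula): marginally uniform at any ρ, with tunable LD-like dependence.
  Blocks (default 10 SNPs over 50 kb) are dealt round-robin across 22
  chromosomes with 2 Mb between block starts, so distinct blocks are
  always outside the default 1 Mb LD distance and within-block pairs are
  always inside it.
* **MAF-dependent power** is imposed by p → p^γ(bin) (default γ ≡ 1):
  monotone within a bin's column (ranks inside the bin are preserved)
  while breaking marginal uniformity per bin — precisely the confound
  the stratified null corrects. γ < 1 deflates significance, γ > 1
  inflates it.
* **Signals** overwrite chosen SNPs with a target p-value in each
  affected study (optionally jittered in log₁₀ space) and are recorded in
  a truth table.
* MAF is uniform on (0.01, 0.5) by default; a rescaled Beta shape is
  available for low-frequency-heavy spectra.

What this does *not* emulate: genotype-level LD (r² structure, MAF-
dependent LD decay), correlated effect sizes between phenotypes beyond
the injected signals, population stratification, or study heterogeneity
in N. Passing calibration tests on these simulations shows the null
construction is correct under the stated dependence model; it does not
certify behaviour under every real-data pathology.

## Numerical choices and scale

* Sampling is vectorised in batches of ≤ 65,536 proposals; per-batch
  pairwise LD masks; results are deterministic given the seed regardless
  of batch boundaries.
* Default B = 10⁵ valid iterations per run is the desk-scale default;
  B = 10⁹ (appropriate for genome-wide Bonferroni thresholds near 10⁻⁸)
  is supported via `--iterations` but is a cluster-scale setting. At
  B = 10⁵ the smallest attainable p is ≈ 10⁻⁵.
* Validation problem sizes: brute-force enumeration oracles at N ≤ 12
  with B = 10⁶; calibration and confound-separation at 5,000 SNPs ×
  3 studies with B = 10⁵; signal recovery at 10,001 SNPs with B = 10⁶.
  These sizes give 3-SD statistical resolution on every asserted property
  while a full run completes in seconds.
* Tie-breaks are deterministic everywhere (snp_id lexicographic), output
  row order is ascending modRP p then snp_id, and floats are written with
  12 significant digits so files round-trip.
* Degenerate inputs: empty study intersections, empty bins, all-invalid
  bins, B = 0, p ∉ (0, 1], MAF ∉ (0, 0.5] all raise typed errors;
  annotation MAF in (0.5, 1) is folded to 1 − maf with a warning, since
  major-allele frequencies are a common dialect difference.

## Known limitations

* LD is a positional-distance proxy; no r² is computed and `ld_distance`
  is a single global constant.
* The per-bin null assumes SNPs within a bin are exchangeable after the
  LD exclusion; strong within-bin substructure (e.g. imputation-quality
  strata) would need finer bins.
* K = 1 inputs are supported by the statistics but the per-bin empirical
  p-values are then only monotone in raw p within a bin; cross-bin
  comparison of single-study empirical p-values is not meaningful.
* The paired-run doubling protocol bounds, but does not eliminate,
  Monte-Carlo disagreement at the extreme tail; non-converged SNPs are
  flagged in the result rather than suppressed.
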