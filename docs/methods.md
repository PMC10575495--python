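# Methods

## Problem setting

Given an n-sample × m-SNP genotype matrix with entries in {0, 1, 2}
(homozygous reference / heterozygous / homozygous variant) and a binary
case/control label per sample, the task is to find k-SNP sets whose joint
genotype distribution separates cases from controls. A candidate set is
summarized by its I×2 contingency table over realized joint genotypes
(I ≤ 3^k) together with per-locus genotype-by-class marginals.

## Objectives

All four objectives are computed from one contingency table per candidate
set, in natural-log space.

* **K2 (minimize).** The Bayesian-Dirichlet marginal likelihood of the table
  is `∏ᵢ (J−1)!/(nᵢ+J−1)! ∏ⱼ nᵢⱼ!` (J = 2 classes); the score is its
  negative natural log, evaluated with log-gamma (direct factorial products
  overflow near n ≈ 170). Lower = stronger association; a perfectly
  separating table scores strictly below the balanced table with the same
  margins. Unrealized cells contribute nothing and are skipped everywhere
  (they add zero under the 0·ln 0 := 0 convention, and 3^k grows quickly).
* **LR / G statistic (maximize).** `2 Σ oᵢⱼ ln(oᵢⱼ/eᵢⱼ)` with the
  independence expectation `eᵢⱼ = nᵢ·n·ⱼ/n` taken from the table's own
  margins. This makes the LR objective identical to the G-test used in
  stage-2 verification.
* **JS (maximize).** `0.5 Σᵢ Σⱼ (nᵢⱼ/nᵢ) ln(2nᵢⱼ/nᵢ)`. Each realized row
  contributes `ln 2 − H(nᵢ₁/nᵢ) ≥ 0`, so the score is non-negative and zero
  exactly when every row splits 50/50. Note this is a one-sided,
  row-normalized divergence, not a full symmetric Jensen–Shannon divergence
  (rows enter unweighted by their mass); it is kept in this form
  deliberately, as the complementary objectives cover the symmetric view.
* **NDJE (minimize).** `ND / JE(control)` where `ND = (Σⱼ dⱼ)/D`,
  `dⱼ = Σₛ (nₛʲ'ᶜᵗʳˡ − nₛʲ'ᶜᵃˢᵉ)²` sums squared per-locus marginal
  differences, `D = Σᵢ |nᵢᶜᵗʳˡ − nᵢᶜᵃˢᵉ|` measures joint-distribution
  separation, and `JE` is the entropy of the control joint distribution.
  Sets with flat marginals but divergent joints — the no-marginal-effect
  signature — take small values. Degenerate denominators (D = 0 identical
  joints, or JE = 0 single-cell control distribution) return `+inf`, a
  sentinel every ranking treats as the worst value regardless of the
  configured direction; this keeps memory orderings total without NaNs.

Optimization directions (K2 min, LR max, JS max, NDJE min) are stored with
the configuration and can be overridden per objective.

## Locus grouping and weighted allocation

Annotations map SNPs to a region (gene) and a functional category. SNPs
sharing a `region_id` form a locus group. Category 1 comprises
coding/promoter/upstream/downstream SNPs; intron and intergenic SNPs — and
any SNP absent from the annotation table — fall to category 2, which is
down-weighted by the divisor w (default 2, exposed in the configuration). A
locus-harmony quota is split between categories proportional to effective
sizes (|c1| vs |c2|/w) with largest-remainder rounding (ties to the larger
effective size, then category 1), so counts always sum to the quota.

A category-1 draw picks a locus group with probability proportional to its
size (uniform choice available), samples up to k distinct members, and fills
any shortfall uniformly from all SNPs; category-2 draws sample from the
category-2 pool the same way. Grouping is by region identity, not
base-pair distance; ambiguous multi-region annotations are resolved by the
first record.

## Search

Four memories (one per objective), each with HMS = 10 harmonies, HMCR = 0.98
and PAR = 0.35 — the standard multi-population setting for this problem
family — and locus fraction 0.5: half of each initial memory is locus-driven,
half uniform random, all distinct within a memory. Improvisation copies each
position from a random memory member with probability HMCR, then
pitch-adjusts by ±1 on the SNP index with probability PAR (wrapping at the
bounds; when the input panel is position-sorted this is a positional
neighborhood move, and a group-aware variant that jumps within the value's
locus group is available behind a flag); otherwise the position is drawn
uniformly. Duplicate indices are repaired by uniform redraw. Replacement is
strict: a candidate enters a memory only if strictly better than the worst
member and not already present (ties keep the incumbent).

Scores are cached by canonical (sorted) SNP set; the evaluation count is the
number of *unique* sets scored, each counted once across all four
objectives. The run terminates when the budget `max_evals` (capped at
C(m, k)) is spent, when an iteration safety cap is reached, or — in power
benchmarks — when the planted set enters a memory. Because memory-driven
improvisation can stagnate on already-scored sets once memories converge,
20 consecutive cache hits trigger one uniform random draw; this guarantees
the budget is actually spent on distinct candidates and gives the search
exhaustive-equivalence when the budget covers the whole candidate space.

Stage 2 verifies the union of final memory members and the all-time best set
per objective: G-test (identical to the LR objective) and Pearson chi-square
on the realized I×2 table with df = I − 1, Bonferroni-corrected over the
union size (a reported candidate list should survive multiple testing;
Bonferroni is the conservative default). A set is reported
significant only if both tests pass. Single-row tables have df 0 and are
flagged degenerate with p = 1.

## Simulator

The simulator emulates a GAMETES-style protocol. Functional genotypes are
drawn per locus under Hardy–Weinberg equilibrium from the model's MAFs;
disease status is Bernoulli in the penetrance of the joint genotype;
rejection sampling fills the case and control quotas exactly (capped at
10⁶ × total draws). Background SNPs are i.i.d. HWE with MAFs uniform in
[0.05, 0.5], independent of status.

* **Marginal models**: `f(g) = baseline·(1+effect)^Σg`, rejected if the top
  cell exceeds 1. Every locus shows a strictly increasing marginal
  penetrance when effect > 0.
* **No-marginal models**: a table is feasible when every HWE-weighted
  per-locus marginal penetrance equals the prevalence (tolerance 10⁻⁶).
  Construction uses cyclic additive projection: for each locus slice, the
  deviation of its conditional marginal from the target prevalence is
  subtracted from the slice, then the table is clipped to [0, 1], cycling
  until convergence. The constant table f ≡ prevalence always satisfies the
  constraints, so the feasible set is non-empty, and a seed far from
  constant (e.g. the XOR/parity table, which is exactly feasible at
  MAF 0.5) converges to a nearby feasible table that keeps a strong
  interaction. Multiplicative (Sinkhorn-style) scaling is *not* used: it
  preserves the seed's zero pattern, and the XOR support is provably
  infeasible for equal marginals at MAF ≠ 0.5. Random restarts cover seeds
  that fail to converge; exhaustion raises a constructive error with the
  best residual deviation.
* **Null model**: constant penetrance, for type-I calibration.

Synthetic annotations place the planted SNPs per scenario: `co_located`
(one shared gene, padded with decoy members to the gene size, default 4,
plus 7 decoy genes — roughly a third of a 100-SNP panel genic, which is
typical of a filtered association panel), `scattered` (each planted SNP in
its own gene), or `no_info` (empty table). Gene size, decoy count and the
promoter/coding mix are configurable.

What the simulator does **not** model: linkage-disequilibrium–correlated
background genotypes (background SNPs are independent), genotyping error or
missingness, covariates, and quantitative traits. Passing benchmarks on
these data therefore demonstrate the search mechanics and the value of
locus priors under idealized annotations, not performance on raw GWAS data,
where LD both helps (real co-location priors) and hurts (correlated decoys).

## Benchmarks and problem sizes

The validation battery (mirrored by `scripts/acceptance.py`) uses problem
sizes chosen to exercise each claim at desk scale:

* **Exhaustive baseline**: 2-order scan of a 100-SNP panel = C(100,2) = 4950
  evaluations, the yardstick against which search budgets are read.
* **Oracle equivalence**: 30 datasets, m = 20, 400/400 samples, strong
  multiplicative signal (baseline 0.01, effect 2.0, MAF 0.3), budget 230 ≥
  C(20,2); the search must return the exhaustive optimum of every objective.
* **Initialization advantage**: 20 datasets, m = 100, 800/800 samples,
  XOR-seeded no-marginal model at MAF 0.4 and prevalence 0.2, co-located
  annotations, equal budget 2500 per arm. Locus-driven initialization
  (fraction 0.5) is compared with random initialization (fraction 0) on
  exact-set detection power and censored mean evaluations-to-detection
  (undetected runs counted at the budget they spent — the uncensored mean,
  also reported, conditions on detection and is biased toward easy
  datasets).
* **Calibration**: HWE sampling within 3 binomial standard errors at
  n = 10⁵; zero-marginal tables flat to 10⁻⁶; G-test type-I error on 200
  null replicates at 200/200 samples, where expected cell counts are large
  enough for the chi-square approximation (at 150/150 with MAF 0.3 the 9×2
  table has expected counts near 1 and the test is visibly
  anti-conservative — a known small-sample limitation, not a bug).

## Known limitations

* Power and evaluation-count numbers are functions of the synthetic study
  conditions above and of the annotation geometry; they are not comparable
  with results on other generators' disease-model parameterizations.
* The pitch-adjustment neighborhood (±1 on the SNP index) is only meaningful
  prior knowledge when the panel is position-sorted.
* Verification assumes the asymptotic chi-square null; very sparse tables
  (high k, small n) need permutation nulls, which are out of scope.
* VCF/PLINK input, live annotation retrieval, LD-aware grouping, and
  inter-memory migration are not implemented.
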