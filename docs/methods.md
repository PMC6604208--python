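# Methods

This note documents the models implemented in `awmnet`, the defaults and why
they were chosen, what the synthetic-data generator does and does not
emulate, and the numerical and design decisions a maintainer should know.

## Mixed-linear-model association

Each variant × trait pair is tested under

    y = 1μ + xb + u + e,   u ~ N(0, G σ²ᵤ),   e ~ N(0, I σ²ₑ),

the MLMA protocol: variance components come from REML on the *null* model
(`b = 0`) and are then fixed for the whole scan.  This is deliberately not a
leave-one-chromosome-out scheme; the tested variant may contribute to the
GRM.  The contamination this causes is negligible when the GRM is built from
thousands of variants (the intended regime) but is visible in toy data: with
only ~100 variants a strong causal variant is partially absorbed by its own
relationship matrix and loses test statistic.  Tests and the acceptance
measurements therefore use ≥ 2,000 variants.  `MlmaGwas` accepts a
`grm_variant_subset` for callers who want a proxy-panel GRM.

**REML.**  After one eigendecomposition `G = U D U'`, the restricted
likelihood is profiled over (μ, total variance) and maximized over the single
ratio h² ∈ [0, 1 − 10⁻⁶] by bounded Brent search (xatol 10⁻⁸).  This is
deterministic, has no starting-value sensitivity, and allows boundary
estimates h² = 0 (an explicit comparison against the h² = 0 profile guards
against returning an interior near-zero optimum).  Degenerate inputs —
constant or non-finite phenotypes — raise instead of returning garbage.

**Scan.**  With `V = σ²ᵤG + σ²ₑI` fixed, the per-variant GLS solution only
needs the eigenbasis once: all dosage columns are rotated (`U'X`) and the
effect, its standard error and the two-sided Wald normal p-value are computed
vectorized.  A variant whose rotated dosages have no variance after removing
the (GLS-weighted) mean is flagged `degenerate` and reported as effect 0,
se = ∞, p = 1 rather than raising — monomorphic or duplicated columns are a
data property, not a programming error.

**−log₁₀P on the log scale.**  p-values underflow double precision near
−log₁₀P ≈ 308 while real dairy signals reach the 500s, so the primary
statistic is −log₁₀P computed from `log_ndtr`; the p-value matrix is derived
from it and floored at the smallest positive double.

## QTL regions

Significant variants (−log₁₀P above the study-wide Bonferroni threshold by
default) are chained per chromosome with single linkage: a gap < 1 Mbp
(strict, matching "less than 1 Mbp apart") keeps the chain growing, so a
region can span much more than 1 Mbp.  Region bounds are the min/max
positions of members in the *upper third of the peak*, interpreted on the
−log₁₀P scale as ≥ 2/3 of the region maximum — the phrase has no standard
numeric definition, so the cutoff sits in one function (`region_bounds`) and
is easy to change.  The best candidate variant is the most significant
*genic* member (gene body ± 10 kb); intergenic variants are only reported
when no member is genic.  Ties break to the lower position, multi-gene hits
to the nearest gene body.  Consequence classes in the synthetic setting are
{genic, upstream, downstream, intergenic}; finer classes (missense, UTR, …)
would come from a user-supplied annotation and are outside the generator's
scope.  Variance explained is 100·2p(1−p)α²/σ²ₚ with σ²ₚ the sample variance
of the analyzed (pre-adjusted) trait and (p, α) taken from the region's most
significant variant for that trait; values > 100 are returned uncapped so
inconsistent inputs remain visible.

## Association weight matrix

Effects are standardized per trait column over variants, z = (b − mean)/sd
with sample sd (n − 1): the convention is irrelevant downstream because
correlations are location/scale-free per column, and a `t_scores=True`
alternative (b/se) is available.  The funnel is:

1. key-trait variants, p ≤ 0.001 boundary-inclusive;
2. correlated traits |r| ≥ 0.25 over the key-selected rows (key trait always
   kept);
3. k = round(mean number of *non-key* correlated traits hit at p ≤ 0.001 by
   the key-selected variants), floored at 1 — k is always recomputed, never
   hard-coded;
4. rescue of excluded variants hitting ≥ k non-key correlated traits;
5. gene assignment within ±10 kb (inclusive at exactly 10,000 bp), nearest
   gene body on multi-hits;
6. one variant per gene: max trait support, then min Σp over selected traits,
   then lower position — provably order-invariant.

Counts at every stage are kept in `AwMatrix.funnel` and the pipeline's JSON
report, because the selection funnel is the main audit artifact of an AWM
analysis.

## PCIT

Edges come from the partial-correlation-and-information-theory algorithm:
pairwise Pearson correlations of gene rows over the selected trait columns;
for every ordered trio (x, y, z) the first-order partials

    r_xy.z = (r_xy − r_xz·r_yz) / √((1 − r²_xz)(1 − r²_yz))   (and rotations)

define the tolerance ε = mean of the valid ratios (r_xy.z/r_xy, r_xz.y/r_xz,
r_yz.x/r_yz); the x–y association is non-significant if some z satisfies
|r_xy| ≤ |ε·r_xz| and |r_xy| ≤ |ε·r_yz|.  Numerical choices: ratio terms
with |denominator| < 10⁻¹² or non-finite partials are dropped from the ε
average; a trio with no valid terms eliminates nothing; elimination uses ≤,
so exact equality prunes; pairs with |r| = 1 are degenerate duplicates —
they are kept as edges unconditionally and reported in a warning.  A
noteworthy property of the published rule, documented here because it often
surprises: in an isolated 3-gene chain (r_xy = r_yz = 0.8, r_xz = 0.64,
partial r_xz.y exactly 0) *no* edge is pruned — ε = 0.5206 puts the
elimination bound at 0.4165 < 0.64.  The mediated-pair pruning that makes
PCIT useful emerges from conditioning genes outside the trio, and the
i.i.d.-noise test shows the realized behavior (well under half of all pairs
survive).  Equicorrelated modules, by contrast, are protected by the 1/ε
margin and stay fully connected — the planted-module test checks this.

The O(g³) triple loop is evaluated blockwise (one g × g slab per
conditioning gene), exact and fast for the few hundred genes an AWM
produces.  A warning is emitted below 8 trait columns, where partials from
short profiles are noisy.  Centralities: degree, and eigenvector centrality
as the principal adjacency eigenvector by power iteration (tol 10⁻¹⁰)
normalized to max 1; an edgeless graph reports the uniform vector (the
principal eigenspace of the zero matrix is degenerate).

## Regulator trios and enrichment

Trio search is exhaustive over C(R, 3) — regulator candidate lists are tens
of genes, and exhaustive ranking dominates greedy set-cover, which nested
neighborhoods can fool (there is a designed test for this).  Coverage counts
1-hop neighbors with trio members excluded from their own coverage; ties
break by within-trio overlap (ascending), then lexicographically, making the
ranking total and deterministic.  Above 200 candidates a greedy pre-filter
to the 60 best-connected candidates engages with a warning.

Enrichment is the upper-tail hypergeometric test on the log scale, BH-step-up
correction, significance gate adjusted p < 0.05, and single-linkage grouping
of significant terms at Cohen's kappa > 0.4 (strict).  The default universe
is the union of the supplied gene sets; pass the AWM-eligible gene list to
restrict it.  GO-hierarchy level filtering is replaced by optional per-set
size bounds, since no ontology graph is shipped.

## Synthetic data

The generator emulates the *structure* of an imputed-sequence dairy study,
not its scale or biology:

- **Genotypes**: biallelic dosages from a pool of 8 haplotypes per LD block
  (default 25 variants/block).  Sharing pool haplotypes creates within-block
  LD while blocks stay independent — enough to exercise region chaining and
  PCIT redundancy, but it is not a coalescent model: LD decays as a step
  function at block boundaries, and block length is a free parameter, not
  calibrated to any breed's LD.  Realized MAF ≥ 0.01 is enforced by
  resampling; dosages are integers unless a mean-preserving uniform jitter
  (clipped to [0, 2]) emulates imputation uncertainty.  Positions are
  1-based throughout.
- **Phenotypes**: y = Xβ + u + e with u matrix-normal — row covariance the
  realized VanRaden GRM of the simulated genotypes (guaranteeing
  model-consistency between generator and fitter), column covariance
  diag(√h²)·C·diag(√h²) for a target genetic correlation matrix C.  The
  non-causal background has unit variance, so h² is the background
  heritability and causal effects add variance on top.
- **Scenario** (`simulate_pleiotropy_scenario`): 5 causal genes on distinct
  chromosomes where possible, one causal variant each, sized so each variant
  explains 5% of the phenotypic variance of every trait it affects; every
  causal variant hits the key trait and a random three-quarters of the
  others with random signs; background h² = 0.3, compound-symmetric genetic
  correlation 0.5.  These are the planted-truth conditions used by the
  recovery tests and the acceptance script (10 seeds at 2,000 individuals ×
  5,000 variants; the small demo in the README uses 500 × 2,000).

What passing tests show — and do not show: recovery and calibration results
demonstrate internal consistency (the fitter matches the generator's model)
and correct algorithmics (oracle equivalence against brute-force
implementations).  They do not demonstrate robustness to the things real
data add: pedigree structure, genotyping/imputation error beyond uniform
jitter, selection, non-normal phenotypes, test-day repeated records, or
realistic LD decay.

## Defaults

| parameter | default | role |
| --- | --- | --- |
| α | 0.05 | genome-wide error rate before Bonferroni |
| merge_bp | 1,000,000 | QTL chaining gap (strict <) |
| p_cut | 0.001 | AWM key-trait / pleiotropy p-value gate |
| r_cut | 0.25 | trait effect-correlation gate |
| gene window | 10,000 bp | genic assignment flank (inclusive) |
| kappa_cut | 0.4 | enrichment grouping threshold (strict >) |
| pool_size | 8 | haplotypes per LD block |
| ld_block_len | 25 | variants per LD block |

## Known limitations

- No leave-one-chromosome-out GWAS, no dominance or interaction terms.
- QTL calling has no conditional analysis, fine-mapping or credible sets.
- PCIT trait-column choice follows the AWM's retained traits; with very few
  traits the partials are noisy (warned).
- Enrichment has no ontology traversal and no live GO/KEGG retrieval; gene
  sets come from GMT files.
- The simulator draws all randomness from one seed per object; end-to-end
  pipeline runs are byte-reproducible, but the generator's haplotype-pool LD
  model is intentionally simplistic.
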