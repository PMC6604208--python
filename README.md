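# awmnet

Multi-trait mixed-model GWAS, QTL-region calling, association weight matrices
(AWM) and PCIT gene-network inference for quantitative genetics.

## The problem

Dense-variant association studies of many correlated quantitative traits — the
motivating case is milk cheese-making and composition phenotypes measured on
thousands of dairy cows genotyped at millions of imputed sequence variants —
face two complementary questions:

1. **Where are the strong signals?**  Single-trait mixed-model GWAS with a
   stringent genome-wide threshold, followed by collapsing significant
   variants into QTL regions and nominating the best candidate gene in each.
2. **What co-associated gene network underlies the trait complex?**  Signals
   too weak for genome-wide significance still carry information when they
   are shared across traits.  The association weight matrix keeps variants
   that are associated with a key phenotype or pleiotropically with several
   correlated traits, reduces them to one representative variant per gene,
   and the PCIT algorithm turns the gene × trait matrix of standardized
   effects into a gene–gene partial-correlation network whose hubs, regulator
   trios and enriched gene sets can be interrogated.

`awmnet` implements this whole chain as a tested, reusable library plus CLI,
together with a synthetic-data generator with known pleiotropic architecture
so every stage can be validated against planted truth.

## The model

For each trait and each variant the association model is the standard MLMA
mixed linear model

```
y = 1μ + xb + u + e,   u ~ N(0, G σ²ᵤ),   e ~ N(0, I σ²ₑ)
```

with `y` the pre-adjusted phenotypes, `x` the allele dosages in [0, 2], and
`G` the VanRaden genomic relationship matrix `ZZ′/Σ 2pⱼ(1−pⱼ)`.  Variance
components are estimated once per trait by REML on the null model (profiled
1-D search on h² after one eigendecomposition of `G`) and held fixed while
every variant is tested by GLS with a two-sided Wald test; −log₁₀P is
computed on the log scale so it stays finite for arbitrarily strong signals.
Downstream:

- **Bonferroni threshold** α/n_tests (0.05 over 8,551,748 tests ⇒ 5.8 × 10⁻⁹,
  −log₁₀P = 8.2);
- **QTL regions**: significant variants < 1 Mbp apart chained together; region
  bounds span the variants in the upper third of the peak; variance explained
  %σ²ₚ = 100·2p(1−p)α²/σ²ₚ;
- **AWM**: variants with p ≤ 0.001 on the key trait, traits with |r| ≥ 0.25
  effect correlation, rescue of variants significant on ≥ k correlated traits
  (k estimated from the data), ±10 kb gene assignment, one variant per gene;
- **PCIT**: for every gene trio the first-order partial correlations define a
  tolerance ε; an edge survives only if no third gene explains it;
- **regulator trios** by exhaustive coverage search, and **gene-set
  enrichment** by hypergeometric test, Benjamini–Hochberg correction and
  Cohen's-kappa functional grouping.

## Worked example

```python
from awmnet import MlmaGwas, simulate_pleiotropy_scenario

geno, panel, ann, arch, causal = simulate_pleiotropy_scenario(
    n_individuals=500, n_variants=2000, n_traits=8, n_causal_genes=5, seed=4)
results = MlmaGwas(panel, geno).fit()      # model -> results
print(results.summary())
regions = results.call_qtl_regions("trait00")
awm = results.build_awm(ann, "trait00")    # selection funnel
net = awm.pcit_network()                   # PCIT gene network
```

or, equivalently, from the shell:

```
$ awmnet all --seed 4 --out run/
pipeline complete: 2 QTL regions, 10 network genes, 29 edges  (report: run/funnel.json)
```

On this 500-cow × 2,000-variant demo the funnel report shows 16,000
variant × trait tests with a study-wide threshold of −log₁₀P > 5.51, two QTL
regions whose best candidate variants land in `gene0076` and `gene0115`
(both planted causal genes), and an AWM funnel of 17 key-trait variants + 1
rescued pleiotropic variant → 17 genic → 10 genes, giving a PCIT network of
10 nodes and 29 edges.  REML heritabilities per trait (true background
h² = 0.3 plus causal variance) are listed in the same report.  At the full
acceptance scale (2,000 individuals, 5,000 variants) all five planted causal
genes are typically recovered both as QTL best candidates and as network
nodes.

## Layout

| module | contents |
| --- | --- |
| `awmnet.simulate` | genotype/annotation/phenotype generators, scenario builder |
| `awmnet.gwas` | GRM, REML, `MlmaGwas` → `GwasResults`, Wald/Bonferroni helpers |
| `awmnet.qtl` | region chaining, bounds, best candidates, variance explained |
| `awmnet.awm` | effect standardization, selection funnel, `AwMatrix` |
| `awmnet.pcit` | PCIT edge pruning, `GeneNetwork`, centralities |
| `awmnet.regulators` | regulator connectivity and exhaustive trio search |
| `awmnet.enrichment` | hypergeometric ORA, BH, kappa grouping |
| `awmnet.io` | VCF (DS), dosage/phenotype TSV, BED, GMT, GraphML |
| `awmnet.pipeline` / `awmnet.cli` | end-to-end orchestration and CLI |

See `docs/methods.md` for the modelling assumptions, parameter defaults and
known limitations.
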