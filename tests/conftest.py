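import numpy as np
import pandas as pd
import pytest

from awmnet.simulate import (
    GenotypeMatrix,
    TrueArchitecture,
    simulate_gene_annotation,
    simulate_genotypes,
    simulate_phenotypes,
)


@pytest.fixture(scope="session")
def small_geno() -> GenotypeMatrix:
    return simulate_genotypes(200, 500, n_chromosomes=2, maf_bounds=(0.05, 0.5),
                              ld_block_len=25, seed=1)


@pytest.fixture(scope="session")
def null_panel(small_geno):
    """Phenotypes with no causal effects and h2 = 0: pure independent noise."""
    arch = TrueArchitecture(
        causal_effects=np.zeros((small_geno.n_variants, 4)),
        h2=0.0,
        genetic_corr=np.eye(4),
        seed=11,
    )
    return simulate_phenotypes(small_geno, arch)


@pytest.fixture(scope="session")
def small_ann(small_geno):
    genome = {
        c: int(small_geno.variants.loc[small_geno.variants["chrom"] == c, "pos"].max())
        + 50_000
        for c in dict.fromkeys(small_geno.variants["chrom"])
    }
    return simulate_gene_annotation(40, genome, mean_gene_len=15_000,
                                    regulator_fraction=0.2, seed=7)


def make_stats(chrom_pos_nlp: list[tuple[str, int, float]]) -> pd.DataFrame:
    """Summary-statistics frame from (chrom, pos, -log10 p) triples."""
    return pd.DataFrame(
        {
            "id": [f"v{i}" for i in range(len(chrom_pos_nlp))],
            "chrom": [c for c, _, _ in chrom_pos_nlp],
            "pos": [p for _, p, _ in chrom_pos_nlp],
            "neglog10p": [n for _, _, n in chrom_pos_nlp],
        }
    )
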