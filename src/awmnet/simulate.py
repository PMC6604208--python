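"""Seeded synthetic genotypes, gene annotations and multi-trait phenotypes.

The generator emulates the inputs of a dense-variant dairy-cattle association
study: biallelic allele dosages in [0, 2] with local LD blocks, a gene map,
and a panel of genetically correlated traits with a polygenic background
structured by the realized genomic relationship matrix (GRM) plus a small
number of pleiotropic causal variants planted inside genes.  Everything is
deterministic for a fixed seed so that every downstream stage (GWAS, QTL
calling, AWM, PCIT) can be tested against planted truth without external
data.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "GenotypeMatrix",
    "TraitPanel",
    "TrueArchitecture",
    "GeneAnnotation",
    "simulate_genotypes",
    "simulate_gene_annotation",
    "simulate_phenotypes",
    "simulate_gene_sets",
    "simulate_pleiotropy_scenario",
]


@dataclass(frozen=True)
class GenotypeMatrix:
    """Individuals x variants allele dosages with per-variant metadata.

    ``dosages`` is an (n_individuals, n_variants) float array with entries in
    [0, 2]; ``variants`` is a DataFrame with columns
    ``id, chrom, pos, ref, alt, maf`` (positions 1-based, strictly increasing
    within a chromosome); ``individuals`` holds sample identifiers.
    """

    dosages: np.ndarray
    variants: pd.DataFrame
    individuals: list[str]

    def __post_init__(self) -> None:
        d = self.dosages
        if d.ndim != 2:
            raise ValueError("dosages must be a 2-D array")
        if d.shape[0] != len(self.individuals):
            raise ValueError("row count does not match number of individuals")
        if d.shape[1] != len(self.variants):
            raise ValueError("column count does not match variant table")
        if d.size and (np.nanmin(d) < 0 or np.nanmax(d) > 2):
            raise ValueError("dosages must lie in [0, 2]")
        if self.variants["id"].duplicated().any():
            raise ValueError("duplicate variant ids")
        for _, grp in self.variants.groupby("chrom", sort=False):
            pos = grp["pos"].to_numpy()
            if np.any(np.diff(pos) <= 0):
                raise ValueError("positions must be strictly increasing within chromosome")

    @property
    def n_individuals(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_variants(self) -> int:
        return self.dosages.shape[1]

    def alt_freq(self) -> np.ndarray:
        """Realized alternate-allele frequency per variant."""
        return self.dosages.mean(axis=0) / 2.0


@dataclass(frozen=True)
class TraitPanel:
    """Individuals x traits phenotype values (pre-adjusted averages)."""

    values: np.ndarray
    traits: list[str]
    key_trait: str
    individuals: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.values.ndim != 2 or self.values.shape[1] != len(self.traits):
            raise ValueError("values shape does not match trait names")
        if len(set(self.traits)) != len(self.traits):
            raise ValueError("trait names must be unique")
        if self.key_trait not in self.traits:
            raise ValueError(f"key_trait {self.key_trait!r} not among traits")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("phenotypes contain non-finite values")

    @property
    def n_traits(self) -> int:
        return len(self.traits)

    def column(self, trait: str) -> np.ndarray:
        return self.values[:, self.traits.index(trait)]

    def to_frame(self) -> pd.DataFrame:
        idx = self.individuals if self.individuals else range(self.values.shape[0])
        return pd.DataFrame(self.values, columns=self.traits, index=idx)


@dataclass(frozen=True)
class TrueArchitecture:
    """Simulation ground truth: causal effects, heritability, genetic correlations.

    ``causal_effects`` is (n_variants, n_traits) in trait units per alt-allele
    copy; ``h2`` is the per-trait polygenic heritability of the non-causal
    background (scalar or length-n_traits); ``genetic_corr`` is the target
    correlation of the polygenic values across traits.
    """

    causal_effects: np.ndarray
    h2: np.ndarray
    genetic_corr: np.ndarray
    seed: int

    def __post_init__(self) -> None:
        h2 = np.atleast_1d(np.asarray(self.h2, dtype=float))
        if np.any(h2 < 0) or np.any(h2 >= 1):
            raise ValueError("h2 must lie in [0, 1)")
        C = np.asarray(self.genetic_corr, dtype=float)
        if C.shape[0] != C.shape[1] or not np.allclose(C, C.T, atol=1e-10):
            raise ValueError("genetic_corr must be symmetric")
        if not np.allclose(np.diag(C), 1.0, atol=1e-10):
            raise ValueError("genetic_corr must have unit diagonal")
        if np.linalg.eigvalsh(C).min() < -1e-8:
            raise ValueError("genetic_corr must be positive semi-definite")


@dataclass(frozen=True)
class GeneAnnotation:
    """Gene intervals (1-based inclusive) plus candidate-regulator flags."""

    genes: pd.DataFrame  # columns: gene_id, chrom, start, end, strand
    regulator_flags: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        g = self.genes
        if g["gene_id"].duplicated().any():
            raise ValueError("duplicate gene ids")
        if (g["start"] > g["end"]).any():
            raise ValueError("gene start must not exceed end")
        unknown = set(self.regulator_flags) - set(g["gene_id"])
        if unknown:
            raise ValueError(f"regulator flags for unknown genes: {sorted(unknown)}")

    @property
    def n_genes(self) -> int:
        return len(self.genes)


def simulate_genotypes(
    n_individuals: int,
    n_variants: int,
    n_chromosomes: int = 1,
    maf_bounds: tuple[float, float] = (0.05, 0.5),
    ld_block_len: int = 25,
    seed: int = 0,
    pool_size: int = 8,
    dosage_jitter: float = 0.0,
    min_gap: int = 500,
    max_gap: int = 5000,
) -> GenotypeMatrix:
    """Simulate dosages with within-block LD from a small haplotype pool.

    Each LD block of ``ld_block_len`` consecutive variants carries a pool of
    ``pool_size`` haplotypes; every individual copies two pool haplotypes per
    block, so variants within a block are correlated while blocks are
    independent.  Realized MAF >= 0.01 is enforced by resampling the offending
    pool column.  ``dosage_jitter`` adds mean-preserving uniform noise on
    [-j, j] (clipped to [0, 2]) emulating imputation dosage uncertainty.
    """
    lo, hi = maf_bounds
    if not (0 < lo <= hi <= 0.5):
        raise ValueError(f"maf_bounds must satisfy 0 < lo <= hi <= 0.5, got {maf_bounds}")
    if n_variants <= 0:
        raise ValueError("n_variants must be positive")
    if n_individuals < 2:
        raise ValueError("need at least 2 individuals")
    if ld_block_len < 1:
        raise ValueError("ld_block_len must be >= 1")

    rng = np.random.default_rng(seed)
    dosages = np.empty((n_individuals, n_variants), dtype=float)

    start = 0
    while start < n_variants:
        blen = min(ld_block_len, n_variants - start)
        freqs = rng.uniform(lo, hi, size=blen)
        pool = (rng.random((pool_size, blen)) < freqs).astype(float)
        hap_idx = rng.integers(0, pool_size, size=(n_individuals, 2))
        block = pool[hap_idx[:, 0]] + pool[hap_idx[:, 1]]

        # enforce realized MAF >= 0.01 by resampling pool columns
        for _ in range(1000):
            p = block.mean(axis=0) / 2.0
            bad = np.minimum(p, 1 - p) < 0.01
            if not bad.any():
                break
            cols = np.where(bad)[0]
            pool[:, cols] = (
                rng.random((pool_size, len(cols))) < rng.uniform(0.3, 0.5, len(cols))
            ).astype(float)
            block[:, cols] = pool[hap_idx[:, 0]][:, cols] + pool[hap_idx[:, 1]][:, cols]
        else:  # pragma: no cover - astronomically unlikely
            raise RuntimeError("could not achieve MAF >= 0.01 within resampling budget")

        dosages[:, start : start + blen] = block
        start += blen

    if dosage_jitter > 0:
        dosages = np.clip(
            dosages + rng.uniform(-dosage_jitter, dosage_jitter, dosages.shape), 0.0, 2.0
        )

    # variant metadata: split across chromosomes, strictly increasing positions
    per_chrom = np.full(n_chromosomes, n_variants // n_chromosomes)
    per_chrom[: n_variants % n_chromosomes] += 1
    chroms: list[str] = []
    positions: list[int] = []
    for c, k in enumerate(per_chrom, start=1):
        gaps = rng.integers(min_gap, max_gap + 1, size=k)
        pos = np.cumsum(gaps)
        chroms.extend([str(c)] * k)
        positions.extend(pos.tolist())

    p = dosages.mean(axis=0) / 2.0
    maf = np.minimum(p, 1 - p)
    alleles = np.array(["A", "C", "G", "T"])
    ref = alleles[rng.integers(0, 4, n_variants)]
    alt = np.array([alleles[(np.flatnonzero(alleles == r)[0] + 1) % 4] for r in ref])
    variants = pd.DataFrame(
        {
            "id": [f"snp_{c}_{p_}" for c, p_ in zip(chroms, positions)],
            "chrom": chroms,
            "pos": positions,
            "ref": ref,
            "alt": alt,
            "maf": maf,
        }
    )
    individuals = [f"ind{i:05d}" for i in range(n_individuals)]
    return GenotypeMatrix(dosages=dosages, variants=variants, individuals=individuals)


def simulate_gene_annotation(
    n_genes: int,
    genome: dict[str, int],
    mean_gene_len: int = 20_000,
    regulator_fraction: float = 0.1,
    seed: int = 0,
) -> GeneAnnotation:
    """Place ``n_genes`` non-overlapping gene intervals uniformly on a genome.

    Genes are apportioned to chromosomes proportionally to length; a fixed
    fraction (rounded) is flagged as candidate regulators, standing in for
    TF/miRNA/lncRNA lists.
    """
    if n_genes < 1:
        raise ValueError("n_genes must be >= 1")
    rng = np.random.default_rng(seed)
    chrom_names = list(genome)
    lengths = np.array([genome[c] for c in chrom_names], dtype=float)
    if np.any(lengths <= 0):
        raise ValueError("chromosome lengths must be positive")
    # proportional apportionment with largest-remainder rounding
    quota = n_genes * lengths / lengths.sum()
    counts = np.floor(quota).astype(int)
    for i in np.argsort(-(quota - counts))[: n_genes - counts.sum()]:
        counts[i] += 1

    rows = []
    gid = 0
    for cname, clen, k in zip(chrom_names, lengths.astype(int), counts):
        if k == 0:
            continue
        glens = np.maximum(200, rng.gamma(shape=2.0, scale=mean_gene_len / 2.0, size=k)).astype(int)
        free = clen - glens.sum()
        if free < k:
            raise ValueError(
                f"chromosome {cname} too short to place {k} disjoint genes "
                f"(total gene length {glens.sum()} vs length {clen})"
            )
        # stick-breaking placement: distribute free space as random gaps
        cuts = np.sort(rng.integers(1, free, size=k))
        starts = cuts + np.concatenate([[0], np.cumsum(glens[:-1])])
        for s, L in zip(starts, glens):
            rows.append((f"gene{gid:04d}", cname, int(s), int(s + L - 1), "+" if rng.random() < 0.5 else "-"))
            gid += 1
    genes = pd.DataFrame(rows, columns=["gene_id", "chrom", "start", "end", "strand"])

    n_reg = int(round(regulator_fraction * n_genes))
    flags: frozenset[str] = frozenset()
    if n_reg > 0:
        flags = frozenset(rng.choice(genes["gene_id"].to_numpy(), size=n_reg, replace=False))
    return GeneAnnotation(genes=genes, regulator_flags=flags)


def simulate_phenotypes(g: GenotypeMatrix, arch: TrueArchitecture) -> TraitPanel:
    """Draw phenotypes y_t = X beta_t + u_t + e_t under the mixed-model assumption.

    The polygenic values u are matrix-normal with row covariance the realized
    VanRaden GRM of ``g`` and column covariance diag(sqrt(h2)) * genetic_corr
    * diag(sqrt(h2)); residuals are independent with variance 1 - h2, so the
    non-causal background of each trait has unit variance and heritability h2.
    Causal effects add on top of that baseline.
    """
    from .gwas import compute_grm  # local import to avoid a cycle

    beta = np.asarray(arch.causal_effects, dtype=float)
    if beta.shape[0] != g.n_variants:
        raise ValueError("causal_effects row count must equal number of variants")
    n, T = g.n_individuals, beta.shape[1]
    h2 = np.broadcast_to(np.atleast_1d(np.asarray(arch.h2, dtype=float)), (T,)).copy()
    C = np.asarray(arch.genetic_corr, dtype=float)
    if C.shape != (T, T):
        raise ValueError("genetic_corr shape does not match number of traits")

    rng = np.random.default_rng(arch.seed)
    genetic = np.zeros((n, T))
    if np.any(h2 > 0):
        grm = compute_grm(g)
        w, U = np.linalg.eigh(grm.matrix)
        w = np.clip(w, 0.0, None)
        A = U * np.sqrt(w)  # A @ A.T = G
        ew, EV = np.linalg.eigh(C)
        ew = np.clip(ew, 0.0, None)
        B = EV * np.sqrt(ew)  # B @ B.T = C
        Z = rng.standard_normal((n, T))
        genetic = (A @ Z @ B.T) * np.sqrt(h2)[None, :]
    noise = rng.standard_normal((n, T)) * np.sqrt(1.0 - h2)[None, :]
    values = g.dosages @ beta + genetic + noise

    traits = [f"trait{t:02d}" for t in range(T)]
    return TraitPanel(values=values, traits=traits, key_trait=traits[0], individuals=list(g.individuals))


def simulate_gene_sets(
    ann: GeneAnnotation,
    n_sets: int = 20,
    size_range: tuple[int, int] = (5, 40),
    seed: int = 0,
) -> dict[str, list[str]]:
    """Random gene sets over the annotated genes, GMT-style (term -> members)."""
    rng = np.random.default_rng(seed)
    genes = ann.genes["gene_id"].to_numpy()
    lo, hi = size_range
    hi = min(hi, len(genes))
    sets = {}
    for i in range(n_sets):
        k = int(rng.integers(lo, hi + 1))
        sets[f"SET{i:03d}"] = sorted(rng.choice(genes, size=k, replace=False).tolist())
    return sets


def simulate_pleiotropy_scenario(
    n_individuals: int = 2000,
    n_variants: int = 5000,
    n_traits: int = 8,
    n_chromosomes: int = 5,
    n_causal_genes: int = 5,
    var_explained: float = 0.05,
    h2: float = 0.3,
    background_corr: float = 0.5,
    n_genes: int = 150,
    seed: int = 0,
) -> tuple[GenotypeMatrix, TraitPanel, GeneAnnotation, TrueArchitecture, list[str]]:
    """A complete study scenario with planted pleiotropic causal genes.

    Picks ``n_causal_genes`` genes that contain at least one variant (on
    distinct chromosomes when possible) and plants one causal variant inside
    each, sized so that it explains a ``var_explained`` fraction of the
    phenotypic variance of every trait it affects.  Every causal variant
    affects the key trait (trait00) and a random majority of the remaining
    traits with random effect signs, creating the pleiotropic co-association
    structure the AWM/PCIT stages are designed to recover.

    Returns (genotypes, phenotypes, annotation, architecture, causal gene ids).
    """
    ss = np.random.SeedSequence(seed)
    s_geno, s_ann, s_pick, s_pheno = [int(s.generate_state(1)[0] % 2**31) for s in ss.spawn(4)]

    geno = simulate_genotypes(
        n_individuals, n_variants, n_chromosomes=n_chromosomes, seed=s_geno
    )
    genome = {
        str(c): int(geno.variants.loc[geno.variants["chrom"] == str(c), "pos"].max()) + 100_000
        for c in range(1, n_chromosomes + 1)
    }
    # keep the gene catalogue placeable on small demo genomes: genes occupy
    # at most ~a quarter of the sequence
    total_bp = sum(genome.values())
    mean_len = int(max(1000, min(20_000, total_bp // (4 * n_genes))))
    ann = simulate_gene_annotation(
        n_genes, genome, mean_gene_len=mean_len, regulator_fraction=0.15, seed=s_ann
    )

    rng = np.random.default_rng(s_pick)
    var_by_chrom = {c: grp for c, grp in geno.variants.groupby("chrom", sort=False)}
    # genes that contain at least one simulated variant
    candidates: list[tuple[str, str, int]] = []  # (gene_id, chrom, variant_index)
    for row in ann.genes.itertuples(index=False):
        grp = var_by_chrom.get(row.chrom)
        if grp is None:
            continue
        inside = grp[(grp["pos"] >= row.start) & (grp["pos"] <= row.end)]
        if len(inside):
            mid = (row.start + row.end) // 2
            j = (inside["pos"] - mid).abs().idxmin()
            candidates.append((row.gene_id, row.chrom, int(geno.variants.index.get_loc(j))))
    if len(candidates) < n_causal_genes:
        raise ValueError("not enough genes containing variants; increase n_genes or density")

    # prefer spreading causal genes over distinct chromosomes
    rng.shuffle(candidates)
    chosen: list[tuple[str, str, int]] = []
    used_chroms: set[str] = set()
    for cand in candidates:
        if cand[1] not in used_chroms:
            chosen.append(cand)
            used_chroms.add(cand[1])
        if len(chosen) == n_causal_genes:
            break
    for cand in candidates:
        if len(chosen) == n_causal_genes:
            break
        if cand not in chosen:
            chosen.append(cand)

    beta = np.zeros((n_variants, n_traits))
    p = geno.alt_freq()
    affects = np.zeros((n_causal_genes, n_traits), dtype=bool)
    affects[:, 0] = True  # every causal variant hits the key trait
    for i in range(n_causal_genes):
        others = rng.choice(np.arange(1, n_traits), size=max(1, (n_traits - 1) * 3 // 4), replace=False)
        affects[i, others] = True
    m_per_trait = affects.sum(axis=0)
    for t in range(n_traits):
        m = m_per_trait[t]
        if m == 0:
            continue
        # each causal variant explains var_explained of the trait's total variance:
        # per-variant genic variance v solves v = q * (1 + m v)  =>  v = q / (1 - m q)
        v = var_explained / (1.0 - m * var_explained)
        for i in range(n_causal_genes):
            if not affects[i, t]:
                continue
            j = chosen[i][2]
            mag = np.sqrt(v / (2.0 * p[j] * (1.0 - p[j])))
            beta[j, t] = mag * (1 if rng.random() < 0.5 else -1)

    C = np.full((n_traits, n_traits), background_corr)
    np.fill_diagonal(C, 1.0)
    arch = TrueArchitecture(causal_effects=beta, h2=np.full(n_traits, h2), genetic_corr=C, seed=s_pheno)
    panel = simulate_phenotypes(geno, arch)
    causal_genes = [c[0] for c in chosen]
    return geno, panel, ann, arch, causal_genes
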