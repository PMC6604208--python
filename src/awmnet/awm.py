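"""Association weight matrix (AWM) construction from multi-trait GWAS results.

Starting from the full variants x traits matrices of z-score-standardized
additive effects and p-values, the AWM procedure

1. keeps variants associated with the key phenotype (p <= p_cut),
2. keeps traits whose effect vectors correlate with the key trait (|r| >= r_cut),
3. estimates k, the average number of other selected traits those variants hit
   at the same p_cut, and rescues variants significant on at least k traits,
4. keeps only variants within (or within 10 kb of) genes, and
5. retains one variant per gene: most supported traits, ties broken by the
   lowest sum of p-values, then the lower position.

The resulting gene x trait matrix of standardized effects is the input of the
PCIT network stage; a funnel of counts is kept at every step for auditing.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import TYPE_CHECKING

import numpy as np
import pandas as pd

from .simulate import GeneAnnotation

if TYPE_CHECKING:  # pragma: no cover
    from .pcit import GeneNetwork

__all__ = [
    "AwMatrix",
    "build_effect_matrices",
    "select_key_trait_snps",
    "select_correlated_traits",
    "estimate_avg_support",
    "rescue_pleiotropic_snps",
    "assign_genes",
    "dedupe_per_gene",
    "awm_trait_correlations",
    "build_awm",
]


@dataclass
class AwMatrix:
    """One representative variant per gene x selected traits, standardized effects."""

    z: pd.DataFrame  # index: variant id, columns: selected traits
    pvals: pd.DataFrame  # same shape/labels
    key_trait: str
    gene_of: dict[str, str]  # variant id -> gene id
    support: pd.Series  # per variant: count of selected traits with p <= p_cut
    funnel: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.z.shape != self.pvals.shape or list(self.z.index) != list(self.pvals.index):
            raise ValueError("z and p matrices must share shape and labels")
        if self.key_trait not in self.z.columns:
            raise ValueError("key trait missing from columns")
        if len(set(self.gene_of.values())) != len(self.gene_of):
            raise ValueError("a gene may carry only one representative variant")

    @property
    def genes(self) -> list[str]:
        return [self.gene_of[v] for v in self.z.index]

    @property
    def selected_traits(self) -> list[str]:
        return list(self.z.columns)

    def pcit_network(self, **kwargs) -> "GeneNetwork":
        """Infer the PCIT gene-gene partial-correlation network from AWM rows."""
        from .pcit import build_network, pcit_edges

        zg = self.z.copy()
        zg.index = pd.Index(self.genes)
        edges = pcit_edges(zg, **kwargs)
        attrs = {
            g: {"variant": v, "support": int(self.support[v])}
            for v, g in self.gene_of.items()
        }
        return build_network(edges, list(zg.index), node_attrs=attrs)


def build_effect_matrices(
    effects: pd.DataFrame, pvalues: pd.DataFrame, t_scores: bool = False, se: pd.DataFrame | None = None
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Standardize additive effects column-wise into z-scores.

    Per trait column, z = (b - mean(b)) / sd(b) over variants (sample sd,
    denominator n-1).  With ``t_scores`` the alternative b/se scaling is used
    instead; per-column correlations and PCIT are invariant to the choice.
    Columns with zero spread raise.
    """
    if t_scores:
        if se is None:
            raise ValueError("t_scores standardization requires the se matrix")
        z = effects / se
    else:
        sd = effects.std(axis=0, ddof=1)
        if (sd == 0).any() or sd.isna().any():
            bad = sd.index[(sd == 0) | sd.isna()].tolist()
            raise ValueError(f"zero-variance effect column(s): {bad}")
        z = (effects - effects.mean(axis=0)) / sd
    return z, pvalues.copy()


def select_key_trait_snps(pvals: pd.DataFrame, key_trait: str, p_cut: float = 0.001) -> pd.Index:
    """Variants associated with the key phenotype at p <= p_cut (inclusive)."""
    if key_trait not in pvals.columns:
        raise ValueError(f"key trait {key_trait!r} not in p-value matrix")
    mask = pvals[key_trait] <= p_cut
    return pvals.index[mask]


def select_correlated_traits(
    z: pd.DataFrame, key_trait: str, r_cut: float = 0.25
) -> list[str]:
    """Traits whose effect vectors satisfy |r| >= r_cut with the key trait.

    Correlations are computed over the supplied (key-selected) variant rows;
    the key trait is always included.  Fewer than 3 rows raise.
    """
    if len(z) < 3:
        raise ValueError("need at least 3 variants to estimate trait correlations")
    r = z.corrwith(z[key_trait])
    keep = [t for t in z.columns if t == key_trait or abs(r[t]) >= r_cut]
    return keep


def estimate_avg_support(
    pvals: pd.DataFrame, key_trait: str, traits: list[str], p_cut: float = 0.001
) -> int:
    """Average number of non-key selected traits hit at p <= p_cut, rounded, >= 1.

    The rows of ``pvals`` are the key-selected variants.  This realizes the
    "on average, k other phenotypes were associated with these SNPs" step; k
    is always recomputed from data, never hard-coded.
    """
    if len(pvals) == 0:
        raise ValueError("empty variant selection")
    others = [t for t in traits if t != key_trait]
    counts = (pvals[others] <= p_cut).sum(axis=1)
    return max(1, int(round(float(counts.mean()))))


def rescue_pleiotropic_snps(
    pvals: pd.DataFrame,
    key_trait: str,
    traits: list[str],
    k: int,
    p_cut: float = 0.001,
    exclude: pd.Index | None = None,
) -> pd.Index:
    """Variants (outside ``exclude``) significant on >= k non-key selected traits."""
    if k < 1:
        raise ValueError("k must be >= 1")
    others = [t for t in traits if t != key_trait]
    counts = (pvals[others] <= p_cut).sum(axis=1)
    idx = pvals.index[counts >= k]
    if exclude is not None:
        idx = idx.difference(exclude, sort=False)
    return idx


def assign_genes(
    variants: pd.DataFrame, ann: GeneAnnotation, window: int = 10_000
) -> dict[str, str]:
    """Map variants to genes within +/- window bp (1-based inclusive bounds).

    Variants mapping to no gene are dropped; multi-gene hits resolve to the
    nearest gene body, ties to the lower gene start.  ``variants`` needs
    columns ``id, chrom, pos``.
    """
    from .qtl import _variant_gene_hits

    mapping: dict[str, str] = {}
    for chrom, grp in variants.groupby("chrom", sort=False):
        hits = _variant_gene_hits(grp["pos"].to_numpy(), str(chrom), ann, window)
        starts = ann.genes.set_index("gene_id")["start"]
        for vid, h in zip(grp["id"], hits):
            if h:
                gene = min(h, key=lambda x: (x[1], starts[x[0]]))[0]
                mapping[str(vid)] = gene
    return mapping


def dedupe_per_gene(
    z: pd.DataFrame,
    pvals: pd.DataFrame,
    gene_of: dict[str, str],
    positions: pd.Series,
    p_cut: float = 0.001,
) -> AwMatrix:
    """Retain one variant per gene.

    Primary criterion: the variant supported by the largest number of selected
    traits at p <= p_cut; ties break to the lowest sum of p-values over the
    selected traits, residual ties to the lower position.  Output is invariant
    to input row order.
    """
    support = (pvals <= p_cut).sum(axis=1)
    psum = pvals.sum(axis=1)
    chosen: dict[str, str] = {}
    for vid in z.index:
        gene = gene_of.get(str(vid))
        if gene is None:
            continue
        cur = chosen.get(gene)
        if cur is None:
            chosen[gene] = vid
            continue
        a = (-support[vid], psum[vid], positions[vid], str(vid))
        b = (-support[cur], psum[cur], positions[cur], str(cur))
        if a < b:
            chosen[gene] = vid
    keep = sorted(chosen.values(), key=lambda v: str(v))
    return AwMatrix(
        z=z.loc[keep],
        pvals=pvals.loc[keep],
        key_trait=z.columns[0],
        gene_of={str(v): g for g, v in chosen.items()},
        support=support.loc[keep],
    )


def awm_trait_correlations(awm: AwMatrix) -> pd.DataFrame:
    """Pearson correlations between trait columns over the retained gene rows.

    The analogue of comparing AWM-derived trait correlations with pedigree
    genetic correlations: with enough informative genes the standardized
    effect correlations track the genetic correlations between traits.
    """
    if len(awm.z) < 3:
        raise ValueError("need at least 3 retained genes")
    return awm.z.corr()


def build_awm(
    results,
    ann: GeneAnnotation,
    key_trait: str,
    p_cut: float = 0.001,
    r_cut: float = 0.25,
    window: int = 10_000,
    k: int | None = None,
    t_scores: bool = False,
) -> AwMatrix:
    """Run the complete AWM selection funnel on :class:`~awmnet.gwas.GwasResults`.

    Records counts at every stage (key-selected, rescued, union, genic,
    deduped genes) in ``funnel``.
    """
    z_all, p_all = build_effect_matrices(
        results.effects, results.pvalues, t_scores=t_scores, se=results.se
    )
    key_idx = select_key_trait_snps(p_all, key_trait, p_cut)
    if len(key_idx) < 3:
        raise ValueError(
            f"only {len(key_idx)} variants pass p <= {p_cut} on {key_trait!r}; AWM needs >= 3"
        )
    traits = select_correlated_traits(z_all.loc[key_idx], key_trait, r_cut)
    if k is None:
        k = estimate_avg_support(p_all.loc[key_idx, traits], key_trait, traits, p_cut)
    rescued = rescue_pleiotropic_snps(
        p_all[traits], key_trait, traits, k, p_cut, exclude=key_idx
    )
    selected = key_idx.append(rescued)

    geno = results.model.genotypes
    vmeta = geno.variants.set_index("id").loc[selected].reset_index()
    gene_of = assign_genes(vmeta, ann, window=window)
    genic = [v for v in selected if str(v) in gene_of]

    positions = geno.variants.set_index("id")["pos"]
    awm = dedupe_per_gene(
        z_all.loc[genic, traits], p_all.loc[genic, traits], gene_of, positions, p_cut
    )
    awm.key_trait = key_trait
    awm.funnel = {
        "key_selected": int(len(key_idx)),
        "rescued": int(len(rescued)),
        "selected_union": int(len(selected)),
        "genic": int(len(genic)),
        "genes": int(len(awm.z)),
        "selected_traits": int(len(traits)),
        "k_support": int(k),
    }
    return awm
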