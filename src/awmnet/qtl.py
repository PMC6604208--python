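"""QTL-region calling from single-trait GWAS summary statistics.

Significant variants (above a -log10 P threshold) are chained into regions by
single linkage: consecutive significant variants on the same chromosome less
than ``merge_bp`` apart share a region.  Region confidence bounds span the
variants in the upper third of the peak (-log10 P >= 2/3 of the region
maximum).  Region-level summaries mirror a classical QTL table: the best
(genic) candidate variant, the percentage of phenotypic variance explained,
and the number of traits affected per trait group.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .simulate import GeneAnnotation

__all__ = [
    "QtlRegion",
    "call_qtl_regions",
    "region_bounds",
    "pct_phenotypic_variance",
    "select_best_candidate",
    "count_affected_traits",
    "summarize_regions",
]

#: ranking of variant consequence classes when one variant maps near several genes
CONSEQUENCE_PRIORITY = [
    "missense",
    "synonymous",
    "utr",
    "intron",
    "genic",
    "upstream",
    "downstream",
    "intergenic",
]


@dataclass
class QtlRegion:
    """One chained association signal on a single chromosome."""

    chromosome: str
    start: int
    end: int
    members: list[str]
    peak_id: str
    peak_neglog10p: float
    best_candidate: tuple[str, str | None, str] | None = None
    traits_affected: dict[str, int] = field(default_factory=dict)
    pct_var: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError("region start must not exceed end")

    @property
    def n_members(self) -> int:
        return len(self.members)


def _check_sorted(stats: pd.DataFrame) -> None:
    for _, grp in stats.groupby("chrom", sort=False):
        if np.any(np.diff(grp["pos"].to_numpy()) <= 0):
            raise ValueError("summary statistics must be sorted by chromosome and position")


def call_qtl_regions(
    stats: pd.DataFrame,
    neglog10_threshold: float,
    merge_bp: int = 1_000_000,
) -> list[QtlRegion]:
    """Chain significant variants (< merge_bp apart, strict) into regions.

    ``stats`` needs columns ``id, chrom, pos, neglog10p`` sorted by chromosome
    and position (unsorted input raises — no silent sorting).  Regions never
    span chromosomes.  Bounds come from :func:`region_bounds`.
    """
    required = {"id", "chrom", "pos", "neglog10p"}
    if not required.issubset(stats.columns):
        raise ValueError(f"stats must have columns {sorted(required)}")
    _check_sorted(stats)

    regions: list[QtlRegion] = []
    sig = stats[stats["neglog10p"] > neglog10_threshold]
    for chrom, grp in sig.groupby("chrom", sort=False):
        pos = grp["pos"].to_numpy()
        breaks = np.where(np.diff(pos) >= merge_bp)[0]  # gap >= merge_bp splits (strict "<" merges)
        starts = np.concatenate([[0], breaks + 1])
        ends = np.concatenate([breaks, [len(pos) - 1]])
        for s, e in zip(starts, ends):
            chunk = grp.iloc[s : e + 1]
            peak = chunk.loc[chunk["neglog10p"].idxmax()]
            lo, hi = region_bounds(chunk)
            regions.append(
                QtlRegion(
                    chromosome=str(chrom),
                    start=int(lo),
                    end=int(hi),
                    members=chunk["id"].tolist(),
                    peak_id=str(peak["id"]),
                    peak_neglog10p=float(peak["neglog10p"]),
                )
            )
    return regions


def region_bounds(members: pd.DataFrame) -> tuple[int, int]:
    """Bounds from the upper third of the peak: min/max position of members
    with -log10 P >= (2/3) * regional maximum."""
    if len(members) == 0:
        raise ValueError("region has no members")
    nlp = members["neglog10p"].to_numpy()
    cutoff = (2.0 / 3.0) * nlp.max()
    top = members[nlp >= cutoff]
    return int(top["pos"].min()), int(top["pos"].max())


def pct_phenotypic_variance(p: float, alpha: float, sigma2_P: float) -> float:
    """Percentage of phenotypic variance explained: 100 * 2 p (1-p) alpha^2 / sigma2_P.

    ``p`` is the allele frequency and ``alpha`` the allele-substitution effect
    of the region's most significant variant for the trait.  The result is not
    capped at 100; values above 100 flag inconsistent inputs to the caller.
    """
    if not 0.0 <= p <= 1.0:
        raise ValueError("allele frequency must lie in [0, 1]")
    if sigma2_P <= 0:
        raise ValueError("phenotypic variance must be positive")
    return 100.0 * 2.0 * p * (1.0 - p) * alpha**2 / sigma2_P


def _variant_gene_hits(
    positions: np.ndarray, chrom: str, ann: GeneAnnotation, window: int
) -> list[list[tuple[str, int, str]]]:
    """Per variant: (gene_id, distance to gene body, consequence class) hits."""
    genes = ann.genes[ann.genes["chrom"] == chrom]
    out: list[list[tuple[str, int, str]]] = [[] for _ in positions]
    if len(genes) == 0:
        return out
    gs = genes["start"].to_numpy()
    ge = genes["end"].to_numpy()
    gid = genes["gene_id"].to_numpy()
    for i, pos in enumerate(positions):
        inside = (pos >= gs - window) & (pos <= ge + window)
        for j in np.flatnonzero(inside):
            if gs[j] <= pos <= ge[j]:
                out[i].append((gid[j], 0, "genic"))
            elif pos < gs[j]:
                out[i].append((gid[j], int(gs[j] - pos), "upstream"))
            else:
                out[i].append((gid[j], int(pos - ge[j]), "downstream"))
    return out


def select_best_candidate(
    region: QtlRegion,
    stats: pd.DataFrame,
    ann: GeneAnnotation,
    window: int = 10_000,
) -> tuple[str, str | None, str]:
    """Best candidate variant: the genic member with the highest -log10 P.

    A member is genic when it lies within a gene or its +/- ``window`` flank.
    Intergenic variants are discarded unless no member is genic, in which case
    the overall peak is returned with gene = None.  Ties in -log10 P break to
    the lower position; a variant near several genes resolves to the nearest
    gene body (ties to the lower gene start).
    """
    if not region.members:
        raise ValueError("region has no members")
    mem = stats.set_index("id").loc[region.members].reset_index()
    hits = _variant_gene_hits(mem["pos"].to_numpy(), region.chromosome, ann, window)

    best: tuple[float, int, str, str, str] | None = None  # (-nlp, pos, id, gene, csq)
    for row, h in zip(mem.itertuples(index=False), hits):
        if not h:
            continue
        gene, _, csq = min(h, key=lambda x: (x[1], x[0]))
        key = (-float(row.neglog10p), int(row.pos), str(row.id), gene, csq)
        if best is None or key[:2] < best[:2]:
            best = key
    if best is not None:
        return best[2], best[3], best[4]
    peak = mem.loc[mem["neglog10p"].idxmax()]
    return str(peak["id"]), None, "intergenic"


def count_affected_traits(
    region: QtlRegion,
    neglog10p: pd.DataFrame,
    threshold: float,
    trait_groups: dict[str, str] | None = None,
    peak_only: bool = False,
) -> dict[str, int]:
    """Traits on which the region has a significant effect, counted per group.

    A region affects a trait when any member variant (or only the peak when
    ``peak_only``) exceeds the threshold for that trait.  ``trait_groups``
    maps trait -> group label; unknown traits raise.
    """
    traits = list(neglog10p.columns)
    if trait_groups is None:
        trait_groups = {t: "all" for t in traits}
    unknown = set(traits) - set(trait_groups)
    if unknown:
        raise ValueError(f"traits missing from group mapping: {sorted(unknown)}")
    rows = [region.peak_id] if peak_only else region.members
    sub = neglog10p.loc[rows]
    affected = (sub > threshold).any(axis=0)
    counts: dict[str, int] = {g: 0 for g in dict.fromkeys(trait_groups.values())}
    for t in traits:
        if affected[t]:
            counts[trait_groups[t]] += 1
    return counts


def summarize_regions(
    results,
    trait: str,
    ann: GeneAnnotation,
    neglog10_threshold: float | None = None,
    merge_bp: int = 1_000_000,
    window: int = 10_000,
    trait_groups: dict[str, str] | None = None,
) -> list[QtlRegion]:
    """Full region-level summary for one discovery trait.

    Calls regions from ``results`` (a :class:`~awmnet.gwas.GwasResults`), then
    fills in the best candidate, per-group affected-trait counts, and the
    percentage of phenotypic variance explained for every trait the region
    affects (using that trait's most significant member variant).
    """
    if neglog10_threshold is None:
        neglog10_threshold = results.bonferroni()[1]
    stats = results.to_frame(trait)
    regions = call_qtl_regions(stats, neglog10_threshold, merge_bp=merge_bp)
    geno = results.model.genotypes
    freq = pd.Series(geno.alt_freq(), index=geno.variants["id"])
    pheno_var = {
        t: float(np.var(results.model.panel.column(t), ddof=1)) for t in results.traits
    }
    for reg in regions:
        reg.best_candidate = select_best_candidate(reg, stats, ann, window=window)
        reg.traits_affected = count_affected_traits(
            reg, results.neglog10p, neglog10_threshold, trait_groups
        )
        sub_nlp = results.neglog10p.loc[reg.members]
        for t in results.traits:
            col = sub_nlp[t]
            if (col > neglog10_threshold).any():
                vid = col.idxmax()
                alpha = float(results.effects.loc[vid, t])
                reg.pct_var[t] = pct_phenotypic_variance(
                    float(freq[vid]), alpha, pheno_var[t]
                )
    return regions


def regions_to_frame(regions: list[QtlRegion]) -> pd.DataFrame:
    """Flatten regions into a report table (one row per region)."""
    rows = []
    for i, r in enumerate(regions, start=1):
        cand = r.best_candidate or (r.peak_id, None, "")
        rows.append(
            {
                "region": i,
                "chrom": r.chromosome,
                "start": r.start,
                "end": r.end,
                "n_variants": r.n_members,
                "peak_id": r.peak_id,
                "peak_neglog10p": r.peak_neglog10p,
                "best_variant": cand[0],
                "best_gene": cand[1] if cand[1] is not None else "-",
                "consequence": cand[2],
                **{f"n_traits_{g}": n for g, n in r.traits_affected.items()},
            }
        )
    return pd.DataFrame(rows)
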