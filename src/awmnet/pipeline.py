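"""End-to-end orchestration: simulate/load -> GWAS -> QTL -> AWM -> PCIT ->
regulator trios -> enrichment, with a reproducible funnel report.

All stage outputs are written to a run directory; a JSON funnel report keeps
the selection counts at every AWM stage together with the QTL and network
sizes, and every stochastic step draws from one seeded generator so that the
same config and seed give byte-identical reports.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as awio
from .awm import awm_trait_correlations
from .gwas import MlmaGwas
from .pcit import centralities
from .qtl import regions_to_frame, summarize_regions
from .regulators import best_trios, trios_to_frame
from .simulate import (
    simulate_gene_sets,
    simulate_pleiotropy_scenario,
)

__all__ = ["PipelineConfig", "run_pipeline"]

log = logging.getLogger("awmnet")


@dataclass
class PipelineConfig:
    """Every tunable of the analysis with its conventional default.

    File paths may be None, in which case the corresponding input is
    simulated (genotypes/phenotypes/annotation/gene sets) from ``seed``.
    """

    genotypes: str | None = None
    phenotypes: str | None = None
    annotation: str | None = None
    gene_sets: str | None = None
    regulators: str | None = None
    key_trait: str | None = None
    alpha: float = 0.05
    p_cut: float = 0.001
    r_cut: float = 0.25
    gene_window: int = 10_000
    merge_bp: int = 1_000_000
    kappa_cut: float = 0.4
    seed: int = 0
    # simulation sizes, used only when inputs are not supplied
    sim: dict = field(default_factory=dict)

    def validate(self) -> None:
        for name, val, lo, hi in [
            ("alpha", self.alpha, 0.0, 1.0),
            ("p_cut", self.p_cut, 0.0, 1.0),
            ("r_cut", self.r_cut, 0.0, 1.0),
            ("kappa_cut", self.kappa_cut, -1.0, 1.0),
        ]:
            if not (lo < val <= hi) and not (name == "kappa_cut" and lo <= val <= hi):
                raise ValueError(f"{name}={val} outside its valid range ({lo}, {hi}]")
        if self.gene_window < 0 or self.merge_bp <= 0:
            raise ValueError("gene_window must be >= 0 and merge_bp > 0")
        for p in (self.genotypes, self.phenotypes, self.annotation, self.gene_sets, self.regulators):
            if p is not None and not Path(p).exists():
                raise FileNotFoundError(p)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        return cls(**data)


def run_pipeline(cfg: PipelineConfig, outdir: str | Path) -> dict:
    """Execute every stage in order and return the funnel report dict.

    Any stage failure aborts with the stage name and cause; partial outputs
    written so far are retained in ``outdir``.
    """
    cfg.validate()
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {"parameters": {
        "alpha": cfg.alpha, "p_cut": cfg.p_cut, "r_cut": cfg.r_cut,
        "gene_window": cfg.gene_window, "merge_bp": cfg.merge_bp,
        "kappa_cut": cfg.kappa_cut, "seed": cfg.seed,
    }}
    stage = "inputs"
    try:
        geno, panel, ann, gene_sets, regulators = _load_inputs(cfg, out)
        key_trait = cfg.key_trait or panel.key_trait
        log.info("inputs: %d individuals, %d variants, %d traits, %d genes",
                 geno.n_individuals, geno.n_variants, panel.n_traits, ann.n_genes)

        stage = "gwas"
        results = MlmaGwas(panel, geno).fit()
        p_thr, nlp_thr = results.bonferroni(cfg.alpha)
        for t in results.traits:
            awio.write_gwas_tsv(results, t, out / f"gwas_{t}.tsv")
        report["gwas"] = {
            "n_tests": results.n_tests,
            "bonferroni_p": p_thr,
            "bonferroni_neglog10": round(float(nlp_thr), 6),
            "h2": {t: round(results.variance_components[t].h2, 4) for t in results.traits},
        }
        log.info("gwas: %d tests, threshold -log10 P > %.2f", results.n_tests, nlp_thr)

        stage = "qtl"
        regions = summarize_regions(results, key_trait, ann, neglog10_threshold=nlp_thr,
                                    merge_bp=cfg.merge_bp, window=cfg.gene_window)
        regions_to_frame(regions).to_csv(out / "qtl_regions.tsv", sep="\t", index=False)
        pv_rows = [
            {"region": i + 1, "trait": t, "pct_var": round(v, 4)}
            for i, r in enumerate(regions) for t, v in sorted(r.pct_var.items())
        ]
        pd.DataFrame(pv_rows, columns=["region", "trait", "pct_var"]).to_csv(
            out / "variance_explained.tsv", sep="\t", index=False
        )
        report["qtl"] = {"n_regions": len(regions),
                         "best_genes": sorted({r.best_candidate[1] for r in regions
                                               if r.best_candidate and r.best_candidate[1]})}
        log.info("qtl: %d regions on trait %s", len(regions), key_trait)

        stage = "awm"
        awm = results.build_awm(ann, key_trait, p_cut=cfg.p_cut, r_cut=cfg.r_cut,
                                window=cfg.gene_window)
        awm_df = awm.z.copy()
        awm_df.insert(0, "gene", awm.genes)
        awm_df.to_csv(out / "awm.tsv", sep="\t", float_format="%.6g")
        awio.write_json(awm.funnel, out / "awm_funnel.json")
        awm_trait_correlations(awm).to_csv(out / "awm_trait_correlations.tsv",
                                           sep="\t", float_format="%.4f")
        report["awm"] = dict(awm.funnel)
        log.info("awm funnel: %s", awm.funnel)

        stage = "network"
        net = awm.pcit_network()
        awio.write_graphml(net, out / "network.graphml")
        net.to_edge_frame().to_csv(out / "edges.tsv", sep="\t", index=False,
                                   float_format="%.6g")
        deg, eig = centralities(net)
        pd.DataFrame(
            {"gene": net.nodes, "degree": [deg[v] for v in net.nodes],
             "eigenvector": [round(eig[v], 6) for v in net.nodes]}
        ).to_csv(out / "centrality.tsv", sep="\t", index=False)
        report["network"] = {"n_nodes": len(net.nodes), "n_edges": net.n_edges}
        log.info("network: %d nodes, %d edges", len(net.nodes), net.n_edges)

        stage = "regulators"
        regs_in_net = sorted(set(regulators) & set(net.nodes))
        if len(regs_in_net) >= 3:
            trios = best_trios(net, regs_in_net, top_n=10)
            trios_to_frame(trios).to_csv(out / "trios.tsv", sep="\t", index=False)
            report["regulators"] = {
                "n_candidates": len(regs_in_net),
                "best_trio": list(trios[0].trio),
                "best_coverage": trios[0].coverage_size,
                "best_overlap": trios[0].overlap,
            }
        else:
            report["regulators"] = {"n_candidates": len(regs_in_net),
                                    "note": "fewer than 3 regulator candidates in network"}

        stage = "enrichment"
        res = net.enrich(gene_sets, alpha=cfg.alpha, kappa_cut=cfg.kappa_cut)
        res.table.to_csv(out / "enrichment.tsv", sep="\t", index=False,
                         float_format="%.6g")
        report["enrichment"] = {"n_terms": int(len(res.table)),
                                "n_significant": int(res.table["significant"].sum()),
                                "n_groups": len(res.groups)}
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    awio.write_json(report, out / "funnel.json")
    return report


def _load_inputs(cfg: PipelineConfig, out: Path):
    """Load user inputs or simulate the missing ones from cfg.seed."""
    sim = dict(cfg.sim)
    if cfg.genotypes is None or cfg.phenotypes is None or cfg.annotation is None:
        geno, panel, ann, arch, causal = simulate_pleiotropy_scenario(
            n_individuals=int(sim.get("n_individuals", 500)),
            n_variants=int(sim.get("n_variants", 2000)),
            n_traits=int(sim.get("n_traits", 8)),
            n_chromosomes=int(sim.get("n_chromosomes", 3)),
            n_causal_genes=int(sim.get("n_causal_genes", 5)),
            var_explained=float(sim.get("var_explained", 0.05)),
            n_genes=int(sim.get("n_genes", 120)),
            seed=cfg.seed,
        )
        awio.write_vcf(geno, out / "genotypes.vcf")
        awio.write_dosage_tsv(geno, out / "dosages.tsv")
        awio.write_phenotypes(panel, out / "phenotypes.tsv")
        awio.write_bed(ann, out / "genes.bed")
        awio.write_json(
            {"causal_genes": causal, "h2": np.asarray(arch.h2).tolist(), "seed": cfg.seed},
            out / "truth.json",
        )
    else:
        p = Path(cfg.genotypes)
        geno = awio.read_vcf(p) if p.suffix in (".vcf", ".gz", ".bcf") else awio.read_dosage_tsv(p)
        panel = awio.read_phenotypes(cfg.phenotypes, key_trait=cfg.key_trait,
                                     samples=list(geno.individuals))
        ann = awio.read_bed(cfg.annotation)

    if cfg.gene_sets is not None:
        gene_sets = awio.read_gmt(cfg.gene_sets)
    else:
        gene_sets = simulate_gene_sets(ann, n_sets=int(sim.get("n_gene_sets", 20)),
                                       seed=cfg.seed + 1)
        awio.write_gmt(gene_sets, out / "gene_sets.gmt")

    if cfg.regulators is not None:
        regulators = [
            ln.strip() for ln in Path(cfg.regulators).read_text().splitlines() if ln.strip()
        ]
    else:
        regulators = sorted(ann.regulator_flags)
    return geno, panel, ann, gene_sets, regulators
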