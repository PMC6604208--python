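"""Readers and writers for the pipeline's on-disk formats.

Genotypes travel as VCF with a ``DS`` (dosage) FORMAT field or as a plain TSV
dosage matrix; phenotypes as TSV (sample id + one column per trait); gene
annotation as 6-column BED (0-based half-open on disk, 1-based inclusive in
memory); gene sets as GMT; networks as GraphML and TSV edge lists; ground
truth and reports as JSON.  VCF reading goes through cyvcf2 and prefers DS
over GT when both are present.
"""

from __future__ import annotations

import json
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from .simulate import GeneAnnotation, GenotypeMatrix, TraitPanel

__all__ = [
    "write_vcf",
    "read_vcf",
    "write_dosage_tsv",
    "read_dosage_tsv",
    "write_phenotypes",
    "read_phenotypes",
    "write_bed",
    "read_bed",
    "read_gmt",
    "write_gmt",
    "write_gwas_tsv",
    "write_graphml",
    "write_json",
]


def write_vcf(g: GenotypeMatrix, path: str | Path) -> None:
    """Write genotypes as VCF 4.2 with GT and DS FORMAT fields.

    Integer dosages are emitted as hard genotypes (0/0, 0/1, 1/1); fractional
    dosages (imputation jitter) get GT ./. with the dosage carried in DS.
    """
    path = Path(path)
    v = g.variants
    with path.open("w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for chrom in dict.fromkeys(v["chrom"]):
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write('##FORMAT=<ID=DS,Number=1,Type=Float,Description="Alt allele dosage">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(g.individuals)
            + "\n"
        )
        gts = {0: "0/0", 1: "0/1", 2: "1/1"}
        for j, row in enumerate(v.itertuples(index=False)):
            ds = g.dosages[:, j]
            cells = []
            for d in ds:
                if float(d).is_integer():
                    cells.append(f"{gts[int(d)]}:{d:g}")
                else:
                    cells.append(f"./.:{d:.4f}")
            fh.write(
                f"{row.chrom}\t{row.pos}\t{row.id}\t{row.ref}\t{row.alt}\t.\t.\t.\tGT:DS\t"
                + "\t".join(cells)
                + "\n"
            )


def read_vcf(path: str | Path) -> GenotypeMatrix:
    """Read a (plain or compressed) VCF into a GenotypeMatrix; DS preferred over GT."""
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    rows = []
    dosage_cols = []
    for i, rec in enumerate(vcf):
        ds = None
        try:
            arr = rec.format("DS")
            if arr is not None:
                ds = np.asarray(arr, dtype=float).reshape(-1)
        except KeyError:
            ds = None
        if ds is None or not np.all(np.isfinite(ds)):
            gt_ds = np.asarray(rec.gt_types, dtype=float)  # 0,1,3->alt counts; 2=unknown
            conv = np.where(gt_ds == 3, 2.0, gt_ds)
            conv = np.where(gt_ds == 2, np.nan, conv)
            if ds is None:
                ds = conv
            else:
                ds = np.where(np.isfinite(ds), ds, conv)
        if np.any(~np.isfinite(ds)):
            raise ValueError(f"missing dosage and genotype at record {rec.ID or i}")
        p = ds.mean() / 2.0
        rows.append(
            {
                "id": rec.ID or f"{rec.CHROM}_{rec.POS}",
                "chrom": str(rec.CHROM),
                "pos": int(rec.POS),
                "ref": rec.REF,
                "alt": rec.ALT[0] if rec.ALT else ".",
                "maf": float(min(p, 1 - p)),
            }
        )
        dosage_cols.append(ds)
    if not rows:
        raise ValueError(f"no variant records in {path}")
    dosages = np.column_stack(dosage_cols)
    return GenotypeMatrix(
        dosages=dosages, variants=pd.DataFrame(rows), individuals=samples
    )


def write_dosage_tsv(g: GenotypeMatrix, path: str | Path) -> None:
    """Plain dosage matrix: variant metadata columns then one column per sample."""
    dos = pd.DataFrame(g.dosages.T, columns=g.individuals)
    df = pd.concat([g.variants.reset_index(drop=True), dos], axis=1)
    df.to_csv(path, sep="\t", index=False, float_format="%.6g")


def read_dosage_tsv(path: str | Path) -> GenotypeMatrix:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    meta_cols = ["id", "chrom", "pos", "ref", "alt", "maf"]
    missing = [c for c in meta_cols if c not in df.columns]
    if missing:
        raise ValueError(f"dosage table missing columns {missing}")
    samples = [c for c in df.columns if c not in meta_cols]
    return GenotypeMatrix(
        dosages=df[samples].to_numpy(dtype=float).T,
        variants=df[meta_cols].reset_index(drop=True),
        individuals=samples,
    )


def write_phenotypes(panel: TraitPanel, path: str | Path) -> None:
    df = panel.to_frame()
    df.index.name = "sample"
    df.to_csv(path, sep="\t", float_format="%.8g")


def read_phenotypes(
    path: str | Path, key_trait: str | None = None, samples: list[str] | None = None
) -> TraitPanel:
    """Read a sample x trait TSV; with ``samples`` given, validate and reorder.

    A phenotype sample absent from ``samples`` (or vice versa) is a hard
    error naming the offending sample.
    """
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    if samples is not None:
        extra = set(df.index) - set(samples)
        missing = set(samples) - set(df.index)
        if extra:
            raise ValueError(f"phenotype table has unknown sample(s): {sorted(extra)[:5]}")
        if missing:
            raise ValueError(f"phenotype table lacks sample(s): {sorted(missing)[:5]}")
        df = df.loc[samples]
    traits = list(df.columns)
    return TraitPanel(
        values=df.to_numpy(dtype=float),
        traits=traits,
        key_trait=key_trait or traits[0],
        individuals=list(df.index),
    )


def write_bed(ann: GeneAnnotation, path: str | Path) -> None:
    """6-column BED: chrom, start-1 (0-based half-open), end, gene id, regulator flag, strand."""
    with Path(path).open("w") as fh:
        for row in ann.genes.itertuples(index=False):
            flag = 1 if row.gene_id in ann.regulator_flags else 0
            fh.write(
                f"{row.chrom}\t{row.start - 1}\t{row.end}\t{row.gene_id}\t{flag}\t{row.strand}\n"
            )


def read_bed(path: str | Path) -> GeneAnnotation:
    """Read 6-column BED, converting 0-based half-open to 1-based inclusive."""
    rows = []
    flags = set()
    for ln, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip() or line.startswith(("#", "track", "browser")):
            continue
        parts = line.split("\t")
        if len(parts) < 4:
            raise ValueError(f"{path}:{ln}: expected >= 4 BED columns, got {len(parts)}")
        try:
            chrom, start, end, name = parts[0], int(parts[1]), int(parts[2]), parts[3]
        except ValueError as exc:
            raise ValueError(f"{path}:{ln}: malformed BED record") from exc
        score = parts[4] if len(parts) > 4 else "0"
        strand = parts[5] if len(parts) > 5 else "+"
        rows.append((name, chrom, start + 1, end, strand))
        if score not in ("0", ".", ""):
            flags.add(name)
    genes = pd.DataFrame(rows, columns=["gene_id", "chrom", "start", "end", "strand"])
    return GeneAnnotation(genes=genes, regulator_flags=frozenset(flags))


def read_gmt(path: str | Path) -> dict[str, list[str]]:
    """GMT gene sets: term <tab> description <tab> gene1 <tab> gene2 ..."""
    sets: dict[str, list[str]] = {}
    for ln, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip():
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 3:
            raise ValueError(f"{path}:{ln}: GMT line needs term, description, >= 1 gene")
        sets[parts[0]] = [g for g in parts[2:] if g]
    return sets


def write_gmt(sets: dict[str, list[str]], path: str | Path, description: str = "na") -> None:
    with Path(path).open("w") as fh:
        for term in sorted(sets):
            fh.write("\t".join([term, description, *sets[term]]) + "\n")


def write_gwas_tsv(results, trait: str, path: str | Path) -> None:
    """Per-trait summary statistics TSV (id, chrom, pos, alleles, MAF, effect, se, p, -log10 p)."""
    results.to_frame(trait).to_csv(path, sep="\t", index=False, float_format="%.6g")


def write_graphml(net, path: str | Path) -> None:
    nx.write_graphml(net.graph, str(path))


def write_json(obj, path: str | Path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")
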