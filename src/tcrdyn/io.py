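"""File round-trips for the pipeline's plain-text formats.

Mutations travel as TSV (chrom, pos, ref, alt, tumor_id; 0-based positions)
or a minimal single-sample VCF; genes as BED6 plus an expression TSV
(gene_id, ntpm) or a GFF3 subset; segment phases as BED6 (S score scaled by
1000 in the score column) with a sidecar TSV of raw scores; genomes as
FASTA.  Surfaces use the TSV/JSON dialects of :mod:`tcrdyn.surface`.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .surface import (  # noqa: F401  (re-exported round-trip API)
    ObsExpSurface,
    read_surface_json,
    read_surface_tsv,
    write_surface_json,
    write_surface_tsv,
)

MUTATION_COLUMNS = ["chrom", "pos", "ref", "alt", "tumor_id"]


# ---------------------------------------------------------------- FASTA

def write_fasta(sequences: dict[str, str], path, width: int = 60) -> None:
    with open(path, "w") as fh:
        for name, seq in sequences.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")


def read_fasta(path) -> dict[str, str]:
    import pyfaidx

    fa = pyfaidx.Fasta(str(path))
    return {name: str(fa[name][:]) for name in fa.keys()}


# ------------------------------------------------------------- mutations

def write_mutations_tsv(mutations: pd.DataFrame, path) -> None:
    mutations[MUTATION_COLUMNS].to_csv(path, sep="\t", index=False)


def read_mutations_tsv(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str, "tumor_id": str})
    missing = set(MUTATION_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing mutation columns {sorted(missing)}")
    return df[MUTATION_COLUMNS]


def write_mutations_vcf(mutations: pd.DataFrame, path,
                        contig_lengths: dict[str, int] | None = None) -> None:
    """Minimal single-sample VCF 4.2 (positions converted to 1-based)."""
    tumors = mutations["tumor_id"].unique()
    if len(tumors) != 1:
        raise ValueError("VCF export is single-sample: one tumor at a time")
    sample = tumors[0]
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for chrom, length in (contig_lengths or {}).items():
            fh.write(f"##contig=<ID={chrom},length={length}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 f"{sample}\n")
        for r in mutations.sort_values(["chrom", "pos"]).itertuples():
            fh.write(f"{r.chrom}\t{r.pos + 1}\t.\t{r.ref}\t{r.alt}\t.\tPASS\t.\t"
                     "GT\t0/1\n")


def read_mutations_vcf(path) -> pd.DataFrame:
    """Read a minimal VCF; the tumor id is the (single) sample name."""
    import pysam

    rows = []
    with pysam.VariantFile(str(path)) as vcf:
        samples = list(vcf.header.samples)
        if len(samples) != 1:
            raise ValueError("expected a single-sample VCF")
        sample = samples[0]
        for rec in vcf:
            for alt in rec.alts or ():
                rows.append({"chrom": rec.chrom, "pos": rec.pos - 1,
                             "ref": rec.ref, "alt": alt, "tumor_id": sample})
    return pd.DataFrame(rows, columns=MUTATION_COLUMNS)


# ----------------------------------------------------------------- genes

def write_genes_bed(genes: pd.DataFrame, path) -> None:
    out = genes[["chrom", "start", "end", "gene_id"]].copy()
    out["score"] = 0
    out["strand"] = genes["strand"]
    out.to_csv(path, sep="\t", index=False, header=False)


def read_genes_bed(path) -> pd.DataFrame:
    df = pd.read_csv(
        path, sep="\t", header=None,
        names=["chrom", "start", "end", "gene_id", "score", "strand"],
        dtype={"chrom": str},
    )
    return df[["chrom", "start", "end", "strand", "gene_id"]]


def read_genes_gff3(path) -> pd.DataFrame:
    """Genes from a GFF3 subset (type == gene, ID attribute), converted to
    0-based half-open coordinates."""
    import gffutils

    db = gffutils.create_db(str(path), ":memory:", force=True,
                            merge_strategy="create_unique")
    rows = []
    for feat in db.features_of_type("gene"):
        gid = feat.attributes.get("ID", [feat.id])[0]
        rows.append({"chrom": feat.seqid, "start": feat.start - 1, "end": feat.end,
                     "strand": feat.strand, "gene_id": gid})
    return pd.DataFrame(rows)


def write_expression_tsv(genes: pd.DataFrame, path) -> None:
    genes[["gene_id", "ntpm"]].to_csv(path, sep="\t", index=False)


def read_expression_tsv(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    if not {"gene_id", "ntpm"}.issubset(df.columns):
        raise ValueError(f"{path}: expression table needs gene_id and ntpm")
    return df


# ---------------------------------------------------------------- phases

def write_phases(phases: pd.DataFrame, bed_path, tsv_path=None) -> None:
    """BED6 with S x 1000 in the score column; raw scores in a sidecar TSV."""
    bed = phases[["chrom", "start", "end"]].copy()
    bed["name"] = phases["tumor_id"]
    s = phases["S"] if "S" in phases.columns else pd.Series(np.nan, index=phases.index)
    bed["score"] = (s * 1000).round().fillna(0).astype(int)
    bed["strand"] = phases["lesion_strand"].map(
        {"forward": "+", "reverse": "-"}).fillna(".")
    bed.to_csv(bed_path, sep="\t", index=False, header=False)
    if tsv_path is not None:
        cols = [c for c in ("tumor_id", "chrom", "start", "end", "n_forward",
                            "n_reverse", "S", "lesion_strand") if c in phases.columns]
        phases[cols].to_csv(tsv_path, sep="\t", index=False)


def read_phases_tsv(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str, "tumor_id": str})
    need = {"tumor_id", "chrom", "start", "end", "lesion_strand"}
    if not need.issubset(df.columns):
        raise ValueError(f"{path}: phase table needs columns {sorted(need)}")
    return df


# ---------------------------------------------------------------- cohort

def write_cohort(out_dir, genome, mutations: pd.DataFrame, phases: pd.DataFrame,
                 manifest: dict | None = None) -> dict[str, str]:
    """Write a synthetic cohort as plain-text files; returns the path map."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "fasta": str(out / "genome.fa"),
        "genes_bed": str(out / "genes.bed"),
        "expression": str(out / "expression.tsv"),
        "mutations": str(out / "mutations.tsv"),
        "phases_bed": str(out / "phases.bed"),
        "phases_tsv": str(out / "phases.tsv"),
        "manifest": str(out / "manifest.json"),
    }
    write_fasta(genome.sequences, paths["fasta"])
    write_genes_bed(genome.genes, paths["genes_bed"])
    write_expression_tsv(genome.genes, paths["expression"])
    write_mutations_tsv(mutations, paths["mutations"])
    write_phases(phases, paths["phases_bed"], paths["phases_tsv"])
    Path(paths["manifest"]).write_text(json.dumps(manifest or {}, indent=1) + "\n")
    return paths
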