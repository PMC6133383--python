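"""Readers and writers for the pipeline's on-disk formats.

Phased genotypes travel as VCF with phased GT fields. VCF has no
convention for which haplotype comes first, so the writer declares one in
the header (``##haplotypeOrder=maternal|paternal``) and the reader
refuses files that do not declare it; sites lacking parent-of-origin
information carry the INFO flag ``POU``. Gene models and DMRs are BED
(0-based half-open); counts, reads and CpG tables are plain TSV.
"""

from __future__ import annotations

import os
import tempfile
from pathlib import Path

import numpy as np
import pandas as pd

from .simulate import PhasedGenotypes

HAPLOTYPE_ORDER_KEY = "##haplotypeOrder=maternal|paternal"
POU_FLAG = "POU"

COUNTS_COLUMNS = ["individual_id", "gene_id", "m", "p", "u"]
READ_COLUMNS = ["read_id", "individual_id", "gene_id", "snp_id", "observed_allele"]
CPG_COLUMNS = ["cpg_id", "chrom", "pos", "individual_id", "value", "scale"]


def atomic_write_text(path, text: str) -> None:
    """Write a text file atomically: full content appears or nothing does."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    fd, tmp = tempfile.mkstemp(dir=path.parent, prefix=f".{path.name}.")
    try:
        with os.fdopen(fd, "w") as fh:
            fh.write(text)
        os.replace(tmp, path)
    except BaseException:
        if os.path.exists(tmp):
            os.unlink(tmp)
        raise


def write_tsv(df: pd.DataFrame, path) -> None:
    atomic_write_text(path, df.to_csv(sep="\t", index=False))


def read_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def read_counts(path) -> pd.DataFrame:
    df = read_tsv(path)
    missing = set(COUNTS_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"counts file {path} lacks columns {sorted(missing)}")
    return df[COUNTS_COLUMNS]


def write_bed(df: pd.DataFrame, path) -> None:
    """Write a BED-like frame; first three columns must be chrom/start/end."""
    cols = ["chrom", "start", "end"] + [c for c in df.columns
                                        if c not in ("chrom", "start", "end")]
    atomic_write_text(path, df[cols].to_csv(sep="\t", index=False, header=False))


def read_bed(path, names=("chrom", "start", "end", "gene_id")) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    df = df.iloc[:, : len(names)]
    df.columns = list(names)
    return df


def write_phased_vcf(genotypes: PhasedGenotypes, path) -> None:
    """Serialise phased genotypes to VCF, maternal haplotype first."""
    lines = [
        "##fileformat=VCFv4.2",
        HAPLOTYPE_ORDER_KEY,
        f'##INFO=<ID={POU_FLAG},Number=0,Type=Flag,'
        f'Description="Parent of origin unknown at this site">',
        '##INFO=<ID=GENE,Number=1,Type=String,Description="Gene id of the SNP">',
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
    ]
    for chrom in genotypes.sites["chrom"].unique():
        lines.append(f"##contig=<ID={chrom}>")
    header = ["#CHROM", "POS", "ID", "REF", "ALT", "QUAL", "FILTER", "INFO", "FORMAT"]
    lines.append("\t".join(header + genotypes.individuals))
    mat, pat = genotypes.maternal, genotypes.paternal
    for i, site in enumerate(genotypes.sites.itertuples(index=False)):
        info = f"GENE={site.gene_id}" + ("" if site.po_known else f";{POU_FLAG}")
        gts = [f"{mat[i, j]}|{pat[i, j]}" for j in range(len(genotypes.individuals))]
        lines.append("\t".join([site.chrom, str(site.pos), site.snp_id, site.ref,
                                site.alt, ".", "PASS", info, "GT"] + gts))
    atomic_write_text(path, "\n".join(lines) + "\n")


def read_phased_vcf(path) -> PhasedGenotypes:
    """Load phased genotypes from VCF written with the declared convention."""
    from cyvcf2 import VCF

    header_ok = False
    with open(path) as fh:
        for line in fh:
            if not line.startswith("##"):
                break
            if line.strip() == HAPLOTYPE_ORDER_KEY:
                header_ok = True
    if not header_ok:
        raise ValueError(
            f"{path} does not declare {HAPLOTYPE_ORDER_KEY!r}; refusing to guess "
            "which haplotype is maternal")

    vcf = VCF(str(path))
    individuals = list(vcf.samples)
    rows, mat_rows, pat_rows = [], [], []
    for var in vcf:
        gts = np.asarray(var.genotype.array())
        if np.any(gts[:, 2] == 0):
            raise ValueError(f"unphased genotype at {var.CHROM}:{var.POS}")
        rows.append((var.ID, var.CHROM, var.POS, var.REF, var.ALT[0],
                     (var.INFO.get("GENE") or ""), var.INFO.get(POU_FLAG) is None))
        mat_rows.append(gts[:, 0])
        pat_rows.append(gts[:, 1])
    sites = pd.DataFrame(rows, columns=["snp_id", "chrom", "pos", "ref", "alt",
                                        "gene_id", "po_known"])
    maternal = np.array(mat_rows, dtype=np.int8) if mat_rows else np.zeros((0, len(individuals)), np.int8)
    paternal = np.array(pat_rows, dtype=np.int8) if pat_rows else np.zeros((0, len(individuals)), np.int8)
    return PhasedGenotypes(sites=sites, individuals=individuals,
                           maternal=maternal, paternal=paternal)
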