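"""Assign reads to parental haplotypes and aggregate per-gene counts.

A read is classifiable only through informative SNPs: sites that are
heterozygous in the individual and whose alleles have known parental
origin. A read matching the maternal allele at one or more informative
sites (and the paternal allele at none) is maternal, and symmetrically for
paternal; everything else — no informative site covered, an observed
allele matching neither haplotype, or conflicting matches across sites —
is counted as unknown. Counts then pass the standard expression filters:
sex chromosomes removed and genes kept only when adequately expressed in
enough individuals.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .simulate import PhasedGenotypes

logger = logging.getLogger(__name__)

ORIGIN_LABELS = ("maternal", "paternal", "unknown")
SEX_CHROMS = frozenset({"chrX", "chrY", "X", "Y"})


@dataclass
class ReadObservation:
    """One sequencing read with its observed alleles at covered SNPs.

    ``allele_calls`` is a list of (snp_id, observed_allele); it may be
    empty when the read covers no genotyped site.
    """

    read_id: str
    individual_id: str
    gene_id: str
    allele_calls: list = field(default_factory=list)


def classify_read(read: ReadObservation, genotypes: PhasedGenotypes) -> str:
    """Classify a read as maternal / paternal / unknown.

    Calls at homozygous or parent-of-origin-unknown sites carry no
    information and are ignored; an observed allele matching neither
    haplotype allele (sequencing error) or matches pointing at both
    haplotypes across sites make the read unknown.
    """
    sites = genotypes.sites
    snp_rows = {s: i for i, s in enumerate(sites["snp_id"])}
    try:
        j = genotypes.individuals.index(read.individual_id)
    except ValueError:
        raise KeyError(f"unknown individual {read.individual_id!r}") from None

    votes = set()
    for snp_id, obs in read.allele_calls:
        if snp_id not in snp_rows:
            raise KeyError(f"unknown variant id {snp_id!r}")
        i = snp_rows[snp_id]
        if not sites["po_known"].iat[i]:
            continue
        mat = genotypes.allele_char(i, genotypes.maternal[i, j])
        pat = genotypes.allele_char(i, genotypes.paternal[i, j])
        if mat == pat:  # homozygous: uninformative
            continue
        if obs == mat:
            votes.add("maternal")
        elif obs == pat:
            votes.add("paternal")
        else:
            return "unknown"  # matches neither haplotype
    if len(votes) == 1:
        return votes.pop()
    return "unknown"  # no informative call, or conflict


def classify_reads(reads: pd.DataFrame, genotypes: PhasedGenotypes) -> pd.DataFrame:
    """Vectorised classification of a read-record table.

    ``reads`` is the long per-call table (read_id, individual_id, gene_id,
    snp_id, observed_allele); rows with snp_id "." are no-call records.
    Returns one row per read with an ``origin`` column. Semantics match
    :func:`classify_read` exactly.
    """
    sites = genotypes.sites
    ind_index = {ind: j for j, ind in enumerate(genotypes.individuals)}
    snp_index = {s: i for i, s in enumerate(sites["snp_id"])}

    df = reads.copy()
    unknown_ind = ~df["individual_id"].isin(ind_index)
    if unknown_ind.any():
        bad = df.loc[unknown_ind, "individual_id"].iloc[0]
        raise KeyError(f"unknown individual {bad!r}")
    has_call = df["snp_id"] != "."
    bad_snp = has_call & ~df["snp_id"].isin(snp_index)
    if bad_snp.any():
        raise KeyError(f"unknown variant id {df.loc[bad_snp, 'snp_id'].iloc[0]!r}")

    j = df["individual_id"].map(ind_index).to_numpy()
    i = df["snp_id"].map(snp_index).fillna(-1).astype(int).to_numpy()
    valid = i >= 0
    ref = sites["ref"].to_numpy()
    alt = sites["alt"].to_numpy()
    po = sites["po_known"].to_numpy()

    mat_allele = np.full(len(df), "", dtype=object)
    pat_allele = np.full(len(df), "", dtype=object)
    informative = np.zeros(len(df), dtype=bool)
    iv, jv = i[valid], j[valid]
    mat_idx = genotypes.maternal[iv, jv]
    pat_idx = genotypes.paternal[iv, jv]
    mat_allele[valid] = np.where(mat_idx == 0, ref[iv], alt[iv])
    pat_allele[valid] = np.where(pat_idx == 0, ref[iv], alt[iv])
    informative[valid] = po[iv] & (mat_idx != pat_idx)

    obs = df["observed_allele"].to_numpy(dtype=object)
    df["_mat_vote"] = informative & (obs == mat_allele)
    df["_pat_vote"] = informative & (obs == pat_allele)
    df["_mismatch"] = informative & ~(df["_mat_vote"] | df["_pat_vote"])

    per_read = df.groupby("read_id", sort=False).agg(
        individual_id=("individual_id", "first"),
        gene_id=("gene_id", "first"),
        mat=("_mat_vote", "any"),
        pat=("_pat_vote", "any"),
        mism=("_mismatch", "any"),
    ).reset_index()
    origin = np.where(per_read["mism"], "unknown",
                      np.where(per_read["mat"] & ~per_read["pat"], "maternal",
                               np.where(per_read["pat"] & ~per_read["mat"], "paternal",
                                        "unknown")))
    per_read["origin"] = origin
    return per_read[["read_id", "individual_id", "gene_id", "origin"]]


def aggregate_counts(classified: pd.DataFrame, gene_bed: pd.DataFrame | None = None,
                     ) -> pd.DataFrame:
    """Aggregate per-read origin labels into (m, p, u) per individual x gene.

    Reads whose gene_id is absent from the gene models (when provided) are
    skipped with a logged warning; conservation m + p + u = retained reads
    holds exactly.
    """
    if classified.empty:
        return pd.DataFrame(columns=["individual_id", "gene_id", "m", "p", "u"])
    df = classified
    if gene_bed is not None:
        known = set(gene_bed["gene_id"])
        missing = ~df["gene_id"].isin(known)
        n_skipped = int(missing.sum())
        if n_skipped:
            logger.warning("skipping %d reads with gene ids absent from gene models",
                           n_skipped)
            df = df[~missing]
    if df.empty:
        return pd.DataFrame(columns=["individual_id", "gene_id", "m", "p", "u"])
    tab = (df.groupby(["individual_id", "gene_id", "origin"], sort=True)
             .size().unstack("origin", fill_value=0))
    for col in ORIGIN_LABELS:
        if col not in tab:
            tab[col] = 0
    out = tab.reset_index().rename(columns={"maternal": "m", "paternal": "p", "unknown": "u"})
    return out[["individual_id", "gene_id", "m", "p", "u"]]


def assign_reads(reads: pd.DataFrame, genotypes: PhasedGenotypes,
                 gene_bed: pd.DataFrame | None = None) -> pd.DataFrame:
    """classify_reads + aggregate_counts in one step."""
    return aggregate_counts(classify_reads(reads, genotypes), gene_bed)


def filter_genes(counts: pd.DataFrame, gene_bed: pd.DataFrame,
                 min_logcpm: float = 1.0, min_individuals: int = 20) -> pd.DataFrame:
    """Apply the expression filters to a counts table.

    Removes genes on chrX/chrY and keeps a gene only when its total count
    (m + p + u) reaches log2(CPM) >= ``min_logcpm`` in at least
    ``min_individuals`` individuals, CPM being total x 1e6 / the
    individual's library size. Individuals with zero library size are
    excluded from the CPM computation with a warning.
    """
    bed = gene_bed.set_index("gene_id")
    chrom = counts["gene_id"].map(bed["chrom"])
    autosomal = ~chrom.isin(SEX_CHROMS)
    df = counts[autosomal].copy()
    if df.empty:
        return df

    df["total"] = df["m"] + df["p"] + df["u"]
    libsize = df.groupby("individual_id")["total"].transform("sum")
    zero_lib = libsize == 0
    if zero_lib.any():
        excluded = df.loc[zero_lib, "individual_id"].unique()
        warnings.warn(f"excluding {len(excluded)} individual(s) with zero library size",
                      stacklevel=2)
        df = df[~zero_lib]
        libsize = libsize[~zero_lib]
    with np.errstate(divide="ignore"):
        logcpm = np.log2(df["total"] * 1e6 / libsize)
    passing = (logcpm >= min_logcpm).groupby(df["gene_id"]).sum()
    keep = set(passing[passing >= min_individuals].index)
    out = df[df["gene_id"].isin(keep)].drop(columns=["total"])
    return out.reset_index(drop=True)


def summarize_assignment(counts: pd.DataFrame) -> pd.DataFrame:
    """Cohort summary of how transcripts were assigned to parental origin.

    Rows: per-gene unknown-origin fraction, per-gene parental fraction and
    per-individual parental fraction, each with mean, SD and range — the
    headline numbers for how sparse the informative signal is.
    """
    if counts.empty:
        raise ValueError("counts table is empty")
    df = counts.copy()
    df["total"] = df["m"] + df["p"] + df["u"]
    df["parental"] = df["m"] + df["p"]

    by_gene = df.groupby("gene_id")[["parental", "total"]].sum()
    by_gene = by_gene[by_gene["total"] > 0]
    gene_parental = by_gene["parental"] / by_gene["total"]
    gene_unknown = 1.0 - gene_parental

    by_ind = df.groupby("individual_id")[["parental", "total"]].sum()
    by_ind = by_ind[by_ind["total"] > 0]
    ind_parental = by_ind["parental"] / by_ind["total"]

    def _row(name: str, s: pd.Series) -> dict:
        return {"statistic": name, "mean": s.mean(), "sd": s.std(ddof=1),
                "min": s.min(), "max": s.max()}

    return pd.DataFrame([
        _row("gene_unknown_fraction", gene_unknown),
        _row("gene_parental_fraction", gene_parental),
        _row("individual_parental_fraction", ind_parental),
    ])


def single_parent_genes(counts: pd.DataFrame) -> tuple[list[str], list[str]]:
    """Genes expressed from only one parental haplotype across the cohort.

    Returns (paternal_only, maternal_only): paternal_only genes have p > 0
    in at least one individual and m = 0 in every individual; maternal_only
    is symmetric. The two lists are disjoint by construction.
    """
    g = counts.groupby("gene_id")[["m", "p"]].sum()
    paternal_only = sorted(g.index[(g["p"] > 0) & (g["m"] == 0)])
    maternal_only = sorted(g.index[(g["m"] > 0) & (g["p"] == 0)])
    return paternal_only, maternal_only
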