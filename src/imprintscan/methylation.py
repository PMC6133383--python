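"""Methylation summaries at candidate imprinting control regions (ICRs).

An ICR carries parent-specific methylation, so in bulk tissue — where each
cell methylates exactly one parental copy — its CpGs sit near 50%
methylation. A region whose CpG medians fall inside the partial band
(beta in [0.25, 0.75] by default) is consistent with imprinting; regions
near 0 or 1 are not. Array intensities are often reported as M-values
(log2 methylated/unmethylated ratio); beta = 2^M / (2^M + 1) maps them
back to the proportion scale.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

CLASSIFICATIONS = ("consistent_with_imprinting", "not_consistent", "insufficient_cpgs")


@dataclass
class DMRSummary:
    region_id: str
    n_cpgs: int
    fraction_partial: float
    classification: str


def m_to_beta(M):
    """Convert M-values to beta values: beta = 2^M / (2^M + 1).

    Accepts scalars or arrays; strictly increasing, maps 0 to 0.5.
    """
    M = np.asarray(M, dtype=float)
    if not np.all(np.isfinite(M)):
        raise ValueError("M-values must be finite")
    # logistic in base 2, written to avoid overflow for large |M|
    out = np.empty_like(M)
    pos = M >= 0
    out[pos] = 1.0 / (1.0 + np.exp2(-M[pos]))
    e = np.exp2(M[~pos])
    out[~pos] = e / (e + 1.0)
    return float(out) if out.ndim == 0 else out


def beta_to_m(beta):
    """Inverse transform: M = log2(beta / (1 - beta)), beta strictly in (0, 1)."""
    beta = np.asarray(beta, dtype=float)
    if np.any((beta <= 0) | (beta >= 1)):
        raise ValueError("beta must lie strictly in (0, 1) for the M transform")
    out = np.log2(beta / (1.0 - beta))
    return float(out) if out.ndim == 0 else out


def to_beta_scale(cpgs: pd.DataFrame) -> pd.DataFrame:
    """Normalise a CpG table (columns value, scale) to the beta scale."""
    df = cpgs.copy()
    is_m = df["scale"] == "M"
    if is_m.any():
        df.loc[is_m, "value"] = m_to_beta(df.loc[is_m, "value"].to_numpy())
        df.loc[is_m, "scale"] = "beta"
    bad = (df["value"] < 0) | (df["value"] > 1)
    if bad.any():
        raise ValueError("beta values outside [0, 1]")
    return df


def summarize_dmr(cpgs: pd.DataFrame, region: pd.Series | dict,
                  band: tuple[float, float] = (0.25, 0.75),
                  min_cpgs: int = 3, min_fraction: float = 0.5) -> DMRSummary:
    """Summarise partial methylation for the CpGs inside one region.

    ``region`` needs chrom, start, end (BED, 0-based half-open) and
    region_id; CpG positions are 1-based, so a CpG is inside when
    start < pos <= end. Per CpG the median beta across individuals is
    taken; fraction_partial is the share of CpGs with median inside the
    inclusive band. The region is consistent_with_imprinting when it has
    at least ``min_cpgs`` CpGs and fraction_partial >= ``min_fraction``.
    """
    region = dict(region)
    df = to_beta_scale(cpgs)
    inside = (df["chrom"] == region["chrom"]) & \
             (df["pos"] > region["start"]) & (df["pos"] <= region["end"])
    df = df[inside]
    medians = df.groupby("cpg_id")["value"].median()
    n = len(medians)
    if n == 0:
        return DMRSummary(str(region["region_id"]), 0, float("nan"), "insufficient_cpgs")
    lo, hi = band
    frac = float(((medians >= lo) & (medians <= hi)).mean())
    if n < min_cpgs:
        cls = "insufficient_cpgs"
    elif frac >= min_fraction:
        cls = "consistent_with_imprinting"
    else:
        cls = "not_consistent"
    return DMRSummary(str(region["region_id"]), n, frac, cls)


def summarize_dmrs(cpgs: pd.DataFrame, dmrs: pd.DataFrame,
                   band: tuple[float, float] = (0.25, 0.75),
                   min_cpgs: int = 3, min_fraction: float = 0.5) -> pd.DataFrame:
    """summarize_dmr over a whole DMR panel; one row per region."""
    rows = [summarize_dmr(cpgs, region, band, min_cpgs, min_fraction)
            for _, region in dmrs.iterrows()]
    return pd.DataFrame([r.__dict__ for r in rows])


def candidate_support(results: pd.DataFrame, dmr_summaries: pd.DataFrame,
                      gene_region_map: pd.DataFrame) -> pd.DataFrame:
    """Join candidate imprinted genes with their mapped regions' methylation.

    A candidate gene mapped to at least one consistent_with_imprinting
    region is 'supported'; a gene with no mapped region is 'unmapped';
    otherwise 'unsupported'. Only genes categorised candidate_imprinted or
    single_parent in ``results`` are considered.
    """
    candidates = results[results["category"].isin(["candidate_imprinted", "single_parent"])]
    summaries = dmr_summaries.set_index("region_id")
    rows = []
    mapped = gene_region_map.groupby("gene_id")["region_id"].apply(list)
    for gene in candidates["gene_id"]:
        regions = mapped.get(gene, [])
        if not regions:
            rows.append((gene, "", "", "unmapped"))
            continue
        for region_id in regions:
            if region_id not in summaries.index:
                rows.append((gene, region_id, "", "unmapped"))
                continue
            cls = summaries.loc[region_id, "classification"]
            status = "supported" if cls == "consistent_with_imprinting" else "unsupported"
            rows.append((gene, region_id, cls, status))
    return pd.DataFrame(rows, columns=["gene_id", "region_id", "region_classification",
                                       "support"])
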