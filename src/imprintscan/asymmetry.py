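"""Two-level exact binomial sign test for parent-of-origin expression asymmetry.

Level one summarises each individual's maternal/paternal read counts for a
gene into a binomial Z-score ``z = (m - n/2) / sqrt(n/4)`` with ``n = m + p``;
only the sign of z is kept. Level two asks, across individuals, whether the
number favouring one parent is compatible with Binomial(n, 1/2) — the exact
sign test. Because only signs enter the second level, count overdispersion
within an individual does not need to be modelled.

Genes are then ranked by Benjamini-Hochberg q-value and classified into
imprinting categories from the pooled allelic counts.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Literal

import numpy as np
import pandas as pd
from scipy.stats import binom
from statsmodels.stats.multitest import multipletests

Category = Literal["single_parent", "candidate_imprinted", "asymmetric_only", "not_significant"]

#: Categories a tested gene can receive, in decreasing strength of evidence
#: for imprinting.
CATEGORIES: tuple[str, ...] = (
    "single_parent",
    "candidate_imprinted",
    "asymmetric_only",
    "not_significant",
)


@dataclass
class AsymmetryResult:
    """Sign-test outcome for one gene across individuals.

    ``n_mat_greater``/``n_pat_greater`` count individuals whose informative
    reads favour the maternal / paternal haplotype (ties excluded);
    ``pooled_major_share`` is the majority parent's share of all pooled
    parental reads, used for category assignment.
    """

    gene_id: str
    n_mat_greater: int
    n_pat_greater: int
    p_value: float
    q_value: float = math.nan
    majority_fraction: float = math.nan
    pooled_major_share: float = math.nan
    pooled_m: int = 0
    pooled_p: int = 0
    category: str = "not_significant"
    testable: bool = True

    @property
    def n(self) -> int:
        return self.n_mat_greater + self.n_pat_greater


def individual_z(m: int, p: int) -> float:
    """Binomial Z-score for one individual's maternal (m) vs paternal (p) counts.

    z = (m - n/2) / sqrt(n/4) with n = m + p; positive when maternal reads
    dominate, zero on an exact tie.
    """
    n = m + p
    if n < 1:
        raise ValueError("individual_z requires m + p >= 1")
    return (m - n / 2.0) / math.sqrt(n / 4.0)


def sign_test_pvalue(k: int, n: int) -> float:
    """Exact two-sided sign-test p-value under Binomial(n, 1/2).

    ``k`` is the count in the smaller (or either, by symmetry) direction.
    Computes min(1, 2 * sum_{i<=min(k, n-k)} C(n, i) / 2^n) via the log-space
    binomial CDF so tail probabilities far below double-precision epsilon
    relative to 1 remain accurate.
    """
    if n < 1:
        raise ValueError("sign test requires n >= 1")
    if not 0 <= k <= n:
        raise ValueError(f"k={k} outside [0, {n}]")
    k = min(k, n - k)
    logp = math.log(2.0) + binom.logcdf(k, n, 0.5)
    return min(1.0, float(np.exp(logp)))


def _sign_test_pvalue_vec(k: np.ndarray, n: np.ndarray) -> np.ndarray:
    k = np.minimum(k, n - k)
    return np.minimum(1.0, np.exp(np.log(2.0) + binom.logcdf(k, n, 0.5)))


def bh_fdr(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, order-preserving."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p <= 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in (0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def test_gene(gene_counts: pd.DataFrame, min_parental: int = 5,
              min_parental_mode: str = "sum") -> AsymmetryResult:
    """Run the sign test for a single gene's counts table.

    ``gene_counts`` needs columns ``m`` and ``p`` (one row per individual).
    Individuals with fewer than ``min_parental`` parental reads are dropped
    (``min_parental_mode``: "sum" applies the threshold to m + p, "each" to
    both m and p separately), then tied individuals (z = 0) are excluded.
    A gene with no individual left is returned untestable with p = NaN.
    """
    gene_id = str(gene_counts["gene_id"].iloc[0]) if "gene_id" in gene_counts else ""
    m = gene_counts["m"].to_numpy(dtype=np.int64)
    p = gene_counts["p"].to_numpy(dtype=np.int64)
    if min_parental_mode == "sum":
        keep = (m + p) >= min_parental
    elif min_parental_mode == "each":
        keep = (m >= min_parental) & (p >= min_parental)
    else:
        raise ValueError("min_parental_mode must be 'sum' or 'each'")
    m, p = m[keep], p[keep]
    n_mat = int(np.sum(m > p))
    n_pat = int(np.sum(p > m))
    n = n_mat + n_pat
    if n == 0:
        return AsymmetryResult(gene_id, 0, 0, math.nan,
                               pooled_m=int(m.sum()), pooled_p=int(p.sum()),
                               testable=False)
    pooled_m, pooled_p = int(m.sum()), int(p.sum())
    return AsymmetryResult(
        gene_id,
        n_mat,
        n_pat,
        sign_test_pvalue(min(n_mat, n_pat), n),
        majority_fraction=max(n_mat, n_pat) / n,
        pooled_major_share=max(pooled_m, pooled_p) / (pooled_m + pooled_p),
        pooled_m=pooled_m,
        pooled_p=pooled_p,
    )


def classify_gene(result: AsymmetryResult, fdr_threshold: float = 0.05,
                  major_share_threshold: float = 0.8) -> str:
    """Assign an imprinting category from the tested gene's metrics.

    single_parent: all pooled parental reads come from one parent.
    candidate_imprinted: significant at the FDR threshold with the majority
    parent holding at least ``major_share_threshold`` of pooled reads.
    asymmetric_only: significant but biallelically expressed — the pattern
    expected from a cis-eQTL rather than imprinting.
    """
    if not result.testable:
        return "not_significant"
    total = result.pooled_m + result.pooled_p
    if total > 0 and min(result.pooled_m, result.pooled_p) == 0:
        return "single_parent"
    if np.isfinite(result.q_value) and result.q_value < fdr_threshold:
        if result.pooled_major_share >= major_share_threshold:
            return "candidate_imprinted"
        return "asymmetric_only"
    return "not_significant"


def test_genes(counts: pd.DataFrame, min_parental: int = 5,
               min_parental_mode: str = "sum", fdr_threshold: float = 0.05,
               major_share_threshold: float = 0.8) -> pd.DataFrame:
    """Sign test + BH FDR + categories for every gene in a counts table.

    ``counts`` has columns individual_id, gene_id, m, p (u optional,
    ignored). Returns one row per gene sorted by p-value then gene_id, with
    untestable genes (no individual passing the filters or all ties) carried
    with NaN p-values and excluded from the FDR correction.

    The per-gene computation is vectorised: the threshold and tie filters,
    the direction counts and the pooled sums are groupby aggregations, and
    the binomial tail is evaluated once over the gene vector.
    """
    required = {"gene_id", "m", "p"}
    if not required.issubset(counts.columns):
        raise ValueError(f"counts table must have columns {sorted(required)}")
    df = counts.copy()
    df["m"] = df["m"].astype(np.int64)
    df["p"] = df["p"].astype(np.int64)
    if min_parental_mode == "sum":
        df = df[(df["m"] + df["p"]) >= min_parental]
    elif min_parental_mode == "each":
        df = df[(df["m"] >= min_parental) & (df["p"] >= min_parental)]
    else:
        raise ValueError("min_parental_mode must be 'sum' or 'each'")

    all_genes = pd.Index(counts["gene_id"].unique(), name="gene_id")
    if df.empty:
        agg = pd.DataFrame(index=all_genes,
                           columns=["n_mat_greater", "n_pat_greater", "pooled_m", "pooled_p"],
                           data=0)
    else:
        df = df.assign(mat_greater=(df["m"] > df["p"]).astype(int),
                       pat_greater=(df["p"] > df["m"]).astype(int))
        agg = df.groupby("gene_id").agg(
            n_mat_greater=("mat_greater", "sum"),
            n_pat_greater=("pat_greater", "sum"),
            pooled_m=("m", "sum"),
            pooled_p=("p", "sum"),
        ).reindex(all_genes, fill_value=0)

    n = (agg["n_mat_greater"] + agg["n_pat_greater"]).to_numpy()
    testable = n > 0
    pval = np.full(len(agg), np.nan)
    if testable.any():
        k = np.minimum(agg["n_mat_greater"], agg["n_pat_greater"]).to_numpy()[testable]
        pval[testable] = _sign_test_pvalue_vec(k, n[testable])

    res = agg.reset_index()
    res["n"] = n
    res["p_value"] = pval
    res["testable"] = testable
    with np.errstate(invalid="ignore", divide="ignore"):
        res["majority_fraction"] = np.where(
            testable, np.maximum(res["n_mat_greater"], res["n_pat_greater"]) / np.where(n > 0, n, 1),
            np.nan)
        pooled_total = (res["pooled_m"] + res["pooled_p"]).to_numpy()
        res["pooled_major_share"] = np.where(
            pooled_total > 0,
            np.maximum(res["pooled_m"], res["pooled_p"]) / np.where(pooled_total > 0, pooled_total, 1),
            np.nan)
    res["q_value"] = np.nan
    if testable.any():
        res.loc[testable, "q_value"] = bh_fdr(res.loc[testable, "p_value"])

    categories = []
    for row in res.itertuples(index=False):
        r = AsymmetryResult(row.gene_id, int(row.n_mat_greater), int(row.n_pat_greater),
                            row.p_value, q_value=row.q_value,
                            pooled_major_share=row.pooled_major_share,
                            pooled_m=int(row.pooled_m), pooled_p=int(row.pooled_p),
                            testable=bool(row.testable))
        categories.append(classify_gene(r, fdr_threshold, major_share_threshold))
    res["category"] = categories
    res = res.sort_values(["p_value", "gene_id"], na_position="last", kind="mergesort")
    cols = ["gene_id", "n_mat_greater", "n_pat_greater", "n", "p_value", "q_value",
            "majority_fraction", "pooled_m", "pooled_p", "pooled_major_share",
            "category", "testable"]
    return res[cols].reset_index(drop=True)


def concordance(results_a: pd.DataFrame, results_b: pd.DataFrame) -> dict:
    """Direction agreement between two independently tested cohorts.

    A gene agrees when sign(n_mat_greater - n_pat_greater) matches between
    the two result tables (e.g. a discovery cohort and a validation cohort
    from a different tissue). Genes untestable in either table are reported
    separately and excluded from the agreement fraction.
    """
    shared = sorted(set(results_a["gene_id"]) & set(results_b["gene_id"]))
    if not shared:
        raise ValueError("result tables share no gene ids")
    a = results_a.set_index("gene_id").loc[shared]
    b = results_b.set_index("gene_id").loc[shared]
    testable = a["testable"].to_numpy(bool) & b["testable"].to_numpy(bool)
    dir_a = np.sign(a["n_mat_greater"].to_numpy() - a["n_pat_greater"].to_numpy())
    dir_b = np.sign(b["n_mat_greater"].to_numpy() - b["n_pat_greater"].to_numpy())
    agree = dir_a == dir_b
    table = pd.DataFrame({
        "gene_id": shared,
        "direction_a": dir_a,
        "direction_b": dir_b,
        "testable_both": testable,
        "agree": np.where(testable, agree, False),
    })
    n_testable = int(testable.sum())
    fraction = float(agree[testable].mean()) if n_testable else math.nan
    return {
        "table": table,
        "agreement_fraction": fraction,
        "n_shared": len(shared),
        "n_testable_both": n_testable,
        "n_untestable": len(shared) - n_testable,
    }
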