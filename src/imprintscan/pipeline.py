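"""End-to-end orchestration: simulate -> assign -> test -> validate -> methyl.

The pipeline mirrors a discovery/validation design: detect asymmetric
genes in one cohort, check direction concordance in an independent cohort
simulated from the same gene-class truth, and corroborate candidates with
partial methylation at their mapped control regions. A JSON manifest
records every threshold, the seed and per-stage row counts so a run can
be reproduced exactly.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import io as iio
from .assign import assign_reads, filter_genes, single_parent_genes, summarize_assignment
from .asymmetry import concordance, test_genes
from .methylation import candidate_support, summarize_dmrs
from .simulate import (SimConfig, make_dmr_panel, simulate_dataset, simulate_methylation)

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Everything that affects a pipeline run, serialised into the manifest."""

    out_dir: str = "imprintscan_run"
    seed: int = 0
    n_individuals: int = 306
    n_genes: int = 1000
    n_validation_individuals: int = 99
    min_parental: int = 5
    min_parental_mode: str = "sum"
    fdr_threshold: float = 0.05
    major_share_threshold: float = 0.8
    min_logcpm: float = 1.0
    min_individuals: int = 20
    band: tuple = (0.25, 0.75)
    min_cpgs: int = 3
    min_fraction: float = 0.5
    simulate_reads: bool = False
    apply_expression_filter: bool = True

    def sim_config(self, seed_offset: int = 0, n_individuals: int | None = None) -> SimConfig:
        return SimConfig(
            n_individuals=n_individuals if n_individuals is not None else self.n_individuals,
            n_genes=self.n_genes,
            seed=self.seed + seed_offset,
        )


@dataclass
class RunResult:
    counts: pd.DataFrame
    results: pd.DataFrame
    validation_results: pd.DataFrame
    concordance: dict
    summary: pd.DataFrame | None
    single_parent: tuple
    dmr_summaries: pd.DataFrame
    support: pd.DataFrame
    manifest: dict


def _config_hash(config: RunConfig) -> str:
    blob = json.dumps(dataclasses.asdict(config), sort_keys=True, default=str)
    return hashlib.sha256(blob.encode()).hexdigest()[:16]


def run_pipeline(config: RunConfig, write: bool = True) -> RunResult:
    """Run the full synthetic pipeline and (optionally) write all outputs.

    Stages: simulate a discovery cohort (optionally down to read records,
    reassigned through the classifier), filter genes, run the sign test
    with FDR control and categories, simulate an independent validation
    cohort from the same gene truth and measure direction concordance,
    then simulate methylation at a DMR panel and join candidates with
    their regions' partial-methylation classification.
    """
    out = Path(config.out_dir)
    manifest: dict = {
        "config": dataclasses.asdict(config),
        "config_hash": _config_hash(config),
        "stages": {},
    }

    sim = simulate_dataset(config.sim_config(), with_reads=config.simulate_reads)
    counts = sim.counts
    if config.simulate_reads:
        counts = assign_reads(sim.reads, sim.genotypes, sim.gene_bed)
        # reindex to full table: cells with zero reads drop out of groupby
        counts = (sim.counts[["individual_id", "gene_id"]]
                  .merge(counts, on=["individual_id", "gene_id"], how="left")
                  .fillna(0).astype({"m": int, "p": int, "u": int}))
    manifest["stages"]["simulate"] = {"n_counts_rows": len(counts),
                                      "n_genes": config.n_genes,
                                      "n_individuals": config.n_individuals}

    if config.apply_expression_filter and not counts.empty:
        counts = filter_genes(counts, sim.gene_bed, config.min_logcpm,
                              config.min_individuals)
    summary = summarize_assignment(counts) if not counts.empty else None
    pat_only, mat_only = single_parent_genes(counts) if not counts.empty else ([], [])
    manifest["stages"]["assign"] = {"n_counts_rows": len(counts),
                                    "n_paternal_only": len(pat_only),
                                    "n_maternal_only": len(mat_only)}

    if counts.empty:
        results = pd.DataFrame(columns=["gene_id", "n_mat_greater", "n_pat_greater", "n",
                                        "p_value", "q_value", "majority_fraction",
                                        "pooled_m", "pooled_p", "pooled_major_share",
                                        "category", "testable"])
    else:
        results = test_genes(counts, config.min_parental, config.min_parental_mode,
                             config.fdr_threshold, config.major_share_threshold)
    manifest["stages"]["test"] = {
        "n_tested": int(results["testable"].sum()) if len(results) else 0,
        "n_significant": int((results["q_value"] < config.fdr_threshold).sum())
        if len(results) else 0,
    }

    val = simulate_dataset(config.sim_config(seed_offset=1,
                                             n_individuals=config.n_validation_individuals),
                           genes=sim.genes)
    if val.counts.empty:
        val_results = results.iloc[0:0]
        conc = {"table": pd.DataFrame(), "agreement_fraction": float("nan"),
                "n_shared": 0, "n_testable_both": 0, "n_untestable": 0}
    else:
        val_results = test_genes(val.counts, config.min_parental, config.min_parental_mode,
                                 config.fdr_threshold, config.major_share_threshold)
        try:
            conc = concordance(results, val_results)
        except ValueError:
            conc = {"table": pd.DataFrame(), "agreement_fraction": float("nan"),
                    "n_shared": 0, "n_testable_both": 0, "n_untestable": 0}
    manifest["stages"]["validate"] = {"agreement_fraction": conc["agreement_fraction"],
                                      "n_testable_both": conc["n_testable_both"]}

    dmrs, gene_region_map = make_dmr_panel(sim.genes, sim.gene_bed)
    if dmrs.empty:
        dmr_summaries = pd.DataFrame(columns=["region_id", "n_cpgs", "fraction_partial",
                                              "classification"])
        support = pd.DataFrame(columns=["gene_id", "region_id", "region_classification",
                                        "support"])
    else:
        cpgs = simulate_methylation(dmrs, config.sim_config())
        dmr_summaries = summarize_dmrs(cpgs, dmrs, tuple(config.band),
                                       config.min_cpgs, config.min_fraction)
        support = candidate_support(results, dmr_summaries, gene_region_map)
    manifest["stages"]["methyl"] = {"n_regions": len(dmr_summaries),
                                    "n_supported": int((support["support"] == "supported").sum())
                                    if len(support) else 0}
    manifest["timestamp"] = time.strftime("%Y-%m-%dT%H:%M:%S", time.gmtime())

    result = RunResult(counts=counts, results=results, validation_results=val_results,
                       concordance=conc, summary=summary,
                       single_parent=(pat_only, mat_only),
                       dmr_summaries=dmr_summaries, support=support, manifest=manifest)
    if write:
        _write_bundle(result, out)
    return result


def _write_bundle(result: RunResult, out: Path) -> None:
    out.mkdir(parents=True, exist_ok=True)
    iio.write_tsv(result.counts, out / "counts.tsv")
    iio.write_tsv(result.results, out / "results.tsv")
    iio.write_tsv(result.validation_results, out / "validation_results.tsv")
    if len(result.concordance["table"]):
        iio.write_tsv(result.concordance["table"], out / "concordance.tsv")
    if result.summary is not None:
        iio.write_tsv(result.summary, out / "assignment_summary.tsv")
    pat_only, mat_only = result.single_parent
    iio.atomic_write_text(out / "single_parent_paternal.txt", "\n".join(pat_only) + "\n")
    iio.atomic_write_text(out / "single_parent_maternal.txt", "\n".join(mat_only) + "\n")
    iio.write_tsv(result.dmr_summaries, out / "dmr_summary.tsv")
    iio.write_tsv(result.support, out / "candidate_support.tsv")
    iio.atomic_write_text(out / "manifest.json",
                          json.dumps(result.manifest, indent=2, default=str) + "\n")
    iio.atomic_write_text(out / "report.md", report(result))


def report(result: RunResult) -> str:
    """Human-readable markdown summary with deterministic ordering."""
    lines = ["# imprintscan run report", ""]
    res = result.results
    lines.append("## Gene categories")
    counts = res["category"].value_counts() if len(res) else pd.Series(dtype=int)
    for cat in ("single_parent", "candidate_imprinted", "asymmetric_only",
                "not_significant"):
        lines.append(f"- {cat}: {int(counts.get(cat, 0))}")
    lines.append("")
    lines.append("## Top genes by p-value")
    if len(res):
        top = (res[res["testable"]]
               .sort_values(["p_value", "gene_id"], kind="mergesort")
               .head(15))
        lines.append("| gene | p | q | M>P | P>M | pooled major share | category |")
        lines.append("|---|---|---|---|---|---|---|")
        for r in top.itertuples(index=False):
            lines.append(f"| {r.gene_id} | {r.p_value:.3g} | {r.q_value:.3g} | "
                         f"{r.n_mat_greater} | {r.n_pat_greater} | "
                         f"{r.pooled_major_share:.3f} | {r.category} |")
    else:
        lines.append("(no tested genes)")
    lines.append("")
    conc = result.concordance
    lines.append("## Validation concordance")
    lines.append(f"- genes testable in both cohorts: {conc['n_testable_both']}")
    frac = conc["agreement_fraction"]
    lines.append(f"- direction agreement: "
                 f"{'n/a' if frac != frac else format(frac, '.3f')}")
    lines.append("")
    lines.append("## Methylation support")
    if len(result.support):
        for r in result.support.sort_values(["gene_id", "region_id"]).itertuples(index=False):
            lines.append(f"- {r.gene_id} -> {r.region_id or '(none)'}: {r.support}")
    else:
        lines.append("(no candidate genes)")
    lines.append("")
    return "\n".join(lines)
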