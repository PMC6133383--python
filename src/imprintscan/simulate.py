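"""Synthetic data with the statistical structure of a parent-of-origin ASE study.

The generator emulates a pedigree-phased cohort: each individual carries a
maternal and a paternal haplotype at a sparse set of exonic SNPs, most
transcripts overlap no informative site (so their parental origin is
unknown), and genes fall into ground-truth classes — fully imprinted with a
maternally or paternally silenced allele, leaky imprinted (residual
expression from the silenced allele), biallelic balanced, and biallelic
with a cis-eQTL allelic imbalance. A companion generator produces CpG
methylation beta values: imprinting control regions (ICRs) sit near 50%
methylation (one methylated parental chromosome per cell), other regions
near 0 or 1.

Everything is driven by a single integer seed; each operation draws from
its own deterministic substream so the operations can be called in any
order or in isolation and still reproduce bit-identical tables.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd

CLASS_LABELS = (
    "imprinted_maternal_silenced",
    "imprinted_paternal_silenced",
    "leaky_imprinted",
    "biallelic_balanced",
    "biallelic_eqtl",
)
IMPRINTED_CLASSES = ("imprinted_maternal_silenced", "imprinted_paternal_silenced",
                     "leaky_imprinted")

#: default class mixture: mostly biallelic genes with a small imprinted
#: minority, roughly the genome-wide situation.
DEFAULT_MIXTURE = {
    "imprinted_maternal_silenced": 0.01,
    "imprinted_paternal_silenced": 0.01,
    "leaky_imprinted": 0.01,
    "biallelic_balanced": 0.92,
    "biallelic_eqtl": 0.05,
}

_AUTOSOMES = tuple(f"chr{i}" for i in range(1, 23))

# substream tags so independently-called operations never share draws
_STREAM_SPECS, _STREAM_GENO, _STREAM_COUNTS, _STREAM_READS, _STREAM_METH = range(5)


@dataclass
class GeneClassSpec:
    """Ground truth for one simulated gene.

    leak_rate is the expected share of parental expression coming from the
    nominally silenced haplotype (0 for complete silencing); eqtl_ratio is
    the expected maternal share in individuals heterozygous for a simulated
    cis-regulatory variant; informative_rate is the probability that a
    transcript covers an informative SNP and drives the unknown-origin
    fraction (1 - informative_rate).
    """

    gene_id: str
    chrom: str
    class_label: str
    leak_rate: float = 0.0
    eqtl_ratio: float = 0.7
    mean_depth: float = 50.0
    n_het_snps: int = 3
    informative_rate: float = 0.018
    silenced_parent: str = "maternal"  # used by leaky_imprinted

    def __post_init__(self) -> None:
        if self.class_label not in CLASS_LABELS:
            raise ValueError(f"unknown class_label {self.class_label!r}")
        if not 0.0 <= self.leak_rate < 0.5:
            raise ValueError("leak_rate must lie in [0, 0.5)")
        if not 0.0 < self.eqtl_ratio < 1.0:
            raise ValueError("eqtl_ratio must lie in (0, 1)")
        if not 0.0 < self.informative_rate <= 1.0:
            raise ValueError("informative_rate must lie in (0, 1]")
        if self.n_het_snps < 1:
            raise ValueError("n_het_snps must be >= 1")
        if self.mean_depth <= 0:
            raise ValueError("mean_depth must be positive")
        if self.silenced_parent not in ("maternal", "paternal"):
            raise ValueError("silenced_parent must be 'maternal' or 'paternal'")

    @property
    def maternal_share(self) -> float:
        """Expected maternal fraction of informative transcripts.

        For biallelic_eqtl this is the share in regulator-heterozygous
        individuals; homozygous individuals express 0.5/0.5.
        """
        if self.class_label == "imprinted_maternal_silenced":
            return self.leak_rate
        if self.class_label == "imprinted_paternal_silenced":
            return 1.0 - self.leak_rate
        if self.class_label == "leaky_imprinted":
            return self.leak_rate if self.silenced_parent == "maternal" else 1.0 - self.leak_rate
        if self.class_label == "biallelic_eqtl":
            return self.eqtl_ratio
        return 0.5


@dataclass
class SimConfig:
    """Cohort-level simulation parameters.

    Defaults mirror the study conditions the pipeline targets: 306
    individuals, ~98% of transcripts of unknown parental origin
    (informative_rate 0.018), 10% of phased sites lacking parent-of-origin
    information, negative-binomial transcript totals with dispersion 0.2.
    """

    n_individuals: int = 306
    n_genes: int = 1000
    seed: int = 0
    class_mixture: dict = field(default_factory=lambda: dict(DEFAULT_MIXTURE))
    methylation_noise_sd: float = 0.05
    het_freq: float = 0.5
    po_unknown_fraction: float = 0.10
    dispersion: float = 0.2
    regulator_het_rate: float = 0.5
    leak_rate: float = 0.05
    mean_depth: float = 50.0
    informative_rate: float = 0.018
    n_het_snps: int = 3
    n_cpgs_per_region: int = 8

    def __post_init__(self) -> None:
        if self.n_individuals <= 0 or self.n_genes < 0:
            raise ValueError("n_individuals must be positive and n_genes non-negative")
        total = sum(self.class_mixture.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"class mixture proportions sum to {total}, not 1")
        unknown = set(self.class_mixture) - set(CLASS_LABELS)
        if unknown:
            raise ValueError(f"unknown class labels in mixture: {sorted(unknown)}")
        if not 0.0 <= self.po_unknown_fraction <= 1.0:
            raise ValueError("po_unknown_fraction must lie in [0, 1]")

    def individuals(self) -> list[str]:
        width = len(str(max(self.n_individuals, 1)))
        return [f"ind{i + 1:0{width}d}" for i in range(self.n_individuals)]

    def rng(self, stream: int) -> np.random.Generator:
        return np.random.default_rng([int(self.seed), stream])


@dataclass
class PhasedGenotypes:
    """Phased biallelic SNPs with parent-of-origin-resolved haplotypes.

    ``maternal``/``paternal`` are (n_sites, n_individuals) arrays of allele
    indices (0 = ref, 1 = alt); ``sites`` carries snp_id, chrom, pos, ref,
    alt, gene_id and the po_known flag (sites without parent-of-origin
    information are never informative).
    """

    sites: pd.DataFrame
    individuals: list[str]
    maternal: np.ndarray
    paternal: np.ndarray

    def informative(self) -> np.ndarray:
        """(n_sites, n_individuals) boolean: heterozygous and po_known."""
        het = self.maternal != self.paternal
        return het & self.sites["po_known"].to_numpy()[:, None]

    def allele_char(self, site_idx: int, allele_idx: int) -> str:
        row = self.sites.iloc[site_idx]
        return row["ref"] if allele_idx == 0 else row["alt"]


def make_gene_specs(config: SimConfig) -> list[GeneClassSpec]:
    """Draw gene class labels from the configured mixture, deterministically."""
    rng = config.rng(_STREAM_SPECS)
    labels = list(config.class_mixture)
    probs = np.array([config.class_mixture[c] for c in labels], dtype=float)
    draws = rng.choice(len(labels), size=config.n_genes, p=probs)
    silenced = rng.choice(["maternal", "paternal"], size=config.n_genes)
    specs = []
    width = len(str(max(config.n_genes, 1)))
    for i, d in enumerate(draws):
        label = labels[d]
        leak = config.leak_rate if label == "leaky_imprinted" else 0.0
        specs.append(GeneClassSpec(
            gene_id=f"g{i + 1:0{width}d}",
            chrom=_AUTOSOMES[i % len(_AUTOSOMES)],
            class_label=label,
            leak_rate=leak,
            mean_depth=config.mean_depth,
            n_het_snps=config.n_het_snps,
            informative_rate=config.informative_rate,
            silenced_parent=str(silenced[i]),
        ))
    return specs


def make_gene_bed(genes: Sequence[GeneClassSpec], gene_length: int = 10_000,
                  spacing: int = 100_000) -> pd.DataFrame:
    """Deterministic gene models (BED, 0-based half-open) for the spec list."""
    per_chrom: dict[str, int] = {}
    rows = []
    for g in genes:
        k = per_chrom.get(g.chrom, 0)
        per_chrom[g.chrom] = k + 1
        start = spacing * (k + 1)
        rows.append((g.chrom, start, start + gene_length, g.gene_id))
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "gene_id"])


def simulate_phased_genotypes(config: SimConfig, genes: Sequence[GeneClassSpec],
                              ) -> tuple[PhasedGenotypes, pd.DataFrame]:
    """Simulate phased parent-of-origin-resolved genotypes plus gene models.

    Each gene gets ``n_het_snps`` exonic SNPs. Per individual and site the
    maternal allele is a fair draw between ref and alt and the site is
    heterozygous with probability ``het_freq``; a ``po_unknown_fraction``
    of sites is flagged as lacking parent-of-origin information and is
    excluded from read classification downstream.
    """
    gene_bed = make_gene_bed(genes)
    starts = gene_bed.set_index("gene_id")
    rng = config.rng(_STREAM_GENO)
    n_ind = config.n_individuals

    rows = []
    for g in genes:
        start = int(starts.loc[g.gene_id, "start"])
        end = int(starts.loc[g.gene_id, "end"])
        pos = np.linspace(start + 1, end, num=g.n_het_snps, dtype=np.int64)
        pos = np.unique(pos)
        for j, p in enumerate(pos):
            rows.append((f"{g.gene_id}_snp{j + 1}", g.chrom, int(p), "A", "G", g.gene_id))
    sites = pd.DataFrame(rows, columns=["snp_id", "chrom", "pos", "ref", "alt", "gene_id"])
    n_sites = len(sites)
    sites["po_known"] = rng.random(n_sites) >= config.po_unknown_fraction

    maternal = (rng.random((n_sites, n_ind)) < 0.5).astype(np.int8)
    het = rng.random((n_sites, n_ind)) < config.het_freq
    paternal = np.where(het, 1 - maternal, maternal).astype(np.int8)
    geno = PhasedGenotypes(sites=sites, individuals=config.individuals(),
                           maternal=maternal, paternal=paternal)
    return geno, gene_bed


def _maternal_prob_matrix(config: SimConfig, genes: Sequence[GeneClassSpec],
                          rng: np.random.Generator) -> np.ndarray:
    """(n_genes, n_individuals) expected maternal share of informative reads."""
    n_ind = config.n_individuals
    pmat = np.empty((len(genes), n_ind))
    for i, g in enumerate(genes):
        if g.class_label == "biallelic_eqtl":
            het = rng.random(n_ind) < config.regulator_het_rate
            pmat[i] = np.where(het, g.eqtl_ratio, 0.5)
        else:
            pmat[i] = g.maternal_share
    return pmat


def simulate_parental_counts(config: SimConfig, genes: Sequence[GeneClassSpec],
                             informative_mask: Optional[np.ndarray] = None,
                             ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate per-individual x gene (maternal, paternal, unknown) counts.

    Transcript totals are negative-binomial (gamma-Poisson) around
    mean_depth / informative_rate; each transcript covers an informative
    SNP with probability informative_rate and, if informative, is maternal
    with the class-specific probability. ``informative_mask`` (genes x
    individuals boolean) optionally zeroes informativeness for individuals
    with no usable heterozygous site, keeping counts consistent with a
    genotype table.

    Returns (counts, truth): counts has columns individual_id, gene_id, m,
    p, u; truth one row per gene with its class and expected maternal share.
    """
    rng = config.rng(_STREAM_COUNTS)
    n_ind, n_genes = config.n_individuals, len(genes)
    individuals = config.individuals()

    mean_total = np.array([g.mean_depth / g.informative_rate for g in genes])
    inf_rate = np.array([g.informative_rate for g in genes])
    shape = 1.0 / config.dispersion
    lam = rng.gamma(shape, (mean_total * config.dispersion)[:, None] / 1.0,
                    size=(n_genes, n_ind)) if config.dispersion > 0 else \
        np.broadcast_to(mean_total[:, None], (n_genes, n_ind))
    total = rng.poisson(lam)

    eff_rate = np.broadcast_to(inf_rate[:, None], (n_genes, n_ind)).copy()
    if informative_mask is not None:
        if informative_mask.shape != (n_genes, n_ind):
            raise ValueError("informative_mask must have shape (n_genes, n_individuals)")
        eff_rate[~informative_mask] = 0.0
    informative = rng.binomial(total, eff_rate)
    pmat = _maternal_prob_matrix(config, genes, rng)
    m = rng.binomial(informative, pmat)
    p = informative - m
    u = total - informative

    counts = pd.DataFrame({
        "individual_id": np.repeat(individuals, n_genes),
        "gene_id": np.tile([g.gene_id for g in genes], n_ind),
        "m": m.T.ravel(),
        "p": p.T.ravel(),
        "u": u.T.ravel(),
    })
    truth = pd.DataFrame({
        "gene_id": [g.gene_id for g in genes],
        "class_label": [g.class_label for g in genes],
        "expected_maternal_share": [g.maternal_share for g in genes],
        "silenced_parent": [g.silenced_parent if g.class_label in IMPRINTED_CLASSES else ""
                            for g in genes],
    })
    return counts, truth


def simulate_reads(counts: pd.DataFrame, genotypes: PhasedGenotypes,
                   error_rate: float = 0.0, seed: int = 0) -> pd.DataFrame:
    """Expand a counts table into per-read allele observations.

    Each maternal (paternal) transcript becomes one read record carrying
    the maternal (paternal) allele at one informative SNP of its gene;
    unknown transcripts carry no allele call (snp_id and allele "."). With
    ``error_rate`` > 0 the observed allele is flipped to the opposite
    haplotype's allele with that probability, emulating sequencing error.

    Requires every individual with parental counts to have at least one
    informative SNP in the gene (guaranteed when counts were produced with
    the genotype-derived informative mask).
    """
    rng = np.random.default_rng([int(seed), _STREAM_READS])
    sites = genotypes.sites
    ind_index = {ind: j for j, ind in enumerate(genotypes.individuals)}
    informative = genotypes.informative()
    gene_sites = {g: idx.to_numpy() for g, idx in sites.groupby("gene_id").groups.items()}
    snp_ids = sites["snp_id"].to_numpy()
    ref = sites["ref"].to_numpy()
    alt = sites["alt"].to_numpy()

    read_ids, inds, gids, snps, alleles = [], [], [], [], []
    counter = 0

    def allele_char(site_rows: np.ndarray, allele_idx: np.ndarray) -> np.ndarray:
        return np.where(allele_idx == 0, ref[site_rows], alt[site_rows])

    for row in counts.itertuples(index=False):
        j = ind_index[row.individual_id]
        m, p, u = int(row.m), int(row.p), int(row.u)
        n_parental = m + p
        if n_parental > 0:
            site_rows = gene_sites.get(row.gene_id)
            if site_rows is None:
                raise ValueError(f"gene {row.gene_id} has no SNPs in the genotype table")
            usable = site_rows[informative[site_rows, j]]
            if usable.size == 0:
                raise ValueError(
                    f"individual {row.individual_id} has no informative SNP in "
                    f"gene {row.gene_id} but carries parental counts")
            chosen = usable[rng.integers(0, usable.size, size=n_parental)]
            hap = np.concatenate([genotypes.maternal[chosen[:m], j],
                                  genotypes.paternal[chosen[m:], j]])
            if error_rate > 0:
                flip = rng.random(n_parental) < error_rate
                hap = np.where(flip, 1 - hap, hap)
            obs = allele_char(chosen, hap)
            for t in range(n_parental):
                read_ids.append(f"r{counter}")
                counter += 1
                inds.append(row.individual_id)
                gids.append(row.gene_id)
                snps.append(snp_ids[chosen[t]])
                alleles.append(obs[t])
        for _ in range(u):
            read_ids.append(f"r{counter}")
            counter += 1
            inds.append(row.individual_id)
            gids.append(row.gene_id)
            snps.append(".")
            alleles.append(".")

    return pd.DataFrame({
        "read_id": read_ids,
        "individual_id": inds,
        "gene_id": gids,
        "snp_id": snps,
        "observed_allele": alleles,
    })


def make_dmr_panel(genes: Sequence[GeneClassSpec], gene_bed: pd.DataFrame,
                   ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Build a DMR panel: an ICR next to each imprinted gene, control regions
    next to a matching number of biallelic genes.

    Returns (dmrs, gene_region_map). ``dmrs`` is BED-like with a
    ground-truth region_class column in {icr, methylated, unmethylated};
    the map links each gene to its nearby region, mirroring how candidate
    imprinted genes are matched to previously characterised ICRs.
    """
    bed = gene_bed.set_index("gene_id")
    rows, links = [], []
    n_controls = 0
    n_imprinted = sum(g.class_label in IMPRINTED_CLASSES for g in genes)
    for g in genes:
        start = int(bed.loc[g.gene_id, "end"]) + 1_000
        if g.class_label in IMPRINTED_CLASSES:
            region_id = f"ICR_{g.gene_id}"
            rows.append((g.chrom, start, start + 2_000, region_id, "icr"))
            links.append((g.gene_id, region_id))
        elif n_controls < n_imprinted:
            region_id = f"CTRL_{g.gene_id}"
            cls = "unmethylated" if n_controls % 2 == 0 else "methylated"
            rows.append((g.chrom, start, start + 2_000, region_id, cls))
            links.append((g.gene_id, region_id))
            n_controls += 1
    dmrs = pd.DataFrame(rows, columns=["chrom", "start", "end", "region_id", "region_class"])
    gene_region_map = pd.DataFrame(links, columns=["gene_id", "region_id"])
    return dmrs, gene_region_map


def simulate_methylation(dmrs: pd.DataFrame, config: SimConfig) -> pd.DataFrame:
    """Simulate CpG beta values for a DMR panel across the cohort.

    ICR CpGs centre on beta 0.5 (one methylated parental chromosome per
    cell); methylated / unmethylated control CpGs centre on 0.97 / 0.03.
    Gaussian noise with sd ``methylation_noise_sd`` is added and values are
    clipped to [0, 1]. Returns a long table: cpg_id, chrom, pos,
    individual_id, value, scale ('beta').
    """
    required = {"chrom", "start", "end", "region_id", "region_class"}
    if not required.issubset(dmrs.columns):
        raise ValueError(f"dmrs must have columns {sorted(required)}")
    centers = {"icr": 0.5, "methylated": 0.97, "unmethylated": 0.03}
    rng = config.rng(_STREAM_METH)
    individuals = config.individuals()
    n_ind = len(individuals)

    frames = []
    for region in dmrs.itertuples(index=False):
        center = centers[region.region_class]
        k = config.n_cpgs_per_region
        pos = np.linspace(region.start + 1, region.end, num=k, dtype=np.int64)
        pos = np.unique(pos)
        betas = center + rng.normal(0.0, config.methylation_noise_sd, size=(len(pos), n_ind)) \
            if config.methylation_noise_sd > 0 else np.full((len(pos), n_ind), center)
        betas = np.clip(betas, 0.0, 1.0)
        frames.append(pd.DataFrame({
            "cpg_id": np.repeat([f"{region.region_id}_cg{i + 1}" for i in range(len(pos))], n_ind),
            "chrom": region.chrom,
            "pos": np.repeat(pos, n_ind),
            "individual_id": np.tile(individuals, len(pos)),
            "value": betas.ravel(),
            "scale": "beta",
        }))
    if not frames:
        return pd.DataFrame(columns=["cpg_id", "chrom", "pos", "individual_id", "value", "scale"])
    return pd.concat(frames, ignore_index=True)


@dataclass
class SimulatedDataset:
    """Bundle of all synthetic inputs plus ground truth for one cohort."""

    config: SimConfig
    genes: list[GeneClassSpec]
    genotypes: PhasedGenotypes
    gene_bed: pd.DataFrame
    counts: pd.DataFrame
    truth: pd.DataFrame
    reads: Optional[pd.DataFrame] = None


def simulate_dataset(config: SimConfig, genes: Optional[Sequence[GeneClassSpec]] = None,
                     with_reads: bool = False, read_error_rate: float = 0.0,
                     ) -> SimulatedDataset:
    """Generate a coherent cohort: genotypes, gene models, counts, reads.

    Counts are conditioned on the genotype table so that individuals without
    any informative SNP in a gene receive only unknown-origin transcripts;
    read records can therefore always be classified back to the exact counts.
    """
    genes = list(genes) if genes is not None else make_gene_specs(config)
    genotypes, gene_bed = simulate_phased_genotypes(config, genes)
    informative = genotypes.informative()
    gene_ids = [g.gene_id for g in genes]
    site_gene = genotypes.sites["gene_id"].to_numpy()
    mask = np.zeros((len(genes), config.n_individuals), dtype=bool)
    for i, gid in enumerate(gene_ids):
        rows = np.flatnonzero(site_gene == gid)
        if rows.size:
            mask[i] = informative[rows].any(axis=0)
    counts, truth = simulate_parental_counts(config, genes, informative_mask=mask)
    reads = None
    if with_reads:
        reads = simulate_reads(counts, genotypes, error_rate=read_error_rate,
                               seed=config.seed)
    return SimulatedDataset(config=config, genes=genes, genotypes=genotypes,
                            gene_bed=gene_bed, counts=counts, truth=truth, reads=reads)
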