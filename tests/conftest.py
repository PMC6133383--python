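import numpy as np
import pandas as pd
import pytest

from imprintscan.simulate import GeneClassSpec, PhasedGenotypes, SimConfig, simulate_dataset


@pytest.fixture
def tiny_genotypes():
    """Two individuals, one gene with three hand-built SNPs.

    ind1: snp1 het (mat=A, pat=G), snp2 het flagged po-unknown, snp3 homozygous A.
    ind2: snp1 homozygous G, snp2 het (mat=G, pat=A), snp3 het (mat=A, pat=G).
    """
    sites = pd.DataFrame({
        "snp_id": ["snp1", "snp2", "snp3"],
        "chrom": ["chr1"] * 3,
        "pos": [101, 201, 301],
        "ref": ["A"] * 3,
        "alt": ["G"] * 3,
        "gene_id": ["geneA"] * 3,
        "po_known": [True, False, True],
    })
    maternal = np.array([[0, 1], [0, 1], [0, 0]], dtype=np.int8)
    paternal = np.array([[1, 1], [1, 0], [0, 1]], dtype=np.int8)
    return PhasedGenotypes(sites=sites, individuals=["ind1", "ind2"],
                           maternal=maternal, paternal=paternal)


@pytest.fixture(scope="session")
def small_dataset():
    """A small coherent cohort with reads, reused across read-level tests."""
    cfg = SimConfig(n_individuals=12, n_genes=20, seed=11)
    return simulate_dataset(cfg, with_reads=True)


def make_specs(n: int, class_label: str, *, leak_rate: float = 0.0,
               silenced_parent: str = "maternal", mean_depth: float = 50.0,
               informative_rate: float = 0.018, start: int = 0) -> list[GeneClassSpec]:
    """Homogeneous gene-spec block for targeted simulations."""
    return [
        GeneClassSpec(gene_id=f"{class_label[:4]}{start + i:04d}", chrom="chr1",
                      class_label=class_label, leak_rate=leak_rate,
                      silenced_parent=silenced_parent, mean_depth=mean_depth,
                      informative_rate=informative_rate)
        for i in range(n)
    ]
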