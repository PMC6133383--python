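import numpy as np
import pandas as pd
import pytest

from imprintscan.assign import (ReadObservation, aggregate_counts, assign_reads,
                                classify_read, classify_reads, filter_genes,
                                single_parent_genes, summarize_assignment)
from imprintscan.simulate import PhasedGenotypes, SimConfig, simulate_dataset

from conftest import make_specs


def _read(ind, calls, gene="geneA", rid="r1"):
    return ReadObservation(read_id=rid, individual_id=ind, gene_id=gene,
                           allele_calls=calls)


class TestClassifyRead:
    def test_matching_maternal_allele(self, tiny_genotypes):
        assert classify_read(_read("ind1", [("snp1", "A")]), tiny_genotypes) == "maternal"

    def test_matching_paternal_allele(self, tiny_genotypes):
        assert classify_read(_read("ind1", [("snp1", "G")]), tiny_genotypes) == "paternal"

    def test_conflicting_snps_are_unknown(self, tiny_genotypes):
        # ind2: snp2 mat=G pat=A, snp3 mat=A pat=G; G at both -> one maternal
        # vote, one paternal vote... but snp2 is po-unknown, so use ind2
        # snp3 maternal (A) plus snp2 made informative via a fresh table
        geno = tiny_genotypes
        geno.sites.loc[1, "po_known"] = True
        read = _read("ind2", [("snp2", "G"), ("snp3", "G")])
        assert classify_read(read, geno) == "unknown"
        geno.sites.loc[1, "po_known"] = False

    def test_homozygous_site_is_uninformative(self, tiny_genotypes):
        assert classify_read(_read("ind1", [("snp3", "A")]), tiny_genotypes) == "unknown"

    def test_po_unknown_site_is_uninformative(self, tiny_genotypes):
        assert classify_read(_read("ind1", [("snp2", "A")]), tiny_genotypes) == "unknown"

    def test_allele_matching_neither_haplotype_is_unknown(self, tiny_genotypes):
        assert classify_read(_read("ind1", [("snp1", "T")]), tiny_genotypes) == "unknown"

    def test_no_calls_is_unknown(self, tiny_genotypes):
        assert classify_read(_read("ind1", []), tiny_genotypes) == "unknown"

    def test_unknown_variant_id_raises(self, tiny_genotypes):
        with pytest.raises(KeyError, match="variant"):
            classify_read(_read("ind1", [("nope", "A")]), tiny_genotypes)


class TestVectorisedAgainstScalarOracle:
    def test_classify_reads_matches_classify_read_on_random_reads(self):
        # brute-force oracle: the scalar classifier enumerates each read's
        # calls against both haplotype sequences; the vectorised path must
        # agree on 1,000 random synthetic reads (incl. errors and no-calls)
        rng = np.random.default_rng(42)
        cfg = SimConfig(n_individuals=8, n_genes=5, seed=21, n_het_snps=4)
        sim = simulate_dataset(cfg)
        geno = sim.genotypes
        sites = geno.sites
        rows = []
        observations = []
        for i in range(1000):
            ind = geno.individuals[rng.integers(len(geno.individuals))]
            gene = sites["gene_id"].iloc[rng.integers(len(sites))]
            gene_sites = sites.index[sites["gene_id"] == gene].to_numpy()
            n_calls = int(rng.integers(0, 3))
            calls = []
            for s in rng.choice(gene_sites, size=n_calls, replace=False):
                allele = rng.choice(["A", "G", "T"], p=[0.45, 0.45, 0.1])
                calls.append((sites["snp_id"].iloc[s], allele))
            rid = f"x{i}"
            observations.append(_read(ind, calls, gene=gene, rid=rid))
            if calls:
                for snp, allele in calls:
                    rows.append((rid, ind, gene, snp, allele))
            else:
                rows.append((rid, ind, gene, ".", "."))
        table = pd.DataFrame(rows, columns=["read_id", "individual_id", "gene_id",
                                            "snp_id", "observed_allele"])
        vec = classify_reads(table, geno).set_index("read_id")["origin"]
        for obs in observations:
            assert vec.loc[obs.read_id] == classify_read(obs, geno), obs


class TestAggregate:
    def test_cell_counts(self, tiny_genotypes):
        classified = pd.DataFrame({
            "read_id": [f"r{i}" for i in range(10)],
            "individual_id": ["ind1"] * 10,
            "gene_id": ["geneA"] * 10,
            "origin": ["maternal"] * 3 + ["paternal"] * 1 + ["unknown"] * 6,
        })
        out = aggregate_counts(classified)
        assert out.iloc[0][["m", "p", "u"]].tolist() == [3, 1, 6]

    def test_empty_table(self):
        out = aggregate_counts(pd.DataFrame(columns=["read_id", "individual_id",
                                                     "gene_id", "origin"]))
        assert out.empty
        assert list(out.columns) == ["individual_id", "gene_id", "m", "p", "u"]

    def test_unknown_gene_skipped_with_warning(self, caplog):
        classified = pd.DataFrame({
            "read_id": ["r1", "r2"],
            "individual_id": ["ind1", "ind1"],
            "gene_id": ["geneA", "ghost"],
            "origin": ["maternal", "maternal"],
        })
        bed = pd.DataFrame({"chrom": ["chr1"], "start": [0], "end": [10],
                            "gene_id": ["geneA"]})
        with caplog.at_level("WARNING"):
            out = aggregate_counts(classified, bed)
        assert "skipping 1 reads" in caplog.text
        assert out["m"].sum() == 1

    def test_roundtrip_recovers_simulator_counts(self, small_dataset):
        sim = small_dataset
        counts = assign_reads(sim.reads, sim.genotypes, sim.gene_bed)
        truth = sim.counts[(sim.counts[["m", "p", "u"]].sum(axis=1)) > 0]
        merged = truth.merge(counts, on=["individual_id", "gene_id"],
                             suffixes=("_t", ""), how="left").fillna(-1)
        for col in ("m", "p", "u"):
            assert (merged[col] == merged[f"{col}_t"]).all()

    def test_conservation(self, small_dataset):
        sim = small_dataset
        counts = assign_reads(sim.reads, sim.genotypes, sim.gene_bed)
        assert counts[["m", "p", "u"]].to_numpy().sum() == len(sim.reads["read_id"].unique())


class TestParentSwapSymmetry:
    def test_swapping_haplotypes_swaps_counts(self, small_dataset):
        sim = small_dataset
        swapped = PhasedGenotypes(sites=sim.genotypes.sites,
                                  individuals=sim.genotypes.individuals,
                                  maternal=sim.genotypes.paternal,
                                  paternal=sim.genotypes.maternal)
        a = assign_reads(sim.reads, sim.genotypes, sim.gene_bed)
        b = assign_reads(sim.reads, swapped, sim.gene_bed)
        merged = a.merge(b, on=["individual_id", "gene_id"], suffixes=("_a", "_b"))
        assert (merged["m_a"] == merged["p_b"]).all()
        assert (merged["p_a"] == merged["m_b"]).all()
        assert (merged["u_a"] == merged["u_b"]).all()
        pa, ma = single_parent_genes(a)
        pb, mb = single_parent_genes(b)
        assert (pa, ma) == (mb, pb)


class TestFilterGenes:
    @staticmethod
    def _counts(n_ind, gene_totals):
        """Build counts where gene g has the same total in every individual."""
        rows = []
        for i in range(n_ind):
            for g, total in gene_totals.items():
                rows.append((f"i{i}", g, 0, 0, total))
        return pd.DataFrame(rows, columns=["individual_id", "gene_id", "m", "p", "u"])

    @staticmethod
    def _bed(chroms):
        return pd.DataFrame({"chrom": list(chroms.values()), "start": 0, "end": 10,
                             "gene_id": list(chroms.keys())})

    def test_sex_chromosome_genes_removed(self):
        counts = self._counts(30, {"gA": 5000, "gX": 900_000})
        bed = self._bed({"gA": "chr1", "gX": "chrX"})
        out = filter_genes(counts, bed)
        assert set(out["gene_id"]) == {"gA"}

    def test_min_individuals_boundary(self):
        # gene gLow reaches log2CPM >= 1 in exactly 20 (kept) or 19
        # (removed) of 30 individuals; gBig keeps library sizes stable
        for n_pass, expect_kept in [(20, True), (19, False)]:
            rows = []
            for i in range(30):
                low_total = 3 if i < n_pass else 1  # lib 1e6 -> CPM=total, log2(3)~1.58 vs 0
                rows.append((f"i{i}", "gLow", 0, 0, low_total))
                rows.append((f"i{i}", "gBig", 0, 0, 1_000_000 - low_total))
            counts = pd.DataFrame(rows, columns=["individual_id", "gene_id", "m", "p", "u"])
            bed = self._bed({"gLow": "chr1", "gBig": "chr2"})
            kept = "gLow" in set(filter_genes(counts, bed)["gene_id"])
            assert kept is expect_kept

    def test_all_zero_gene_removed(self):
        counts = self._counts(30, {"gA": 5000, "gZero": 0})
        bed = self._bed({"gA": "chr1", "gZero": "chr2"})
        assert "gZero" not in set(filter_genes(counts, bed)["gene_id"])

    def test_zero_library_individual_excluded_with_warning(self):
        counts = self._counts(25, {"gA": 5000})
        empty = pd.DataFrame([("ghost", "gA", 0, 0, 0)],
                             columns=["individual_id", "gene_id", "m", "p", "u"])
        counts = pd.concat([counts, empty], ignore_index=True)
        bed = self._bed({"gA": "chr1"})
        with pytest.warns(UserWarning, match="zero library"):
            out = filter_genes(counts, bed)
        assert "ghost" not in set(out["individual_id"])


class TestSummaries:
    def test_single_cell_fractions(self):
        counts = pd.DataFrame([("i1", "g1", 1, 1, 8)],
                              columns=["individual_id", "gene_id", "m", "p", "u"])
        s = summarize_assignment(counts).set_index("statistic")
        assert s.loc["gene_parental_fraction", "mean"] == pytest.approx(0.2)
        assert s.loc["gene_unknown_fraction", "mean"] == pytest.approx(0.8)

    def test_no_unknowns(self):
        counts = pd.DataFrame([("i1", "g1", 3, 4, 0), ("i2", "g2", 1, 0, 0)],
                              columns=["individual_id", "gene_id", "m", "p", "u"])
        s = summarize_assignment(counts).set_index("statistic")
        assert s.loc["gene_parental_fraction", ["mean", "min", "max"]].tolist() == [1, 1, 1]

    def test_empty_counts_rejected(self):
        with pytest.raises(ValueError):
            summarize_assignment(pd.DataFrame(columns=["individual_id", "gene_id",
                                                       "m", "p", "u"]))

    def test_simulator_calibration_appears_in_summary(self):
        cfg = SimConfig(n_individuals=30, n_genes=200, seed=31)
        genes = make_specs(200, "biallelic_balanced")
        from imprintscan.simulate import simulate_parental_counts
        counts, _ = simulate_parental_counts(cfg, genes)
        s = summarize_assignment(counts).set_index("statistic")
        assert s.loc["gene_parental_fraction", "mean"] == pytest.approx(0.018, abs=0.005)


class TestSingleParentGenes:
    def test_definition(self):
        counts = pd.DataFrame([
            ("i1", "gPat", 0, 4, 10), ("i2", "gPat", 0, 0, 5),
            ("i1", "gMixed", 1, 4, 0), ("i2", "gMixed", 0, 9, 0),
            ("i1", "gMat", 2, 0, 3), ("i2", "gMat", 0, 0, 0),
            ("i1", "gNone", 0, 0, 7),
        ], columns=["individual_id", "gene_id", "m", "p", "u"])
        pat, mat = single_parent_genes(counts)
        assert pat == ["gPat"]
        assert mat == ["gMat"]
        assert not set(pat) & set(mat)

    def test_fully_imprinted_simulated_genes_recovered(self):
        cfg = SimConfig(n_individuals=40, n_genes=20, seed=37)
        genes = (make_specs(10, "imprinted_maternal_silenced", start=0) +
                 make_specs(10, "imprinted_paternal_silenced", start=10))
        from imprintscan.simulate import simulate_parental_counts
        counts, truth = simulate_parental_counts(cfg, genes)
        pat, mat = single_parent_genes(counts)
        mat_silenced = set(truth[truth["class_label"] == "imprinted_maternal_silenced"]["gene_id"])
        pat_silenced = set(truth[truth["class_label"] == "imprinted_paternal_silenced"]["gene_id"])
        assert set(pat) == mat_silenced
        assert set(mat) == pat_silenced
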