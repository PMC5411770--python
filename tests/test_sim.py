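"""Simulator: genomes, partitions, reads, truth files, determinism."""

import numpy as np
import pytest

from linkasm._seq import revcomp
from linkasm.io import (
    read_fastq_pair,
    read_molecule_table,
    read_variant_table,
    write_fastq_pair,
    write_molecule_table,
    write_variant_table,
)
from linkasm.model import LibraryModel, MoleculeLengthDist, model_calculator
from linkasm.sim import (
    TrueMolecule,
    barcode_whitelist,
    simulate_diploid_genome,
    simulate_library,
    simulate_partitions,
    simulate_reads,
)


class TestDiploidGenome:
    def test_snp_count_binomial(self):
        g = simulate_diploid_genome(1_000_000, het_snp_rate=1e-3, het_indel_rate=0, seed=3)
        n = len([v for v in g.variants if v.kind == "SNP"])
        # thinning removes a few close pairs; 4 sigma of Binomial(1e6, 1e-3)
        assert abs(n - 1000) < 4 * np.sqrt(1000 * 0.999) + 30

    def test_zero_rates_identical_haplotypes(self):
        g = simulate_diploid_genome(20_000, het_snp_rate=0, het_indel_rate=0, seed=1)
        assert g.haplotype0 == g.haplotype1
        assert g.variants == []

    def test_determinism(self):
        a = simulate_diploid_genome(30_000, seed=11)
        b = simulate_diploid_genome(30_000, seed=11)
        assert a.haplotype0 == b.haplotype0
        assert a.haplotype1 == b.haplotype1
        assert a.variants == b.variants

    def test_variants_reconstruct_haplotype1(self):
        g = simulate_diploid_genome(50_000, het_indel_rate=5e-4, seed=5)
        # positions strictly increasing, alleles differ
        pos = [v.pos for v in g.variants]
        assert pos == sorted(pos) and len(set(pos)) == len(pos)
        for v in g.variants:
            assert v.ref != v.alt
            if v.kind == "SNP":
                assert g.haplotype0[v.pos] == v.ref
                assert g.haplotype1[g.hap1_pos(v.pos)] == v.alt

    def test_invalid_rate(self):
        with pytest.raises(ValueError):
            simulate_diploid_genome(1000, het_snp_rate=1.0)


class TestPartitions:
    def _model(self, genome_size, n_part=1000, m=10.0):
        return LibraryModel(
            genome_size=genome_size,
            n_partitions=n_part,
            molecules_per_partition=m,
            molecule_length=MoleculeLengthDist("fixed", 10_000),
            total_reads=1e6,
        )

    def test_total_molecules_poisson(self):
        g = simulate_diploid_genome(200_000, seed=1)
        mols = simulate_partitions(g, self._model(200_000), seed=2)
        assert abs(len(mols) - 10_000) < 4 * np.sqrt(10_000)

    def test_zero_molecules(self):
        g = simulate_diploid_genome(50_000, seed=1)
        mols = simulate_partitions(g, self._model(50_000, m=0.0), seed=2)
        assert mols == []

    def test_fixed_length_except_truncation(self):
        g = simulate_diploid_genome(200_000, seed=1)
        mols = simulate_partitions(g, self._model(200_000, n_part=200), seed=2)
        assert all(m.length <= 10_000 for m in mols)
        full = [m for m in mols if m.length == 10_000]
        # molecules overlapping a chromosome end are clipped:
        # P(full) = (G - l + 1)/(G + l - 1) ~ 0.905 here
        assert len(full) > 0.85 * len(mols)

    def test_barcodes_unique_per_partition(self):
        g = simulate_diploid_genome(100_000, seed=1)
        mols = simulate_partitions(g, self._model(100_000, n_part=300), seed=2)
        by_bc = {}
        for m in mols:
            by_bc.setdefault(m.barcode, set()).add(m.partition_id)
        assert all(len(parts) == 1 for parts in by_bc.values())

    def test_whitelist_distinct_and_bounded(self):
        wl = barcode_whitelist(2000, seed=0)
        assert len(set(wl)) == 2000
        assert all(len(b) == 16 for b in wl)
        with pytest.raises(ValueError):
            barcode_whitelist(17, barcode_length=2)


class TestReads:
    def test_pairs_per_molecule_mean(self):
        """1000 50-kb molecules at 0.36x per-molecule depth: mean pair
        count within 2% of 60."""
        g = simulate_diploid_genome(100_000, het_snp_rate=0, seed=1)
        model = LibraryModel(
            genome_size=100_000,
            n_partitions=1000,
            molecules_per_partition=1.0,
            molecule_length=MoleculeLengthDist("fixed", 50_000),
            total_reads=2 * 60 * 1000,
        )
        wl = barcode_whitelist(1000, seed=1)
        mols = [TrueMolecule(i, wl[i], i, 0, 0, 50_000, i) for i in range(1000)]
        reads = simulate_reads(mols, g, model, seed=4)
        mean_pairs = reads.n_pairs / 1000
        assert mean_pairs == pytest.approx(60.0, rel=0.02)

    def test_error_free_reads_match_haplotype(self):
        g, model, mols, reads = simulate_library(40_000, error_rate=0.0, seed=9)
        for i in range(0, reads.n_pairs, 37):
            row = reads.truth.iloc[i]
            hap = g.haplotype(int(row.haplotype))
            frag = hap[int(row.start) : int(row.start) + int(row["insert"])]
            assert frag.startswith(reads.r1[i])
            assert frag.endswith(revcomp(reads.r2[i]))

    def test_conservation_reads_to_molecules(self):
        g, model, mols, reads = simulate_library(40_000, seed=9)
        by_id = {m.molecule_id: m for m in mols}
        assert len(reads.truth) == reads.n_pairs
        for i in range(0, reads.n_pairs, 53):
            row = reads.truth.iloc[i]
            m = by_id[int(row.molecule_id)]
            assert m.haplotype == int(row.haplotype)
            assert m.start <= int(row.start)
            assert int(row.start) + int(row["insert"]) <= m.end

    def test_length_weighted_mean_matches_distribution(self):
        dist = MoleculeLengthDist("lognormal", 50_000, 0.6)
        rng = np.random.default_rng(2)
        x = dist.sample(rng, 20_000)
        lwm = float(np.sum(x**2) / np.sum(x))
        assert lwm == pytest.approx(dist.lwm(), rel=0.02)

    def test_empirical_model_consistency(self):
        """Empirical LPM and coverage converge to the model expectations
        (with the finite-chromosome clipping correction on coverage)."""
        g, model, mols, reads = simulate_library(500_000, seed=3)
        exp = model_calculator(model)
        lpm = reads.n_pairs / len(mols)
        sd = np.sqrt(exp.read_pairs_per_molecule / len(mols))
        # molecule clipping at chromosome ends shortens some molecules
        mol_len = model.molecule_length.expectation()
        clip = 500_000 / (500_000 + mol_len - 1)
        assert abs(lpm - exp.read_pairs_per_molecule * clip) < 6 * sd + 1.0
        bases = sum(len(r) for r in reads.r1) + sum(len(r) for r in reads.r2)
        cov = bases / 500_000
        # read 1 carries 16 barcode bases that are not genomic
        expected_cov = exp.genome_coverage * clip * (284 / 300)
        assert cov == pytest.approx(expected_cov, rel=0.05)


class TestDeterminismAndIO:
    def test_same_seed_identical_library(self):
        a = simulate_library(30_000, seed=42)
        b = simulate_library(30_000, seed=42)
        assert a[3].r1 == b[3].r1
        assert a[3].r2 == b[3].r2
        assert list(a[3].barcode_ids) == list(b[3].barcode_ids)

    @pytest.mark.parametrize("dialect", ["raw", "trimmed"])
    def test_fastq_roundtrip(self, dialect, tmp_path):
        _, _, _, reads = simulate_library(20_000, seed=5)
        p1, p2 = write_fastq_pair(reads, tmp_path / "lib", dialect=dialect)
        back = read_fastq_pair(p1, p2, dialect=dialect)
        assert back.r1 == reads.r1
        assert back.r2 == reads.r2
        assert [back.barcode_of(i) for i in range(back.n_pairs)] == [
            reads.barcode_of(i) for i in range(reads.n_pairs)
        ]

    def test_truth_tables_roundtrip(self, tmp_path):
        g, _, mols, _ = simulate_library(20_000, seed=5)
        mp = write_molecule_table(mols, tmp_path / "mols.tsv")
        vp = write_variant_table(g, tmp_path / "vars.tsv")
        mols2 = read_molecule_table(mp)
        assert [(m.barcode, m.start, m.end) for m in mols2] == [
            (m.barcode, m.start, m.end) for m in mols
        ]
        vars2 = read_variant_table(vp)
        assert vars2 == g.variants
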