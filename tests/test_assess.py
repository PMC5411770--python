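"""Assessment statistics: N-values, perfect stretches, phasing error,
k-mer completeness, long-range consistency, molecule LWM, novel windows."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from linkasm import assess
from linkasm._seq import revcomp
from linkasm.sim import DiploidGenome, Variant


def rand_seq(seed, n):
    rng = np.random.default_rng(seed)
    return "".join("ACGT"[c] for c in rng.integers(0, 4, n))


class TestNxx:
    @pytest.mark.parametrize(
        "lengths,x,expected",
        [([10], 50, 10), ([4, 3, 2, 1], 50, 3), ([5, 5], 75, 5), ([9, 1, 1], 50, 9)],
    )
    def test_examples(self, lengths, x, expected):
        assert assess.nxx(lengths, x) == expected

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            assess.nxx([], 50)

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(st.lists(st.integers(1, 1000), min_size=1, max_size=40),
           st.sampled_from([25, 50, 75, 90]))
    def test_matches_cumulative_sum_oracle(self, lengths, x):
        total = sum(lengths)
        best = None
        for cand in sorted(set(lengths), reverse=True):
            if sum(l for l in lengths if l >= cand) >= total * x / 100:
                best = cand
                break
        assert assess.nxx(lengths, x) == best


class TestFilterAndContigs:
    def test_ten_kb_boundary(self):
        recs = [("a", "A" * 9_999), ("b", "C" * 10_000)]
        out = assess.filter_scaffolds(recs)
        assert [n for n, _ in out] == ["b"]

    def test_all_pass_unchanged(self):
        recs = [("a", "A" * 20_000)]
        assert assess.filter_scaffolds(recs) == recs

    def test_empty(self):
        assert assess.filter_scaffolds([]) == []

    def test_contig_split_and_gap_fraction(self):
        lengths, frac = assess.contig_lengths(["ACGTNNNNACG"])
        assert lengths == [4, 3]
        assert frac == pytest.approx(4 / 11)

    def test_no_ns_single_contig(self):
        lengths, frac = assess.contig_lengths(["ACGTACGT"])
        assert lengths == [8] and frac == 0.0

    def test_all_ns(self):
        lengths, frac = assess.contig_lengths(["NNNN"])
        assert lengths == [] and frac == 1.0


class TestPerfectStretch:
    def test_identical_assembly(self):
        t = rand_seq(1, 10_000)
        assert assess.perfect_stretch_n50([("a", t)], [t]) == 10_000

    def test_single_substitution_splits(self):
        """A substitution at base 5000 (1-based) splits a 10 kb truth into
        stretches of 4999 and 5000; N50 = 5000."""
        t = rand_seq(2, 10_000)
        a = t[:4999] + ("A" if t[4999] != "A" else "C") + t[5000:]
        lengths = assess.perfect_stretches([("a", a)], [t])
        assert sorted(lengths) == [4999, 5000]
        assert assess.perfect_stretch_n50([("a", a)], [t]) == 5000

    def test_reverse_complement_counts(self):
        t = rand_seq(3, 5_000)
        assert assess.perfect_stretch_n50([("a", revcomp(t))], [t]) == 5_000

    def test_gap_terminates_stretch(self):
        t = rand_seq(4, 6_000)
        a = t[:3000] + "N" * 100 + t[3000:]
        lengths = assess.perfect_stretches([("a", a)], [t])
        assert sorted(lengths) == [3000, 3000]

    def test_wrong_allele_counts_as_error(self):
        """Displaying the other haplotype's allele breaks the stretch."""
        t0 = rand_seq(5, 8_000)
        pos = 4000
        t1 = t0[:pos] + ("G" if t0[pos] != "G" else "T") + t0[pos + 1 :]
        # assembly displays haplotype 1's allele: perfect for t1, split for t0
        assert assess.perfect_stretch_n50([("a", t1)], [t1]) == 8000
        lengths = assess.perfect_stretches([("a", t1)], [t0])
        assert max(lengths) < 8000

    def test_requires_truth(self):
        with pytest.raises(ValueError):
            assess.perfect_stretch_n50([("a", "ACGT" * 100)], [])


def _genome_with_snps(seed, n_snps=10, spacing=300):
    hap0 = rand_seq(seed, (n_snps + 1) * spacing)
    variants = []
    hap1 = list(hap0)
    for i in range(n_snps):
        p = (i + 1) * spacing
        alt = "A" if hap0[p] != "A" else "C"
        hap1[p] = alt
        variants.append(Variant(p, hap0[p], alt, "SNP"))
    return DiploidGenome("t", hap0, "".join(hap1), variants)


class TestPhasingError:
    def test_perfect_phasing_rate_zero(self):
        g = _genome_with_snps(6)
        v, w, rate = assess.phasing_error([(g.haplotype0, g.haplotype1)], g, min_size=100)
        assert v == 10 and w == 0 and rate == 0.0

    def test_six_four_majority(self):
        """Top arm carries haplotype 0 at six SNPs and haplotype 1 at four:
        4 wrong votes, rate 0.4."""
        g = _genome_with_snps(7)
        top = list(g.haplotype0)
        bottom = list(g.haplotype1)
        for i in range(6, 10):  # swap alleles at the last four SNPs
            p = (i + 1) * 300
            top[p], bottom[p] = bottom[p], top[p]
        v, w, rate = assess.phasing_error([("".join(top), "".join(bottom))], g, min_size=100)
        assert v == 10 and w == 4
        assert rate == pytest.approx(0.4)

    def test_engineered_long_switch_hand_count(self):
        """A single switch after SNP 7 leaves 3 minority votes: rate 0.3."""
        g = _genome_with_snps(8)
        sw = 7 * 300 + 150
        top = g.haplotype0[:sw] + g.haplotype1[sw:]
        bottom = g.haplotype1[:sw] + g.haplotype0[sw:]
        v, w, rate = assess.phasing_error([(top, bottom)], g, min_size=100)
        assert v == 10 and w == 3 and rate == pytest.approx(0.3)

    def test_no_votes_rate_none(self):
        g = _genome_with_snps(9)
        v, w, rate = assess.phasing_error([("ACGT" * 100, "TTAA" * 100)], g, min_size=1)
        assert v == 0 and rate is None

    def test_megabubble_size_threshold(self):
        g = _genome_with_snps(10)
        v, _, _ = assess.phasing_error(
            [(g.haplotype0, g.haplotype1)], g, min_size=10**7
        )
        assert v == 0


class TestMissingKmers:
    def test_identical_assembly_zero(self):
        ref = [("r", rand_seq(11, 2000))]
        out = assess.missing_kmer_fraction(ref, ref)
        assert out["missing_fraction"] == 0.0

    def test_truncated_assembly_fraction(self):
        """A 200-base reference with unique 100-mers, assembly holding its
        first 150 bases: 51 of 101 k-mers present, 50/101 missing."""
        r = rand_seq(12, 200)
        out = assess.missing_kmer_fraction([("a", r[:150])], [("r", r)])
        assert out["n_nonduplicate"] == 101
        assert out["missing_fraction"] == pytest.approx(50 / 101)

    def test_k_longer_than_reference_rejected(self):
        with pytest.raises(ValueError):
            assess.missing_kmer_fraction([("a", "ACGT" * 50)], [("r", "ACGT" * 10)])

    def test_duplicate_kmers_excluded(self):
        u = rand_seq(13, 400)
        rep = rand_seq(14, 200)
        ref = [("r", u + rep + rand_seq(15, 150) + rep)]
        out = assess.missing_kmer_fraction([("a", u)], ref)
        assert out["duplicate_fraction"] > 0

    def test_gc_strata(self):
        r = rand_seq(16, 3000)
        out = assess.missing_kmer_fraction([("a", r)], [("r", r)], stratify=True)
        assert out["strata"]["gc_40_60"] == 0.0


class TestLongRange:
    def test_identical_assembly_consistent(self):
        ref = [("r", rand_seq(17, 60_000))]
        assert assess.longrange_consistency(ref, ref, 10_000) == 0.0

    def test_interchromosomal_fusion_hand_count(self):
        """Fusing 35 kb from each of two chromosomes: of the 7 tiled 10-kb
        segments, the one spanning the junction is inconsistent."""
        c1, c2 = rand_seq(18, 60_000), rand_seq(19, 60_000)
        fused = c1[:35_000] + c2[:35_000]
        frac = assess.longrange_consistency(
            [("a", fused)], [("c1", c1), ("c2", c2)], 10_000
        )
        assert frac == pytest.approx(1 / 7)

    def test_twelve_percent_expansion_inconsistent(self):
        """A segment whose implied reference span is 12% longer than the
        segment size violates the 10% rule."""
        r = rand_seq(20, 40_000)
        a = r[:5_000] + r[6_200:]  # 1.2 kb deletion inside the first segment
        frac = assess.longrange_consistency([("a", a)], [("r", r)], 10_000)
        assert frac > 0

    def test_five_percent_within_tolerance(self):
        r = rand_seq(21, 40_000)
        a = r[:5_000] + r[5_500:]  # 0.5 kb deletion: span 10.5 kb, within 10%
        frac = assess.longrange_consistency([("a", a)], [("r", r)], 10_000)
        assert frac == 0.0

    def test_no_qualifying_segments(self):
        assert assess.longrange_consistency(
            [("a", "ACGT" * 100)], [("r", rand_seq(22, 50_000))], 10_000
        ) is None


class TestMoleculeLWM:
    def test_equal_spans(self):
        assert assess.inferred_molecule_lwm(spans=[10, 10]) == pytest.approx(10)

    def test_weighted_example(self):
        assert assess.inferred_molecule_lwm(spans=[10, 30]) == pytest.approx(25)

    def test_none_without_molecules(self):
        assert assess.inferred_molecule_lwm(spans=[]) is None

    def test_simulated_spans_recover_molecule_length(self):
        """Spans of ~60 uniform reads on 50 kb molecules underestimate the
        true length by ~2 read spacings: LWM within 15% of 50 kb."""
        rng = np.random.default_rng(23)
        spans = []
        for _ in range(800):
            n = max(rng.poisson(60), 2)
            pos = np.sort(rng.integers(0, 50_000, size=n))
            spans.append(int(pos[-1] - pos[0]))
        lwm = assess.inferred_molecule_lwm(spans=spans)
        assert abs(lwm - 50_000) / 50_000 < 0.15


class TestNovelWindows:
    def test_subset_assembly_no_windows(self):
        r = rand_seq(24, 60_000)
        out = assess.novel_windows([("a", r[5000:45_000])], [("r", r)])
        assert out == []

    def test_insertion_detected_and_merged(self):
        r = rand_seq(25, 80_000)
        novel = rand_seq(26, 20_000)
        a = r[:40_000] + novel + r[40_000:]
        out = assess.novel_windows([("a", a)], [("r", r)])
        assert len(out) == 1
        w = out[0]
        assert w.start <= 40_000 + 1000 and w.end >= 60_000 - 1000
        assert w.unique_fraction > 0.9

    def test_redundant_haplotype_copy_filtered(self):
        r = rand_seq(27, 60_000)
        novel = rand_seq(28, 15_000)
        a1 = ("h1", r[:30_000] + novel + r[30_000:])
        a2 = ("h2", r[:30_000] + novel + r[30_000:])
        out = assess.novel_windows([a1, a2], [("r", r)])
        assert len(out) == 1
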