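"""Scaffolding: O&O penalty, winner margin, pair/barcode merging, gap fill."""

import numpy as np
import pytest

from linkasm._seq import revcomp
from linkasm.lines import Arm, Bub, Gap, Line, Seg
from linkasm.scaffold import (
    Placements,
    barcode_scaffold,
    choose_oo,
    fill_gaps,
    oo_penalty,
    pair_scaffold,
    place_reads,
)
from linkasm.sim import ReadSet

from conftest import make_tiled_readset


class TestOOPenalty:
    def test_worked_jump_example(self):
        """Placements at 0/10/20 kb on line A and 20 kb into line B
        (offset 100 kb): mean separation 40 kb, jump quotient 2.5 >= 2.0,
        penalty 2.5."""
        positions = {0: {7: [0, 10_000, 20_000]}, 1: {7: [20_000]}}
        lengths = {0: 100_000, 1: 40_000}
        p = oo_penalty([(0, 1), (1, 1)], positions, lengths)
        assert p == pytest.approx(2.5)

    def test_small_quotient_discarded(self):
        """Jump separation 30 kb against mean 16.7 kb: quotient 1.8 < 2.0
        contributes nothing."""
        positions = {0: {7: [0, 10_000, 20_000]}, 1: {7: [0]}}
        lengths = {0: 50_000, 1: 40_000}
        p = oo_penalty([(0, 1), (1, 1)], positions, lengths)
        assert p == 0.0

    def test_no_bridging_barcode(self):
        positions = {0: {1: [0, 500]}, 1: {2: [100, 700]}}
        lengths = {0: 10_000, 1: 10_000}
        assert oo_penalty([(0, 1), (1, 1)], positions, lengths) == 0.0

    def test_missing_coordinate_system(self):
        with pytest.raises(ValueError):
            oo_penalty([(0, 1), (5, 1)], {0: {}}, {0: 1000})

    def test_orientation_symmetry(self):
        """A configuration and its global reverse complement score equally."""
        rng = np.random.default_rng(3)
        lengths = {0: 50_000, 1: 80_000, 2: 30_000}
        positions = {
            li: {
                bc: sorted(rng.integers(0, lengths[li], size=rng.integers(1, 6)).tolist())
                for bc in range(8)
            }
            for li in lengths
        }
        cfg = [(0, 1), (1, -1), (2, 1)]
        rc_cfg = [(2, -1), (1, 1), (0, -1)]
        a = oo_penalty(cfg, positions, lengths)
        b = oo_penalty(rc_cfg, positions, lengths)
        assert a == pytest.approx(b)


class TestChooseOO:
    def test_clear_winner(self):
        assert choose_oo([("a", 10.0), ("b", 90.0)]) == "a"

    def test_insufficient_margin(self):
        assert choose_oo([("a", 10.0), ("b", 50.0)]) is None

    def test_single_candidate(self):
        assert choose_oo([("a", 0.0)]) is None


def _line_of(seq: str) -> Line:
    return Line([Seg(seq, ())], [0])


def _mk_placements(units):
    """units: list of (line, pos, strand, barcode)."""
    arr = np.array(units, dtype=np.int64)
    return Placements(
        arr[:, 0], arr[:, 1], arr[:, 2].astype(np.int8), arr[:, 3], int(arr[:, 0].max()) + 1
    )


def _mk_reads(n_pairs, read_len=100):
    return ReadSet(
        barcodes=["A" * 16],
        barcode_ids=np.zeros(n_pairs, dtype=np.int64),
        r1=["A" * read_len] * n_pairs,
        r2=["A" * read_len] * n_pairs,
        read_length=read_len,
    )


class TestPairScaffold:
    def _fixture(self, partners):
        """5 pairs from the right end of line 0 to the left ends of the
        given partner lines."""
        rng = np.random.default_rng(0)
        seqs = ["".join("ACGT"[c] for c in rng.integers(0, 4, 5000)) for _ in range(3)]
        lines = [_line_of(s) for s in seqs]
        units = []
        for i, partner in enumerate(partners):
            units.append((0, 4800 - 5 * i, 1, i))  # near right end of line 0
            units.append((partner, 60 + 5 * i, -1, i))  # near left end of partner
        placements = _mk_placements(units)
        reads = _mk_reads(len(partners))
        return lines, placements, reads

    def test_unambiguous_merge(self):
        lines, placements, reads = self._fixture([1, 1, 1, 1, 1])
        merged, n = pair_scaffold(lines, placements, reads)
        assert n == 1
        assert len(merged) == 2
        big = max(merged, key=lambda l: l.length)
        kinds = [type(e).__name__ for e in big.elements]
        assert kinds == ["Seg", "Gap", "Seg"]
        assert big.elements[1].kind == "pair"

    def test_ambiguous_ends_not_merged(self):
        lines, placements, reads = self._fixture([1, 1, 1, 1, 2, 2, 2, 2])
        merged, n = pair_scaffold(lines, placements, reads)
        assert n == 0
        assert len(merged) == 3

    def test_below_threshold_not_merged(self):
        lines, placements, reads = self._fixture([1, 1])
        merged, n = pair_scaffold(lines, placements, reads)
        assert n == 0

    def test_no_links_unchanged(self):
        lines = [_line_of("ACGT" * 500), _line_of("TTGC" * 500)]
        placements = _mk_placements([(0, 10, 1, 0), (1, 10, 1, 0)])
        merged, n = pair_scaffold(lines, placements, _mk_reads(1))
        assert n == 0 and len(merged) == 2


def _simulate_line_level(rng, chunk_len=100_000, mol_len=50_000, lpm=60):
    """Molecule placements over two adjacent genome chunks A|B.

    Returns (positions dict per line, placements for barcode_scaffold).
    Line 0 covers [0, chunk_len), line 1 covers [chunk_len, 2*chunk_len).
    """
    g = 2 * chunk_len
    n_mol = int(np.ceil(g * 155 / mol_len))
    units = []
    for bc in range(n_mol):
        start = int(rng.integers(-(mol_len - 1), g))
        end = min(start + mol_len, g)
        start = max(start, 0)
        n_reads = rng.poisson(lpm * (end - start) / mol_len)
        for p in np.sort(rng.integers(start, max(end, start + 1), size=n_reads)):
            li = 0 if p < chunk_len else 1
            pos = int(p) if li == 0 else int(p) - chunk_len
            units.append((li, pos, 1, bc))
    return _mk_placements(units)


class TestBarcodeScaffold:
    def test_adjacent_chunks_merge_in_truth_orientation(self):
        rng = np.random.default_rng(1)
        rng2 = np.random.default_rng(2)
        a = "".join("ACGT"[c] for c in rng2.integers(0, 4, 100_000))
        b = "".join("ACGT"[c] for c in rng2.integers(0, 4, 100_000))
        lines = [_line_of(a), _line_of(b)]
        placements = _simulate_line_level(rng)
        merged, n = barcode_scaffold(lines, placements)
        assert n == 1
        assert len(merged) == 1
        sp = merged[0].spelled()
        # truth order and orientation: A forward then B forward
        assert sp.startswith(a[:500]) and sp.endswith(b[-500:])

    def test_twenty_replicates_no_contradicted_merges(self):
        """Across 20 replicates, every accepted merge must agree with the
        truth order and orientation (misassembly-free at the 60.0 margin)."""
        wrong = 0
        total = 0
        for rep in range(20):
            rng = np.random.default_rng(100 + rep)
            a = "A" * 50_000 + "C" * 50_000  # distinguishable halves
            b = "G" * 50_000 + "T" * 50_000
            lines = [_line_of(a), _line_of(b)]
            placements = _simulate_line_level(rng)
            merged, n = barcode_scaffold(lines, placements)
            total += n
            for line in merged:
                sp = line.spelled()
                if len(sp) > 150_000 and not (
                    sp.startswith("A") and sp.endswith("T")
                ):
                    wrong += 1
        assert total >= 15  # merges happen in nearly every replicate
        assert wrong == 0

    def test_unrelated_lines_not_merged(self):
        """Lines sharing few barcodes (different chromosomes) stay apart."""
        rng = np.random.default_rng(5)
        a = "".join("ACGT"[c] for c in rng.integers(0, 4, 100_000))
        b = "".join("ACGT"[c] for c in rng.integers(0, 4, 100_000))
        lines = [_line_of(a), _line_of(b)]
        units = []
        for bc in range(300):  # separate barcode pools per line
            li = bc % 2
            for p in rng.integers(0, 100_000, size=20):
                units.append((li, int(p), 1, bc))
        merged, n = barcode_scaffold(lines, _mk_placements(units))
        assert n == 0

    def test_single_line_unchanged(self):
        lines = [_line_of("ACGT" * 6000)]
        units = [(0, int(p), 1, b) for b in range(20) for p in range(0, 24_000, 1000)]
        merged, n = barcode_scaffold(lines, _mk_placements(units))
        assert n == 0 and len(merged) == 1


class TestGapFill:
    def test_gap_closed_matches_truth(self):
        rng = np.random.default_rng(11)
        truth = "".join("ACGT"[c] for c in rng.integers(0, 4, 5000))
        left, mid, right = truth[:2000], truth[2000:3000], truth[3000:]
        line = Line([Seg(left, ()), Gap("barcode", 1000), Seg(right, ())], [0, 0, 0])
        reads = make_tiled_readset([truth], stride=6)
        placements = place_reads(reads, [line], 48)
        filled, n = fill_gaps(
            line, reads, reads.pairs_of_barcode(), placements, 0, 48
        )
        assert n == 1
        assert filled.spelled() == truth

    def test_unfillable_gap_unchanged(self):
        """No reads span the gap: the gap edge stays."""
        rng = np.random.default_rng(12)
        left = "".join("ACGT"[c] for c in rng.integers(0, 4, 2000))
        right = "".join("ACGT"[c] for c in rng.integers(0, 4, 2000))
        line = Line([Seg(left, ()), Gap("barcode", 500), Seg(right, ())], [0, 0, 0])
        reads = make_tiled_readset([left, right], stride=6)
        placements = place_reads(reads, [line], 48)
        filled, n = fill_gaps(
            line, reads, reads.pairs_of_barcode(), placements, 0, 48
        )
        assert n == 0
        assert any(isinstance(e, Gap) for e in filled.elements)

    def test_repeat_flanked_gap_unchanged(self):
        """Flanks ending in a long shared repeat give ambiguous anchors."""
        rng = np.random.default_rng(13)
        u1 = "".join("ACGT"[c] for c in rng.integers(0, 4, 1500))
        u2 = "".join("ACGT"[c] for c in rng.integers(0, 4, 1500))
        rep = "".join("ACGT"[c] for c in rng.integers(0, 4, 700))
        left = u1 + rep
        right = rep + u2
        truth = left + right  # zero-size gap between repeat copies
        line = Line([Seg(left, ()), Gap("barcode", 100), Seg(right, ())], [0, 0, 0])
        reads = make_tiled_readset([truth], stride=6)
        placements = place_reads(reads, [line], 48)
        filled, n = fill_gaps(
            line, reads, reads.pairs_of_barcode(), placements, 0, 48
        )
        if n:  # if it closed, the sequence must still match the truth
            assert filled.spelled() in truth
        else:
            assert any(isinstance(e, Gap) for e in filled.elements)
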