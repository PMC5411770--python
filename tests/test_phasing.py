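"""Phasing: molecules, the Max-Min score, greedy optimisation, blocks."""

import numpy as np
import pytest

from linkasm.lines import Arm, Bub, Line, Seg
from linkasm.phasing import (
    MoleculeObservation,
    PhasingState,
    finalize_phase_blocks,
    infer_molecules,
    optimize_phasing,
    phasing_score,
)
from linkasm.scaffold import Placements


def _placements(units):
    arr = np.array(units, dtype=np.int64)
    return Placements(
        arr[:, 0], arr[:, 1], arr[:, 2].astype(np.int8), arr[:, 3],
        int(arr[:, 0].max()) + 1,
    )


def _line_with_bubbles(n, spacing=1000):
    """n simple bubbles separated by homozygous segments."""
    elements = [Seg("A" * spacing, ())]
    seams = [0]
    for i in range(n):
        elements.append(Bub([Arm("C" * 60, ()), Arm("G" * 60, ())]))
        seams.append(0)
        elements.append(Seg("T" * spacing, ()))
        seams.append(0)
    return Line(elements, seams)


class TestInferMolecules:
    def test_split_at_100kb_gap(self):
        units = [(0, p, 1, 5) for p in (0, 30_000, 60_000, 200_000, 230_000)]
        mols = infer_molecules(0, None, _placements(units), {})
        assert len(mols) == 2
        assert (mols[0].start, mols[0].end) == (0, 60_000)
        assert (mols[1].start, mols[1].end) == (200_000, 230_000)

    def test_single_read_single_molecule(self):
        mols = infer_molecules(0, None, _placements([(0, 42, 1, 1)]), {})
        assert len(mols) == 1 and mols[0].votes == {}

    def test_dense_reads_one_molecule(self):
        units = [(0, p, 1, 2) for p in range(0, 500_001, 10_000)]
        mols = infer_molecules(0, None, _placements(units), {})
        assert len(mols) == 1

    def test_vote_majority_per_bubble(self):
        units = [(0, p, 1, 3) for p in range(5)]
        votes = {0: [(0, 7, 0)], 1: [(0, 7, 0)], 2: [(0, 7, 1)], 3: [(0, 9, 1)], 4: [(0, 9, 1)]}
        mols = infer_molecules(0, None, _placements(units), votes)
        assert mols[0].votes == {7: 1, 9: -1}


class TestScore:
    def test_worked_example(self):
        """Votes (+1,+1,0,-1) score 1; (+1,+1) score 2; total 3."""
        m1 = MoleculeObservation(0, 0, [0], {0: 1, 1: 1, 3: -1})
        m2 = MoleculeObservation(1, 0, [0], {0: 1, 1: 1})
        state = PhasingState([0, 1, 2, 3], {i: 1 for i in range(4)})
        assert phasing_score([m1, m2], state) == 3

    def test_all_silent(self):
        m = MoleculeObservation(0, 0, [0], {})
        state = PhasingState([0, 1], {0: 1, 1: 1})
        assert phasing_score([m], state) == 0

    def test_coherent_molecule_scores_its_votes(self):
        m = MoleculeObservation(0, 0, [0], {i: -1 for i in range(7)})
        state = PhasingState(list(range(7)), {i: 1 for i in range(7)})
        assert phasing_score([m], state) == 7

    def test_global_flip_symmetry(self):
        rng = np.random.default_rng(0)
        mols = []
        for i in range(30):
            votes = {int(b): int(v) for b, v in zip(rng.choice(20, 5, replace=False), rng.choice([-1, 1], 5))}
            mols.append(MoleculeObservation(i, 0, [0], votes))
        s1 = PhasingState(list(range(20)), {i: 1 for i in range(20)})
        s2 = PhasingState(list(range(20)), {i: -1 for i in range(20)})
        assert phasing_score(mols, s1) == phasing_score(mols, s2)


def _simulate_votes(rng, n_bub, truth, mol_span=50, lpm_frac=0.3, err=1e-3, n_mol=300):
    """Molecule observations consistent with a truth orientation."""
    mols = []
    for i in range(n_mol):
        start = int(rng.integers(-mol_span, n_bub))
        hap = int(rng.integers(2))
        votes = {}
        for b in range(max(start, 0), min(start + mol_span, n_bub)):
            if rng.random() < lpm_frac:
                v = truth[b] if hap == 0 else -truth[b]
                if rng.random() < err:
                    v = -v
                votes[b] = int(v)
        if votes:
            mols.append(MoleculeObservation(i, 0, sorted(votes), votes))
    return mols


class TestOptimize:
    def test_no_molecules_unchanged(self):
        state = PhasingState([0, 1], {0: 1, 1: 1})
        out = optimize_phasing([], state)
        assert out.orientation == {0: 1, 1: 1} and out.score == 0

    def test_coherent_molecules_reach_perfect_state(self):
        rng = np.random.default_rng(1)
        truth = rng.choice([-1, 1], 25)
        mols = _simulate_votes(rng, 25, truth, mol_span=10, lpm_frac=0.8, err=0.0, n_mol=120)
        state = optimize_phasing(mols, PhasingState(list(range(25)), {i: 1 for i in range(25)}))
        total_votes = sum(len(m.votes) for m in mols)
        assert state.score == total_votes
        s = np.array([state.orientation[i] for i in range(25)])
        agreement = np.mean(s == truth)
        assert agreement in (0.0, 1.0)  # exact up to a global flip

    def test_score_never_decreases(self):
        rng = np.random.default_rng(2)
        truth = rng.choice([-1, 1], 30)
        mols = _simulate_votes(rng, 30, truth, err=0.05)
        init = PhasingState(list(range(30)), {i: 1 for i in range(30)})
        s0 = phasing_score(mols, init)
        out = optimize_phasing(mols, init)
        assert out.score >= s0
        assert out.score == phasing_score(mols, out)

    def test_parameter_recovery_twenty_replicates(self):
        """At the study conditions (50 kb molecules with ~60 pairs, het
        sites every ~1 kb, 0.1% vote noise), the recovered orientations
        match truth at >99% of bubbles within each block, with long
        switches in at most 2 of 20 replicates."""
        n_rep = 20
        bad_rate = 0
        long_switches = 0
        for rep in range(n_rep):
            rng = np.random.default_rng(1000 + rep)
            n_bub = 200  # a 200-kb line at 1 het/kb
            truth = rng.choice([-1, 1], n_bub)
            mols = _simulate_votes(rng, n_bub, truth, mol_span=50, lpm_frac=0.3, err=1e-3, n_mol=700)
            state = optimize_phasing(
                mols, PhasingState(list(range(n_bub)), {i: 1 for i in range(n_bub)})
            )
            state = finalize_phase_blocks(mols, state, None)
            errs = 0
            tot = 0
            for lo, hi in state.blocks:
                idx = [i for i in range(lo, hi + 1) if i in state.orientation and i not in state.excluded]
                s = np.array([state.orientation[i] for i in idx])
                t = np.array([truth[i] for i in idx])
                agree = int(np.sum(s == t))
                errs += min(agree, len(idx) - agree)
                tot += len(idx)
                wrong = s != (t if agree * 2 >= len(idx) else -t)
                run = 0
                for w in wrong:
                    run = run + 1 if w else 0
                    if run >= 10:
                        long_switches += 1
                        break
            if tot:
                bad_rate += errs / tot
        assert bad_rate / n_rep < 1e-2
        assert long_switches <= 2


class TestFinalize:
    def test_single_vote_bubble_excluded(self):
        mols = [
            MoleculeObservation(0, 0, [0], {0: 1, 1: 1}),
            MoleculeObservation(1, 0, [0], {0: 1, 1: 1}),
            MoleculeObservation(2, 0, [0], {0: 1, 1: 1, 2: 1}),
        ]
        state = optimize_phasing(mols, PhasingState([0, 1, 2], {i: 1 for i in range(3)}))
        state = finalize_phase_blocks(mols, state, None)
        # bubble 2 has a single vote: flipping changes the score by 2 < 4
        assert 2 in state.excluded
        assert 0 not in state.excluded and 1 not in state.excluded

    def test_homozygous_stretch_breaks_blocks(self):
        """No molecule spans the gap between two vote clusters: the
        phasing breaks there into two blocks."""
        rng = np.random.default_rng(4)
        truth = rng.choice([-1, 1], 60)
        left = _simulate_votes(rng, 25, truth[:25], mol_span=10, lpm_frac=0.8, err=0.0, n_mol=150)
        right_raw = _simulate_votes(rng, 25, truth[35:], mol_span=10, lpm_frac=0.8, err=0.0, n_mol=150)
        right = [
            MoleculeObservation(m.barcode, 0, [p + 35 for p in m.positions],
                                {b + 35: v for b, v in m.votes.items()})
            for m in right_raw
        ]
        mols = left + right
        state = optimize_phasing(mols, PhasingState(list(range(60)), {i: 1 for i in range(60)}))
        state = finalize_phase_blocks(mols, state, None)
        assert len(state.blocks) >= 2
        spans = [(lo, hi) for lo, hi in state.blocks]
        assert any(hi <= 30 for lo, hi in spans) and any(lo >= 30 for lo, hi in spans)

    def test_all_coherent_single_block(self):
        rng = np.random.default_rng(5)
        truth = rng.choice([-1, 1], 20)
        mols = _simulate_votes(rng, 20, truth, mol_span=12, lpm_frac=0.9, err=0.0, n_mol=200)
        state = optimize_phasing(mols, PhasingState(list(range(20)), {i: 1 for i in range(20)}))
        state = finalize_phase_blocks(mols, state, None)
        assert len(state.blocks) == 1
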