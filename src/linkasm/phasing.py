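"""Phasing lines into megabubbles from molecule votes.

Each simple (two-arm) bubble on a line gets an orientation: one arm on
"top", one on the "bottom".  A molecule -- the reads of one barcode on one
line, split wherever successive reads are more than 100 kb apart -- votes
+1/-1/0 at each bubble depending on which arm its reads support.  The
score of a phasing is the sum over molecules of Max(pluses, minuses) -
Min(pluses, minuses); it is maximised greedily by three perturbation
families (make one molecule coherent, flip one bubble, pivot all bubbles
left of a point), accepting only score increases.  Bubbles whose flip
barely changes the score are excluded (copied to both arms); pivots that
barely change it break the line into separate phase blocks, whose phased
extents become megabubbles.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .kmers import encode_batch, packed_kmers
from .lines import Bub, Line

MOLECULE_GAP = 100_000  # split molecules at larger read gaps
BUBBLE_EXCLUDE_THRESHOLD = 4  # |score change of a flip| below this -> excluded
PIVOT_BREAK_THRESHOLD = 10  # |score change of a pivot| below this -> phase break


@dataclass
class MoleculeObservation:
    """Same-barcode reads on one line, with votes over its simple bubbles."""

    barcode: int
    line: int
    positions: list[int]
    votes: dict[int, int]  # bubble element index -> +1 (arm 0) / -1 (arm 1)

    @property
    def start(self) -> int:
        return self.positions[0]

    @property
    def end(self) -> int:
        return self.positions[-1]


@dataclass
class PhasingState:
    """Orientation of each simple bubble plus block structure."""

    bubble_elems: list[int]  # element indices of simple bubbles, left to right
    orientation: dict[int, int]  # elem -> +1 (arm0 on top) / -1
    excluded: set[int] = field(default_factory=set)
    breaks: list[int] = field(default_factory=list)  # bubble-order break points
    score: int = 0
    blocks: list[tuple[int, int]] = field(default_factory=list)  # elem spans

    @classmethod
    def initial(cls, line: Line) -> "PhasingState":
        elems = [i for i, el in line.bubbles() if el.is_simple]
        return cls(elems, {i: 1 for i in elems})

    def top_arm(self, elem: int) -> int:
        return 0 if self.orientation.get(elem, 1) > 0 else 1


# ---------------------------------------------------------------- votes


def build_vote_index(lines: list[Line], k: int):
    """Canonical k-mer -> (line, bubble element, arm) for arm-distinctive
    k-mers of simple bubbles; ambiguous k-mers are dropped."""
    idx: dict[int, tuple[int, int, int] | None] = {}
    for li, line in enumerate(lines):
        for ei, el in line.bubbles():
            if not el.is_simple:
                continue
            keysets = []
            for arm in el.arms:
                if len(arm.seq) < k:
                    keysets.append(set())
                    continue
                codes = encode_batch([arm.seq])
                hi, lo, valid, _ = packed_kmers(codes, k)
                keysets.append(
                    {
                        (int(h) << 64) | int(l)
                        for h, l, v in zip(hi[0], lo[0], valid[0])
                        if v
                    }
                )
            for a in (0, 1):
                for key in keysets[a] - keysets[1 - a]:
                    if key in idx:
                        idx[key] = None
                    else:
                        idx[key] = (li, ei, a)
    return {key: val for key, val in idx.items() if val is not None}


def read_votes(reads, vote_index, k: int, batch: int = 8000):
    """Per read unit: (line, elem, vote) hits from arm-distinctive k-mers.

    A read votes for an arm only if all its distinctive hits agree; reads
    touching both arms' k-mers (e.g. via errors) stay silent.
    """
    hits: dict[int, tuple[int, int, int]] = {}

    def scan(seqs, units):
        codes = encode_batch(seqs)
        hi, lo, valid, _ = packed_kmers(codes, k)
        for r, u in enumerate(units):
            h, l, v = hi[r], lo[r], valid[r]
            found: dict[tuple[int, int], set[int]] = {}
            for j in range(len(h)):
                if not v[j]:
                    continue
                hit = vote_index.get((int(h[j]) << 64) | int(l[j]))
                if hit is not None:
                    li, ei, a = hit
                    found.setdefault((li, ei), set()).add(a)
            clean = [(li, ei, arms.pop()) for (li, ei), arms in found.items() if len(arms) == 1]
            if len(clean) == 1:
                hits[u] = clean[0]
            elif len(clean) > 1:
                # a read can legitimately span two nearby bubbles; keep all
                for li, ei, a in clean:
                    hits.setdefault(u, None)
                hits[u] = ("multi", clean)
    for b0 in range(0, reads.n_pairs, batch):
        b1 = min(b0 + batch, reads.n_pairs)
        ids = list(range(b0, b1))
        scan([reads.r1[i] for i in ids], [2 * i for i in ids])
        scan([reads.r2[i] for i in ids], [2 * i + 1 for i in ids])
    out: dict[int, list[tuple[int, int, int]]] = {}
    for u, h in hits.items():
        if h is None:
            continue
        if h[0] == "multi":
            out[u] = h[1]
        else:
            out[u] = [h]
    return out


def infer_molecules(
    line_id: int,
    line: Line,
    placements,
    unit_votes: dict[int, list[tuple[int, int, int]]],
    max_gap: int = MOLECULE_GAP,
) -> list[MoleculeObservation]:
    """Group placed reads by barcode and split at gaps > max_gap.

    Each fragment becomes a molecule observation; its vote at a bubble is
    the majority over its reads (ties are silent).
    """
    per_bc: dict[int, list[int]] = {}
    for u in np.flatnonzero(placements.line == line_id):
        per_bc.setdefault(int(placements.barcode[u]), []).append(int(u))
    molecules = []
    for bc in sorted(per_bc):
        units = sorted(per_bc[bc], key=lambda u: int(placements.pos[u]))
        frags: list[list[int]] = [[units[0]]]
        for prev, u in zip(units, units[1:]):
            if int(placements.pos[u]) - int(placements.pos[prev]) > max_gap:
                frags.append([])
            frags[-1].append(u)
        for frag in frags:
            tallies: dict[int, int] = {}
            for u in frag:
                for (li, ei, a) in unit_votes.get(u, []):
                    if li != line_id:
                        continue
                    tallies[ei] = tallies.get(ei, 0) + (1 if a == 0 else -1)
            votes = {ei: (1 if t > 0 else -1) for ei, t in tallies.items() if t != 0}
            molecules.append(
                MoleculeObservation(
                    bc, line_id, [int(placements.pos[u]) for u in frag], votes
                )
            )
    return molecules


# ---------------------------------------------------------------- score & moves


class _VoteMatrix:
    """Sparse molecule x bubble vote bookkeeping in bubble order."""

    def __init__(self, molecules: list[MoleculeObservation], state: PhasingState):
        order = {ei: b for b, ei in enumerate(state.bubble_elems)}
        self.n_bub = len(state.bubble_elems)
        self.mols: list[tuple[np.ndarray, np.ndarray]] = []
        self.by_bubble: dict[int, list[int]] = {}
        for mol in molecules:
            bs, vs = [], []
            for ei, v in sorted(mol.votes.items()):
                if ei in order:
                    bs.append(order[ei])
                    vs.append(v)
            if not bs:
                continue
            m = len(self.mols)
            self.mols.append((np.array(bs), np.array(vs)))
            for b in bs:
                self.by_bubble.setdefault(b, []).append(m)

    def totals(self, s: np.ndarray) -> np.ndarray:
        return np.array([int(np.sum(v * s[b])) for b, v in self.mols])


def phasing_score_matrix(vm: _VoteMatrix, s: np.ndarray) -> int:
    return int(np.sum(np.abs(vm.totals(s))))


def phasing_score(molecules: list[MoleculeObservation], state: PhasingState) -> int:
    """Sum over molecules of Max(pluses, minuses) - Min(pluses, minuses)."""
    total = 0
    for mol in molecules:
        plus = minus = 0
        for ei, v in mol.votes.items():
            sv = v * state.orientation.get(ei, 1)
            if sv > 0:
                plus += 1
            elif sv < 0:
                minus += 1
        total += max(plus, minus) - min(plus, minus)
    return total


def _flip_delta(vm: _VoteMatrix, s, t, flip_set: set[int]) -> tuple[int, dict[int, int]]:
    affected: dict[int, int] = {}
    for b in flip_set:
        for m in vm.by_bubble.get(b, []):
            bs, vs = vm.mols[m]
            a = affected.get(m, 0)
            for bb, vv in zip(bs, vs):
                if bb == b:
                    a += vv * s[b]
            affected[m] = a
    delta = 0
    for m, a in affected.items():
        delta += abs(t[m] - 2 * a) - abs(t[m])
    return delta, affected


def optimize_phasing(
    molecules: list[MoleculeObservation],
    state: PhasingState,
    max_sweeps: int = 50,
) -> PhasingState:
    """Greedy hill climb over the three perturbation families.

    Sweeps molecule-coherence moves, single-bubble flips, then pivots,
    accepting only strict score increases, until a full cycle changes
    nothing.  Deterministic: fixed sweep order, first-improvement.
    """
    vm = _VoteMatrix(molecules, state)
    n = vm.n_bub
    if n == 0 or not vm.mols:
        state.score = phasing_score(molecules, state)
        return state
    s = np.array([state.orientation[ei] for ei in state.bubble_elems], dtype=np.int64)
    t = vm.totals(s)

    def apply_flip(flip_set, affected):
        for b in flip_set:
            s[b] = -s[b]
        for m, a in affected.items():
            t[m] = t[m] - 2 * a

    for _ in range(max_sweeps):
        improved = False
        # 1. make each molecule coherent
        for m, (bs, vs) in enumerate(vm.mols):
            if abs(t[m]) == len(bs):
                continue
            target = 1 if t[m] >= 0 else -1
            flip_set = {int(b) for b, v in zip(bs, vs) if v * s[b] == -target}
            if not flip_set:
                continue
            delta, affected = _flip_delta(vm, s, t, flip_set)
            if delta > 0:
                apply_flip(flip_set, affected)
                improved = True
        # 2. individual bubble flips
        for b in range(n):
            delta, affected = _flip_delta(vm, s, t, {b})
            if delta > 0:
                apply_flip({b}, affected)
                improved = True
        # 3. pivots: flip everything left of p
        while True:
            deltas = _pivot_deltas(vm, s, t, n)
            p = int(np.argmax(deltas))
            if deltas[p] <= 0:
                break
            flip_set = set(range(p))
            delta, affected = _flip_delta(vm, s, t, flip_set)
            apply_flip(flip_set, affected)
            improved = True
        if not improved:
            break
    for b, ei in enumerate(state.bubble_elems):
        state.orientation[ei] = int(s[b])
    state.score = int(np.sum(np.abs(t)))
    return state


def _pivot_deltas(vm: _VoteMatrix, s, t, n) -> np.ndarray:
    """Score change of pivoting at each point p (flip bubbles b < p)."""
    diff = np.zeros(n + 2, dtype=np.int64)
    for m, (bs, vs) in enumerate(vm.mols):
        sv = vs * s[bs]
        prefix = 0
        tm = t[m]
        # between consecutive vote positions the partial sum is constant
        for i in range(len(bs)):
            prefix += int(sv[i])
            lo = int(bs[i]) + 1
            hi = int(bs[i + 1]) if i + 1 < len(bs) else n - 1
            if lo > hi:
                continue
            contrib = abs(tm - 2 * prefix) - abs(tm)
            diff[lo] += contrib
            diff[hi + 1] -= contrib
    out = np.cumsum(diff)[: n + 1]
    out[0] = 0  # pivot at 0 flips nothing
    if n >= 1:
        out[n] = 0  # flipping everything leaves the score unchanged
    return out[:n] if n > 0 else out


def finalize_phase_blocks(
    molecules: list[MoleculeObservation],
    state: PhasingState,
    line: Line,
    bubble_threshold: int = BUBBLE_EXCLUDE_THRESHOLD,
    pivot_threshold: int = PIVOT_BREAK_THRESHOLD,
) -> PhasingState:
    """Exclude weak bubbles, break weak pivots, and emit megabubble spans.

    A bubble is excluded when flipping it changes the score by less than
    bubble_threshold (e.g. one molecule with one vote: effect 2).  The
    phasing breaks at pivots whose effect is below pivot_threshold --
    notably across long homozygous stretches, where no molecule links the
    two sides.  Megabubbles span the phased bubbles between breaks.
    """
    vm = _VoteMatrix(molecules, state)
    n = vm.n_bub
    s = np.array(
        [state.orientation[ei] for ei in state.bubble_elems], dtype=np.int64
    ) if n else np.zeros(0, dtype=np.int64)
    t = vm.totals(s) if n else np.zeros(0, dtype=np.int64)
    excluded = set()
    for b, ei in enumerate(state.bubble_elems):
        delta, _ = _flip_delta(vm, s, t, {b})
        if abs(delta) < bubble_threshold:
            excluded.add(ei)
    breaks = []
    if n:
        deltas = _pivot_deltas(vm, s, t, n)
        for p in range(1, n):
            if abs(int(deltas[p])) < pivot_threshold:
                breaks.append(p)
    state.excluded = excluded
    state.breaks = breaks
    # blocks over phased bubbles
    phased = [ei for ei in state.bubble_elems if ei not in excluded]
    order = {ei: b for b, ei in enumerate(state.bubble_elems)}
    blocks: list[tuple[int, int]] = []
    cur: list[int] = []
    break_set = set(breaks)
    for b, ei in enumerate(state.bubble_elems):
        if b in break_set and cur:
            blocks.append((cur[0], cur[-1]))
            cur = []
        if ei not in excluded:
            cur.append(ei)
    if cur:
        blocks.append((cur[0], cur[-1]))
    state.blocks = blocks
    return state


def phase_line(
    line_id: int,
    line: Line,
    placements,
    unit_votes,
    bubble_threshold: int = BUBBLE_EXCLUDE_THRESHOLD,
    pivot_threshold: int = PIVOT_BREAK_THRESHOLD,
) -> tuple[PhasingState, list[MoleculeObservation]]:
    """Full phasing of one line; attaches the state to the line."""
    state = PhasingState.initial(line)
    molecules = infer_molecules(line_id, line, placements, unit_votes)
    state = optimize_phasing(molecules, state)
    state = finalize_phase_blocks(
        molecules, state, line, bubble_threshold, pivot_threshold
    )
    line.phasing = state
    return state, molecules
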