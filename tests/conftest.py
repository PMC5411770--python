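"""Shared fixtures: deterministic read sets, tiny graphs, one desk-scale run."""

import numpy as np
import pytest

from linkasm._seq import revcomp
from linkasm.sim import ReadSet


def make_tiled_readset(
    seqs, insert=350, stride=7, glen1=134, glen2=150, n_barcodes=4
):
    """Error-free read pairs tiling each sequence densely.

    Pairs start every `stride` bases; barcodes cycle so every k-mer is seen
    in at least two barcodes (the prefilter then keeps everything).
    """
    r1, r2, bids = [], [], []
    bc = 0
    for seq in seqs:
        for start in range(0, len(seq) - insert + 1, stride):
            frag = seq[start : start + insert]
            r1.append(frag[:glen1])
            r2.append(revcomp(frag[-glen2:]))
            bids.append(bc % n_barcodes)
            bc += 1
    barcodes = [f"{'ACGT'[i % 4] * 16}"[:16] for i in range(n_barcodes)]
    barcodes = ["".join("ACGT"[(i + j) % 4] for j in range(16)) for i in range(n_barcodes)]
    return ReadSet(
        barcodes=barcodes,
        barcode_ids=np.array(bids, dtype=np.int64),
        r1=r1,
        r2=r2,
        read_length=glen2,
        barcode_length=16,
    )


def readset_kmer_iter(reads):
    for i in range(reads.n_pairs):
        b = int(reads.barcode_ids[i])
        yield reads.r1[i], b
        yield reads.r2[i], b


class FakeGraph:
    """Minimal sequence-graph protocol for structural tests.

    Built from explicit edge descriptions (seq, tail vertex, head vertex);
    a reverse-complement partner is synthesised for every edge, living on
    mirrored vertices.
    """

    def __init__(self, edges, k=1):
        # edges: list of (seq, tail, head)
        self.k = k
        n = len(edges)
        self._seqs = [e[0] for e in edges] + [revcomp(e[0]) for e in edges]
        self._tail = [e[1] for e in edges] + [("m", e[2]) for e in edges]
        self._head = [e[2] for e in edges] + [("m", e[1]) for e in edges]
        self._rc = [i + n for i in range(n)] + list(range(n))
        vmap = {}
        self._tv, self._hv = [], []
        self._out, self._in = {}, {}
        for i in range(2 * n):
            t = vmap.setdefault(self._tail[i], len(vmap))
            h = vmap.setdefault(self._head[i], len(vmap))
            self._tv.append(t)
            self._hv.append(h)
            self._out.setdefault(t, []).append(i)
            self._in.setdefault(h, []).append(i)
        self.n_vertices = len(vmap)

    @property
    def n_edges(self):
        return len(self._seqs)

    def seq(self, e):
        return self._seqs[e]

    def rc(self, e):
        return self._rc[e]

    def support(self, e):
        return 1.0

    def tail_vertex(self, e):
        return self._tv[e]

    def head_vertex(self, e):
        return self._hv[e]

    def out_edges(self, v):
        return self._out.get(v, [])

    def in_edges(self, v):
        return self._in.get(v, [])

    def succs(self, e):
        return self.out_edges(self._hv[e])

    def preds(self, e):
        return self.in_edges(self._tv[e])


@pytest.fixture(scope="session")
def desk_run():
    """One desk-scale end-to-end assembly shared across tests.

    150 kb diploid genome at the standard library conditions (50 kb
    molecules, 60 read pairs per molecule, 0.36x per-molecule depth,
    het SNP rate 1e-3).
    """
    from linkasm.pipeline import run_assembly
    from linkasm.sim import simulate_library

    genome, model, molecules, reads = simulate_library(150_000, seed=7)
    bundle = run_assembly(reads)
    return {
        "genome": genome,
        "model": model,
        "molecules": molecules,
        "reads": reads,
        "bundle": bundle,
    }
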