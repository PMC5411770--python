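"""The base graph: a de Bruijn graph whose edges are unbranched sequences.

Edges represent maximal unbranched DNA stretches; abutting edges overlap by
k-1 bases.  The graph carries an involution pairing every edge with its
reverse complement, so both strands are always represented.  Construction
is the standard unitig compression of the k-mer set; cleaning removes
weakly supported dead-end tips and recompresses.
"""

from __future__ import annotations

from typing import Iterable

import numpy as np

from ._seq import revcomp
from .kmers import KmerTable, encode_batch, packed_kmers

class BaseGraph:
    """Bidirected sequence graph with reverse-complement involution.

    Vertices are the (k-1)-base overlaps; edge e runs from tail_vertex(e)
    to head_vertex(e).  rc(e) is the edge spelling the reverse complement.
    """

    def __init__(self, k: int, edges: list[str], support: list[float] | None = None):
        self.k = k
        self.edges = list(edges)
        self.support_arr = list(support) if support is not None else [1.0] * len(edges)
        seq_to_id: dict[str, int] = {}
        for i, s in enumerate(self.edges):
            seq_to_id.setdefault(s, i)
        self._rc = [seq_to_id[revcomp(s)] for s in self.edges]
        vmap: dict[str, int] = {}
        self._tail: list[int] = []
        self._head: list[int] = []
        self._out: dict[int, list[int]] = {}
        self._in: dict[int, list[int]] = {}
        for i, s in enumerate(self.edges):
            t = vmap.setdefault(s[: k - 1], len(vmap))
            h = vmap.setdefault(s[-(k - 1) :], len(vmap))
            self._tail.append(t)
            self._head.append(h)
            self._out.setdefault(t, []).append(i)
            self._in.setdefault(h, []).append(i)
        self.n_vertices = len(vmap)

    # -- protocol shared with the super graph -------------------------------
    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def seq(self, e: int) -> str:
        return self.edges[e]

    def rc(self, e: int) -> int:
        return self._rc[e]

    def support(self, e: int) -> float:
        return self.support_arr[e]

    def tail_vertex(self, e: int) -> int:
        return self._tail[e]

    def head_vertex(self, e: int) -> int:
        return self._head[e]

    def out_edges(self, v: int) -> list[int]:
        return self._out.get(v, [])

    def in_edges(self, v: int) -> list[int]:
        return self._in.get(v, [])

    def succs(self, e: int) -> list[int]:
        return self.out_edges(self._head[e])

    def preds(self, e: int) -> list[int]:
        return self.in_edges(self._tail[e])

    # ------------------------------------------------------------------

    def spell(self, walk: Iterable[int]) -> str:
        """Sequence of a walk of abutting edges (k-1 overlaps)."""
        walk = list(walk)
        out = [self.edges[walk[0]]]
        for e in walk[1:]:
            out.append(self.edges[e][self.k - 1 :])
        return "".join(out)

    def kmer_index(self) -> dict[int, tuple[int, int, int]]:
        """Canonical k-mer (packed int) -> (edge, offset, strand).

        strand is +1 when the edge window at `offset` equals the canonical
        form, -1 when it equals its reverse complement.  Each canonical
        k-mer is stored once (for the lower of the two mirror edges).
        """
        idx: dict[int, tuple[int, int, int]] = {}
        for e, s in enumerate(self.edges):
            if self._rc[e] < e:
                continue
            codes = encode_batch([s])
            hi, lo, valid, fwd = packed_kmers(codes, self.k)
            keys = (hi[0].astype(object) << 64) | lo[0].astype(object)
            for off, (key, f) in enumerate(zip(keys, fwd[0])):
                if key not in idx:
                    idx[key] = (e, off, 1 if f else -1)
        return idx

    def check_invariants(self) -> None:
        k = self.k
        for e, s in enumerate(self.edges):
            assert len(s) >= k, "edge shorter than k"
            r = self._rc[e]
            assert self._rc[r] == e, "involution not self-inverse"
            assert self.edges[r] == revcomp(s), "involution breaks reverse complement"
            for f in self.succs(e):
                assert self.edges[f][: k - 1] == s[-(k - 1) :], "bad overlap"
        # unbranched maximality: no mergeable vertex
        for v in range(self.n_vertices):
            outs, ins = self.out_edges(v), self.in_edges(v)
            if len(outs) == 1 and len(ins) == 1 and outs[0] != self._rc[ins[0]]:
                i, o = ins[0], outs[0]
                if i != o:  # a self-loop at v cannot be merged
                    raise AssertionError("graph contains a mergeable vertex")


def _canon(w: str) -> str:
    r = revcomp(w)
    return w if w <= r else r


_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


def _void_keys(hi: np.ndarray, lo: np.ndarray) -> np.ndarray:
    """16-byte keys whose memcmp order equals numeric (hi, lo) order."""
    pair = np.empty((len(hi), 2), dtype=">u8")
    pair[:, 0] = hi
    pair[:, 1] = lo
    return np.ascontiguousarray(pair).view("V16").ravel()


def build_from_arrays(
    chi: np.ndarray, clo: np.ndarray, counts: np.ndarray, k: int
) -> BaseGraph:
    """Unitig-compress a packed canonical k-mer set (fully vectorised
    successor/predecessor resolution; only the walk itself is a loop)."""
    if len(chi) == 0:
        raise ValueError("empty k-mer set")
    from .kmers import rc_packed, unpack_codes

    u64 = np.uint64
    order = np.lexsort((clo, chi))
    chi, clo, counts = chi[order], clo[order], np.asarray(counts, float)[order]
    N = len(chi)
    rhi, rlo = rc_packed(chi, clo, k)
    # oriented k-mers: 0..N-1 canonical-forward, N..2N-1 reverse complement
    ohi = np.concatenate([chi, rhi])
    olo = np.concatenate([clo, rlo])
    orhi = np.concatenate([rhi, chi])
    orlo = np.concatenate([rlo, clo])
    kl = min(k, 32)
    kh = k - kl
    mask_l = u64((1 << (2 * kl)) - 1) if kl < 32 else u64(0xFFFFFFFFFFFFFFFF)
    mask_h = u64((1 << (2 * kh)) - 1) if kh else u64(0)
    ckey = _void_keys(chi, clo)

    succ_cnt = np.zeros(2 * N, dtype=np.int8)
    succ_idx = np.full(2 * N, -1, dtype=np.int64)
    with np.errstate(over="ignore"):
        for c in range(4):
            comp = u64(3 - c)
            if kh:
                nhi = ((ohi << u64(2)) | (olo >> u64(2 * (kl - 1)))) & mask_h
            else:
                nhi = np.zeros(2 * N, dtype=u64)
            nlo = ((olo << u64(2)) | u64(c)) & mask_l
            # rc of candidate: drop last base of rc(w), prepend complement
            thi = orhi >> u64(2)
            tlo = orlo >> u64(2)
            if kh:
                tlo |= (orhi & u64(3)) << u64(2 * (kl - 1))
                nrhi = thi | (comp << u64(2 * (kh - 1)))
                nrlo = tlo
            else:
                nrhi = thi
                nrlo = tlo | (comp << u64(2 * (kl - 1)))
            less = (nhi < nrhi) | ((nhi == nrhi) & (nlo <= nrlo))
            canh = np.where(less, nhi, nrhi)
            canl = np.where(less, nlo, nrlo)
            keys = _void_keys(canh, canl)
            pos = np.searchsorted(ckey, keys)
            pos_c = np.minimum(pos, N - 1)
            found = ckey[pos_c] == keys
            oidx = pos_c + np.where(less, 0, N)
            succ_cnt += found
            succ_idx[found] = oidx[found]
    mirror = np.concatenate([np.arange(N, 2 * N), np.arange(N)])
    pred_cnt = succ_cnt[mirror]

    is_start = pred_cnt != 1
    single_pred = np.flatnonzero(~is_start)
    pred_of = mirror[succ_idx[mirror[single_pred]]]
    is_start[single_pred] |= succ_cnt[pred_of] != 1
    is_start[single_pred] |= pred_of == single_pred  # self-loop

    base_chars = _BASES[(olo & u64(3)).astype(np.uint8)]
    seqs: dict[str, float] = {}
    visited = np.zeros(N, dtype=bool)
    lut = b"ACGT"

    def kmer_str(u: int) -> str:
        codes = unpack_codes(ohi[u : u + 1], olo[u : u + 1], k)[0]
        return bytes(lut[c] for c in codes).decode()

    def emit(idxs: list[int]):
        seq = kmer_str(idxs[0]) + bytes(base_chars[idxs[1:]]).decode()
        sup = float(np.mean(counts[np.asarray(idxs) % N]))
        if seq not in seqs:
            seqs[seq] = sup
            seqs.setdefault(revcomp(seq), sup)

    sc = succ_cnt
    si = succ_idx
    pc = pred_cnt
    for u in np.flatnonzero(is_start):
        u = int(u)
        idxs = [u]
        in_walk = {u}
        cur = u
        while sc[cur] == 1:
            nxt = int(si[cur])
            if pc[nxt] != 1 or nxt in in_walk:
                break
            idxs.append(nxt)
            in_walk.add(nxt)
            cur = nxt
        visited[np.asarray(idxs) % N] = True
        emit(idxs)
    # leftover: simple cycles (every remaining k-mer has in = out = 1)
    for j in np.flatnonzero(~visited):
        j = int(j)
        if visited[j]:
            continue
        idxs = [j]
        visited[j] = True
        cur = j
        for _ in range(2 * N):
            if sc[cur] != 1:
                break
            nxt = int(si[cur])
            if nxt == j:
                break
            if visited[nxt % N] and nxt % N != j % N:
                break
            idxs.append(nxt)
            visited[nxt % N] = True
            cur = nxt
        emit(idxs)
    ordered = sorted(seqs)
    return BaseGraph(k, ordered, [seqs[s] for s in ordered])


def build_from_kmers(kmer_counts: dict[str, float], k: int) -> BaseGraph:
    """Unitig-compress a canonical k-mer dict into a BaseGraph."""
    from .kmers import pack_kmer

    if not kmer_counts:
        raise ValueError("empty k-mer set")
    items = sorted(kmer_counts.items())
    hi = np.empty(len(items), dtype=np.uint64)
    lo = np.empty(len(items), dtype=np.uint64)
    cnt = np.empty(len(items), dtype=float)
    for i, (w, c) in enumerate(items):
        if _canon(w) != w:
            raise ValueError("k-mer dict must be canonical")
        h, l = pack_kmer(w)
        hi[i], lo[i], cnt[i] = h, l, c
    return build_from_arrays(hi, lo, cnt, k)


def build_base_graph(table: KmerTable, k: int | None = None) -> BaseGraph:
    """Build the base graph from a (prefiltered) k-mer table."""
    k = k or table.k
    if k != table.k:
        raise ValueError("k mismatch with table")
    if len(table) == 0:
        raise ValueError("empty k-mer table")
    return build_from_arrays(table.hi, table.lo, table.count.astype(float), k)


def clean_graph(
    graph: BaseGraph, tip_len_factor: float = 2.0, support_frac: float = 0.1
) -> BaseGraph:
    """Remove weak dead-end tips and recompress.

    A tip is an edge dangling at one end, shorter than tip_len_factor * k,
    whose support is below support_frac of the median support of the other
    edges at its attachment vertex.  Applying the operation twice is a
    fixed point on typical inputs.
    """
    k = graph.k
    drop: set[int] = set()
    for e in range(graph.n_edges):
        if e in drop:
            continue
        s = graph.edges[e]
        if len(s) >= tip_len_factor * k:
            continue
        dangling_head = not graph.succs(e)
        dangling_tail = not graph.preds(e)
        if dangling_head == dangling_tail:
            continue  # either isolated or internal
        v = graph.tail_vertex(e) if dangling_head else graph.head_vertex(e)
        others = [
            f
            for f in set(graph.out_edges(v)) | set(graph.in_edges(v))
            if f not in (e, graph.rc(e))
        ]
        if not others:
            continue
        med = float(np.median([graph.support(f) for f in others]))
        if graph.support(e) < support_frac * med:
            drop.add(e)
            drop.add(graph.rc(e))
    if not drop:
        return graph
    keep = set(range(graph.n_edges)) - drop
    if not keep:
        return graph
    from .kmers import packed_kmers as _pk, encode_batch as _eb

    his, los, sups = [], [], []
    for e in sorted(keep):
        s = graph.edges[e]
        hi, lo, valid, _ = _pk(_eb([s]), k)
        his.append(hi[0])
        los.append(lo[0])
        sups.append(np.full(len(hi[0]), graph.support(e)))
    hi = np.concatenate(his)
    lo = np.concatenate(los)
    sup = np.concatenate(sups)
    order = np.lexsort((lo, hi))
    hi, lo, sup = hi[order], lo[order], sup[order]
    first = np.empty(len(hi), dtype=bool)
    first[0] = True
    np.logical_or(hi[1:] != hi[:-1], lo[1:] != lo[:-1], out=first[1:])
    return build_from_arrays(hi[first], lo[first], sup[first], k)
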