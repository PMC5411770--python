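"""Read threading and the super graph.

Each read pair is threaded through the base graph to recover the walk of
edges spelling its originating insert.  Walks that perfectly overlap by at
least k' = 200 bases (suffix/prefix or containment, measured on the spelled
sequence) are glued via an equivalence relation on their edge instances;
the quotient, compressed along unbranched chains, is the super graph.  Its
edges are paths in the base graph, and on clean data the construction
approximates collapsing the underlying genome along identical 200-base
sequences: repeats and homozygous stretches shorter than ~k' are resolved
(duplicated into their contexts), longer ones stay collapsed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._seq import revcomp
from .kmers import encode_batch, packed_kmers


# ---------------------------------------------------------------- threading


@dataclass(frozen=True)
class ReadPath:
    """A read (pair) threaded through the base graph."""

    walk: tuple[int, ...]  # base-graph edge ids, consecutive edges abut
    offset: int  # of the first read base on the first edge
    mismatches: int


def _count_mm(a: str, b: str, budget: int) -> int:
    """Mismatches between equal-length strings, early exit past budget."""
    if a == b:
        return 0
    mm = 0
    for x, y in zip(a, b):
        if x != y:
            mm += 1
            if mm > budget:
                return mm
    return mm


def _extend_forward(graph, seq, pos, edge, epos, mm, budget, walk, out, depth=0):
    """Match seq[pos:] along the graph starting at edge[epos]."""
    es = graph.seq(edge)
    take = min(len(seq) - pos, len(es) - epos)
    mm2 = mm + _count_mm(seq[pos : pos + take], es[epos : epos + take], budget - mm)
    if mm2 > budget:
        return
    pos += take
    walk = walk + (edge,)
    if pos == len(seq):
        out.append((walk, mm2))
        return
    if depth > 24:
        return
    for nxt in graph.succs(edge):
        _extend_forward(graph, seq, pos, nxt, graph.k - 1, mm2, budget, walk, out, depth + 1)


def _thread_from(graph, seq, edge, start, budget):
    """All placements of seq given that it starts at offset `start` on `edge`
    (start may be negative: the read begins on a predecessor edge)."""
    k = graph.k
    results: list[ReadPath] = []
    frontier = [(edge, start)]
    seen = set(frontier)
    guard = 0
    while frontier and guard < 200:
        guard += 1
        e, s = frontier.pop()
        if s >= 0:
            out: list[tuple[tuple[int, ...], int]] = []
            _extend_forward(graph, seq, 0, e, s, 0, budget, (), out)
            for walk, mm in out:
                results.append(ReadPath(walk, s, mm))
            continue
        for p in graph.preds(e):
            s2 = s + (len(graph.seq(p)) - (k - 1))
            if (p, s2) not in seen:
                seen.add((p, s2))
                frontier.append((p, s2))
    return results


def place_read(seq, graph, index, max_mm: int = 3, max_anchor_tries: int = 6):
    """Thread one read through the base graph.

    Anchors the read by its first indexed k-mer and verifies/extends the
    placement along the graph, allowing up to max_mm substitutions.
    Returns a list of ReadPath (empty when unplaceable, several at repeats).
    """
    k = graph.k
    if len(seq) < k:
        return []
    codes = encode_batch([seq])
    hi, lo, valid, fwd = packed_kmers(codes, k)
    keys = (hi[0].astype(object) << 64) | lo[0].astype(object)
    tries = 0
    results = []
    for j in range(len(keys)):
        if not valid[0][j]:
            continue
        hit = index.get(keys[j])
        if hit is None:
            continue
        tries += 1
        e, off, estrand = hit
        rstrand = 1 if fwd[0][j] else -1
        if estrand == rstrand:
            edge, epos = e, off
        else:
            edge = graph.rc(e)
            epos = len(graph.seq(e)) - k - off
        start = epos - j
        results = _thread_from(graph, seq, edge, start, max_mm)
        if results:
            break
        if tries >= max_anchor_tries:
            break
    return _best_placements(results)


def _best_placements(results: list[ReadPath]) -> list[ReadPath]:
    """Deduplicate and keep only minimum-mismatch placements, so a read
    covering a het site picks its own arm rather than both."""
    if not results:
        return []
    seen = {}
    for rp in results:
        key = (rp.walk, rp.offset)
        if key not in seen or rp.mismatches < seen[key].mismatches:
            seen[key] = rp
    best = min(r.mismatches for r in seen.values())
    return sorted(
        (r for r in seen.values() if r.mismatches == best),
        key=lambda r: (r.walk, r.offset),
    )


def spell_len(graph, walk) -> int:
    """Spelled length of a walk of abutting edges."""
    k = graph.k
    n = len(graph.seq(walk[0]))
    for e in walk[1:]:
        n += len(graph.seq(e)) - (k - 1)
    return n


def _read_end(graph, rp: ReadPath, read_len: int) -> tuple[int, int]:
    """(index into walk, offset just past the read end on that edge)."""
    k = graph.k
    pos = rp.offset + read_len  # position in walk coordinates
    cum = 0
    for i, e in enumerate(rp.walk):
        elen = len(graph.seq(e))
        if pos <= cum + elen or i == len(rp.walk) - 1:
            return i, pos - cum
        cum += elen - (k - 1)
    return len(rp.walk) - 1, pos - cum


def combine_pair_paths(
    graph,
    p1s: list[ReadPath],
    p2s: list[ReadPath],
    len1: int,
    len2: int,
    insert_min: int = 150,
    insert_max: int = 600,
    max_paths: int = 6,
):
    """Merge placements of the two reads of a pair into insert walks.

    Bridges from the end of read 1 to the start of (reverse-complemented)
    read 2 along the graph, keeping merged walks whose implied fragment
    length lies within the insert-size bounds.
    """
    k = graph.k
    out = set()
    for p1 in p1s[:4]:
        i1, _ = _read_end(graph, p1, len1)
        prefix = tuple(p1.walk[: i1 + 1])
        d_last = 0
        for e in prefix[:-1]:
            d_last += len(graph.seq(e)) - (k - 1)
        for p2 in p2s[:4]:
            # containment: read 2 already inside read 1's walk
            if _subwalk_at(p1.walk, p2.walk) is not None:
                out.add(p1.walk)
                continue
            first2 = p2.walk[0]
            frontier = [(prefix[-1], d_last, prefix)]
            seen = {prefix}
            steps = 0
            while frontier and steps < 2000 and len(out) < max_paths:
                e, d, walk = frontier.pop(0)
                steps += 1
                if e == first2:
                    frag = d + p2.offset - p1.offset + len2
                    if insert_min <= frag <= insert_max:
                        merged = walk + p2.walk[1:]
                        if _walk_ok(graph, merged):
                            out.add(merged)
                base = d + len(graph.seq(e)) - (k - 1)
                if base + p2.offset - p1.offset + len2 > insert_max:
                    continue
                for nxt in graph.succs(e):
                    nw = walk + (nxt,)
                    if nw not in seen:
                        seen.add(nw)
                        frontier.append((nxt, base, nw))
    return sorted(out)


def find_read_paths(
    r1: str,
    r2: str,
    graph,
    index,
    insert_min: int = 150,
    insert_max: int = 600,
    max_mm: int = 3,
    max_paths: int = 6,
):
    """Candidate walks spelling the insert of a read pair.

    Both reads must place; the gap between read 1 and the (reverse
    complemented) read 2 is bridged along the graph within the insert-size
    bounds.  Returns a list of walks (each a tuple of edge ids); empty when
    the pair cannot be placed, several when the insert lies in a repeat.
    """
    p1s = place_read(r1, graph, index, max_mm=max_mm)
    if not p1s:
        return []
    r2f = revcomp(r2)
    p2s = place_read(r2f, graph, index, max_mm=max_mm)
    if not p2s:
        return []
    return combine_pair_paths(
        graph, p1s, p2s, len(r1), len(r2f), insert_min, insert_max, max_paths
    )


def _place_from_keys(seq, graph, index, keys_row, valid_row, fwd_row, max_mm, max_tries=6):
    """Like place_read but with precomputed packed keys for the read."""
    k = graph.k
    tries = 0
    for j in range(len(keys_row)):
        if not valid_row[j]:
            continue
        key = (int(keys_row[j][0]) << 64) | int(keys_row[j][1])
        hit = index.get(key)
        if hit is None:
            continue
        tries += 1
        e, off, estrand = hit
        rstrand = 1 if fwd_row[j] else -1
        if estrand == rstrand:
            edge, epos = e, off
        else:
            edge = graph.rc(e)
            epos = len(graph.seq(e)) - k - off
        start = epos - j
        # fast path: read fits on this edge with no mismatches
        if 0 <= start and start + len(seq) <= len(graph.seq(edge)):
            if graph.seq(edge)[start : start + len(seq)] == seq:
                return [ReadPath((edge,), start, 0)]
        results = _thread_from(graph, seq, edge, start, max_mm)
        if results:
            return _best_placements(results)
        if tries >= max_tries:
            break
    return []


def thread_pairs(
    reads,
    graph,
    index,
    insert_min: int = 150,
    insert_max: int = 600,
    max_mm: int = 3,
    batch: int = 8000,
):
    """Thread every read pair of a ReadSet through the base graph.

    Returns (paths, stats): paths[i] is the list of candidate insert walks
    of pair i, and stats counts unplaced / unique / ambiguous pairs.
    Anchor k-mers are computed in vectorised batches.
    """
    k = graph.k
    n = reads.n_pairs
    paths: list[list[tuple[int, ...]]] = [[] for _ in range(n)]
    fallbacks: list[tuple[int, ...]] = []
    stats = {"unplaced": 0, "unique": 0, "ambiguous": 0, "single_read": 0}

    def batch_keys(seqs):
        codes = encode_batch(seqs)
        hi, lo, valid, fwd = packed_kmers(codes, k)
        keys = np.stack([hi, lo], axis=-1)
        return keys, valid, fwd

    for b0 in range(0, n, batch):
        b1 = min(b0 + batch, n)
        idxs = range(b0, b1)
        s1 = [reads.r1[i] for i in idxs]
        s2 = [revcomp(reads.r2[i]) for i in idxs]
        k1, v1, f1 = batch_keys(s1)
        k2, v2, f2 = batch_keys(s2)
        for rel, i in enumerate(idxs):
            p1s = _place_from_keys(s1[rel], graph, index, k1[rel], v1[rel], f1[rel], max_mm)
            p2s = (
                _place_from_keys(s2[rel], graph, index, k2[rel], v2[rel], f2[rel], max_mm)
                if p1s
                else []
            )
            merged = (
                combine_pair_paths(
                    graph, p1s, p2s, len(s1[rel]), len(s2[rel]), insert_min, insert_max
                )
                if p1s and p2s
                else []
            )
            paths[i] = merged
            if len(merged) == 1:
                stats["unique"] += 1
                continue
            stats["ambiguous" if len(merged) > 1 else "unplaced"] += 1
            # the pair is ambiguous or unplaced as an insert, but each read's
            # own unique walk is still valid join evidence
            for ps in (p1s, p2s):
                if len(ps) == 1:
                    fallbacks.append(ps[0].walk)
                    stats["single_read"] += 1
    return paths, fallbacks, stats


def _walk_ok(graph, walk) -> bool:
    for a, b in zip(walk, walk[1:]):
        if b not in graph.succs(a):
            return False
    return True


def _subwalk_at(big: tuple, small: tuple):
    n, m = len(big), len(small)
    for i in range(n - m + 1):
        if big[i : i + m] == small:
            return i
    return None


# ---------------------------------------------------------------- super graph


class _UF:
    def __init__(self, n):
        self.p = list(range(n))

    def find(self, a):
        p = self.p
        while p[a] != a:
            p[a] = p[p[a]]
            a = p[a]
        return a

    def union(self, a, b):
        ra, rb = self.find(a), self.find(b)
        if ra != rb:
            if rb < ra:
                ra, rb = rb, ra
            self.p[rb] = ra


class SuperGraph:
    """Graph whose edges are paths (walks) in the base graph."""

    def __init__(self, base, walks: list[tuple[int, ...]], connections: set[tuple[int, int]],
                 chain_of_class: dict[int, int], class_chains: list[list[int]],
                 class_mirror: dict[int, int]):
        self.base = base
        self.k = base.k
        self.base_walks = walks  # per super edge
        self._seqs = [base.spell(w) for w in walks]
        self._support = [
            sum(base.support(e) * len(base.seq(e)) for e in w)
            / sum(len(base.seq(e)) for e in w)
            for w in walks
        ]
        # involution via class mirrors
        chain_key = {tuple(c): i for i, c in enumerate(class_chains)}
        self._rc = []
        for c in class_chains:
            mc = tuple(class_mirror[x] for x in reversed(c))
            self._rc.append(chain_key[mc])
        # vertices from inter-chain connections
        uf: dict[tuple, tuple] = {}

        def find(t):
            while uf.get(t, t) != t:
                uf[t] = uf.get(uf[t], uf[t])
                t = uf[t]
            return t

        def union(a, b):
            ra, rb = find(a), find(b)
            if ra != rb:
                uf[rb] = ra

        for (c, d) in connections:
            union(("h", c), ("t", d))
        tokens = {}
        self._tail = []
        self._head = []
        for c in class_chains:
            t = find(("t", c[0]))
            h = find(("h", c[-1]))
            self._tail.append(tokens.setdefault(t, len(tokens)))
            self._head.append(tokens.setdefault(h, len(tokens)))
        self.n_vertices = len(tokens)
        # adjacency: f follows e iff a connection links e's last class to f's first
        self._succ: dict[int, list[int]] = {e: [] for e in range(len(walks))}
        self._pred: dict[int, list[int]] = {e: [] for e in range(len(walks))}
        last_class = {i: c[-1] for i, c in enumerate(class_chains)}
        first_class = {i: c[0] for i, c in enumerate(class_chains)}
        by_first: dict[int, list[int]] = {}
        for i, c in enumerate(class_chains):
            by_first.setdefault(c[0], []).append(i)
        for (c, d) in connections:
            e_from = chain_of_class[c]
            if last_class[e_from] != c:
                continue
            for e_to in by_first.get(d, []):
                if first_class[e_to] == d:
                    self._succ[e_from].append(e_to)
                    self._pred[e_to].append(e_from)
        for e in self._succ:
            self._succ[e] = sorted(set(self._succ[e]))
        for e in self._pred:
            self._pred[e] = sorted(set(self._pred[e]))
        self._out = {}
        self._in = {}
        for e in range(len(walks)):
            self._out.setdefault(self._tail[e], []).append(e)
            self._in.setdefault(self._head[e], []).append(e)

    @property
    def n_edges(self) -> int:
        return len(self.base_walks)

    def seq(self, e: int) -> str:
        return self._seqs[e]

    def rc(self, e: int) -> int:
        return self._rc[e]

    def support(self, e: int) -> float:
        return self._support[e]

    def succs(self, e: int) -> list[int]:
        return self._succ[e]

    def preds(self, e: int) -> list[int]:
        return self._pred[e]

    def tail_vertex(self, e: int) -> int:
        return self._tail[e]

    def head_vertex(self, e: int) -> int:
        return self._head[e]

    def out_edges(self, v: int) -> list[int]:
        return sorted(set(self._out.get(v, [])))

    def in_edges(self, v: int) -> list[int]:
        return sorted(set(self._in.get(v, [])))


def join_read_paths(walks, graph, k_prime: int = 200) -> SuperGraph:
    """Glue read walks that perfectly overlap by >= k_prime spelled bases.

    Overlaps are exact suffix/prefix (dovetail) or containment matches in
    edge space.  Every base edge contributes a singleton walk so uncovered
    edges survive; contained walks shorter than k_prime are redundant and
    dropped.  The glued equivalence classes, compressed along unbranched
    chains, become the super edges.
    """

    def rc_walk(w):
        return tuple(graph.rc(e) for e in reversed(w))

    canon = set()
    for w in walks:
        w = tuple(w)
        canon.add(min(w, rc_walk(w)))
    for e in range(graph.n_edges):
        canon.add(min((e,), (graph.rc(e),)))

    canon = sorted(canon)
    # occurrence index over both orientations for containment tests
    oriented_all = []
    for w in canon:
        rw = rc_walk(w)
        oriented_all.append((w, rw))
    occ: dict[int, list[tuple[int, int, int]]] = {}  # edge -> (walk idx, orient, pos)
    for wi, (w, rw) in enumerate(oriented_all):
        for o, ww in enumerate((w, rw)):
            for pos, e in enumerate(ww):
                occ.setdefault(e, []).append((wi, o, pos))

    def contained(wi) -> list[tuple[int, int, int]]:
        """Occurrences of walk wi inside other walks: (walk idx, orient, pos)."""
        w = oriented_all[wi][0]
        res = []
        for (pj, o, pos) in occ.get(w[0], []):
            if pj == wi:
                continue
            big = oriented_all[pj][o]
            if len(big) >= pos + len(w) and tuple(big[pos : pos + len(w)]) == w:
                res.append((pj, o, pos))
        return res

    keep = []
    containments = []  # (small wi, big wi, big orient, pos)
    for wi, (w, rw) in enumerate(oriented_all):
        inside = contained(wi)
        if not inside:
            keep.append(wi)
            continue
        if spell_len(graph, w) >= k_prime:
            keep.append(wi)
            containments.append((wi, inside))
        # else: redundant short walk, dropped

    keep_ids = {wi: i for i, wi in enumerate(keep)}
    paths = []  # oriented paths: (walk tuple, mirror oriented id)
    orient_id = {}
    for wi in keep:
        w, rw = oriented_all[wi]
        a = len(paths)
        paths.append(w)
        if rw == w:
            orient_id[(wi, 0)] = a
            orient_id[(wi, 1)] = a
        else:
            paths.append(rw)
            orient_id[(wi, 0)] = a
            orient_id[(wi, 1)] = a + 1

    # instances
    inst_start = []
    n_inst = 0
    for p in paths:
        inst_start.append(n_inst)
        n_inst += len(p)
    mirror_path = {}
    for wi in keep:
        a, b = orient_id[(wi, 0)], orient_id[(wi, 1)]
        mirror_path[a] = b
        mirror_path[b] = a

    def inst(p, i):
        return inst_start[p] + i

    def mirror(p, i):
        return inst(mirror_path[p], len(paths[p]) - 1 - i)

    uf = _UF(n_inst)

    def glue(p, i, q, j):
        uf.union(inst(p, i), inst(q, j))
        uf.union(mirror(p, i), mirror(q, j))

    # containment gluing
    for wi, inside in containments:
        p = orient_id[(wi, 0)]
        w = paths[p]
        for (pj, o, pos) in inside:
            if pj not in keep_ids:
                continue
            q = orient_id[(pj, o)]
            for i in range(len(w)):
                glue(p, i, q, pos + i)

    # dovetail gluing
    by_first: dict[int, list[int]] = {}
    for p, w in enumerate(paths):
        by_first.setdefault(w[0], []).append(p)
    for p, w in enumerate(paths):
        for s in range(1, len(w)):
            t = len(w) - s
            shared = w[s:]
            if spell_len(graph, shared) < k_prime:
                continue
            for q in by_first.get(w[s], []):
                wq = paths[q]
                if len(wq) < t:
                    continue
                if tuple(wq[:t]) == shared:
                    for i in range(t):
                        glue(p, s + i, q, i)

    # quotient classes
    class_of = {}
    class_edge = {}
    for p, w in enumerate(paths):
        for i, e in enumerate(w):
            r = uf.find(inst(p, i))
            class_of[(p, i)] = r
            class_edge[r] = e
    connections = set()
    for p, w in enumerate(paths):
        for i in range(len(w) - 1):
            connections.add((class_of[(p, i)], class_of[(p, i + 1)]))
    class_mirror = {}
    for p, w in enumerate(paths):
        for i in range(len(w)):
            class_mirror[class_of[(p, i)]] = uf.find(mirror(p, i))

    # compress unbranched chains of classes
    out_c: dict[int, set[int]] = {}
    in_c: dict[int, set[int]] = {}
    for (c, d) in connections:
        out_c.setdefault(c, set()).add(d)
        in_c.setdefault(d, set()).add(c)
    classes = sorted(class_edge)
    visited = set()
    chains: list[list[int]] = []
    chain_of_class: dict[int, int] = {}

    def is_start(c):
        ins = in_c.get(c, set())
        if len(ins) != 1:
            return True
        p = next(iter(ins))
        return len(out_c.get(p, set())) != 1

    for c in classes:
        if c in visited or not is_start(c):
            continue
        chain = [c]
        visited.add(c)
        cur = c
        while True:
            outs = out_c.get(cur, set())
            if len(outs) != 1:
                break
            nxt = next(iter(outs))
            if len(in_c.get(nxt, set())) != 1 or nxt in visited:
                break
            chain.append(nxt)
            visited.add(nxt)
            cur = nxt
        cid = len(chains)
        chains.append(chain)
        for x in chain:
            chain_of_class[x] = cid
    for c in classes:  # leftover cycles
        if c in visited:
            continue
        chain = [c]
        visited.add(c)
        cur = c
        while True:
            outs = out_c.get(cur, set())
            nxt = next(iter(sorted(outs))) if outs else None
            if nxt is None or nxt == chain[0] or nxt in visited:
                break
            chain.append(nxt)
            visited.add(nxt)
            cur = nxt
        cid = len(chains)
        chains.append(chain)
        for x in chain:
            chain_of_class[x] = cid

    super_walks = [tuple(class_edge[c] for c in chain) for chain in chains]
    return SuperGraph(graph, super_walks, connections, chain_of_class, chains, class_mirror)
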