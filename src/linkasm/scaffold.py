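"""Scaffolding lines with read pairs and barcodes, and gap filling.

Read pairs connect lines across short gaps; barcodes connect them across
long ones.  Candidate orders and orientations (O&O) of line sets are
scored by a barcode-separation penalty: for each barcode, read placements
are concatenated into the hypothetical merged coordinate system, and every
consecutive placement pair that jumps between constituent lines
contributes its separation divided by the barcode's mean separation --
quotients below 2.0 are discarded, the rest add to the penalty.  A
candidate wins only if it beats every competitor by at least 60.0.  Gaps
are later filled by local assembly of the reads from barcodes incident on
the flanks.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

log = logging.getLogger("linkasm")

from ._seq import revcomp
from .graph import build_from_arrays
from .kmers import count_kmers, encode_batch, packed_kmers
from .lines import Arm, Bub, Gap, Line, Seg, decompose_lines

OO_QUOTIENT_BOUND = 2.0
OO_WIN_MARGIN = 60.0


# ---------------------------------------------------------------- placements


@dataclass
class Placements:
    """Unique read placements on line coordinates.

    Read units are indexed 2*pair (read 1) and 2*pair+1 (read 2, placed as
    sequenced, i.e. reverse-complement of its genomic strand).
    """

    line: np.ndarray  # per read unit; -1 = unplaced
    pos: np.ndarray  # start of the read on the line (approximate for alt arms)
    strand: np.ndarray  # +1 read matches line spelling, -1 reverse
    barcode: np.ndarray  # per read unit
    n_lines: int

    def by_line(self) -> dict[int, np.ndarray]:
        out: dict[int, np.ndarray] = {}
        order = np.argsort(self.pos, kind="stable")
        for u in order:
            li = int(self.line[u])
            if li >= 0:
                out.setdefault(li, []).append(int(u))
        return {li: np.array(v) for li, v in out.items()}

    def barcode_positions(self, li: int) -> dict[int, list[int]]:
        """Barcode -> sorted placement positions on line li."""
        mask = self.line == li
        out: dict[int, list[int]] = {}
        for u in np.flatnonzero(mask):
            out.setdefault(int(self.barcode[u]), []).append(int(self.pos[u]))
        return {b: sorted(v) for b, v in out.items()}


def build_line_index(lines: list[Line], k: int):
    """Canonical k-mer -> (line, pos, strand) for k-mers unique across lines.

    Indexes every element (segments and all bubble arms) at its line
    coordinate; k-mers seen at more than one locus are dropped.
    """
    idx: dict[int, tuple[int, int, int] | None] = {}
    for li, line in enumerate(lines):
        offs = line.offsets()
        for ei, el in enumerate(line.elements):
            seqs: list[str] = []
            if isinstance(el, Seg):
                seqs = [el.seq]
            elif isinstance(el, Bub):
                seqs = [a.seq for a in el.arms]
            else:
                continue
            for s in seqs:
                if len(s) < k:
                    continue
                codes = encode_batch([s])
                hi, lo, valid, fwd = packed_kmers(codes, k)
                h, l, v, f = hi[0], lo[0], valid[0], fwd[0]
                base = offs[ei]
                for j in range(len(h)):
                    if not v[j]:
                        continue
                    key = (int(h[j]) << 64) | int(l[j])
                    if key in idx:
                        if idx[key] is not None and idx[key][:2] != (li, base + j):
                            idx[key] = None
                    else:
                        idx[key] = (li, base + j, 1 if f[j] else -1)
    return {key: val for key, val in idx.items() if val is not None}


def place_reads(reads, lines: list[Line], k: int, batch: int = 8000) -> Placements:
    """Anchor every read on the lines by its first unique k-mer."""
    n_units = 2 * reads.n_pairs
    line_arr = np.full(n_units, -1, dtype=np.int64)
    pos_arr = np.zeros(n_units, dtype=np.int64)
    strand_arr = np.zeros(n_units, dtype=np.int8)
    bc_arr = np.zeros(n_units, dtype=np.int64)
    idx = build_line_index(lines, k)

    def place_batch(seqs, units):
        codes = encode_batch(seqs)
        hi, lo, valid, fwd = packed_kmers(codes, k)
        for r, u in enumerate(units):
            h, l, v, f = hi[r], lo[r], valid[r], fwd[r]
            for j in range(len(h)):
                if not v[j]:
                    continue
                hit = idx.get((int(h[j]) << 64) | int(l[j]))
                if hit is None:
                    continue
                li, p, s = hit
                rstrand = 1 if f[j] else -1
                if s == rstrand:
                    line_arr[u] = li
                    pos_arr[u] = p - j
                    strand_arr[u] = 1
                else:
                    line_arr[u] = li
                    pos_arr[u] = p - (len(seqs[r]) - k - j)
                    strand_arr[u] = -1
                break

    for b0 in range(0, reads.n_pairs, batch):
        b1 = min(b0 + batch, reads.n_pairs)
        ids = list(range(b0, b1))
        place_batch([reads.r1[i] for i in ids], [2 * i for i in ids])
        place_batch([reads.r2[i] for i in ids], [2 * i + 1 for i in ids])
        for i in ids:
            bc_arr[2 * i] = bc_arr[2 * i + 1] = reads.barcode_ids[i]
    return Placements(line_arr, pos_arr, strand_arr, bc_arr, len(lines))


# ---------------------------------------------------------------- pair scaffolding


def _merge_two(a: Line, b: Line, gap: Gap) -> Line:
    elements = a.elements + [gap] + b.elements
    seams = a.seams + [0] + [0] + b.seams[1:]
    return Line(elements, seams)


def pair_scaffold(
    lines: list[Line],
    placements: Placements,
    reads,
    min_pairs: int = 3,
    end_window: int = 600,
    insert_mean: float = 350.0,
    min_line: int = 1000,
) -> tuple[list[Line], int]:
    """Join lines whose ends are unambiguously linked by read pairs.

    A pair links the right end of one line to the left end of another when
    its two reads place near those ends in bridging orientation.  An end is
    merged only when at least min_pairs pairs support a single partner end
    and no pairs support any other.  Lines shorter than min_line (whose
    position is uncertain) neither link nor block links.
    """
    lengths = [ln.length for ln in lines]
    counts: dict[tuple, int] = {}
    gaps: dict[tuple, list[int]] = {}
    for i in range(reads.n_pairs):
        u1, u2 = 2 * i, 2 * i + 1
        l1, l2 = int(placements.line[u1]), int(placements.line[u2])
        if l1 < 0 or l2 < 0 or l1 == l2:
            continue
        if lengths[l1] < min_line or lengths[l2] < min_line:
            continue
        p1, s1 = int(placements.pos[u1]), int(placements.strand[u1])
        p2, s2 = int(placements.pos[u2]), int(placements.strand[u2])
        len1 = len(reads.r1[i])
        len2 = len(reads.r2[i])
        # port of read 1's line
        if s1 > 0:
            d1 = lengths[l1] - (p1 + len1)
            port1 = (l1, "R")
        else:
            d1 = p1
            port1 = (l1, "L")
        if s2 < 0:
            d2 = p2
            port2 = (l2, "L")
        else:
            d2 = lengths[l2] - (p2 + len2)
            port2 = (l2, "R")
        if d1 > end_window or d2 > end_window or d1 < -len1 or d2 < -len2:
            continue
        key = (port1, port2) if port1 <= port2 else (port2, port1)
        counts[key] = counts.get(key, 0) + 1
        est = int(round(insert_mean - len1 - len2 - d1 - d2))
        gaps.setdefault(key, []).append(est)

    by_port: dict[tuple, list[tuple]] = {}
    for (pa, pb), c in counts.items():
        by_port.setdefault(pa, []).append((pb, c))
        by_port.setdefault(pb, []).append((pa, c))
    accepted = []
    for (pa, pb), c in sorted(counts.items()):
        if c < min_pairs:
            continue
        if len(by_port[pa]) > 1 or len(by_port[pb]) > 1:
            continue  # ambiguous end
        est = max(0, int(np.median(gaps.get((pa, pb), [0]))))
        accepted.append((pa, pb, est))

    return _apply_merges(lines, accepted, "pair"), len(accepted)


def _apply_merges(lines, accepted, kind) -> list[Line]:
    """accepted: list of (portA, portB, gap_est); each port used at most once."""
    link_of: dict[tuple, tuple] = {}
    for pa, pb, est in accepted:
        if pa in link_of or pb in link_of:
            continue
        link_of[pa] = (pb, est)
        link_of[pb] = (pa, est)
    in_chain: set[int] = set()
    out_lines: list[Line] = []
    for li in range(len(lines)):
        if li in in_chain:
            continue
        l_port, r_port = (li, "L"), (li, "R")
        if l_port in link_of and r_port in link_of:
            # possibly interior of a chain (or a ring); find the chain start
            start, flip = _find_chain_start(li, link_of)
        else:
            start, flip = li, l_port in link_of
        if start is None:  # ring: keep as-is, drop its links
            in_chain.add(li)
            out_lines.append(lines[li])
            continue
        cur, cur_flip = start, flip
        merged = lines[cur].rc() if cur_flip else lines[cur]
        in_chain.add(cur)
        right = (cur, "L" if cur_flip else "R")
        while right in link_of:
            (nxt_port, est) = link_of[right]
            nl, side = nxt_port
            if nl in in_chain:
                break
            nxt_flip = side == "R"
            nxt = lines[nl].rc() if nxt_flip else lines[nl]
            merged = _merge_two(merged, nxt, Gap(kind, est))
            in_chain.add(nl)
            cur, cur_flip = nl, nxt_flip
            right = (cur, "L" if cur_flip else "R")
        out_lines.append(merged)
    return out_lines


def _find_chain_start(li, link_of):
    """Walk left from line li to the chain's leftmost line; None for rings."""
    cur, cur_flip = li, False
    seen = {li}
    while True:
        left = (cur, "R" if cur_flip else "L")
        if left not in link_of:
            return cur, cur_flip
        (prev_port, _est) = link_of[left]
        pl, side = prev_port
        if pl in seen:
            return None, False
        seen.add(pl)
        cur, cur_flip = pl, side == "L"


# ---------------------------------------------------------------- O&O scoring


def oo_penalty(
    config: list[tuple[int, int]],
    positions: dict[int, dict[int, list[int]]],
    lengths: dict[int, int],
    bound: float = OO_QUOTIENT_BOUND,
) -> float:
    """Barcode-separation penalty of one order-and-orientation candidate.

    config: ordered (line id, orientation) with orientation +1 forward, -1
    reversed.  positions: line -> barcode -> placement positions.  For each
    barcode: mean separation m = span/(count-1) over its merged placements;
    every consecutive placement pair that bridges a jump between lines
    contributes q = separation/m when q >= bound.
    """
    offsets = {}
    cum = 0
    for li, orient in config:
        if li not in lengths:
            raise ValueError(f"line {li} has no coordinate system")
        offsets[li] = cum
        cum += lengths[li]
    merged: dict[int, list[tuple[int, int]]] = {}
    for li, orient in config:
        for bc, pos_list in positions.get(li, {}).items():
            for p in pos_list:
                q = offsets[li] + (p if orient > 0 else lengths[li] - p)
                merged.setdefault(bc, []).append((q, li))
    penalty = 0.0
    for bc, plist in merged.items():
        if len(plist) < 2:
            continue
        plist.sort()
        span = plist[-1][0] - plist[0][0]
        if span <= 0:
            continue
        m = span / (len(plist) - 1)
        for (a, la), (b, lb) in zip(plist, plist[1:]):
            if la == lb:
                continue
            q = (b - a) / m
            if q >= bound:
                penalty += q
    return penalty


def choose_oo(candidates: list[tuple[object, float]], margin: float = OO_WIN_MARGIN):
    """Winning candidate, or None without a clear margin.

    candidates: (config, penalty) pairs scored over the same line set.  The
    minimum-penalty candidate wins only if the runner-up is at least
    `margin` worse; a single candidate never wins (no competitor).
    """
    if len(candidates) < 2:
        return None
    ranked = sorted(candidates, key=lambda t: t[1])
    if ranked[1][1] - ranked[0][1] >= margin:
        return ranked[0][0]
    return None


def barcode_scaffold(
    lines: list[Line],
    placements: Placements,
    min_shared: int = 10,
    min_line: int = 20_000,
    margin: float = OO_WIN_MARGIN,
    bound: float = OO_QUOTIENT_BOUND,
    max_gap_est: int = 100_000,
) -> tuple[list[Line], int]:
    """One round of barcode scaffolding.

    Candidate neighbours share at least min_shared barcodes; lines shorter
    than min_line are excluded (their position is uncertain).  For each
    candidate pair the four order/orientation classes are scored with
    oo_penalty and merged only with a choose_oo winner.
    """
    lengths = {li: ln.length for li, ln in enumerate(lines)}
    eligible = [li for li in range(len(lines)) if lengths[li] >= min_line]
    pos = {li: placements.barcode_positions(li) for li in eligible}
    bc_lines: dict[int, list[int]] = {}
    for li in eligible:
        for bc in pos[li]:
            bc_lines.setdefault(bc, []).append(li)
    shared: dict[tuple[int, int], int] = {}
    for bc, ls in bc_lines.items():
        for i in range(len(ls)):
            for j in range(i + 1, len(ls)):
                key = (ls[i], ls[j])
                shared[key] = shared.get(key, 0) + 1
    cands = sorted(
        ((c, a, b) for (a, b), c in shared.items() if c >= min_shared),
        key=lambda t: (-t[0], t[1], t[2]),
    )
    accepted = []
    used: set[int] = set()
    for c, a, b in cands:
        if a in used or b in used:
            continue
        configs = [
            [(a, 1), (b, 1)],
            [(a, 1), (b, -1)],
            [(a, -1), (b, 1)],
            [(a, -1), (b, -1)],
        ]
        scored = [(cfg, oo_penalty(cfg, pos, lengths, bound)) for cfg in configs]
        win = choose_oo(scored, margin)
        if win is None:
            continue
        # translate the winning config into a port link
        (la, oa), (lb, ob) = win
        porta = (la, "R" if oa > 0 else "L")
        portb = (lb, "L" if ob > 0 else "R")
        est = _gap_estimate(win, pos, lengths, max_gap_est)
        accepted.append((porta, portb, est))
        used.add(a)
        used.add(b)
    return _apply_merges(lines, accepted, "barcode"), len(accepted)


def _gap_estimate(config, positions, lengths, max_gap: int) -> int:
    """Median implied jump spacing of bridging barcodes, clamped to [0, max]."""
    (la, oa), (lb, ob) = config
    seps = []
    pa = positions.get(la, {})
    pb = positions.get(lb, {})
    for bc in set(pa) & set(pb):
        xa = [(p if oa > 0 else lengths[la] - p) for p in pa[bc]]
        xb = [(p if ob > 0 else lengths[lb] - p) for p in pb[bc]]
        seps.append((lengths[la] - max(xa)) + min(xb))
    if not seps:
        return 0
    return int(min(max(np.median(seps), 0), max_gap))


# ---------------------------------------------------------------- gap filling


def fill_gaps(
    line: Line,
    reads,
    pairs_by_barcode: dict[int, list[int]],
    placements: Placements,
    line_id: int,
    k: int,
    flank: int = 50_000,
    min_count: int = 2,
    max_reads: int = 60_000,
) -> tuple[Line, int]:
    """Try to replace each gap edge of a line by locally assembled sequence.

    Barcodes incident on the terminal `flank` bases of each side recruit
    all their reads; those are assembled into a local graph (no barcode
    prefilter, k-mers below min_count dropped) and a path between the flank
    anchor k-mers replaces the gap.  Heterozygous content inside the gap
    appears as bubbles in the spliced chunk.
    """
    n_closed = 0
    # right-to-left so earlier gap indices stay valid after a splice
    gi_list = [i for i, el in enumerate(line.elements) if isinstance(el, Gap)]
    for gi in reversed(gi_list):
        new_line = _fill_one(
            line, gi, reads, pairs_by_barcode, placements, line_id, k, flank,
            min_count, max_reads,
        )
        log.debug("gap fill line %d elem %d: %s", line_id, gi,
                  "closed" if new_line is not None else "open")
        if new_line is not None:
            line = new_line
            n_closed += 1
    return line, n_closed


def _fill_one(
    line, gi, reads, pairs_by_barcode, placements, line_id, k, flank, min_count, max_reads
):
    offs = line.offsets()
    gap_start = offs[gi]
    gap_end = gap_start + len(line.elements[gi])
    mask = placements.line == line_id
    bcs = set()
    for u in np.flatnonzero(mask):
        p = int(placements.pos[u])
        if gap_start - flank <= p < gap_start or gap_end <= p < gap_end + flank:
            bcs.add(int(placements.barcode[u]))
    if not bcs:
        return None
    pair_ids = []
    for bc in sorted(bcs):
        pair_ids.extend(pairs_by_barcode.get(bc, []))
    if not pair_ids or len(pair_ids) * 2 > max_reads:
        pair_ids = pair_ids[: max_reads // 2]
    if not pair_ids:
        return None

    def read_iter():
        for i in pair_ids:
            yield reads.r1[i], 0
            yield reads.r2[i], 0

    table = count_kmers(read_iter(), k)
    keep = table.count >= min_count
    if not keep.any():
        return None
    local = build_from_arrays(
        table.hi[keep], table.lo[keep], table.count[keep].astype(float), k
    )

    left_el = line.elements[gi - 1] if gi > 0 else None
    right_el = line.elements[gi + 1] if gi + 1 < len(line.elements) else None
    if left_el is None or right_el is None:
        return None
    left_seq = left_el.seq if isinstance(left_el, Seg) else left_el.arms[0].seq
    right_seq = right_el.seq if isinstance(right_el, Seg) else right_el.arms[0].seq
    if len(left_seq) < k or len(right_seq) < k:
        return None
    anchor_l = left_seq[-k:]
    anchor_r = right_seq[:k]

    local_lines = decompose_lines(local)
    for ll in local_lines:
        for cand in (ll, ll.rc()):
            spliced = _splice_chunk(cand, anchor_l, anchor_r, k)
            if spliced is not None:
                chunk_elems, chunk_seams = spliced
                elements = (
                    line.elements[:gi] + chunk_elems + line.elements[gi + 1 :]
                )
                seams = (
                    line.seams[:gi]
                    + chunk_seams
                    + [k]
                    + line.seams[gi + 2 :]
                )
                return Line(elements, seams, line.is_circle)
    return None


def _splice_chunk(ll: Line, anchor_l: str, anchor_r: str, k: int):
    """Extract the element run between the two anchors of a local line.

    Returns (elements, seams) spanning from the start of anchor_l to the
    end of anchor_r, or None.  Anchors must land inside common segments.
    """
    offs = ll.offsets()
    spell = ll.spelled()
    pl = spell.find(anchor_l)
    pr = spell.find(anchor_r, pl + 1 if pl >= 0 else 0)
    if pl < 0 or pr < 0 or pr <= pl:
        return None
    # locate elements containing the anchor positions
    def elem_at(pos):
        for i in range(len(ll.elements) - 1, -1, -1):
            rendered_start = offs[i] + ll.seams[i]
            if rendered_start <= pos:
                return i
        return 0

    ei_l = elem_at(pl)
    ei_r = elem_at(pr + k - 1)
    el_l = ll.elements[ei_l]
    el_r = ll.elements[ei_r]
    if not isinstance(el_l, Seg) or not isinstance(el_r, Seg):
        return None
    cut_l = pl - offs[ei_l]
    cut_r = pr + k - offs[ei_r]
    if cut_l < 0 or cut_r > len(el_r.seq):
        return None
    elems = [e for e in ll.elements[ei_l : ei_r + 1]]
    seams = list(ll.seams[ei_l : ei_r + 1])
    if ei_l == ei_r:
        elems = [Seg(el_l.seq[cut_l:cut_r], (), el_l.support)]
        seams = [k]
    else:
        elems[0] = Seg(el_l.seq[cut_l:], (), el_l.support)
        elems[-1] = Seg(el_r.seq[:cut_r], (), el_r.support)
        seams[0] = k
    if any(len(e) <= 0 for e in elems):
        return None
    return elems, seams
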