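"""FASTA output styles for a finished assembly.

Four styles are supported.  "raw" writes one record per edge of the final
graph -- including microbubble arms, gap edges printed as Ns (100 for
pair-bridged gaps, the estimated size when larger for barcode-bridged
ones), and the reverse complement of every edge.  The flattened styles
first replace each microbubble by its highest-coverage arm and merge gaps
into adjacent sequence as Ns; unresolved cycles become a covering path
followed by 10 Ns.  "megabubble" emits one record per megabubble arm and
per intervening homozygous stretch; "pseudohap" a single record per
scaffold with one arm per megabubble; "pseudohap2" two parallel
pseudohaplotype files whose records agree at homozygous coordinates.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

from .io import write_fasta
from .lines import Bub, Gap, Line, Seg

STYLES = ("raw", "megabubble", "pseudohap", "pseudohap2")
PAIR_GAP_NS = 100
CYCLE_NS = 10


@dataclass
class AssemblyBundle:
    """Final assembly: phased scaffolds plus provenance."""

    scaffolds: list[Line]
    k: int
    config: dict = field(default_factory=dict)
    stats: dict = field(default_factory=dict)

    @property
    def edge_count(self) -> int:
        """Edges of the final graph: segments, bubble arms, gap edges."""
        n = 0
        for line in self.scaffolds:
            for el in line.elements:
                n += len(el.arms) if isinstance(el, Bub) else 1
        return n


def flatten_arm(bub: Bub) -> int:
    """Index of the branch kept when a microbubble is flattened:
    highest coverage, ties to the lexicographically smaller sequence."""
    best = 0
    for i, a in enumerate(bub.arms[1:], start=1):
        b = bub.arms[best]
        if (a.support, ) > (b.support, ) or (a.support == b.support and a.seq < b.seq):
            best = i
    return best


def cycle_flatten(graph, edges) -> str:
    """Covering path through a cyclic edge set, plus 10 Ns.

    Greedy walk from the smallest edge, preferring unused edges, until
    every edge has been traversed at least once.
    """
    edges = sorted(set(edges))
    start = edges[0]
    unused = set(edges)
    walk = [start]
    unused.discard(start)
    cur = start
    guard = 0
    while unused and guard < 10 * len(edges) + 20:
        guard += 1
        nxts = [e for e in graph.succs(cur) if e in unused]
        if not nxts:
            nxts = [e for e in graph.succs(cur) if e in set(edges)]
            if not nxts:
                break
        nxt = sorted(nxts)[0]
        walk.append(nxt)
        unused.discard(nxt)
        cur = nxt
    seq = graph.seq(walk[0])
    for e in walk[1:]:
        seq += graph.seq(e)[graph.k - 1 :]
    return seq + "N" * CYCLE_NS


def _bubble_mode(line: Line):
    """elem index -> ('phased', block_id) | 'flatten' for each bubble."""
    mode = {}
    st = line.phasing
    blocks = st.blocks if st else []
    for ei, el in line.bubbles():
        mode[ei] = "flatten"
    for bi, (lo, hi) in enumerate(blocks):
        for ei, el in line.bubbles():
            if lo <= ei <= hi and el.is_simple and ei not in st.excluded:
                mode[ei] = ("phased", bi)
    return mode


def _render_range(line: Line, lo: int, hi: int, hap: int, trim_first: bool) -> str:
    """Flattened spelling of elements [lo, hi] taking the hap-side arm at
    phased bubbles."""
    st = line.phasing
    mode = _bubble_mode(line)
    out = []
    for i in range(lo, hi + 1):
        el = line.elements[i]
        seam = line.seams[i] if (i > lo or trim_first) else 0
        if isinstance(el, Gap):
            s = "N" * el.render_size
            seam = 0
        elif isinstance(el, Bub):
            if mode.get(i) == "flatten" or not isinstance(mode.get(i), tuple):
                arm = flatten_arm(el)
            else:
                top = st.top_arm(i)
                arm = top if hap == 0 else 1 - top
            s = el.arms[arm].seq
        else:
            s = el.seq
        out.append(s[seam:] if seam else s)
    return "".join(out)


def _scaffold_pieces(line: Line):
    """Partition element indices into intervening runs and megabubble blocks."""
    st = line.phasing
    blocks = sorted(st.blocks) if st else []
    pieces = []
    cur = 0
    for (lo, hi) in blocks:
        if cur <= lo - 1:
            pieces.append(("homo", cur, lo - 1))
        pieces.append(("mega", lo, hi))
        cur = hi + 1
    if cur <= len(line.elements) - 1:
        pieces.append(("homo", cur, len(line.elements) - 1))
    return pieces


def emit_fasta(bundle: AssemblyBundle, style: str):
    """Records for a style; for pseudohap2, a pair of record lists."""
    if style not in STYLES:
        raise ValueError(f"unknown FASTA style {style!r}")
    if style == "raw":
        return _emit_raw(bundle)
    if style == "megabubble":
        return _emit_megabubble(bundle)
    if style == "pseudohap":
        return _emit_pseudohap(bundle, 0)
    return _emit_pseudohap(bundle, 0), _emit_pseudohap(bundle, 1)


def _emit_raw(bundle):
    from ._seq import revcomp

    records = []
    for sid, line in enumerate(bundle.scaffolds):
        pieces = []
        for i, el in enumerate(line.elements):
            if isinstance(el, Gap):
                pieces.append((f"gap kind={el.kind}", "N" * el.render_size))
            elif isinstance(el, Bub):
                for a, arm in enumerate(el.arms):
                    pieces.append((f"arm={a}", arm.seq))
            else:
                kind = "cycle" if line.is_circle else "seg"
                pieces.append((kind, el.seq))
        for pi, (tag, seq) in enumerate(pieces):
            records.append(
                (f"raw scaffold={sid} piece={pi} {tag} len={len(seq)}", seq)
            )
            records.append(
                (
                    f"raw scaffold={sid} piece={pi} {tag} rc len={len(seq)}",
                    revcomp(seq),
                )
            )
    return records


def _circle_record(line: Line) -> str:
    return line.spelled() + "N" * CYCLE_NS


def _emit_megabubble(bundle):
    records = []
    for sid, line in enumerate(bundle.scaffolds):
        if line.is_circle:
            records.append((f"megabubble scaffold={sid} cycle", _circle_record(line)))
            continue
        for n, (kind, lo, hi) in enumerate(_scaffold_pieces(line)):
            trim = lo > 0
            if kind == "homo":
                seq = _render_range(line, lo, hi, 0, trim)
                records.append(
                    (f"megabubble scaffold={sid} piece={n} homozygous len={len(seq)}", seq)
                )
            else:
                for hap in (0, 1):
                    seq = _render_range(line, lo, hi, hap, trim)
                    records.append(
                        (
                            f"megabubble scaffold={sid} piece={n} arm={hap} len={len(seq)}",
                            seq,
                        )
                    )
    return records


def _emit_pseudohap(bundle, hap: int):
    records = []
    name = "pseudohap" if hap == 0 else "pseudohap2"
    for sid, line in enumerate(bundle.scaffolds):
        if line.is_circle:
            records.append((f"{name} scaffold={sid} cycle", _circle_record(line)))
            continue
        seq = _render_range(line, 0, len(line.elements) - 1, hap, False)
        records.append((f"{name} scaffold={sid} len={len(seq)}", seq))
    return records


def megabubble_arms(bundle: AssemblyBundle) -> list[tuple[str, str]]:
    """(top, bottom) sequences of every megabubble, for phasing assessment."""
    out = []
    for line in bundle.scaffolds:
        st = line.phasing
        if not st:
            continue
        for lo, hi in st.blocks:
            out.append(
                (_render_range(line, lo, hi, 0, False), _render_range(line, lo, hi, 1, False))
            )
    return out


def write_style(bundle: AssemblyBundle, style: str, out_dir, prefix: str = "assembly"):
    """Write one style to FASTA file(s); returns the paths."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    if style == "pseudohap2":
        r1, r2 = emit_fasta(bundle, style)
        p1 = write_fasta(r1, out_dir / f"{prefix}.pseudohap2.1.fasta")
        p2 = write_fasta(r2, out_dir / f"{prefix}.pseudohap2.2.fasta")
        return [p1, p2]
    recs = emit_fasta(bundle, style)
    return [write_fasta(recs, out_dir / f"{prefix}.{style}.fasta")]
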