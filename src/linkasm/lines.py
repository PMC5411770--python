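"""Lines: the linear units of scaffolding and phasing.

A line is a maximal acyclic part of the graph with a unique source and
sink, alternating common segments with bubbles (places where the sequence
diverges along parallel paths that reconnect).  Every edge of the graph
lies in exactly one line (up to reverse complement); degenerate cases are
single-edge lines and circles.  Bubbles are found as superbubbles, and a
bubble with internal branching is represented by the set of all its
source-to-sink paths.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from ._seq import revcomp


@dataclass
class Seg:
    seq: str
    edges: tuple[int, ...]
    support: float = 1.0

    def rc(self) -> "Seg":
        return Seg(revcomp(self.seq), tuple(reversed(self.edges)), self.support)

    def __len__(self):
        return len(self.seq)


@dataclass
class Arm:
    seq: str
    edges: tuple[int, ...]
    support: float = 1.0

    def rc(self) -> "Arm":
        return Arm(revcomp(self.seq), tuple(reversed(self.edges)), self.support)


@dataclass
class Bub:
    arms: list[Arm]

    def rc(self) -> "Bub":
        return Bub([a.rc() for a in self.arms])

    @property
    def is_simple(self) -> bool:
        return len(self.arms) == 2

    def __len__(self):
        return len(self.arms[0].seq)


@dataclass
class Gap:
    kind: str  # "pair" | "barcode"
    size: int | None = None

    def rc(self) -> "Gap":
        return Gap(self.kind, self.size)

    @property
    def render_size(self) -> int:
        if self.kind == "pair" or self.size is None:
            return 100
        return max(100, int(self.size))

    def __len__(self):
        return self.size if self.size is not None else 100


@dataclass
class Line:
    """Alternating common segments and bubbles, with optional gap edges."""

    elements: list
    seams: list[int]  # seams[i] = bases shared between elements i-1 and i
    is_circle: bool = False
    phasing: "object | None" = None  # attached by the phasing stage

    def __post_init__(self):
        assert len(self.seams) == len(self.elements)

    def rc(self) -> "Line":
        n = len(self.elements)
        elems = [e.rc() for e in reversed(self.elements)]
        seams = [0] + [self.seams[n - i] for i in range(1, n)]
        return Line(elems, seams, self.is_circle)

    def element_lengths(self) -> list[int]:
        return [len(e) for e in self.elements]

    def offsets(self) -> list[int]:
        """Coordinate of each element's full sequence start (arm 0 spelling)."""
        out = []
        cum = 0
        for e, seam in zip(self.elements, self.seams):
            out.append(cum - seam)
            cum += len(e) - seam
        return out

    @property
    def length(self) -> int:
        return sum(len(e) - s for e, s in zip(self.elements, self.seams))

    def spelled(self, arm_for: dict | None = None) -> str:
        """Linear spelling of the line: one arm per bubble, gaps as Ns.

        arm_for maps element index -> arm index; bubbles default to arm 0.
        Defines the line's coordinate system.
        """
        arm_for = arm_for or {}
        out = []
        for i, (el, seam) in enumerate(zip(self.elements, self.seams)):
            if isinstance(el, Gap):
                s = "N" * len(el)
            elif isinstance(el, Bub):
                s = el.arms[arm_for.get(i, 0) % len(el.arms)].seq
            else:
                s = el.seq
            out.append(s[seam:] if seam else s)
        return "".join(out)

    def edge_set(self) -> set[int]:
        out: set[int] = set()
        for e in self.elements:
            if isinstance(e, Seg):
                out.update(e.edges)
            elif isinstance(e, Bub):
                for a in e.arms:
                    out.update(a.edges)
        return out

    def bubbles(self) -> list[tuple[int, "Bub"]]:
        return [(i, e) for i, e in enumerate(self.elements) if isinstance(e, Bub)]

    def n_common_segments(self) -> int:
        return sum(1 for e in self.elements if isinstance(e, Seg))

    def n_bubbles(self) -> int:
        return sum(1 for e in self.elements if isinstance(e, Bub))


# ---------------------------------------------------------------- bubbles


def _superbubble(graph, v, max_edges: int = 64):
    """Superbubble with entrance v; returns (exit, interior edges) or None."""
    seen_v = {v}
    visited_v: set[int] = set()
    seen_e: set[int] = set()
    stack = [v]
    while stack:
        u = stack.pop()
        visited_v.add(u)
        outs = graph.out_edges(u)
        if not outs:
            return None  # dead end inside
        for e in outs:
            w = graph.head_vertex(e)
            if w == v:
                return None  # cycle back to the entrance
            seen_e.add(e)
            if len(seen_e) > max_edges:
                return None
            seen_v.add(w)
            if all(f in seen_e for f in graph.in_edges(w)):
                if w not in visited_v and w not in stack:
                    stack.append(w)
        if len(stack) == 1 and seen_v - visited_v == {stack[0]}:
            t = stack[0]
            if t == v:
                return None
            return t, seen_e
    return None


def _arm_walks(graph, v, t, inside, max_arms: int = 16, max_depth: int = 40):
    """All edge walks v -> t using only interior edges."""
    arms: list[tuple[int, ...]] = []
    stack = [(v, ())]
    while stack:
        u, walk = stack.pop()
        if len(arms) > max_arms:
            return None
        for e in sorted(graph.out_edges(u), reverse=True):
            if e not in inside:
                continue
            w = graph.head_vertex(e)
            nw = walk + (e,)
            if len(nw) > max_depth:
                return None
            if w == t:
                arms.append(nw)
            else:
                stack.append((w, nw))
    if not arms or len(arms) > max_arms:
        return None
    return sorted(arms)


def find_bubbles(graph):
    """Map entrance vertex -> (exit vertex, arm walks) for clean bubbles."""
    bubbles = {}
    interior: set[int] = set()
    n_vert = getattr(graph, "n_vertices")
    for v in range(n_vert):
        if len(graph.out_edges(v)) < 2:
            continue
        r = _superbubble(graph, v)
        if r is None:
            continue
        t, inside = r
        arms = _arm_walks(graph, v, t, inside)
        if arms is None or len(arms) < 2:
            continue
        bubbles[v] = (t, arms)
        interior.update(inside)
    return bubbles, interior


# ---------------------------------------------------------------- lines


def _spell_arm(graph, walk) -> tuple[str, float]:
    seq = graph.seq(walk[0])
    tot = graph.support(walk[0]) * len(graph.seq(walk[0]))
    n = len(graph.seq(walk[0]))
    for e in walk[1:]:
        seq += graph.seq(e)[graph.k - 1 :]
        tot += graph.support(e) * len(graph.seq(e))
        n += len(graph.seq(e))
    return seq, tot / n


def _forward(graph, start_edge, bubbles, claimed):
    """Walk rightward from start_edge; returns (raw elements, is_circle)."""
    elements: list[tuple] = []
    in_line = {start_edge}
    v = graph.head_vertex(start_edge)
    just_bubbled = False
    while True:
        ins = graph.in_edges(v)
        outs = graph.out_edges(v)
        if len(ins) != 1 and not just_bubbled:
            break
        just_bubbled = False
        if len(outs) == 0:
            break
        if len(outs) == 1:
            e = outs[0]
            if e in in_line:
                return elements, True
            elements.append(("seg", e))
            in_line.add(e)
            v = graph.head_vertex(e)
            continue
        if v in bubbles:
            t, arms = bubbles[v]
            arm_edges = {e for a in arms for e in a}
            if arm_edges & in_line or arm_edges & claimed:
                break
            elements.append(("bub", arms))
            in_line.update(arm_edges)
            v = t
            just_bubbled = True
            continue
        break
    return elements, False


def _raw_to_elements(graph, raw):
    out = []
    for kind, data in raw:
        if kind == "seg":
            out.append(Seg(graph.seq(data), (data,), graph.support(data)))
        else:
            arms = []
            for w in data:
                seq, sup = _spell_arm(graph, w)
                arms.append(Arm(seq, tuple(w), sup))
            arms.sort(key=lambda a: (a.seq, a.edges))
            out.append(Bub(arms))
    return out


def decompose_lines(graph) -> list[Line]:
    """Partition the graph into lines (each edge in exactly one, up to rc)."""
    bubbles, interior = find_bubbles(graph)
    used: set[int] = set()
    lines: list[Line] = []
    for seed in range(graph.n_edges):
        if seed in used or seed in interior or graph.rc(seed) in interior:
            continue
        fwd_raw, circ = _forward(graph, seed, bubbles, used)
        if circ:
            raw = [("seg", seed)] + fwd_raw
            elements = _raw_to_elements(graph, raw)
            line = Line(elements, [0] + [graph.k - 1] * (len(elements) - 1), is_circle=True)
        else:
            back_raw, _ = _forward(graph, graph.rc(seed), bubbles, used)
            # reverse-complement the backward extension and prepend
            pre_raw = []
            for kind, data in reversed(back_raw):
                if kind == "seg":
                    pre_raw.append(("seg", graph.rc(data)))
                else:
                    pre_raw.append(
                        ("bub", sorted(tuple(graph.rc(e) for e in reversed(w)) for w in data))
                    )
            raw = pre_raw + [("seg", seed)] + fwd_raw
            elements = _raw_to_elements(graph, raw)
            line = Line(elements, [0] + [graph.k - 1] * (len(elements) - 1))
        for e in line.edge_set():
            used.add(e)
            used.add(graph.rc(e))
        lines.append(line)
    # leftovers (complex tangles): single-edge lines
    for e in range(graph.n_edges):
        if e not in used:
            line = Line([Seg(graph.seq(e), (e,), graph.support(e))], [0])
            used.add(e)
            used.add(graph.rc(e))
            lines.append(line)
    return lines
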