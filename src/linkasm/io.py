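"""File formats: FASTQ dialects, FASTA, truth tables, GFA1.

Two FASTQ dialects are supported.  In the "raw" dialect the 16-base
partition barcode is the first 16 bases of read 1, exactly as sequenced; in
the "trimmed" dialect read 1 carries only genomic bases and the barcode is
appended to the read name as "/BX:<seq>".  Qualities are written as constant
Q30: the assembler never consults them.
"""

from __future__ import annotations

import gzip
from pathlib import Path

import numpy as np
import pandas as pd
from Bio.SeqIO.QualityIO import FastqGeneralIterator

from .sim import DiploidGenome, ReadSet, TrueMolecule, Variant


def _open(path, mode="rt"):
    path = str(path)
    if path.endswith(".gz"):
        return gzip.open(path, mode)
    return open(path, mode)


# ---------------------------------------------------------------- FASTQ


def write_fastq_pair(reads: ReadSet, prefix, dialect: str = "raw") -> tuple[Path, Path]:
    if dialect not in ("raw", "trimmed"):
        raise ValueError(f"unknown FASTQ dialect {dialect!r}")
    prefix = Path(prefix)
    p1 = prefix.with_name(prefix.name + "_R1.fastq.gz")
    p2 = prefix.with_name(prefix.name + "_R2.fastq.gz")
    with _open(p1, "wt") as f1, _open(p2, "wt") as f2:
        for i in range(reads.n_pairs):
            bc = reads.barcode_of(i)
            if dialect == "raw":
                name = f"pair{i}"
                s1 = bc + reads.r1[i]
            else:
                name = f"pair{i}/BX:{bc}"
                s1 = reads.r1[i]
            s2 = reads.r2[i]
            f1.write(f"@{name}\n{s1}\n+\n{'?' * len(s1)}\n")
            f2.write(f"@{name}\n{s2}\n+\n{'?' * len(s2)}\n")
    return p1, p2


def read_fastq_pair(
    path1, path2, dialect: str = "raw", barcode_length: int = 16
) -> ReadSet:
    if dialect not in ("raw", "trimmed"):
        raise ValueError(f"unknown FASTQ dialect {dialect!r}")
    barcodes: list[str] = []
    index: dict[str, int] = {}
    bids: list[int] = []
    r1: list[str] = []
    r2: list[str] = []
    read_length = 0
    with _open(path1) as f1, _open(path2) as f2:
        it2 = FastqGeneralIterator(f2)
        for lineno, (title, seq, _q) in enumerate(FastqGeneralIterator(f1)):
            try:
                title2, seq2, _q2 = next(it2)
            except StopIteration:
                raise ValueError(f"read 2 file ended early at record {lineno}") from None
            if dialect == "raw":
                if len(seq) <= barcode_length:
                    raise ValueError(
                        f"record {lineno} ({title}): read 1 shorter than the barcode"
                    )
                bc, genomic = seq[:barcode_length], seq[barcode_length:]
            else:
                if "/BX:" not in title:
                    raise ValueError(f"record {lineno} ({title}): missing /BX: barcode tag")
                bc = title.rsplit("/BX:", 1)[1].strip()
                if len(bc) != barcode_length:
                    raise ValueError(f"record {lineno} ({title}): bad barcode {bc!r}")
                genomic = seq
            if bc not in index:
                index[bc] = len(barcodes)
                barcodes.append(bc)
            bids.append(index[bc])
            r1.append(genomic.upper())
            r2.append(seq2.upper())
            read_length = max(read_length, len(seq))
    if not r1:
        raise ValueError("empty FASTQ input")
    return ReadSet(
        barcodes=barcodes,
        barcode_ids=np.array(bids, dtype=np.int64),
        r1=r1,
        r2=r2,
        read_length=read_length,
        barcode_length=barcode_length,
    )


# ---------------------------------------------------------------- FASTA


def write_fasta(records, path, width: int = 60) -> Path:
    """records: iterable of (name, sequence)."""
    path = Path(path)
    with _open(path, "wt") as f:
        for name, seq in records:
            f.write(f">{name}\n")
            for i in range(0, len(seq), width):
                f.write(seq[i : i + width] + "\n")
            if not seq:
                f.write("\n")
    return path


def read_fasta(path) -> list[tuple[str, str]]:
    from Bio import SeqIO

    with _open(path) as f:
        return [(rec.description, str(rec.seq).upper()) for rec in SeqIO.parse(f, "fasta")]


def write_haplotype_fasta(genome: DiploidGenome, path) -> Path:
    return write_fasta(
        [
            (f"{genome.name}_hap0", genome.haplotype0),
            (f"{genome.name}_hap1", genome.haplotype1),
        ],
        path,
    )


# ---------------------------------------------------------------- truth tables


def write_molecule_table(molecules: list[TrueMolecule], path) -> Path:
    df = pd.DataFrame(
        [
            (m.molecule_id, m.barcode, m.haplotype, m.start, m.end, m.partition_id)
            for m in molecules
        ],
        columns=["molecule_id", "barcode", "haplotype", "start", "end", "partition"],
    )
    df.to_csv(path, sep="\t", index=False)
    return Path(path)


def read_molecule_table(path) -> list[TrueMolecule]:
    df = pd.read_csv(path, sep="\t")
    barcode_ids = {bc: i for i, bc in enumerate(dict.fromkeys(df["barcode"]))}
    return [
        TrueMolecule(
            int(r.molecule_id),
            r.barcode,
            barcode_ids[r.barcode],
            int(r.haplotype),
            int(r.start),
            int(r.end),
            int(r.partition),
        )
        for r in df.itertuples()
    ]


def write_variant_table(genome: DiploidGenome, path) -> Path:
    """Minimal phased-variant table: pos (hap0), ref, alt, kind; alt is on hap1."""
    df = pd.DataFrame(
        [(v.pos, v.ref or ".", v.alt or ".", v.kind) for v in genome.variants],
        columns=["pos", "ref", "alt", "kind"],
    )
    df.to_csv(path, sep="\t", index=False)
    return Path(path)


def read_variant_table(path) -> list[Variant]:
    df = pd.read_csv(path, sep="\t")
    out = []
    for r in df.itertuples():
        ref = "" if r.ref == "." else r.ref
        alt = "" if r.alt == "." else r.alt
        out.append(Variant(int(r.pos), ref, alt, r.kind))
    return out


# ---------------------------------------------------------------- reports


def write_super_mapping(super_graph, path) -> Path:
    """TSV mapping each super edge to its base-graph edge path."""
    rows = [
        (e, super_graph.rc(e), len(super_graph.seq(e)),
         ",".join(str(b) for b in super_graph.base_walks[e]))
        for e in range(super_graph.n_edges)
    ]
    pd.DataFrame(rows, columns=["super_edge", "rc", "length", "base_path"]).to_csv(
        path, sep="\t", index=False
    )
    return Path(path)


def write_scaffold_layout(scaffolds, path) -> Path:
    """TSV of scaffold structure: one row per element."""
    from .lines import Bub, Gap

    rows = []
    for sid, line in enumerate(scaffolds):
        for ei, el in enumerate(line.elements):
            if isinstance(el, Gap):
                rows.append((sid, ei, "gap", len(el), el.kind, ""))
            elif isinstance(el, Bub):
                rows.append(
                    (sid, ei, "bubble", len(el), "",
                     ",".join(str(len(a.seq)) for a in el.arms))
                )
            else:
                rows.append((sid, ei, "segment", len(el), "", ""))
    pd.DataFrame(
        rows, columns=["scaffold", "element", "kind", "length", "gap_kind", "arm_lengths"]
    ).to_csv(path, sep="\t", index=False)
    return Path(path)


def write_phasing_report(scaffolds, path) -> Path:
    """TSV of megabubbles: scaffold, block span, bubble counts, score."""
    rows = []
    for sid, line in enumerate(scaffolds):
        st = line.phasing
        if st is None:
            continue
        offs = line.offsets()
        for bi, (lo, hi) in enumerate(st.blocks):
            n_bub = sum(1 for e in st.bubble_elems if lo <= e <= hi)
            n_exc = sum(1 for e in st.excluded if lo <= e <= hi)
            span = offs[hi] + len(line.elements[hi]) - offs[lo]
            rows.append((sid, bi, offs[lo], span, n_bub, n_exc, st.score))
    pd.DataFrame(
        rows,
        columns=["scaffold", "block", "start", "span", "n_bubbles", "n_excluded", "line_score"],
    ).to_csv(path, sep="\t", index=False)
    return Path(path)


# ---------------------------------------------------------------- GFA


def write_gfa(graph, path) -> Path:
    """GFA1 for a sequence graph (base or super): segments + k-1 overlap links."""
    k = graph.k
    path = Path(path)
    with _open(path, "wt") as f:
        f.write("H\tVN:Z:1.0\n")
        emitted = set()
        for e in range(graph.n_edges):
            r = graph.rc(e)
            if r in emitted:
                continue
            emitted.add(e)
            f.write(f"S\ts{e}\t{graph.seq(e)}\n")

        def ref(e):
            # orientation of edge e relative to its emitted representative
            return (f"s{e}", "+") if e in emitted else (f"s{graph.rc(e)}", "-")

        links = set()
        for e in range(graph.n_edges):
            for s in graph.succs(e):
                a, ao = ref(e)
                b, bo = ref(s)
                key = (a, ao, b, bo)
                rkey = (b, "-" if bo == "+" else "+", a, "-" if ao == "+" else "+")
                if key in links or rkey in links:
                    continue
                links.add(key)
                f.write(f"L\t{a}\t{ao}\t{b}\t{bo}\t{k - 1}M\n")
    return path
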