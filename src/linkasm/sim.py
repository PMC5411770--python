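"""Simulator for diploid genomes and barcoded linked reads.

The generator emulates the droplet workflow: a diploid genome (two
haplotypes differing by heterozygous SNPs and small indels), long molecules
drawn from either haplotype and dealt into barcoded partitions (~10 per
partition), and shallow 2x150 read-pair coverage of each molecule (~0.36x,
i.e. ~60 pairs on a 50 kb molecule) with the 16-base partition barcode at
the start of read 1.  Alongside the reads it emits truth tables (molecule
intervals, phased variants, haplotype FASTA) for downstream assessment.

Coordinates are 0-based, half-open throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._seq import BASES, random_seq, revcomp
from .model import LibraryModel, model_calculator


@dataclass(frozen=True)
class Variant:
    pos: int  # position on haplotype 0
    ref: str  # allele on haplotype 0 ("" for insertions)
    alt: str  # allele on haplotype 1 ("" for deletions)
    kind: str  # "SNP" | "insertion" | "deletion"


@dataclass
class DiploidGenome:
    name: str
    haplotype0: str
    haplotype1: str
    variants: list[Variant]

    def __len__(self) -> int:
        return len(self.haplotype0)

    def haplotype(self, h: int) -> str:
        return self.haplotype0 if h == 0 else self.haplotype1

    def hap1_pos(self, pos0: int) -> int:
        """Map a haplotype-0 coordinate to haplotype 1."""
        shift = 0
        for v in self.variants:
            if v.pos >= pos0:
                break
            shift += len(v.alt) - len(v.ref)
        return pos0 + shift


def _apply_variants(hap0: str, variants: list[Variant]) -> str:
    pieces = []
    cur = 0
    for v in variants:
        pieces.append(hap0[cur : v.pos])
        pieces.append(v.alt)
        cur = v.pos + len(v.ref)
    pieces.append(hap0[cur:])
    return "".join(pieces)


def simulate_diploid_genome(
    length: int,
    het_snp_rate: float = 1e-3,
    het_indel_rate: float = 1e-4,
    max_indel: int = 10,
    gc: float = 0.5,
    seed: int = 0,
    name: str = "sim",
) -> DiploidGenome:
    """Random diploid genome: i.i.d. haplotype 0 plus heterozygous variants.

    Variant counts are Binomial(length, rate); indel sizes are uniform on
    [1, max_indel].  Variants closer than max_indel + 1 bases are thinned so
    alleles never overlap.  Deterministic for a given seed.
    """
    for rate in (het_snp_rate, het_indel_rate):
        if rate < 0 or rate >= 1:
            raise ValueError("heterozygosity rates must be in [0, 1)")
    rng = np.random.default_rng(seed)
    hap0 = random_seq(rng, length, gc=gc)
    n_snp = rng.binomial(length, het_snp_rate)
    n_indel = rng.binomial(length, het_indel_rate)
    pad = max_indel + 1
    pos_snp = rng.choice(max(length - 2 * pad, 1), size=min(n_snp, length), replace=False) + pad
    pos_indel = rng.choice(max(length - 2 * pad, 1), size=min(n_indel, length), replace=False) + pad

    events: dict[int, str] = {}
    for p in np.sort(pos_snp):
        events[int(p)] = "SNP"
    for p in np.sort(pos_indel):
        events.setdefault(int(p), "indel")

    variants: list[Variant] = []
    last_end = -1
    for pos in sorted(events):
        if pos <= last_end + pad:
            continue  # keep alleles non-overlapping and well separated
        if events[pos] == "SNP":
            ref = hap0[pos]
            alt = BASES[(BASES.index(ref) + int(rng.integers(1, 4))) % 4]
            variants.append(Variant(pos, ref, alt, "SNP"))
            last_end = pos
        else:
            size = int(rng.integers(1, max_indel + 1))
            if rng.random() < 0.5:  # deletion on haplotype 1
                ref = hap0[pos : pos + size]
                variants.append(Variant(pos, ref, "", "deletion"))
                last_end = pos + size - 1
            else:  # insertion on haplotype 1
                ins = random_seq(rng, size, gc=gc)
                variants.append(Variant(pos, "", ins, "insertion"))
                last_end = pos
    hap1 = _apply_variants(hap0, variants)
    return DiploidGenome(name, hap0, hap1, variants)


@dataclass(frozen=True)
class TrueMolecule:
    molecule_id: int
    barcode: str
    barcode_id: int
    haplotype: int
    start: int  # on its haplotype, 0-based half-open
    end: int
    partition_id: int

    @property
    def length(self) -> int:
        return self.end - self.start


def barcode_whitelist(n: int, barcode_length: int = 16, seed: int = 0) -> list[str]:
    """n distinct random barcodes (not the commercial whitelist)."""
    if n > 4**barcode_length:
        raise ValueError("more partitions than possible barcodes")
    rng = np.random.default_rng(seed)
    seen: set[int] = set()
    out: list[str] = []
    while len(out) < n:
        for v in rng.integers(0, 4**barcode_length, size=2 * (n - len(out))):
            v = int(v)
            if v in seen:
                continue
            seen.add(v)
            bc = "".join(BASES[(v >> (2 * i)) & 3] for i in range(barcode_length))
            out.append(bc)
            if len(out) == n:
                break
    return out


def simulate_partitions(
    genome: DiploidGenome, model: LibraryModel, seed: int = 0
) -> list[TrueMolecule]:
    """Deal molecules into partitions.

    Molecule count per partition is Poisson(M); each molecule picks a
    haplotype uniformly, a uniform start, and a length from the configured
    distribution, truncated at the chromosome end.
    """
    model.validate()
    if model.n_partitions > 4**model.barcode_length:
        raise ValueError("more partitions than possible barcodes")
    exp = model_calculator(model)
    m = exp.molecules_per_partition
    rng = np.random.default_rng(seed)
    counts = rng.poisson(m, size=model.n_partitions)
    occupied = np.flatnonzero(counts)
    # barcodes are only materialised for occupied partitions
    wl_occ = barcode_whitelist(
        len(occupied), model.barcode_length, seed=int(rng.integers(2**31))
    )
    wl = {int(pid): wl_occ[i] for i, pid in enumerate(occupied)}
    molecules: list[TrueMolecule] = []
    mol_id = 0
    for pid in occupied:
        pid = int(pid)
        for _ in range(int(counts[pid])):
            hap = int(rng.integers(2))
            hap_len = len(genome.haplotype(hap))
            length = int(round(float(model.molecule_length.sample(rng, 1)[0])))
            length = max(length, 1)
            # sample as if from a longer chromosome and clip at both ends, so
            # interior physical coverage is uniform
            start = int(rng.integers(-(length - 1), hap_len)) if length > 1 else int(
                rng.integers(hap_len)
            )
            end = min(start + length, hap_len)
            start = max(start, 0)
            if end - start <= 0:
                continue
            molecules.append(
                TrueMolecule(mol_id, wl[pid], pid, hap, start, end, pid)
            )
            mol_id += 1
    return molecules


@dataclass(frozen=True)
class BarcodedReadPair:
    """One barcoded read pair: the atomic input of the assembler."""

    barcode: str
    read1: str  # genomic part (barcode removed)
    read2: str  # as sequenced (reverse complement of the fragment end)


@dataclass
class ReadSet:
    """In-memory barcoded read pairs plus simulation truth.

    `r1` holds the genomic part of read 1 (the 16-base barcode is prepended
    only when writing the raw FASTQ dialect); `r2` is as sequenced, i.e. the
    reverse complement of the genomic fragment end.
    """

    barcodes: list[str]  # whitelist, indexed by barcode_id
    barcode_ids: np.ndarray  # per pair
    r1: list[str]
    r2: list[str]
    read_length: int = 150
    barcode_length: int = 16
    truth: "object | None" = None  # pandas DataFrame when simulated
    n_skipped: int = 0

    @property
    def n_pairs(self) -> int:
        return len(self.r1)

    def barcode_of(self, i: int) -> str:
        return self.barcodes[int(self.barcode_ids[i])]

    def pair(self, i: int) -> BarcodedReadPair:
        return BarcodedReadPair(self.barcode_of(i), self.r1[i], self.r2[i])

    def pairs_of_barcode(self) -> dict[int, list[int]]:
        by: dict[int, list[int]] = {}
        for i, b in enumerate(self.barcode_ids):
            by.setdefault(int(b), []).append(i)
        return by


def simulate_reads(
    molecules: list[TrueMolecule],
    genome: DiploidGenome,
    model: LibraryModel,
    seed: int = 0,
) -> ReadSet:
    """Shallow read-pair coverage of each molecule.

    Pair count per molecule is Poisson(molecule length x per-molecule depth
    / (2 x read length)); fragment starts are uniform within the molecule;
    substitution errors are i.i.d. at the configured rate.  Pairs whose
    insert exceeds the molecule are skipped and counted.
    """
    if not molecules:
        raise ValueError("no molecules to sequence")
    import pandas as pd

    model.validate()
    exp = model_calculator(model)
    mean_len = model.molecule_length.expectation()
    lpm = exp.read_pairs_per_molecule
    rng = np.random.default_rng(seed)
    glen1 = model.read_length - model.barcode_length  # genomic bases in read 1
    glen2 = model.read_length

    wl_index: dict[str, int] = {}
    barcodes: list[str] = []
    r1: list[str] = []
    r2: list[str] = []
    bids: list[int] = []
    truth_rows: list[tuple] = []
    skipped = 0

    mol_list = sorted(molecules, key=lambda m: m.molecule_id)
    n_pairs_per_mol = rng.poisson([lpm * m.length / mean_len for m in mol_list])
    for mol, n in zip(mol_list, n_pairs_per_mol):
        if n == 0:
            continue
        hap = genome.haplotype(mol.haplotype)
        if mol.barcode not in wl_index:
            wl_index[mol.barcode] = len(barcodes)
            barcodes.append(mol.barcode)
        bid = wl_index[mol.barcode]
        inserts = np.maximum(
            np.round(rng.normal(model.insert_mean, model.insert_sd, size=n)).astype(int),
            model.read_length,
        )
        for ins in inserts:
            ins = int(ins)
            if ins > mol.length:
                skipped += 1
                continue
            start = mol.start + int(rng.integers(mol.length - ins + 1))
            frag = hap[start : start + ins]
            s1 = frag[:glen1]
            s2 = revcomp(frag[-glen2:])
            if model.error_rate > 0:
                s1 = _mutate(s1, rng, model.error_rate)
                s2 = _mutate(s2, rng, model.error_rate)
            bids.append(bid)
            r1.append(s1)
            r2.append(s2)
            truth_rows.append((mol.molecule_id, mol.haplotype, start, ins))

    truth = pd.DataFrame(
        truth_rows, columns=["molecule_id", "haplotype", "start", "insert"]
    )
    return ReadSet(
        barcodes=barcodes,
        barcode_ids=np.array(bids, dtype=np.int64),
        r1=r1,
        r2=r2,
        read_length=model.read_length,
        barcode_length=model.barcode_length,
        truth=truth,
        n_skipped=skipped,
    )


def _mutate(seq: str, rng: np.random.Generator, rate: float) -> str:
    n_err = rng.binomial(len(seq), rate)
    if n_err == 0:
        return seq
    pos = rng.choice(len(seq), size=n_err, replace=False)
    chars = list(seq)
    for p in pos:
        p = int(p)
        chars[p] = BASES[(BASES.index(chars[p]) + int(rng.integers(1, 4))) % 4]
    return "".join(chars)


def simulate_library(
    genome_length: int,
    coverage: float = 56.25,
    het_snp_rate: float = 1e-3,
    het_indel_rate: float = 1e-4,
    molecule_length=None,
    molecules_per_partition: float | None = None,
    error_rate: float = 0.001,
    seed: int = 0,
    name: str = "sim",
):
    """One-call generator: genome + molecules + reads with a desk-scaled model.

    Returns (genome, model, molecules, readset).
    """
    rng = np.random.default_rng(seed)
    s_genome, s_part, s_reads = (int(x) for x in rng.integers(2**31, size=3))
    genome = simulate_diploid_genome(
        genome_length, het_snp_rate, het_indel_rate, seed=s_genome, name=name
    )
    kw = {}
    if molecule_length is not None:
        kw["molecule_length"] = molecule_length
    model = LibraryModel.desk(
        genome_length,
        coverage=coverage,
        molecules_per_partition=molecules_per_partition,
        error_rate=error_rate,
        **kw,
    )
    molecules = simulate_partitions(genome, model, seed=s_part)
    reads = simulate_reads(molecules, genome, model, seed=s_reads)
    return genome, model, molecules, reads
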