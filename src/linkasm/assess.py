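"""Assembly assessment: continuity, accuracy, completeness, phasing.

All statistics operate on FASTA-style records and, where truth is needed,
on the simulator's haplotype sequences and phased-variant tables.  The
scaffold-level statistics follow a fixed protocol: scaffolds shorter than
10 kb are removed first, contigs are the maximal N-free runs, and N50/N75
are cumulative-sum thresholds.  Accuracy metrics are exact by design:
a "perfect stretch" is a maximal truth region reproduced without a single
error or gap (showing the wrong allele counts as an error), and k-mer
based completeness/consistency metrics use k = 100.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np

from ._seq import revcomp
from .kmers import encode_batch, hash_set, in_hash_set, kmer_hashes, packed_kmers

DEFAULT_K = 100
SCAFFOLD_MIN = 10_000


# ---------------------------------------------------------------- N statistics


def nxx(lengths, x: float) -> int:
    """Smallest L with sum(lengths >= L) >= x% of the total (N50, N75...)."""
    if not 0 < x < 100:
        raise ValueError("x must be in (0, 100)")
    lengths = sorted((int(l) for l in lengths), reverse=True)
    if not lengths or lengths[0] <= 0:
        raise ValueError("need a non-empty list of positive lengths")
    total = sum(lengths)
    cum = 0
    for l in lengths:
        cum += l
        if cum >= total * x / 100.0:
            return l
    return lengths[-1]


def filter_scaffolds(records, min_len: int = SCAFFOLD_MIN):
    """Drop records shorter than min_len (default: shorter than 10 kb)."""
    return [(name, seq) for name, seq in records if len(seq) >= min_len]


_N_RUN = re.compile(r"N+")


def contig_lengths(seqs) -> tuple[list[int], float]:
    """Contig lengths (maximal N-free runs) and the overall N fraction."""
    lengths: list[int] = []
    n_bases = 0
    total = 0
    for seq in seqs:
        total += len(seq)
        n_bases += seq.count("N")
        lengths.extend(len(p) for p in _N_RUN.split(seq) if p)
    frac = n_bases / total if total else 0.0
    return lengths, frac


# ---------------------------------------------------------------- perfect stretch


def perfect_stretches(
    assembly_records, truth_seqs, seed_k: int = 48, max_occ: int = 8
) -> list[int]:
    """Lengths of maximal truth regions exactly reproduced in the assembly.

    A stretch is a maximal exact match between a truth sequence and one
    assembly record (either strand): any substitution, indel, wrong
    allele, or gap terminates it.  Found by seeding with shared k-mers and
    verifying/splitting on the exact sequence; stretches shorter than
    seed_k are not reported.
    """
    asm = []
    for name, seq in assembly_records:
        asm.append(seq)
        asm.append(revcomp(seq))
    # forward k-mer table of the assembly: opaque 16-byte keys + (record, pos)
    keys, recs, poss = [], [], []
    for ri, seq in enumerate(asm):
        if len(seq) < seed_k:
            continue
        kk = _forward_keys(seq, seed_k)
        keys.append(kk)
        recs.append(np.full(len(kk), ri, dtype=np.int64))
        poss.append(np.arange(len(kk), dtype=np.int64))
    if not keys:
        return []
    akey = np.concatenate(keys)
    rec = np.concatenate(recs)
    pos = np.concatenate(poss)
    order = np.argsort(akey, kind="stable")
    akey, rec, pos = akey[order], rec[order], pos[order]

    stretches: list[tuple[int, int, int]] = []  # (truth idx, start, end)
    for ti, t in enumerate(truth_seqs):
        if len(t) < seed_k:
            continue
        tkey = _forward_keys(t, seed_k)
        left = np.searchsorted(akey, tkey, side="left")
        right = np.searchsorted(akey, tkey, side="right")
        cnt = np.minimum(right - left, max_occ)
        cnt[tkey == np.frombuffer(b"\xff" * 16, dtype="V16")[0]] = 0
        total = int(cnt.sum())
        if total == 0:
            continue
        starts = np.cumsum(cnt) - cnt
        aidx = np.repeat(left, cnt) + (np.arange(total) - np.repeat(starts, cnt))
        tpos = np.repeat(np.arange(len(tkey)), cnt)
        srec = rec[aidx]
        spos = pos[aidx]
        diag = tpos - spos
        g = np.lexsort((tpos, diag, srec))
        srec, diag, tpos = srec[g], diag[g], tpos[g]
        new = np.empty(total, dtype=bool)
        new[0] = True
        new[1:] = (srec[1:] != srec[:-1]) | (diag[1:] != diag[:-1])
        bounds = np.flatnonzero(new).tolist() + [total]
        for i, j in zip(bounds, bounds[1:]):
            r, d = int(srec[i]), int(diag[i])
            t0, t1 = int(tpos[i]), int(tpos[j - 1])
            # candidate truth interval [t0, t1 + seed_k); verify and split
            for s, e in _exact_runs(t, asm[r], t0, t1 + seed_k, d):
                if e - s >= seed_k:
                    stretches.append((ti, s, e))
    # drop intervals contained in others (per truth sequence)
    out_lengths: list[int] = []
    by_t: dict[int, list[tuple[int, int]]] = {}
    for ti, s, e in stretches:
        by_t.setdefault(ti, []).append((s, e))
    for ti, ivs in by_t.items():
        ivs.sort(key=lambda p: (p[0], -p[1]))
        best_end = -1
        for s, e in ivs:
            if e > best_end:
                out_lengths.append(e - s)
                best_end = e
    return sorted(out_lengths, reverse=True)


def _forward_keys(seq: str, k: int) -> np.ndarray:
    """Opaque 16-byte key per forward k-mer (consistent equality/order only);
    windows touching non-ACGT bases get a sentinel that never matches."""
    from .kmers import _rolling_values

    codes = encode_batch([seq])
    kl = min(k, 32)
    kh = k - kl
    lo = _rolling_values(codes, kl)
    hi = (
        _rolling_values(codes, kh)
        if kh
        else np.zeros((1, codes.shape[1] - kl + 1), dtype=np.uint64)
    )
    m = codes.shape[1] - k + 1
    pair = np.empty((m, 2), dtype=np.uint64)
    pair[:, 0] = hi[0][:m]
    pair[:, 1] = lo[0][kh : kh + m]
    bad = codes[0] > 3
    if bad.any():
        run = np.concatenate([[0], np.cumsum(bad)])
        ok = (run[k:] - run[: len(bad) - k + 1]) == 0
        pair[~ok] = np.uint64(0xFFFFFFFFFFFFFFFF)
    return np.ascontiguousarray(pair).view("V16").ravel()


def _exact_runs(t: str, a: str, t0: int, t1: int, d: int):
    """Maximal exactly matching truth intervals within [t0, t1) on diagonal d,
    extended outward as far as the match continues."""
    # extend left
    while t0 > 0 and t0 - d > 0 and t[t0 - 1] == a[t0 - d - 1]:
        t0 -= 1
    while t1 < len(t) and t1 - d < len(a) and t[t1] == a[t1 - d]:
        t1 += 1
    s = t0
    runs = []
    for i in range(t0, t1):
        if t[i] != a[i - d] or t[i] == "N":
            if i > s:
                runs.append((s, i))
            s = i + 1
    if t1 > s:
        runs.append((s, t1))
    return runs


def perfect_stretch_n50(assembly_records, truth_seqs, seed_k: int = 48) -> int:
    """N50 of the perfect stretches; 0 when none are found."""
    if not truth_seqs:
        raise ValueError("perfect-stretch assessment needs truth sequences")
    lengths = perfect_stretches(assembly_records, truth_seqs, seed_k)
    return nxx(lengths, 50) if lengths else 0


# ---------------------------------------------------------------- phasing error


def phasing_error(
    megabubble_arms,
    genome,
    min_size: int = 1_000_000,
    context: int = 50,
) -> tuple[int, int, float | None]:
    """Trio-style phasing votes over megabubbles.

    megabubble_arms: list of (top sequence, bottom sequence).  For every
    het SNP of the (simulated) genome, the haplotype-0 and haplotype-1
    context k-mers are searched in both arms; a resolvable site votes 0
    when the top arm carries haplotype 0, 1 otherwise.  Within each
    megabubble of size >= min_size the minority votes are wrong; returns
    (votes, wrong votes, rate) with rate None when there are no votes.
    """
    k = 2 * context + 1
    snps = [v for v in genome.variants if v.kind == "SNP"]
    contexts = []
    for v in snps:
        p0 = v.pos
        c0 = genome.haplotype0[p0 - context : p0 + context + 1]
        p1 = genome.hap1_pos(p0)
        c1 = genome.haplotype1[p1 - context : p1 + context + 1]
        if len(c0) == k and len(c1) == k:
            contexts.append((c0, c1))
    votes = wrong = 0
    for top, bottom in megabubble_arms:
        if max(len(top), len(bottom)) < min_size:
            continue
        top_set = hash_set([top], k)
        bot_set = hash_set([bottom], k)
        mb_votes = []
        for c0, c1 in contexts:
            h0 = hash_set([c0], k)
            h1 = hash_set([c1], k)
            c0_top = bool(in_hash_set(h0, top_set).all()) and len(h0)
            c1_top = bool(in_hash_set(h1, top_set).all()) and len(h1)
            c0_bot = bool(in_hash_set(h0, bot_set).all()) and len(h0)
            c1_bot = bool(in_hash_set(h1, bot_set).all()) and len(h1)
            if c0_top and c1_bot and not c1_top and not c0_bot:
                mb_votes.append(0)
            elif c1_top and c0_bot and not c0_top and not c1_bot:
                mb_votes.append(1)
        if not mb_votes:
            continue
        n1 = sum(mb_votes)
        n0 = len(mb_votes) - n1
        majority = 1 if n1 >= n0 else 0
        votes += len(mb_votes)
        wrong += n0 if majority == 1 else n1
    rate = wrong / votes if votes else None
    return votes, wrong, rate


# ---------------------------------------------------------------- k-mer completeness


def missing_kmer_fraction(
    assembly_records, reference_records, k: int = DEFAULT_K, stratify: bool = False
):
    """Fraction of nonduplicate reference k-mers absent from the assembly.

    Nonduplicate = k-mers occurring exactly once in the reference (both
    strands identified).  With stratify=True, also returns the missing
    fraction per GC bin and for duplicate k-mers.
    """
    ref_ids = []
    ref_gc = []
    for name, seq in reference_records:
        if len(seq) < k:
            raise ValueError(f"k={k} exceeds reference sequence length {len(seq)}")
        ids, valid = kmer_hashes(seq, k)
        ref_ids.append(ids[valid])
        if stratify:
            gc = np.isin(np.frombuffer(seq.encode(), np.uint8), np.frombuffer(b"GC", np.uint8))
            run = np.concatenate([[0], np.cumsum(gc)])
            frac = (run[k:] - run[: len(seq) - k + 1]) / k
            ref_gc.append(frac[valid])
    ids = np.concatenate(ref_ids)
    uniq, idx, counts = np.unique(ids, return_index=True, return_counts=True)
    asm_set = hash_set((seq for _, seq in assembly_records), k)
    present = in_hash_set(uniq, asm_set)
    nondup = counts == 1
    if nondup.sum() == 0:
        raise ValueError("no nonduplicate reference k-mers")
    result = {
        "missing_fraction": float(np.mean(~present[nondup])),
        "n_nonduplicate": int(nondup.sum()),
        "duplicate_fraction": float(np.mean(counts > 1)),
    }
    if stratify:
        gc_all = np.concatenate(ref_gc)[idx]
        bins = [(0.0, 0.2), (0.2, 0.4), (0.4, 0.6), (0.6, 0.8), (0.8, 1.01)]
        strata = {}
        for lo, hi in bins:
            m = nondup & (gc_all >= lo) & (gc_all < hi)
            strata[f"gc_{int(lo*100)}_{int(hi*100) if hi <= 1 else 100}"] = (
                float(np.mean(~present[m])) if m.any() else None
            )
        strata["duplicate"] = (
            float(np.mean(~present[~nondup])) if (~nondup).any() else None
        )
        result["strata"] = strata
    return result


# ---------------------------------------------------------------- long-range consistency


def _ref_unique_index(reference_records, k: int):
    """Forward-hash -> (record, pos) for reference k-mers unique on both strands."""
    fwd = {}
    canon_counts: dict[int, int] = {}
    for ri, (name, seq) in enumerate(reference_records):
        ids, valid = kmer_hashes(seq, k)
        fh = _fwd_hashes(seq, k)
        for p in range(len(ids)):
            if not valid[p]:
                continue
            c = int(ids[p])
            canon_counts[c] = canon_counts.get(c, 0) + 1
            fwd.setdefault(int(fh[p]), (ri, p))
    return fwd, canon_counts


def _fwd_hashes(seq: str, k: int) -> np.ndarray:
    from .kmers import _hash_windows
    from ._seq import CODE

    codes = CODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]
    return _hash_windows(codes, k)


def longrange_consistency(
    assembly_records,
    reference_records,
    segment_size: int,
    k: int = DEFAULT_K,
    length_tol: float = 0.10,
    ref_gap_min: int = 100,
) -> float | None:
    """Fraction of fixed-size scaffold segments placed inconsistently.

    Segments are tiled per record; each needs both end k-mers unique in
    the reference.  Consistent means: same reference record, same strand,
    correct order, and an implied span within length_tol of the segment
    size.  Segments whose implied reference span bridges a reference gap
    (>= ref_gap_min Ns) are excluded.  None when no segment qualifies.
    """
    fwd, canon_counts = _ref_unique_index(reference_records, k)
    ref_seqs = [seq for _, seq in reference_records]
    total = inconsistent = 0
    for name, seq in assembly_records:
        n_seg = len(seq) // segment_size
        for si in range(n_seg):
            a = si * segment_size
            b = a + segment_size
            k1 = seq[a : a + k]
            k2 = seq[b - k : b]
            p1 = _lookup_fwd(k1, fwd, canon_counts, k)
            p2 = _lookup_fwd(k2, fwd, canon_counts, k)
            if p1 is None or p2 is None:
                continue
            (r1, pos1, s1), (r2, pos2, s2) = p1, p2
            # exclusion: bridged reference gap
            if r1 == r2:
                lo = min(pos1, pos2)
                hi = max(pos1, pos2) + k
                if 0 <= lo < hi <= len(ref_seqs[r1]):
                    if _has_gap_run(ref_seqs[r1], lo, hi, ref_gap_min):
                        continue  # span bridges a reference gap
            total += 1
            ok = False
            if r1 == r2 and s1 == s2:
                if s1 > 0:
                    span = (pos2 + k) - pos1
                    ordered = pos2 > pos1
                else:
                    span = (pos1 + k) - pos2
                    ordered = pos1 > pos2
                if ordered and abs(span - segment_size) <= length_tol * segment_size:
                    ok = True
            if not ok:
                inconsistent += 1
    if total == 0:
        return None
    return inconsistent / total


def _lookup_fwd(kmer: str, fwd, canon_counts, k):
    if "N" in kmer or len(kmer) < k:
        return None
    h = int(_fwd_hashes(kmer, k)[0])
    hit = fwd.get(h)
    strand = 1
    if hit is None:
        h2 = int(_fwd_hashes(revcomp(kmer), k)[0])
        hit = fwd.get(h2)
        strand = -1
    if hit is None:
        return None
    ids, _ = kmer_hashes(kmer, k)
    if canon_counts.get(int(ids[0]), 0) != 1:
        return None
    return hit[0], hit[1], strand


def _has_gap_run(seq: str, lo: int, hi: int, min_run: int) -> bool:
    segment = seq[lo:hi]
    return ("N" * min_run) in segment


# ---------------------------------------------------------------- molecule length


def molecule_spans(placements, max_gap: int = 100_000) -> list[int]:
    """Inferred molecule span lengths from read placements (per barcode,
    per line, split at read gaps > max_gap)."""
    spans: list[int] = []
    per: dict[tuple[int, int], list[int]] = {}
    for u in range(len(placements.line)):
        li = int(placements.line[u])
        if li < 0:
            continue
        per.setdefault((int(placements.barcode[u]), li), []).append(
            int(placements.pos[u])
        )
    for key in sorted(per):
        ps = sorted(per[key])
        start = ps[0]
        prev = ps[0]
        for p in ps[1:]:
            if p - prev > max_gap:
                spans.append(prev - start)
                start = p
            prev = p
        spans.append(prev - start)
    return spans


def inferred_molecule_lwm(
    placements=None, spans=None, max_gap: int = 100_000, end_correction: int = 0
) -> float | None:
    """Length-weighted mean (sum l^2 / sum l) of inferred molecule spans.

    Spans underestimate true molecule length (unsequenced molecule ends);
    end_correction bases are added to each span before averaging.
    """
    if spans is None:
        spans = molecule_spans(placements, max_gap)
    spans = [s + end_correction for s in spans if s + end_correction > 0]
    tot = sum(spans)
    if tot <= 0:
        return None
    return sum(s * s for s in spans) / tot


# ---------------------------------------------------------------- novel windows


@dataclass
class NovelWindow:
    record: str
    start: int
    end: int
    unique_fraction: float

    @property
    def length(self) -> int:
        return self.end - self.start


def novel_windows(
    assembly_records,
    reference_records,
    k: int = DEFAULT_K,
    window: int = 10_000,
    step: int = 1_000,
    max_contained: float = 0.10,
    redundancy: float = 0.90,
) -> list[NovelWindow]:
    """Windows of assembly sequence essentially absent from the reference.

    Flags every `window`-sized window (stride `step`) in which at most
    max_contained of the gap-free k-mers occur in the reference, merges
    overlapping flagged windows, and drops windows sharing >= redundancy
    of their k-mers with an already kept window (novelty shared between
    haplotypes is reported once).
    """
    ref_set = hash_set((seq for _, seq in reference_records), k)
    merged: list[tuple[str, int, int]] = []
    seqs = {}
    for name, seq in assembly_records:
        seqs[name] = seq
        if len(seq) < window:
            continue
        ids, valid = kmer_hashes(seq, k)
        present = in_hash_set(ids, ref_set) & valid
        pv = np.concatenate([[0], np.cumsum(valid)])
        pp = np.concatenate([[0], np.cumsum(present)])
        flagged: list[tuple[int, int]] = []
        for a in range(0, len(seq) - window + 1, step):
            b = a + window - k + 1
            nv = pv[b] - pv[a]
            np_ = pp[b] - pp[a]
            if nv > 0 and np_ <= max_contained * nv:
                if flagged and a <= flagged[-1][1]:
                    flagged[-1] = (flagged[-1][0], a + window)
                else:
                    flagged.append((a, a + window))
        merged.extend((name, a, b) for a, b in flagged)
    # redundancy filter, largest first
    merged.sort(key=lambda t: (-(t[2] - t[1]), t[0], t[1]))
    kept: list[NovelWindow] = []
    kept_sets: list[np.ndarray] = []
    for name, a, b in merged:
        wseq = seqs[name][a:b]
        wset = hash_set([wseq], k)
        if len(wset) == 0:
            continue
        redundant = False
        for ks in kept_sets:
            sharing = float(np.mean(in_hash_set(wset, ks)))
            if sharing >= redundancy:
                redundant = True
                break
        if redundant:
            continue
        ids, valid = kmer_hashes(wseq, k)
        ids = ids[valid]
        uniq_frac = len(np.unique(ids)) / len(ids) if len(ids) else 0.0
        kept.append(NovelWindow(name, a, b, uniq_frac))
        kept_sets.append(wset)
    kept.sort(key=lambda w: (w.record, w.start))
    return kept


# ---------------------------------------------------------------- report


@dataclass
class StatsReport:
    n50_contig: int | None = None
    n50_scaffold: int | None = None
    n75_scaffold: int | None = None
    n50_phase_block: int | None = None
    gap_fraction: float | None = None
    n50_perfect_stretch: int | None = None
    missing_haploid: float | None = None
    missing_diploid: float | None = None
    inconsistent_1mb: float | None = None
    inconsistent_10mb: float | None = None
    phasing_votes: int | None = None
    phasing_wrong: int | None = None
    phasing_error_rate: float | None = None
    molecule_lwm: float | None = None
    extras: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        d = {k: v for k, v in self.__dict__.items() if k != "extras"}
        d.update(self.extras)
        return d
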