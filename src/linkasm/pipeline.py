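"""End-to-end assembly pipeline: reads -> phased diploid scaffolds.

Stage order: k-mer counting with barcode prefilter -> base graph (k=48) ->
cleaning -> read threading -> super graph (k'=200) -> line decomposition ->
read-pair scaffolding -> barcode scaffolding (O&O penalty) -> gap filling
-> phasing into megabubbles.  All parameters live in PipelineConfig; the
defaults are the method's published constants and identical config + seed
reproduce byte-identical output.
"""

from __future__ import annotations

import logging
import pickle
from dataclasses import asdict, dataclass, field
from pathlib import Path

from .graph import build_base_graph, clean_graph
from .kmers import count_kmers, prefilter_kmers
from .lines import decompose_lines
from .output import AssemblyBundle
from .paths import join_read_paths, thread_pairs
from .phasing import build_vote_index, phase_line, read_votes
from .scaffold import barcode_scaffold, fill_gaps, pair_scaffold, place_reads

log = logging.getLogger("linkasm")


@dataclass
class PipelineConfig:
    k: int = 48
    k_prime: int = 200
    prefilter_min_barcodes: int = 2
    tip_len_factor: float = 2.0
    tip_support_frac: float = 0.1
    max_mismatches: int = 3
    insert_min: int = 150
    insert_max: int = 600
    scaffold_min_pairs: int = 3
    scaffold_end_window: int = 600
    insert_mean: float = 350.0
    min_shared_barcodes: int = 10
    min_line_for_oo: int = 20_000
    oo_quotient_bound: float = 2.0
    oo_win_margin: float = 60.0
    molecule_gap: int = 100_000
    bubble_exclude_threshold: int = 4
    pivot_break_threshold: int = 10
    gap_flank: int = 50_000
    fill_min_count: int = 2
    max_rounds: int = 5
    seed: int = 0
    styles: tuple = ("raw", "megabubble", "pseudohap", "pseudohap2")

    def to_yaml(self, path) -> None:
        import yaml

        d = asdict(self)
        d["styles"] = list(d["styles"])
        Path(path).write_text(yaml.safe_dump(d))

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        import yaml

        d = yaml.safe_load(Path(path).read_text())
        d["styles"] = tuple(d.get("styles", cls.styles))
        return cls(**d)


def _checkpoint(out_dir, name, obj):
    if out_dir is None:
        return
    p = Path(out_dir) / "checkpoints"
    p.mkdir(parents=True, exist_ok=True)
    with open(p / f"{name}.pkl", "wb") as f:
        pickle.dump(obj, f)


def load_checkpoint(out_dir, name):
    with open(Path(out_dir) / "checkpoints" / f"{name}.pkl", "rb") as f:
        return pickle.load(f)


def run_assembly(reads, config: PipelineConfig | None = None, out_dir=None) -> AssemblyBundle:
    """Assemble a ReadSet into phased scaffolds.

    Returns an AssemblyBundle; intermediate stages are checkpointed under
    out_dir/checkpoints when out_dir is given.
    """
    cfg = config or PipelineConfig()
    if reads.n_pairs == 0:
        raise ValueError("empty read set")

    def read_iter():
        for i in range(reads.n_pairs):
            b = int(reads.barcode_ids[i])
            yield reads.r1[i], b
            yield reads.r2[i], b

    log.info("counting %d-mers over %d read pairs", cfg.k, reads.n_pairs)
    table = count_kmers(read_iter(), cfg.k)
    log.info("%d distinct k-mers", len(table))
    table = prefilter_kmers(table, cfg.prefilter_min_barcodes)
    log.info("%d k-mers after barcode prefilter", len(table))
    _checkpoint(out_dir, "kmers", table)

    base = clean_graph(
        build_base_graph(table), cfg.tip_len_factor, cfg.tip_support_frac
    )
    log.info("base graph: %d edges", base.n_edges)
    _checkpoint(out_dir, "base_graph", base)

    index = base.kmer_index()
    paths, fallbacks, stats = thread_pairs(
        reads, base, index,
        insert_min=cfg.insert_min, insert_max=cfg.insert_max,
        max_mm=cfg.max_mismatches,
    )
    log.info("read threading: %s", stats)
    # ambiguous pairs contribute no insert walks, only single-read walks
    walks = [p[0] for p in paths if len(p) == 1] + fallbacks
    del index
    super_graph = join_read_paths(walks, base, cfg.k_prime)
    log.info("super graph: %d edges", super_graph.n_edges)
    _checkpoint(out_dir, "super_graph", super_graph)

    lines = decompose_lines(super_graph)
    log.info("%d lines", len(lines))

    for rnd in range(cfg.max_rounds):
        placements = place_reads(reads, lines, cfg.k)
        lines, n_merged = pair_scaffold(
            lines, placements, reads,
            min_pairs=cfg.scaffold_min_pairs,
            end_window=cfg.scaffold_end_window,
            insert_mean=cfg.insert_mean,
        )
        log.info("pair scaffolding round %d: %d merges", rnd, n_merged)
        if n_merged == 0:
            break
    for rnd in range(cfg.max_rounds):
        placements = place_reads(reads, lines, cfg.k)
        lines, n_merged = barcode_scaffold(
            lines, placements,
            min_shared=cfg.min_shared_barcodes,
            min_line=cfg.min_line_for_oo,
            margin=cfg.oo_win_margin,
            bound=cfg.oo_quotient_bound,
        )
        log.info("barcode scaffolding round %d: %d merges", rnd, n_merged)
        if n_merged == 0:
            break
    _checkpoint(out_dir, "scaffolds", lines)

    placements = place_reads(reads, lines, cfg.k)
    pairs_by_bc = reads.pairs_of_barcode()
    total_closed = 0
    for li in range(len(lines)):
        lines[li], closed = fill_gaps(
            lines[li], reads, pairs_by_bc, placements, li, cfg.k,
            flank=cfg.gap_flank, min_count=cfg.fill_min_count,
        )
        total_closed += closed
    log.info("gap filling: %d gaps closed", total_closed)
    _checkpoint(out_dir, "filled", lines)

    placements = place_reads(reads, lines, cfg.k)
    vote_index = build_vote_index(lines, cfg.k)
    unit_votes = read_votes(reads, vote_index, cfg.k)
    for li, line in enumerate(lines):
        phase_line(
            li, line, placements, unit_votes,
            bubble_threshold=cfg.bubble_exclude_threshold,
            pivot_threshold=cfg.pivot_break_threshold,
        )
    n_blocks = sum(len(l.phasing.blocks) for l in lines if l.phasing)
    log.info("phasing: %d phase blocks", n_blocks)

    d = asdict(cfg)
    d["styles"] = list(d["styles"])
    bundle = AssemblyBundle(scaffolds=lines, k=cfg.k, config=d)
    _checkpoint(out_dir, "bundle", bundle)
    if out_dir is not None:
        from .io import write_gfa, write_phasing_report, write_scaffold_layout, write_super_mapping

        out = Path(out_dir)
        write_gfa(super_graph, out / "super_graph.gfa")
        write_super_mapping(super_graph, out / "super_edges.tsv")
        write_scaffold_layout(lines, out / "scaffold_layout.tsv")
        write_phasing_report(lines, out / "phasing_report.tsv")
    return bundle


def run_from_fastq(
    fastq1, fastq2, config: PipelineConfig | None = None,
    dialect: str = "raw", out_dir=None,
) -> AssemblyBundle:
    from .io import read_fastq_pair

    reads = read_fastq_pair(fastq1, fastq2, dialect=dialect)
    return run_assembly(reads, config, out_dir=out_dir)
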