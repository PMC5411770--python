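# Methods

This note documents the models and algorithmic choices behind `linkasm`:
what the simulator emulates, how each assembly stage works, the tunable
parameters and their defaults, and the known limitations of desk-scale
validation.

## The linked-read data model

A linked-read library is characterised by a handful of quantities tied
together by the closed-form model in `linkasm.model`:

| quantity | default | meaning |
|---|---|---|
| Nₚ | 10⁶ | barcoded partitions (a device property) |
| M | ~10 (full scale) | molecules per partition, Poisson-distributed |
| molecule length | 50 kb fixed (lognormal optional) | input DNA size; the lognormal option is parameterised by its length-weighted mean (LWM = Σl²/Σl) and log-σ (0.6) |
| R | 1200 M reads | 2×150 sequencing, 56.25× genome coverage |
| LPM | 60 | read pairs per molecule, (R/2)/(Nₚ·M) |
| per-molecule depth | 0.36× | LPM·2L / molecule length |
| insert | 350 ± 35 | genomic fragment span |
| barcode | 16 bases at the start of read 1 | exact (no barcode errors simulated) |
| error rate | 0.1 % | i.i.d. substitutions |
| recovery fraction | 0.40 | loaded DNA that survives into the library |

The operating regime is *shallow coverage of many long molecules*: a
molecule contributes ~60 read pairs spread over 50 kb, so molecules are
never locally assemblable on their own — all long-range information is
statistical, carried by barcodes.

### Desk scaling

`LibraryModel.desk(G)` scales the design to a small genome by keeping
every per-molecule statistic fixed (molecule length, LPM = 60, 0.36×
depth, 56.25× coverage) and reducing the **loaded mass**, i.e. the
molecule count, while keeping the partition count at the device's 10⁶.
This mirrors the recommended small-genome workflow (load less DNA, same
chip) and, crucially, preserves the *barcode uniqueness regime* of the
full-scale data: the probability that two molecules share a barcode and
fall within the 100 kb molecule-merge radius of each other is ~0.1 % at
1 Mb, the same as at human scale.  Fixing M ≈ 10 instead would make
same-barcode haplotype collisions the norm on a megabase genome (we
measured 30–50 % of inferred molecules being two-haplotype mixtures),
corrupting both the phasing votes and the inferred molecule LWM in ways
that simply do not occur at full scale.

Molecule starts are drawn over `[-(l-1), G)` and clipped at both
chromosome ends, so interior physical coverage is uniform; clipped
molecules are correspondingly shorter, which lowers realised coverage by
the finite-chromosome factor G/(G+l−1) and makes the truth molecule LWM
the correct reference for the inferred-LWM statistic at desk scale.

The simulator does **not** model PCR duplicates, chimeric molecules,
barcode collisions or sequencing-quality structure, and genome
composition is i.i.d. uniform — so passing tests demonstrate algorithmic
correctness under the stated statistical model, not robustness to real
genomic repeat structure or coverage bias.

## Assembly stages

**k-mer counting and prefilter.** Canonical k-mers (k = 48; lexicographic
minimum of a window and its reverse complement) are counted exactly with
per-barcode occupancy, packed two-bits-per-base into 128-bit integers so
counting is fully vectorised.  k-mers present in a single barcode are
removed: a true locus is sampled by ~150 molecules from different
partitions, so single-barcode k-mers are almost surely errors.

**Base graph.** The surviving k-mer set is unitig-compressed into a
bidirected graph (edges = maximal unbranched sequences, k−1 overlaps,
reverse-complement involution).  Successor/predecessor resolution is
vectorised over packed k-mers.  Cleaning removes dead-end tips shorter
than 2k whose support is below 10 % of the median support at their
attachment vertex — thresholds that stand in for the much richer error
recovery of the full-scale tool — and recompresses; the operation is a
fixed point on clean input.

**Read threading.** Each read is anchored by its first indexed k-mer and
verified along the graph, allowing up to 3 substitutions; only
minimum-mismatch placements are kept, so a read covering a het site
selects its own arm (the wrong arm always costs one extra mismatch).
Mates are bridged along the graph within insert-size bounds (150–600).
Pairs with several candidate insert walks — typically pairs bracketing a
het bubble without covering it — contribute no joins, but each mate's own
unique walk is still used as joining evidence: walks are extended to full
edge boundaries, so even a 150-base read carries its edges' full context.

**Super graph (k′ = 200).** Distinct walks (plus a singleton walk per
edge, so uncovered edges survive) are glued wherever two walks share an
exact terminal (suffix/prefix) or containment overlap in edge space whose
spelled length is ≥ k′; contained walks spelling < k′ are redundant and
dropped.  Union-find over walk edge-instances, followed by unbranched
chain compression, yields super edges that are paths in the base graph
(abutting super edges still overlap k−1 bases).  On clean data the result
approximates collapsing the genome along identical 200-mers: repeats and
inter-SNP homozygous stretches shorter than ~200 bases are duplicated
into their haplotype contexts (quantised at edge boundaries, hence
"approximates"), while longer shared sequence stays collapsed.

**Lines.** Superbubbles (entrance/exit vertices with an acyclic interior)
are detected at every branch vertex; a bubble is represented by the set
of all its entrance→exit paths (capped at 16 arms, 64 interior edges).
Lines are maximal alternations of common segments and bubbles; circles
and single-edge tangles are their own degenerate lines; every edge lands
in exactly one line up to reverse complement.

**Scaffolding.** Reads are re-placed on line coordinates by their first
globally unique k-mer.  Pair scaffolding joins a right end to a left end
only when ≥ 3 pairs support exactly one partner and none support any
other; lines < 1 kb neither link nor veto (their position is uncertain,
and error-derived crumbs would otherwise block every junction).  Barcode
scaffolding scores the four order/orientation classes of each candidate
pair of lines (≥ 10 shared barcodes, both ≥ 20 kb) with the O&O penalty —
jump separation / per-barcode mean separation, quotients below 2.0
discarded — and merges only when the best candidate beats the runner-up
by ≥ 60.0; iterated pairwise merging realises the small-set enumeration.
Barcode-bridged gap sizes are estimated as the median implied jump
spacing, clamped to [0, 100 kb] — a crude but serviceable estimate.

**Gap filling.** For each gap, barcodes with placements in the terminal
50 kb of either flank recruit all their reads; these are assembled
locally (same k, no barcode prefilter, k-mers below count 2 dropped) and
the line walk between the two flank-anchor k-mers, bubbles included,
replaces the gap when the anchors land unambiguously in common segments
of one local line.  Gaps whose anchors are ambiguous (e.g. inside long
repeats) stay open.

**Phasing.** Molecules are same-barcode placements split at > 100 kb
gaps.  A read votes for an arm when it contains arm-distinctive k-mers of
exactly one arm; a molecule's vote per bubble is its reads' majority.
The phasing score is Σ_molecules |Σ_bubbles vote·orientation| (the
Max−Min form), climbed by sweeps of the three perturbation families in a
fixed order (molecule-coherence, single flips, pivots; first
improvement), which terminates because the score is bounded and strictly
increases.  The initial orientation puts the lexicographically smaller
arm on top — a deterministic stand-in for an arbitrary start.  A bubble
is excluded when |Δscore of flipping it| < 4 (a single coherent molecule
vote contributes 2, so this requires at least two independent molecules);
the phasing breaks where |Δscore of a pivot| < 10, e.g. across
homozygous stretches longer than the molecule span.  Blocks of phased
bubbles become megabubbles; excluded bubbles are flattened identically
into both arms.

**Output.** Flattening picks the higher-supported arm (ties to the
lexicographically smaller).  Pair-bridged gaps print exactly 100 Ns;
barcode-bridged gaps print max(100, estimate) Ns; unresolved cycles print
a greedy covering path plus 10 Ns.  Pseudohaplotype 1 takes the "top" arm
of every megabubble and pseudohaplotype 2 the other, so the two files are
structurally parallel (record counts match; per-record lengths can differ
where het indels separate the arms).  Reruns with identical input and
configuration are byte-identical: there is no randomness anywhere in the
assembler, and every iteration order is fixed.

## Assessment details

All scaffold statistics are computed after removing scaffolds < 10 kb.
Perfect stretches are maximal *exact* matches between truth and one
assembly record (either strand), found by shared-48-mer seeding on
diagonals with exact verification — no scoring alignment, because
"perfectly represented" is an exact criterion; stretches shorter than the
seed (48) are not reported, and matching against the megabubble-style
records stands in for path-level matching of the raw graph (at desk scale
megabubble records are far longer than perfect stretches, so the
difference is negligible).  The phasing error follows the trio protocol:
at every het SNP whose two ±50-base context k-mers land on opposite arms
of a megabubble (≥ 1 Mb at full scale; size configurable for desk runs),
record which haplotype is on top; within a megabubble the minority votes
are wrong, and the rate is Σwrong/Σvotes.  k = 100 k-mer metrics
(missing fraction with GC/duplicity strata, unique-end-k-mer long-range
consistency with the ±10 % span rule and reference-gap exclusion,
novel-window scan at 1 kb stride with the ≥ 90 % redundancy filter)
identify k-mers by a strand-symmetric 64-bit rolling hash; collisions are
~n²/2⁶⁴ and negligible at desk scale.  Molecule spans use the same
100 kb split rule as phasing, with an optional end-correction (default
0) for the unobserved molecule ends; spans are measured per scaffold, so
molecules crossing scaffold boundaries truncate — negligible once
scaffolds are much longer than molecules, visible on sub-200 kb toy
genomes.

## Problem sizes

Unit tests run on 1.5–6 kb constructed fixtures and 20–150 kb
simulations; the shared end-to-end test assembles a 150 kb diploid
genome, and the acceptance script a 1 Mb genome (≈ 10 minutes on one
CPU).  These sizes were chosen so the whole validation suite runs on a
laptop; all rates and per-molecule parameters stay at the full-scale
values, and only counts (genome size, partitions, replicates) shrink.

## Known limitations

- Tip cleaning is a deliberate simplification of full-scale error
  recovery; with the barcode prefilter it suffices at 0.1 % error, but
  residual error walks leave sub-500 b "crumb" scaffolds (removed by the
  10 kb assessment filter).
- Bubble detection caps arm count and interior size; pathological tangles
  degrade to single-edge lines rather than bubbles.
- The k′ gluing quantises overlap length at edge boundaries, so the
  resolved/collapsed transition sits at ~200±50 spelled bases rather than
  exactly 200.
- Phasing across megabubbles is out of scope by design (successive
  megabubbles are not phased relative to each other), as is any
  reference-guided step.
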