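"""Assess an assembly against the simulation truth.

Computes the full statistic suite: N50 contig/scaffold, gap fraction,
N50 perfect stretch (exact-match accuracy), trio-style phasing error,
missing-100-mer completeness, long-range consistency, and the inferred
molecule length-weighted mean.
"""

from linkasm import assess, simulate_library
from linkasm.output import emit_fasta, megabubble_arms
from linkasm.pipeline import run_assembly
from linkasm.scaffold import place_reads

genome, model, molecules, reads = simulate_library(100_000, seed=42)
bundle = run_assembly(reads)
truth = [genome.haplotype0, genome.haplotype1]

ph = assess.filter_scaffolds(emit_fasta(bundle, "pseudohap"))
clens, nfrac = assess.contig_lengths([s for _, s in ph])
print(f"N50 scaffold        {assess.nxx([len(s) for _, s in ph], 50):,}")
print(f"N50 contig          {assess.nxx(clens, 50):,}")
print(f"gap fraction        {nfrac:.3%}")

mb = assess.filter_scaffolds(emit_fasta(bundle, "megabubble"), 1000)
stretches = assess.perfect_stretches(mb, truth)
print(f"N50 perfect stretch {assess.nxx(stretches, 50):,} over {len(stretches)} stretches")

arms = megabubble_arms(bundle)
votes, wrong, rate = assess.phasing_error(arms, genome, min_size=10_000)
print(f"phasing error       {wrong}/{votes} votes wrong (rate {rate})")

p1, p2 = emit_fasta(bundle, "pseudohap2")
ref = [("hap0", genome.haplotype0)]
hap = assess.missing_kmer_fraction(assess.filter_scaffolds(p1), ref)
dip = assess.missing_kmer_fraction(
    assess.filter_scaffolds(p1) + assess.filter_scaffolds(p2), ref
)
print(f"missing 100-mers    haploid {hap['missing_fraction']:.3%}, "
      f"diploid {dip['missing_fraction']:.3%}")

placements = place_reads(reads, bundle.scaffolds, bundle.k)
lwm = assess.inferred_molecule_lwm(placements)
tl = [m.length for m in molecules]
truth_lwm = sum(l * l for l in tl) / sum(tl)
print(f"inferred molecule LWM {lwm/1e3:.1f} kb "
      f"(truth molecules, clipped at chromosome ends: {truth_lwm/1e3:.1f} kb)")
print("-> the haploid missing fraction is dominated by the het alleles a")
print("   single pseudohaplotype cannot carry; the diploid output recovers")
print("   them.  Molecule spans are measured per scaffold, so on a genome")
print("   this small (2 molecule lengths) the inferred LWM underestimates")
print("   the truth; at 1 Mb the two agree within a few percent.")
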