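"""The closed-form linked-read library model.

Computes the expected statistics of the standard design -- 10^6 barcoded
partitions, ~10 molecules of 50 kb per partition, 1200 M reads of 150
bases -- and of the same chip loaded with a tenfold smaller genome.
"""

from linkasm import LibraryModel, model_calculator

human = LibraryModel()  # the reference human design
e = model_calculator(human)
print("reference design (3.2 Gb genome, 1200 M reads):")
print(f"  molecules per partition      {e.molecules_per_partition:.1f}")
print(f"  DNA per partition            {e.dna_per_partition/1e6:.2f} Mb")
print(f"  read pairs per molecule      {e.read_pairs_per_molecule:.0f}")
print(f"  per-molecule read depth      {e.per_molecule_depth:.2f}x")
print(f"  genome coverage              {e.genome_coverage:.2f}x")

small = LibraryModel(genome_size=320e6, total_reads=56.25 * 320e6 / 150)
es = model_calculator(small)
print("same mass and depth on a 320 Mb genome:")
print(f"  read pairs per molecule      {es.read_pairs_per_molecule:.1f}")
print(f"  spacing between read pairs   {es.read_spacing/1e3:.1f} kb")
print("-> shallow per-molecule coverage is the operating regime; a small")
print("   genome dilutes the read budget per molecule tenfold, which is")
print("   why desk-scale simulations keep the per-molecule statistics and")
print("   shrink the loaded mass instead.")
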