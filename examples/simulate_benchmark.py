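"""Generate a small truth-labelled diploid benchmark and inspect it.

A 100-kb diploid genome at heterozygosity 0.04 is turned into the contig
set a stringent assembler would produce: homotigs from homozygous runs and
heterotig pairs from heterozygous blocks, plus error-free paired reads with
per-read haplotype provenance."""

from hapscaffold import build_universe

universe = build_universe(length=100_000, coverage=20, seed=42)

truth = universe.truth
n_het = len(truth.heterotig_ids)
n_hom = len(truth.contigs) - n_het
print(f"genome: {universe.genome.length_a} bp (A) / {universe.genome.length_b} bp (B), "
      f"{len(universe.genome.variants)} variant sites")
print(f"contigs: {len(truth.contigs)} ({n_hom} homotigs, {n_het} heterotigs "
      f"forming {len(truth.homolotig_pairs)} homolotig pairs)")
for lib in universe.libraries:
    print(f"library {lib.spec.name}: {len(lib.reads)} pairs, "
          f"insert {lib.spec.mean_insert} bp, rank {lib.spec.rank}")

# depth separates ploidy: heterotigs carry one haplotype's reads, homotigs both
hets = [universe.depth_table[c.id] for c in truth.contigs.values()
        if c.cls == "HETEROTIG" and c.id in universe.depth_table]
homs = [universe.depth_table[c.id] for c in truth.contigs.values()
        if c.cls == "HOMOTIG" and c.id in universe.depth_table]
print(f"mean heterotig depth {sum(hets)/len(hets):.1f}x vs homotig {sum(homs)/len(homs):.1f}x "
      "(haploid vs diploid coverage, the signal the classifier exploits)")
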