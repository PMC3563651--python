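"""Chain homology anchors into syntenic blocks between two simulated genomes.

Simulates a speciation followed by a whole-genome duplication in genome A,
emits an all-vs-all homology table with 5% spurious hits, and chains the
filtered anchors (e-value <= 0.01) into collinear blocks in gene-rank space.
"""

from famarch import chain_genome_pair, emit_homology_hits, genes_in_blocks, simulate_genome_pair

pair = simulate_genome_pair(seed=7)
homology = emit_homology_hits(pair, spurious_rate=0.05, seed=8)
blocks = chain_genome_pair(pair.genome_a, pair.genome_b, homology,
                           max_evalue=0.01, min_anchors=4, max_gap=10)

print(f"genome A: {len(pair.genome_a)} genes   genome B: {len(pair.genome_b)} genes")
print(f"homology rows: {len(homology)}   syntenic blocks: {len(blocks)}")
for b in blocks[:5]:
    print(f"  {b.chrom_a} ~ {b.chrom_b}  {len(b)} anchors  "
          f"score {b.chain_score:.1f}  {b.orientation}")

members = pair.true_family_members["b"]
distinct, multiplicity = genes_in_blocks(blocks, members, side="b")
print(f"family members of B in blocks: {distinct}/{len(members)} distinct "
      f"({multiplicity} gene-block incidences)")
# After the WGD in A, one B region matches two A regions, so the incidence
# count exceeds the distinct count: the one-to-many relationships.
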