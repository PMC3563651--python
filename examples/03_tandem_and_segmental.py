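"""Detect tandem arrays and segmental duplications, then compare to ground truth.

Genome B carries 20 simulated tandem duplication events; genome A carries a
whole-genome duplication with 60% gene retention.  Tandem arrays are runs of
near-adjacent homologous family genes; segmental duplications are collinear
within-genome blocks after local (tandem-range) anchors are excluded.
"""

from famarch import (
    detect_segmental_duplications,
    detect_tandem_arrays,
    emit_homology_hits,
    simulate_genome_pair,
)

pair = simulate_genome_pair(seed=5)
homology = emit_homology_hits(pair, spurious_rate=0.0, seed=6)

arrays = detect_tandem_arrays(pair.genome_b, pair.true_family_members["b"],
                              homology, max_intervening=1)
truth = pair.true_tandem_arrays["b"]
print(f"tandem arrays detected in B: {len(arrays)} (simulated: {len(truth)})")
exact = sorted(map(sorted, (a.genes for a in arrays))) == sorted(map(sorted, truth))
print(f"exact recovery of ground truth: {exact}")

in_a = pair.genome_a.gene_ids
self_a = homology[homology["query_id"].isin(in_a) & homology["subject_id"].isin(in_a)]
segdups = detect_segmental_duplications(pair.genome_a, self_a)
covered = {tuple(sorted((a.gene_a, a.gene_b)))
           for s in segdups for a in s.block.anchors}
truth_pairs = {tuple(sorted(p)) for p in pair.true_segmental_pairs["a"]}
print(f"segmental blocks in A: {len(segdups)}")
print(f"retained WGD paralog pairs inside blocks: "
      f"{len(covered & truth_pairs)}/{len(truth_pairs)}")
# At 60% retention the duplicated chromosomes keep long collinear stretches,
# so nearly all surviving paralog pairs chain into segmental blocks.
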