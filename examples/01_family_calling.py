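"""Call family members from a domain-hit table with the clan e-value/coverage filter.

Simulates a genome in which 3% of genes carry the family label, emits domain
hits with decoys engineered to fail exactly one filter criterion, and calls
members.  With a clean table the calls match the ground truth exactly.
"""

from famarch import call_family_members, emit_domain_hits, simulate_ancestor
from famarch.synthetic_data import CLAN_DOMAINS

genome = simulate_ancestor(n_chromosomes=2, genes_per_chromosome=200,
                           family_fraction=0.03, seed=42)
hits = emit_domain_hits(genome, true_positive_rate=1.0, decoy_rate=0.3, seed=43)
calls = call_family_members(hits, set(CLAN_DOMAINS), max_evalue=1.0, min_coverage=0.5)

n_decoy_hits = len([h for h in hits if h.gene_id not in genome.family_genes])
print(f"genes: {len(genome)}   true family members: {len(genome.family_genes)}")
print(f"domain hits: {len(hits)} ({n_decoy_hits} decoys straddling the filter)")
print(f"called members: {len(calls.members)}")
print(f"false positives: {len(calls.members - genome.family_genes)}")
print(f"false negatives: {len(genome.family_genes - calls.members)}")
# Every decoy fails exactly one of (e-value <= 1.0, coverage >= 0.5), so the
# two-criterion filter removes all of them while keeping every true member.
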