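# Methods

This note records the models, parameter choices and numerical conventions
behind `famarch`, and what the simulation-based tests do and do not
establish about real data.

## Coordinate system

All structure detection operates in **gene-rank space**: a gene's rank is
its 1-based position in start-coordinate order along its chromosome (ties
broken by end coordinate, then gene id).  Rank space makes gap penalties
independent of genome size and intergenic geometry; base-pair coordinates
are kept only for reporting (array spans, BED output).  GFF3 input/output is
1-based inclusive; BED output is 0-based half-open; the converters are
inverse bijections on valid records.  Gene models without usable coordinates
or an `ID` attribute cannot be placed in rank space; readers drop them,
count every drop by reason, and never repair records silently.

## Family calling

A gene is a family member iff it has at least one hit to a clan domain with
`e_value ≤ max_evalue` (default 1.0) and model coverage
`(hmm_to − hmm_from + 1) / model_length ≥ min_coverage` (default 0.5).  The
permissive e-value ceiling avoids false negatives among fast-evolving
members; the coverage floor controls the false positives it would otherwise
admit.  Coverage is measured on the HMM **model** span and the threshold is
applied to the per-domain independent e-value when parsing HMMER output —
the alternative (full-sequence e-value, target-side span) is a configurable
reading, but model span matches the notion of "fraction of the domain
aligned".  Evidence recorded per member is the minimum-e-value qualifying
hit, ties broken by larger coverage then lexicographic domain name.  The
filter is monotone: raising `max_evalue` or lowering `min_coverage` can only
grow the member set (property-tested).

Potentially inactive members are non-member genes with ≥ 1 homology hit at
`e ≤ 0.01` to a called member — candidates that lost the diagnostic domain
but retain family-wide similarity.

## Anchor chaining

Anchors are filtered hits (`e ≤ 0.01`, self-hits removed, reciprocal
duplicates collapsed to the smaller e-value) scored
`min(50, −log10(max(e, 1e-50)))`.  Within one chromosome pair, blocks are
chains strictly increasing in `rank_a` and strictly monotone in `rank_b`
(increasing = same orientation, decreasing = inverted, found by negating
`rank_b`); a link may skip at most `max_gap` ranks per axis (default 10) and
pays `gap_penalty` (default 1.0) per skipped rank.  The optimal chain is
found by O(n²) longest-path dynamic programming over anchors sorted by
`(rank_a, rank_b)`.

Extraction is greedy: each iteration reports the best-scoring chain (either
orientation) whose optimal traceback has at least `min_anchors` anchors
(default 4), removes its anchors, and repeats; reported blocks are therefore
anchor-disjoint.  Ties prefer the same orientation, then the smaller first
`rank_a`.  Two consequences worth knowing: (i) with `min_anchors=1` the
first extracted chain is exactly the global optimum — this is what the
brute-force oracle test verifies on all instances with ≤ 12 anchors; (ii)
with larger `min_anchors` the length filter applies to each anchor's
*optimal* traceback, so a marginal chain whose score is below that of a
single contained anchor may be reported from one axis direction but not the
other.  Such chains score less than one of their own anchors and are noise
by construction; exact reversal invariance holds for the optimum and is
property-tested at `min_anchors=1`.

## Tandem arrays and segmental duplications

A tandem array is a run of member genes on one chromosome in which
consecutive members are separated by at most `max_intervening` non-member
genes (default 5), restricted to single-linkage components of the homology
graph within the run (edges: hits at `e ≤ 0.01`).  Connectivity is
transitive (single linkage) because array-wide mutual alignability is not
required for common descent.  Passing no homology table switches to pure
positional runs — the mode the permutation null uses, since shuffled labels
carry no homology structure.

Segmental duplications are within-genome blocks chained from self-homology
anchors after excluding self-hits, pairs inside one tandem array, and
same-chromosome pairs with `|rank_a − rank_b| ≤ max_intervening` (segmental
duplication is by definition non-local).  Same-chromosome blocks whose two
rank windows overlap are discarded.

## Permutation null

The enrichment question is answered against a **label-shuffling** null:
gene positions, blocks and arrays are fixed properties of the map; each of
`n_reps` replicates (default 10,000) redraws `|members|` labels uniformly
without replacement over all gene positions and recomputes the statistic.
Blocks are *not* re-chained per replicate — relabeling cannot change
homology-derived structure, and this is the only reading that scales.  The
statistic is the distinct count of member genes in blocks by default; the
incidence (multiplicity) count, where a gene in k blocks contributes k, is
exposed for one-to-many duplication relationships.  For the tandem null,
replicates count positional runs only (no homology splitting), a deliberate
conservative approximation.  Empirical p-values use the add-one estimator
`p = (1 + #{null ≥ obs}) / (n_reps + 1)`, which is never zero and never
anti-conservative; calibration (rejection rate ≤ α under the null itself)
is tested directly.

## Expression

Per-gene z-scores use the population standard deviation (`ddof=0`,
switchable); zero-variance rows are zeroed and flagged rather than dropped.
Clustering is scipy agglomerative clustering on `1 − Pearson r` with average
linkage (the customary defaults of heatmap tools in this field), fully
deterministic; constant rows are excluded under the correlation distance
with a warning.  Transcription calls on raw matrices use a strict
`value > 10.0` threshold in at least one tissue (the microarray-style
convention; RNA-seq-style matrices should use a caller-chosen threshold).
Tissue preference is the argmax tissue when its z-score is ≥ `min_z`
(default 1.5); ties and sub-threshold maxima yield no call.  Note a
geometric constraint: with k tissues a one-hot profile's maximum z-score is
`(k−1)/√(k−1) = √(k−1)`, so `min_z=1.5` requires ≥ 4 tissues to be
attainable for single-tissue genes.  An array is *divergent* if ≥ 2 members
prefer different tissues, *concordant* if ≥ 2 share one preference and none
differ, else *untranscribed*.

## Synthetic data: what it emulates, and what it does not

The generator produces the study conditions the detectors are validated
under: a multi-chromosome ancestor (default 4 × 250 genes) with uniform gene
lengths (500–5,000 bp) and gaps (200–2,000 bp) — nothing downstream depends
on base-pair geometry, only on rank order; a family labeling at 3% of genes,
matching the ~2–3% share large families such as the F-box family hold of
real plant gene complements; WGD as simultaneous duplication of all
chromosomes followed by independent per-gene loss (default retention 0.6),
without fractionation bias; tandem events inserting adjacent downstream
copies (sizes uniform on {2,3,4}), with source genes kept ≥ 2 ranks apart so
distinct events never coalesce into one physical run.  Evidence noise is
adversarial by construction: domain-hit decoys fail *exactly one* of the two
filter criteria, so both branches are exercised; spurious homology hits
straddle the 0.01 threshold.  All generators take explicit seeds; there is
no global random state.

Because copies are inserted strictly adjacently, the matched
`max_intervening` for simulated data is 0–1; the library default of 5
reflects real genomes, where arrays are interrupted by insertions.

Not modeled: nucleotide or protein sequences, biased fractionation,
inversions and translocations after WGD, gene conversion between paralogs,
expression correlated with duplication age.  Passing round-trip tests
therefore shows the detectors are correct for cleanly generated histories
and robust to the modeled noise; it does not show robustness to assembly
artifacts, annotation errors, or rearrangement-fragmented synteny in real
genomes.

## Problem sizes and numerical notes

Round-trip suites run at 2 × 200–250 genes per chromosome; the chaining
oracle compares the DP to exhaustive enumeration on 200 instances of ≤ 12
anchors; null calibration uses 500 experiments of 500 replicates on a
1,000-gene genome — sizes chosen so the full suite completes in well under a
minute while every statistical check retains power.  DP score comparisons
use a 1e-12 slack to keep tie-breaking deterministic under floating-point
addition order.  Percentages are rounded half-away-from-zero (via `decimal`)
so printed values recompute exactly from their count pairs; 38.75 → 38.8,
never banker's 38.7.  Correlation distances are clipped at 0 to absorb tiny
negative rounding.  Empirical p-values are bounded below by
`1/(n_reps + 1)` by construction.
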