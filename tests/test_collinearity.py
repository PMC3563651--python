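import itertools

import numpy as np
import pandas as pd
import pytest

from famarch import (
    Anchor,
    ValidationError,
    anchor_score,
    apply_tandem_duplications,
    apply_wgd,
    chain_anchors,
    chain_genome_pair,
    detect_segmental_duplications,
    detect_tandem_arrays,
    emit_homology_hits,
    genes_in_blocks,
    simulate_ancestor,
    simulate_genome_pair,
)
from famarch.io_formats import BLAST_COLUMNS, GenomeAnnotation


def mk_anchor(ra, rb, score=10.0, ca="c1", cb="c2"):
    return Anchor(f"a{ra}", f"b{rb}", ca, cb, ra, rb, score)


def hom_table(rows):
    """rows of (query, subject, e_value) -> 12-column table."""
    full = [(q, s, 90.0, 200, 20, 0, 1, 200, 1, 200, e, 300.0) for q, s, e in rows]
    return pd.DataFrame(full, columns=BLAST_COLUMNS)


def brute_force_best_chain(anchors, max_gap, gap_penalty):
    """Oracle: enumerate every monotone-increasing chain and score it.

    Independent of the DP: all subsets in rank_a order, validity checked
    link by link.  Exponential, usable only for ~12 anchors.
    """
    best = 0.0
    idx = sorted(range(len(anchors)), key=lambda i: (anchors[i].rank_a, anchors[i].rank_b))
    for r in range(1, len(anchors) + 1):
        for combo in itertools.combinations(idx, r):
            score = anchors[combo[0]].score
            ok = True
            for i, j in zip(combo, combo[1:]):
                da = anchors[j].rank_a - anchors[i].rank_a
                db = anchors[j].rank_b - anchors[i].rank_b
                if da < 1 or db < 1 or da - 1 > max_gap or db - 1 > max_gap:
                    ok = False
                    break
                score += anchors[j].score - gap_penalty * ((da - 1) + (db - 1))
            if ok and score > best:
                best = score
    return best


class TestAnchorScore:
    @pytest.mark.parametrize("e,expected", [(1e-10, 10.0), (1e-80, 50.0), (0.0, 50.0)])
    def test_capped_neglog(self, e, expected):
        assert anchor_score(e) == pytest.approx(expected)

    def test_negative_evalue_rejected(self):
        with pytest.raises(ValidationError):
            anchor_score(-1.0)


class TestChainAnchors:
    def test_perfect_diagonal_single_block(self):
        anchors = [mk_anchor(i, i) for i in range(1, 5)]
        blocks = chain_anchors(anchors)
        assert len(blocks) == 1
        assert blocks[0].chain_score == pytest.approx(40.0)
        assert blocks[0].orientation == "same"
        assert len(blocks[0]) == 4

    def test_min_anchors_discards_short_diagonal(self):
        anchors = [mk_anchor(i, i) for i in range(1, 4)]
        assert chain_anchors(anchors, min_anchors=4) == []
        assert len(chain_anchors(anchors, min_anchors=3)) == 1

    def test_inverted_block_found(self):
        anchors = [mk_anchor(i, 10 - i) for i in range(1, 5)]
        blocks = chain_anchors(anchors)
        assert len(blocks) == 1 and blocks[0].orientation == "inverted"
        assert blocks[0].chain_score == pytest.approx(40.0)

    def test_gap_penalty_applied(self):
        anchors = [mk_anchor(1, 1), mk_anchor(3, 3), mk_anchor(4, 4), mk_anchor(5, 5)]
        blocks = chain_anchors(anchors, min_anchors=4)
        # one skipped rank on each axis between the first two anchors
        assert blocks[0].chain_score == pytest.approx(40.0 - 2.0)

    def test_max_gap_splits_distant_runs(self):
        anchors = [mk_anchor(i, i) for i in (1, 2, 3, 4, 50, 51, 52, 53)]
        blocks = chain_anchors(anchors, max_gap=10)
        assert len(blocks) == 2
        assert all(len(b) == 4 for b in blocks)

    def test_mixed_chromosome_pairs_rejected(self):
        with pytest.raises(ValidationError):
            chain_anchors([mk_anchor(1, 1, ca="c1"), mk_anchor(2, 2, ca="c9")])

    def test_blocks_are_anchor_disjoint(self):
        rng = np.random.default_rng(7)
        anchors = [
            mk_anchor(int(ra), int(rb), float(s))
            for ra, rb, s in zip(
                rng.choice(60, 30, replace=False) + 1,
                rng.choice(60, 30, replace=False) + 1,
                rng.uniform(5, 15, 30),
            )
        ]
        blocks = chain_anchors(anchors, min_anchors=2)
        seen = []
        for b in blocks:
            seen.extend((a.gene_a, a.gene_b) for a in b.anchors)
        assert len(seen) == len(set(seen))

    def test_dp_matches_brute_force_on_small_instances(self, rng):
        """DP optimum equals exhaustive enumeration of all increasing chains."""
        for _ in range(40):
            n = int(rng.integers(2, 13))
            ra = rng.choice(20, size=n, replace=False) + 1
            rb = rng.choice(20, size=n, replace=False) + 1
            scores = rng.uniform(1, 20, size=n)
            anchors = [mk_anchor(int(a), int(b), float(s)) for a, b, s in zip(ra, rb, scores)]
            blocks = chain_anchors(anchors, min_anchors=1, max_gap=8, gap_penalty=1.0,
                                   orientations=("same",))
            dp_best = max(b.chain_score for b in blocks) if blocks else 0.0
            assert dp_best == pytest.approx(brute_force_best_chain(anchors, 8, 1.0))

    def test_invariant_under_joint_axis_reversal(self, rng):
        """Reversing both genomes' rank axes preserves optimal chain scores."""
        for _ in range(10):
            n = 25
            ra = rng.choice(40, size=n, replace=False) + 1
            rb = rng.choice(40, size=n, replace=False) + 1
            scores = rng.uniform(5, 15, size=n)
            fwd = [mk_anchor(int(a), int(b), float(s)) for a, b, s in zip(ra, rb, scores)]
            rev = [mk_anchor(41 - int(a), 41 - int(b), float(s))
                   for a, b, s in zip(ra, rb, scores)]
            s1 = sorted(round(b.chain_score, 9) for b in chain_anchors(fwd, min_anchors=1))
            s2 = sorted(round(b.chain_score, 9) for b in chain_anchors(rev, min_anchors=1))
            assert s1 == s2

    def test_reversal_invariance_at_default_min_anchors(self):
        anchors = [mk_anchor(i, i) for i in (1, 2, 3, 4, 20, 21, 22, 23, 24)]
        rev = [mk_anchor(30 - a.rank_a, 30 - a.rank_b, a.score) for a in anchors]
        s1 = sorted(b.chain_score for b in chain_anchors(anchors))
        s2 = sorted(b.chain_score for b in chain_anchors(rev))
        assert s1 == pytest.approx(s2)

    def test_invariant_under_gene_relabeling(self):
        anchors = [mk_anchor(i, i) for i in range(1, 6)]
        relabeled = [
            Anchor(f"x{a.rank_a}", f"y{a.rank_b}", a.chrom_a, a.chrom_b,
                   a.rank_a, a.rank_b, a.score)
            for a in anchors
        ]
        b1, b2 = chain_anchors(anchors), chain_anchors(relabeled)
        assert [b.chain_score for b in b1] == [b.chain_score for b in b2]


class TestDetectTandemArrays:
    def setup_method(self):
        rows = [(f"g{i}", "chr1", 1000 * i + 1, 1000 * i + 500, "+") for i in range(1, 13)]
        self.ann = GenomeAnnotation(rows)

    def test_three_adjacent_homologous_members_one_array(self):
        members = {"g2", "g3", "g4"}
        hom = hom_table([("g2", "g3", 1e-20), ("g3", "g4", 1e-20)])
        arrays = detect_tandem_arrays(self.ann, members, hom)
        assert len(arrays) == 1 and arrays[0].genes == ["g2", "g3", "g4"]

    def test_gap_rule_boundary_splits_runs(self):
        members = {"g1", "g5"}  # 3 intervening genes
        hom = hom_table([("g1", "g5", 1e-20)])
        assert detect_tandem_arrays(self.ann, members, hom, max_intervening=2) == []
        arrays = detect_tandem_arrays(self.ann, members, hom, max_intervening=3)
        assert len(arrays) == 1

    def test_homology_splits_positional_run(self):
        members = {"g2", "g3", "g4", "g5"}
        hom = hom_table([("g2", "g3", 1e-20), ("g4", "g5", 1e-20)])
        arrays = detect_tandem_arrays(self.ann, members, hom, max_intervening=0)
        assert sorted(a.genes for a in arrays) == [["g2", "g3"], ["g4", "g5"]]

    def test_positional_mode_without_homology(self):
        arrays = detect_tandem_arrays(self.ann, {"g2", "g3"}, None, max_intervening=0)
        assert len(arrays) == 1

    def test_span_bp_covers_members(self):
        hom = hom_table([("g2", "g3", 1e-20)])
        (arr,) = detect_tandem_arrays(self.ann, {"g2", "g3"}, hom)
        assert arr.span_bp == (3000 + 500) - 2001 + 1


class TestDetectSegmentalDuplications:
    def test_full_retention_wgd_recovered_as_one_block_per_chromosome(self):
        ann = simulate_ancestor(1, 10, 0.0, seed=1)
        post, pairs = apply_wgd(ann, 1.0, seed=2)
        hom = hom_table([(a, b, 1e-30) for a, b in pairs])
        segs = detect_segmental_duplications(post, hom)
        assert len(segs) == 1
        assert len(segs[0].block) == 10

    def test_tandem_only_genome_yields_no_segdup(self):
        ann = simulate_ancestor(1, 50, 0.2, seed=3)
        post, arrays = apply_tandem_duplications(ann, 5, seed=4)
        rows = []
        for arr in arrays:
            for i, g1 in enumerate(arr):
                for g2 in arr[i + 1:]:
                    rows.append((g1, g2, 1e-30))
        segs = detect_segmental_duplications(post, hom_table(rows), arrays)
        assert segs == []

    def test_partial_retention_blocks_cover_most_pairs(self):
        ann = simulate_ancestor(1, 200, 0.0, seed=5)
        post, pairs = apply_wgd(ann, 0.6, seed=6)
        hom = hom_table([(a, b, 1e-30) for a, b in pairs])
        segs = detect_segmental_duplications(post, hom)
        covered = {
            tuple(sorted((a.gene_a, a.gene_b)))
            for s in segs
            for a in s.block.anchors
        }
        truth = {tuple(sorted(p)) for p in pairs}
        assert len(covered & truth) / len(truth) >= 0.9


class TestGenesInBlocks:
    def test_empty_blocks(self):
        assert genes_in_blocks([], {"g1"}) == (0, 0)

    def test_multiplicity_counts_per_block_incidence(self):
        a1 = [mk_anchor(i, i) for i in range(1, 5)]
        a2 = [Anchor("a1", f"z{i}", "c1", "c3", 1 + i, i, 10.0) for i in range(1, 5)]
        blocks = chain_anchors(a1) + chain_anchors(a2)
        distinct, multiplicity = genes_in_blocks(blocks, {"a1"}, side="a")
        assert (distinct, multiplicity) == (1, 2)

    def test_noiseless_pair_distinct_equals_family_with_retained_ortholog(self):
        pair = simulate_genome_pair(n_chromosomes=2, genes_per_chromosome=60,
                                    family_fraction=0.15, wgd_retention_a=1.0,
                                    n_tandem_b=0, seed=7)
        hom = emit_homology_hits(pair, spurious_rate=0.0, seed=8)
        blocks = chain_genome_pair(pair.genome_a, pair.genome_b, hom)
        members = pair.true_family_members["a"]
        with_ortholog = {a for a, _ in pair.true_orthologs if a in members}
        distinct, _ = genes_in_blocks(blocks, members, side="a")
        assert distinct == len(with_ortholog)
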