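import numpy as np
import pytest
from scipy import stats

from famarch import (
    ValidationError,
    apply_tandem_duplications,
    apply_wgd,
    call_family_members,
    detect_tandem_arrays,
    emit_domain_hits,
    emit_homology_hits,
    simulate_ancestor,
    simulate_expression,
    simulate_genome_pair,
)
from famarch.family_calls import domain_coverage
from famarch.synthetic_data import CLAN_DOMAINS


class TestSimulateAncestor:
    def test_zero_family_fraction(self):
        ann = simulate_ancestor(1, 10, 0.0, seed=1)
        assert len(ann) == 10 and len(ann.family_genes) == 0

    def test_family_count_is_floor_of_fraction(self):
        ann = simulate_ancestor(2, 100, 0.1, seed=7)
        assert len(ann) == 200 and len(ann.family_genes) == 20

    def test_deterministic_under_seed(self):
        assert simulate_ancestor(3, 50, 0.5, seed=3) == simulate_ancestor(3, 50, 0.5, seed=3)

    def test_coordinates_sorted_and_non_overlapping(self):
        ann = simulate_ancestor(2, 50, 0.2, seed=5)
        for chrom in ann.chromosomes:
            sub = ann.genes_on(chrom)
            assert (sub["start"].to_numpy()[1:] > sub["end"].to_numpy()[:-1]).all()
            assert list(sub["rank"]) == list(range(1, len(sub) + 1))

    @pytest.mark.parametrize("frac", [-0.1, 1.5, float("nan"), float("inf")])
    def test_bad_family_fraction_rejected(self, frac):
        with pytest.raises(ValidationError):
            simulate_ancestor(1, 10, frac, seed=0)


class TestApplyWGD:
    def test_full_retention_doubles_genome(self):
        ann = simulate_ancestor(1, 10, 0.2, seed=2)
        post, pairs = apply_wgd(ann, 1.0, seed=3)
        assert len(post) == 20 and len(pairs) == 10

    def test_full_loss_is_identity_on_gene_count(self):
        ann = simulate_ancestor(1, 10, 0.2, seed=2)
        post, pairs = apply_wgd(ann, 0.0, seed=3)
        assert len(post) == 10 and pairs == frozenset()

    def test_retained_count_within_binomial_bounds(self):
        # 99.9% central interval of Binomial(1000, 0.5)
        ann = simulate_ancestor(2, 500, 0.0, seed=4)
        _, pairs = apply_wgd(ann, 0.5, seed=5)
        lo, hi = stats.binom.ppf([0.0005, 0.9995], 1000, 0.5)
        assert lo <= len(pairs) <= hi

    def test_family_label_inherited_by_copies(self):
        ann = simulate_ancestor(1, 20, 0.5, seed=6)
        post, pairs = apply_wgd(ann, 1.0, seed=7)
        for orig, dup in pairs:
            assert (orig in post.family_genes) == (dup in post.family_genes)


class TestApplyTandem:
    def test_zero_events_is_noop(self):
        ann = simulate_ancestor(1, 30, 0.3, seed=8)
        post, arrays = apply_tandem_duplications(ann, 0, seed=9)
        assert post == ann and arrays == []

    def test_array_genes_have_consecutive_ranks(self):
        ann = simulate_ancestor(1, 30, 0.3, seed=8)
        post, arrays = apply_tandem_duplications(
            ann, 1, array_size_sampler=lambda rng: 3, seed=9
        )
        (arr,) = arrays
        ranks = sorted(post.rank_of(g) for g in arr)
        assert len(arr) == 3 and ranks == list(range(ranks[0], ranks[0] + 3))

    def test_too_many_events_rejected(self):
        ann = simulate_ancestor(1, 30, 0.1, seed=8)  # 3 family genes
        with pytest.raises(ValidationError):
            apply_tandem_duplications(ann, 10, seed=9)

    def test_round_trip_recovery_of_ground_truth_arrays(self):
        ann = simulate_ancestor(2, 250, 0.2, seed=10)
        post, arrays = apply_tandem_duplications(ann, 20, seed=11)
        # homology edges only within true arrays; no spurious hits
        import pandas as pd

        from famarch.io_formats import BLAST_COLUMNS
        rows = []
        for arr in arrays:
            for i, g1 in enumerate(arr):
                for g2 in arr[i + 1:]:
                    rows.append((g1, g2, 95.0, 200, 10, 0, 1, 200, 1, 200, 1e-40, 300.0))
        homology = pd.DataFrame(rows, columns=BLAST_COLUMNS)
        detected = detect_tandem_arrays(post, post.family_genes, homology, max_intervening=0)
        assert sorted(map(sorted, (a.genes for a in detected))) == sorted(map(sorted, arrays))


class TestEmitDomainHits:
    def test_noiseless_round_trip(self):
        ann = simulate_ancestor(2, 100, 0.1, seed=12)
        hits = emit_domain_hits(ann, true_positive_rate=1.0, decoy_rate=0.0, seed=13)
        calls = call_family_members(hits, set(CLAN_DOMAINS))
        assert calls.members == ann.family_genes

    def test_decoys_fail_exactly_one_criterion(self):
        ann = simulate_ancestor(2, 200, 0.1, seed=14)
        hits = emit_domain_hits(ann, true_positive_rate=1.0, decoy_rate=1.0, seed=15)
        decoys = [h for h in hits if h.gene_id not in ann.family_genes]
        assert decoys
        for h in decoys:
            fails_e = h.e_value > 1.0
            fails_cov = domain_coverage(h) < 0.5
            assert fails_e != fails_cov  # exactly one branch
        branches = {(h.e_value > 1.0) for h in decoys}
        assert branches == {True, False}  # both filter branches exercised

    def test_deterministic_under_seed(self):
        ann = simulate_ancestor(1, 50, 0.2, seed=16)
        assert emit_domain_hits(ann, 0.8, 0.3, seed=17) == emit_domain_hits(ann, 0.8, 0.3, seed=17)


class TestEmitHomologyHits:
    def test_noiseless_table_contains_exactly_true_pairs(self):
        pair = simulate_genome_pair(n_chromosomes=2, genes_per_chromosome=40,
                                    family_fraction=0.1, wgd_retention_a=0.5,
                                    n_tandem_b=3, seed=18)
        table = emit_homology_hits(pair, spurious_rate=0.0, seed=19)
        assert (table["e_value"] <= 0.01).all()
        got = {tuple(sorted(p)) for p in zip(table["query_id"], table["subject_id"])}
        expected = {tuple(sorted(p)) for p in pair.true_orthologs}
        expected |= {tuple(sorted(p)) for p in pair.true_segmental_pairs["a"]}
        for arr in pair.true_tandem_arrays["b"]:
            for i, g1 in enumerate(arr):
                for g2 in arr[i + 1:]:
                    expected.add(tuple(sorted((g1, g2))))
        assert got == expected

    def test_reciprocal_rows_for_true_pairs(self):
        pair = simulate_genome_pair(n_chromosomes=1, genes_per_chromosome=20,
                                    family_fraction=0.2, wgd_retention_a=1.0,
                                    n_tandem_b=1, seed=20)
        table = emit_homology_hits(pair, spurious_rate=0.0, seed=21)
        pairs = set(zip(table["query_id"], table["subject_id"]))
        assert all((s, q) in pairs for q, s in pairs)

    def test_deterministic_under_seed(self, small_pair):
        t1 = emit_homology_hits(small_pair, spurious_rate=0.2, seed=22)
        t2 = emit_homology_hits(small_pair, spurious_rate=0.2, seed=22)
        assert t1.equals(t2)

    def test_spurious_evalues_straddle_threshold(self, small_pair):
        table = emit_homology_hits(small_pair, spurious_rate=0.5, seed=23)
        assert (table["e_value"] > 0.01).any() and (table["e_value"] <= 0.01).any()


class TestSimulateExpression:
    def test_noiseless_argmax_equals_planted_tissue(self):
        genes = [f"g{i}" for i in range(30)]
        tissues = ["root", "leaf", "nodule"]
        clusters = {g: i % 3 for i, g in enumerate(genes)}
        m = simulate_expression(genes, tissues, clusters, effect_size=5.0,
                                noise_sd=0.0, baseline=2.0, seed=24)
        prefs = {g: tissues[int(np.argmax(m.row(g)))] for g in genes}
        for g in genes:
            assert prefs[g] == tissues[clusters[g] % 3]

    def test_values_floored_at_zero(self):
        m = simulate_expression(["g1", "g2"], ["t1", "t2"], {}, effect_size=0.0,
                                noise_sd=10.0, baseline=0.5, seed=25)
        assert (m.values >= 0).all()

    def test_unknown_tissue_in_cluster_map_rejected(self):
        with pytest.raises(ValidationError):
            simulate_expression(["g1"], ["t1"], {"g1": "c"}, 1.0, 0.1, 1.0, seed=26,
                                cluster_tissues={"c": "no_such_tissue"})


class TestSimulatedGenomePair:
    def test_ground_truth_ids_exist_in_annotations(self, small_pair):
        for ga, gb in small_pair.true_orthologs:
            assert ga in small_pair.genome_a and gb in small_pair.genome_b
        for arr in small_pair.true_tandem_arrays["b"]:
            assert len(arr) >= 2
            chroms = {small_pair.genome_b.chrom_of(g) for g in arr}
            assert len(chroms) == 1

    def test_orthologs_consistent_with_wgd_event(self, small_pair):
        # every retained WGD copy is co-orthologous to its original's partner
        b_of = {}
        for ga, gb in small_pair.true_orthologs:
            b_of.setdefault(ga, set()).add(gb)
        for orig, dup in small_pair.true_segmental_pairs["a"]:
            assert b_of.get(orig) == b_of.get(dup)

    def test_truth_sidecar_json(self, small_pair, tmp_path):
        import json

        path = tmp_path / "truth.json"
        small_pair.truth_to_json(str(path))
        payload = json.loads(path.read_text())
        assert set(payload) == {
            "true_orthologs", "true_tandem_arrays", "true_segmental_pairs",
            "true_family_members", "event_log",
        }
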