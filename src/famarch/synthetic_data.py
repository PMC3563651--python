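"""Simulated genomes with known duplication histories and evidence tables.

Every downstream stage of the pipeline (family calling, chaining, tandem and
segmental duplication detection, enrichment, expression clustering) is
validated against ground truth produced here.  The generator builds an
ancestral multi-chromosome gene order carrying a labeled gene family, then
applies duplication events:

* whole-genome duplication (WGD): every chromosome duplicated at once,
  followed by independent per-gene loss at ``1 - retention_rate``
  (fractionation without bias — enough to produce the segmental-duplication
  signal the detectors consume);
* tandem duplication: a source gene gains adjacent downstream copies,
  shifting coordinates and ranks.

Evidence tables are emitted with controllable noise: domain-hit tables with
decoys built to fail *exactly one* of the two family-filter criteria (so both
filter branches are exercised), and homology tables with spurious hits whose
e-values straddle the filter threshold.  Expression matrices carry planted
cluster structure (a tissue-specific effect on top of baseline plus Gaussian
noise, floored at zero).

No sequences are simulated — the analysis operates on gene orders and
tabular evidence only.  All generators are deterministic under a fixed seed
and take the seed as an explicit argument; there is no global random state.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ValidationError
from .io_formats import BLAST_COLUMNS, GenomeAnnotation

__all__ = [
    "SimulatedGenomePair",
    "simulate_ancestor",
    "apply_wgd",
    "apply_tandem_duplications",
    "emit_domain_hits",
    "emit_homology_hits",
    "simulate_expression",
    "simulate_genome_pair",
    "CLAN_DOMAINS",
]

#: The three Pfam F-box clan domain names used for simulated hit tables.
CLAN_DOMAINS = ("F-box", "F-box-like", "F-box-like_2")

#: Gene geometry defaults (bp); nothing downstream depends on base-pair scale,
#: only on rank order, so simple uniform draws suffice.
GENE_LENGTH_RANGE = (500, 5000)
INTERGENIC_GAP_RANGE = (200, 2000)
DOMAIN_MODEL_LENGTH = 48  # typical F-box domain model length


@dataclass
class SimulatedGenomePair:
    """Two genomes descended from one ancestor, with full ground truth.

    ``true_orthologs`` holds cross-genome gene-id pairs (including WGD
    co-orthologs); ``true_segmental_pairs`` and ``true_tandem_arrays`` are
    per-genome (keys ``"a"``/``"b"``); ``event_log`` records the simulated
    history as ``(event_kind, params)`` tuples.
    """

    genome_a: GenomeAnnotation
    genome_b: GenomeAnnotation
    true_orthologs: frozenset[tuple[str, str]]
    true_tandem_arrays: dict[str, list[list[str]]]
    true_segmental_pairs: dict[str, frozenset[tuple[str, str]]]
    true_family_members: dict[str, frozenset[str]]
    event_log: list[tuple[str, dict]] = field(default_factory=list)

    def __post_init__(self):
        genomes = {"a": self.genome_a, "b": self.genome_b}
        for ga, gb in self.true_orthologs:
            if ga not in self.genome_a or gb not in self.genome_b:
                raise ValidationError(f"ortholog pair ({ga}, {gb}) not in annotations")
        for side, genome in genomes.items():
            for arr in self.true_tandem_arrays.get(side, []):
                if len(set(arr)) < 2:
                    raise ValidationError("tandem array ground truth needs >= 2 genes")
                chroms = {genome.chrom_of(g) for g in arr}
                if len(chroms) != 1:
                    raise ValidationError("tandem array spans multiple chromosomes")
            for g1, g2 in self.true_segmental_pairs.get(side, frozenset()):
                if g1 not in genome or g2 not in genome:
                    raise ValidationError(f"segmental pair ({g1}, {g2}) not in genome {side}")
            unknown = self.true_family_members.get(side, frozenset()) - genome.gene_ids
            if unknown:
                raise ValidationError(f"family members absent from genome {side}: {sorted(unknown)[:5]}")

    def truth_to_json(self, path: str) -> None:
        """Write the ground-truth sidecar as JSON."""
        payload = {
            "true_orthologs": sorted(map(list, self.true_orthologs)),
            "true_tandem_arrays": {k: v for k, v in self.true_tandem_arrays.items()},
            "true_segmental_pairs": {
                k: sorted(map(list, v)) for k, v in self.true_segmental_pairs.items()
            },
            "true_family_members": {
                k: sorted(v) for k, v in self.true_family_members.items()
            },
            "event_log": [[kind, params] for kind, params in self.event_log],
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1, sort_keys=True)


def _layout_chromosome(n_genes: int, rng: np.random.Generator):
    """Non-overlapping 1-based coordinates: alternating gene/gap lengths."""
    lengths = rng.integers(GENE_LENGTH_RANGE[0], GENE_LENGTH_RANGE[1] + 1, size=n_genes)
    gaps = rng.integers(INTERGENIC_GAP_RANGE[0], INTERGENIC_GAP_RANGE[1] + 1, size=n_genes)
    coords = []
    pos = 1
    for length, gap in zip(lengths, gaps):
        coords.append((pos, pos + int(length) - 1))
        pos += int(length) + int(gap)
    return coords


def simulate_ancestor(
    n_chromosomes: int,
    genes_per_chromosome: int,
    family_fraction: float,
    seed: int,
) -> GenomeAnnotation:
    """Ancestral genome: uniform gene geometry, random strands, family labels.

    Exactly ``floor(family_fraction * total_genes)`` genes carry the family
    label, drawn uniformly over all positions.
    """
    if n_chromosomes < 1 or genes_per_chromosome < 1:
        raise ValidationError("need >= 1 chromosome and >= 1 gene per chromosome")
    if not (isinstance(family_fraction, (int, float)) and math.isfinite(family_fraction)):
        raise ValidationError(f"family_fraction must be finite, got {family_fraction!r}")
    if not (0.0 <= family_fraction <= 1.0):
        raise ValidationError(f"family_fraction must be in [0, 1], got {family_fraction}")
    rng = np.random.default_rng(seed)
    rows = []
    ids = []
    for c in range(1, n_chromosomes + 1):
        chrom = f"chr{c}"
        coords = _layout_chromosome(genes_per_chromosome, rng)
        for i, (start, end) in enumerate(coords, start=1):
            gid = f"g{c:02d}_{i:04d}"
            strand = "+" if rng.random() < 0.5 else "-"
            rows.append((gid, chrom, start, end, strand))
            ids.append(gid)
    n_family = int(family_fraction * len(ids))
    family = rng.choice(np.array(ids), size=n_family, replace=False) if n_family else []
    return GenomeAnnotation(rows, family_genes=set(map(str, family)))


def apply_wgd(
    genome: GenomeAnnotation, retention_rate: float, seed: int
) -> tuple[GenomeAnnotation, frozenset[tuple[str, str]]]:
    """Duplicate every chromosome, then lose each duplicated gene independently.

    Duplicated chromosomes are named ``<chrom>_d`` and duplicated genes
    ``<gene>_d``; each copy survives with probability ``retention_rate``.
    Returns the post-WGD annotation and the surviving (original, copy)
    paralog pairs.  Family labels are inherited by surviving copies.
    """
    if not (0.0 <= retention_rate <= 1.0):
        raise ValidationError(f"retention_rate must be in [0, 1], got {retention_rate}")
    rng = np.random.default_rng(seed)
    rows = [tuple(r) for r in genome.genes[["gene_id", "chrom", "start", "end", "strand"]].itertuples(index=False)]
    family = set(genome.family_genes)
    pairs = set()
    new_rows = list(rows)
    for gid, chrom, start, end, strand in rows:
        if rng.random() < retention_rate:
            dup = f"{gid}_d"
            new_rows.append((dup, f"{chrom}_d", start, end, strand))
            pairs.add((gid, dup))
            if gid in family:
                family.add(dup)
    return GenomeAnnotation(new_rows, family_genes=family), frozenset(pairs)


def apply_tandem_duplications(
    genome: GenomeAnnotation,
    n_events: int,
    array_size_sampler: Callable[[np.random.Generator], int] | None = None,
    family_only: bool = True,
    seed: int = 0,
    min_source_spacing: int = 2,
) -> tuple[GenomeAnnotation, list[list[str]]]:
    """Insert tandem arrays: adjacent downstream copies of sampled source genes.

    Each event picks a distinct source gene (restricted to family genes when
    ``family_only``), draws an array size ``k >= 2`` from
    ``array_size_sampler`` (default: uniform over {2, 3, 4}), and inserts
    ``k - 1`` copies immediately downstream of the source, shifting the
    coordinates and ranks of everything downstream.  Copies inherit the
    family label.  Sources are kept at least ``min_source_spacing`` ranks
    apart so distinct events never coalesce into one physical run.

    Returns the expanded annotation and the ground-truth arrays (source gene
    first, copies in insertion order).
    """
    if n_events < 0:
        raise ValidationError("n_events must be >= 0")
    if n_events == 0:
        return genome, []
    sampler = array_size_sampler or (lambda rng: int(rng.integers(2, 5)))
    rng = np.random.default_rng(seed)

    df = genome.genes
    candidates = df[df["gene_id"].isin(genome.family_genes)] if family_only else df
    # sample spaced sources: greedy rejection in random order
    cand = list(candidates[["gene_id", "chrom", "rank"]].itertuples(index=False))
    rng.shuffle(cand)
    chosen: list = []
    taken: dict[str, list[int]] = {}
    for row in cand:
        ranks = taken.setdefault(row.chrom, [])
        if all(abs(row.rank - r) > min_source_spacing for r in ranks):
            chosen.append(row)
            ranks.append(row.rank)
            if len(chosen) == n_events:
                break
    if len(chosen) < n_events:
        raise ValidationError(
            f"cannot place {n_events} spaced tandem events: only {len(chosen)} "
            f"eligible source genes"
        )
    sizes = {row.gene_id: sampler(rng) for row in chosen}
    for gid, k in sizes.items():
        if k < 2:
            raise ValidationError(f"array_size_sampler returned {k} < 2")

    family = set(genome.family_genes)
    arrays: list[list[str]] = []
    new_rows = []
    for chrom in genome.chromosomes:
        offset = 0
        for row in genome.genes_on(chrom).itertuples(index=False):
            length = row.end - row.start + 1
            new_rows.append((row.gene_id, chrom, row.start + offset, row.end + offset, row.strand))
            if row.gene_id in sizes:
                k = sizes[row.gene_id]
                arr = [row.gene_id]
                copy_start = row.end + offset + 1 + 100
                for j in range(1, k):
                    cid = f"{row.gene_id}_t{j}"
                    new_rows.append((cid, chrom, copy_start, copy_start + length - 1, row.strand))
                    arr.append(cid)
                    if row.gene_id in family:
                        family.add(cid)
                    copy_start += length + 100
                offset += (k - 1) * (length + 100)
                arrays.append(arr)
    # keep arrays in a stable, rank-sorted order
    out = GenomeAnnotation(new_rows, family_genes=family)
    arrays.sort(key=lambda a: (out.chrom_of(a[0]), out.rank_of(a[0])))
    return out, arrays


# ---------------------------------------------------------------------------
# Evidence tables


def emit_domain_hits(
    genome: GenomeAnnotation,
    true_positive_rate: float = 1.0,
    decoy_rate: float = 0.0,
    model_length: int = DOMAIN_MODEL_LENGTH,
    seed: int = 0,
):
    """Domain-hit rows for family genes, plus filter-straddling decoys.

    Family genes receive a hit passing the family filter (e-value <= 1.0 and
    model coverage >= 0.5) with probability ``true_positive_rate``.
    Non-family genes receive, with probability ``decoy_rate``, a decoy hit to
    a clan domain that fails *exactly one* of the two criteria — half the
    decoys carry a passing e-value with sub-threshold coverage, half a
    super-threshold e-value with passing coverage — so both branches of the
    filter are exercised.  Returns a list of DomainHit.
    """
    from .family_calls import DomainHit

    for name, rate in (("true_positive_rate", true_positive_rate), ("decoy_rate", decoy_rate)):
        if not (0.0 <= rate <= 1.0):
            raise ValidationError(f"{name} must be in [0, 1], got {rate}")
    rng = np.random.default_rng(seed)
    hits: list[DomainHit] = []
    family = genome.family_genes
    for gid in sorted(genome.gene_ids):
        if gid in family:
            if rng.random() >= true_positive_rate:
                continue
            dom = CLAN_DOMAINS[int(rng.integers(len(CLAN_DOMAINS)))]
            e_value = 10.0 ** rng.uniform(-30, -0.5)  # <= ~0.32, always passing
            coverage = rng.uniform(0.5, 1.0)
            span = max(int(math.ceil(coverage * model_length)), (model_length + 1) // 2)
            span = min(span, model_length)
            hmm_from = 1 + int(rng.integers(0, model_length - span + 1))
            hits.append(DomainHit(gid, dom, e_value, hmm_from, hmm_from + span - 1, model_length))
        else:
            if rng.random() >= decoy_rate:
                continue
            dom = CLAN_DOMAINS[int(rng.integers(len(CLAN_DOMAINS)))]
            if rng.random() < 0.5:
                # fails coverage only: passing e-value, span strictly below half
                e_value = 10.0 ** rng.uniform(-5, -0.5)
                span = int(rng.integers(1, (model_length + 1) // 2))  # < 0.5 coverage
            else:
                # fails e-value only: coverage fine, e-value above 1.0
                e_value = 10.0 ** rng.uniform(0.05, 2.0)
                span = int(rng.integers((model_length + 1) // 2 + 1, model_length + 1))
            hmm_from = 1 + int(rng.integers(0, model_length - span + 1))
            hits.append(DomainHit(gid, dom, e_value, hmm_from, hmm_from + span - 1, model_length))
    return hits


def _hit_rows(pairs, rng, evalue_low_exp, evalue_high_exp):
    """Reciprocal BLAST-style rows for gene pairs with log-uniform e-values."""
    rows = []
    for g1, g2 in pairs:
        ev = 10.0 ** rng.uniform(evalue_low_exp, evalue_high_exp)
        ident = rng.uniform(60, 99)
        aln = int(rng.integers(150, 500))
        bit = max(30.0, -10.0 * math.log10(max(ev, 1e-180)))
        for q, s in ((g1, g2), (g2, g1)):
            rows.append((q, s, round(ident, 2), aln, int(aln * (1 - ident / 100)), 0,
                         1, aln, 1, aln, ev, round(bit, 1)))
    return rows


def emit_homology_hits(
    pair: SimulatedGenomePair,
    spurious_rate: float = 0.0,
    seed: int = 0,
) -> pd.DataFrame:
    """All-vs-all homology table for a simulated genome pair.

    Every true relationship — cross-genome orthologs, within-genome segmental
    (WGD) paralogs, and within-array tandem paralogs — yields a reciprocal
    hit with e-value sampled below the 0.01 anchor filter.  Spurious hits
    between uniform random gene pairs are added at ``spurious_rate`` (per
    true pair), with e-values straddling 0.01 so the filter is exercised in
    both directions.
    """
    if not (0.0 <= spurious_rate <= 1.0):
        raise ValidationError(f"spurious_rate must be in [0, 1], got {spurious_rate}")
    rng = np.random.default_rng(seed)
    true_pairs: list[tuple[str, str]] = sorted(pair.true_orthologs)
    for side in ("a", "b"):
        true_pairs.extend(sorted(pair.true_segmental_pairs.get(side, frozenset())))
        for arr in pair.true_tandem_arrays.get(side, []):
            for i, g1 in enumerate(arr):
                for g2 in arr[i + 1:]:
                    true_pairs.append((g1, g2))
    rows = _hit_rows(true_pairs, rng, -50, -5)

    n_spurious = int(round(spurious_rate * len(true_pairs)))
    if n_spurious:
        all_ids = sorted(pair.genome_a.gene_ids | pair.genome_b.gene_ids)
        ids = np.array(all_ids)
        spurious = []
        while len(spurious) < n_spurious:
            g1, g2 = rng.choice(ids, size=2, replace=False)
            spurious.append((str(g1), str(g2)))
        # e-values straddle the 0.01 threshold: log-uniform over [1e-4, 1e2]
        rows.extend(_hit_rows(spurious, rng, -4, 2))
    return pd.DataFrame(rows, columns=BLAST_COLUMNS)


# ---------------------------------------------------------------------------
# Expression


def simulate_expression(
    genes: Sequence[str],
    tissues: Sequence[str],
    cluster_assignments: Mapping[str, object],
    effect_size: float,
    noise_sd: float,
    baseline: float,
    seed: int,
    cluster_tissues: Mapping[object, str] | None = None,
):
    """Expression with planted tissue-specific cluster structure.

    Each gene's value in tissue t is
    ``baseline + effect_size * 1[t is the gene's cluster's preferred tissue]
    + Normal(0, noise_sd)``, floored at 0.  ``cluster_tissues`` maps each
    cluster to its preferred tissue; by default clusters are assigned tissues
    round-robin in sorted cluster order.  Genes without a cluster get
    baseline plus noise everywhere.
    """
    from .expression import ExpressionMatrix

    if effect_size < 0 or noise_sd < 0 or baseline < 0:
        raise ValidationError("effect_size, noise_sd and baseline must be >= 0")
    tissues = list(tissues)
    clusters = sorted({str(c) for c in cluster_assignments.values()})
    if cluster_tissues is None:
        cluster_tissues = {c: tissues[i % len(tissues)] for i, c in enumerate(clusters)}
    else:
        cluster_tissues = {str(k): v for k, v in cluster_tissues.items()}
    unknown = set(cluster_tissues.values()) - set(tissues)
    if unknown:
        raise ValidationError(f"unknown tissues in cluster map: {sorted(unknown)}")

    rng = np.random.default_rng(seed)
    values = np.full((len(genes), len(tissues)), float(baseline))
    tissue_index = {t: j for j, t in enumerate(tissues)}
    for i, g in enumerate(genes):
        c = cluster_assignments.get(g)
        if c is not None:
            values[i, tissue_index[cluster_tissues[str(c)]]] += effect_size
    values += rng.normal(0.0, noise_sd, size=values.shape) if noise_sd > 0 else 0.0
    values = np.maximum(values, 0.0)
    return ExpressionMatrix(
        gene_ids=list(genes), tissue_names=tissues, values=values, standardized=False
    )


# ---------------------------------------------------------------------------
# Convenience: a full two-genome study


def simulate_genome_pair(
    n_chromosomes: int = 4,
    genes_per_chromosome: int = 250,
    family_fraction: float = 0.03,
    wgd_retention_a: float = 0.6,
    n_tandem_b: int = 20,
    array_size_sampler: Callable[[np.random.Generator], int] | None = None,
    seed: int = 0,
) -> SimulatedGenomePair:
    """One ancestor, speciation, WGD in genome A, tandem expansion in genome B.

    This emulates the contrast the analysis is built to detect: a genome
    whose family grew through segmental (whole-genome) duplication versus a
    sister genome dominated by local tandem duplication.  Gene ids are
    prefixed ``A_``/``B_``; WGD co-orthologs (``x_d`` copies in A) are
    included in ``true_orthologs``; tandem copies in B are recent paralogs
    and are *not* orthologous to anything in A.
    """
    rng = np.random.default_rng(seed)
    s_anc, s_wgd, s_tnd = (int(x) for x in rng.integers(0, 2**31 - 1, size=3))
    ancestor = simulate_ancestor(n_chromosomes, genes_per_chromosome, family_fraction, s_anc)

    def relabel(genome: GenomeAnnotation, prefix: str) -> GenomeAnnotation:
        rows = [
            (f"{prefix}{r.gene_id}", r.chrom, r.start, r.end, r.strand)
            for r in genome.genes.itertuples(index=False)
        ]
        return GenomeAnnotation(rows, family_genes={f"{prefix}{g}" for g in genome.family_genes})

    genome_a = relabel(ancestor, "A_")
    genome_b = relabel(ancestor, "B_")
    base_orthologs = {(f"A_{g}", f"B_{g}") for g in ancestor.gene_ids}
    event_log: list[tuple[str, dict]] = [
        ("speciation", {"n_genes": len(ancestor)}),
    ]

    genome_a, wgd_pairs = apply_wgd(genome_a, wgd_retention_a, s_wgd)
    event_log.append(("wgd", {"genome": "a", "retention_rate": wgd_retention_a,
                              "n_retained": len(wgd_pairs)}))
    # a WGD copy A_x_d is co-orthologous to the same B gene as A_x
    ortho = set(base_orthologs)
    b_of = {a: b for a, b in base_orthologs}
    for orig, dup in wgd_pairs:
        if orig in b_of:
            ortho.add((dup, b_of[orig]))

    genome_b, arrays_b = apply_tandem_duplications(
        genome_b, n_tandem_b, array_size_sampler=array_size_sampler, seed=s_tnd
    )
    event_log.append(("tandem", {"genome": "b", "n_events": n_tandem_b}))

    return SimulatedGenomePair(
        genome_a=genome_a,
        genome_b=genome_b,
        true_orthologs=frozenset(ortho),
        true_tandem_arrays={"a": [], "b": arrays_b},
        true_segmental_pairs={"a": wgd_pairs, "b": frozenset()},
        true_family_members={"a": genome_a.family_genes, "b": genome_b.family_genes},
        event_log=event_log,
    )
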