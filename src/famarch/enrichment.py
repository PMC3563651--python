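"""Label-shuffling permutation nulls for family prevalence in genomic structures.

The question: are family genes over- (or under-) represented inside syntenic
blocks, or inside tandem arrays, relative to genes at random positions?  The
null keeps gene *positions* and the detected structures fixed and shuffles
the family *labels* uniformly over positions, recomputing the statistic for
each relabelled copy of the map.  Synteny blocks are therefore not re-chained
per replicate — block membership is a property of a position, and a shuffled
label landing on a position that belongs to k blocks contributes k to the
multiplicity count and 1 to the distinct count.  For the tandem null,
homology connectivity is dropped in the replicates (positional runs only),
because shuffled labels carry no homology structure.

Empirical p-values use the add-one estimator
``p = (1 + #{null >= observed}) / (n_reps + 1)`` so that p is never zero and
the test is valid (never anti-conservative) at any replicate count.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np

from .collinearity import SyntenyBlock, detect_tandem_arrays
from .errors import ValidationError
from .io_formats import GenomeAnnotation

__all__ = [
    "PermutationResult",
    "shuffle_labels",
    "synteny_permutation_test",
    "tandem_permutation_test",
]


@dataclass
class PermutationResult:
    """Observed statistic, its permutation null, and empirical p-values."""

    observed: int
    null_counts: np.ndarray
    null_mean: float
    null_sd: float
    p_greater: float
    p_less: float
    n_reps: int
    seed: int

    def to_dict(self, include_null: bool = False) -> dict:
        d = {
            "observed": int(self.observed),
            "null_mean": float(self.null_mean),
            "null_sd": float(self.null_sd),
            "p_greater": float(self.p_greater),
            "p_less": float(self.p_less),
            "n_reps": int(self.n_reps),
            "seed": int(self.seed),
        }
        if include_null:
            d["null_counts"] = [int(x) for x in self.null_counts]
        return d


def shuffle_labels(
    annotation: GenomeAnnotation, n_labels: int, rng: np.random.Generator
) -> frozenset[str]:
    """Draw ``n_labels`` gene ids uniformly without replacement."""
    ids = annotation.genes["gene_id"].to_numpy()
    if n_labels > len(ids):
        raise ValidationError(f"n_labels={n_labels} exceeds {len(ids)} genes")
    if n_labels < 0:
        raise ValidationError("n_labels must be >= 0")
    return frozenset(rng.choice(ids, size=n_labels, replace=False))


def _finalize(observed, null, n_reps, seed):
    null = np.asarray(null)
    p_greater = (1 + int((null >= observed).sum())) / (n_reps + 1)
    p_less = (1 + int((null <= observed).sum())) / (n_reps + 1)
    return PermutationResult(
        observed=int(observed),
        null_counts=null,
        null_mean=float(null.mean()),
        null_sd=float(null.std()),
        p_greater=p_greater,
        p_less=p_less,
        n_reps=n_reps,
        seed=seed,
    )


def synteny_permutation_test(
    annotation: GenomeAnnotation,
    members: set[str] | frozenset[str],
    blocks: Sequence[SyntenyBlock],
    side: Literal["a", "b"] = "a",
    n_reps: int = 10_000,
    counting: Literal["distinct", "multiplicity"] = "distinct",
    seed: int = 0,
) -> PermutationResult:
    """Permutation test for family prevalence inside syntenic blocks.

    The statistic is the number of member genes located in blocks on the
    chosen genome side — distinct genes by default, or (gene, block)
    incidences with ``counting="multiplicity"``, which distributes a label
    over one-to-many duplication relationships.  Each of ``n_reps``
    replicates redraws ``len(members)`` labels uniformly over all gene
    positions and recomputes the statistic on the fixed block map.
    """
    if n_reps < 1:
        raise ValidationError("n_reps must be >= 1")
    if len(members) < 1:
        raise ValidationError("need at least one member gene")
    if counting not in ("distinct", "multiplicity"):
        raise ValidationError(f"unknown counting mode {counting!r}")
    unknown = set(members) - set(annotation.gene_ids)
    if unknown:
        raise ValidationError(f"members absent from annotation: {sorted(unknown)[:5]}")

    ids = annotation.genes["gene_id"].to_numpy()
    index = {g: i for i, g in enumerate(ids)}
    # per-position block incidence (one per block even if a gene anchors twice)
    incidence = np.zeros(len(ids), dtype=np.int64)
    for block in blocks:
        genes_in_block = {
            (a.gene_a if side == "a" else a.gene_b) for a in block.anchors
        }
        for g in genes_in_block:
            if g in index:
                incidence[index[g]] += 1

    def stat(idx: np.ndarray) -> int:
        vals = incidence[idx]
        return int(np.count_nonzero(vals)) if counting == "distinct" else int(vals.sum())

    member_idx = np.array([index[g] for g in members])
    observed = stat(member_idx)

    rng = np.random.default_rng(seed)
    m, n = len(members), len(ids)
    null = np.empty(n_reps, dtype=np.int64)
    for r in range(n_reps):
        null[r] = stat(rng.choice(n, size=m, replace=False))
    return _finalize(observed, null, n_reps, seed)


def tandem_permutation_test(
    annotation: GenomeAnnotation,
    members: set[str] | frozenset[str],
    n_reps: int = 10_000,
    seed: int = 0,
    homology=None,
    max_intervening: int = 5,
    max_evalue: float = 0.01,
) -> PermutationResult:
    """Permutation test for family prevalence inside tandem arrays.

    The observed statistic counts member genes inside tandem arrays detected
    for the member set (with homology connectivity when a table is given).
    Null replicates shuffle the member label over all gene positions and
    re-detect *positional* runs with the same ``max_intervening`` — a
    deliberate approximation, since random labels have no homology graph.
    """
    if n_reps < 1:
        raise ValidationError("n_reps must be >= 1")
    if len(members) < 1:
        raise ValidationError("need at least one member gene")
    observed_arrays = detect_tandem_arrays(
        annotation, set(members), homology,
        max_intervening=max_intervening, max_evalue=max_evalue,
    )
    observed = sum(len(a.genes) for a in observed_arrays)

    # per-position chromosome codes and ranks for fast positional-run counting
    df = annotation.genes
    rank_of = df["rank"].to_numpy()
    _, chrom_idx = np.unique(df["chrom"].to_numpy(), return_inverse=True)

    rng = np.random.default_rng(seed)
    m, n = len(members), len(df)
    null = np.empty(n_reps, dtype=np.int64)
    for r in range(n_reps):
        idx = rng.choice(n, size=m, replace=False)
        null[r] = _count_in_runs(chrom_idx[idx], rank_of[idx], max_intervening)
    return _finalize(observed, null, n_reps, seed)


def _count_in_runs(chrom_idx: np.ndarray, ranks: np.ndarray, max_intervening: int) -> int:
    """Members lying in positional runs of >= 2 (gap rule per chromosome)."""
    order = np.lexsort((ranks, chrom_idx))
    c, rk = chrom_idx[order], ranks[order]
    if len(c) < 2:
        return 0
    same_chrom = c[1:] == c[:-1]
    linked = same_chrom & (np.diff(rk) - 1 <= max_intervening)
    # a member is in a run iff linked to predecessor or successor
    in_run = np.zeros(len(c), dtype=bool)
    in_run[1:] |= linked
    in_run[:-1] |= linked
    return int(in_run.sum())
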