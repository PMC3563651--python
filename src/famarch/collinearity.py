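"""Synteny blocks, tandem arrays and segmental duplications from homology anchors.

An *anchor* is a filtered all-vs-all protein hit placed in gene-rank space:
the pair ``(rank_a, rank_b)`` of the two genes' 1-based positions along their
chromosomes.  Collinear (syntenic) blocks are maximal-scoring chains of
anchors found by longest-path dynamic programming, in the style of
DAGchainer: anchors must increase strictly in ``rank_a`` and either increase
(same orientation) or decrease (inverted) strictly in ``rank_b``; each link
may skip at most ``max_gap`` ranks on each axis and pays a linear gap
penalty per skipped rank.  Working in rank space rather than base pairs
makes gap penalties independent of genome size and intergenic geometry.

Tandem arrays are runs of family genes at near-adjacent ranks on one
chromosome, connected by homology (single linkage within the run).
Segmental duplications are within-genome collinear blocks after excluding
local (tandem-range) anchors.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd

from .errors import ValidationError
from .io_formats import GenomeAnnotation

__all__ = [
    "Anchor",
    "SyntenyBlock",
    "TandemArray",
    "SegmentalDuplication",
    "anchor_score",
    "chain_anchors",
    "chain_genome_pair",
    "anchors_from_homology",
    "detect_tandem_arrays",
    "detect_segmental_duplications",
    "genes_in_blocks",
    "blocks_to_table",
]

_EVALUE_FLOOR = 1e-50
_SCORE_CAP = 50.0


@dataclass(frozen=True)
class Anchor:
    """A filtered homologous gene pair in rank space."""

    gene_a: str
    gene_b: str
    chrom_a: str
    chrom_b: str
    rank_a: int
    rank_b: int
    score: float

    def __post_init__(self):
        if not self.score > 0:
            raise ValidationError(f"anchor score must be > 0, got {self.score}")


@dataclass
class SyntenyBlock:
    """A chain of anchors collinear between two chromosomes."""

    anchors: list[Anchor]
    orientation: Literal["same", "inverted"]
    chain_score: float
    chrom_a: str
    chrom_b: str

    def __post_init__(self):
        ra = [a.rank_a for a in self.anchors]
        rb = [a.rank_b for a in self.anchors]
        if any(x >= y for x, y in zip(ra, ra[1:])):
            raise ValidationError("block rank_a not strictly increasing")
        ok_b = (
            all(x < y for x, y in zip(rb, rb[1:]))
            if self.orientation == "same"
            else all(x > y for x, y in zip(rb, rb[1:]))
        )
        if not ok_b:
            raise ValidationError(f"block rank_b not strictly {self.orientation}-monotone")

    def __len__(self) -> int:
        return len(self.anchors)

    @property
    def rank_window_a(self) -> tuple[int, int]:
        return self.anchors[0].rank_a, self.anchors[-1].rank_a

    @property
    def rank_window_b(self) -> tuple[int, int]:
        rb = [a.rank_b for a in self.anchors]
        return min(rb), max(rb)


@dataclass
class TandemArray:
    """A run of locally duplicated family genes on one chromosome."""

    chrom: str
    genes: list[str]
    span_bp: int

    def __post_init__(self):
        if len(self.genes) < 2:
            raise ValidationError("a tandem array needs >= 2 genes")


@dataclass
class SegmentalDuplication:
    """A within-genome collinear block (tandem-range anchors excluded)."""

    block: SyntenyBlock
    excludes_tandem: bool = True


def anchor_score(e_value: float) -> float:
    """DAGchainer-style anchor score: capped negative log10 of the e-value."""
    if e_value < 0:
        raise ValidationError(f"e_value must be >= 0, got {e_value}")
    return min(_SCORE_CAP, -math.log10(max(e_value, _EVALUE_FLOOR)))


def _best_chain(
    ra: np.ndarray,
    rb: np.ndarray,
    scores: np.ndarray,
    max_gap: int,
    gap_penalty: float,
    min_anchors: int,
) -> tuple[float, list[int]] | None:
    """Best-scoring chain (strictly increasing in both axes) via DP.

    Returns ``(score, indices)`` of the optimal chain whose DP traceback has
    at least ``min_anchors`` anchors, or None.  Anchors are processed in
    ``(ra, rb)`` order; a link i->j requires ``ra[j] > ra[i]``,
    ``rb[j] > rb[i]`` and at most ``max_gap`` skipped ranks per axis, and
    costs ``gap_penalty`` per skipped rank.
    """
    n = len(ra)
    order = np.lexsort((rb, ra))
    ra, rb, scores = ra[order], rb[order], scores[order]
    dp = scores.astype(float).copy()
    length = np.ones(n, dtype=int)
    prev = np.full(n, -1)
    for j in range(n):
        for i in range(j):
            da, db = ra[j] - ra[i], rb[j] - rb[i]
            if da < 1 or db < 1 or da - 1 > max_gap or db - 1 > max_gap:
                continue
            cand = dp[i] + scores[j] - gap_penalty * ((da - 1) + (db - 1))
            if cand > dp[j] + 1e-12 or (
                abs(cand - dp[j]) <= 1e-12 and length[i] + 1 > length[j]
            ):
                dp[j] = cand
                prev[j] = i
                length[j] = length[i] + 1
    eligible = np.nonzero(length >= min_anchors)[0]
    if len(eligible) == 0:
        return None
    # deterministic: best score, tie -> earlier start rank via smaller index
    end = eligible[np.lexsort((eligible, -dp[eligible]))[0]]
    chain = []
    i = int(end)
    while i != -1:
        chain.append(i)
        i = int(prev[i])
    chain.reverse()
    return float(dp[end]), [int(order[i]) for i in chain]


def chain_anchors(
    anchors: Sequence[Anchor],
    min_anchors: int = 4,
    max_gap: int = 10,
    gap_penalty: float = 1.0,
    orientations: Sequence[str] = ("same", "inverted"),
) -> list[SyntenyBlock]:
    """Chain anchors of one chromosome pair into collinear blocks.

    Blocks are extracted greedily in descending chain-score order: the
    optimal chain (same or inverted orientation) among those with at least
    ``min_anchors`` anchors is reported and its anchors removed, until no
    qualifying chain remains.  Reported blocks are therefore anchor-disjoint.
    Inverted blocks are found by negating ``rank_b`` and re-running the DP.
    """
    if min_anchors < 1:
        raise ValidationError("min_anchors must be >= 1")
    anchors = list(anchors)
    if not anchors:
        return []
    pairs = {(a.chrom_a, a.chrom_b) for a in anchors}
    if len(pairs) > 1:
        raise ValidationError(f"anchors span multiple chromosome pairs: {sorted(pairs)}")
    chrom_a, chrom_b = next(iter(pairs))

    remaining = list(range(len(anchors)))
    blocks: list[SyntenyBlock] = []
    while remaining:
        ra = np.array([anchors[i].rank_a for i in remaining])
        rb = np.array([anchors[i].rank_b for i in remaining])
        sc = np.array([anchors[i].score for i in remaining])
        cands = []
        if "same" in orientations:
            fwd = _best_chain(ra, rb, sc, max_gap, gap_penalty, min_anchors)
            if fwd is not None:
                cands.append((fwd[0], 0, "same", fwd[1]))
        if "inverted" in orientations:
            inv = _best_chain(ra, -rb, sc, max_gap, gap_penalty, min_anchors)
            if inv is not None:
                # ties prefer the same-orientation chain, then smaller first rank_a
                cands.append((inv[0], 1, "inverted", inv[1]))
        if not cands:
            break
        cands.sort(key=lambda c: (-c[0], c[1], ra[c[3][0]]))
        score, _, orientation, local_idx = cands[0]
        chain = [anchors[remaining[i]] for i in local_idx]
        blocks.append(
            SyntenyBlock(
                anchors=chain,
                orientation=orientation,  # type: ignore[arg-type]
                chain_score=score,
                chrom_a=chrom_a,
                chrom_b=chrom_b,
            )
        )
        used = {remaining[i] for i in local_idx}
        remaining = [i for i in remaining if i not in used]
    blocks.sort(key=lambda b: (b.chrom_a, b.chrom_b, b.anchors[0].rank_a, -b.chain_score))
    return blocks


def anchors_from_homology(
    annotation_a: GenomeAnnotation,
    annotation_b: GenomeAnnotation,
    homology: pd.DataFrame,
    max_evalue: float = 0.01,
) -> dict[tuple[str, str], list[Anchor]]:
    """Place filtered cross-genome hits in rank space, grouped by chromosome pair.

    Hits are kept when the query resolves in genome A, the subject in genome
    B, and ``e_value <= max_evalue``.  Reciprocal duplicates (the same gene
    pair hit in both directions) collapse to one anchor keeping the smaller
    e-value.
    """
    keep = homology[homology["e_value"] <= max_evalue]
    best: dict[tuple[str, str], float] = {}
    for q, s, ev in zip(keep["query_id"], keep["subject_id"], keep["e_value"]):
        if q in annotation_a and s in annotation_b:
            key = (q, s)
        elif s in annotation_a and q in annotation_b:
            key = (s, q)
        else:
            continue
        if key not in best or ev < best[key]:
            best[key] = ev
    grouped: dict[tuple[str, str], list[Anchor]] = {}
    for (ga, gb), ev in best.items():
        anchor = Anchor(
            gene_a=ga,
            gene_b=gb,
            chrom_a=annotation_a.chrom_of(ga),
            chrom_b=annotation_b.chrom_of(gb),
            rank_a=annotation_a.rank_of(ga),
            rank_b=annotation_b.rank_of(gb),
            score=anchor_score(ev),
        )
        grouped.setdefault((anchor.chrom_a, anchor.chrom_b), []).append(anchor)
    return grouped


def chain_genome_pair(
    annotation_a: GenomeAnnotation,
    annotation_b: GenomeAnnotation,
    homology: pd.DataFrame,
    max_evalue: float = 0.01,
    min_anchors: int = 4,
    max_gap: int = 10,
    gap_penalty: float = 1.0,
) -> list[SyntenyBlock]:
    """Filter hits, build anchors and chain every chromosome pair."""
    grouped = anchors_from_homology(annotation_a, annotation_b, homology, max_evalue)
    blocks: list[SyntenyBlock] = []
    for key in sorted(grouped):
        blocks.extend(
            chain_anchors(grouped[key], min_anchors=min_anchors, max_gap=max_gap,
                          gap_penalty=gap_penalty)
        )
    return blocks


# ---------------------------------------------------------------------------
# Tandem arrays


def detect_tandem_arrays(
    annotation: GenomeAnnotation,
    members: set[str] | frozenset[str],
    homology: pd.DataFrame | None,
    max_intervening: int = 5,
    max_evalue: float = 0.01,
) -> list[TandemArray]:
    """Find runs of locally duplicated member genes.

    A *positional run* is a maximal set of member genes on one chromosome in
    which consecutive members are separated by at most ``max_intervening``
    non-member genes in rank space.  When ``homology`` is provided, each run
    is further split into single-linkage components of the homology graph
    restricted to the run (edges: hit pairs at ``e_value <= max_evalue``);
    components of at least two genes are reported as arrays.  With
    ``homology=None`` positional runs of at least two genes are reported
    directly — the mode used by the permutation null, where shuffled labels
    carry no homology structure.
    """
    unknown = set(members) - set(annotation.gene_ids)
    if unknown:
        raise ValidationError(f"members absent from annotation: {sorted(unknown)[:5]}")

    edges: set[tuple[str, str]] | None = None
    if homology is not None:
        keep = homology[homology["e_value"] <= max_evalue]
        edges = set()
        for q, s in zip(keep["query_id"], keep["subject_id"]):
            if q != s and q in members and s in members:
                edges.add((q, s) if q < s else (s, q))

    arrays: list[TandemArray] = []
    df = annotation.genes
    for chrom in annotation.chromosomes:
        sub = df[df["chrom"] == chrom]
        mrows = sub[sub["gene_id"].isin(members)]
        if len(mrows) < 2:
            continue
        runs: list[list[tuple[str, int, int, int]]] = [[]]
        prev_rank = None
        for row in mrows.itertuples(index=False):
            if prev_rank is not None and row.rank - prev_rank - 1 > max_intervening:
                runs.append([])
            runs[-1].append((row.gene_id, row.rank, row.start, row.end))
            prev_rank = row.rank
        for run in runs:
            if len(run) < 2:
                continue
            groups = [run] if edges is None else _homology_components(run, edges)
            for grp in groups:
                if len(grp) < 2:
                    continue
                grp = sorted(grp, key=lambda g: g[1])
                arrays.append(
                    TandemArray(
                        chrom=chrom,
                        genes=[g[0] for g in grp],
                        span_bp=max(g[3] for g in grp) - min(g[2] for g in grp) + 1,
                    )
                )
    arrays.sort(key=lambda a: (a.chrom, annotation.rank_of(a.genes[0])))
    return arrays


def _homology_components(run, edges):
    """Single-linkage components of the run under the homology edge set."""
    ids = [g[0] for g in run]
    parent = {g: g for g in ids}

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    idset = set(ids)
    for a, b in edges:
        if a in idset and b in idset:
            parent[find(a)] = find(b)
    comps: dict[str, list] = {}
    for g in run:
        comps.setdefault(find(g[0]), []).append(g)
    return list(comps.values())


# ---------------------------------------------------------------------------
# Segmental duplications


def detect_segmental_duplications(
    annotation: GenomeAnnotation,
    self_homology: pd.DataFrame,
    tandem_arrays: Sequence[TandemArray] | Sequence[Sequence[str]] = (),
    max_evalue: float = 0.01,
    max_intervening: int = 5,
    min_anchors: int = 4,
    max_gap: int = 10,
    gap_penalty: float = 1.0,
) -> list[SegmentalDuplication]:
    """Chain within-genome anchors into segmental (non-local) duplications.

    Before chaining, three classes of hits are excluded: self-hits, pairs
    inside one tandem array, and same-chromosome pairs within tandem range
    (``|rank_a - rank_b| <= max_intervening``) — segmental duplication is by
    definition non-local.  Same-chromosome blocks whose two rank windows
    overlap are discarded (a region cannot be segmentally duplicated onto
    itself).
    """
    in_same_array: set[tuple[str, str]] = set()
    for arr in tandem_arrays:
        genes = arr.genes if isinstance(arr, TandemArray) else list(arr)
        for i, g1 in enumerate(genes):
            for g2 in genes[i + 1:]:
                in_same_array.add((g1, g2) if g1 < g2 else (g2, g1))

    keep = self_homology[self_homology["e_value"] <= max_evalue]
    best: dict[tuple[str, str], float] = {}
    for q, s, ev in zip(keep["query_id"], keep["subject_id"], keep["e_value"]):
        if q == s or q not in annotation or s not in annotation:
            continue
        key = (q, s) if q < s else (s, q)
        if key in in_same_array:
            continue
        if key not in best or ev < best[key]:
            best[key] = ev

    grouped: dict[tuple[str, str], list[Anchor]] = {}
    for (g1, g2), ev in best.items():
        c1, c2 = annotation.chrom_of(g1), annotation.chrom_of(g2)
        r1, r2 = annotation.rank_of(g1), annotation.rank_of(g2)
        if c1 == c2 and abs(r1 - r2) <= max_intervening:
            continue  # tandem-range local hit
        # canonical sides: (chrom, rank) order puts side a first
        if (c1, r1) <= (c2, r2):
            ga, gb, ca, cb, ra, rb = g1, g2, c1, c2, r1, r2
        else:
            ga, gb, ca, cb, ra, rb = g2, g1, c2, c1, r2, r1
        anchor = Anchor(ga, gb, ca, cb, ra, rb, anchor_score(ev))
        grouped.setdefault((ca, cb), []).append(anchor)

    out: list[SegmentalDuplication] = []
    for key in sorted(grouped):
        for block in chain_anchors(grouped[key], min_anchors=min_anchors,
                                   max_gap=max_gap, gap_penalty=gap_penalty):
            if block.chrom_a == block.chrom_b:
                a_lo, a_hi = block.rank_window_a
                b_lo, b_hi = block.rank_window_b
                if a_lo <= b_hi and b_lo <= a_hi:
                    continue  # overlapping self-alignment, not a duplication
            out.append(SegmentalDuplication(block=block, excludes_tandem=True))
    return out


# ---------------------------------------------------------------------------
# Block membership counting


def genes_in_blocks(
    blocks: Sequence[SyntenyBlock],
    members: set[str] | frozenset[str],
    side: Literal["a", "b"] = "a",
) -> tuple[int, int]:
    """Count member genes appearing as anchor endpoints in blocks.

    Returns ``(distinct_count, multiplicity_count)``: the number of distinct
    member genes found in at least one block on the chosen side, and the
    number of (gene, block) incidences — a gene syntenic to several regions
    (one-to-many duplication relationships) contributes once per block to the
    multiplicity count.
    """
    if side not in ("a", "b"):
        raise ValidationError(f"side must be 'a' or 'b', got {side!r}")
    distinct: set[str] = set()
    multiplicity = 0
    for block in blocks:
        seen_in_block: set[str] = set()
        for anchor in block.anchors:
            g = anchor.gene_a if side == "a" else anchor.gene_b
            if g in members:
                seen_in_block.add(g)
        distinct |= seen_in_block
        multiplicity += len(seen_in_block)
    return len(distinct), multiplicity


def blocks_to_table(blocks: Sequence[SyntenyBlock]) -> pd.DataFrame:
    """Flatten blocks to one anchor per row (DAGchainer aligncoords style)."""
    rows = []
    for bid, block in enumerate(blocks):
        for anchor in block.anchors:
            rows.append(
                (bid, block.chrom_a, block.chrom_b, block.orientation,
                 anchor.gene_a, anchor.gene_b, anchor.rank_a, anchor.rank_b,
                 anchor.score, block.chain_score)
            )
    return pd.DataFrame(
        rows,
        columns=["block_id", "chrom_a", "chrom_b", "orientation", "gene_a",
                 "gene_b", "rank_a", "rank_b", "anchor_score", "chain_score"],
    )
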