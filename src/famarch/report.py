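"""Assemble per-genome architecture summaries into one reproducible report.

The summary aggregates, for each genome of a pairwise comparison: family
size, how many family genes sit in syntenic blocks (and of those, in
segmentally duplicated regions), how many sit in tandem arrays, and how many
tandem family genes are transcriptionally active — each with the matching
percentage.  Percentages are computed with half-away-from-zero rounding so
that printed values recompute exactly from their numerator/denominator
pairs.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from typing import Mapping, Sequence

import pandas as pd

from .collinearity import SegmentalDuplication, SyntenyBlock, TandemArray, genes_in_blocks
from .enrichment import PermutationResult
from .errors import ValidationError
from .family_calls import FamilyCallSet
from .io_formats import GenomeAnnotation

__all__ = ["percentage", "GenomeSummary", "ArchitectureSummary", "build_summary"]


def percentage(numerator: int, denominator: int, decimals: int = 1) -> float:
    """``100 * numerator / denominator`` rounded half-away-from-zero.

    Counts only: requires ``0 <= numerator <= denominator`` and a positive
    denominator.
    """
    if denominator <= 0:
        raise ValidationError(f"denominator must be > 0, got {denominator}")
    if not (0 <= numerator <= denominator):
        raise ValidationError(
            f"need 0 <= numerator <= denominator, got {numerator}/{denominator}"
        )
    exact = Decimal(100) * Decimal(numerator) / Decimal(denominator)
    q = Decimal(1).scaleb(-decimals)
    return float(exact.quantize(q, rounding=ROUND_HALF_UP))


@dataclass
class GenomeSummary:
    """Counts and percentages for one genome of a comparison."""

    genome: str
    n_genes: int
    family_size: int
    n_syntenic: int = 0
    pct_syntenic: float | None = None
    n_syntenic_in_segdup: int = 0
    pct_syntenic_in_segdup: float | None = None
    n_tandem: int = 0
    pct_tandem: float | None = None
    n_tandem_transcribed: int = 0
    pct_tandem_transcribed: float | None = None


@dataclass
class ArchitectureSummary:
    """Pairwise comparison report: two genome summaries plus test results."""

    genome_a: GenomeSummary
    genome_b: GenomeSummary
    permutation: dict[str, dict] = field(default_factory=dict)
    parameters: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "genome_a": _clean(asdict(self.genome_a)),
            "genome_b": _clean(asdict(self.genome_b)),
            "permutation": self.permutation,
            "parameters": self.parameters,
        }

    def to_json(self, path: str | None = None) -> str:
        text = json.dumps(self.to_dict(), indent=1, sort_keys=True)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text + "\n")
        return text

    def to_tsv(self, path: str) -> None:
        """Flattened convenience view: one row per genome."""
        rows = [
            _clean(asdict(self.genome_a), keep_none=True),
            _clean(asdict(self.genome_b), keep_none=True),
        ]
        pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def _clean(d: dict, keep_none: bool = False) -> dict:
    # percentages with undefined denominators are omitted, not printed as null
    return d if keep_none else {k: v for k, v in d.items() if v is not None}


def _one_genome(
    name: str,
    annotation: GenomeAnnotation,
    members: frozenset[str],
    blocks: Sequence[SyntenyBlock],
    side: str,
    segdups: Sequence[SegmentalDuplication],
    arrays: Sequence[TandemArray],
    transcribed: frozenset[str],
) -> GenomeSummary:
    fam = len(members)
    s = GenomeSummary(genome=name, n_genes=len(annotation), family_size=fam)
    syntenic_distinct, _ = genes_in_blocks(blocks, members, side=side)  # type: ignore[arg-type]
    s.n_syntenic = syntenic_distinct
    # which syntenic members also sit in a segmental-duplication block
    syn_genes = {
        (a.gene_a if side == "a" else a.gene_b)
        for b in blocks
        for a in b.anchors
    } & set(members)
    seg_genes = {
        g for sd in segdups for a in sd.block.anchors for g in (a.gene_a, a.gene_b)
    }
    s.n_syntenic_in_segdup = len(syn_genes & seg_genes)
    tandem_genes = {g for arr in arrays for g in arr.genes} & set(members)
    s.n_tandem = len(tandem_genes)
    s.n_tandem_transcribed = len(tandem_genes & set(transcribed))
    if fam > 0:
        s.pct_syntenic = percentage(s.n_syntenic, fam)
        s.pct_tandem = percentage(s.n_tandem, fam)
    if s.n_syntenic > 0:
        s.pct_syntenic_in_segdup = percentage(s.n_syntenic_in_segdup, s.n_syntenic)
    if s.n_tandem > 0:
        s.pct_tandem_transcribed = percentage(s.n_tandem_transcribed, s.n_tandem)
    return s


def build_summary(
    annotation_a: GenomeAnnotation,
    annotation_b: GenomeAnnotation,
    calls_a: FamilyCallSet,
    calls_b: FamilyCallSet,
    blocks: Sequence[SyntenyBlock],
    segdups_a: Sequence[SegmentalDuplication] = (),
    segdups_b: Sequence[SegmentalDuplication] = (),
    arrays_a: Sequence[TandemArray] = (),
    arrays_b: Sequence[TandemArray] = (),
    transcribed_a: frozenset[str] = frozenset(),
    transcribed_b: frozenset[str] = frozenset(),
    permutation_results: Mapping[str, PermutationResult] | None = None,
    parameters: Mapping | None = None,
    name_a: str = "genome_a",
    name_b: str = "genome_b",
) -> ArchitectureSummary:
    """Populate an :class:`ArchitectureSummary` from the upstream products.

    All inputs must refer to one genome pair; gene ids in the call sets that
    resolve in neither annotation raise :class:`ValidationError` listing the
    offenders.
    """
    universe = annotation_a.gene_ids | annotation_b.gene_ids
    offenders = sorted((calls_a.members | calls_b.members) - universe)
    if offenders:
        raise ValidationError(f"family calls outside both annotations: {offenders[:10]}")

    summary_a = _one_genome(name_a, annotation_a, calls_a.members, blocks, "a",
                            segdups_a, arrays_a, transcribed_a)
    summary_b = _one_genome(name_b, annotation_b, calls_b.members, blocks, "b",
                            segdups_b, arrays_b, transcribed_b)
    perm = {
        key: res.to_dict() for key, res in (permutation_results or {}).items()
    }
    return ArchitectureSummary(
        genome_a=summary_a,
        genome_b=summary_b,
        permutation=perm,
        parameters=dict(parameters or {}),
    )
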