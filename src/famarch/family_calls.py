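"""Call gene-family members from protein-domain hit tables.

A gene belongs to the family when it carries at least one hit to a clan
domain that simultaneously clears an e-value ceiling and a minimum fraction
of the domain model aligned.  A deliberately permissive e-value ceiling
(default 1.0) keeps fast-evolving members from being missed, while the
coverage floor (default 50% of the model) controls the false positives such
a ceiling would otherwise admit.  Genes that fail the domain filter but
remain sequence-similar to called members are flagged separately as
*potentially inactive* family members — likely pseudogenes or members that
lost the diagnostic domain.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import pandas as pd

from .errors import ValidationError
from .io_formats import GenomeAnnotation

__all__ = [
    "DomainHit",
    "FamilyCallSet",
    "domain_coverage",
    "call_family_members",
    "detect_inactive_members",
]


@dataclass(frozen=True)
class DomainHit:
    """One domain alignment row: gene, model name, e-value, model span.

    ``hmm_from``/``hmm_to`` are 1-based coordinates on the domain model;
    ``e_value`` is the per-domain independent e-value when parsed from
    HMMER output.
    """

    gene_id: str
    domain_name: str
    e_value: float
    hmm_from: int
    hmm_to: int
    model_length: int

    def __post_init__(self):
        if self.model_length <= 0:
            raise ValidationError(f"model_length must be positive, got {self.model_length}")
        if not (1 <= self.hmm_from <= self.hmm_to <= self.model_length):
            raise ValidationError(
                f"need 1 <= hmm_from <= hmm_to <= model_length, got "
                f"{self.hmm_from}..{self.hmm_to}/{self.model_length}"
            )
        if not (self.e_value >= 0):
            raise ValidationError(f"e_value must be >= 0, got {self.e_value}")


@dataclass
class FamilyCallSet:
    """Family membership calls with the best supporting hit per member."""

    members: frozenset[str]
    inactive_candidates: frozenset[str] = frozenset()
    per_gene_evidence: dict[str, DomainHit] = field(default_factory=dict)

    def __post_init__(self):
        if self.members & self.inactive_candidates:
            raise ValidationError("members and inactive_candidates must be disjoint")


def domain_coverage(hit: DomainHit) -> float:
    """Fraction of the domain model covered by the alignment, in (0, 1]."""
    return (hit.hmm_to - hit.hmm_from + 1) / hit.model_length


def call_family_members(
    hits: Iterable[DomainHit],
    clan_domains: set[str],
    max_evalue: float = 1.0,
    min_coverage: float = 0.5,
    annotation: GenomeAnnotation | None = None,
) -> FamilyCallSet:
    """Apply the clan/e-value/coverage filter to a domain-hit table.

    A gene is a member iff it has at least one hit with
    ``domain_name in clan_domains``, ``e_value <= max_evalue`` and
    ``domain_coverage >= min_coverage``.  The recorded evidence is the
    qualifying hit with minimum e-value (ties: larger coverage, then
    lexicographic domain name).

    If ``annotation`` is given, hit gene ids absent from it raise
    :class:`ValidationError` — silent drops would hide id-mapping bugs.
    """
    if not clan_domains:
        raise ValidationError("clan_domains must be non-empty")
    best: dict[str, DomainHit] = {}
    for hit in hits:
        if annotation is not None and hit.gene_id not in annotation:
            raise ValidationError(
                f"hit references gene {hit.gene_id!r} absent from the annotation"
            )
        if hit.domain_name not in clan_domains:
            continue
        if hit.e_value > max_evalue or domain_coverage(hit) < min_coverage:
            continue
        cur = best.get(hit.gene_id)
        if cur is None or _better(hit, cur):
            best[hit.gene_id] = hit
    return FamilyCallSet(members=frozenset(best), per_gene_evidence=best)


def _better(a: DomainHit, b: DomainHit) -> bool:
    ka = (a.e_value, -domain_coverage(a), a.domain_name)
    kb = (b.e_value, -domain_coverage(b), b.domain_name)
    return ka < kb


def detect_inactive_members(
    calls: FamilyCallSet,
    homology: pd.DataFrame,
    max_evalue: float = 0.01,
) -> frozenset[str]:
    """Flag non-member genes that retain sequence similarity to members.

    These are candidate inactive family genes: they lost (or never had) a
    qualifying domain hit yet align to at least one called member at
    ``e_value <= max_evalue`` in the all-vs-all homology table.  Member
    genes are never flagged.
    """
    keep = homology[homology["e_value"] <= max_evalue]
    members = calls.members
    flagged: set[str] = set()
    q, s = keep["query_id"].to_numpy(), keep["subject_id"].to_numpy()
    for a, b in zip(q, s):
        if a not in members and b in members:
            flagged.add(a)
        if b not in members and a in members:
            flagged.add(b)
    return frozenset(flagged)
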