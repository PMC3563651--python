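"""Readers, writers and validation for the external formats shared by all modules.

The central in-memory object is :class:`GenomeAnnotation`: an ordered table of
gene models with a per-chromosome *rank* index (1-based position in
start-coordinate order).  Rank space is the coordinate system used by the
collinearity and enrichment modules, so it is computed once here and treated
as immutable downstream.

Formats handled:

* GFF3 (gene features only, 1-based inclusive coordinates, ``ID=`` attribute)
* BLAST tabular output format 6 (12 columns, tab-separated)
* HMMER3 per-domain tabular output (``domtblout``) and a simple 6-column TSV
  dialect carrying the same fields
* expression matrices as TSV (genes in rows, tissue names in the header)
* BED (0-based half-open) for tandem arrays

Every reader *rejects* invariant violations rather than silently repairing
them, and counts every dropped record in a :class:`ReadReport`.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ParseError, ValidationError

__all__ = [
    "GenomeAnnotation",
    "ReadReport",
    "read_gff3",
    "write_gff3",
    "read_blast_tab",
    "write_blast_tab",
    "read_domtblout",
    "write_domtblout",
    "read_expression_tsv",
    "write_expression_tsv",
    "write_bed",
    "BLAST_COLUMNS",
]

#: Canonical column names of BLAST ``-outfmt 6``.
BLAST_COLUMNS = [
    "query_id",
    "subject_id",
    "pct_identity",
    "aln_len",
    "mismatches",
    "gap_opens",
    "q_start",
    "q_end",
    "s_start",
    "s_end",
    "e_value",
    "bit_score",
]

_STRANDS = {"+", "-"}


@dataclass
class ReadReport:
    """Accounting of records dropped (never silently) while reading a file."""

    n_read: int = 0
    n_kept: int = 0
    dropped: dict[str, int] = field(default_factory=dict)

    def drop(self, reason: str) -> None:
        self.dropped[reason] = self.dropped.get(reason, 0) + 1

    @property
    def n_dropped(self) -> int:
        return sum(self.dropped.values())


class GenomeAnnotation:
    """Ordered gene models with a derived per-chromosome rank index.

    Parameters
    ----------
    genes
        Iterable of ``(gene_id, chromosome, start, end, strand)`` tuples with
        1-based inclusive coordinates.
    family_genes
        Optional set of gene ids carrying the family-of-interest label.  The
        label is carried as annotation metadata (it round-trips through GFF3
        as a ``family=1`` attribute) so that simulated genomes keep their
        ground truth attached.

    Invariants enforced at construction: unique gene ids; ``start <= end``;
    no two genes share ``(chromosome, start, end)``.  Rank is start-coordinate
    order within each chromosome, ties broken by end coordinate then gene id.
    """

    def __init__(
        self,
        genes: Iterable[tuple[str, str, int, int, str]],
        family_genes: Iterable[str] = (),
    ):
        rows = list(genes)
        df = pd.DataFrame(rows, columns=["gene_id", "chrom", "start", "end", "strand"])
        if len(df) != df["gene_id"].nunique():
            dups = df["gene_id"][df["gene_id"].duplicated()].unique()
            raise ValidationError(f"duplicate gene ids: {sorted(dups)[:5]}")
        bad = df[df["start"] > df["end"]]
        if len(bad):
            raise ValidationError(
                f"start > end for genes: {bad['gene_id'].tolist()[:5]}"
            )
        bad_strand = set(df["strand"]) - _STRANDS
        if bad_strand:
            raise ValidationError(f"invalid strand values: {sorted(bad_strand)}")
        if df.duplicated(subset=["chrom", "start", "end"]).any():
            raise ValidationError("two genes share (chromosome, start, end)")
        df = df.sort_values(
            ["chrom", "start", "end", "gene_id"], kind="mergesort"
        ).reset_index(drop=True)
        df["rank"] = df.groupby("chrom", sort=False).cumcount() + 1
        self._df = df
        self._rank = dict(zip(df["gene_id"], df["rank"]))
        self._chrom = dict(zip(df["gene_id"], df["chrom"]))
        fam = frozenset(family_genes)
        unknown = fam - set(self._rank)
        if unknown:
            raise ValidationError(
                f"family label on genes absent from annotation: {sorted(unknown)[:5]}"
            )
        self.family_genes: frozenset[str] = fam

    # -- basic accessors ---------------------------------------------------

    @property
    def genes(self) -> pd.DataFrame:
        """Copy of the gene table (gene_id, chrom, start, end, strand, rank)."""
        return self._df.copy()

    @property
    def gene_ids(self) -> frozenset[str]:
        return frozenset(self._rank)

    @property
    def chromosomes(self) -> list[str]:
        return list(dict.fromkeys(self._df["chrom"]))

    def __len__(self) -> int:
        return len(self._df)

    def __contains__(self, gene_id: str) -> bool:
        return gene_id in self._rank

    def rank_of(self, gene_id: str) -> int:
        return self._rank[gene_id]

    def chrom_of(self, gene_id: str) -> str:
        return self._chrom[gene_id]

    def genes_on(self, chrom: str) -> pd.DataFrame:
        """Genes of one chromosome in rank order."""
        return self._df[self._df["chrom"] == chrom].reset_index(drop=True)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, GenomeAnnotation):
            return NotImplemented
        return self._df.equals(other._df) and self.family_genes == other.family_genes

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return (
            f"GenomeAnnotation({len(self)} genes, "
            f"{len(self.chromosomes)} chromosomes, "
            f"{len(self.family_genes)} family members)"
        )


# ---------------------------------------------------------------------------
# GFF3


_GFF_ATTR_RE = re.compile(r"([^;=]+)=([^;]*)")


def _parse_attrs(field9: str) -> dict[str, str]:
    return {m.group(1).strip(): m.group(2).strip() for m in _GFF_ATTR_RE.finditer(field9)}


def read_gff3(path: str) -> tuple[GenomeAnnotation, ReadReport]:
    """Read gene features from a GFF3 file.

    Only rows whose type column is ``gene`` are considered.  Features lacking
    usable coordinates (``.`` placeholders) or an ``ID=`` attribute are
    dropped and counted in the report — they correspond to gene models with
    unknown genomic loci, which the downstream analysis cannot place in rank
    space.  Malformed (non-integer, non-placeholder) coordinates raise
    :class:`ParseError` with the line number.
    """
    rows: list[tuple[str, str, int, int, str]] = []
    family: set[str] = set()
    report = ReadReport()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise ParseError(
                    f"expected 9 tab-separated columns, got {len(fields)}",
                    path=path,
                    line=lineno,
                )
            seqid, _src, ftype, start_s, end_s, _score, strand, _phase, attrs_s = fields
            if ftype != "gene":
                continue
            report.n_read += 1
            if start_s == "." or end_s == ".":
                report.drop("missing_coordinates")
                continue
            try:
                start, end = int(start_s), int(end_s)
            except ValueError:
                raise ParseError(
                    f"malformed coordinates {start_s!r}..{end_s!r}",
                    path=path,
                    line=lineno,
                ) from None
            attrs = _parse_attrs(attrs_s)
            gid = attrs.get("ID")
            if not gid:
                report.drop("missing_ID")
                continue
            if strand not in _STRANDS:
                strand = "+"  # GFF3 allows '.'/'?'; rank space ignores strand
            rows.append((gid, seqid, start, end, strand))
            if attrs.get("family") == "1":
                family.add(gid)
            report.n_kept += 1
    return GenomeAnnotation(rows, family_genes=family), report


def write_gff3(annotation: GenomeAnnotation, path: str, source: str = "famarch") -> None:
    """Write gene features as GFF3 (1-based inclusive); family label as attribute."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for row in annotation.genes.itertuples(index=False):
            attrs = f"ID={row.gene_id}"
            if row.gene_id in annotation.family_genes:
                attrs += ";family=1"
            fh.write(
                f"{row.chrom}\t{source}\tgene\t{row.start}\t{row.end}\t.\t"
                f"{row.strand}\t.\t{attrs}\n"
            )


# ---------------------------------------------------------------------------
# BLAST outfmt 6


def read_blast_tab(
    path: str, max_evalue: float = float("inf")
) -> tuple[pd.DataFrame, ReadReport]:
    """Read 12-column BLAST tabular hits, dropping self-hits and high e-values.

    Rows with ``e_value > max_evalue`` and self-hits (query == subject) are
    dropped and counted.  A wrong column count raises :class:`ParseError`
    with the line number.
    """
    report = ReadReport()
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 12:
                raise ParseError(
                    f"expected 12 tab-separated columns, got {len(fields)}",
                    path=path,
                    line=lineno,
                )
            report.n_read += 1
            try:
                rec = (
                    fields[0],
                    fields[1],
                    float(fields[2]),
                    int(fields[3]),
                    int(fields[4]),
                    int(fields[5]),
                    int(fields[6]),
                    int(fields[7]),
                    int(fields[8]),
                    int(fields[9]),
                    float(fields[10]),
                    float(fields[11]),
                )
            except ValueError:
                raise ParseError("malformed numeric field", path=path, line=lineno) from None
            if rec[0] == rec[1]:
                report.drop("self_hit")
                continue
            if rec[10] > max_evalue:
                report.drop("evalue_above_threshold")
                continue
            rows.append(rec)
            report.n_kept += 1
    table = pd.DataFrame(rows, columns=BLAST_COLUMNS)
    return table, report


def write_blast_tab(table: pd.DataFrame, path: str) -> None:
    table[BLAST_COLUMNS].to_csv(path, sep="\t", header=False, index=False)


# ---------------------------------------------------------------------------
# HMMER domtblout (and a 6-column TSV dialect)

# Column indices in HMMER3 domtblout (whitespace-delimited, 23 columns):
# 0 target name, 3 query (model) name, 5 model length, 12 i-Evalue,
# 15 hmm from, 16 hmm to.
_DOMTBL_MIN_COLS = 23

_TSV_DIALECT_HEADER = ["gene_id", "domain_name", "e_value", "hmm_from", "hmm_to", "model_length"]


def read_domtblout(path: str):
    """Read domain hits from HMMER3 ``domtblout`` or the 6-column TSV dialect.

    The dialect is auto-detected: a tab-separated header line naming the six
    fields selects the TSV dialect, otherwise HMMER3's whitespace layout is
    assumed (``#`` comment lines ignored).  Returns a list of
    :class:`~famarch.family_calls.DomainHit`.
    """
    from .family_calls import DomainHit  # local import: avoid cycle

    hits: list[DomainHit] = []
    with open(path) as fh:
        first = fh.readline()
        is_tsv = first.rstrip("\n").split("\t") == _TSV_DIALECT_HEADER
        if not is_tsv:
            fh.seek(0)
        for lineno, line in enumerate(fh, start=2 if is_tsv else 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            if is_tsv:
                fields = line.split("\t")
                if len(fields) != 6:
                    raise ParseError(
                        f"expected 6 columns, got {len(fields)}", path=path, line=lineno
                    )
                gid, dom, ev_s, hf_s, ht_s, ml_s = fields
            else:
                fields = line.split()
                if len(fields) < _DOMTBL_MIN_COLS:
                    raise ParseError(
                        f"expected >= {_DOMTBL_MIN_COLS} whitespace-separated columns, "
                        f"got {len(fields)}",
                        path=path,
                        line=lineno,
                    )
                gid, dom = fields[0], fields[3]
                ml_s, ev_s = fields[5], fields[12]
                hf_s, ht_s = fields[15], fields[16]
            try:
                ev, hf, ht, ml = float(ev_s), int(hf_s), int(ht_s), int(ml_s)
            except ValueError:
                raise ParseError("malformed numeric field", path=path, line=lineno) from None
            try:
                hits.append(DomainHit(gid, dom, ev, hf, ht, ml))
            except ValidationError as exc:
                raise ParseError(str(exc), path=path, line=lineno) from None
    return hits


def write_domtblout(hits, path: str, dialect: str = "tsv") -> None:
    """Write domain hits; ``dialect`` is ``"tsv"`` (default) or ``"hmmer"``.

    The hmmer dialect emits 23 whitespace-separated columns with placeholder
    values in the fields this analysis does not consume, so files re-read as
    genuine domtblout.
    """
    with open(path, "w") as fh:
        if dialect == "tsv":
            fh.write("\t".join(_TSV_DIALECT_HEADER) + "\n")
            for h in hits:
                fh.write(
                    f"{h.gene_id}\t{h.domain_name}\t{h.e_value:.3g}\t"
                    f"{h.hmm_from}\t{h.hmm_to}\t{h.model_length}\n"
                )
        elif dialect == "hmmer":
            fh.write("# target name - tlen query name accession qlen ... (domtblout layout)\n")
            for h in hits:
                cols = [
                    h.gene_id, "-", "500", h.domain_name, "-", str(h.model_length),
                    f"{h.e_value:.2g}", "0.0", "0.0", "1", "1",
                    f"{h.e_value:.2g}", f"{h.e_value:.2g}", "0.0", "0.0",
                    str(h.hmm_from), str(h.hmm_to), "1", "100", "1", "100",
                    "0.9", "-",
                ]
                fh.write(" ".join(cols) + "\n")
        else:  # pragma: no cover - guarded by callers
            raise ValidationError(f"unknown domtblout dialect: {dialect!r}")


# ---------------------------------------------------------------------------
# Expression TSV


def read_expression_tsv(path: str):
    """Read a genes x tissues TSV into an ExpressionMatrix (raw)."""
    from .expression import ExpressionMatrix  # local import: avoid cycle

    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.isna().any().any():
        raise ValidationError(f"missing values in expression matrix {path}")
    return ExpressionMatrix(
        gene_ids=list(df.index.astype(str)),
        tissue_names=list(df.columns.astype(str)),
        values=df.to_numpy(dtype=float),
        standardized=False,
    )


def write_expression_tsv(matrix, path: str) -> None:
    df = pd.DataFrame(matrix.values, index=matrix.gene_ids, columns=matrix.tissue_names)
    df.index.name = "gene_id"
    df.to_csv(path, sep="\t")


# ---------------------------------------------------------------------------
# BED (0-based half-open)


def write_bed(intervals: Sequence[tuple[str, int, int, str]], path: str) -> None:
    """Write ``(chrom, start_1based, end_1based_inclusive, name)`` as BED.

    Conversion to BED's 0-based half-open convention is ``start-1, end``; the
    two conventions are inverse bijections on valid records.
    """
    with open(path, "w") as fh:
        for chrom, start, end, name in intervals:
            if start < 1 or end < start:
                raise ValidationError(f"invalid interval {chrom}:{start}-{end}")
            fh.write(f"{chrom}\t{start - 1}\t{end}\t{name}\n")
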