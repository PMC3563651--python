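"""Expression standardization, clustering, and duplicate-gene divergence.

Pipeline: a raw gene x tissue matrix is row-standardized (z-score across
tissues), genes are clustered hierarchically on the standardized profiles,
each gene is assigned a preferred tissue (its argmax tissue when the z-score
there clears a threshold), and tandem arrays are classified as transcription-
ally concordant or divergent from the preferences of their member genes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Literal, Mapping, Sequence

import numpy as np
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist

from .collinearity import TandemArray
from .errors import ValidationError

__all__ = [
    "ExpressionMatrix",
    "ClusterResult",
    "zscore_rows",
    "call_transcribed",
    "hierarchical_cluster",
    "tissue_preference",
    "divergence_within_arrays",
]


@dataclass
class ExpressionMatrix:
    """Gene x tissue expression values, raw or z-standardized."""

    gene_ids: list[str]
    tissue_names: list[str]
    values: np.ndarray
    standardized: bool = False
    degenerate_genes: frozenset[str] = frozenset()

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.gene_ids), len(self.tissue_names)):
            raise ValidationError(
                f"values shape {self.values.shape} inconsistent with "
                f"{len(self.gene_ids)} genes x {len(self.tissue_names)} tissues"
            )
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise ValidationError("duplicate gene ids in expression matrix")
        if np.isnan(self.values).any():
            raise ValidationError("missing values in expression matrix")

    def row(self, gene_id: str) -> np.ndarray:
        return self.values[self.gene_ids.index(gene_id)]


def zscore_rows(matrix: ExpressionMatrix, ddof: int = 0) -> ExpressionMatrix:
    """Standardize each gene's profile to zero mean and unit sd across tissues.

    Uses the population standard deviation by default (``ddof=0``); pass
    ``ddof=1`` for the sample convention.  Rows with zero variance cannot be
    standardized; they are set to all-zero and recorded in
    ``degenerate_genes``.
    """
    if len(matrix.tissue_names) < 2:
        raise ValidationError("z-score standardization needs >= 2 tissues")
    x = matrix.values
    mean = x.mean(axis=1, keepdims=True)
    sd = x.std(axis=1, ddof=ddof, keepdims=True)
    degenerate = (sd == 0).ravel()
    safe_sd = np.where(sd == 0, 1.0, sd)
    z = (x - mean) / safe_sd
    z[degenerate, :] = 0.0
    return ExpressionMatrix(
        gene_ids=list(matrix.gene_ids),
        tissue_names=list(matrix.tissue_names),
        values=z,
        standardized=True,
        degenerate_genes=frozenset(np.array(matrix.gene_ids)[degenerate]),
    )


def call_transcribed(matrix: ExpressionMatrix, threshold: float = 10.0) -> frozenset[str]:
    """Genes whose expression exceeds ``threshold`` (strictly) in >= 1 tissue.

    Applies to raw (normalized but not z-scored) values; a gene peaking at
    exactly the threshold is *not* called.
    """
    if matrix.standardized:
        raise ValidationError("call_transcribed requires a raw (non-standardized) matrix")
    mask = (matrix.values > threshold).any(axis=1)
    return frozenset(np.array(matrix.gene_ids)[mask])


@dataclass
class ClusterResult:
    """Agglomerative clustering of gene profiles.

    ``linkage_matrix`` is the scipy linkage encoding of the merge tree over
    ``gene_ids`` (degenerate rows excluded under the correlation distance,
    listed in ``excluded``); ``cut(k)`` returns a gene -> cluster-label map.
    """

    gene_ids: list[str]
    linkage_matrix: np.ndarray
    leaf_order: list[str]
    excluded: list[str] = field(default_factory=list)

    def cut(self, k: int) -> dict[str, int]:
        labels = hierarchy.fcluster(self.linkage_matrix, t=k, criterion="maxclust")
        return dict(zip(self.gene_ids, (int(l) for l in labels)))

    def to_newick(self) -> str:
        """Dendrogram as a Newick string with merge distances as branch lengths."""
        tree = hierarchy.to_tree(self.linkage_matrix)

        def rec(node) -> str:
            if node.is_leaf():
                return self.gene_ids[node.id]
            l, r = node.get_left(), node.get_right()
            bl = node.dist - l.dist
            br = node.dist - r.dist
            return f"({rec(l)}:{bl:.6g},{rec(r)}:{br:.6g})"

        return rec(tree) + ";"


def hierarchical_cluster(
    matrix: ExpressionMatrix,
    distance: Literal["pearson", "euclidean"] = "pearson",
    linkage: Literal["average", "complete", "single"] = "average",
) -> ClusterResult:
    """Deterministic agglomerative clustering of standardized gene profiles.

    The Pearson distance between two genes is ``1 - r`` over their profiles.
    All-zero (degenerate) rows are undefined under this distance; they are
    excluded with a warning and listed in ``ClusterResult.excluded``.
    """
    if not matrix.standardized:
        raise ValidationError("hierarchical_cluster expects a standardized matrix")
    if distance not in ("pearson", "euclidean"):
        raise ValidationError(f"unknown distance {distance!r}")
    if linkage not in ("average", "complete", "single"):
        raise ValidationError(f"unknown linkage {linkage!r}")

    ids = list(matrix.gene_ids)
    x = matrix.values
    excluded: list[str] = []
    if distance == "pearson":
        degen = np.all(x == x[:, :1], axis=1)  # constant rows (incl. all-zero)
        if degen.any():
            excluded = [g for g, d in zip(ids, degen) if d]
            import warnings

            warnings.warn(
                f"excluding {len(excluded)} constant rows from correlation clustering",
                stacklevel=2,
            )
            ids = [g for g, d in zip(ids, degen) if not d]
            x = x[~degen]
    if len(ids) < 2:
        raise ValidationError("need >= 2 clusterable genes")
    metric = "correlation" if distance == "pearson" else "euclidean"
    d = pdist(x, metric=metric)
    d = np.clip(d, 0.0, None)  # guard tiny negative rounding under correlation
    z = hierarchy.linkage(d, method=linkage)
    order = hierarchy.leaves_list(z)
    return ClusterResult(
        gene_ids=ids,
        linkage_matrix=z,
        leaf_order=[ids[i] for i in order],
        excluded=excluded,
    )


def tissue_preference(
    matrix: ExpressionMatrix, min_z: float = 1.5
) -> dict[str, str | None]:
    """Assign each gene its argmax tissue when the z-score there is >= min_z.

    Genes whose maximum falls below the threshold, or whose maximum is tied
    between tissues, get ``None`` (no call).
    """
    if not matrix.standardized:
        raise ValidationError("tissue_preference expects a standardized matrix")
    prefs: dict[str, str | None] = {}
    tissues = matrix.tissue_names
    for gid, row in zip(matrix.gene_ids, matrix.values):
        mx = row.max()
        if mx < min_z or (row == mx).sum() > 1:
            prefs[gid] = None
        else:
            prefs[gid] = tissues[int(row.argmax())]
    return prefs


def divergence_within_arrays(
    preferences: Mapping[str, str | None],
    arrays: Sequence[TandemArray],
) -> list[dict]:
    """Classify each tandem array by the tissue preferences of its genes.

    ``divergent``: at least two members prefer *different* tissues —
    transcriptional divergence after local duplication.  ``concordant``: at
    least two members share one preference and none differ.  Otherwise
    ``untranscribed`` (fewer than two members with a preference call; genes
    absent from the expression data count as no-call).
    """
    reports = []
    for i, arr in enumerate(arrays):
        called = [preferences.get(g) for g in arr.genes]
        tissues = [t for t in called if t is not None]
        distinct = set(tissues)
        if len(distinct) >= 2:
            status = "divergent"
        elif len(tissues) >= 2:
            status = "concordant"
        else:
            status = "untranscribed"
        reports.append(
            {
                "array_index": i,
                "chrom": arr.chrom,
                "genes": list(arr.genes),
                "preferences": {g: preferences.get(g) for g in arr.genes},
                "status": status,
            }
        )
    return reports
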