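"""Microbe-derived sample clustering (MD-Clusters).

Tumors are clustered on their relative microbial abundance profiles using
average-linkage agglomeration on the distance 1 - Spearman rho, the tree is
cut into k clusters (k = 2 by default, the two major microbe-derived
clusters), and the cluster/group contingency is tested with Fisher's exact
test. Distances use 1 - rho rather than (1 - rho)/2: only the ordering of
distances matters for the linkage, and merge heights then read directly as
"one minus correlation".
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.cluster.hierarchy import cut_tree, linkage
from scipy.spatial.distance import squareform

from .io import FeatureTable, SampleAnnotation
from .stats import ContingencyResult, DegenerateInputError, fisher_exact, spearman_matrix

logger = logging.getLogger(__name__)


@dataclass
class SampleClustering:
    """Cluster labels for samples plus the agglomeration history.

    Labels run 1..k, numbered by decreasing cluster size (ties broken by the
    lexicographically smallest member sample ID). ``linkage_record`` is the
    scipy linkage matrix (merge pairs + heights) for dendrogram inspection.
    """

    sample_ids: list[str]
    labels: np.ndarray
    k: int
    linkage_record: np.ndarray

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)
        if len(self.labels) != len(self.sample_ids):
            raise ValueError("one label per sample required")
        present = set(self.labels.tolist())
        if present != set(range(1, self.k + 1)):
            raise ValueError(f"labels must cover 1..{self.k}, got {sorted(present)}")

    def members(self, label: int) -> list[str]:
        return [s for s, l in zip(self.sample_ids, self.labels) if l == label]

    def label_of(self, sample_id: str) -> int:
        return int(self.labels[self.sample_ids.index(sample_id)])


def relative_abundance(microbes: FeatureTable) -> FeatureTable:
    """Scale each sample column to proportions summing to 1."""
    totals = microbes.counts.sum(axis=0)
    zero = np.nonzero(totals == 0)[0]
    if len(zero):
        raise DegenerateInputError(
            f"sample(s) with zero total microbial count: "
            f"{[microbes.sample_ids[i] for i in zero]}"
        )
    return microbes.with_counts(microbes.counts / totals)


def _size_ordered_labels(raw: np.ndarray, ids: Sequence[str]) -> tuple[np.ndarray, int]:
    """Renumber arbitrary cluster codes to 1..k by decreasing size.

    Ties in size break on the lexicographically smallest member ID.
    """
    codes = np.unique(raw)
    keyed = sorted(
        codes,
        key=lambda c: (-(raw == c).sum(), min(ids[i] for i in np.nonzero(raw == c)[0])),
    )
    remap = {c: i + 1 for i, c in enumerate(keyed)}
    return np.array([remap[c] for c in raw], dtype=int), len(codes)


def spearman_average_linkage(values: np.ndarray, row_ids: Sequence[str]) -> np.ndarray:
    """Average-linkage tree over rows of ``values`` at distance 1 - Spearman rho.

    Rows must be non-constant (Spearman is undefined otherwise); callers
    pre-filter and report constant rows.
    """
    values = np.asarray(values, dtype=float)
    const = np.nonzero(np.ptp(values, axis=1) == 0)[0]
    if len(const):
        raise DegenerateInputError(
            f"constant profile(s): {[row_ids[i] for i in const[:5]]}"
        )
    corr = spearman_matrix(values)
    dist = 1.0 - corr
    np.fill_diagonal(dist, 0.0)
    # average linkage on the condensed upper triangle
    return linkage(squareform(dist, checks=False), method="average")


def cluster_samples(abundance: FeatureTable, k: int = 2) -> SampleClustering:
    """Cluster samples by their abundance profiles into exactly k clusters.

    Sample-sample distance is 1 - Spearman rho across features; features that
    are constant across all samples are dropped first (with a warning) since
    they carry no rank information. The average-linkage tree is cut to exactly
    k clusters. Deterministic: no randomness is involved.
    """
    if k < 1 or k > abundance.n_samples:
        raise ValueError(f"k={k} outside 1..{abundance.n_samples}")
    keep = np.ptp(abundance.counts, axis=1) > 0
    if not keep.all():
        dropped = [f for f, m in zip(abundance.feature_ids, keep) if not m]
        logger.warning("dropping %d constant feature(s) before clustering: %s",
                       len(dropped), dropped[:5])
    values = abundance.counts[keep]
    if values.shape[0] < 3:
        raise DegenerateInputError("need >= 3 non-constant features to cluster samples")
    Z = spearman_average_linkage(values.T, abundance.sample_ids)
    raw = cut_tree(Z, n_clusters=k).ravel()
    labels, k_found = _size_ordered_labels(raw, abundance.sample_ids)
    return SampleClustering(
        sample_ids=list(abundance.sample_ids),
        labels=labels, k=k_found, linkage_record=Z,
    )


def associate_clusters_with_group(
    clustering: SampleClustering, ann: Sequence[SampleAnnotation]
) -> ContingencyResult:
    """Fisher exact test of the 2x2 cluster-by-group contingency.

    Samples with a missing group label are dropped. Requires exactly two
    clusters and two groups among the retained samples.
    """
    by_id = {a.sample_id: a for a in ann}
    pairs = [
        (clustering.label_of(s), by_id[s].group)
        for s in clustering.sample_ids
        if s in by_id and by_id[s].group is not None
    ]
    clusters = sorted({c for c, _ in pairs})
    groups = sorted({g for _, g in pairs})
    if len(clusters) != 2 or len(groups) != 2:
        raise DegenerateInputError(
            f"need 2 clusters x 2 groups, got {len(clusters)} x {len(groups)}"
        )
    table = [
        [sum(1 for c, g in pairs if c == cl and g == gr) for gr in groups]
        for cl in clusters
    ]
    return fisher_exact(table)
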