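"""Host-gene / microbe co-abundance integration.

The host expression matrix and the microbial abundance matrix are stacked
into one feature table, features are hierarchically clustered (average
linkage on 1 - Spearman rho across samples, tree cut into K clusters), each
cluster is classified as host-only, microbe-only (together: homologous) or
heterologous (at least one of each kind), and heterologous clusters are
screened for high-confidence cross-kind pairs: a (gene, microbe) pair with
both members non-zero in at least ``min_presence`` of samples and Spearman
rho above ``rho_min``.

Each table is first library-size normalized per sample (columns scaled to
the median column total, separately for host and microbe tables) and then
log2(x+1)-transformed. Normalization matters: sequencing-depth variation is
shared by every feature in a sample and, left in, correlates unrelated
genes and microbes enough to cross the 0.7 calling threshold by chance;
depth-normalized values leave only biological co-abundance. The log2
transform puts host (large) and microbe (small) scales side by side;
Spearman's rank basis makes it inert for the correlations themselves.

The presence filter applies per feature within a candidate pair — both
members must individually be non-zero in >= min_presence of samples — the
most conservative reading that still yields per-pair calls.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.cluster.hierarchy import cut_tree

from .clustering import spearman_average_linkage
from .io import HOST_GENE, MICROBE, FeatureTable
from .markers import log2_transform
from .stats import spearman_matrix

logger = logging.getLogger(__name__)

HOST_ONLY = "host_only"
MICROBE_ONLY = "microbe_only"
HETEROLOGOUS = "heterologous"


@dataclass(frozen=True)
class IntegrationConfig:
    """Knobs of the integration stage.

    n_clusters
        Number of clusters K to cut the feature tree into (1000 in a
        transcriptome-scale run; capped at half the feature count so small
        cohorts remain clusterable).
    rho_min
        Spearman correlation a cross-kind pair must exceed (strictly) to be
        called high-confidence. Default 0.7.
    min_presence
        Fraction of samples in which each pair member must be non-zero.
        Default 0.5.
    normalize
        Library-size normalize each table per sample (columns scaled to the
        median column total) before the log2 transform. Default True.
    """

    n_clusters: int = 1000
    rho_min: float = 0.7
    min_presence: float = 0.5
    normalize: bool = True

    def __post_init__(self) -> None:
        if self.n_clusters < 2:
            raise ValueError("n_clusters must be >= 2")
        if not 0.0 < self.rho_min < 1.0:
            raise ValueError("rho_min must be in (0, 1)")
        if not 0.0 <= self.min_presence <= 1.0:
            raise ValueError("min_presence must be in [0, 1]")

    def effective_k(self, n_features: int) -> int:
        """K actually used: min(n_clusters, floor(n_features / 2))."""
        return min(self.n_clusters, n_features // 2)


@dataclass
class FeatureClustering:
    """Feature -> cluster assignment plus features dropped as constant."""

    feature_ids: list[str]
    labels: np.ndarray  # cluster id 1..K per retained feature
    k: int
    dropped_constant: list[str] = field(default_factory=list)

    def assignment(self) -> dict[str, int]:
        return {f: int(l) for f, l in zip(self.feature_ids, self.labels)}


@dataclass
class HeteroClusterRecord:
    """One feature cluster with its classification and best cross-kind pair."""

    cluster_id: int
    member_features: list[tuple[str, str]]  # (feature_id, kind)
    classification: str
    best_pair: tuple[str, str] | None = None  # (gene_id, microbe_id)
    best_rho: float | None = None
    presence_ok: bool | None = None
    high_confidence: bool = False
    #: all eligible cross-kind pairs with their rho, sorted by decreasing rho
    pair_detail: list[tuple[str, str, float]] = field(default_factory=list)


def normalize_library_size(table: FeatureTable) -> FeatureTable:
    """Scale each sample column to the median column total (zeros stay zero)."""
    totals = table.counts.sum(axis=0)
    zero = np.nonzero(totals == 0)[0]
    if len(zero):
        raise ValueError(
            f"cannot normalize sample(s) with zero total: "
            f"{[table.sample_ids[i] for i in zero]}"
        )
    return table.with_counts(table.counts * (np.median(totals) / totals))


def combine_tables(host: FeatureTable, microbes: FeatureTable) -> FeatureTable:
    """Stack host and microbe tables into one matrix, aligned to host samples."""
    hs, ms = set(host.sample_ids), set(microbes.sample_ids)
    if hs != ms:
        raise ValueError(
            f"sample ID mismatch; only-host={sorted(hs - ms)[:5]}, "
            f"only-microbe={sorted(ms - hs)[:5]}"
        )
    collision = set(host.feature_ids) & set(microbes.feature_ids)
    if collision:
        raise ValueError(f"feature ID collision: {sorted(collision)[:5]}")
    microbes_aligned = microbes.subset_samples(host.sample_ids)
    return FeatureTable(
        feature_ids=host.feature_ids + microbes_aligned.feature_ids,
        feature_kinds=host.feature_kinds + microbes_aligned.feature_kinds,
        sample_ids=list(host.sample_ids),
        counts=np.vstack([host.counts, microbes_aligned.counts]),
    )


def cluster_features(combined: FeatureTable, k: int) -> FeatureClustering:
    """Cut the average-linkage Spearman tree over features into exactly k clusters.

    ``combined`` is expected on the log2(x+1) scale (see
    :func:`integrate_host_microbiome` for the orchestrated path). Constant
    features are dropped with a warning and listed in the result.
    """
    keep = np.ptp(combined.counts, axis=1) > 0
    retained = [f for f, m in zip(combined.feature_ids, keep) if m]
    dropped = [f for f, m in zip(combined.feature_ids, keep) if not m]
    if dropped:
        logger.warning("dropping %d constant feature(s): %s", len(dropped), dropped[:5])
    if k > len(retained):
        raise ValueError(f"k={k} exceeds {len(retained)} retained features")
    Z = spearman_average_linkage(combined.counts[keep], retained)
    raw = cut_tree(Z, n_clusters=k).ravel()
    return FeatureClustering(
        feature_ids=retained, labels=raw + 1, k=k, dropped_constant=dropped,
    )


def classify_clusters(
    assignment: dict[str, int], kinds: dict[str, str]
) -> list[HeteroClusterRecord]:
    """Label each cluster host_only / microbe_only / heterologous."""
    clusters: dict[int, list[tuple[str, str]]] = {}
    for fid, cid in assignment.items():
        clusters.setdefault(cid, []).append((fid, kinds[fid]))
    records = []
    for cid in sorted(clusters):
        members = sorted(clusters[cid])
        kindset = {k for _, k in members}
        if kindset == {HOST_GENE}:
            cls = HOST_ONLY
        elif kindset == {MICROBE}:
            cls = MICROBE_ONLY
        else:
            cls = HETEROLOGOUS
        records.append(HeteroClusterRecord(
            cluster_id=cid, member_features=members, classification=cls,
        ))
    return records


def class_counts(records: Sequence[HeteroClusterRecord]) -> dict[str, int]:
    counts = {HOST_ONLY: 0, MICROBE_ONLY: 0, HETEROLOGOUS: 0}
    for r in records:
        counts[r.classification] += 1
    return counts


def call_high_confidence(
    records: Sequence[HeteroClusterRecord],
    combined: FeatureTable,
    cfg: IntegrationConfig,
) -> list[HeteroClusterRecord]:
    """Fill pair flags on heterologous clusters.

    For each heterologous cluster, every (gene, microbe) cross-kind pair
    whose members are each non-zero in >= min_presence of samples is
    evaluated; the best pair is the eligible pair with maximal Spearman rho
    (ties break to the lexicographically smallest (gene, microbe) pair), and
    the cluster is high-confidence iff best_rho > rho_min. Clusters with no
    eligible pair get presence_ok=False.
    """
    frame = combined.to_frame()
    n = combined.n_samples
    presence = (frame.to_numpy() != 0).sum(axis=1) / n
    present_ok = dict(zip(combined.feature_ids, presence >= cfg.min_presence))
    row_index = {f: i for i, f in enumerate(combined.feature_ids)}

    out = []
    for rec in records:
        rec = HeteroClusterRecord(
            cluster_id=rec.cluster_id,
            member_features=list(rec.member_features),
            classification=rec.classification,
        )
        if rec.classification != HETEROLOGOUS:
            out.append(rec)
            continue
        genes = sorted(f for f, k in rec.member_features if k == HOST_GENE)
        mics = sorted(f for f, k in rec.member_features if k == MICROBE)
        eligible = [
            (g, m) for g in genes for m in mics
            if present_ok[g] and present_ok[m]
        ]
        if not eligible:
            rec.presence_ok = False
            rec.high_confidence = False
            out.append(rec)
            continue
        feats = sorted({f for pair in eligible for f in pair})
        sub = combined.counts[[row_index[f] for f in feats]]
        rho_mat = spearman_matrix(sub)
        pos = {f: i for i, f in enumerate(feats)}
        detail = [
            (g, m, float(rho_mat[pos[g], pos[m]])) for g, m in eligible
        ]
        detail.sort(key=lambda t: (-t[2], t[0], t[1]))
        best_g, best_m, best_rho = detail[0]
        rec.presence_ok = True
        rec.best_pair = (best_g, best_m)
        rec.best_rho = best_rho
        rec.high_confidence = bool(best_rho > cfg.rho_min)
        rec.pair_detail = detail
        out.append(rec)
    return out


def integrate_host_microbiome(
    host: FeatureTable,
    microbes: FeatureTable,
    cfg: IntegrationConfig | None = None,
) -> tuple[list[HeteroClusterRecord], FeatureClustering]:
    """Run the full integration stage: combine, transform, cluster, classify, call.

    Returns the per-cluster records (flags filled) and the feature clustering.
    """
    cfg = cfg or IntegrationConfig()
    if cfg.normalize:
        host = normalize_library_size(host)
        microbes = normalize_library_size(microbes)
    combined = log2_transform(combine_tables(host, microbes))
    n_clusterable = int((np.ptp(combined.counts, axis=1) > 0).sum())
    k = cfg.effective_k(n_clusterable)
    fc = cluster_features(combined, k)
    kinds = dict(zip(combined.feature_ids, combined.feature_kinds))
    records = classify_clusters(fc.assignment(), kinds)
    records = call_high_confidence(records, combined, cfg)
    return records, fc
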