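"""Reading, writing and validating the tabular inputs of the pipeline.

Three kinds of table flow through the analysis:

* feature count matrices (features x samples, TSV) for host genes and for
  microbial transcripts, wrapped in :class:`FeatureTable`;
* per-sample clinical metadata (group label, stage, treatment flags,
  disease-free-survival time and event), wrapped in :class:`SampleAnnotation`;
* externally produced differential-expression tables (gene, log2 fold change,
  FDR), filtered with :func:`filter_de_table`.

Microbial counts may also be assembled from per-sample PathSeq score files
(:func:`read_pathseq_scores`), keeping only rows of one taxonomic rank.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

HOST_GENE = "host_gene"
MICROBE = "microbe"
VALID_KINDS = (HOST_GENE, MICROBE)

#: canonical metadata column names (External Interfaces contract)
METADATA_COLUMNS = [
    "sample_id", "group", "stage", "grade",
    "neoadjuvant", "adjuvant", "radiation",
    "dfs_time", "dfs_event",
]

#: columns a PathSeq score table must provide
PATHSEQ_COLUMNS = ["tax_id", "taxonomy", "type", "name", "reads", "unambiguous", "score"]


class TableValidationError(ValueError):
    """A table violates a structural invariant (duplicates, negatives, shape)."""


@dataclass
class FeatureTable:
    """Non-negative count matrix (features x samples) with per-feature kind tags.

    Parameters
    ----------
    feature_ids : list of str
        Unique feature identifiers (gene symbols or taxon names), row order.
    feature_kinds : list of str
        One of ``"host_gene"`` / ``"microbe"`` per feature.
    sample_ids : list of str
        Unique sample identifiers, column order.
    counts : ndarray, shape (n_features, n_samples)
        Non-negative real values.
    """

    feature_ids: list[str]
    feature_kinds: list[str]
    sample_ids: list[str]
    counts: np.ndarray

    def __post_init__(self) -> None:
        self.feature_ids = list(map(str, self.feature_ids))
        self.feature_kinds = list(self.feature_kinds)
        self.sample_ids = list(map(str, self.sample_ids))
        self.counts = np.asarray(self.counts, dtype=float)
        dup = _first_duplicate(self.feature_ids)
        if dup is not None:
            raise TableValidationError(f"duplicate feature ID: {dup!r}")
        dup = _first_duplicate(self.sample_ids)
        if dup is not None:
            raise TableValidationError(f"duplicate sample ID: {dup!r}")
        if self.counts.ndim != 2 or self.counts.shape != (
            len(self.feature_ids), len(self.sample_ids)
        ):
            raise TableValidationError(
                f"counts shape {self.counts.shape} does not match "
                f"{len(self.feature_ids)} features x {len(self.sample_ids)} samples"
            )
        if len(self.feature_kinds) != len(self.feature_ids):
            raise TableValidationError("feature_kinds length mismatch")
        bad = set(self.feature_kinds) - set(VALID_KINDS)
        if bad:
            raise TableValidationError(f"unknown feature kind(s): {sorted(bad)}")
        if not np.all(np.isfinite(self.counts)):
            raise TableValidationError("counts contain non-finite values")
        if (self.counts < 0).any():
            i, j = np.argwhere(self.counts < 0)[0]
            raise TableValidationError(
                f"negative count at feature {self.feature_ids[i]!r}, "
                f"sample {self.sample_ids[j]!r}"
            )

    # -- convenience -------------------------------------------------------
    @property
    def n_features(self) -> int:
        return len(self.feature_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def to_frame(self) -> pd.DataFrame:
        """Counts as a DataFrame indexed by feature, columns = samples."""
        return pd.DataFrame(self.counts, index=self.feature_ids, columns=self.sample_ids)

    def kind_of(self, feature_id: str) -> str:
        return self.feature_kinds[self.feature_ids.index(feature_id)]

    def subset_samples(self, sample_ids: Sequence[str]) -> "FeatureTable":
        """Reorder/subset columns to ``sample_ids`` (all must exist)."""
        idx = [self.sample_ids.index(s) for s in sample_ids]
        return FeatureTable(
            feature_ids=list(self.feature_ids),
            feature_kinds=list(self.feature_kinds),
            sample_ids=list(sample_ids),
            counts=self.counts[:, idx],
        )

    def subset_features(self, feature_ids: Sequence[str]) -> "FeatureTable":
        idx = [self.feature_ids.index(f) for f in feature_ids]
        return FeatureTable(
            feature_ids=list(feature_ids),
            feature_kinds=[self.feature_kinds[i] for i in idx],
            sample_ids=list(self.sample_ids),
            counts=self.counts[idx, :],
        )

    def with_counts(self, counts: np.ndarray) -> "FeatureTable":
        """Same IDs/kinds with a replacement matrix (e.g. after a transform)."""
        return FeatureTable(
            feature_ids=list(self.feature_ids),
            feature_kinds=list(self.feature_kinds),
            sample_ids=list(self.sample_ids),
            counts=counts,
        )


@dataclass
class SampleAnnotation:
    """Clinical metadata for one sample.

    ``dfs_time`` is disease-free survival in months; ``dfs_event`` is 1 for an
    event (death or confirmed disease) and 0 for censoring. ``md_cluster`` is
    filled in by the clustering stage and is ``None`` until then. Any clinical
    field may be missing (``None``); analyses drop incomplete samples listwise.
    """

    sample_id: str
    group: str | None = None
    stage: str | None = None
    grade: str | None = None
    neoadjuvant: bool | None = None
    adjuvant: bool | None = None
    radiation: bool | None = None
    dfs_time: float | None = None
    dfs_event: int | None = None
    md_cluster: int | None = None

    def __post_init__(self) -> None:
        if self.dfs_event is not None and self.dfs_event not in (0, 1):
            raise TableValidationError(
                f"sample {self.sample_id!r}: dfs_event must be 0/1, got {self.dfs_event!r}"
            )
        if self.dfs_time is not None and not self.dfs_time > 0:
            raise TableValidationError(
                f"sample {self.sample_id!r}: dfs_time must be > 0, got {self.dfs_time!r}"
            )


@dataclass(frozen=True)
class DeTableRow:
    """One row of an externally produced differential-expression table."""

    gene_id: str
    l2fc: float
    fdr: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.fdr <= 1.0:
            raise TableValidationError(
                f"gene {self.gene_id!r}: FDR {self.fdr} outside [0, 1]"
            )


# ---------------------------------------------------------------------------
# feature tables
# ---------------------------------------------------------------------------

def _first_duplicate(items: Iterable[str]) -> str | None:
    seen: set[str] = set()
    for x in items:
        if x in seen:
            return x
        seen.add(x)
    return None


def read_feature_table(path: str | Path, kind: str) -> FeatureTable:
    """Read a delimited features-x-samples matrix, tagging every feature ``kind``.

    The first column holds feature IDs, the header row sample IDs, and the body
    numeric non-negative values. Row and column order are preserved.
    """
    if kind not in VALID_KINDS:
        raise ValueError(f"kind must be one of {VALID_KINDS}, got {kind!r}")
    df = pd.read_csv(path, sep="\t", index_col=0, dtype={0: str})
    if df.shape[0] == 0:
        raise TableValidationError(f"{path}: no features (header-only file)")
    if df.shape[1] == 0:
        raise TableValidationError(f"{path}: no sample columns")
    numeric = df.apply(pd.to_numeric, errors="coerce")
    if numeric.isna().any().any():
        i, j = np.argwhere(numeric.isna().to_numpy())[0]
        raise TableValidationError(
            f"{path}: non-numeric value {df.iat[i, j]!r} at feature "
            f"{df.index[i]!r}, sample {df.columns[j]!r}"
        )
    return FeatureTable(
        feature_ids=[str(i) for i in df.index],
        feature_kinds=[kind] * df.shape[0],
        sample_ids=[str(c) for c in df.columns],
        counts=numeric.to_numpy(dtype=float),
    )


def write_feature_table(table: FeatureTable, path: str | Path) -> None:
    """Write a TSV that :func:`read_feature_table` reads back identically."""
    df = table.to_frame()
    df.index.name = "feature_id"
    df.to_csv(path, sep="\t")


def read_pathseq_scores(
    paths: dict[str, str | Path],
    level: str = "genus",
    value_column: str = "unambiguous",
) -> FeatureTable:
    """Merge per-sample PathSeq score tables into one microbe count matrix.

    Parameters
    ----------
    paths : dict sample_id -> file path
        One tab-delimited PathSeq score table per sample.
    level : str
        Taxonomic rank to keep (matched against the ``type`` column).
    value_column : {"unambiguous", "reads", "score"}
        Which PathSeq quantity to use as abundance. Unambiguously mapped read
        counts are the default because they avoid double-counting reads that
        hit multiple taxa; the normalized PathSeq score is also accepted.

    Taxa are keyed on the PathSeq ``name`` string; a taxon absent from a
    sample's file gets count 0 for that sample.
    """
    if value_column not in ("unambiguous", "reads", "score"):
        raise ValueError(f"value_column must be unambiguous/reads/score, got {value_column!r}")
    per_sample: dict[str, pd.Series] = {}
    for sample_id, path in paths.items():
        df = pd.read_csv(path, sep="\t")
        missing = [c for c in PATHSEQ_COLUMNS if c not in df.columns]
        if missing:
            raise TableValidationError(f"{path}: missing PathSeq column(s) {missing}")
        sub = df[df["type"].astype(str).str.lower() == level.lower()]
        names = sub["name"].astype(str)
        dup = _first_duplicate(list(names))
        if dup is not None:
            dup_vals = sub.loc[names == dup, value_column].unique()
            if len(dup_vals) > 1:
                raise TableValidationError(
                    f"{path}: conflicting duplicate rows for taxon {dup!r}"
                )
            sub = sub.drop_duplicates(subset="name")
            names = sub["name"].astype(str)
        per_sample[str(sample_id)] = pd.Series(
            sub[value_column].to_numpy(dtype=float), index=list(names)
        )
    merged = pd.DataFrame(per_sample).fillna(0.0)
    # stable taxon order: first appearance across input files
    order: list[str] = []
    for s in per_sample.values():
        for name in s.index:
            if name not in order:
                order.append(name)
    merged = merged.loc[order, list(paths.keys())]
    return FeatureTable(
        feature_ids=list(merged.index),
        feature_kinds=[MICROBE] * merged.shape[0],
        sample_ids=[str(s) for s in merged.columns],
        counts=merged.to_numpy(dtype=float),
    )


# ---------------------------------------------------------------------------
# sample metadata
# ---------------------------------------------------------------------------

def _opt_bool(v) -> bool | None:
    if v is None or (isinstance(v, float) and np.isnan(v)) or v == "":
        return None
    if isinstance(v, (bool, np.bool_)):
        return bool(v)
    s = str(v).strip().lower()
    if s in ("1", "true", "yes", "y"):
        return True
    if s in ("0", "false", "no", "n"):
        return False
    raise TableValidationError(f"cannot parse boolean field value {v!r}")


def _opt_str(v) -> str | None:
    if v is None or (isinstance(v, float) and np.isnan(v)) or str(v) == "":
        return None
    return str(v)


def _opt_float(v) -> float | None:
    if v is None or v == "":
        return None
    f = float(v)
    return None if np.isnan(f) else f


def read_sample_annotations(path: str | Path) -> list[SampleAnnotation]:
    """Read the metadata TSV (columns of :data:`METADATA_COLUMNS`; extras kept aside)."""
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str})
    if "sample_id" not in df.columns:
        raise TableValidationError(f"{path}: missing required column 'sample_id'")
    anns = []
    for _, row in df.iterrows():
        ev = _opt_float(row.get("dfs_event"))
        anns.append(SampleAnnotation(
            sample_id=str(row["sample_id"]),
            group=_opt_str(row.get("group")),
            stage=_opt_str(row.get("stage")),
            grade=_opt_str(row.get("grade")),
            neoadjuvant=_opt_bool(row.get("neoadjuvant")),
            adjuvant=_opt_bool(row.get("adjuvant")),
            radiation=_opt_bool(row.get("radiation")),
            dfs_time=_opt_float(row.get("dfs_time")),
            dfs_event=None if ev is None else int(ev),
            md_cluster=(lambda m: None if m is None else int(m))(_opt_float(row.get("md_cluster"))),
        ))
    dup = _first_duplicate([a.sample_id for a in anns])
    if dup is not None:
        raise TableValidationError(f"{path}: duplicate sample_id {dup!r}")
    return anns


def write_sample_annotations(anns: Sequence[SampleAnnotation], path: str | Path) -> None:
    rows = []
    for a in anns:
        rows.append({
            "sample_id": a.sample_id, "group": a.group, "stage": a.stage,
            "grade": a.grade,
            "neoadjuvant": a.neoadjuvant, "adjuvant": a.adjuvant,
            "radiation": a.radiation, "dfs_time": a.dfs_time,
            "dfs_event": a.dfs_event, "md_cluster": a.md_cluster,
        })
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# DE tables
# ---------------------------------------------------------------------------

def read_de_table(path: str | Path) -> list[DeTableRow]:
    """Read an external DE table TSV with columns gene_id, l2fc, fdr."""
    df = pd.read_csv(path, sep="\t", dtype={"gene_id": str})
    for col in ("gene_id", "l2fc", "fdr"):
        if col not in df.columns:
            raise TableValidationError(f"{path}: missing column {col!r}")
    return [
        DeTableRow(gene_id=str(r.gene_id), l2fc=float(r.l2fc), fdr=float(r.fdr))
        for r in df.itertuples()
    ]


def filter_de_table(
    rows: Sequence[DeTableRow],
    l2fc_min: float = 1.0,
    fdr_max: float = 0.05,
) -> tuple[list[DeTableRow], list[DeTableRow]]:
    """Partition DE rows into (upregulated, downregulated) at inclusive thresholds.

    Upregulated: l2fc >= l2fc_min and fdr <= fdr_max.
    Downregulated: l2fc <= -l2fc_min and fdr <= fdr_max.
    Rows meeting neither are dropped; the partition is disjoint for l2fc_min > 0.
    """
    up = [r for r in rows if r.l2fc >= l2fc_min and r.fdr <= fdr_max]
    down = [r for r in rows if r.l2fc <= -l2fc_min and r.fdr <= fdr_max]
    return up, down
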