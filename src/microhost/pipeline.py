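"""End-to-end orchestration: simulate/load -> MD-Clusters -> differential
abundance -> host-microbe integration -> survival stratification.

Produces a report bundle in an output directory:

* ``report.json`` — the :class:`PipelineReport` (schema shipped as
  ``report_schema.json`` next to this module);
* ``md_cluster_labels.tsv``, ``markers.tsv``, ``hetero_pairs.tsv`` — stage
  tables;
* ``MANIFEST.json`` — stages completed, written even when a stage fails so
  partial output remains interpretable.

All randomness flows from the single top-level seed (the synthetic
generator is the only stochastic stage). Logging goes to stderr; results
never do.
"""

from __future__ import annotations

import json
import logging
import time
from pathlib import Path
from typing import Any, Optional

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field

from . import __version__
from .clustering import (associate_clusters_with_group, cluster_samples,
                         relative_abundance)
from .integration import (HETEROLOGOUS, IntegrationConfig, class_counts,
                          integrate_host_microbiome)
from .io import (FeatureTable, SampleAnnotation, read_feature_table,
                 read_sample_annotations, write_sample_annotations)
from .markers import select_markers
from .simulate import SimulationConfig, simulate_cohort, write_cohort
from .survival import cox_ph, km_fit, logrank_test, median_split

logger = logging.getLogger(__name__)

STAGES = ["input", "mdcluster", "diffabund", "integrate", "survive"]


class PipelineError(RuntimeError):
    """A stage failed; the MANIFEST records how far the run got."""


# ---------------------------------------------------------------------------
# report schema (pydantic model; JSON Schema shipped alongside)
# ---------------------------------------------------------------------------

class ClusterAssociation(BaseModel):
    table: list[list[int]]
    test_name: str
    p_value: float = Field(ge=0, le=1)


class MdClusterSection(BaseModel):
    k: int
    labels: dict[str, int]
    cluster_sizes: dict[str, int]
    association: Optional[ClusterAssociation] = None


class MarkerRow(BaseModel):
    feature_id: str
    delta: float
    t_statistic: float
    p_value: float = Field(ge=0, le=1)
    q_value: float = Field(ge=0, le=1)
    significant: bool


class HighConfidencePair(BaseModel):
    cluster_id: int
    gene_id: str
    microbe_id: str
    rho: float = Field(ge=-1, le=1)


class IntegrationSection(BaseModel):
    k: int
    host_only: int
    microbe_only: int
    heterologous: int
    n_high_confidence: int
    high_confidence_pairs: list[HighConfidencePair]


class LogrankRow(BaseModel):
    stratification: str
    groups: dict[str, int]
    statistic: float
    p_value: float = Field(ge=0, le=1)


class CoxRow(BaseModel):
    covariate: str
    coefficient: float
    hazard_ratio: float
    p_value: float = Field(ge=0, le=1)


class CoxSection(BaseModel):
    feature: str
    mode: str  # binary (median split) or continuous
    converged: bool
    n: int
    n_events: int
    rows: list[CoxRow]


class SurvivalSection(BaseModel):
    logrank: list[LogrankRow]
    cox: Optional[CoxSection] = None


class PipelineReport(BaseModel):
    """Schema of report.json; class counts always sum to the integration K."""

    version: str
    seed: int
    config: dict[str, Any]
    md_cluster: MdClusterSection
    markers: list[MarkerRow]
    integration: IntegrationSection
    survival: SurvivalSection


def report_json_schema() -> dict:
    return PipelineReport.model_json_schema()


# ---------------------------------------------------------------------------
# orchestration
# ---------------------------------------------------------------------------

def _load_inputs(config: dict, outdir: Path, seed: int):
    if config.get("simulate", True):
        sim_kwargs = dict(config.get("simulation", {}))
        sim_kwargs["seed"] = seed
        sim_cfg = SimulationConfig(**sim_kwargs)
        host, microbes, ann, truth = simulate_cohort(sim_cfg)
        write_cohort(outdir, host, microbes, ann, truth)
        return host, microbes, ann
    paths = config.get("inputs", {})
    for key in ("host", "microbes", "metadata"):
        if key not in paths:
            raise PipelineError(f"simulate=false requires inputs.{key}")
        if not Path(paths[key]).exists():
            raise PipelineError(f"input file not found: {paths[key]}")
    host = read_feature_table(paths["host"], kind="host_gene")
    microbes = read_feature_table(paths["microbes"], kind="microbe")
    ann = read_sample_annotations(paths["metadata"])
    return host, microbes, ann


def _survival_frame(ann: list[SampleAnnotation]) -> pd.DataFrame:
    rows = [
        {"sample_id": a.sample_id, "time": a.dfs_time, "event": a.dfs_event,
         "group": a.group, "md_cluster": a.md_cluster, "stage": a.stage}
        for a in ann
        if a.dfs_time is not None and a.dfs_event is not None
    ]
    return pd.DataFrame(rows)


def _logrank_row(name: str, df: pd.DataFrame, labels: pd.Series) -> LogrankRow | None:
    mask = labels.notna()
    sub, lab = df[mask], labels[mask]
    if lab.nunique() != 2:
        return None
    res = logrank_test(sub["time"].to_numpy(), sub["event"].to_numpy(),
                       lab.to_numpy())
    sizes = lab.value_counts().to_dict()
    return LogrankRow(stratification=name,
                      groups={str(k): int(v) for k, v in sizes.items()},
                      statistic=res.statistic, p_value=res.p_value)


def run_pipeline(config: dict, outdir: str | Path) -> PipelineReport:
    """Run every stage in order and write the report bundle to ``outdir``."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    seed = int(config.get("seed", 0))
    completed: list[str] = []
    manifest_path = outdir / "MANIFEST.json"

    def _manifest(status: str) -> None:
        manifest_path.write_text(json.dumps(
            {"status": status, "completed_stages": completed}, indent=2))

    try:
        t0 = time.perf_counter()
        host, microbes, ann = _load_inputs(config, outdir, seed)
        completed.append("input")
        logger.info("input stage done (%.2fs): %d genes, %d microbes, %d samples",
                    time.perf_counter() - t0, host.n_features,
                    microbes.n_features, host.n_samples)

        # --- MD-Clusters -------------------------------------------------
        t0 = time.perf_counter()
        k = int(config.get("md_cluster_k", 2))
        clustering = cluster_samples(relative_abundance(microbes), k=k)
        for a in ann:
            if a.sample_id in clustering.sample_ids:
                a.md_cluster = clustering.label_of(a.sample_id)
        assoc = None
        try:
            res = associate_clusters_with_group(clustering, ann)
            assoc = ClusterAssociation(
                table=[list(r) for r in res.table],
                test_name=res.test_name, p_value=res.p_value)
        except Exception as exc:  # association is best-effort (needs 2x2)
            logger.warning("cluster/group association skipped: %s", exc)
        md_section = MdClusterSection(
            k=clustering.k,
            labels={s: int(l) for s, l in zip(clustering.sample_ids, clustering.labels)},
            cluster_sizes={str(c): int((clustering.labels == c).sum())
                           for c in range(1, clustering.k + 1)},
            association=assoc,
        )
        pd.DataFrame({"sample_id": clustering.sample_ids,
                      "md_cluster": clustering.labels}).to_csv(
            outdir / "md_cluster_labels.tsv", sep="\t", index=False)
        write_sample_annotations(ann, outdir / "metadata_with_clusters.tsv")
        completed.append("mdcluster")
        logger.info("mdcluster stage done (%.2fs)", time.perf_counter() - t0)

        # --- differential abundance --------------------------------------
        t0 = time.perf_counter()
        alpha = float(config.get("alpha", 0.05))
        markers = select_markers(microbes, ann, alpha=alpha,
                                 group_a=config.get("group_a"),
                                 variant=config.get("t_test_variant", "student"))
        marker_rows = [MarkerRow(
            feature_id=m.feature_id, delta=m.delta, t_statistic=m.t_statistic,
            p_value=m.p_value, q_value=m.q_value, significant=m.significant)
            for m in markers]
        pd.DataFrame([m.__dict__ for m in markers]).to_csv(
            outdir / "markers.tsv", sep="\t", index=False)
        completed.append("diffabund")
        logger.info("diffabund stage done (%.2fs): %d/%d significant",
                    time.perf_counter() - t0,
                    sum(m.significant for m in markers), len(markers))

        # --- integration ---------------------------------------------------
        t0 = time.perf_counter()
        int_cfg = IntegrationConfig(**config.get("integration", {}))
        records, fc = integrate_host_microbiome(host, microbes, int_cfg)
        counts = class_counts(records)
        hc_pairs = [
            HighConfidencePair(cluster_id=r.cluster_id, gene_id=r.best_pair[0],
                               microbe_id=r.best_pair[1], rho=r.best_rho)
            for r in records if r.high_confidence
        ]
        pair_rows = []
        for r in records:
            if r.classification != HETEROLOGOUS:
                continue
            for g, m, rho in r.pair_detail:
                pair_rows.append({
                    "cluster_id": r.cluster_id, "gene_id": g, "microbe_id": m,
                    "rho": rho, "high_confidence_cluster": r.high_confidence,
                    "is_best_pair": (g, m) == r.best_pair,
                })
        pd.DataFrame(pair_rows, columns=[
            "cluster_id", "gene_id", "microbe_id", "rho",
            "high_confidence_cluster", "is_best_pair"]).to_csv(
            outdir / "hetero_pairs.tsv", sep="\t", index=False)
        integration_section = IntegrationSection(
            k=fc.k, host_only=counts["host_only"],
            microbe_only=counts["microbe_only"],
            heterologous=counts["heterologous"],
            n_high_confidence=len(hc_pairs),
            high_confidence_pairs=hc_pairs,
        )
        completed.append("integrate")
        logger.info("integrate stage done (%.2fs): K=%d, %d high-confidence",
                    time.perf_counter() - t0, fc.k, len(hc_pairs))

        # --- survival ------------------------------------------------------
        t0 = time.perf_counter()
        surv = _survival_frame(ann)
        logranks: list[LogrankRow] = []
        cox_section = None
        if len(surv) >= 4 and surv["event"].sum() > 0:
            row = _logrank_row("group", surv, surv["group"])
            if row:
                logranks.append(row)
            row = _logrank_row("md_cluster", surv, surv["md_cluster"])
            if row:
                logranks.append(row)
            # median-split stratification on each high-confidence pair member
            strat_features: list[str] = []
            for p in hc_pairs[: int(config.get("max_survival_features", 4))]:
                strat_features.extend([p.gene_id, p.microbe_id])
            combined_frames = {**dict(zip(host.feature_ids, host.counts)),
                               **dict(zip(microbes.feature_ids, microbes.counts))}
            sample_pos = {s: i for i, s in enumerate(host.sample_ids)}
            for feat in dict.fromkeys(strat_features):
                vec = combined_frames[feat]
                vals = np.array([vec[sample_pos[s]] for s in surv["sample_id"]])
                try:
                    labels = pd.Series(median_split(np.log2(vals + 1)),
                                       index=surv.index)
                except Exception as exc:
                    logger.warning("median split skipped for %s: %s", feat, exc)
                    continue
                row = _logrank_row(f"median:{feat}", surv, labels)
                if row:
                    logranks.append(row)
            # Cox adjustment on the first stratification feature, if any
            cox_feature = config.get("cox_feature")
            if cox_feature is None and strat_features:
                cox_feature = strat_features[0]
            if cox_feature is not None and cox_feature in combined_frames:
                cox_section = _fit_cox(surv, combined_frames[cox_feature],
                                       sample_pos, cox_feature,
                                       mode=config.get("cox_mode", "binary"))
        survival_section = SurvivalSection(logrank=logranks, cox=cox_section)
        completed.append("survive")
        logger.info("survive stage done (%.2fs)", time.perf_counter() - t0)

        report = PipelineReport(
            version=__version__, seed=seed, config=config,
            md_cluster=md_section, markers=marker_rows,
            integration=integration_section, survival=survival_section,
        )
        (outdir / "report.json").write_text(report.model_dump_json(indent=2))
        _manifest("ok")
        return report
    except Exception as exc:
        _manifest(f"failed: {exc}")
        if isinstance(exc, PipelineError):
            raise
        raise PipelineError(f"stage after {completed} failed: {exc}") from exc


def _fit_cox(surv: pd.DataFrame, feature_vec: np.ndarray,
             sample_pos: dict[str, int], feature_name: str,
             mode: str = "binary") -> CoxSection | None:
    vals = np.log2(np.array(
        [feature_vec[sample_pos[s]] for s in surv["sample_id"]]) + 1.0)
    df = surv.copy()
    if mode == "binary":
        try:
            df["feature_high"] = (median_split(vals) == "high").astype(float)
        except Exception:
            return None
        feat_col = "feature_high"
    else:
        if np.ptp(vals) == 0:
            return None
        feat_col = "feature_log2"
        df[feat_col] = vals
    covs = pd.DataFrame(index=df.index)
    covs[feat_col] = df[feat_col]
    if df["group"].nunique() == 2:
        covs["group_b"] = (df["group"] == sorted(df["group"].unique())[1]).astype(float)
    if df["md_cluster"].notna().all() and df["md_cluster"].nunique() == 2:
        covs["md_cluster_2"] = (df["md_cluster"] == 2).astype(float)
    stage_map = {"I": 1.0, "II": 2.0, "III": 3.0, "IV": 4.0}
    stages = df["stage"].map(stage_map)
    if stages.notna().all() and stages.nunique() > 1:
        covs["stage"] = stages
    covs = covs.loc[:, covs.nunique() > 1]
    try:
        fit = cox_ph(df["time"].to_numpy(), df["event"].to_numpy(), covs)
    except Exception as exc:
        logger.warning("Cox fit skipped: %s", exc)
        return None
    rows = []
    if fit.converged:
        rows = [CoxRow(covariate=c, coefficient=float(b), hazard_ratio=float(h),
                       p_value=float(p))
                for c, b, h, p in zip(fit.covariates, fit.coefficients,
                                      fit.hazard_ratios, fit.p_values)]
    return CoxSection(feature=feature_name, mode=mode, converged=fit.converged,
                      n=fit.n, n_events=fit.n_events, rows=rows)
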