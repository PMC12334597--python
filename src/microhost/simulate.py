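"""Synthetic two-group tumor cohorts with planted statistical structure.

The generator emulates the data regime the analysis assumes:

* two patient groups (defaults 17 "AA" vs 19 "EA" samples, the size of a
  small single-institution cohort);
* host gene counts drawn negative-binomial around lognormal base means with
  per-sample lognormal library-size factors (dense, over-dispersed RNA-seq
  counts);
* microbial transcript counts drawn zero-inflated negative-binomial (sparse,
  low-abundance taxa typical of tumor microbiomes); the excess-dropout
  probability decays with the expected count
  (``zi * exp(-mean / dropout_scale)``), emulating detection limits — a taxon
  expected at hundreds of reads is essentially never missed entirely, while
  rare taxa frequently are;
* a configurable set of group-differential microbes (group-B means scaled by
  2**diff_l2fc);
* planted host-gene/microbe pairs whose members share a per-sample latent
  factor z ~ N(0, 1) entering both negative-binomial means as
  exp(pair_loading * z) — the log-linear mechanism that produces rank
  correlation robust to the log2(x+1) transform;
* exponential disease-free-survival times whose hazard is proportional to
  exp(log_hr * standardized log2 abundance) of one designated feature, with
  independent uniform censoring.

Everything is reproducible from the single ``seed``; a :class:`SimTruth`
ledger records which features carry which planted effect so that every
pipeline stage can be scored against ground truth.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from .io import (HOST_GENE, MICROBE, FeatureTable, SampleAnnotation,
                 write_feature_table, write_sample_annotations)

GROUP_A = "AA"
GROUP_B = "EA"


@dataclass
class SimulationConfig:
    """All knobs of the synthetic cohort. See the module docstring for the model.

    ``hazard_feature="auto"`` links the hazard to the first planted pair's
    host gene (mirroring a prognostic gene whose correlated microbe is under
    study); ``None`` disables the link and survival is pure baseline noise.
    """

    n_group_a: int = 17
    n_group_b: int = 19
    n_host_genes: int = 300
    n_microbes: int = 60
    n_diff_microbes: int = 8
    diff_l2fc: float = 3.0
    n_hetero_pairs: int = 5
    pair_loading: float = 1.5
    microbe_zero_inflation: float = 0.25
    dropout_scale: float = 30.0  # mean count at which excess dropout decays to 1/e
    nb_dispersion: float = 5.0
    library_size_log_sd: float = 0.3
    hazard_feature: str | None = "auto"
    log_hr: float = 1.0
    baseline_hazard: float = 0.01  # events per month
    censor_rate: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_group_a < 2 or self.n_group_b < 2:
            raise ValueError("each group needs >= 2 samples")
        if self.n_diff_microbes + self.n_hetero_pairs > self.n_microbes:
            raise ValueError(
                "n_diff_microbes + n_hetero_pairs exceeds n_microbes "
                f"({self.n_diff_microbes}+{self.n_hetero_pairs} > {self.n_microbes})"
            )
        if self.n_hetero_pairs > self.n_host_genes:
            raise ValueError("n_hetero_pairs exceeds n_host_genes")
        if not 0.0 <= self.microbe_zero_inflation < 1.0:
            raise ValueError("microbe_zero_inflation must be in [0, 1)")
        if self.dropout_scale <= 0:
            raise ValueError("dropout_scale must be > 0")
        if self.nb_dispersion <= 0:
            raise ValueError("nb_dispersion must be > 0")
        if self.library_size_log_sd < 0:
            raise ValueError("library_size_log_sd must be >= 0")
        if self.baseline_hazard <= 0:
            raise ValueError("baseline_hazard must be > 0")
        if not 0.0 <= self.censor_rate < 1.0:
            raise ValueError("censor_rate must be in [0, 1)")
        if not 0.0 <= self.pair_loading <= 5.0:
            raise ValueError("pair_loading outside a sane range [0, 5]")


@dataclass
class SimTruth:
    """Ground-truth ledger of every planted effect."""

    diff_microbes: dict[str, float]  # microbe id -> true A-vs-B log2 effect
    hetero_pairs: list[tuple[str, str, float]]  # (gene, microbe, loading)
    hazard_feature: str | None
    log_hr: float
    group_assignment: dict[str, str]  # sample id -> group label

    def to_json(self, path: str | Path) -> None:
        payload = asdict(self)
        payload["hetero_pairs"] = [list(t) for t in self.hetero_pairs]
        Path(path).write_text(json.dumps(payload, indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "SimTruth":
        d = json.loads(Path(path).read_text())
        d["hetero_pairs"] = [tuple(t) for t in d["hetero_pairs"]]
        return cls(**d)


def _nb_draw(rng: np.random.Generator, mean: np.ndarray, size_param: float) -> np.ndarray:
    """Negative-binomial draw with mean ``mean`` and variance mean + mean^2/size."""
    mean = np.maximum(np.asarray(mean, dtype=float), 1e-12)
    p = size_param / (size_param + mean)
    return rng.negative_binomial(size_param, p)


def simulate_cohort(
    cfg: SimulationConfig,
) -> tuple[FeatureTable, FeatureTable, list[SampleAnnotation], SimTruth]:
    """Draw one cohort: host table, microbe table, annotations, truth ledger."""
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_group_a + cfg.n_group_b
    sample_ids = [f"S{i + 1:03d}" for i in range(n)]
    groups = [GROUP_A] * cfg.n_group_a + [GROUP_B] * cfg.n_group_b
    is_b = np.array([g == GROUP_B for g in groups])

    gene_ids = [f"gene{i + 1:04d}" for i in range(cfg.n_host_genes)]
    microbe_ids = [f"microbe{i + 1:03d}" for i in range(cfg.n_microbes)]

    # planted-feature selection (disjoint microbe roles keep effects separable)
    mic_perm = rng.permutation(cfg.n_microbes)
    diff_idx = mic_perm[: cfg.n_diff_microbes]
    pair_mic_idx = mic_perm[cfg.n_diff_microbes: cfg.n_diff_microbes + cfg.n_hetero_pairs]
    pair_gene_idx = rng.permutation(cfg.n_host_genes)[: cfg.n_hetero_pairs]

    size_factor = np.exp(rng.normal(0.0, cfg.library_size_log_sd, size=n))

    # host genes: lognormal base means, dense NB counts
    gene_base = np.exp(rng.normal(np.log(50.0), 1.2, size=cfg.n_host_genes))
    gene_mean = np.outer(gene_base, size_factor)

    # microbes: lower lognormal base means, group effect on planted microbes
    mic_base = np.exp(rng.normal(np.log(20.0), 0.8, size=cfg.n_microbes))
    mic_mean = np.outer(mic_base, size_factor)
    mic_mean[np.ix_(diff_idx, np.nonzero(is_b)[0])] *= 2.0 ** cfg.diff_l2fc

    # planted gene-microbe pairs share a per-sample latent factor
    pairs: list[tuple[str, str, float]] = []
    for gi, mi in zip(pair_gene_idx, pair_mic_idx):
        z = rng.normal(0.0, 1.0, size=n)
        bump = np.exp(cfg.pair_loading * z)
        gene_mean[gi] *= bump
        mic_mean[mi] *= bump
        pairs.append((gene_ids[gi], microbe_ids[mi], cfg.pair_loading))

    host_counts = _nb_draw(rng, gene_mean, cfg.nb_dispersion).astype(float)
    mic_counts = _nb_draw(rng, mic_mean, cfg.nb_dispersion).astype(float)
    if cfg.microbe_zero_inflation > 0:
        p_drop = cfg.microbe_zero_inflation * np.exp(-mic_mean / cfg.dropout_scale)
        mic_counts[rng.random(mic_counts.shape) < p_drop] = 0.0

    host = FeatureTable(gene_ids, [HOST_GENE] * cfg.n_host_genes, sample_ids, host_counts)
    microbes = FeatureTable(microbe_ids, [MICROBE] * cfg.n_microbes, sample_ids, mic_counts)

    # survival linked to one feature's standardized log2 abundance
    hazard_feature = cfg.hazard_feature
    if hazard_feature == "auto":
        hazard_feature = pairs[0][0] if pairs else None
    rate = np.full(n, cfg.baseline_hazard)
    if hazard_feature is not None:
        if hazard_feature in gene_ids:
            vec = host_counts[gene_ids.index(hazard_feature)]
        elif hazard_feature in microbe_ids:
            vec = mic_counts[microbe_ids.index(hazard_feature)]
        else:
            raise ValueError(f"hazard_feature {hazard_feature!r} not in the cohort")
        x = np.log2(vec + 1.0)
        sd = x.std()
        xs = (x - x.mean()) / sd if sd > 0 else np.zeros(n)
        rate = cfg.baseline_hazard * np.exp(cfg.log_hr * xs)
    event_time = rng.exponential(1.0 / rate)
    censored = rng.random(n) < cfg.censor_rate
    obs_time = np.where(censored, rng.uniform(0.0, event_time), event_time)
    obs_time = np.maximum(obs_time, 1e-3)
    dfs_event = (~censored).astype(int)

    stages = rng.choice(["II", "III", "IV"], size=n, p=[0.78, 0.19, 0.03])
    grades = rng.choice(["II/III", "III/III"], size=n, p=[0.08, 0.92])
    ann = [
        SampleAnnotation(
            sample_id=s, group=g,
            stage=str(stages[i]), grade=str(grades[i]),
            neoadjuvant=bool(rng.random() < 0.25),
            adjuvant=bool(rng.random() < 0.8),
            radiation=bool(rng.random() < 0.6),
            dfs_time=float(obs_time[i]), dfs_event=int(dfs_event[i]),
        )
        for i, (s, g) in enumerate(zip(sample_ids, groups))
    ]

    truth = SimTruth(
        # A-vs-B log2 effect: group B was scaled up, so the A-minus-B delta
        # a marker test estimates is -diff_l2fc
        diff_microbes={microbe_ids[i]: -cfg.diff_l2fc for i in diff_idx},
        hetero_pairs=pairs,
        hazard_feature=hazard_feature,
        log_hr=cfg.log_hr if hazard_feature is not None else 0.0,
        group_assignment=dict(zip(sample_ids, groups)),
    )
    return host, microbes, ann, truth


def expected_pair_rho(
    pair_loading: float,
    nb_dispersion: float,
    zero_inflation: float,
    n_mc: int = 20000,
    seed: int = 12345,
    gene_mean: float = 50.0,
    microbe_mean: float = 20.0,
    dropout_scale: float = 30.0,
) -> float:
    """Monte-Carlo estimate of the population Spearman rho a loading induces.

    Draws one large synthetic (gene, microbe) pair under the latent-factor
    model and returns the sample Spearman correlation — used to choose
    loadings that land above or below the 0.7 calling threshold.
    """
    from scipy.stats import spearmanr

    rng = np.random.default_rng(seed)
    z = rng.normal(0.0, 1.0, size=n_mc)
    bump = np.exp(pair_loading * z)
    mic_mean = microbe_mean * bump
    g = _nb_draw(rng, gene_mean * bump, nb_dispersion).astype(float)
    m = _nb_draw(rng, mic_mean, nb_dispersion).astype(float)
    if zero_inflation > 0:
        p_drop = zero_inflation * np.exp(-mic_mean / dropout_scale)
        m[rng.random(n_mc) < p_drop] = 0.0
    if np.ptp(g) == 0 or np.ptp(m) == 0:
        return 0.0
    return float(spearmanr(g, m).statistic)


def write_cohort(
    outdir: str | Path,
    host: FeatureTable,
    microbes: FeatureTable,
    ann: list[SampleAnnotation],
    truth: SimTruth,
) -> dict[str, Path]:
    """Write host.tsv / microbes.tsv / metadata.tsv / truth.json to a directory."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "host": outdir / "host.tsv",
        "microbes": outdir / "microbes.tsv",
        "metadata": outdir / "metadata.tsv",
        "truth": outdir / "truth.json",
    }
    write_feature_table(host, paths["host"])
    write_feature_table(microbes, paths["microbes"])
    write_sample_annotations(ann, paths["metadata"])
    truth.to_json(paths["truth"])
    return paths
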