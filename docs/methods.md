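# Methods

This document records the statistical model behind each analysis stage, the
meaning and default of every tunable parameter, what the synthetic-cohort
generator does and does not emulate, and the numerical conventions the
implementation commits to.

## 1. Data model

Two count matrices over the same samples:

- **Host table** — gene × sample RNA-seq read counts (nonnegative integers
  or floats).
- **Microbe table** — genus × sample taxonomic read counts, typically from
  per-sample taxonomic classification score files (`read_pathseq_scores`
  merges these, keying on the genus name and filling absent taxa with 0;
  conflicting duplicate entries are an error, not a silent overwrite).

Sample metadata carries patient group, disease stage, disease-free-survival
time (`dfs_time` > 0, in months) and event indicator (`dfs_event` ∈ {0, 1}).

## 2. MD-clustering (microbially derived sample clusters)

1. Convert microbial counts to **relative abundance** per sample (columns sum
   to 1; an all-zero sample is an error naming the sample, because its
   profile is undefined).
2. Distance between samples = **1 − Spearman ρ** of their abundance
   profiles. Rank correlation is used because genus abundances are heavily
   skewed and the read depth varies per sample; ranks remove both effects
   without choosing a normalization.
3. **Average-linkage** hierarchical clustering, cut at exactly K clusters
   (default **K = 2**, matching a two-group cohort design). Constant
   features are dropped with a warning before ranking (they carry no order
   information). Cluster labels are canonicalized by decreasing size, ties
   broken by smallest member sample.
4. Association between cluster membership and a binary sample attribute is a
   **Fisher exact test** (two-sided, point-probability rule: the p-value sums
   all tables with point probability ≤ the observed one). Samples with a
   missing attribute are dropped; the test requires the result to be 2 × 2.

## 3. Clinical contingency statistics

- r × c tables with r or c > 2: **Pearson chi-square without continuity
  correction** (df = (r−1)(c−1)).
- 2 × 2 tables: **Yates-corrected chi-square**; the correction clamps at
  zero, so a table whose corrected statistic would be negative reports
  χ² = 0, p = 1 exactly.
- A zero row/column margin is an error for chi-square; for Fisher a zero
  margin yields p = 1 (only one table is possible).

## 4. Marker selection (differential abundance)

- Transform: **log2(count + 1)** per cell. The +1 pseudocount keeps zeros
  finite and is the conventional variance-stabilizer for count data at this
  depth.
- Test: **two-sample Student t** (pooled variance) per genus between groups;
  a Welch variant is available (`variant="welch"`). Genera that are all-zero
  in both groups are excluded from testing (and from the multiple-testing
  denominator).
- Multiplicity: **Benjamini–Hochberg step-up** over the tested genera;
  significance at **q ≤ 0.05**.
- Effect direction: `delta = mean_log2(group A) − mean_log2(group B)`.
- Output rows are sorted by (q, −|t|, feature id) so results are stable.

The exact **Wilcoxon rank-sum** test is provided as a companion
nonparametric test: for combined n ≤ 12 the null distribution of the rank
sum is enumerated exactly over all assignments (midranks for ties; two-sided
p = 2 × smaller tail, capped at 1); larger samples use the tie-corrected
normal approximation with continuity correction.

## 5. Host–microbiome integration

1. **Library-size normalization** (on by default): each table's columns are
   scaled so every sample's total equals the table's median total. Without
   this, a shared per-sample depth factor induces positive correlation
   between *all* feature pairs and inflates spurious gene–microbe calls.
   Normalization is per table because host and microbial depths are
   unrelated.
2. log2(x + 1), then the host and microbe tables are stacked (sample sets
   must match; duplicate feature ids across tables are an error).
3. **Feature clustering**: average linkage on 1 − Spearman ρ between feature
   profiles, cut at exactly **K = min(n_clusters, n_features // 2)** with
   `n_clusters` defaulting to 1000. The `// 2` cap guarantees K is feasible
   while keeping clusters small, so membership in a cluster is itself
   evidence of co-variation. Constant features are dropped and reported; K
   is computed from the retained count.
4. Each cluster is classified **host-only / microbe-only / heterologous**
   (contains both kinds). The three class counts always partition K.
5. **High-confidence pair calling** within each heterologous cluster:
   - every gene–microbe pair must pass a **presence gate** — both members
     nonzero in ≥ `min_presence` (default **0.5**) of samples — before its
     ρ is considered, so a correlation driven by shared zeros cannot win;
   - the **best pair** is the one with the largest Spearman ρ among gated
     pairs (ties broken lexicographically);
   - the cluster is high-confidence iff best ρ > `rho_min` (default
     **0.7**), a threshold high enough that unrelated count vectors at
     n ≈ 36 rarely cross it (the test suite measures this null rate
     directly).

## 6. Survival analysis

- **Kaplan–Meier** product-limit curves; `survival_at(t)` is the step
  function evaluated at t.
- **Log-rank test** (df = 1 for two groups). With zero events the
  convention is (statistic, p) = (0, 1).
- **Median split** of a feature: values strictly above the median are
  "high"; **ties at the median go to "low"**. A feature whose median split
  would leave one side empty is a degenerate-input error.
- **Cox proportional hazards** with **Breslow tie handling**. A constant
  covariate is rejected up front; the fit requires at least as many events
  as covariates. Convergence warnings are escalated: a fit that fails to
  converge (monotone likelihood / separation, common at n ≈ 36 with few
  events) is reported with `converged = False` and NaN hazard ratios
  rather than inflated estimates.

## 7. Synthetic-cohort generator

Defaults describe the study conditions the package targets:
two groups of **17 and 19** samples, **300** host genes, **60** microbial
genera.

| Parameter | Default | Meaning / rationale |
|---|---|---|
| `n_group_a`, `n_group_b` | 17, 19 | cohort group sizes |
| `n_host_genes` | 300 | host panel size (keeps K-clustering fast) |
| `n_microbes` | 60 | genus panel size |
| `n_diff_microbes` | 8 | planted group-differential genera |
| `diff_l2fc` | 3.0 | log2 fold change of group B means for planted genera |
| `n_hetero_pairs` | 5 | planted correlated gene–microbe pairs |
| `pair_loading` | 1.5 | latent-factor loading; `expected_pair_rho` maps loading → population Spearman ρ by Monte-Carlo (e.g. 2.5 → ≈ 0.9) |
| `microbe_zero_inflation` | 0.25 | maximum excess dropout probability for rare genera |
| `dropout_scale` | 30.0 | mean-abundance scale of dropout decay (counts) |
| `nb_dispersion` | 5.0 | NB size parameter (variance = m + m²/size) |
| `library_size_log_sd` | 0.3 | lognormal per-sample depth factor sd |
| `log_hr` | 1.0 | planted log hazard ratio per sd of log2 abundance |
| `baseline_hazard` | 0.01 | exponential baseline hazard (1/month) |
| `censor_rate` | 0.5 | Bernoulli probability of uniform censoring |
| `hazard_feature` | "auto" | the first planted pair's gene carries the hazard |
| `seed` | 0 | all randomness from one `numpy` Generator |

Mechanics:

- Host counts are **negative binomial** around lognormal base means
  (ln-mean ln 50, sd 1.2) times a per-sample lognormal depth factor.
- Microbe counts are **zero-inflated negative binomial** (base means around
  ln 20, sd 0.8). Excess dropout is **abundance-dependent**:
  `p_drop = zi · exp(−mean / dropout_scale)`, modeling a detection limit —
  rare genera are frequently missed entirely, abundant ones almost never.
  (A constant dropout rate would add ≈ π(1−π)·log2(mean)² of variance on
  the log2 scale to *every* genus, which at n = 17/19 makes even an 8-fold
  planted difference statistically invisible; abundance-dependent dropout is
  both the more realistic mechanism and the one under which the planted
  effects are recoverable.)
- Planted differential genera multiply the group-B mean by `2^diff_l2fc`;
  the truth ledger stores the effect in A − B orientation (−`diff_l2fc`).
- Planted pairs share a latent `z ~ N(0, 1)` per sample; both members'
  means are multiplied by `exp(loading · z)`.
- Survival times are exponential with hazard
  `baseline_hazard · exp(log_hr · standardized log2 abundance)` of the
  hazard feature; censoring is Bernoulli(`censor_rate`) with uniform
  censoring times.

**What the generator does not emulate:** compositionality constraints
(genera are drawn independently, not as a closed composition),
batch/contamination structure, taxonomic misassignment,
gene–gene co-expression modules beyond the planted pairs, non-proportional
hazards, and informative censoring. Conclusions about those phenomena
cannot be drawn from these cohorts.

## 8. Numerical conventions

- Spearman ρ uses midranks and is clipped to [−1, 1]; a constant vector is
  a degenerate-input error (ρ undefined), and matrices are ranked
  column-wise and correlated via one `corrcoef` call.
- Hierarchical cuts use exact-K tree cutting, never a distance threshold,
  so K is always honored.
- BH adjustment is the standard step-up with a running minimum; adjusted
  values are capped at 1.
- Fisher's exact two-sided rule is the point-probability rule (tables with
  probability ≤ observed, within a 1 + 10⁻⁹ relative tolerance in the
  test oracle).
- All simulations draw from `numpy.random.default_rng(seed)`; identical
  seeds give bit-identical cohorts and byte-identical pipeline reports.
- `expected_pair_rho` is itself Monte-Carlo (default 20 000 draws, fixed
  internal seed) and is treated as a calibration utility, not a test
  statistic.

## 9. Limitations

- At n ≈ 36 the chi-square and log-rank approximations are only roughly
  calibrated; the test suite measures the log-rank type-I rate under an
  all-events exponential null and requires it to sit in [0.03, 0.07] at
  α = 0.05 rather than pretending exactness.
- High-confidence pair calling takes a maximum over many within-cluster
  pairs, which inflates the null tail of the best ρ; precision of pair
  recovery therefore varies seed to seed and should be read as a
  Monte-Carlo estimate, not a guarantee.
- The multivariate Cox model frequently fails to converge at this cohort
  size (few events, separation); the package reports that honestly instead
  of returning unstable hazard ratios, so downstream consumers must handle
  `converged = False`.
- Marker testing uses per-genus t-tests on log2 counts, not a
  count-model GLM; with heavier zero inflation than the generator's default
  a rank-based or hurdle model would be more appropriate.
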