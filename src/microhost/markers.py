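"""Differential microbial abundance between two patient groups.

Comparative marker selection: counts are log2(x+1) transformed, each microbe
is tested with a two-sample t-test between the groups (pooled-variance
Student by default, Welch by flag), p-values are Benjamini-Hochberg
adjusted across all tested microbes, and markers are called at q <= alpha.

The tests run on raw log2(counts+1), not relative abundance — the sample
clustering stage alone normalizes to proportions. Microbes that are zero in
every sample are excluded before testing (shrinking m for the BH adjustment)
and logged.

Sign convention: ``delta = mean_log2_a - mean_log2_b``, so delta > 0 means
higher abundance in group A. Group A defaults to the lexicographically first
group label; pass ``group_a`` to pin the orientation explicitly.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .io import FeatureTable, SampleAnnotation
from .stats import DegenerateInputError, bh_adjust, t_test

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class MarkerResult:
    feature_id: str
    mean_log2_a: float
    mean_log2_b: float
    delta: float
    t_statistic: float
    p_value: float
    q_value: float
    significant: bool


def log2_transform(counts: FeatureTable) -> FeatureTable:
    """Replace every cell x by log2(x + 1)."""
    return counts.with_counts(np.log2(counts.counts + 1.0))


def select_markers(
    microbes: FeatureTable,
    ann: Sequence[SampleAnnotation],
    alpha: float = 0.05,
    group_a: str | None = None,
    variant: str = "student",
) -> list[MarkerResult]:
    """Call differentially abundant microbes between two groups at FDR alpha.

    Returns one :class:`MarkerResult` per tested microbe, sorted by q-value
    then decreasing |t|. Deterministic for a given input.
    """
    by_id = {a.sample_id: a for a in ann}
    groups = sorted({
        by_id[s].group for s in microbes.sample_ids
        if s in by_id and by_id[s].group is not None
    })
    if len(groups) != 2:
        raise DegenerateInputError(f"need exactly two groups, found {groups}")
    if group_a is None:
        group_a = groups[0]
    elif group_a not in groups:
        raise ValueError(f"group_a={group_a!r} not among groups {groups}")
    group_b = next(g for g in groups if g != group_a)

    idx_a = [i for i, s in enumerate(microbes.sample_ids)
             if s in by_id and by_id[s].group == group_a]
    idx_b = [i for i, s in enumerate(microbes.sample_ids)
             if s in by_id and by_id[s].group == group_b]
    if len(idx_a) < 2 or len(idx_b) < 2:
        raise DegenerateInputError(
            f"each group needs >= 2 samples (got {len(idx_a)}/{len(idx_b)})"
        )

    log2 = log2_transform(microbes)
    nonzero = log2.counts[:, idx_a + idx_b].sum(axis=1) > 0
    if not nonzero.all():
        dropped = [f for f, m in zip(log2.feature_ids, nonzero) if not m]
        logger.info("excluding %d all-zero microbe(s) before testing: %s",
                    len(dropped), dropped[:5])

    tested_ids, stats_t, pvals, means_a, means_b = [], [], [], [], []
    for i in np.nonzero(nonzero)[0]:
        va = log2.counts[i, idx_a]
        vb = log2.counts[i, idx_b]
        res = t_test(va, vb, variant=variant)
        tested_ids.append(log2.feature_ids[i])
        stats_t.append(res.statistic)
        pvals.append(res.p_value)
        means_a.append(float(va.mean()))
        means_b.append(float(vb.mean()))

    if not tested_ids:
        return []
    qvals = bh_adjust(pvals)
    results = [
        MarkerResult(
            feature_id=f,
            mean_log2_a=ma, mean_log2_b=mb, delta=ma - mb,
            t_statistic=t, p_value=p, q_value=float(q),
            significant=bool(q <= alpha),
        )
        for f, ma, mb, t, p, q in zip(tested_ids, means_a, means_b, stats_t, pvals, qvals)
    ]
    results.sort(key=lambda r: (r.q_value, -abs(r.t_statistic), r.feature_id))
    return results
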