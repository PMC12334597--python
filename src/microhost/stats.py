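"""Statistical primitives shared by every stage of the pipeline.

Thin, convention-pinning wrappers over scipy.stats / statsmodels. The
conventions matter more than the arithmetic:

* the two-sided Fisher exact p is the point-probability ("minimum-likelihood")
  sum — the rule scipy implements and the one that reproduces classical
  2x2 contingency reporting;
* the Yates continuity correction subtracts min(0.5, |O-E|) from each |O-E|,
  so a 2x2 table that is nearly independent clamps to X^2 = 0, p = 1;
* the Wilcoxon rank-sum test is exact (full enumeration over group
  assignments, midranks for ties) when n_a + n_b <= 12 and a tie-corrected
  normal approximation otherwise;
* Benjamini-Hochberg adjustment is the classical step-up, returning q-values
  in input order.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Sequence

import numpy as np
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests


class DegenerateInputError(ValueError):
    """Input admits no defined test statistic (constant vectors, bad shapes)."""


@dataclass(frozen=True)
class TestResult:
    """Statistic + two-sided p-value (+ degrees of freedom where defined)."""

    statistic: float
    p_value: float
    df: float | None = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_value <= 1.0:
            raise ValueError(f"p_value {self.p_value} outside [0, 1]")


@dataclass(frozen=True)
class ContingencyResult:
    """Result of a contingency-table test.

    ``statistic`` and ``df`` are ``None`` for the Fisher exact test.
    """

    table: tuple[tuple[int, ...], ...]
    test_name: str  # fisher_exact | chi_square | chi_square_yates
    p_value: float
    statistic: float | None = None
    df: int | None = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_value <= 1.0:
            raise ValueError(f"p_value {self.p_value} outside [0, 1]")


def _as_1d(x, name: str) -> np.ndarray:
    arr = np.asarray(x, dtype=float)
    if arr.ndim != 1:
        raise ValueError(f"{name} must be 1-dimensional")
    if not np.all(np.isfinite(arr)):
        raise ValueError(f"{name} contains non-finite values")
    return arr


# ---------------------------------------------------------------------------
# correlation
# ---------------------------------------------------------------------------

def spearman_rho(x: Sequence[float], y: Sequence[float]) -> float:
    """Spearman rank correlation (Pearson correlation of midranks).

    Requires n >= 3 and neither vector constant; callers that may hold
    constant features must pre-filter them.
    """
    xa, ya = _as_1d(x, "x"), _as_1d(y, "y")
    if len(xa) != len(ya):
        raise ValueError("x and y must have equal length")
    if len(xa) < 3:
        raise DegenerateInputError("spearman_rho needs n >= 3")
    if np.ptp(xa) == 0 or np.ptp(ya) == 0:
        raise DegenerateInputError("spearman_rho undefined for a constant vector")
    return float(sps.spearmanr(xa, ya).statistic)


def rank_matrix(values: np.ndarray, axis: int = 1) -> np.ndarray:
    """Midranks of each row (axis=1) or column (axis=0) of a 2-D array."""
    return np.apply_along_axis(sps.rankdata, axis, np.asarray(values, dtype=float))


def spearman_matrix(values: np.ndarray) -> np.ndarray:
    """All pairwise Spearman correlations between the rows of ``values``.

    Constant rows yield NaN correlations; filter them beforehand when a
    defined distance is required.
    """
    r = rank_matrix(values, axis=1)
    r = r - r.mean(axis=1, keepdims=True)
    norm = np.sqrt((r ** 2).sum(axis=1))
    with np.errstate(invalid="ignore", divide="ignore"):
        c = (r @ r.T) / np.outer(norm, norm)
    return np.clip(c, -1.0, 1.0, out=c)


# ---------------------------------------------------------------------------
# two-sample location tests
# ---------------------------------------------------------------------------

def t_test(a: Sequence[float], b: Sequence[float], variant: str = "student") -> TestResult:
    """Two-sided two-sample t-test.

    variant="student" pools the variance (the marker-selection default);
    variant="welch" does not assume equal variances.

    Two groups with zero variance and equal means return t=0, p=1 by
    convention (such features carry no signal); zero pooled variance with
    unequal means is an error.
    """
    aa, bb = _as_1d(a, "a"), _as_1d(b, "b")
    if len(aa) < 2 or len(bb) < 2:
        raise DegenerateInputError("each group needs n >= 2")
    if variant not in ("student", "welch"):
        raise ValueError(f"variant must be student or welch, got {variant!r}")
    if aa.var(ddof=1) == 0 and bb.var(ddof=1) == 0:
        if aa.mean() == bb.mean():
            df = len(aa) + len(bb) - 2 if variant == "student" else float("nan")
            return TestResult(statistic=0.0, p_value=1.0, df=df)
        raise DegenerateInputError("zero variance in both groups with unequal means")
    res = sps.ttest_ind(aa, bb, equal_var=(variant == "student"))
    return TestResult(statistic=float(res.statistic), p_value=float(res.pvalue),
                      df=float(res.df))


def _rank_sum_exact_p(pooled_ranks: np.ndarray, n_a: int, w_obs: float) -> float:
    """Exact two-sided p for the rank-sum statistic by full enumeration.

    Enumerates every choice of n_a positions out of the pooled midranks and
    doubles the smaller tail (capped at 1).
    """
    n = len(pooled_ranks)
    sums = np.array([
        pooled_ranks[list(idx)].sum() for idx in combinations(range(n), n_a)
    ])
    total = len(sums)
    eps = 1e-9
    lo = np.sum(sums <= w_obs + eps) / total
    hi = np.sum(sums >= w_obs - eps) / total
    return float(min(1.0, 2.0 * min(lo, hi)))


def wilcoxon_rank_sum(a: Sequence[float], b: Sequence[float]) -> TestResult:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney) test.

    The statistic is W, the rank sum of the first group in the pooled
    midranking. Exact by enumeration when n_a + n_b <= 12 (handles ties via
    midranks); tie-corrected normal approximation with continuity correction
    otherwise. All values tied across both groups gives p = 1.
    """
    aa, bb = _as_1d(a, "a"), _as_1d(b, "b")
    if len(aa) == 0 or len(bb) == 0:
        raise DegenerateInputError("both groups must be non-empty")
    pooled = np.concatenate([aa, bb])
    if np.ptp(pooled) == 0:
        w = float(sps.rankdata(pooled)[: len(aa)].sum())
        return TestResult(statistic=w, p_value=1.0)
    ranks = sps.rankdata(pooled)
    w = float(ranks[: len(aa)].sum())
    n = len(pooled)
    if n <= 12:
        p = _rank_sum_exact_p(ranks, len(aa), w)
    else:
        res = sps.mannwhitneyu(aa, bb, alternative="two-sided",
                               method="asymptotic", use_continuity=True)
        p = float(res.pvalue)
    return TestResult(statistic=w, p_value=min(1.0, p))


# ---------------------------------------------------------------------------
# multiple testing
# ---------------------------------------------------------------------------

def bh_adjust(p: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, in the input's order."""
    arr = _as_1d(p, "p")
    if len(arr) == 0:
        return np.array([])
    if (arr < 0).any() or (arr > 1).any():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(arr, method="fdr_bh")[1]


# ---------------------------------------------------------------------------
# contingency tables
# ---------------------------------------------------------------------------

def _validate_table(table) -> np.ndarray:
    arr = np.asarray(table)
    if arr.ndim != 2:
        raise ValueError("contingency table must be 2-dimensional")
    if (arr < 0).any():
        raise ValueError("contingency table cells must be non-negative")
    if not np.allclose(arr, np.round(arr)):
        raise ValueError("contingency table cells must be integers")
    return arr.astype(int)


def chi_square_test(table, yates: bool = False) -> ContingencyResult:
    """Pearson chi-square test of independence.

    With ``yates=True`` (2x2 tables only) each |O-E| is reduced by
    min(0.5, |O-E|) before squaring, so the statistic clamps at 0 instead of
    overshooting for near-independent tables.
    """
    arr = _validate_table(table)
    if yates and arr.shape != (2, 2):
        raise ValueError("Yates correction applies to 2x2 tables only")
    if (arr.sum(axis=0) == 0).any() or (arr.sum(axis=1) == 0).any():
        raise DegenerateInputError("chi-square undefined with a zero margin")
    stat, p, df, _ = sps.chi2_contingency(arr, correction=yates)
    return ContingencyResult(
        table=tuple(map(tuple, arr.tolist())),
        test_name="chi_square_yates" if yates else "chi_square",
        statistic=float(stat), df=int(df), p_value=float(p),
    )


def fisher_exact(table) -> ContingencyResult:
    """Two-sided Fisher exact test on a 2x2 table (point-probability rule).

    p = sum of hypergeometric point probabilities not exceeding the observed
    table's point probability. A zero margin gives p = 1 by convention.
    """
    arr = _validate_table(table)
    if arr.shape != (2, 2):
        raise ValueError("fisher_exact requires a 2x2 table")
    if (arr.sum(axis=0) == 0).any() or (arr.sum(axis=1) == 0).any():
        p = 1.0
    else:
        p = float(sps.fisher_exact(arr, alternative="two-sided")[1])
    return ContingencyResult(
        table=tuple(map(tuple, arr.tolist())),
        test_name="fisher_exact", p_value=min(1.0, p),
    )
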