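"""Disease-free-survival analysis.

Kaplan-Meier product-limit estimation, the two-group log-rank test,
median-split stratification of a per-sample feature into high/low groups,
and Cox proportional-hazards fits (Breslow tie handling) — the stack used
to ask whether a microbe's or gene's abundance stratifies outcome.

Estimation delegates to lifelines (KaplanMeierFitter, logrank statistics,
CoxPHFitter); this module pins the conventions: the median split sends
values equal to the median to the "low" arm (ties at the median are common
for sparse microbial counts in small cohorts), a cohort with no events
returns a zero log-rank statistic with p = 1, and a non-converged or
separated Cox fit is reported as such with no hazard ratios.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from scipy.linalg import LinAlgWarning
from lifelines.exceptions import ConvergenceError, ConvergenceWarning
from lifelines.statistics import logrank_test as _ll_logrank

from .stats import DegenerateInputError, TestResult


@dataclass
class KmCurve:
    """Product-limit survival estimate tabulated at the event times."""

    event_times: np.ndarray  # increasing, times with >= 1 observed event
    survival_probs: np.ndarray  # S(t) just after each event time
    at_risk: np.ndarray  # risk-set size just before each event time
    n_events: np.ndarray  # observed events at each event time

    def survival_at(self, t: float) -> float:
        """S(t); 1 before the first event, step function afterwards."""
        idx = np.searchsorted(self.event_times, t, side="right") - 1
        return 1.0 if idx < 0 else float(self.survival_probs[idx])


@dataclass
class CoxFit:
    """A fitted Cox proportional-hazards model (Breslow partial likelihood)."""

    covariates: list[str]
    coefficients: np.ndarray
    hazard_ratios: np.ndarray
    standard_errors: np.ndarray
    p_values: np.ndarray  # Wald
    converged: bool
    n: int = 0
    n_events: int = 0


def _check_surv(times, events) -> tuple[np.ndarray, np.ndarray]:
    t = np.asarray(times, dtype=float)
    e = np.asarray(events, dtype=int)
    if t.ndim != 1 or e.shape != t.shape:
        raise ValueError("times and events must be equal-length vectors")
    if len(t) == 0:
        raise DegenerateInputError("empty survival input")
    if (t <= 0).any():
        raise ValueError("times must be > 0")
    if not set(np.unique(e)).issubset({0, 1}):
        raise ValueError("events must be 0/1")
    return t, e


def km_fit(times, events) -> KmCurve:
    """Kaplan-Meier product-limit estimate S(t) = prod(1 - d_i / n_i)."""
    t, e = _check_surv(times, events)
    kmf = KaplanMeierFitter()
    kmf.fit(t, event_observed=e)
    tbl = kmf.event_table
    ev = tbl[tbl["observed"] > 0]
    event_times = ev.index.to_numpy(dtype=float)
    surv = np.array([float(kmf.survival_function_at_times(x).iloc[0]) for x in event_times])
    return KmCurve(
        event_times=event_times,
        survival_probs=surv,
        at_risk=ev["at_risk"].to_numpy(dtype=int),
        n_events=ev["observed"].to_numpy(dtype=int),
    )


def logrank_test(times, events, group_labels) -> TestResult:
    """Two-group log-rank test (chi-square, df = 1, two-sided)."""
    t, e = _check_surv(times, events)
    g = np.asarray(group_labels)
    if g.shape != t.shape:
        raise ValueError("one group label per subject required")
    labels = sorted(set(g.tolist()))
    if len(labels) != 2:
        raise DegenerateInputError(f"log-rank needs exactly two groups, got {labels}")
    if (np.array([g == l for l in labels]).sum(axis=1) == 0).any():
        raise DegenerateInputError("both groups must be non-empty")
    if e.sum() == 0:
        return TestResult(statistic=0.0, p_value=1.0, df=1)
    m0, m1 = (g == labels[0]), (g == labels[1])
    res = _ll_logrank(t[m0], t[m1], event_observed_A=e[m0], event_observed_B=e[m1])
    return TestResult(statistic=float(res.test_statistic), p_value=float(res.p_value), df=1)


def median_split(values) -> np.ndarray:
    """Dichotomize at the median: value > median -> "high", else "low"."""
    v = np.asarray(values, dtype=float)
    if v.ndim != 1 or len(v) < 2:
        raise ValueError("need a vector of >= 2 values")
    if np.ptp(v) == 0:
        raise DegenerateInputError("degenerate split: all values identical")
    med = float(np.median(v))
    labels = np.where(v > med, "high", "low")
    if len(set(labels.tolist())) < 2:
        raise DegenerateInputError("degenerate split: one arm is empty")
    return labels


def cox_ph(times, events, covariates: pd.DataFrame) -> CoxFit:
    """Fit a Cox PH model (Breslow ties, Newton iteration via lifelines).

    Constant covariates are rejected; a fit that fails to converge (for
    example under monotone separation) is returned with ``converged=False``
    and NaN estimates rather than misleading hazard ratios.
    """
    t, e = _check_surv(times, events)
    if not isinstance(covariates, pd.DataFrame):
        covariates = pd.DataFrame(np.asarray(covariates, dtype=float))
        covariates.columns = [f"x{i}" for i in range(covariates.shape[1])]
    if len(covariates) != len(t):
        raise ValueError("covariates must have one row per subject")
    names = list(covariates.columns)
    const = [c for c in names if covariates[c].nunique() <= 1]
    if const:
        raise DegenerateInputError(f"constant covariate(s): {const}")
    if e.sum() < len(names):
        raise DegenerateInputError(
            f"{int(e.sum())} events for {len(names)} covariates"
        )
    df = covariates.copy()
    df["__time"] = t
    df["__event"] = e
    cph = CoxPHFitter()
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("error", ConvergenceWarning)
            # ill-conditioned Hessians en route to a flagged failure are noise
            warnings.simplefilter("ignore", LinAlgWarning)
            cph.fit(df, duration_col="__time", event_col="__event")
    except (ConvergenceError, ConvergenceWarning, Exception) as exc:  # noqa: BLE001
        if isinstance(exc, (ConvergenceError, ConvergenceWarning)) or \
                "onvergence" in str(exc) or "delta contains nan" in str(exc).lower():
            nan = np.full(len(names), np.nan)
            return CoxFit(covariates=names, coefficients=nan, hazard_ratios=nan,
                          standard_errors=nan, p_values=nan, converged=False,
                          n=len(t), n_events=int(e.sum()))
        raise
    coef = cph.params_.loc[names].to_numpy()
    return CoxFit(
        covariates=names,
        coefficients=coef,
        hazard_ratios=np.exp(coef),
        standard_errors=cph.standard_errors_.loc[names].to_numpy(),
        p_values=cph.summary.loc[names, "p"].to_numpy(),
        converged=True,
        n=len(t), n_events=int(e.sum()),
    )
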