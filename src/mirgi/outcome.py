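"""Survival analysis of score groups and matched-group selection.

Kaplan-Meier estimation, the log-rank test and Cox proportional-hazards
regression are delegated to lifelines (Efron handling of tied event
times).  The matched-group selection algorithm — sort both groups
together on a balancing covariate and keep every adjacent
opposite-label pair — is implemented here; it produces two equal-sized
groups with nearly identical covariate distributions, disentangling the
score's prognostic value from raw mutation burden.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data_io import ValidationError
from .stats import mann_whitney

__all__ = [
    "SurvivalCurve",
    "km_estimate",
    "survival_rate_at",
    "LogrankResult",
    "logrank_test",
    "CoxFit",
    "cox_fit",
    "MatchedGroups",
    "matched_group_selection",
    "balance_test",
]


@dataclass
class SurvivalCurve:
    """Product-limit survival estimate.

    ``times`` are the distinct observed event times (years), prefixed by
    time 0 where survival is 1; ``survival`` is the step-function value
    at each time; ``at_risk`` and ``events`` are the risk-set size and
    event count at each time.
    """

    times: np.ndarray
    survival: np.ndarray
    at_risk: np.ndarray
    events: np.ndarray

    def __post_init__(self) -> None:
        if len(self.times) == 0:
            raise ValidationError("empty survival curve")


def km_estimate(times, events) -> SurvivalCurve:
    """Kaplan-Meier product-limit estimator.

    ``events`` is boolean (True = event observed, False = censored).
    Censored-only data yield a flat curve at 1.
    """
    from lifelines import KaplanMeierFitter

    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=bool)
    if len(times) == 0:
        raise ValidationError("km_estimate requires at least one subject")
    if (times < 0).any():
        raise ValidationError("negative survival time")
    kmf = KaplanMeierFitter()
    kmf.fit(times, event_observed=events)
    table = kmf.event_table
    surv = kmf.survival_function_["KM_estimate"]
    t = table.index.to_numpy(dtype=float)
    if t[0] != 0.0:
        t = np.concatenate([[0.0], t])
        at_risk = np.concatenate([[len(times)], table["at_risk"].to_numpy()])
        ev = np.concatenate([[0], table["observed"].to_numpy()])
        s = np.concatenate([[1.0], surv.reindex(table.index).to_numpy()])
    else:
        at_risk = table["at_risk"].to_numpy()
        ev = table["observed"].to_numpy()
        s = surv.reindex(table.index).to_numpy()
    return SurvivalCurve(times=t, survival=s, at_risk=at_risk.astype(int), events=ev.astype(int))


def survival_rate_at(curve: SurvivalCurve, t: float) -> float:
    """Evaluate the survival step function at time ``t`` (right-continuous).

    Beyond the last observed time the last value is returned with an
    extrapolation warning.
    """
    if t < 0:
        raise ValidationError("time must be non-negative")
    if t > curve.times[-1]:
        warnings.warn("time beyond last observed time: extrapolating the last survival value")
        return float(curve.survival[-1])
    idx = np.searchsorted(curve.times, t, side="right") - 1
    return float(curve.survival[max(idx, 0)])


@dataclass
class LogrankResult:
    statistic: float
    p: float
    df: int
    n_groups: int


def logrank_test(group_labels, times, events) -> LogrankResult:
    """Log-rank test across two or more groups (chi-squared reference)."""
    from lifelines.statistics import multivariate_logrank_test

    labels = np.asarray(group_labels)
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=bool)
    groups = pd.unique(labels)
    if len(groups) < 2:
        raise ValidationError("log-rank test requires at least two groups")
    res = multivariate_logrank_test(times, labels, events)
    return LogrankResult(
        statistic=float(res.test_statistic),
        p=float(res.p_value),
        df=len(groups) - 1,
        n_groups=len(groups),
    )


@dataclass
class CoxFit:
    """Cox proportional-hazards fit summary."""

    covariates: list[str]
    coefficients: np.ndarray
    hazard_ratios: np.ndarray
    ci_low: np.ndarray
    ci_high: np.ndarray
    p_values: np.ndarray
    n: int
    n_events: int
    converged: bool
    log_likelihood: float

    def summary_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "coef": self.coefficients,
                "hazard_ratio": self.hazard_ratios,
                "ci_low": self.ci_low,
                "ci_high": self.ci_high,
                "p": self.p_values,
            },
            index=self.covariates,
        )


def cox_fit(covariates: pd.DataFrame, times, events) -> CoxFit:
    """Fit a Cox proportional-hazards model (partial likelihood, Efron ties).

    Wald 95% confidence intervals and p-values per covariate.  A constant
    covariate is rejected up front; non-convergence or separation is
    reported on the returned fit, never silently.
    """
    from lifelines import CoxPHFitter
    from lifelines.exceptions import ConvergenceError, ConvergenceWarning

    X = covariates.copy()
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=bool)
    if events.sum() < 1:
        raise ValidationError("Cox fit requires at least one event")
    constant = [c for c in X.columns if X[c].nunique(dropna=True) <= 1]
    if constant:
        raise ValidationError(f"constant covariate(s): {constant}")
    df = X.reset_index(drop=True)
    df["__time"] = times
    df["__event"] = events.astype(int)
    cph = CoxPHFitter()
    converged = True
    with warnings.catch_warnings():
        warnings.simplefilter("always")
        try:
            with warnings.catch_warnings(record=True) as caught:
                warnings.simplefilter("always")
                cph.fit(df, duration_col="__time", event_col="__event")
            if any(issubclass(w.category, ConvergenceWarning) for w in caught):
                converged = False
                warnings.warn(
                    "Cox partial likelihood may be monotone (separation): "
                    "coefficients can diverge", stacklevel=2,
                )
        except ConvergenceError as exc:
            raise ValidationError(f"Cox fit failed to converge: {exc}") from exc
    summ = cph.summary
    return CoxFit(
        covariates=list(summ.index),
        coefficients=summ["coef"].to_numpy(),
        hazard_ratios=summ["exp(coef)"].to_numpy(),
        ci_low=np.exp(summ["coef lower 95%"].to_numpy()),
        ci_high=np.exp(summ["coef upper 95%"].to_numpy()),
        p_values=summ["p"].to_numpy(),
        n=len(df),
        n_events=int(events.sum()),
        converged=converged,
        log_likelihood=float(cph.log_likelihood_),
    )


@dataclass
class MatchedGroups:
    """Result of the adjacent-pair matched-group selection."""

    kept_group_a: list
    kept_group_b: list
    discarded: list
    balance_p: float | None = None
    label_a: str = "A"
    label_b: str = "B"


def matched_group_selection(
    group_labels: pd.Series,
    covariate: pd.Series,
    *,
    strict_order: str | None = None,
) -> MatchedGroups:
    """Select equal-sized groups matched on a covariate.

    Samples are sorted by the covariate (ascending, ties broken by
    sample identifier for determinism) and scanned left to right:
    whenever two consecutive unconsumed samples carry different labels,
    both are kept — one to each output group — and consumed; everything
    else is discarded.  By construction the kept groups are equal-sized
    and have near-identical covariate distributions.

    ``strict_order`` restricts pairing to pairs whose first (lower-
    covariate) member carries that label; the default accepts either
    order, which retains far more of an interleaved cohort.  With no
    cross-label adjacency both kept groups are empty, with a warning.
    ``balance_p`` is the two-sided Mann-Whitney p comparing the kept
    groups' covariate values (None when empty).
    """
    labels = group_labels.dropna()
    cov = covariate.reindex(labels.index)
    if cov.isna().any():
        raise ValidationError("covariate missing for some labelled samples")
    uniq = sorted(set(labels))
    if len(uniq) > 2:
        raise ValidationError(f"matched selection requires at most two labels, got {uniq}")
    if len(uniq) == 1:
        warnings.warn("only one group label present: matched groups are empty")
        return MatchedGroups([], [], list(labels.index), None, uniq[0], uniq[0])
    la, lb = uniq
    if strict_order is not None and strict_order not in uniq:
        raise ValidationError(f"strict_order {strict_order!r} is not one of the labels {uniq}")
    order = sorted(labels.index, key=lambda s: (cov[s], str(s)))
    kept_a: list = []
    kept_b: list = []
    discarded: list = []
    i = 0
    while i < len(order):
        if i + 1 < len(order):
            s1, s2 = order[i], order[i + 1]
            if labels[s1] != labels[s2] and (
                strict_order is None or labels[s1] == strict_order
            ):
                (kept_a if labels[s1] == la else kept_b).append(s1)
                (kept_a if labels[s2] == la else kept_b).append(s2)
                i += 2
                continue
        discarded.append(order[i])
        i += 1
    if not kept_a:
        warnings.warn("no cross-label adjacency: matched groups are empty")
        return MatchedGroups([], [], discarded, None, la, lb)
    balance = mann_whitney(cov[kept_a].to_numpy(), cov[kept_b].to_numpy())
    return MatchedGroups(kept_a, kept_b, discarded, balance.p_two_sided, la, lb)


def balance_test(groups: MatchedGroups, covariate: pd.Series) -> float:
    """Two-sided Mann-Whitney p on the matching covariate between the kept groups."""
    if not groups.kept_group_a or not groups.kept_group_b:
        raise ValidationError("balance test requires non-empty kept groups")
    res = mann_whitney(
        covariate[groups.kept_group_a].to_numpy(),
        covariate[groups.kept_group_b].to_numpy(),
    )
    return res.p_two_sided
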