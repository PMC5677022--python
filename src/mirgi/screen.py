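"""Median-split miRNA screen and contingency-table enrichment statistics.

For each miRNA the cohort is split at the median of its expression
("high" strictly above, "low" strictly below, ties at the median set
aside) and somatic mutation burden is compared between the two halves by
the Mann-Whitney U test.  Both one-sided p-values are computed; the
smaller is reported with its direction.  Flagging at a raw alpha without
multiple-testing correction therefore behaves like a two-sided screen
with effective size at most twice the nominal alpha — see the methods
note.  The module also houses the Fisher exact, chi-squared and
hypergeometric enrichment statistics used downstream.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .data_io import ExpressionMatrix, ValidationError, normalize_mirna_id
from .stats import mann_whitney

__all__ = [
    "median_split",
    "screen_mirnas",
    "FisherResult",
    "fisher_exact_2x2",
    "chi2_2x2",
    "hypergeom_enrichment",
    "NetworkEnrichment",
    "network_enrichment",
    "benjamini_hochberg",
]

#: Relative tolerance for the "probability no larger than observed"
#: comparison in the two-sided Fisher tail.
_FISHER_RELTOL = 1e-7


def median_split(values: pd.Series | np.ndarray) -> pd.Series:
    """Label each sample high/low/at_median relative to the median.

    ``high`` means strictly above the median of the non-missing values,
    ``low`` strictly below; exact ties with the median are labelled
    ``at_median`` (they join neither group).  Requires at least 4
    non-missing values; all-identical values raise (no split exists).
    """
    s = pd.Series(values, dtype=float) if not isinstance(values, pd.Series) else values.astype(float)
    obs = s.dropna()
    if len(obs) < 4:
        raise ValidationError("median split requires at least 4 non-missing values")
    if obs.nunique() == 1:
        raise ValidationError("all values identical: no median split possible")
    med = obs.median()
    labels = pd.Series("at_median", index=s.index, dtype=object)
    labels[s > med] = "high"
    labels[s < med] = "low"
    labels[s.isna()] = "missing"
    return labels


def screen_mirnas(
    expr: ExpressionMatrix,
    index: pd.Series,
    alpha: float = 0.01,
    *,
    max_missing_frac: float = 0.2,
    bh: bool = False,
) -> pd.DataFrame:
    """Screen every miRNA for association with mutation burden.

    For each miRNA, samples are split at the median of its expression and
    the mutation counts of the high and low halves are compared by the
    Mann-Whitney U test.  ``p_one_sided`` is the smaller of the two
    one-sided p-values and ``direction`` the side it favours (positive:
    high expression accompanies higher burden).  ``significant`` flags
    ``p_one_sided < alpha`` with no multiple-testing correction; with
    ``bh=True`` a Benjamini-Hochberg-adjusted column ``q`` is added and
    used instead.

    miRNAs with more than ``max_missing_frac`` missing samples, or whose
    split leaves an empty group, are skipped with a warning and listed in
    ``result.attrs["skipped"]``.
    """
    if not 0 < alpha < 1:
        raise ValidationError("alpha must be in (0, 1)")
    index = index.reindex(expr.sample_ids)
    if index.isna().any():
        raise ValidationError("instability index missing for some expression samples")
    rows = []
    skipped: dict[str, str] = {}
    for mirna in expr.mirna_ids:
        values = expr.values.loc[mirna]
        if values.isna().mean() > max_missing_frac:
            skipped[mirna] = "too many missing values"
            continue
        try:
            labels = median_split(values)
        except ValidationError as exc:
            skipped[mirna] = str(exc)
            continue
        hi = index[labels == "high"]
        lo = index[labels == "low"]
        if len(hi) == 0 or len(lo) == 0:
            skipped[mirna] = "empty group after median split"
            continue
        res = mann_whitney(hi.to_numpy(), lo.to_numpy())
        if res.median1 > res.median2:
            direction = "positive"
        elif res.median1 < res.median2:
            direction = "negative"
        else:
            direction = "positive" if res.p_greater <= res.p_less else "negative"
        rows.append(
            {
                "mirna_id": mirna,
                "direction": direction,
                "p_one_sided": res.p_one_sided_min,
                "median_high_expr_mut": res.median1,
                "median_low_expr_mut": res.median2,
                "n_high": res.n1,
                "n_low": res.n2,
            }
        )
    if skipped:
        warnings.warn(f"{len(skipped)} miRNA(s) skipped during screening")
    out = pd.DataFrame(
        rows,
        columns=[
            "mirna_id", "direction", "p_one_sided",
            "median_high_expr_mut", "median_low_expr_mut", "n_high", "n_low",
        ],
    )
    if bh and len(out):
        out["q"] = benjamini_hochberg(out["p_one_sided"].to_numpy())
        out["significant"] = out["q"] < alpha
    else:
        out["significant"] = out["p_one_sided"] < alpha
    out.attrs["skipped"] = skipped
    out.attrs["alpha"] = alpha
    return out


def benjamini_hochberg(pvalues: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values (step-up FDR)."""
    p = np.asarray(pvalues, dtype=float)
    n = len(p)
    order = np.argsort(p)
    ranked = p[order] * n / np.arange(1, n + 1)
    q = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(n)
    out[order] = np.minimum(q, 1.0)
    return out


# ---------------------------------------------------------------------------
# Contingency statistics
# ---------------------------------------------------------------------------


@dataclass
class FisherResult:
    p: float
    odds_ratio: float
    table: tuple[int, int, int, int]
    sidedness: str


def _check_table(a: int, b: int, c: int, d: int) -> None:
    cells = (a, b, c, d)
    if any(int(x) != x or x < 0 for x in cells):
        raise ValidationError("2x2 table cells must be non-negative integers")
    if sum(cells) == 0:
        raise ValidationError("2x2 table total must be positive")


def fisher_exact_2x2(
    table: Sequence[int],
    sidedness: str = "two_sided",
) -> FisherResult:
    """Fisher's exact test on a 2x2 table (a, b, c, d), rows = condition.

    The two-sided p-value sums the hypergeometric probabilities of all
    tables with the observed margins whose probability is no larger than
    the observed table's (with a small relative tolerance on the
    comparison).  The odds ratio is ad/bc, infinite when bc = 0 with
    ad > 0.  A zero margin gives p = 1 by convention, with a warning.
    """
    a, b, c, d = (int(x) for x in table)
    _check_table(a, b, c, d)
    if sidedness not in {"two_sided", "greater", "less"}:
        raise ValidationError(f"unknown sidedness {sidedness!r}")
    n = a + b + c + d
    row1 = a + b
    col1 = a + c
    if b * c == 0:
        odds = math.inf if a * d > 0 else math.nan
    else:
        odds = (a * d) / (b * c)
    if min(row1, col1, n - row1, n - col1) == 0:
        warnings.warn("2x2 table has a zero margin; p = 1 by convention")
        return FisherResult(1.0, odds, (a, b, c, d), sidedness)

    lo = max(0, row1 + col1 - n)
    hi = min(row1, col1)
    support = np.arange(lo, hi + 1)
    pmf = sps.hypergeom.pmf(support, n, col1, row1)
    p_obs = pmf[a - lo]
    if sidedness == "greater":
        p = float(pmf[support >= a].sum())
    elif sidedness == "less":
        p = float(pmf[support <= a].sum())
    else:
        p = float(pmf[pmf <= p_obs * (1 + _FISHER_RELTOL)].sum())
    return FisherResult(min(p, 1.0), odds, (a, b, c, d), sidedness)


def chi2_2x2(table: Sequence[int], correction: bool = False) -> tuple[float, float]:
    """Pearson chi-squared test on a 2x2 table (1 df).

    ``correction`` applies the Yates continuity correction (default off).
    An expected cell below 1 attaches a warning but still returns the
    statistic; a zero margin returns (0, 1) with a warning.
    """
    a, b, c, d = (int(x) for x in table)
    _check_table(a, b, c, d)
    t = np.array([[a, b], [c, d]], dtype=float)
    n = t.sum()
    expected = np.outer(t.sum(axis=1), t.sum(axis=0)) / n
    if (expected == 0).any():
        warnings.warn("2x2 table has a zero margin; chi-squared undefined, returning (0, 1)")
        return 0.0, 1.0
    if (expected < 1).any():
        warnings.warn("expected cell count below 1; chi-squared approximation unreliable")
    stat, p, _, _ = sps.chi2_contingency(t, correction=correction)
    return float(stat), float(p)


def hypergeom_enrichment(
    hits_in_set: int,
    set_size: int,
    hits_total: int,
    universe: int,
) -> tuple[float, float]:
    """Fold enrichment and upper-tail hypergeometric p-value.

    ``fold`` = (hits_in_set/set_size) / (hits_total/universe);
    ``p`` = P(X >= hits_in_set) with X ~ Hypergeom(universe, hits_total,
    set_size).  Zero hits report fold 0 and p = 1.
    """
    if universe <= 0:
        raise ValidationError("universe must be positive")
    if hits_in_set > min(set_size, hits_total):
        raise ValidationError("hits_in_set exceeds set_size or hits_total")
    if hits_total > universe or set_size > universe:
        raise ValidationError("set sizes exceed the universe")
    if hits_in_set == 0:
        return 0.0, 1.0
    fold = (hits_in_set / set_size) / (hits_total / universe)
    p = float(sps.hypergeom.sf(hits_in_set - 1, universe, hits_total, set_size))
    return fold, min(p, 1.0)


@dataclass
class NetworkEnrichment:
    """Enrichment of screen hits among network-member miRNAs."""

    table: tuple[int, int, int, int]
    fisher: FisherResult
    in_network_significant: list[str]
    out_network_significant: list[str]
    n_network_in_universe: int
    n_universe: int


def network_enrichment(
    screened: pd.DataFrame,
    network: pd.DataFrame,
    universe: Iterable[str],
) -> NetworkEnrichment:
    """Fisher enrichment of significant screen miRNAs in the network.

    Builds the 2x2 table (in-network significant, in-network
    non-significant, out-network significant, out-network
    non-significant) over the tested universe and returns the two-sided
    Fisher result with the membership lists.
    """
    universe = [normalize_mirna_id(m) for m in universe]
    if not universe:
        raise ValidationError("empty miRNA universe")
    uset = set(universe)
    members = {normalize_mirna_id(m) for m in network["mirna_id"]} & uset
    sig = {
        normalize_mirna_id(m)
        for m in screened.loc[screened["significant"], "mirna_id"]
    } & uset
    in_sig = sorted(sig & members)
    out_sig = sorted(sig - members)
    a = len(in_sig)
    b = len(members) - a
    c = len(out_sig)
    d = len(uset) - len(members) - c
    fisher = fisher_exact_2x2((a, b, c, d))
    return NetworkEnrichment(
        table=(a, b, c, d),
        fisher=fisher,
        in_network_significant=in_sig,
        out_network_significant=out_sig,
        n_network_in_universe=len(members),
        n_universe=len(uset),
    )
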