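"""Shared rank-test machinery.

One Mann-Whitney implementation backs the miRNA screen, the defect/burden
comparisons, the tumour-vs-normal score comparison and the matched-group
balance test.  The exact null distribution is used for small untied
samples; otherwise the tie-corrected normal approximation with continuity
correction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

from .data_io import ValidationError

__all__ = ["MannWhitneyResult", "mann_whitney"]

#: Exact enumeration is used when both groups are at most this large and
#: the pooled sample has no ties.
EXACT_MAX_N = 12

#: With ties, exact permutation enumeration is still used when the pooled
#: sample is at most this large (C(16,8) = 12870 assignments).
EXACT_TIES_MAX_TOTAL = 16


@dataclass
class MannWhitneyResult:
    """Mann-Whitney U comparison of two samples.

    ``u`` is the U statistic of the first sample (number of pairs it
    wins); ``p_greater``/``p_less`` are the one-sided p-values for the
    first sample tending larger/smaller.
    """

    u: float
    p_two_sided: float
    p_greater: float
    p_less: float
    n1: int
    n2: int
    median1: float
    median2: float
    method: str

    @property
    def p_one_sided_min(self) -> float:
        return min(self.p_greater, self.p_less)


def _exact_tied_enumeration(x, y) -> tuple[float, float, float, float]:
    """Exact U distribution for a tied pool, by exhausting group assignments.

    U is computed from average ranks; one-sided p-values include ties with
    the observed statistic, and the two-sided p is twice the smaller
    one-sided value (capped at 1), matching the exact-test convention.
    """
    import itertools

    pooled = np.concatenate([x, y])
    n1 = len(x)
    ranks = sps.rankdata(pooled)
    offset = n1 * (n1 + 1) / 2
    u_obs = float(ranks[:n1].sum() - offset)
    ge = le = total = 0
    for idx in itertools.combinations(range(len(pooled)), n1):
        u = ranks[list(idx)].sum() - offset
        ge += u >= u_obs - 1e-9
        le += u <= u_obs + 1e-9
        total += 1
    p_greater = ge / total
    p_less = le / total
    return u_obs, p_greater, p_less, min(1.0, 2 * min(p_greater, p_less))


def mann_whitney(x, y) -> MannWhitneyResult:
    """Compare two samples with the Mann-Whitney U test.

    Exact p-values (full null enumeration) when both groups have at most
    ``EXACT_MAX_N`` observations and the pooled data are untied; exact
    permutation enumeration for tied pools of at most
    ``EXACT_TIES_MAX_TOTAL`` observations; tie-corrected normal
    approximation with continuity correction otherwise.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    x = x[~np.isnan(x)]
    y = y[~np.isnan(y)]
    if len(x) == 0 or len(y) == 0:
        raise ValidationError("Mann-Whitney comparison requires two non-empty groups")
    pooled = np.concatenate([x, y])
    no_ties = len(np.unique(pooled)) == len(pooled)
    if len(x) <= EXACT_MAX_N and len(y) <= EXACT_MAX_N and no_ties:
        method_name = "exact"
        u, p_greater = sps.mannwhitneyu(x, y, alternative="greater", method="exact")
        _, p_less = sps.mannwhitneyu(x, y, alternative="less", method="exact")
        _, p_two = sps.mannwhitneyu(x, y, alternative="two-sided", method="exact")
    elif len(pooled) <= EXACT_TIES_MAX_TOTAL:
        method_name = "exact"
        u, p_greater, p_less, p_two = _exact_tied_enumeration(x, y)
    else:
        method_name = "asymptotic"
        u, p_greater = sps.mannwhitneyu(x, y, alternative="greater", method="asymptotic")
        _, p_less = sps.mannwhitneyu(x, y, alternative="less", method="asymptotic")
        _, p_two = sps.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic")
    return MannWhitneyResult(
        u=float(u),
        p_two_sided=float(p_two),
        p_greater=float(p_greater),
        p_less=float(p_less),
        n1=len(x),
        n2=len(y),
        median1=float(np.median(x)),
        median2=float(np.median(y)),
        method=method_name,
    )
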