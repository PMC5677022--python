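"""The k-miRNA point score.

A signature is a signed miRNA set: a sample earns one point for every
positive-direction miRNA expressed strictly above the cohort median and
one point for every negative-direction miRNA strictly below it.  The
integer score (0..k) is deliberately weightless — no coefficients are
fitted — which makes it rank-based and robust to monotone transformations
of any single miRNA's expression.  The default shipped signature is the
10-miRNA set (6 positive, 4 negative) used throughout the package
examples.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .data_io import ExpressionMatrix, ValidationError, normalize_mirna_id, read_table
from .stats import MannWhitneyResult, mann_whitney

__all__ = [
    "SignatureSpec",
    "default_signature",
    "load_signature",
    "compute_scores",
    "assign_groups",
    "ScoreAssociation",
    "score_instability_association",
    "TrendReport",
    "response_rate_trend",
    "compare_tumour_normal_scores",
]

#: Exact permutation p-value for the level-median Spearman is used up to
#: this many score levels (8! = 40320 permutations).
_EXACT_SPEARMAN_LEVELS = 8


@dataclass(frozen=True)
class SignatureSpec:
    """A signed miRNA signature defining a k-miRNA score."""

    positive_mirnas: tuple[str, ...]
    negative_mirnas: tuple[str, ...]
    name: str = "signature"

    def __post_init__(self) -> None:
        pos = tuple(normalize_mirna_id(m) for m in self.positive_mirnas)
        neg = tuple(normalize_mirna_id(m) for m in self.negative_mirnas)
        object.__setattr__(self, "positive_mirnas", pos)
        object.__setattr__(self, "negative_mirnas", neg)
        overlap = set(pos) & set(neg)
        if overlap:
            raise ValidationError(f"signature miRNA(s) in both directions: {sorted(overlap)}")
        if not pos and not neg:
            raise ValidationError("signature must name at least one miRNA")
        if len(set(pos)) != len(pos) or len(set(neg)) != len(neg):
            raise ValidationError("signature lists contain duplicates")

    @property
    def k(self) -> int:
        return len(self.positive_mirnas) + len(self.negative_mirnas)

    @property
    def mirnas(self) -> tuple[str, ...]:
        return self.positive_mirnas + self.negative_mirnas

    def reversed(self) -> "SignatureSpec":
        return SignatureSpec(self.negative_mirnas, self.positive_mirnas, self.name + "_reversed")


def default_signature() -> SignatureSpec:
    """The 10-miRNA genome-instability signature (6 positive, 4 negative)."""
    return SignatureSpec(
        positive_mirnas=("mir-151", "mir-301b", "mir-505*", "mir-324", "mir-502", "mir-421"),
        negative_mirnas=("let-7a*", "mir-320", "mir-146a*", "mir-193a"),
        name="10-miRNA-score",
    )


def load_signature(path, name: str | None = None) -> SignatureSpec:
    """Load a signature from a TSV with columns (mirna, direction in {+,-})."""
    frame = read_table(path)
    cols = {c.lower(): c for c in frame.columns}
    if "mirna" not in cols or "direction" not in cols:
        raise ValidationError("signature file needs columns 'mirna' and 'direction'")
    direction = frame[cols["direction"]].astype(str).str.strip()
    bad = sorted(set(direction) - {"+", "-"})
    if bad:
        raise ValidationError(f"signature direction(s) outside {{+,-}}: {bad}")
    pos = tuple(frame.loc[direction == "+", cols["mirna"]])
    neg = tuple(frame.loc[direction == "-", cols["mirna"]])
    return SignatureSpec(pos, neg, name or "signature")


def compute_scores(expr: ExpressionMatrix, sig: SignatureSpec) -> pd.DataFrame:
    """Score every sample against a signed signature.

    Medians are computed per signature miRNA across the scored cohort
    (missing values ignored).  A point is earned for expression strictly
    above the median (positive-direction miRNAs) or strictly below it
    (negative-direction miRNAs); exact ties with the median earn nothing.
    A sample missing a signature miRNA's value contributes no point for
    it and is flagged in ``attrs["missing_flags"]``.

    Raises if any signature miRNA is absent from the matrix (listing the
    absentees).  The per-miRNA point breakdown is kept in
    ``attrs["breakdown"]`` for audit.
    """
    idx = pd.Index([normalize_mirna_id(m) for m in expr.mirna_ids])
    missing = [m for m in sig.mirnas if m not in set(idx)]
    if missing:
        raise ValidationError(f"signature miRNA(s) absent from expression matrix: {missing}")
    values = expr.values.copy()
    values.index = idx
    breakdown = pd.DataFrame(0, index=expr.sample_ids, columns=list(sig.mirnas), dtype=int)
    missing_flags: list[tuple[str, str]] = []
    for mirna in sig.mirnas:
        row = values.loc[mirna]
        med = row.median(skipna=True)
        if mirna in sig.positive_mirnas:
            pts = (row > med).astype(int)
        else:
            pts = (row < med).astype(int)
        pts[row.isna()] = 0
        missing_flags.extend((s, mirna) for s in row.index[row.isna()])
        breakdown[mirna] = pts
    out = pd.DataFrame(
        {"sample_id": expr.sample_ids, "score": breakdown.sum(axis=1).to_numpy()}
    )
    out.attrs["breakdown"] = breakdown
    out.attrs["missing_flags"] = missing_flags
    out.attrs["k"] = sig.k
    out.attrs["signature"] = sig.name
    return out


def assign_groups(scores: pd.DataFrame, cutoff: int = 6, k: int | None = None) -> pd.DataFrame:
    """Partition scored samples into high (score >= cutoff) and low groups."""
    k = k if k is not None else scores.attrs.get("k", int(scores["score"].max()))
    if not 0 < cutoff <= k:
        raise ValidationError(f"cutoff {cutoff} out of range (0, {k}]")
    out = scores.copy()
    out["group"] = np.where(out["score"] >= cutoff, "high", "low")
    for key, val in scores.attrs.items():
        out.attrs[key] = val
    out.attrs["cutoff"] = cutoff
    return out


@dataclass
class ScoreAssociation:
    """Spearman association of score level with median mutation burden."""

    levels: list[int]
    level_medians: list[float]
    rho: float
    p: float
    method: str
    degenerate: bool = False
    n_samples: int = 0


def _spearman_exact_perm(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Spearman rho with an exact two-sided permutation p-value."""
    rx = sps.rankdata(x)
    ry = sps.rankdata(y)
    rho_obs = float(np.corrcoef(rx, ry)[0, 1])
    m = len(x)
    count = 0
    total = 0
    for perm in itertools.permutations(range(m)):
        rho = float(np.corrcoef(rx, ry[list(perm)])[0, 1])
        if abs(rho) >= abs(rho_obs) - 1e-12:
            count += 1
        total += 1
    return rho_obs, count / total


def score_instability_association(scores: pd.DataFrame, index: pd.Series) -> ScoreAssociation:
    """Correlate score level with the median mutation count per level.

    For each score value present, the median burden of its samples is
    computed; Spearman's rho is then taken over the (level, median) pairs
    with average-rank ties.  An exact permutation p-value is used up to
    8 levels, the t-approximation beyond.  Constant level medians are
    degenerate: rho reported as 0 with p = 1.
    """
    index = index.reindex(scores["sample_id"].to_numpy())
    if index.isna().any():
        raise ValidationError("instability index missing for some scored samples")
    per_level = (
        pd.DataFrame({"score": scores["score"].to_numpy(), "mut": index.to_numpy()})
        .groupby("score")["mut"]
        .median()
        .sort_index()
    )
    levels = [int(v) for v in per_level.index]
    medians = [float(v) for v in per_level.to_numpy()]
    if len(levels) < 3:
        raise ValidationError("score-instability association needs at least 3 score levels")
    x = np.asarray(levels, dtype=float)
    y = np.asarray(medians, dtype=float)
    if np.all(y == y[0]):
        return ScoreAssociation(levels, medians, 0.0, 1.0, "degenerate", True, len(scores))
    if len(levels) <= _EXACT_SPEARMAN_LEVELS:
        rho, p = _spearman_exact_perm(x, y)
        method = "exact_permutation"
    else:
        rho, p = sps.spearmanr(x, y)
        method = "t_approximation"
    return ScoreAssociation(levels, medians, float(rho), float(p), method, False, len(scores))


@dataclass
class TrendReport:
    """Per-score-level outcome rates and their linear trend."""

    levels: list[int]
    rates: list[float]
    n_per_level: list[int]
    r: float
    p: float
    degenerate: bool = False


def response_rate_trend(
    scores: pd.DataFrame,
    outcome: pd.Series,
    *,
    method: str = "pearson",
) -> TrendReport:
    """Correlate the per-level response rate with the score level.

    ``rate(level)`` is the fraction of outcome-true samples at that
    score; levels with no outcome data are excluded.  The trend is the
    Pearson correlation of rate against level (Spearman available via
    ``method``).  Constant rates are degenerate: r = 0, p = 1.
    """
    outcome = outcome.reindex(scores["sample_id"].to_numpy())
    frame = pd.DataFrame({"score": scores["score"].to_numpy(), "y": outcome.to_numpy()})
    frame = frame.dropna()
    grouped = frame.groupby("score")["y"]
    levels = [int(v) for v in grouped.mean().index]
    rates = [float(v) for v in grouped.mean().to_numpy()]
    counts = [int(v) for v in grouped.size().to_numpy()]
    if len(levels) < 3:
        raise ValidationError("response trend needs at least 3 usable score levels")
    y = np.asarray(rates)
    if np.all(y == y[0]):
        return TrendReport(levels, rates, counts, 0.0, 1.0, True)
    if method == "pearson":
        r, p = sps.pearsonr(np.asarray(levels, dtype=float), y)
    elif method == "spearman":
        r, p = sps.spearmanr(np.asarray(levels, dtype=float), y)
    else:
        raise ValidationError(f"unknown trend method {method!r}")
    return TrendReport(levels, rates, counts, float(r), float(p), False)


def compare_tumour_normal_scores(
    scores_tumour: pd.DataFrame | Sequence[int],
    scores_normal: pd.DataFrame | Sequence[int],
) -> MannWhitneyResult:
    """Mann-Whitney comparison of tumour vs normal scores.

    Both sets should have been scored against shared (pooled) medians —
    score the combined expression matrix once, then split.  The first
    group of the result is the tumour one.
    """
    t = scores_tumour["score"].to_numpy() if isinstance(scores_tumour, pd.DataFrame) else np.asarray(scores_tumour)
    n = scores_normal["score"].to_numpy() if isinstance(scores_normal, pd.DataFrame) else np.asarray(scores_normal)
    if len(t) == 0 or len(n) == 0:
        raise ValidationError("both tumour and normal score sets must be non-empty")
    return mann_whitney(t, n)
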