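"""One-shot orchestration of the analysis as a model/results pair.

:class:`GenomeInstabilityModel` is built from a :class:`~mirgi.data_io.CohortBundle`
(plus an optional fixed signature); :meth:`~GenomeInstabilityModel.fit`
executes the full sequence — mutation burden, median-split screen,
signature scoring and grouping, score-burden association, defect
enrichment, Kaplan-Meier/log-rank/Cox survival, matched-group
comparison — and returns a :class:`PipelineResults` carrying every
intermediate table, with optional stages degrading gracefully to
explicit ``SKIPPED`` markers.  ``run_pipeline`` is the functional
equivalent.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd

from . import __version__
from .data_io import CohortBundle, ValidationError, write_table
from .instability import mutation_counts
from .outcome import (
    CoxFit,
    LogrankResult,
    MatchedGroups,
    SurvivalCurve,
    cox_fit,
    km_estimate,
    logrank_test,
    matched_group_selection,
)
from .score import (
    ScoreAssociation,
    SignatureSpec,
    TrendReport,
    assign_groups,
    compute_scores,
    response_rate_trend,
    score_instability_association,
)
from .screen import NetworkEnrichment, fisher_exact_2x2, network_enrichment, screen_mirnas

__all__ = ["GenomeInstabilityModel", "PipelineResults", "run_pipeline"]

SKIPPED = "SKIPPED"


def _fingerprint(bundle: CohortBundle, config: dict) -> str:
    """Provenance hash over inputs and configuration."""
    h = hashlib.sha256()
    h.update(json.dumps(config, sort_keys=True, default=str).encode())
    h.update(pd.util.hash_pandas_object(bundle.expression.values, index=True).to_numpy().tobytes())
    h.update(pd.util.hash_pandas_object(bundle.mutations.astype(str), index=False).to_numpy().tobytes())
    h.update(pd.util.hash_pandas_object(bundle.clinical.astype(str), index=False).to_numpy().tobytes())
    if bundle.defects is not None:
        h.update(pd.util.hash_pandas_object(bundle.defects.astype(str), index=False).to_numpy().tobytes())
    if bundle.network is not None:
        h.update(pd.util.hash_pandas_object(bundle.network.astype(str), index=False).to_numpy().tobytes())
    return h.hexdigest()


@dataclass
class PipelineResults:
    """Everything the fitted pipeline computed.

    Optional stages that could not run hold the string ``"SKIPPED"`` in
    :attr:`stage_status` with a reason; every numeric result is
    re-derivable from the bundle inputs and recorded configuration.
    """

    model: "GenomeInstabilityModel"
    mutation_burden: pd.Series
    screen: pd.DataFrame | None
    signature: SignatureSpec
    scores: pd.DataFrame
    association: ScoreAssociation | None
    network_enrichment: NetworkEnrichment | None
    defect_enrichment: dict[str, Any] | None
    response_trends: dict[str, TrendReport]
    km_curves: dict[str, SurvivalCurve] | None
    logrank: LogrankResult | None
    cox_univariate: CoxFit | None
    cox_multivariate: CoxFit | None
    matched_by_score: MatchedGroups | None
    matched_logrank: LogrankResult | None
    stage_status: dict[str, str] = field(default_factory=dict)
    provenance: dict[str, str] = field(default_factory=dict)

    def summary(self) -> str:
        """Human-readable stage-by-stage report."""
        lines = [
            "Genome-instability miRNA score pipeline",
            "=" * 55,
            f"samples: {self.model.bundle.n_samples}   "
            f"signature: {self.signature.name} (k={self.signature.k})",
            f"provenance: {self.provenance.get('hash', '')[:16]}",
            "",
        ]
        if self.screen is not None:
            nsig = int(self.screen["significant"].sum())
            lines.append(f"screen: {nsig}/{len(self.screen)} miRNAs significant "
                         f"(alpha={self.screen.attrs.get('alpha')})")
        else:
            lines.append(f"screen: {self.stage_status.get('screen', SKIPPED)}")
        if self.network_enrichment is not None:
            ne = self.network_enrichment
            lines.append(f"network enrichment: table={ne.table}, Fisher p={ne.fisher.p:.3g}")
        grp = self.scores.get("group")
        if grp is not None:
            lines.append(
                f"score groups: high={int((grp == 'high').sum())}, "
                f"low={int((grp == 'low').sum())} (cutoff {self.scores.attrs.get('cutoff')})"
            )
        if self.association is not None:
            lines.append(
                f"score-burden association: rho={self.association.rho:.3f}, "
                f"p={self.association.p:.3g} over {len(self.association.levels)} levels"
            )
        for name, trend in self.response_trends.items():
            lines.append(f"{name} trend: r={trend.r:.3f}, p={trend.p:.3g}")
        if self.defect_enrichment is not None:
            for key, fr in self.defect_enrichment.items():
                lines.append(f"defect enrichment [{key}]: table={fr.table}, p={fr.p:.3g}")
        if self.logrank is not None:
            lines.append(f"log-rank high vs low: chi2={self.logrank.statistic:.3f}, "
                         f"p={self.logrank.p:.3g}")
        for label, fit in (("Cox univariate", self.cox_univariate),
                           ("Cox multivariate", self.cox_multivariate)):
            if fit is not None:
                i = fit.covariates.index("score_high") if "score_high" in fit.covariates else 0
                lines.append(
                    f"{label}: HR={fit.hazard_ratios[i]:.3f} "
                    f"[{fit.ci_low[i]:.2f}-{fit.ci_high[i]:.2f}], p={fit.p_values[i]:.3g}"
                )
        if self.matched_by_score is not None:
            m = self.matched_by_score
            extra = ""
            if self.matched_logrank is not None:
                extra = f", matched log-rank p={self.matched_logrank.p:.3g}"
            lines.append(
                f"matched groups (balanced on burden): {len(m.kept_group_a)}+{len(m.kept_group_b)} kept, "
                f"{len(m.discarded)} discarded, balance p={m.balance_p:.3g}{extra}"
            )
        skipped = {k: v for k, v in self.stage_status.items() if v != "ok"}
        if skipped:
            lines.append("")
            for stage, status in skipped.items():
                lines.append(f"  [{stage}] {status}")
        return "\n".join(lines)

    def save(self, outdir) -> None:
        """Write the report tables (TSV) and a JSON summary to a directory."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        if self.screen is not None:
            write_table(self.screen, outdir / "screen.tsv")
        write_table(self.scores, outdir / "scores.tsv")
        write_table(
            self.mutation_burden.rename_axis("sample_id").reset_index(),
            outdir / "mutation_burden.tsv",
        )
        if self.km_curves:
            rows = []
            for label, curve in self.km_curves.items():
                for t, s, r, e in zip(curve.times, curve.survival, curve.at_risk, curve.events):
                    rows.append({"group": label, "time": t, "survival": s,
                                 "at_risk": r, "events": e})
            write_table(pd.DataFrame(rows), outdir / "km_curves.tsv")
        summary = {
            "provenance": self.provenance,
            "stage_status": self.stage_status,
            "summary": self.summary(),
        }
        (outdir / "report.json").write_text(json.dumps(summary, indent=2))


class GenomeInstabilityModel:
    """miRNA genome-instability scoring model over a cohort bundle.

    Parameters
    ----------
    bundle:
        Aligned cohort inputs (expression, mutations, clinical, optional
        defects and network).
    signature:
        Fixed signed signature.  When None, one is derived from the
        screen: significant miRNAs (restricted to network members when a
        network is present), with directions from the screen.
    alpha:
        Screen significance level (raw, uncorrected).
    cutoff:
        Score-group cutoff; default splits k at floor(k/2)+1 (6 for
        k = 10).
    covariates:
        Clinical covariates for the multivariate Cox fit.
    """

    def __init__(
        self,
        bundle: CohortBundle,
        signature: SignatureSpec | None = None,
        *,
        alpha: float = 0.01,
        cutoff: int | None = None,
        exclude_classes: tuple[str, ...] = (),
        covariates: tuple[str, ...] = ("age", "figo_stage", "grade", "debulking"),
    ) -> None:
        self.bundle = bundle
        self.signature = signature
        self.alpha = alpha
        self.cutoff = cutoff
        self.exclude_classes = exclude_classes
        self.covariates = covariates

    @classmethod
    def from_tables(cls, expression, mutations, clinical, defects=None, network=None, **kwargs):
        from .data_io import assemble_cohort

        return cls(assemble_cohort(expression, mutations, clinical, defects, network), **kwargs)

    # -- fitting ---------------------------------------------------------

    def fit(self, run_screen: bool = True) -> PipelineResults:
        bundle = self.bundle
        status: dict[str, str] = {}
        config = {
            "alpha": self.alpha,
            "cutoff": self.cutoff,
            "exclude_classes": list(self.exclude_classes),
            "covariates": list(self.covariates),
            "signature": None if self.signature is None else {
                "positive": self.signature.positive_mirnas,
                "negative": self.signature.negative_mirnas,
            },
            "version": __version__,
        }

        burden = mutation_counts(
            bundle.mutations, bundle.sample_ids, exclude_classes=self.exclude_classes
        )
        status["burden"] = "ok"

        screen_df = None
        net_enrich = None
        if run_screen:
            screen_df = screen_mirnas(bundle.expression, burden, alpha=self.alpha)
            status["screen"] = "ok"
            if bundle.network is not None:
                net_enrich = network_enrichment(
                    screen_df, bundle.network, screen_df["mirna_id"]
                )
                status["network_enrichment"] = "ok"
            else:
                status["network_enrichment"] = f"{SKIPPED}: no network provided"
        else:
            status["screen"] = "signature: fixed"
            status["network_enrichment"] = f"{SKIPPED}: screen not run"

        signature = self.signature
        if signature is None:
            if screen_df is None:
                raise ValidationError("no signature provided and screening disabled")
            sig_rows = screen_df[screen_df["significant"]]
            if net_enrich is not None:
                members = set(net_enrich.in_network_significant)
                sig_rows = sig_rows[sig_rows["mirna_id"].isin(members)]
            if sig_rows.empty:
                raise ValidationError("screen flagged no miRNAs: cannot derive a signature")
            signature = SignatureSpec(
                tuple(sig_rows.loc[sig_rows["direction"] == "positive", "mirna_id"]),
                tuple(sig_rows.loc[sig_rows["direction"] == "negative", "mirna_id"]),
                name="screen-derived",
            )

        scores = compute_scores(bundle.expression, signature)
        cutoff = self.cutoff if self.cutoff is not None else signature.k // 2 + 1
        scores = assign_groups(scores, cutoff=cutoff, k=signature.k)
        status["score"] = "ok"

        try:
            association = score_instability_association(scores, burden)
            status["association"] = "ok"
        except ValidationError as exc:
            association, status["association"] = None, f"{SKIPPED}: {exc}"

        trends: dict[str, TrendReport] = {}
        clin = bundle.clinical.set_index("sample_id")
        for col in ("platinum_sensitive", "complete_response"):
            if col in clin.columns and clin[col].notna().any():
                try:
                    trends[col] = response_rate_trend(scores, clin[col].astype("boolean").astype(object))
                    status[f"trend:{col}"] = "ok"
                except ValidationError as exc:
                    status[f"trend:{col}"] = f"{SKIPPED}: {exc}"
            else:
                status[f"trend:{col}"] = f"{SKIPPED}: no data"

        defect_enrichment = None
        if bundle.defects is not None:
            defect_enrichment = {}
            dft = bundle.defects.set_index("sample_id")
            grp = scores.set_index("sample_id")["group"]
            for flag in ("hr_defect", "brca_defect", "emsy_amplified", "pten_deleted"):
                if flag not in dft.columns:
                    continue
                f = dft[flag].reindex(grp.index).astype(bool)
                a = int((f & (grp == "high")).sum())
                b = int((~f & (grp == "high")).sum())
                c = int((f & (grp == "low")).sum())
                d = int((~f & (grp == "low")).sum())
                defect_enrichment[flag] = fisher_exact_2x2((a, b, c, d))
            status["defect_enrichment"] = "ok"
        else:
            status["defect_enrichment"] = f"{SKIPPED}: no defect table"

        km_curves = logrank = cox_uni = cox_multi = None
        matched = matched_lr = None
        has_surv = {"os_time", "os_event"} <= set(bundle.clinical.columns) and clin["os_time"].notna().any()
        if has_surv:
            merged = scores.merge(bundle.clinical, on="sample_id")
            merged = merged[merged["os_time"].notna()]
            times = merged["os_time"].to_numpy(float)
            events = merged["os_event"].astype(bool).to_numpy()
            km_curves = {
                label: km_estimate(times[merged["group"] == label],
                                   events[merged["group"] == label])
                for label in ("high", "low")
                if (merged["group"] == label).any()
            }
            if len(km_curves) == 2:
                logrank = logrank_test(merged["group"], times, events)
            merged["score_high"] = (merged["group"] == "high").astype(int)
            try:
                cox_uni = cox_fit(merged[["score_high"]], times, events)
                status["cox_univariate"] = "ok"
            except ValidationError as exc:
                status["cox_univariate"] = f"{SKIPPED}: {exc}"
            multi_cols = ["score_high"]
            for cov in self.covariates:
                if cov not in merged.columns:
                    continue
                if cov == "debulking":
                    merged["debulking_suboptimal"] = (merged[cov] == "suboptimal").astype(int)
                    multi_cols.append("debulking_suboptimal")
                else:
                    merged[cov] = pd.to_numeric(merged[cov], errors="coerce")
                    if merged[cov].notna().all() and merged[cov].nunique() > 1:
                        multi_cols.append(cov)
            try:
                cox_multi = cox_fit(merged[multi_cols], times, events)
                status["cox_multivariate"] = "ok"
            except ValidationError as exc:
                status["cox_multivariate"] = f"{SKIPPED}: {exc}"

            # matched-group comparison: score groups balanced on burden
            grp_series = merged.set_index("sample_id")["group"]
            cov_series = burden.reindex(grp_series.index).astype(float)
            matched = matched_group_selection(grp_series, cov_series)
            if matched.kept_group_a:
                kept = matched.kept_group_a + matched.kept_group_b
                sub = merged.set_index("sample_id").loc[kept]
                matched_lr = logrank_test(
                    sub["group"], sub["os_time"].to_numpy(float),
                    sub["os_event"].astype(bool).to_numpy(),
                )
            status["survival"] = "ok"
        else:
            status["survival"] = f"{SKIPPED}: no survival data"

        provenance = {
            "hash": _fingerprint(bundle, config),
            "version": __version__,
            "n_samples": str(bundle.n_samples),
        }
        return PipelineResults(
            model=self,
            mutation_burden=burden,
            screen=screen_df,
            signature=signature,
            scores=scores,
            association=association,
            network_enrichment=net_enrich,
            defect_enrichment=defect_enrichment,
            response_trends=trends,
            km_curves=km_curves,
            logrank=logrank,
            cox_univariate=cox_uni,
            cox_multivariate=cox_multi,
            matched_by_score=matched,
            matched_logrank=matched_lr,
            stage_status=status,
            provenance=provenance,
        )


def run_pipeline(bundle: CohortBundle, signature: SignatureSpec | None = None, **kwargs) -> PipelineResults:
    """Functional wrapper: build the model and fit it in one call."""
    run_screen = kwargs.pop("run_screen", True)
    return GenomeInstabilityModel(bundle, signature, **kwargs).fit(run_screen=run_screen)
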