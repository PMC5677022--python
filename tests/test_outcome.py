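"""Survival machinery and the matched-group selection algorithm."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mirgi.data_io import ValidationError
from mirgi.instability import mutation_counts
from mirgi.outcome import (
    balance_test,
    cox_fit,
    km_estimate,
    logrank_test,
    matched_group_selection,
    survival_rate_at,
)
from mirgi.score import SignatureSpec, assign_groups, compute_scores
from mirgi.synthetic import simulate_cohort


class TestKaplanMeier:
    def test_no_events_flat_curve(self):
        curve = km_estimate([1, 2, 3], [False, False, False])
        assert (curve.survival == 1.0).all()

    def test_two_events_closed_form(self):
        curve = km_estimate([1, 2], [True, True])
        assert survival_rate_at(curve, 1) == pytest.approx(0.5)
        assert survival_rate_at(curve, 2) == pytest.approx(0.0)

    def test_five_subject_product_limit(self):
        # events at 1 and 3, censored at 2, 4, 5: S(3) = (4/5)*(2/3)
        curve = km_estimate([1, 2, 3, 4, 5], [True, False, True, False, False])
        assert survival_rate_at(curve, 3) == pytest.approx(8 / 15)

    def test_product_limit_recursion_reconstructs_curve(self):
        rng = np.random.default_rng(2)
        t = rng.exponential(3, 40)
        e = rng.random(40) < 0.7
        curve = km_estimate(t, e)
        recon = np.cumprod(1 - curve.events / curve.at_risk)
        assert np.allclose(curve.survival, recon)

    def test_empty_input_rejected(self):
        with pytest.raises(ValidationError):
            km_estimate([], [])


class TestSurvivalRateAt:
    def test_step_conventions(self):
        curve = km_estimate([1, 2], [True, True])
        assert survival_rate_at(curve, 0) == 1.0
        assert survival_rate_at(curve, 1.5) == pytest.approx(0.5)

    def test_extrapolation_warns(self):
        curve = km_estimate([1, 2], [True, True])
        with pytest.warns(UserWarning, match="extrapolat"):
            assert survival_rate_at(curve, 10) == pytest.approx(0.0)


def hand_logrank_two_groups(times_a, times_b):
    """O-E log-rank statistic for two fully-observed groups."""
    all_times = sorted(set(times_a) | set(times_b))
    o_minus_e = 0.0
    var = 0.0
    for t in all_times:
        n_a = sum(1 for x in times_a if x >= t)
        n_b = sum(1 for x in times_b if x >= t)
        d_a = times_a.count(t)
        d = d_a + times_b.count(t)
        n = n_a + n_b
        e_a = d * n_a / n
        o_minus_e += d_a - e_a
        if n > 1:
            var += d * (n_a / n) * (n_b / n) * (n - d) / (n - 1)
    return o_minus_e**2 / var


class TestLogrank:
    def test_identical_groups_null(self):
        t = [1, 2, 3, 1, 2, 3]
        res = logrank_test(["a"] * 3 + ["b"] * 3, t, [True] * 6)
        assert res.statistic == pytest.approx(0.0, abs=1e-12)
        assert res.p == pytest.approx(1.0)

    def test_matches_hand_computation(self):
        ta, tb = [1.0, 2.0, 3.0], [4.0, 5.0, 6.0]
        res = logrank_test(["a"] * 3 + ["b"] * 3, ta + tb, [True] * 6)
        assert res.statistic == pytest.approx(hand_logrank_two_groups(ta, tb))

    def test_invariant_to_affine_time_rescaling(self):
        rng = np.random.default_rng(8)
        t = rng.exponential(2, 50)
        e = rng.random(50) < 0.8
        g = rng.choice(["a", "b"], 50)
        r1 = logrank_test(g, t, e)
        r2 = logrank_test(g, 3.7 * t + 0.0, e)
        assert r1.statistic == pytest.approx(r2.statistic)

    def test_single_group_rejected(self):
        with pytest.raises(ValidationError):
            logrank_test(["a", "a"], [1, 2], [True, True])


class TestCox:
    def test_identical_event_patterns_null_coefficient(self):
        x = pd.DataFrame({"g": [0, 0, 0, 1, 1, 1]})
        res = cox_fit(x, [1, 2, 3, 1, 2, 3], [True] * 6)
        assert res.coefficients[0] == pytest.approx(0.0, abs=1e-6)
        assert res.hazard_ratios[0] == pytest.approx(1.0, abs=1e-6)

    def test_newton_matches_grid_search_partial_likelihood(self):
        x = np.array([1, 0, 1, 0, 0, 1])
        times = np.array([1.0, 2.0, 3.0, 4.0, 5.0, 6.0])
        events = np.array([1, 1, 0, 1, 1, 1], bool)

        def pll(beta):
            ll = 0.0
            for i in range(6):
                if not events[i]:
                    continue
                risk = times >= times[i]
                ll += beta * x[i] - np.log(np.sum(np.exp(beta * x[risk])))
            return ll

        grid = np.linspace(-3, 3, 600001)
        beta_star = grid[int(np.argmax([pll(b) for b in grid[::100]])) * 100]
        fine = np.linspace(beta_star - 0.01, beta_star + 0.01, 20001)
        beta_star = fine[int(np.argmax([pll(b) for b in fine]))]
        fit = cox_fit(pd.DataFrame({"x": x}), times, events)
        assert fit.coefficients[0] == pytest.approx(beta_star, abs=1e-4)

    def test_constant_covariate_rejected(self):
        with pytest.raises(ValidationError, match="constant"):
            cox_fit(pd.DataFrame({"x": [1, 1, 1]}), [1, 2, 3], [True] * 3)

    def test_parameter_recovery_binary_covariate(self):
        rng = np.random.default_rng(12)
        n = 2000
        g = rng.binomial(1, 0.5, n)
        t = rng.exponential(1 / (0.2 * np.exp(np.log(0.5) * g)))
        fit = cox_fit(pd.DataFrame({"g": g}), t, np.ones(n, bool))
        se = np.sqrt(1 / (g == 1).sum() + 1 / (g == 0).sum())
        assert abs(fit.coefficients[0] - np.log(0.5)) < 3 * se


def series(vals, idx=None):
    idx = idx or [f"S{i}" for i in range(len(vals))]
    return pd.Series(vals, index=idx)


class TestMatchedSelection:
    def test_perfect_interleaving_keeps_everything(self):
        labels = series(["A", "B", "A", "B"])
        cov = series([1.0, 2.0, 3.0, 4.0])
        res = matched_group_selection(labels, cov)
        assert sorted(res.kept_group_a) == ["S0", "S2"]
        assert sorted(res.kept_group_b) == ["S1", "S3"]
        assert res.discarded == []

    def test_blocked_labels_keep_middle_pair(self):
        labels = series(["A", "A", "B", "B"])
        cov = series([1.0, 2.0, 3.0, 4.0])
        res = matched_group_selection(labels, cov)
        assert res.kept_group_a == ["S1"] and res.kept_group_b == ["S2"]
        assert sorted(res.discarded) == ["S0", "S3"]

    def test_single_label_empty_with_warning(self):
        labels = series(["A", "A", "A"])
        cov = series([1.0, 2.0, 3.0])
        with pytest.warns(UserWarning, match="one group label"):
            res = matched_group_selection(labels, cov)
        assert res.kept_group_a == [] and res.kept_group_b == []
        assert sorted(res.discarded) == ["S0", "S1", "S2"]

    def test_no_adjacency_when_one_label_exhausted_first(self):
        labels = series(["A", "B"], idx=["S0", "S1"])
        cov = series([1.0, 5.0], idx=["S0", "S1"])
        res = matched_group_selection(labels, cov)
        assert res.kept_group_a == ["S0"] and res.kept_group_b == ["S1"]

    def test_strict_order_only_pairs_in_requested_direction(self):
        labels = series(["B", "A", "A", "B"])
        cov = series([1.0, 2.0, 3.0, 4.0])
        res = matched_group_selection(labels, cov, strict_order="A")
        # scan: (B,A) skipped under strict A-first, (A,A) no, (A,B) kept
        assert res.kept_group_a == ["S2"] and res.kept_group_b == ["S3"]

    @given(st.lists(st.sampled_from("AB"), min_size=2, max_size=60), st.randoms(use_true_random=False))
    @settings(max_examples=60, deadline=None)
    def test_kept_groups_equal_size_and_partition(self, labs, rnd):
        if len(set(labs)) < 2:
            labs = labs + ["A", "B"]
        cov = [rnd.random() for _ in labs]
        labels = series(labs, idx=[f"S{i}" for i in range(len(labs))])
        res = matched_group_selection(labels, series(cov, idx=list(labels.index)))
        assert len(res.kept_group_a) == len(res.kept_group_b)
        kept = set(res.kept_group_a) | set(res.kept_group_b)
        assert kept | set(res.discarded) == set(labels.index)
        assert kept & set(res.discarded) == set()

    def test_rerunning_on_kept_samples_keeps_everything(self):
        rng = np.random.default_rng(14)
        labs = rng.choice(["A", "B"], 40)
        cov = rng.normal(size=40)
        labels = series(list(labs))
        covs = series(cov, idx=list(labels.index))
        first = matched_group_selection(labels, covs)
        kept = first.kept_group_a + first.kept_group_b
        second = matched_group_selection(labels[kept], covs[kept])
        assert second.discarded == []
        assert set(second.kept_group_a) == set(first.kept_group_a)


class TestBalance:
    def test_identical_multisets(self):
        labels = series(["A", "B", "A", "B"])
        cov = series([1.0, 1.0, 2.0, 2.0])
        res = matched_group_selection(labels, cov)
        assert balance_test(res, cov) == pytest.approx(1.0)

    def test_extreme_separation_exact(self):
        groups = matched_group_selection(
            series(["A", "B", "A", "B"]), series([1.0, 2.0, 3.0, 4.0])
        )
        cov = series([1.0, 100.0, 2.0, 200.0])
        assert balance_test(groups, cov) == pytest.approx(1 / 3)


class TestScoreVersusBurdenPrognosis:
    """Matching one factor while varying the other isolates which is prognostic.

    Survival is generated from the latent deficiency only; score groups
    matched on mutation burden should stay prognostic, while burden
    groups matched on score should not.
    """

    def test_directional_property_at_fixed_seeds(self):
        score_ps, burden_ps = [], []
        for seed in range(8):
            c = simulate_cohort(seed=seed)
            burden = mutation_counts(c.bundle.mutations, c.bundle.sample_ids).astype(float)
            sig = SignatureSpec(
                tuple(c.planted.loc[c.planted["sign"] > 0, "mirna_id"]),
                tuple(c.planted.loc[c.planted["sign"] < 0, "mirna_id"]),
            )
            scores = assign_groups(compute_scores(c.bundle.expression, sig), cutoff=6, k=10)
            scores = scores.set_index("sample_id")
            clin = c.bundle.clinical.set_index("sample_id")

            def matched_logrank(labels, covariate):
                mg = matched_group_selection(labels, covariate)
                kept = mg.kept_group_a + mg.kept_group_b
                return logrank_test(
                    labels[kept],
                    clin.loc[kept, "os_time"].to_numpy(float),
                    clin.loc[kept, "os_event"].to_numpy(bool),
                ).p

            score_ps.append(matched_logrank(scores["group"], burden))
            burden_labels = pd.Series(
                np.where(burden >= burden.median(), "high", "low"), index=burden.index
            )
            burden_ps.append(matched_logrank(burden_labels, scores["score"].astype(float)))
        # pool evidence across replicates (Fisher's method): matched score
        # groups are jointly prognostic, matched burden groups are not
        def fisher_combine(ps):
            stat = -2 * np.sum(np.log(ps))
            from scipy import stats as sps

            return sps.chi2.sf(stat, 2 * len(ps))

        assert fisher_combine(score_ps) < 0.01
        assert fisher_combine(burden_ps) > 0.05
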