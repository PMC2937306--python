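"""Kaplan-Meier, area between curves, Cox partial likelihood, and optimal
stratification — each checked against hand computations, independent
naive oracles, and lifelines."""

import math

import numpy as np
import pandas as pd
import pytest
from lifelines import CoxPHFitter, KaplanMeierFitter
from scipy import optimize

import pathsig as ps
from pathsig.errors import ValidationError
from pathsig.survival import COX_COEF_CAP

from conftest import (
    make_signature,
    naive_area,
    naive_cox_loglik,
    naive_km,
    naive_optimal_stratify,
    random_survival_table,
)


def surv_table(times, events, ids=None):
    ids = ids or [f"s{i}" for i in range(len(times))]
    return pd.DataFrame(
        {"time": times, "event": events},
        index=pd.Index(ids, name="sample_id"),
    )


class TestKaplanMeier:
    def test_all_censored_curve_stays_at_one(self):
        curve = ps.km_estimate(surv_table([1.0, 2.0, 3.0], [0, 0, 0]))
        assert len(curve.times) == 0
        assert curve.survival_at([0.0, 1.5, 3.0]).tolist() == [1.0, 1.0, 1.0]

    def test_two_subject_hand_values(self):
        curve = ps.km_estimate(surv_table([1.0, 2.0], [1, 1]))
        np.testing.assert_allclose(curve.times, [1.0, 2.0])
        np.testing.assert_allclose(curve.survival, [0.5, 0.0])
        assert curve.survival_at(1.5) == pytest.approx(0.5)

    def test_three_subject_with_censoring_hand_values(self):
        curve = ps.km_estimate(surv_table([1.0, 1.5, 3.0], [1, 0, 1]))
        np.testing.assert_allclose(curve.times, [1.0, 3.0])
        np.testing.assert_allclose(curve.survival, [2.0 / 3.0, 0.0])
        np.testing.assert_array_equal(curve.at_risk, [3, 1])

    def test_negative_time_rejected(self):
        with pytest.raises(ValidationError):
            ps.km_estimate(surv_table([-1.0, 2.0], [1, 1]))

    def test_no_censoring_equals_empirical_survival(self):
        for seed in range(50):
            rng = np.random.default_rng(seed)
            n = int(rng.integers(2, 31))
            table = random_survival_table(rng, n, censor_frac=0.0)
            curve = ps.km_estimate(table)
            t = table["time"].to_numpy()
            for et, s in zip(curve.times, curve.survival):
                assert s == pytest.approx((t > et).sum() / n)

    def test_matches_lifelines(self):
        rng = np.random.default_rng(0)
        table = random_survival_table(rng, 60, censor_frac=0.3)
        curve = ps.km_estimate(table)
        kmf = KaplanMeierFitter().fit(table["time"], table["event"])
        ours = curve.survival_at(curve.times)
        theirs = kmf.survival_function_at_times(curve.times).to_numpy()
        np.testing.assert_allclose(ours, theirs, atol=1e-10)


class TestAreaBetween:
    def test_identical_curves_zero(self):
        curve = ps.km_estimate(surv_table([1.0, 2.0, 3.0], [1, 1, 0]))
        assert ps.area_between(curve, curve) == pytest.approx(0.0)

    def test_full_separation_equals_horizon(self):
        alive = ps.km_estimate(surv_table([10.0, 10.0], [0, 0]))
        dead = ps.km_estimate(surv_table([0.0, 0.0], [1, 1]))
        assert ps.area_between(alive, dead, horizon=7.0) == pytest.approx(7.0)

    def test_two_step_hand_rectangles(self):
        c1 = ps.km_estimate(surv_table([1.0, 3.0], [1, 1]))
        c2 = ps.km_estimate(surv_table([2.0, 4.0], [1, 1]))
        # |S1-S2| is 0 on [0,1), 0.5 on [1,2), 0 on [2,3); horizon = 3
        assert ps.area_between(c1, c2) == pytest.approx(0.5)

    def test_invalid_horizon(self):
        c = ps.km_estimate(surv_table([1.0], [1]))
        with pytest.raises(ValidationError):
            ps.area_between(c, c, horizon=0.0)

    def test_metric_properties_on_random_curves(self):
        rng = np.random.default_rng(1)
        for _ in range(20):
            tables = [random_survival_table(rng, 15) for _ in range(3)]
            curves = [ps.km_estimate(t) for t in tables]
            horizon = min(c.max_observed for c in curves)
            if horizon <= 0:
                continue
            d12 = ps.area_between(curves[0], curves[1], horizon)
            d21 = ps.area_between(curves[1], curves[0], horizon)
            d13 = ps.area_between(curves[0], curves[2], horizon)
            d32 = ps.area_between(curves[2], curves[1], horizon)
            assert d12 == pytest.approx(d21)
            assert d12 <= d13 + d32 + 1e-12


class TestCoxFit:
    def test_three_subject_score_equation_root(self):
        """Subjects with event times 1, 2, 3 (all events) and the covariate
        on the middle event: the coefficient solves
        1 = e^b/(2+e^b) + e^b/(1+e^b), i.e. b = ln(2)/2."""
        table = surv_table([1.0, 2.0, 3.0], [1, 1, 1])
        fit = ps.cox_fit([0.0, 1.0, 0.0], table)

        def score(b):
            eb = math.exp(b)
            return 1.0 - eb / (2.0 + eb) - eb / (1.0 + eb)

        root = optimize.bisect(score, -5.0, 5.0, xtol=1e-13)
        assert root == pytest.approx(math.log(2.0) / 2.0, abs=1e-10)
        assert fit.coef == pytest.approx(root, abs=1e-6)
        assert fit.converged

    def test_monotone_likelihood_flagged(self):
        """If the earliest event carries all the covariate mass the partial
        likelihood increases without bound; the fit must flag divergence
        and cap the coefficient."""
        table = surv_table([1.0, 2.0, 3.0], [1, 1, 1])
        fit = ps.cox_fit([1.0, 0.0, 0.0], table)
        assert fit.diverged
        assert abs(fit.coef) == pytest.approx(COX_COEF_CAP)

    def test_null_covariate_small_coefficient(self):
        rng = np.random.default_rng(0)
        table = random_survival_table(rng, 150, censor_frac=0.2)
        x = rng.normal(size=150)  # independent of outcome
        fit = ps.cox_fit(x, table)
        assert abs(fit.coef) < 3 * fit.se

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_grid_search_of_partial_likelihood(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(5, 11))
        table = random_survival_table(rng, n, censor_frac=0.2)
        if table["event"].sum() == 0:
            table.iloc[0, table.columns.get_loc("event")] = 1
        x = rng.normal(size=n)
        times = table["time"].to_numpy()
        events = table["event"].to_numpy()
        res = optimize.minimize_scalar(
            lambda b: -naive_cox_loglik(b, times, events, x - x.mean()),
            bounds=(-COX_COEF_CAP, COX_COEF_CAP), method="bounded",
            options={"xatol": 1e-10},
        )
        fit = ps.cox_fit(x, table)
        if fit.diverged:
            assert abs(res.x) > COX_COEF_CAP - 1.0
        else:
            assert fit.coef == pytest.approx(res.x, abs=1e-3)
            assert fit.loglik == pytest.approx(
                naive_cox_loglik(fit.coef, times, events, x - x.mean()),
                abs=1e-8,
            )

    def test_matches_lifelines_breslow(self):
        rng = np.random.default_rng(3)
        act = pd.Series(rng.normal(size=200),
                        index=[f"s{i}" for i in range(200)])
        table = ps.simulate_survival(act, log_hr=1.0, censor_rate=0.02,
                                     seed=4)
        fit = ps.cox_fit(act, table)
        df = table.assign(x=act)
        cph = CoxPHFitter().fit(df, "time", "event")
        assert fit.coef == pytest.approx(cph.params_["x"], abs=1e-4)
        assert fit.se == pytest.approx(cph.standard_errors_["x"], rel=1e-3)

    def test_error_contracts(self):
        table = surv_table([1.0, 2.0], [1, 1])
        with pytest.raises(ValidationError, match="constant"):
            ps.cox_fit([1.0, 1.0], table)
        with pytest.raises(ValidationError, match="events"):
            ps.cox_fit([0.0, 1.0], surv_table([1.0, 2.0], [0, 0]))


class TestOptimalStratify:
    def test_four_sample_fixture_separates_event_group(self):
        table = surv_table([1.5, 1.5, 1.0, 2.0], [0, 0, 1, 1])
        scores = pd.Series([1.0, 2.0, 3.0, 4.0], index=table.index)
        res = ps.optimal_stratify(scores, table, min_group_frac=0.25)
        assert res.threshold == pytest.approx(2.5)
        assert set(res.groups[res.groups == "high"].index) == {"s2", "s3"}
        thr, area = naive_optimal_stratify(scores, table, 0.25)
        assert res.threshold == pytest.approx(thr)
        assert res.area == pytest.approx(area)

    def test_identical_records_tie_break_to_lowest_threshold(self):
        table = surv_table([5.0] * 6, [1] * 6)
        scores = pd.Series([1.0, 2.0, 3.0, 4.0, 5.0, 6.0], index=table.index)
        res = ps.optimal_stratify(scores, table, min_group_frac=0.1)
        assert res.area == pytest.approx(0.0)
        assert res.threshold == pytest.approx(1.5)  # lowest admissible

    def test_constant_scores_rejected(self):
        table = surv_table([1.0, 2.0, 3.0], [1, 1, 1])
        with pytest.raises(ValidationError, match="no admissible split"):
            ps.optimal_stratify(pd.Series([2.0, 2.0, 2.0], index=table.index),
                                table)

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_exhaustive_scan(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(10, 40))
        table = random_survival_table(rng, n)
        if table["event"].sum() == 0:
            table.iloc[0, table.columns.get_loc("event")] = 1
        scores = pd.Series(rng.normal(size=n), index=table.index)
        res = ps.optimal_stratify(scores, table, min_group_frac=0.1)
        thr, area = naive_optimal_stratify(scores, table, 0.1)
        assert res.threshold == pytest.approx(thr)
        assert res.area == pytest.approx(area)

    def test_area_consistent_with_groups(self):
        rng = np.random.default_rng(11)
        table = random_survival_table(rng, 40)
        scores = pd.Series(rng.normal(size=40), index=table.index)
        res = ps.optimal_stratify(scores, table)
        recomputed = ps.area_between(res.curve_high, res.curve_low)
        assert res.area == pytest.approx(recomputed)

    def test_reports_both_cox_models(self):
        rng = np.random.default_rng(12)
        act = pd.Series(rng.normal(size=80),
                        index=[f"s{i}" for i in range(80)])
        table = ps.simulate_survival(act, log_hr=1.0, censor_rate=0.02,
                                     seed=13)
        res = ps.optimal_stratify(act, table)
        assert res.cox_group.n_events == res.cox_score.n_events
        assert 0 <= res.cox_group.p <= 1
        assert 0 <= res.cox_score.p <= 1


class TestStratifyByGene:
    def test_delegates_to_score_stratification(self):
        rng = np.random.default_rng(0)
        n = 40
        values = rng.normal(size=n)
        expr = pd.DataFrame(
            [values, rng.normal(size=n)],
            index=pd.Index(["probeX", "probeY"], name="probe_id"),
            columns=[f"s{i}" for i in range(n)],
        )
        table = random_survival_table(rng, n)
        by_gene = ps.stratify_by_gene(expr, "probeX", table)
        by_score = ps.optimal_stratify(
            pd.Series(values, index=expr.columns), table
        )
        assert by_gene.threshold == pytest.approx(by_score.threshold)
        assert by_gene.area == pytest.approx(by_score.area)
        assert (by_gene.groups == by_score.groups).all()

    def test_constant_probe_row_rejected(self):
        expr = pd.DataFrame(
            [[1.0, 1.0, 1.0]], index=pd.Index(["p"], name="probe_id"),
            columns=["a", "b", "c"],
        )
        table = surv_table([1.0, 2.0, 3.0], [1, 1, 1], ids=["a", "b", "c"])
        with pytest.raises(ValidationError, match="no admissible split"):
            ps.stratify_by_gene(expr, "p", table)

    def test_unknown_probe_rejected(self):
        expr = pd.DataFrame(
            [[1.0, 2.0]], index=pd.Index(["p"], name="probe_id"),
            columns=["a", "b"],
        )
        table = surv_table([1.0, 2.0], [1, 1], ids=["a", "b"])
        with pytest.raises(ValidationError, match="unknown probe"):
            ps.stratify_by_gene(expr, "nope", table)

    def test_signal_probe_selects_same_risk_group_as_scores(self):
        """When one probe carries the activity signal, gene-based and
        score-based stratification pick overlapping high-risk groups."""
        rng = np.random.default_rng(5)
        model = make_signature(
            rng.uniform(0.8, 1.0, 30),
            rng.choice([-1, 1], 30) * rng.uniform(0.5, 2.0, 30),
            rng.uniform(0.1, 0.5, 30),
        )
        cohort, act = ps.simulate_cohort(
            model, ps.CohortConfig(n_tumors=100, noise_scale=0.3, seed=6)
        )
        # append a dedicated probe tracking the activity directly
        gene_row = pd.DataFrame(
            [act.to_numpy() + rng.normal(0, 0.3, len(act))],
            index=pd.Index(["reporter"], name="probe_id"),
            columns=cohort.columns,
        )
        cohort_plus = pd.concat([cohort, gene_row])
        table = ps.simulate_survival(act, log_hr=1.0, censor_rate=0.02,
                                     seed=7)
        sv = ps.project_signature(model, cohort)
        by_score = ps.optimal_stratify(sv, table)
        by_gene = ps.stratify_by_gene(cohort_plus, "reporter", table)
        high_score = set(by_score.groups[by_score.groups == "high"].index)
        high_gene = set(by_gene.groups[by_gene.groups == "high"].index)
        jaccard = len(high_score & high_gene) / len(high_score | high_gene)
        assert jaccard >= 0.6
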