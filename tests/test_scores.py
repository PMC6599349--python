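"""Individual-scores arm: signed-rank test, response, logistic regression."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import stats

from honosnet.data import CohortTable, ItemProfile, PatientRecord, classify_severity
from honosnet.scores import (
    NON_RESPONDER,
    RESPONDER,
    cohort_wilcoxon,
    fit_response_logistic,
    paired_wilcoxon,
    response_proportion,
    response_status,
)

from .oracles import signed_rank_exact_p


class TestPairedWilcoxon:
    def test_all_pairs_equal_is_degenerate(self):
        res = paired_wilcoxon(np.ones(10), np.ones(10))
        assert res.degenerate and res.p_value == 1.0 and res.V == 0.0

    def test_all_positive_differences_give_maximal_v(self):
        # differences (baseline - endpoint) of 1, 2, 3 -> V = 3*4/2
        res = paired_wilcoxon(np.array([2, 4, 6.0]), np.array([1, 2, 3.0]))
        assert res.V == 6.0

    def test_exact_p_matches_full_enumeration_distinct(self):
        x = np.array([5.0, 1.0, 4.0, 2.0, 6.0, 3.0])
        y = np.array([1.0, 2.0, 1.0, 1.0, 1.0, 4.0])
        res = paired_wilcoxon(x, y)
        assert res.method == "exact"
        assert res.p_value == pytest.approx(signed_rank_exact_p(x, y), abs=1e-12)

    @pytest.mark.parametrize("seed", range(6))
    def test_exact_p_matches_full_enumeration_with_ties(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.integers(0, 5, 9).astype(float)
        y = rng.integers(0, 5, 9).astype(float)
        res = paired_wilcoxon(x, y)
        if res.degenerate:
            return
        assert res.p_value == pytest.approx(signed_rank_exact_p(x, y), abs=1e-12)

    def test_approximate_p_matches_scipy_with_tie_correction(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            x = rng.integers(0, 5, 60).astype(float)
            y = rng.integers(0, 5, 60).astype(float)
            mine = paired_wilcoxon(x, y)
            if mine.degenerate or mine.method != "approx":
                continue
            ref = stats.wilcoxon(
                x, y, zero_method="wilcox", correction=True, method="approx"
            )
            assert mine.p_value == pytest.approx(ref.pvalue, abs=1e-12)

    @given(
        st.lists(st.integers(0, 4), min_size=5, max_size=12),
        st.lists(st.integers(0, 4), min_size=12, max_size=12),
        st.integers(-3, 3),
    )
    def test_p_invariant_to_common_shift(self, xs, ys, shift):
        x = np.array(xs + [0] * (12 - len(xs)), dtype=float)
        y = np.array(ys, dtype=float)
        a = paired_wilcoxon(x, y)
        b = paired_wilcoxon(x + shift, y + shift)
        assert a.p_value == pytest.approx(b.p_value, abs=1e-12)
        assert a.V == b.V

    def test_statistic_bound(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            x = rng.integers(0, 5, 30).astype(float)
            y = rng.integers(0, 5, 30).astype(float)
            res = paired_wilcoxon(x, y)
            assert 0 <= res.V <= res.n_effective * (res.n_effective + 1) / 2


class TestResponse:
    def test_all_items_mild_is_responder(self):
        assert response_status(ItemProfile((2,) * 12)) == RESPONDER

    def test_single_severe_item_is_non_responder(self):
        assert response_status(ItemProfile((0,) * 11 + (4,))) == NON_RESPONDER

    def test_agrees_with_severity_negation_on_random_profiles(self, rng):
        for _ in range(1000):
            profile = ItemProfile(tuple(rng.integers(0, 5, 12)))
            expected = (
                RESPONDER if classify_severity(profile) == "non-severe"
                else NON_RESPONDER
            )
            assert response_status(profile) == expected

    def test_proportion_extremes(self):
        sev = ItemProfile((3,) + (0,) * 11)
        mild = ItemProfile((1,) + (0,) * 11)
        all_resp = CohortTable(tuple(
            PatientRecord(f"p{i}", 30, "female", sev, mild, 100.0)
            for i in range(5)
        ))
        none_resp = CohortTable(tuple(
            PatientRecord(f"p{i}", 30, "female", sev, sev, 100.0)
            for i in range(5)
        ))
        assert response_proportion(all_resp) == (5, 1.0)
        assert response_proportion(none_resp) == (0, 0.0)

    def test_cohort_wilcoxon_runs_per_item(self, study_cohort):
        cohort, _ = study_cohort
        results = cohort_wilcoxon(cohort)
        assert len(results) == 12
        assert all(0 <= r.p_value <= 1 for r in results)


def _cohort_from_arrays(base, end, ages, genders, delays):
    records = tuple(
        PatientRecord(
            f"p{i}", int(ages[i]), genders[i],
            ItemProfile(tuple(int(v) for v in base[i])),
            ItemProfile(tuple(int(v) for v in end[i])),
            float(delays[i]),
        )
        for i in range(len(ages))
    )
    return CohortTable(records)


def _random_cohort(rng, n, responder_logit=None):
    base = rng.integers(0, 5, (n, 12))
    base[:, 0] = np.maximum(base[:, 0], 3)  # all severe at baseline
    ages = rng.integers(20, 70, n)
    genders = np.where(rng.random(n) < 0.5, "male", "female")
    if responder_logit is None:
        responder = rng.random(n) < 0.5
    else:
        responder = rng.random(n) < 1 / (1 + np.exp(-responder_logit))
    end = np.where(responder[:, None], rng.integers(0, 3, (n, 12)), 0)
    end[~responder, 0] = 3
    delays = rng.normal(462, 170, n).clip(30)
    return _cohort_from_arrays(base, end, ages, genders, delays)


class TestLogistic:
    def test_null_model_slopes_within_three_se(self, rng):
        cohort = _random_cohort(rng, 500)
        fit = fit_response_logistic(cohort)
        assert fit.converged and not fit.separation_flag
        for name, coef, se in zip(
            fit.predictors[1:], fit.coefficients[1:], fit.standard_errors[1:]
        ):
            assert abs(coef) < 3 * se, name

    def test_matches_statsmodels(self, rng):
        import statsmodels.api as sm

        cohort = _random_cohort(rng, 300)
        fit = fit_response_logistic(cohort)
        X = np.column_stack([
            np.ones(len(cohort)),
            cohort.baseline_matrix(),
            cohort.ages(),
            [1.0 if g == "male" else 0.0 for g in cohort.genders()],
        ])
        y = np.array([
            1.0 if response_status(r.endpoint) == RESPONDER else 0.0
            for r in cohort
        ])
        ref = sm.Logit(y, X).fit(disp=0)
        assert np.allclose(fit.coefficients, ref.params, atol=1e-6)
        assert np.allclose(fit.standard_errors, ref.bse, atol=1e-5)

    def test_two_by_two_table_recovers_log_odds_ratio(self):
        # one binary predictor: the ML slope is exactly the log odds ratio
        # of the collapsed 2x2 table
        from honosnet.scores import _irls_logistic

        counts = {(0, 0): 30, (0, 1): 10, (1, 0): 15, (1, 1): 45}
        xs, ys = [], []
        for (x, resp), m in counts.items():
            xs += [x] * m
            ys += [resp] * m
        X = np.column_stack([np.ones(len(xs)), np.array(xs, float)])
        beta, _, converged, _ = _irls_logistic(X, np.array(ys, float))
        odds_ratio = (45 / 15) / (10 / 30)
        assert converged
        assert beta[1] == pytest.approx(np.log(odds_ratio), abs=1e-8)
        assert beta[0] == pytest.approx(np.log(10 / 30), abs=1e-8)

    def test_separation_flagged(self):
        # item 2 perfectly separates responders; other items vary freely
        n = 40
        rng = np.random.default_rng(1)
        base = rng.integers(0, 5, (n, 12))
        base[:, 0] = np.maximum(base[:, 0], 3)
        base[: n // 2, 1] = 4
        base[n // 2:, 1] = 0
        end = np.zeros((n, 12), dtype=int)
        end[n // 2:, 0] = 3  # non-responders exactly when item 2 was 0
        cohort = _cohort_from_arrays(
            base, end, rng.integers(20, 60, n),
            np.where(rng.random(n) < 0.5, "male", "female"),
            np.full(n, 365.0),
        )
        with pytest.warns(UserWarning, match="separation"):
            fit = fit_response_logistic(cohort)
        assert fit.separation_flag

    def test_deviance_never_increases_across_irls_iterations(self, rng):
        from honosnet.scores import _irls_logistic

        for _ in range(5):
            n = 120
            X = np.column_stack([np.ones(n), rng.normal(size=(n, 4))])
            logits = X @ rng.normal(scale=1.5, size=5)
            y = (rng.random(n) < 1 / (1 + np.exp(-logits))).astype(float)
            if len(np.unique(y)) < 2:
                continue
            trace: list[float] = []
            _irls_logistic(X, y, deviance_trace=trace)
            assert np.all(np.diff(trace) <= 1e-10)

    def test_single_class_outcome_rejected(self, rng):
        cohort = _random_cohort(rng, 50)
        records = tuple(
            PatientRecord(
                r.patient_id, r.age, r.gender, r.baseline,
                ItemProfile((0,) * 12), r.delay_days,
            )
            for r in cohort
        )
        with pytest.raises(ValueError, match="both classes"):
            fit_response_logistic(CohortTable(records))

    def test_rank_deficient_design_names_columns(self, rng):
        cohort = _random_cohort(rng, 100)
        # make item 12 a copy of item 11 at baseline
        records = tuple(
            PatientRecord(
                r.patient_id, r.age, r.gender,
                ItemProfile(r.baseline.scores[:11] + (r.baseline.scores[10],)),
                r.endpoint, r.delay_days,
            )
            for r in cohort
        )
        with pytest.raises(ValueError, match="collinear"):
            fit_response_logistic(CohortTable(records))
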