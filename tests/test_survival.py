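"""Cutoff scanning, binary and multivariate Cox fits, KM estimation."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from hallmarksurv.containers import MutationTable
from hallmarksurv.errors import EstimationError, InsufficientDataError
from hallmarksurv.survival import (
    SurvivalEndpoint,
    bh_qvalues,
    binary_group_from_mutations,
    candidate_cutoffs,
    cutoff_scan,
    endpoint_from_clinical,
    fit_cox_binary,
    km_curve,
    multivariate_cox,
)

from _oracles import (
    bh_stepup,
    brute_force_cox_binary,
    brute_force_cox_multivariate,
    kaplan_meier_table,
    logrank_o_e_v,
)
from conftest import make_clinical


def endpoint_of(times, events):
    ids = [f"S{i}" for i in range(len(times))]
    return SurvivalEndpoint(
        pd.Series(np.asarray(times, dtype=float), index=ids),
        pd.Series(np.asarray(events, dtype=float), index=ids),
    )


class TestCandidateCutoffs:
    def test_values_1_to_8(self):
        # Q1 = 2.75, Q3 = 6.25 under linear interpolation
        cuts = candidate_cutoffs(np.arange(1.0, 9.0))
        assert cuts.tolist() == [3.0, 4.0, 5.0, 6.0]

    def test_constant_values_empty(self):
        assert len(candidate_cutoffs(np.full(10, 3.0))) == 0

    def test_outlier_never_candidate(self):
        values = np.array([1, 2, 3, 4, 5, 6, 7, 1000.0])
        assert 1000.0 not in candidate_cutoffs(values)

    def test_fewer_than_8_values_is_error(self):
        with pytest.raises(InsufficientDataError):
            candidate_cutoffs(np.arange(7.0))

    def test_min_group_restricts_candidates(self):
        values = np.arange(1.0, 9.0)
        wide = candidate_cutoffs(values, min_group=1)
        narrow = candidate_cutoffs(values, min_group=4)
        assert set(narrow) <= set(wide)
        for v in narrow:
            assert (values <= v).sum() >= 4 and (values > v).sum() >= 4


class TestFitCoxBinary:
    def test_identical_groups_hr_one_p_one(self):
        times = [2.0, 4.0, 7.0, 2.0, 4.0, 7.0]
        events = [1, 1, 0, 1, 1, 0]
        group = [False, False, False, True, True, True]
        fit = fit_cox_binary(group, endpoint_of(times, events))
        assert fit.hr == pytest.approx(1.0, abs=1e-10)
        assert fit.p == pytest.approx(1.0, abs=1e-10)

    def test_matches_brute_force_and_handrolled_logrank(self):
        times = [2.0, 4.0, 1.0, 3.0]
        events = [1, 1, 1, 1]
        group = [False, False, True, True]
        fit = fit_cox_binary(group, endpoint_of(times, events))
        beta_oracle = brute_force_cox_binary(times, events, group)
        _, p_oracle = logrank_o_e_v(times, events, group)
        assert fit.log_hr == pytest.approx(beta_oracle, rel=1e-6, abs=1e-8)
        assert fit.p == pytest.approx(p_oracle, rel=1e-10)

    def test_matches_lifelines_on_random_instances(self):
        from lifelines import CoxPHFitter

        rng = np.random.default_rng(12)
        for _ in range(10):
            n = 30
            times = np.round(rng.exponential(12, n), 1) + 0.1
            events = (rng.uniform(size=n) < 0.7).astype(float)
            group = rng.uniform(size=n) < 0.5
            if events[group].sum() < 2 or events[~group].sum() < 2:
                continue
            fit = fit_cox_binary(group, endpoint_of(times, events))
            cph = CoxPHFitter()
            cph.fit(
                pd.DataFrame({"t": times, "e": events, "z": group.astype(float)}),
                "t", "e",
            )
            # lifelines' own stopping rule is looser than the Newton tol here
            assert fit.log_hr == pytest.approx(cph.params_.iloc[0], rel=1e-2, abs=5e-4)
            se = np.log(fit.ci_high / fit.hr) / 1.959963984540054
            assert se == pytest.approx(cph.standard_errors_.iloc[0], rel=1e-3)

    def test_all_censored_high_group_is_degenerate(self):
        times = [1.0, 2.0, 3.0, 4.0, 5.0, 6.0]
        events = [1, 1, 1, 0, 0, 0]
        group = [False, False, False, True, True, True]
        fit = fit_cox_binary(group, endpoint_of(times, events))
        assert fit.degenerate
        assert fit.hr == 0.0  # no events in the high group
        assert np.isnan(fit.ci_low) and np.isnan(fit.ci_high)

    def test_hazard_increase_in_high_group_gives_hr_above_one(self):
        rng = np.random.default_rng(3)
        n = 200
        group = np.arange(n) < n // 2
        hazard = np.where(group, 0.09, 0.03)
        times = rng.exponential(1 / hazard)
        fit = fit_cox_binary(group, endpoint_of(times, np.ones(n)))
        assert fit.hr > 1.0
        assert fit.ci_low <= fit.hr <= fit.ci_high

    def test_empty_group_is_error(self):
        with pytest.raises(EstimationError):
            fit_cox_binary([True, True], endpoint_of([1.0, 2.0], [1, 1]))


class TestBenjaminiHochberg:
    def test_worked_example(self):
        q = bh_qvalues([0.01, 0.02, 0.04, 0.5])
        np.testing.assert_allclose(q, [0.04, 0.04, 0.04 * 4 / 3, 0.5], rtol=1e-12)

    @settings(derandomize=True, deadline=None, max_examples=200)
    @given(
        st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=1, max_size=12)
    )
    def test_matches_stepup_definition(self, p_values):
        np.testing.assert_allclose(
            bh_qvalues(p_values), bh_stepup(p_values), rtol=1e-12, atol=1e-12
        )


class TestCutoffScan:
    @staticmethod
    def scan_inputs(n=60, seed=5, effect=None):
        rng = np.random.default_rng(seed)
        values = rng.gamma(3, 100, n)
        hazard = np.full(n, 0.05)
        if effect is not None:
            cutoff, hr = effect
            hazard[values > np.quantile(values, cutoff)] *= hr
        times = rng.exponential(1 / hazard)
        events = np.ones(n)
        ids = [f"S{i}" for i in range(n)]
        series = pd.Series(values, index=ids)
        return series, SurvivalEndpoint(
            pd.Series(times, index=ids), pd.Series(events, index=ids)
        )

    def test_single_candidate_q_equals_p(self):
        # Q1 = 1, Q3 = 1.25: the only usable cutoff is 1.0
        values = pd.Series(
            [1.0, 1.0, 1.0, 1.0, 1.0, 1.0, 2.0, 2.0],
            index=[f"S{i}" for i in range(8)],
        )
        endpoint = endpoint_of([3, 1, 4, 2, 6, 5, 8, 7], [1] * 8)
        scan = cutoff_scan(values, endpoint)
        assert len(scan.cutoffs) == 1
        assert scan.q_values[0] == pytest.approx(scan.p_values[0], rel=1e-12)
        assert scan.significant == (scan.p_values[0] < 0.10)

    def test_scan_pvalues_match_isolated_fits(self):
        values, endpoint = self.scan_inputs(n=40)
        scan = cutoff_scan(values, endpoint)
        for cutoff, p in zip(scan.cutoffs, scan.p_values):
            fit = fit_cox_binary((values > cutoff).to_numpy(), endpoint)
            assert p == pytest.approx(fit.p, rel=1e-12)

    def test_monotone_transform_leaves_pvalues_unchanged(self):
        values, endpoint = self.scan_inputs(n=50)
        scan = cutoff_scan(values, endpoint)
        transformed = cutoff_scan(np.exp(values / values.max()) * 7, endpoint)
        np.testing.assert_allclose(scan.p_values, transformed.p_values, rtol=1e-12)
        # best cutoffs correspond to the same split
        assert scan.best_cutoff_quantile == pytest.approx(
            transformed.best_cutoff_quantile
        )

    def test_best_cutoff_attains_min_p_tie_to_smaller(self):
        values, endpoint = self.scan_inputs(n=45, seed=9)
        scan = cutoff_scan(values, endpoint)
        assert scan.best_fit.p == pytest.approx(scan.p_values.min(), rel=1e-12)
        winners = scan.cutoffs[scan.p_values == scan.p_values.min()]
        assert scan.best_cutoff == winners.min()

    def test_q_geq_p_elementwise_and_lengths(self):
        values, endpoint = self.scan_inputs(n=50, seed=2)
        scan = cutoff_scan(values, endpoint)
        assert len(scan.cutoffs) == len(scan.p_values) == len(scan.q_values)
        assert (scan.q_values >= scan.p_values - 1e-15).all()

    def test_planted_effect_recovered(self):
        values, endpoint = self.scan_inputs(n=200, seed=7, effect=(0.6, 3.0))
        scan = cutoff_scan(values, endpoint)
        assert scan.significant
        assert scan.best_fit.hr > 1.0
        assert abs(scan.best_cutoff_quantile - 0.6) <= 0.15

    def test_constant_values_not_evaluable(self):
        values = pd.Series(np.full(20, 5.0), index=[f"S{i}" for i in range(20)])
        endpoint = endpoint_of(np.arange(1.0, 21.0), np.ones(20))
        scan = cutoff_scan(values, endpoint)
        assert not scan.evaluable and not scan.significant
        assert scan.best_fit is None

    def test_missing_values_dropped_pairwise(self):
        values, endpoint = self.scan_inputs(n=40, seed=4)
        with_nan = values.copy()
        with_nan.iloc[:5] = np.nan
        scan = cutoff_scan(with_nan, endpoint)
        trimmed = cutoff_scan(values.iloc[5:], endpoint.subset(values.index[5:]))
        np.testing.assert_allclose(scan.p_values, trimmed.p_values, rtol=1e-12)


class TestMultivariate:
    def test_collinear_covariate_dropped(self):
        clinical = make_clinical(60, np.random.default_rng(8))
        endpoint = endpoint_from_clinical(clinical, "os")
        group = pd.Series(
            np.arange(len(endpoint)) % 2 == 0, index=endpoint.sample_ids
        )
        # stage copied from the feature indicator -> perfectly collinear
        frame = clinical.data.copy()
        frame["stage"] = group.astype(float)
        from hallmarksurv.containers import ClinicalTable

        result = multivariate_cox(
            group, ClinicalTable(frame), endpoint, covariates=["stage", "age"]
        )
        assert result.dropped.get("stage") == "collinear"
        assert "age" in result.terms.index

    def test_constant_covariate_dropped(self):
        clinical = make_clinical(50, np.random.default_rng(9))
        frame = clinical.data.copy()
        frame["sex"] = "F"
        from hallmarksurv.containers import ClinicalTable

        endpoint = endpoint_from_clinical(ClinicalTable(frame), "os")
        group = pd.Series(np.arange(len(endpoint)) % 2 == 0, index=endpoint.sample_ids)
        result = multivariate_cox(
            group, ClinicalTable(frame), endpoint, covariates=["sex", "age"]
        )
        assert result.dropped.get("sex_M") == "constant"

    def test_matches_brute_force_newton_on_small_dataset(self):
        rng = np.random.default_rng(21)
        n = 12
        times = np.round(rng.exponential(10, n), 1) + 0.5
        events = np.ones(n)
        group = np.tile([True, False], 6)
        age = np.round(rng.normal(60, 8, n), 1)
        clinical = make_clinical(n, rng, times=times, events=events)
        frame = clinical.data.copy()
        frame["age"] = age
        from hallmarksurv.containers import ClinicalTable

        clinical = ClinicalTable(frame)
        endpoint = endpoint_from_clinical(clinical, "os")
        group_s = pd.Series(group, index=endpoint.sample_ids)
        result = multivariate_cox(
            group_s, clinical, endpoint, covariates=["age"], min_events=5
        )
        design = np.column_stack([group.astype(float), age])
        beta = brute_force_cox_multivariate(times, events, design)
        fitted = np.log(result.terms["hr"].to_numpy())
        np.testing.assert_allclose(fitted, beta, rtol=1e-4, atol=1e-6)

    def test_independent_covariate_preserves_feature_hr(self):
        rng = np.random.default_rng(30)
        n = 2000
        group = rng.uniform(size=n) < 0.5
        hazard = np.where(group, 0.06, 0.02)
        times = rng.exponential(1 / hazard)
        events = np.ones(n)
        clinical = make_clinical(n, rng, times=times, events=events)
        endpoint = endpoint_from_clinical(clinical, "os")
        group_s = pd.Series(group, index=endpoint.sample_ids)
        uni = fit_cox_binary(group, endpoint)
        multi = multivariate_cox(group_s, clinical, endpoint, covariates=["age"])
        feature_hr = multi.terms.loc["feature_high", "hr"]
        assert feature_hr == pytest.approx(uni.hr, rel=0.10)

    def test_too_few_events_is_error(self):
        rng = np.random.default_rng(31)
        clinical = make_clinical(20, rng, times=np.arange(1.0, 21.0),
                                 events=np.array([1.0] * 5 + [0.0] * 15))
        endpoint = endpoint_from_clinical(clinical, "os")
        group = pd.Series(np.arange(20) % 2 == 0, index=endpoint.sample_ids)
        with pytest.raises(InsufficientDataError):
            multivariate_cox(group, clinical, endpoint, covariates=["age"])


class TestMutationGrouping:
    def test_empty_table_all_wild_type(self):
        table = MutationTable(
            pd.DataFrame(columns=["sample_id", "gene_symbol", "variant_classification"])
        )
        labels = binary_group_from_mutations(table, "TP53", ["S1", "S2"])
        assert not labels.any()

    def test_missense_marks_mutant(self, toy_mutations):
        labels = binary_group_from_mutations(toy_mutations, "TP53", ["S1", "S2", "S3"])
        assert labels.tolist() == [True, False, False]

    def test_silent_only_is_wild_type(self):
        table = MutationTable(
            pd.DataFrame(
                {
                    "sample_id": ["S1"],
                    "gene_symbol": ["TP53"],
                    "variant_classification": ["Silent"],
                }
            )
        )
        labels = binary_group_from_mutations(table, "TP53", ["S1", "S2"])
        assert not labels.any()


class TestKaplanMeier:
    def test_no_censoring_equals_empirical_survival(self):
        endpoint = endpoint_of([1.0, 2.0, 3.0, 4.0], [1, 1, 1, 1])
        curve = km_curve(["a"] * 4, endpoint)["a"]
        np.testing.assert_allclose(curve.survival, [0.75, 0.5, 0.25, 0.0])
        assert curve.median == 2.0

    def test_all_censored_survival_one_median_undefined(self):
        endpoint = endpoint_of([1.0, 2.0, 3.0, 4.0], [0, 0, 0, 0])
        curve = km_curve(["a"] * 4, endpoint)["a"]
        assert len(curve.times) == 0
        assert np.isnan(curve.median)

    def test_mixed_censoring_matches_hand_table(self, toy_endpoint):
        curve = km_curve(["a"] * 6, toy_endpoint)["a"]
        t, s, n = kaplan_meier_table(
            toy_endpoint.time.to_numpy(), toy_endpoint.event.to_numpy()
        )
        np.testing.assert_allclose(curve.times, t)
        np.testing.assert_allclose(curve.survival, s)
        np.testing.assert_array_equal(curve.at_risk, n)

    def test_matches_lifelines(self, toy_endpoint):
        from lifelines import KaplanMeierFitter

        curve = km_curve(["a"] * 6, toy_endpoint)["a"]
        kmf = KaplanMeierFitter()
        kmf.fit(toy_endpoint.time, toy_endpoint.event)
        for t, s in zip(curve.times, curve.survival):
            assert s == pytest.approx(
                float(kmf.survival_function_at_times(t).iloc[0]), rel=1e-12
            )

    def test_two_groups_keyed_by_label(self, toy_endpoint):
        curves = km_curve(["low", "low", "low", "high", "high", "high"], toy_endpoint)
        assert set(curves) == {"low", "high"}
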