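"""Partial-likelihood ERR engine: oracles, recovery, invariances."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from radcohort.err_engine import (
    CHI2_95_1DF,
    RiskSet,
    assign_birth_cohort,
    build_risk_sets,
    fit_categorical_rr,
    fit_linear_err,
    linear_err_loglik,
)
from radcohort.err_engine import test_heterogeneity as heterogeneity_test
from radcohort.err_engine import test_trend as trend_test


class TestLogLikelihood:
    def test_null_reduces_to_uniform_choice(self, toy_risk_sets):
        ll = linear_err_loglik(0.0, toy_risk_sets)
        assert ll == pytest.approx(-(np.log(3) + np.log(2)), abs=1e-14)

    @pytest.mark.parametrize("beta", [-0.05, 0.0, 0.01, 0.04, 0.2])
    def test_matches_hand_enumeration(self, toy_risk_sets, beta):
        hand = (np.log(1 + 10 * beta) - np.log(3 + 10 * beta)
                - np.log(2 + 10 * beta))
        assert linear_err_loglik(beta, toy_risk_sets) == \
            pytest.approx(hand, abs=1e-12)

    def test_constant_when_no_exposure_variation(self):
        rs = [RiskSet(5.0, ("s",), "a", np.arange(3),
                      np.array([7.0, 7.0, 7.0]))]
        lls = [linear_err_loglik(b, rs) for b in (0.0, 0.05, 0.1)]
        assert np.ptp(lls) < 1e-12

    def test_inadmissible_beta_is_minus_inf(self, toy_risk_sets):
        assert linear_err_loglik(-0.2, toy_risk_sets) == -np.inf


class TestLinearFit:
    def test_analytic_root(self, toy_risk_sets):
        fit = fit_linear_err(toy_risk_sets)
        assert fit.beta_hat == pytest.approx((np.sqrt(2) - 1) / 10,
                                             abs=1e-6)
        assert fit.status == "ok"

    def test_profile_ci_endpoints_satisfy_deviance(self, toy_risk_sets):
        fit = fit_linear_err(toy_risk_sets)
        for bound in (fit.ci_low, fit.ci_high):
            dev = 2 * (fit.loglik - linear_err_loglik(bound, toy_risk_sets))
            assert dev == pytest.approx(CHI2_95_1DF, abs=1e-6)

    def test_all_zero_doses_non_identifiable(self):
        rs = [RiskSet(5.0, ("s",), "a", np.arange(4), np.zeros(4))]
        fit = fit_linear_err(rs)
        assert fit.status == "non_identifiable"
        assert np.isnan(fit.beta_hat)

    def test_no_cases(self):
        fit = fit_linear_err([])
        assert fit.status == "no_cases"

    def test_deterministic(self, toy_risk_sets):
        a = fit_linear_err(toy_risk_sets)
        b = fit_linear_err(toy_risk_sets)
        assert a.beta_hat == b.beta_hat
        assert a.ci_low == b.ci_low and a.ci_high == b.ci_high


def _brute_force_risk_sets(cohort, endpoint_ids, lag=2.0):
    """Direct enumeration oracle: loop persons x cases with pandas only."""
    fu = cohort.with_followup().followup.set_index("person_id")
    persons = cohort.persons.set_index("person_id", drop=False)
    bc = assign_birth_cohort(persons["birth_date"])
    persons = persons.assign(bc=bc)
    dose = cohort.dose_summary.set_index("exam_id")["abm_dose_mean"]
    exams = cohort.exams.assign(dose=cohort.exams["exam_id"].map(dose))
    out = []
    for pid in endpoint_ids:
        t = float(fu.loc[pid, "exit_age"])
        if not (fu.loc[pid, "entry_age"] < t <= fu.loc[pid, "exit_age"]):
            continue
        p = persons.loc[pid]
        same = persons[(persons["sex"] == p["sex"])
                       & (persons["country"] == p["country"])
                       & (persons["bc"] == p["bc"])]
        members, expos = [], []
        for mid, m in same.iterrows():
            if fu.loc[mid, "entry_age"] < t <= fu.loc[mid, "exit_age"]:
                e = exams[exams["person_id"] == mid]
                z = e.loc[e["age_at_exam"] <= t - lag, "dose"].sum()
                members.append(mid)
                expos.append(z)
        out.append((pid, t, dict(zip(members, expos))))
    return out


class TestRiskSetConstruction:
    @pytest.fixture(scope="class")
    def built(self, small_sim):
        rs = build_risk_sets(small_sim.cohort, "all_heme", lag=2.0)
        return small_sim, rs

    def test_membership_against_brute_force(self, built):
        sim, rs = built
        case_ids = [r.case_id for r in rs][:25]
        oracle = {pid: (t, mem) for pid, t, mem in
                  _brute_force_risk_sets(sim.cohort, case_ids)}
        persons = sim.cohort.persons.reset_index(drop=True)
        checked = 0
        for r in rs:
            if r.case_id not in oracle:
                continue
            t, mem = oracle[r.case_id]
            ids = persons["person_id"].to_numpy()[r.member_idx]
            assert set(ids) == set(mem)
            got = dict(zip(ids, np.asarray(r.exposures, float)))
            for mid, z in mem.items():
                assert got[mid] == pytest.approx(z, abs=1e-9)
            checked += 1
        assert checked == len(oracle)

    def test_membership_window_validity(self, built):
        sim, rs = built
        fu = sim.cohort.followup.set_index("person_id")
        persons = sim.cohort.persons.reset_index(drop=True)
        for r in rs:
            ids = persons["person_id"].to_numpy()[r.member_idx]
            entry = fu.loc[ids, "entry_age"].to_numpy()
            exit_ = fu.loc[ids, "exit_age"].to_numpy()
            assert (entry < r.event_age).all()
            assert (r.event_age <= exit_ + 1e-12).all()
            assert ids[0] == r.case_id

    def test_strata_never_mix_countries(self, built):
        sim, rs = built
        country = sim.cohort.persons["country"].to_numpy()
        for r in rs:
            assert len(np.unique(country[r.member_idx])) == 1

    def test_case_with_no_peers_warns(self):
        persons = pd.DataFrame({
            "person_id": ["a", "b"], "sex": ["male", "female"],
            "country": ["UK", "UK"], "birth_date": [1990.0, 1990.0],
            "registry_start": [1971.0, 1971.0],
            "death_date": [np.nan] * 2, "emigration_date": [np.nan] * 2,
            "admin_end_date": [2016.0] * 2})
        exams = pd.DataFrame({
            "exam_id": ["e1", "e2"], "person_id": ["a", "b"],
            "age_at_exam": [3.0, 3.0], "calendar_year": [1993, 1993],
            "body_region": ["head_neck"] * 2, "hospital_id": ["h"] * 2})
        outcomes = pd.DataFrame({
            "person_id": ["a"], "age_at_diagnosis": [10.0],
            "morphology_code": ["9650"], "behavior_code": [3]})
        ds = pd.DataFrame({"exam_id": ["e1", "e2"],
                           "abm_dose_mean": [5.0, 5.0]})
        from radcohort.cohort_data import Cohort
        cohort = Cohort(persons, exams, outcomes, dose_summary=ds)
        with pytest.warns(UserWarning, match="no stratum peers"):
            rs = build_risk_sets(cohort, "all_heme")
        assert len(rs) == 1 and rs[0].n == 1

    def test_control_sampling_caps_set_size(self, built):
        sim, _ = built
        rng = np.random.default_rng(5)
        rs = build_risk_sets(sim.cohort, "all_heme", control_sample=50,
                             rng=rng)
        assert all(r.n <= 51 for r in rs)
        persons = sim.cohort.persons.reset_index(drop=True)
        ids = persons["person_id"].to_numpy()
        assert all(ids[r.member_idx[0]] == r.case_id for r in rs)


class TestCategorical:
    def test_reference_category_is_unity_without_ci(self, small_sim):
        rs = build_risk_sets(small_sim.cohort, "all_heme")
        cat = fit_categorical_rr(rs)
        assert cat.rr[0] == 1.0
        assert np.isnan(cat.ci_low[0]) and np.isnan(cat.ci_high[0])
        assert cat.categories[0] == "[0,5)"

    def test_no_dose_variation_gives_unit_rr(self):
        rng = np.random.default_rng(0)
        rs = [RiskSet(float(i), ("s",), f"c{i}", np.arange(30),
                      np.full(30, 7.0)) for i in range(40)]
        cat = fit_categorical_rr(rs, cutpoints=(5.0,))
        assert np.allclose(cat.rr[~np.isnan(cat.rr)], 1.0, atol=1e-6)

    def test_rr2_recovery(self):
        """Cases drawn with doubled rate in the exposed category."""
        rng = np.random.default_rng(8)
        rs = []
        for i in range(2000):
            expo = np.r_[np.zeros(100), np.full(50, 10.0)]
            # P(case exposed) = 50*2 / (100 + 50*2) = 0.5
            case_exposed = rng.random() < 0.5
            case_pos = (rng.integers(100, 150) if case_exposed
                        else rng.integers(0, 100))
            order = np.r_[case_pos, np.delete(np.arange(150), case_pos)]
            rs.append(RiskSet(float(i), ("s",), f"c{i}", order,
                              expo[order]))
        cat = fit_categorical_rr(rs, cutpoints=(5.0,))
        assert 1.8 <= cat.rr[1] <= 2.2


class TestTrend:
    def test_strong_gradient_detected(self, small_sim):
        rs = build_risk_sets(small_sim.cohort, "all_heme")
        res = trend_test(rs)
        assert res.p_value < 0.01
        assert res.slope > 0

    def test_permutation_null_uniform(self):
        """Cases picked uniformly at random => p-values ~ U(0,1)."""
        rng = np.random.default_rng(10)
        pvals = []
        for rep in range(200):
            rs = []
            for i in range(60):
                expo = rng.lognormal(1.5, 1.0, 40)
                case_pos = rng.integers(0, 40)
                order = np.r_[case_pos, np.delete(np.arange(40), case_pos)]
                rs.append(RiskSet(float(i), ("s",), f"c{i}", order,
                                  expo[order]))
            pvals.append(trend_test(rs).p_value)
        ks = stats.kstest(pvals, "uniform")
        assert ks.pvalue > 0.01

    def test_single_occupied_category_undefined(self):
        rs = [RiskSet(1.0, ("s",), "a", np.arange(3),
                      np.array([1.0, 1.0, 2.0]))]
        res = trend_test(rs, cutpoints=(5.0,))
        assert res.status == "single_category"
        assert np.isnan(res.p_value)

    def test_mean_dose_score_variant_runs(self, small_sim):
        rs = build_risk_sets(small_sim.cohort, "all_heme")
        res = trend_test(rs, score="mean_dose")
        assert 0 <= res.p_value <= 1


class TestHeterogeneity:
    def test_three_windows_give_three_betas_df_two(self, small_sim):
        rs = build_risk_sets(small_sim.cohort, "all_heme",
                             windows=((0, 5), (5, 10), (10, 200)))
        het = heterogeneity_test(rs, ci=False)
        assert het.betas.shape == (3,)
        assert het.df == 2
        assert 0 <= het.p_value <= 1

    def test_all_exposure_in_one_window_gives_zero_lrt(self):
        rng = np.random.default_rng(2)
        rs = []
        for i in range(30):
            z = np.zeros((25, 3))
            z[:, 1] = rng.lognormal(1.0, 0.8, 25)
            rs.append(RiskSet(float(i), ("s",), f"c{i}", np.arange(25), z))
        het = heterogeneity_test(rs, ci=False)
        assert het.lrt_statistic == pytest.approx(0.0, abs=1e-6)
        assert het.df == 0
        assert np.isnan(het.betas[0]) and np.isnan(het.betas[2])

    def test_profile_ci_brackets_estimate(self, small_sim):
        rs = build_risk_sets(small_sim.cohort, "all_heme",
                             windows=((0, 10), (10, 200)))
        het = heterogeneity_test(rs, ci=True)
        for j in range(2):
            if np.isnan(het.betas[j]):
                continue
            assert het.ci_low[j] <= het.betas[j] <= het.ci_high[j]

    def test_sex_interaction_routes_dose_by_subgroup(self, small_sim):
        rs = build_risk_sets(small_sim.cohort, "all_heme",
                             strata_vars=("country", "birth_cohort"),
                             interaction="sex")
        assert rs[0].exposures.shape[1] == 2
        assert rs[0].window_labels == ("female", "male")
        het = heterogeneity_test(rs, ci=False)
        assert het.df == 1


class TestSmallCohortOracle:
    def test_engine_equals_direct_enumeration(self, tiny_cohort):
        """<=10 persons: engine loglik equals hand enumeration to 1e-12."""
        rs = build_risk_sets(tiny_cohort, "all_heme", lag=2.0)
        # p1 (UK male, diagnosed at 14) has no same-stratum peers: p2 is
        # female, p3 is Swedish -> single risk set of size 1
        assert len(rs) == 1
        assert rs[0].n == 1
        # enlarge: put p2 in the same stratum by making it male
        persons = tiny_cohort.persons.copy()
        persons.loc[1, "sex"] = "male"
        from radcohort.cohort_data import Cohort
        cohort = Cohort(persons, tiny_cohort.exams, tiny_cohort.outcomes,
                        dose_summary=tiny_cohort.dose_summary)
        rs = build_risk_sets(cohort, "all_heme", lag=2.0)
        assert len(rs) == 1 and rs[0].n == 2
        # case p1 at t=14: Z = 10 + 5 (both exams lagged in);
        # p2: one exam at 5 -> Z = 8
        for beta in (0.0, 0.01, 0.05):
            hand = np.log(1 + beta * 15.0) - np.log(
                (1 + beta * 15.0) + (1 + beta * 8.0))
            assert linear_err_loglik(beta, rs) == \
                pytest.approx(hand, abs=1e-12)
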