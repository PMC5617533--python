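"""Survival machinery: KM, log-rank, cutoff search, Cox, composite score."""

import itertools

import numpy as np
import pandas as pd
import pytest

from ohscc.survival import (
    OS_RISK_DEFINITION,
    PREVIOUS_SYSTEM_DEFINITION,
    RFS_RISK_DEFINITION,
    RiskDefinition,
    RiskRule,
    assign_score,
    compare_systems,
    find_cutoff,
    fit_cox,
    km_estimate,
    logrank_test,
    stratify_and_compare,
    survival_at,
)
from ohscc.synthetic import CohortSpec, generate_cohort
from oracles import cox_single_covariate_brute, km_brute, logrank_brute


class TestKaplanMeier:
    def test_no_censoring_half_events(self):
        curve = km_estimate([1, 1, 10, 10], [1, 1, 0, 0])
        assert survival_at(curve, 5.0) == pytest.approx(0.5)

    def test_all_censored_curve_stays_at_one(self):
        curve = km_estimate([3, 5, 7], [0, 0, 0])
        assert survival_at(curve, 6.0) == 1.0

    def test_hand_product_limit(self):
        curve = km_estimate([1, 2, 3], [1, 1, 1])
        assert survival_at(curve, 2.0) == pytest.approx(1 / 3)
        assert survival_at(curve, 0.5) == 1.0

    def test_t_zero_is_one_and_beyond_followup_flags(self):
        curve = km_estimate([1, 2], [1, 0])
        assert survival_at(curve, 0.0) == 1.0
        with pytest.warns(UserWarning, match="follow-up"):
            survival_at(curve, 100.0)

    def test_matches_brute_force_on_exhaustive_small_sets(self):
        """Product-limit values equal the risk-table computation on every
        censoring pattern of 5 patients with tied and untied times."""
        times = np.array([1.0, 2.0, 2.0, 3.0, 4.0])
        for events in itertools.product([0, 1], repeat=5):
            if sum(events) == 0:
                continue
            curve = km_estimate(times, list(events))
            bt, bs = km_brute(times, list(events))
            for t, s in zip(bt, bs):
                assert survival_at(curve, t) == pytest.approx(s, abs=1e-12)


class TestLogrank:
    def test_identical_groups_give_zero_statistic(self):
        g = ([1, 2, 3, 4], [1, 1, 0, 1])
        stat, p = logrank_test([g, g])
        assert stat == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_hand_computed_two_group_example(self):
        # O-E/V risk-table arithmetic done by hand: chi2 = 0.36/0.74
        stat, p = logrank_test([([1, 3, 5], [1, 1, 0]), ([2, 4, 6], [1, 0, 1])])
        assert stat == pytest.approx(0.6**2 / 0.74, rel=1e-9)

    def test_matches_brute_force_on_exhaustive_small_sets(self, rng):
        times = np.array([1.0, 2.0, 3.0, 4.0, 5.0, 6.0, 7.0, 8.0])
        for trial in range(30):
            events = rng.integers(0, 2, size=8)
            labels = rng.integers(0, 2, size=8)
            if events.sum() == 0 or len(set(labels)) < 2:
                continue
            groups = [(times[labels == g], events[labels == g]) for g in (0, 1)]
            try:
                expected = logrank_brute(groups)
            except np.linalg.LinAlgError:
                continue  # zero-variance degenerate pattern
            stat, _ = logrank_test(groups)
            assert stat == pytest.approx(expected, rel=1e-9, abs=1e-12)

    def test_four_strata_null_p_roughly_uniform(self, rng):
        pvals = []
        for _ in range(60):
            times = rng.exponential(10, size=80)
            events = (rng.random(80) < 0.8).astype(int)
            labels = rng.integers(0, 4, size=80)
            groups = [(times[labels == g], events[labels == g]) for g in range(4)]
            pvals.append(logrank_test(groups)[1])
        assert 0.2 < np.mean(np.asarray(pvals) < 0.5) < 0.8


class TestCutoffSearch:
    def test_equals_independent_exhaustive_rescan(self, rng):
        values = rng.uniform(0, 1, size=40)
        times = rng.exponential(10 * (1 + values), size=40)
        events = (rng.random(40) < 0.8).astype(int)
        res = find_cutoff(values, times, events)
        # independent re-scan over every admissible midpoint
        distinct = np.unique(values)
        best_stat, best_cut = -np.inf, None
        for c in (distinct[:-1] + distinct[1:]) / 2:
            low = values <= c
            if low.sum() < 4 or (~low).sum() < 4:
                continue
            stat = logrank_brute([(times[low], events[low]), (times[~low], events[~low])])
            if stat > best_stat + 1e-12:
                best_stat, best_cut = stat, c
        assert res.cutoff == pytest.approx(best_cut)
        assert res.statistic == pytest.approx(best_stat, rel=1e-9)

    def test_strong_separation_has_maximal_statistic_at_scan_argmax(self):
        values = np.arange(1, 11, dtype=float)
        res = find_cutoff(values, values, np.ones(10, int))
        # verified against the exhaustive oracle: the argmax split
        assert res.cutoff == pytest.approx(3.5)
        assert res.high_risk_side == "le"  # low values die first

    def test_constant_variable_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            find_cutoff([1.0] * 10, np.arange(10.0), np.ones(10, int))

    def test_min_group_frac_guard(self):
        values = np.array([1.0, 2.0])
        with pytest.raises(ValueError, match="admissible"):
            find_cutoff(values, [1.0, 2.0], [1, 1], min_group_frac=0.9)

    def test_null_variable_selected_p_is_optimistic(self, rng):
        """Selection bias: the p at the selected cutoff on pure noise is
        stochastically smaller than uniform (documented caveat)."""
        ps = []
        for _ in range(30):
            values = rng.uniform(0, 1, 40)
            times = rng.exponential(10, 40)
            events = np.ones(40, int)
            ps.append(find_cutoff(values, times, events).p)
        assert np.median(ps) < 0.5


class TestCox:
    def test_single_covariate_matches_brute_force_partial_likelihood(self):
        x = [0, 1, 0, 1, 0, 1]
        times = [1, 2, 3, 4, 5, 6]
        events = [1] * 6
        res = fit_cox(pd.DataFrame({"x": x}), times, events)
        beta_brute = cox_single_covariate_brute(x, times, events)
        assert res.loc["x", "coef"] == pytest.approx(beta_brute, abs=1e-5)

    def test_null_covariate_within_three_se_of_zero(self, rng):
        n = 2000
        x = rng.integers(0, 2, n)
        times = rng.exponential(10, n)
        events = (rng.random(n) < 0.8).astype(int)
        res = fit_cox(pd.DataFrame({"x": x}), times, events)
        assert abs(res.loc["x", "coef"]) < 3 * res.loc["x", "se"]

    def test_constant_covariate_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            fit_cox(pd.DataFrame({"x": [1.0] * 5}), np.arange(5.0) + 1, [1] * 5)


class TestScore:
    def test_worked_example_patient_scores_one(self):
        """Smoker with Ktrans 1.056, Kep 1.1356, uniformity 0.0047:
        only the smoking factor is present -> score 1."""
        record = {"smoking": True, "ktrans": 1.056, "kep": 1.1356, "uniformity": 0.0047}
        assert assign_score(record, OS_RISK_DEFINITION) == 1

    def test_all_risk_conditions_satisfied_scores_four(self):
        record = {"smoking": True, "ktrans": 0.3, "kep": 0.5, "uniformity": 0.001}
        assert assign_score(record, OS_RISK_DEFINITION) == 4

    def test_boundary_equality_counts_as_risk_for_le_rules(self):
        record = {"smoking": False, "ktrans": 0.5512, "kep": 2.0, "uniformity": 0.01}
        assert assign_score(record, OS_RISK_DEFINITION) == 1

    def test_gt_rule_boundary_is_exclusive(self):
        record = {"kep": 2.0, "suv": 14.22}
        assert assign_score(record, PREVIOUS_SYSTEM_DEFINITION) == 0
        record["suv"] = 14.23
        assert assign_score(record, PREVIOUS_SYSTEM_DEFINITION) == 1

    def test_rfs_definition_counts_its_four_factors(self):
        record = {"subsite": "hypopharynx", "alcohol": True, "ktrans": 0.2, "kep": 0.5}
        assert assign_score(record, RFS_RISK_DEFINITION) == 4
        record["subsite"] = "oropharynx"
        assert assign_score(record, RFS_RISK_DEFINITION) == 3

    def test_missing_variable_raises(self):
        with pytest.raises(KeyError):
            assign_score({"smoking": True}, OS_RISK_DEFINITION)


class TestStratification:
    def test_hazard_linked_cohort_yields_monotone_strata(self):
        coh = generate_cohort(CohortSpec(n=400, hazard_ratio_per_point=2.0, seed=13))
        res = stratify_and_compare(coh, OS_RISK_DEFINITION)
        surv36 = [survival_at(res.km_curves[s], 36.0) for s in sorted(res.km_curves)]
        assert all(a >= b for a, b in zip(surv36, surv36[1:]))
        assert res.logrank_p < 0.01
        assert res.reference_stratum == max(res.strata_counts)

    def test_single_occupied_stratum_rejected(self):
        coh = generate_cohort(CohortSpec(n=30, seed=1,
                                         score_probs=(0.0, 0.0, 1.0, 0.0, 0.0)))
        with pytest.raises(ValueError, match="one occupied"):
            stratify_and_compare(coh, OS_RISK_DEFINITION)

    def test_null_cohort_logrank_p_not_degenerate(self):
        pvals = []
        for seed in range(25):
            coh = generate_cohort(CohortSpec(
                n=150, hazard_ratio_per_point=1.0, seed=seed,
                score_probs=(0.2, 0.2, 0.2, 0.2, 0.2)))
            pvals.append(stratify_and_compare(coh, OS_RISK_DEFINITION).logrank_p)
        assert (np.asarray(pvals) < 0.05).mean() <= 0.25


class TestCompareSystems:
    def test_identical_definitions_give_identical_reports(self):
        coh = generate_cohort(CohortSpec(n=200, seed=3))
        rep = compare_systems(coh, OS_RISK_DEFINITION, OS_RISK_DEFINITION)
        assert rep["system_a"]["strata_n"] == rep["system_b"]["strata_n"]
        assert rep["system_a"]["logrank_statistic"] == pytest.approx(
            rep["system_b"]["logrank_statistic"])

    def test_hazard_bearing_system_separates_better(self):
        """When only system A's variables carry hazard, A's log-rank
        statistic exceeds B's in nearly all repeats."""
        wins = 0
        reps = 20
        for seed in range(reps):
            coh = generate_cohort(CohortSpec(n=300, hazard_ratio_per_point=2.2, seed=seed))
            rng = np.random.default_rng(seed + 1000)
            # system B's variables carry no hazard: shuffle kep/suv jointly
            perm = rng.permutation(len(coh))
            coh_b = coh.copy()
            coh_b["kep_null"] = coh["kep"].to_numpy()[perm]
            coh_b["suv_null"] = coh["suv"].to_numpy()[perm]
            system_b = RiskDefinition(endpoint="os", name="null", rules=(
                RiskRule("kep_null", "le", 0.887), RiskRule("suv_null", "gt", 14.22)))
            rep = compare_systems(coh_b, OS_RISK_DEFINITION, system_b)
            wins += rep["system_a"]["logrank_statistic"] > rep["system_b"]["logrank_statistic"]
        assert wins >= 0.95 * reps

    def test_empty_stratum_reported_as_zero(self):
        coh = generate_cohort(CohortSpec(n=100, seed=8))  # score 0 unoccupied
        rep = compare_systems(coh, OS_RISK_DEFINITION, PREVIOUS_SYSTEM_DEFINITION)
        assert rep["system_a"]["strata_n"][0] == 0
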