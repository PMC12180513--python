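"""Subject-level logistic knowledge fits, exclusions, and group-level models."""

import numpy as np
import pandas as pd
import pytest

from netcog import (
    ConsensusConfig,
    build_design,
    consensus_communities,
    exclude_outliers,
    fit_change_model,
    fit_current_model,
    fit_interaction_model,
    fit_subject_knowledge,
    marginal_predictions,
    meso_ties,
    run_base_partitions,
)
from netcog.models import SubjectKnowledge


def _rows(guess, friend, comm):
    return pd.DataFrame(
        {"guess": guess, "true_friendship": friend, "true_community": comm}
    )


def _simulate_rows(rng, n, beta=(-2.0, 1.5, 1.0), p_friend=0.11, p_comm=0.30):
    friend = (rng.random(n) < p_friend).astype(int)
    comm = np.where(friend == 1, rng.random(n) < 0.8, rng.random(n) < p_comm).astype(int)
    eta = beta[0] + beta[1] * friend + beta[2] * comm
    guess = (rng.random(n) < 1 / (1 + np.exp(-eta))).astype(int)
    return _rows(guess, friend, comm)


def _knowledge(subject, micro, meso, se=0.3, wave=2, converged=True):
    return SubjectKnowledge(
        subject=subject, wave=wave, beta0=-2.0, beta_micro=micro, beta_meso=meso,
        se_micro=se, se_meso=se, converged=converged,
    )


class TestBuildDesign:
    @pytest.fixture()
    def wave_context(self, small_cohort):
        net = small_cohort["networks"][0]
        parts = run_base_partitions(net, ConsensusConfig(seed=1))
        consensus = consensus_communities(parts, min_size=5)
        return net, meso_ties(consensus), consensus

    def test_rows_match_brute_force_lookup(self, wave_context):
        net, ties, _ = wave_context
        nodes = sorted(net.nodes())
        responses = pd.DataFrame(
            {
                "subject": ["s000"] * 3,
                "block_target": [nodes[1], nodes[2], nodes[3]],
                "probe": [nodes[2], nodes[3], nodes[4]],
                "guess": [1, 0, 1],
            }
        )
        design = build_design(responses, net, ties)
        for row, (a, b) in zip(
            design.itertuples(), [(nodes[1], nodes[2]), (nodes[2], nodes[3]), (nodes[3], nodes[4])]
        ):
            assert row.true_friendship == int(net.has_edge(a, b))
            assert row.true_community == ties.tie(a, b)

    def test_unassigned_member_gives_zero_community(self, wave_context):
        net, ties, consensus = wave_context
        if not consensus.unassigned:
            pytest.skip("no unassigned nodes in this draw")
        u = sorted(consensus.unassigned)[0]
        other = sorted(set(net.nodes()) - {u})[0]
        responses = pd.DataFrame(
            {"subject": ["x"], "block_target": [u], "probe": [other], "guess": [1]}
        )
        assert build_design(responses, net, ties)["true_community"].iloc[0] == 0

    def test_unknown_subject_in_trial_rejected(self, wave_context):
        net, ties, _ = wave_context
        responses = pd.DataFrame(
            {"subject": ["x"], "block_target": ["ghost"], "probe": ["s000"], "guess": [1]}
        )
        with pytest.raises(ValueError, match="ghost"):
            build_design(responses, net, ties)


class TestSubjectFit:
    def test_monte_carlo_recovery_unbiased(self):
        rng = np.random.default_rng(1)
        truth = (-2.0, 1.5, 1.0)
        micro, meso = [], []
        for _ in range(60):
            est = fit_subject_knowledge(
                _simulate_rows(rng, 870, beta=truth), subject="a", min_trials=0
            )
            assert est.converged
            micro.append(est.beta_micro)
            meso.append(est.beta_meso)
        assert abs(np.mean(micro) - truth[1]) < 0.1
        assert abs(np.mean(meso) - truth[2]) < 0.1

    def test_consistency_error_shrinks_with_trials(self):
        rng = np.random.default_rng(2)
        errors = []
        for n in (100, 870, 5000):
            errs = []
            for _ in range(40):
                est = fit_subject_knowledge(
                    _simulate_rows(rng, n), subject="a", min_trials=0
                )
                if est.converged:
                    errs.append(abs(est.beta_micro - 1.5))
            errors.append(np.median(errs))
        assert errors[0] > errors[1] > errors[2]

    def test_always_guessing_friend_flags_nonconvergence(self):
        rng = np.random.default_rng(3)
        rows = _simulate_rows(rng, 870)
        rows["guess"] = 1  # degenerate responder: separation on the intercept
        est = fit_subject_knowledge(rows, subject="a", min_trials=0)
        assert not est.converged
        assert est.excluded and est.reason == "nonconvergence"

    def test_coin_flip_responder_has_null_coefficients(self):
        rng = np.random.default_rng(4)
        inside = 0
        n_rep = 100
        z = 1.959963984540054
        for _ in range(n_rep):
            rows = _simulate_rows(rng, 870)
            rows["guess"] = rng.integers(0, 2, len(rows))
            est = fit_subject_knowledge(rows, subject="a", min_trials=0)
            inside += abs(est.beta_micro) <= z * est.se_micro
        # ~95% of Wald intervals should cover the true zero effect
        assert inside / n_rep > 0.88

    def test_constant_predictor_flags_not_crashes(self):
        rows = _rows([1, 0, 1, 0] * 50, [0] * 200, [0, 1] * 100)
        est = fit_subject_knowledge(rows, subject="a", min_trials=0)
        assert not est.converged and est.reason == "nonconvergence"

    def test_minimum_trial_precondition(self):
        rng = np.random.default_rng(5)
        with pytest.raises(ValueError, match="minimum"):
            fit_subject_knowledge(_simulate_rows(rng, 100), subject="a", min_trials=870)


class TestExclusions:
    def _cohort(self, n=50, seed=6):
        rng = np.random.default_rng(seed)
        return [
            _knowledge(f"s{i}", rng.normal(1.5, 0.3), rng.normal(1.0, 0.3),
                       se=abs(rng.normal(0.3, 0.03)))
            for i in range(n)
        ]

    def test_injected_beta_outlier_is_the_only_exclusion(self):
        cohort = self._cohort()
        betas = np.array([e.beta_micro for e in cohort])
        spike = betas.mean() + 5 * betas.std()
        cohort.append(_knowledge("spike", spike, 1.0))
        flagged = exclude_outliers(cohort)
        excluded = [e for e in flagged if e.excluded]
        assert [e.subject for e in excluded] == ["spike"]
        assert excluded[0].reason == "beta_outlier"

    def test_se_outlier_flagged_with_reason(self):
        cohort = self._cohort()
        ses = np.array([e.se_micro for e in cohort])
        cohort.append(_knowledge("wild", 1.5, 1.0, se=ses.mean() + 6 * ses.std()))
        flagged = exclude_outliers(cohort)
        assert next(e for e in flagged if e.subject == "wild").reason == "se_outlier"

    def test_identical_betas_exclude_nobody(self):
        cohort = [_knowledge(f"s{i}", 1.5, 1.0, se=0.3) for i in range(10)]
        assert not any(e.excluded for e in exclude_outliers(cohort))

    def test_matches_brute_force_rule(self):
        cohort = self._cohort(n=80, seed=7)
        flagged = exclude_outliers(cohort)
        for attr in ("beta_micro", "beta_meso", "se_micro", "se_meso"):
            values = np.array([getattr(e, attr) for e in cohort])
            mean, sd = values.mean(), values.std()
            for e, f in zip(cohort, flagged):
                if abs(getattr(e, attr) - mean) > 3 * sd:
                    assert f.excluded

    def test_idempotent_on_own_output(self):
        cohort = self._cohort()
        cohort.append(_knowledge("spike", 10.0, 1.0))
        once = exclude_outliers(cohort)
        twice = exclude_outliers(once)
        assert [(e.subject, e.excluded, e.reason) for e in once] == [
            (e.subject, e.excluded, e.reason) for e in twice
        ]

    def test_too_few_subjects_rejected(self):
        with pytest.raises(ValueError, match="at least 3"):
            exclude_outliers([_knowledge("a", 1, 1), _knowledge("b", 1, 1)])


class TestGroupModels:
    def _cohort_with_effect(self, seed, n=100, slope=0.1, sigma=0.23):
        rng = np.random.default_rng(seed)
        micro = rng.normal(1.5, 0.75, n)
        meso = rng.normal(1.0, 1.0, n)
        knowledge = [_knowledge(f"s{i}", micro[i], meso[i]) for i in range(n)]
        delta = dict(
            zip([f"s{i}" for i in range(n)], slope * meso + sigma * rng.standard_normal(n))
        )
        return knowledge, delta, rng

    def test_planted_meso_effect_detected_with_power(self):
        hits = 0
        for seed in range(40):
            knowledge, delta, _ = self._cohort_with_effect(seed)
            result = fit_change_model(knowledge, delta, "delta_influence")
            term = result.term("fall_meso")
            hits += term.p_value < 0.05 and term.beta > 0
        assert hits / 40 >= 0.8

    def test_null_outcome_rejects_at_nominal_rate(self):
        rejections = 0
        n_rep = 120
        for seed in range(n_rep):
            knowledge, _, rng = self._cohort_with_effect(seed, slope=0.0)
            delta = {e.subject: 0.23 * rng.standard_normal() for e in knowledge}
            result = fit_change_model(knowledge, delta, "delta_influence")
            rejections += result.term("fall_meso").p_value < 0.05
        assert 0.0 < rejections / n_rep < 0.11

    def test_zero_variance_predictor_raises_rank_error(self):
        knowledge = [_knowledge(f"s{i}", 1.5, 1.0) for i in range(20)]
        delta = {f"s{i}": 0.1 for i in range(20)}
        with pytest.raises(ValueError, match="rank-deficient"):
            fit_change_model(knowledge, delta, "delta_influence")

    def test_too_few_subjects_precondition(self):
        knowledge, delta, _ = self._cohort_with_effect(0, n=8)
        with pytest.raises(ValueError, match=">= 10"):
            fit_change_model(knowledge, delta, "delta_influence")

    def test_current_model_recovers_contemporaneous_micro_effect(self):
        rng = np.random.default_rng(11)
        n = 100
        micro = rng.normal(1.5, 0.75, n)
        knowledge = [
            _knowledge(f"s{i}", micro[i], rng.normal(1.0, 1.0)) for i in range(n)
        ]
        centrality = {
            f"s{i}": 0.15 * micro[i] + 0.2 * rng.standard_normal() for i in range(n)
        }
        result = fit_current_model(knowledge, centrality, "influence", season="fall")
        term = result.term("fall_micro")
        assert term.beta > 0 and term.p_value < 0.05

    def test_shuffled_knowledge_kills_the_association(self):
        rng = np.random.default_rng(12)
        rejections = 0
        for rep in range(60):
            n = 100
            micro = rng.normal(1.5, 0.75, n)
            centrality = {f"s{i}": 0.15 * micro[i] + 0.2 * rng.standard_normal() for i in range(n)}
            shuffled = rng.permutation(micro)
            knowledge = [
                _knowledge(f"s{i}", shuffled[i], rng.normal(1.0, 1.0)) for i in range(n)
            ]
            result = fit_current_model(knowledge, centrality, "influence", season="fall")
            rejections += result.term("fall_micro").p_value < 0.05
        assert rejections / 60 < 0.15

    def test_interaction_model_recovers_planted_product_effect(self):
        detected = 0
        for seed in range(30):
            rng = np.random.default_rng(100 + seed)
            n = 100
            fall_meso = rng.normal(1.0, 1.0, n)
            spring_micro = rng.normal(1.5, 0.75, n)
            outcome = {
                f"s{i}": 0.1 * fall_meso[i] * spring_micro[i] + 0.2 * rng.standard_normal()
                for i in range(n)
            }
            fall = [_knowledge(f"s{i}", rng.normal(1.5, 0.75), fall_meso[i]) for i in range(n)]
            spring = [
                _knowledge(f"s{i}", spring_micro[i], rng.normal(1.0, 1.0), wave=4)
                for i in range(n)
            ]
            result = fit_interaction_model(fall, spring, outcome)
            term = result.term("fall_meso_x_spring_micro")
            detected += term.p_value < 0.05 and term.beta > 0
        assert detected / 30 >= 0.8

    def test_full_interaction_model_isolates_the_planted_product(self):
        # with the fall-meso x spring-micro product planted, the other three
        # products should be significant far less often
        focal_hits = 0
        other_hits = 0
        n_rep = 30
        for seed in range(n_rep):
            rng = np.random.default_rng(200 + seed)
            n = 120
            fall_micro = rng.normal(1.5, 0.75, n)
            fall_meso = rng.normal(1.0, 1.0, n)
            spring_micro = rng.normal(1.5, 0.75, n)
            spring_meso = rng.normal(1.0, 1.0, n)
            outcome = {
                f"s{i}": 0.1 * fall_meso[i] * spring_micro[i] + 0.2 * rng.standard_normal()
                for i in range(n)
            }
            fall = [_knowledge(f"s{i}", fall_micro[i], fall_meso[i]) for i in range(n)]
            spring = [
                _knowledge(f"s{i}", spring_micro[i], spring_meso[i], wave=4)
                for i in range(n)
            ]
            result = fit_interaction_model(fall, spring, outcome, full=True)
            focal_hits += result.term("fall_meso_x_spring_micro").p_value < 0.05
            for name in (
                "fall_micro_x_spring_micro",
                "fall_micro_x_spring_meso",
                "fall_meso_x_spring_meso",
            ):
                other_hits += result.term(name).p_value < 0.05
        assert focal_hits / n_rep >= 0.8
        assert other_hits / (3 * n_rep) < 0.2

    def test_interaction_ci_bounds_bracket_estimates(self):
        knowledge, delta, _ = self._cohort_with_effect(3)
        result = fit_change_model(knowledge, delta, "delta_influence")
        for term in result.terms:
            assert term.ci_low <= term.beta <= term.ci_high
            assert 0 < term.p_value <= 1


class TestMarginalPredictions:
    def _fitted(self, seed=13):
        rng = np.random.default_rng(seed)
        n = 80
        micro = rng.normal(1.5, 0.75, n)
        meso = rng.normal(1.0, 1.0, n)
        knowledge = [_knowledge(f"s{i}", micro[i], meso[i]) for i in range(n)]
        delta = dict(
            zip([f"s{i}" for i in range(n)], 0.1 * meso + 0.05 * rng.standard_normal(n))
        )
        controls = pd.DataFrame(
            {"extroversion": pd.Series(rng.normal(3.5, 0.8, n), index=[f"s{i}" for i in range(n)])}
        )
        return fit_change_model(knowledge, delta, "delta_influence", controls=controls)

    def test_curve_slope_matches_focal_coefficient(self):
        result = self._fitted()
        grid = [0.0, 1.0, 2.0]
        curve = marginal_predictions(result, "fall_meso", grid)
        slopes = np.diff(curve["predicted"]) / np.diff(grid)
        assert np.allclose(slopes, result.term("fall_meso").beta)

    def test_predictions_match_hand_computed_linear_form(self):
        result = self._fitted()
        grid = [-1.0, 0.5, 3.0]
        curve = marginal_predictions(result, "fall_meso", grid)
        means = result.design_means
        for g, pred in zip(grid, curve["predicted"]):
            expected = sum(
                result.term(name).beta * (g if name == "fall_meso" else means[name])
                for name in means
            )
            assert pred == pytest.approx(expected)

    def test_ci_ribbon_brackets_predictions(self):
        result = self._fitted()
        curve = marginal_predictions(result, "fall_micro", [0, 1, 2, 3])
        assert (curve["ci_low"] < curve["predicted"]).all()
        assert (curve["predicted"] < curve["ci_high"]).all()

    def test_missing_focal_term_rejected(self):
        result = self._fitted()
        with pytest.raises(KeyError, match="nonexistent"):
            marginal_predictions(result, "nonexistent", [0, 1])
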