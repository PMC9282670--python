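"""Adaptive testing engine: estimation, selection, stopping, fit."""

import numpy as np
import pytest

from sccat.cat import (
    CatSession,
    ReplayResponder,
    SimulatedResponder,
    StopRule,
    converge_theta,
    fit_statistics,
    impute_unanswered,
    run_cat,
    select_next_item,
    sem_from_reliability,
    should_stop,
    standard_error,
    t_transform,
    trajectory_flatness,
    update_theta,
)
from sccat.item_bank import ItemBank, ItemParameters
from sccat.pcm import expected_score, item_information


def make_bank(specs):
    """specs: list of (overall, steps) tuples."""
    return ItemBank(
        items=[
            ItemParameters(
                item_id=i + 1, text=f"q{i + 1}", overall_difficulty=o, step_thresholds=tuple(s)
            )
            for i, (o, s) in enumerate(specs)
        ]
    )


def session_with(bank, administered, theta=0.0):
    s = CatSession(bank=bank, initial_theta=theta)
    for iid, obs in administered:
        s.administer(iid, obs)
    return s


class TestUpdateTheta:
    def test_forced_arithmetic_single_dichotomous(self):
        # O=1 on delta=0 at theta=0: step = (1 - 0.5) / 0.25 = 2
        bank = make_bank([(0.0, (0.0,))])
        s = session_with(bank, [(1, 1)])
        assert update_theta(s, max_step=None, clamp=None) == pytest.approx(2.0, abs=1e-12)

    def test_fixed_point_when_observed_equals_expected(self):
        bank = make_bank([(0.3, (-0.5, 0.5)), (-0.2, (0.0,))])
        theta = 0.7
        s = CatSession(bank=bank, initial_theta=theta)
        for iid in (1, 2):
            s.administer(iid, expected_score(theta, bank[iid]))  # real-valued probe
        assert update_theta(s) == pytest.approx(theta, abs=1e-12)

    def test_step_cap_and_clamp(self):
        bank = make_bank([(0.0, (0.0,))])
        s = session_with(bank, [(1, 1)])
        assert update_theta(s) == pytest.approx(1.0)  # capped at 1 logit
        s2 = session_with(bank, [(1, 1)], theta=5.9)
        assert update_theta(s2) <= 6.0

    def test_convergence_matches_grid_search_root(self, bank):
        # 5-item response pattern; oracle = fine grid scan of the score equation
        pattern = [(2, 1), (5, 2), (9, 0), (14, 3), (30, 1)]
        s = session_with(bank, pattern)
        theta_hat = converge_theta(s, tol=1e-9)
        grid = np.linspace(-6, 6, 240_001)
        items = [bank[iid] for iid in (2, 5, 9, 14, 30)]
        obs = np.array([o for _, o in pattern], dtype=float)
        resid = [abs(sum(obs) - sum(expected_score(t, it) for it in items)) for t in grid]
        assert theta_hat == pytest.approx(grid[int(np.argmin(resid))], abs=1e-3)

    def test_requires_administered_items(self, bank):
        with pytest.raises(ValueError):
            update_theta(CatSession(bank=bank))


class TestStandardError:
    def test_total_information_four_gives_half(self):
        # 16 dichotomous items at their difficulty: information 0.25 each
        bank = make_bank([(0.0, (0.0,))] * 16)
        s = session_with(bank, [(i, 1) for i in range(1, 17)], theta=0.0)
        assert standard_error(s, theta=0.0) == pytest.approx(0.5, abs=1e-12)

    def test_adding_an_item_decreases_se(self, bank):
        s = session_with(bank, [(1, 1)])
        se1 = standard_error(s, theta=0.0)
        s.administer(2, 2)
        assert standard_error(s, theta=0.0) < se1

    def test_sem_threshold_crossed_at_sufficient_information(self):
        # SEM = 0.469 corresponds to total information 1/0.469^2 ~ 4.546
        bank = make_bank([(0.0, (0.0,))] * 20)
        s = session_with(bank, [(i, 1) for i in range(1, 20)], theta=0.0)
        total_info = sum(item_information(0.0, bank[i]) for i in range(1, 20))
        assert total_info > 1 / 0.469**2
        assert standard_error(s, theta=0.0) < 0.469


class TestSelection:
    def test_picks_item_at_current_ability(self):
        bank = make_bank([(3.0, (0.0,)), (0.0, (0.0,)), (2.0, (0.0,))])
        s = session_with(bank, [(3, 1)], theta=0.0)
        s.theta_trajectory = [0.0]
        assert select_next_item(s) == 2  # information peaks at theta = delta

    def test_never_returns_administered(self, bank):
        s = session_with(bank, [(1, 1), (2, 2), (3, 0)])
        for _ in range(27):
            nxt = select_next_item(s)
            assert nxt not in s.administered_ids
            s.administer(nxt, 0)
        with pytest.raises(ValueError):
            select_next_item(s)

    def test_matches_exhaustive_scan(self, bank, rng):
        for _ in range(20):
            used = rng.choice(np.arange(1, 31), size=rng.integers(1, 10), replace=False)
            theta = float(rng.uniform(-3, 3))
            s = CatSession(bank=bank, initial_theta=theta)
            for iid in used:
                s.administer(int(iid), 0)
            brute = max(
                (iid for iid in range(1, 31) if iid not in set(used.tolist())),
                key=lambda iid: (item_information(theta, bank[iid]), -iid),
            )
            assert select_next_item(s) == brute


class TestStopRule:
    def test_sem_derivation(self):
        assert sem_from_reliability(0.78, 1.0) == pytest.approx(0.469, abs=5e-4)
        rule = StopRule.from_reliability(0.78)
        assert rule.sem_threshold == pytest.approx(0.469, abs=5e-4)

    def test_stop_reasons(self):
        bank = make_bank([(0.0, (0.0,))] * 30)
        # plenty of information at theta=0 -> sem_reached
        s = session_with(bank, [(i, 1) for i in range(1, 20)], theta=0.0)
        s.theta_trajectory = [0.0] * 19
        stop, reason = should_stop(s, StopRule())
        assert stop and reason == "sem_reached"
        # few items, flat trajectory -> theta_converged
        s2 = session_with(bank, [(i, 1) for i in range(1, 7)], theta=4.0)
        s2.theta_trajectory = [4.0, 4.01, 4.015, 4.016, 4.016, 4.016]
        stop, reason = should_stop(s2, StopRule(sem_threshold=0.1))
        assert stop and reason == "theta_converged"
        # bank exhausted
        s3 = session_with(bank, [(i, 0) for i in range(1, 31)], theta=-6.0)
        s3.theta_trajectory = [-6.0, -5.0] * 15
        stop, reason = should_stop(s3, StopRule(sem_threshold=1e-6, theta_residual_tol=1e-9))
        assert stop and reason == "items_exhausted"


class TestImputation:
    def test_fully_answered_is_identity(self, bank, rng):
        obs = [(iid, int(rng.integers(0, bank[iid].max_score + 1))) for iid in range(1, 31)]
        s = session_with(bank, obs)
        s.final_theta = 1.0
        np.testing.assert_array_equal(impute_unanswered(s), [o for _, o in obs])

    def test_unanswered_dichotomous_at_difficulty_imputes_half(self):
        bank = make_bank([(0.7, (0.0,)), (0.0, (0.0,))])
        s = session_with(bank, [(2, 1)])
        s.final_theta = 0.7
        assert impute_unanswered(s)[0] == pytest.approx(0.5, abs=1e-12)

    def test_imputed_values_recompute_expected_score(self, bank):
        s = session_with(bank, [(1, 1), (5, 3)])
        s.final_theta = 0.9
        vec = impute_unanswered(s)
        for iid in range(1, 31):
            if iid in (1, 5):
                continue
            assert vec[iid - 1] == pytest.approx(expected_score(0.9, bank[iid]), abs=1e-12)


class TestFitStatistics:
    def test_df_adjusted_mean_square_and_t(self):
        # worked example: outfit 0.52 over 9 items
        v = 0.52 * 9 / (9 - 1)
        assert v == pytest.approx(0.585, abs=1e-12)
        assert t_transform(v, 8) == pytest.approx(-0.95, abs=5e-3)

    def test_perfect_probe_gives_zero_mean_squares(self, bank):
        theta = 0.4
        s = CatSession(bank=bank, initial_theta=theta)
        for iid in (1, 2, 3):
            s.administer(iid, expected_score(theta, bank[iid]))
        s.final_theta = theta
        report = fit_statistics(s)
        assert report.outfit_mnsq == pytest.approx(0.0, abs=1e-24)
        assert report.infit_mnsq == pytest.approx(0.0, abs=1e-24)
        assert np.allclose(report.z_scores, 0.0)

    def test_outfit_equals_independent_loop(self, bank, rng):
        obs = [(iid, int(rng.integers(0, bank[iid].max_score + 1))) for iid in range(1, 10)]
        s = session_with(bank, obs)
        s.final_theta = 0.3
        report = fit_statistics(s)
        z2 = []
        for iid, o in obs:
            e = expected_score(0.3, bank[iid])
            var = item_information(0.3, bank[iid])
            z2.append((o - e) ** 2 / var)
        assert report.outfit_mnsq == pytest.approx(float(np.mean(z2)), abs=1e-12)
        assert report.df == len(obs) - 1
        infit = sum((o - expected_score(0.3, bank[iid])) ** 2 for iid, o in obs) / sum(
            item_information(0.3, bank[iid]) for iid, _ in obs
        )
        assert report.infit_mnsq == pytest.approx(infit, abs=1e-12)

    def test_aberrant_pattern_flagged(self, bank):
        # extreme responses against the model expectation at theta ~ 0
        pattern = {2: 0, 26: 0, 27: 0, 9: 4, 12: 1, 10: 4}  # easy items 0, hard items max
        s = session_with(bank, list(pattern.items()))
        s.final_theta = converge_theta(s)
        report = fit_statistics(s)
        assert report.outfit_mnsq > 2.0
        assert report.aberrant

    def test_wilson_hilferty_alternative(self):
        # cube-root standardisation is monotone in v and ~0 at v=1
        assert abs(t_transform(1.0, 8, method="wilson_hilferty")) < 0.2
        assert t_transform(2.0, 8, method="wilson_hilferty") > t_transform(
            0.5, 8, method="wilson_hilferty"
        )


class TestRunCat:
    def test_stop_contract_and_trajectory_shapes(self, bank):
        s = run_cat(bank, SimulatedResponder(0.5, rng=3), seed=3)
        assert s.stopped_because in {"sem_reached", "theta_converged", "items_exhausted"}
        assert len(s.theta_trajectory) == len(s.se_trajectory) == s.n_administered
        assert s.final_se == pytest.approx(standard_error(s, theta=s.final_theta))
        assert len(s.imputed_vector) == 30
        if s.stopped_because == "sem_reached":
            assert s.se_trajectory[-1] < 0.469

    def test_same_seed_same_session(self, bank):
        a = run_cat(bank, SimulatedResponder(1.0, rng=11), seed=11)
        b = run_cat(bank, SimulatedResponder(1.0, rng=11), seed=11)
        assert a.administered == b.administered
        assert a.theta_trajectory == b.theta_trajectory

    def test_replay_responder_converges(self, bank, rng):
        vec = [int(rng.integers(0, m + 1)) for m in bank.max_scores]
        s = run_cat(bank, ReplayResponder(vec), rule=StopRule(max_items=30), seed=1)
        # final theta solves the score equation over administered items
        assert abs(converge_theta(s) - s.final_theta) < 1e-6

    def test_out_of_range_response_rejected(self, bank):
        with pytest.raises(ValueError, match="out of range"):
            run_cat(bank, lambda item: item.max_score + 1, seed=0)

    def test_efficiency_and_consistency_over_simulated_respondents(self, bank):
        rng = np.random.default_rng(2024)
        thetas = rng.normal(0, 1, 200)
        estimates, lengths = [], []
        for i, theta in enumerate(thetas):
            s = run_cat(bank, SimulatedResponder(theta, rng=5000 + i), seed=5000 + i)
            estimates.append(s.final_theta)
            lengths.append(s.n_administered)
        assert np.mean(lengths) < 30  # CAT saves items on average
        corr = np.corrcoef(thetas, estimates)[0, 1]
        assert corr >= 0.85  # reliability .78 implies ~sqrt(.78) attenuation

    def test_flatness_diagnostic(self, bank):
        s = run_cat(bank, SimulatedResponder(0.0, rng=1), rule=StopRule(sem_threshold=0.35), seed=1)
        flat = trajectory_flatness(s)
        assert flat is None or -1.0 <= flat <= 1.0

    def test_session_log_round_trip(self, bank, tmp_path):
        import json

        s = run_cat(bank, SimulatedResponder(1.2, rng=7), seed=7)
        s.to_json(tmp_path / "session.json")
        doc = json.loads((tmp_path / "session.json").read_text())
        assert doc["final_theta"] == pytest.approx(s.final_theta)
        assert len(doc["imputed_vector"]) == 30
        assert doc["fit"]["df"] == s.n_administered - 1
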