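import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from selfreg.scores import (
    compute_trial_scores,
    decision_conflict,
    fit_taste_health_weights,
    orthogonalize_modulator,
    score_self_control,
    stakes,
    subjective_value,
)
from selfreg.types import WeightFit


def logistic_trials(rng, n, beta0, w_taste, w_health):
    """Bernoulli choices from a plain logistic model on centered ratings."""
    tr = rng.uniform(-5, 5, n)
    hr = rng.uniform(-5, 5, n)
    eta = beta0 + w_taste * (tr - tr.mean()) + w_health * (hr - hr.mean())
    yes = rng.random(n) < 1 / (1 + np.exp(-eta))
    return pd.DataFrame(
        {"tr": tr, "hr": hr, "choice": np.where(yes, "yes", "no")}
    )


def grid_loglik(trials, b0, wt, wh):
    """Independent likelihood oracle: direct Bernoulli log-likelihood."""
    tr_c = trials["tr"] - trials["tr"].mean()
    hr_c = trials["hr"] - trials["hr"].mean()
    resp = trials["choice"].isin(["yes", "no"])
    y = (trials["choice"] == "yes")[resp].to_numpy(float)
    eta = (b0 + wt * tr_c + wh * hr_c)[resp].to_numpy(float)
    p = 1 / (1 + np.exp(-eta))
    p = np.clip(p, 1e-12, 1 - 1e-12)
    return float(np.sum(y * np.log(p) + (1 - y) * np.log(1 - p)))


class TestWeightFit:
    def test_recovers_generating_weights(self, rng):
        trials = logistic_trials(rng, 5000, 0.2, 1.5, 1.5)
        fit = fit_taste_health_weights(trials)
        assert not fit.separation_flag
        assert abs(fit.w_taste - 1.5) < 0.1
        assert abs(fit.w_health - 1.5) < 0.1

    def test_matches_grid_search_oracle(self, rng):
        """The IRLS optimum dominates a coarse likelihood grid, and the
        grid optimum sits next to the IRLS solution (50 trials)."""
        trials = logistic_trials(rng, 50, 0.0, 0.8, 0.6)
        fit = fit_taste_health_weights(trials)
        ll_fit = grid_loglik(trials, fit.beta0, fit.w_taste, fit.w_health)
        grid = np.linspace(-2.5, 2.5, 26)
        best_ll, best_pt = -np.inf, None
        for b0 in np.linspace(-1, 1, 11):
            for wt in grid:
                for wh in grid:
                    ll = grid_loglik(trials, b0, wt, wh)
                    if ll > best_ll:
                        best_ll, best_pt = ll, (b0, wt, wh)
        assert ll_fit >= best_ll - 1e-9
        assert abs(best_pt[1] - fit.w_taste) <= 0.2  # one grid step
        assert abs(best_pt[2] - fit.w_health) <= 0.2

    def test_never_eats_sets_separation_flag(self, rng):
        trials = logistic_trials(rng, 80, 0.0, 1.0, 1.0)
        trials["choice"] = "no"
        fit = fit_taste_health_weights(trials)
        assert fit.separation_flag
        assert np.isfinite(fit.w_taste) and np.isfinite(fit.w_health)

    def test_zero_variance_attribute_rejected(self, rng):
        trials = logistic_trials(rng, 40, 0.0, 1.0, 1.0)
        trials["tr"] = 2.0
        with pytest.raises(ValueError):
            fit_taste_health_weights(trials)

    def test_all_missed_rejected(self, rng):
        trials = logistic_trials(rng, 10, 0.0, 1.0, 1.0)
        trials["choice"] = "missed"
        with pytest.raises(ValueError):
            fit_taste_health_weights(trials)


class TestTrialScores:
    fit = WeightFit(0.0, 1.47, 1.46, converged=True, separation_flag=False)

    def test_subjective_value_arithmetic(self):
        assert subjective_value(1.0, -1.0, self.fit) == pytest.approx(0.01)
        assert subjective_value(0.0, 0.0, self.fit) == 0.0
        doubled = WeightFit(0.0, 2 * 1.47, 2 * 1.46, True, False)
        assert subjective_value(1.3, -0.4, doubled) == pytest.approx(
            2 * subjective_value(1.3, -0.4, self.fit)
        )

    def test_conflict_examples_and_symmetry(self):
        assert decision_conflict(0.0, 0.0, self.fit) == 0.0
        sv = subjective_value(1.0, -2.0, self.fit)
        assert decision_conflict(1.0, -2.0, self.fit) == -abs(sv)
        assert decision_conflict(-1.0, 2.0, self.fit) == pytest.approx(
            decision_conflict(1.0, -2.0, self.fit)
        )

    @pytest.mark.parametrize(
        "tr, hr, expected",
        [(4, -3, 7.0), (2, 3, 0.0), (-1, -4, 0.0), (-2, 3, 5.0)],
    )
    def test_stakes(self, tr, hr, expected):
        assert stakes(tr, hr) == expected

    def test_stakes_neutral_zone_rejected(self):
        with pytest.raises(ValueError):
            stakes(-0.2, 3.0)

    @given(
        tr=st.floats(min_value=-5, max_value=5),
        hr=st.floats(min_value=-5, max_value=5),
    )
    @settings(max_examples=200, derandomize=True)
    def test_stakes_nonnegative_and_positive_iff_challenge(self, tr, hr):
        from selfreg.design import classify_trial_type

        tt = classify_trial_type(tr, hr)
        if tt is None:
            with pytest.raises(ValueError):
                stakes(tr, hr)
        else:
            s = stakes(tr, hr)
            assert s >= 0
            assert (s > 0) == (tt in ("HTLH", "LTHH"))


class TestOrthogonalization:
    def test_orthogonal_target_unchanged(self, rng):
        ref = rng.standard_normal(30)
        ref -= ref.mean()
        t = rng.standard_normal(30)
        t -= t.mean()
        t -= (t @ ref) / (ref @ ref) * ref  # already orthogonal
        out = orthogonalize_modulator(t, ref)
        np.testing.assert_allclose(out, t, atol=1e-12)

    def test_collinear_target_vanishes(self, rng):
        ref = rng.standard_normal(25)
        out = orthogonalize_modulator(ref, ref)
        np.testing.assert_allclose(out, 0.0, atol=1e-12)

    def test_matches_normal_equations_oracle(self, rng):
        t = rng.standard_normal(20)
        r = rng.standard_normal(20)
        out = orthogonalize_modulator(t, r)
        # independent oracle: residual of OLS with explicit normal equations
        X = np.column_stack([np.ones(20), r - r.mean()])
        beta = np.linalg.solve(X.T @ X, X.T @ (t - t.mean()))
        oracle = (t - t.mean()) - X @ beta
        np.testing.assert_allclose(out, oracle, atol=1e-12)
        assert abs(out @ (r - r.mean())) < 1e-10
        assert abs(out.mean()) < 1e-12

    def test_invariant_to_affine_function_of_reference(self, rng):
        t = rng.standard_normal(40)
        r = rng.standard_normal(40)
        out1 = orthogonalize_modulator(t, r)
        out2 = orthogonalize_modulator(t + 3.0 * r - 1.7, r)
        np.testing.assert_allclose(out1, out2, atol=1e-10)

    def test_constant_reference_warns(self, rng):
        t = rng.standard_normal(10)
        with pytest.warns(RuntimeWarning):
            out = orthogonalize_modulator(t, np.ones(10))
        np.testing.assert_allclose(out, t - t.mean(), atol=1e-12)


def _trials(rows):
    return pd.DataFrame(rows, columns=["trial_type", "choice"])


class TestSelfControlScoring:
    def test_counting(self):
        trials = _trials(
            [
                ("HTLH", "no"),
                ("HTLH", "no"),
                ("LTHH", "yes"),
                ("HTLH", "yes"),
            ]
        )
        s = score_self_control(trials)
        assert s.level == 0.75
        assert s.n_challenge_responded == 4

    def test_all_htlh_refused_gives_unit_level(self):
        trials = _trials([("HTLH", "no")] * 5 + [("HTHH", "yes")] * 3)
        s = score_self_control(trials)
        assert s.level_htlh == 1.0
        assert s.level == 1.0

    def test_missed_trials_excluded_from_both_sides(self):
        trials = _trials(
            [("HTLH", "no"), ("HTLH", "missed"), ("LTHH", "missed"), ("LTHH", "no")]
        )
        s = score_self_control(trials)
        assert s.n_challenge_responded == 2
        assert s.n_missed_challenge == 2
        assert s.level == 0.5

    def test_no_responded_challenges_flagged_undefined(self):
        trials = _trials([("HTHH", "yes"), ("HTLH", "missed")])
        s = score_self_control(trials)
        assert not s.defined
        assert s.level is None

    def test_success_plus_failure_is_one(self, small_cohort):
        for _, g in small_cohort.choices.groupby("participant_id"):
            s = score_self_control(g)
            resp = g[g["trial_type"].isin(["HTLH", "LTHH"]) & g["choice"].isin(["yes", "no"])]
            failures = (
                ((resp["trial_type"] == "HTLH") & (resp["choice"] == "yes"))
                | ((resp["trial_type"] == "LTHH") & (resp["choice"] == "no"))
            ).mean()
            assert s.level + failures == pytest.approx(1.0)

    def test_refusal_bias_with_weak_health_weight_favors_htlh(self, small_cohort):
        """Under the refusal-biased generator, HTLH success (refusing
        temptations) exceeds LTHH success (accepting healthy-untasty)."""
        levels_h, levels_l = [], []
        for _, g in small_cohort.choices.groupby("participant_id"):
            s = score_self_control(g)
            if s.level_htlh is not None and s.level_lthh is not None:
                levels_h.append(s.level_htlh)
                levels_l.append(s.level_lthh)
        assert np.mean(levels_h) > np.mean(levels_l)


class TestComputeTrialScores:
    def test_table_invariants(self, small_cohort):
        pid, g = next(iter(small_cohort.choices.groupby("participant_id")))
        fit = fit_taste_health_weights(g)
        scores = compute_trial_scores(g, fit)
        assert (scores["conflict"] <= 0).all()
        ch = scores["trial_type"].isin(["HTLH", "LTHH"])
        assert (scores.loc[ch, "stakes"] > 0).all()
        assert (scores.loc[~ch, "stakes"] == 0).all()
        orth = scores.loc[ch, "stakes_orth"]
        conf = scores.loc[ch, "conflict"]
        assert abs((orth * (conf - conf.mean())).sum()) < 1e-8
        np.testing.assert_allclose(scores["conflict"], -scores["sv"].abs())
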