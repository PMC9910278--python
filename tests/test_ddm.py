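import numpy as np
import pytest
from scipy import integrate

from selfreg import ddm
from selfreg.types import ConfigurationError, DDMParams


class TestDensity:
    def test_zero_drift_symmetric_start_equal_densities(self):
        p = DDMParams(a=1.2, z_rel=0.5, t0=0.0)
        t = np.linspace(0.01, 3.0, 50)
        up = ddm.wiener_fpt_density(t, p, 0.0, "upper")
        lo = ddm.wiener_fpt_density(t, p, 0.0, "lower")
        np.testing.assert_allclose(up, lo, rtol=1e-9)

    @pytest.mark.parametrize("v", [-1.2, 0.0, 0.9])
    @pytest.mark.parametrize("z_rel", [1 / 3, 0.5, 0.7])
    def test_total_absorption_mass_is_one(self, v, z_rel):
        p = DDMParams(a=1.5, z_rel=z_rel, t0=0.0)
        total = sum(
            integrate.quad(
                lambda t: ddm.wiener_fpt_density(t, p, v, b), 1e-9, 60, limit=200
            )[0]
            for b in ("upper", "lower")
        )
        assert total == pytest.approx(1.0, abs=1e-6)

    def test_nonnegative(self):
        p = DDMParams()
        t = np.linspace(1e-4, 3, 200)
        for b in ("upper", "lower"):
            assert (ddm.wiener_fpt_density(t, p, 0.5, b) >= 0).all()

    def test_nonpositive_time_rejected(self):
        with pytest.raises(ValueError):
            ddm.wiener_fpt_density(0.0, DDMParams(), 0.0, "upper")


class TestChoiceProbability:
    def test_zero_drift_equals_relative_start(self):
        p = DDMParams(z_rel=1 / 3)
        assert ddm.upper_choice_probability(p, 0.0) == pytest.approx(1 / 3)

    def test_continuity_at_zero_drift(self):
        p = DDMParams(z_rel=1 / 3)
        assert ddm.upper_choice_probability(p, 1e-12) == pytest.approx(1 / 3, abs=1e-9)
        assert ddm.upper_choice_probability(p, -1e-12) == pytest.approx(1 / 3, abs=1e-9)

    @pytest.mark.parametrize("v", [-2.0, -0.4, 0.3, 1.5])
    def test_matches_density_quadrature(self, v):
        p = DDMParams(a=1.8, z_rel=0.4, t0=0.0)
        mass = integrate.quad(
            lambda t: ddm.wiener_fpt_density(t, p, v, "upper"), 1e-9, 80, limit=200
        )[0]
        assert ddm.upper_choice_probability(p, v) == pytest.approx(mass, abs=1e-6)

    def test_extreme_drifts_saturate(self):
        p = DDMParams(z_rel=0.5)
        assert ddm.upper_choice_probability(p, 500.0) == pytest.approx(1.0)
        assert ddm.upper_choice_probability(p, -500.0) == pytest.approx(0.0, abs=1e-12)


class TestSurvival:
    @pytest.mark.parametrize("v", [-0.8, 0.0, 0.6])
    def test_matches_quadrature(self, v):
        p = DDMParams(a=1.5, z_rel=1 / 3, t0=0.0)
        T = 2.7
        absorbed = sum(
            integrate.quad(
                lambda t: ddm.wiener_fpt_density(t, p, v, b), 1e-9, T, limit=200
            )[0]
            for b in ("upper", "lower")
        )
        assert ddm.survival_probability(T, p, v) == pytest.approx(1 - absorbed, abs=1e-7)


class TestSimulator:
    def test_zero_drift_yes_fraction(self):
        p = DDMParams(a=1.5, z_rel=1 / 3, t0=0.3)
        ch, rt = ddm.simulate_trials(p, np.zeros(100_000), seed=1)
        resp = ch != "missed"
        assert abs((ch[resp] == "yes").mean() - 1 / 3) < 0.01

    def test_nondecision_time_additivity(self):
        p = DDMParams(t0=0.3)
        ch, rt = ddm.simulate_trials(p, np.full(2000, 0.5), seed=2)
        assert np.nanmin(rt) > 0.3

    @pytest.mark.parametrize("z_rel, faster", [(2 / 3, "yes"), (1 / 3, "no")])
    def test_nearer_boundary_answered_faster(self, z_rel, faster):
        """The boundary nearer the starting point is reached faster: a
        start biased toward accepting speeds yes responses, a refusal
        bias speeds refusals (the fast-refusal pattern of the task),
        even under strong positive drift."""
        p = DDMParams(a=1.5, z_rel=z_rel, t0=0.3)
        ch, rt = ddm.simulate_trials(p, np.full(20000, 1.5), seed=3)
        yes, no = rt[ch == "yes"], rt[ch == "no"]
        if faster == "yes":
            assert np.median(yes) < np.median(no)
        else:
            assert np.median(no) < np.median(yes)

    @pytest.mark.parametrize("v", [-0.7, 0.4])
    def test_choice_fractions_match_analytic(self, v):
        """Simulated choice fractions agree with the closed-form absorption
        probability within binomial error at n = 1e5."""
        p = DDMParams(a=1.5, z_rel=1 / 3, t0=0.3)
        n = 100_000
        ch, rt = ddm.simulate_trials(p, np.full(n, v), seed=4, max_rt=30.0)
        p_up = ddm.upper_choice_probability(p, v)
        se = np.sqrt(p_up * (1 - p_up) / n)
        assert abs((ch == "yes").mean() - p_up) < 5 * se + 1e-3


class TestFit:
    def test_recovers_starting_point(self):
        gen = DDMParams(a=1.5, z_rel=1 / 3, t0=0.3, drift_scale=0.8)
        rng = np.random.default_rng(7)
        sv = rng.uniform(-3, 3, 1000)
        ch, rt = ddm.simulate_trials(gen, gen.drift_scale * sv, seed=8)
        fit = ddm.fit_mle(rt, ch, sv, seed=9)
        assert fit.converged
        assert abs(fit.params.z_rel - 1 / 3) < 0.05
        assert abs(fit.params.a - 1.5) < 0.25
        assert abs(fit.params.t0 - 0.3) < 0.05

    def test_unbiased_null_case(self):
        gen = DDMParams(a=1.5, z_rel=0.5, t0=0.3, drift_scale=0.0)
        rng = np.random.default_rng(11)
        sv = rng.uniform(-3, 3, 1500)
        ch, rt = ddm.simulate_trials(gen, 0.0 * sv, seed=12)
        fit = ddm.fit_mle(rt, ch, sv, seed=13)
        assert abs(fit.params.z_rel - 0.5) < 0.05
        assert abs(fit.params.drift_scale) < 0.1

    def test_underdetermined_fit_flagged(self):
        gen = DDMParams()
        rng = np.random.default_rng(14)
        sv = rng.uniform(-3, 3, 5)
        ch, rt = ddm.simulate_trials(gen, gen.drift_scale * sv, seed=15)
        if (ch != "missed").sum() == 0:
            pytest.skip("all missed in tiny sample")
        fit = ddm.fit_mle(rt, ch, sv, seed=16)
        assert not fit.converged

    def test_one_boundary_warns(self):
        gen = DDMParams(a=1.5, z_rel=0.9, t0=0.3, drift_scale=0.0)
        ch = np.array(["yes"] * 50, dtype=object)
        rt = 0.3 + np.random.default_rng(17).gamma(2.0, 0.15, 50)
        with pytest.warns(RuntimeWarning):
            fit = ddm.fit_mle(rt, ch, np.zeros(50), seed=18)
        assert fit.boundary_warning

    def test_likelihood_minimal_near_generating_parameters(self):
        """Averaged over replicate datasets, the censored negative
        log-likelihood at the generating parameters undercuts values at
        perturbed parameters."""
        gen = DDMParams(a=1.5, z_rel=1 / 3, t0=0.3, drift_scale=0.8)
        rng = np.random.default_rng(19)
        truth = np.array([gen.a, gen.z_rel, gen.t0, gen.drift_scale])
        perturbations = [
            truth + np.array([0.3, 0, 0, 0]),
            truth + np.array([0, 0.15, 0, 0]),
            truth + np.array([0, 0, -0.1, 0]),
            truth + np.array([0, 0, 0, 0.4]),
        ]
        diffs = {i: [] for i in range(len(perturbations))}
        for _ in range(5):
            sv = rng.uniform(-3, 3, 400)
            ch, rt = ddm.simulate_trials(gen, gen.drift_scale * sv, rng=rng)
            missed = ch == "missed"
            yes = ch == "yes"
            base = ddm.negative_log_likelihood(truth, rt, yes, missed, sv)
            for i, pert in enumerate(perturbations):
                diffs[i].append(ddm.negative_log_likelihood(pert, rt, yes, missed, sv) - base)
        for i, d in diffs.items():
            assert np.mean(d) > 0, f"perturbation {i} not worse on average"

    def test_vectorized_likelihood_matches_reference(self):
        gen = DDMParams()
        rng = np.random.default_rng(23)
        sv = rng.uniform(-3, 3, 200)
        ch, rt = ddm.simulate_trials(gen, gen.drift_scale * sv, rng=rng)
        theta = (1.4, 0.4, 0.25, 0.7)
        missed = ch == "missed"
        yes = ch == "yes"
        ref = ddm.negative_log_likelihood(theta, rt, yes, missed, sv)
        fast = ddm._nll_vectorized(theta, rt, yes, missed, sv, 3.0)
        assert fast == pytest.approx(ref, rel=1e-9)


class TestParamsValidation:
    @pytest.mark.parametrize(
        "kwargs",
        [{"a": 0.0}, {"z_rel": 0.0}, {"z_rel": 1.0}, {"t0": -0.1}, {"sigma": 2.0}],
    )
    def test_invalid_rejected(self, kwargs):
        with pytest.raises(ConfigurationError):
            DDMParams(**kwargs)


class TestRecoveryConsistency:
    def test_z_rel_bias_shrinks_with_trials(self):
        """The starting-point estimate concentrates on its generating
        value as trials per participant grow (100 -> 500 -> 2000)."""
        gen = DDMParams(a=1.5, z_rel=1 / 3, t0=0.3, drift_scale=0.8)
        rng = np.random.default_rng(29)
        err = {}
        for n in (100, 500, 2000):
            errors = []
            for _ in range(4):
                sv = rng.uniform(-3, 3, n)
                ch, rt = ddm.simulate_trials(gen, gen.drift_scale * sv, rng=rng)
                fit = ddm.fit_mle(rt, ch, sv, seed=int(rng.integers(2**31)))
                errors.append(abs(fit.params.z_rel - 1 / 3))
            err[n] = np.mean(errors)
        assert err[2000] < err[100] + 0.02
        assert err[2000] < 0.04
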