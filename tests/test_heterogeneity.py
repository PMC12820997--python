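"""Step extraction/scaling, Gaussian step models, Rayleigh mixtures, AIC rule."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from piezospt.heterogeneity import (
    RayleighMixtureFit,
    extract_steps,
    fit_rayleigh_mixture,
    fit_step_gaussians,
    population_summary,
    scale_steps,
    select_k,
)
from piezospt.trajectory import Trajectory


class TestExtractSteps:
    def test_simple_steps(self):
        t = Trajectory("a", [0, 1, 2], [[0, 0], [1, 0], [1, 1]], 0.1)
        s = extract_steps(t)
        np.testing.assert_allclose(s.dxy, [[1, 0], [0, 1]])
        np.testing.assert_allclose(s.lengths, [1, 1])

    def test_gap_policy(self):
        """A gap at frame 2 of 4 leaves only the 0->1 step; 1->3 is skipped."""
        xy = np.array([[0, 0], [1, 0], [np.nan, np.nan], [3, 0]], float)
        t = Trajectory("a", np.arange(4), xy, 0.1)
        s = extract_steps(t)
        assert s.n_steps == 1
        np.testing.assert_allclose(s.dxy, [[1, 0]])


class TestScaleSteps:
    def test_hand_example(self):
        t = Trajectory("a", [0, 1, 2], [[0, 0], [2, 2], [0, 0]], 0.1)
        s = scale_steps(extract_steps(t))
        np.testing.assert_allclose(s.dxy, [[1, 1], [-1, -1]])

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(st.integers(0, 10_000))
    def test_rms_is_one_to_machine_precision(self, seed):
        rng = np.random.default_rng(seed)
        n = rng.integers(3, 100)
        xy = np.cumsum(rng.normal(0, rng.uniform(0.01, 1.0), size=(n, 2)), axis=0)
        s = scale_steps(extract_steps(Trajectory("a", np.arange(n), xy, 0.1)))
        np.testing.assert_allclose(np.sqrt(np.mean(s.dxy**2, axis=0)), 1.0, rtol=1e-12)

    def test_zero_rms_axis_rejected(self):
        t = Trajectory("a", [0, 1, 2], [[0, 0], [1, 0], [2, 0]], 0.1)  # dy always 0
        with pytest.raises(ValueError):
            scale_steps(extract_steps(t))


class TestStepGaussians:
    def test_symmetric_input_means_near_zero(self):
        rng = np.random.default_rng(5)
        x = rng.standard_normal(5000)
        x = np.concatenate([x, -x])
        m = fit_step_gaussians(x, seed=0)
        assert abs(m.mean) < 1e-12
        assert np.all(np.abs(m.mix_means) < 0.1)

    def test_mixture_gain_vanishes_on_single_gaussian(self):
        rng = np.random.default_rng(6)
        x = rng.standard_normal(20_000)
        m = fit_step_gaussians(x, seed=0)
        assert m.loglik_mixture >= m.loglik_single - 1e-6  # nested models
        assert (m.loglik_mixture - m.loglik_single) / x.size < 1e-3

    def test_two_state_steps_prefer_mixture(self, two_state_ensemble):
        pooled = np.concatenate(
            [scale_steps(extract_steps(t)).dxy.ravel() for t in two_state_ensemble.trajectories]
        )
        m = fit_step_gaussians(pooled, seed=0)
        assert m.loglik_mixture > m.loglik_single + 10  # clear non-Gaussianity


class TestRayleighMixture:
    def test_k1_closed_form(self):
        f = fit_rayleigh_mixture(np.array([1.0, 1.0]), 1, 0.1)
        assert np.isclose(f.sigmas[0], np.sqrt(0.5))  # sqrt(sum r^2 / 2n) = 0.7071
        assert f.aic == pytest.approx(2 * 1 - 2 * f.loglik)

    def test_apparent_d_arithmetic(self):
        rng = np.random.default_rng(7)
        r = np.hypot(rng.normal(0, 0.1, 5000), rng.normal(0, 0.1, 5000))
        f = fit_rayleigh_mixture(r, 1, dt=0.1)
        assert np.isclose(f.apparent_D[0], 0.05, rtol=0.05)  # sigma^2 / (2 dt)

    def test_em_equals_closed_form_for_k1_path(self):
        """The k=1 EM fixed point is the closed-form MLE; fitting k=2 on pure
        Rayleigh data must not beat it by more than numerical slack per AIC."""
        rng = np.random.default_rng(8)
        r = np.hypot(rng.normal(0, 0.08, 2000), rng.normal(0, 0.08, 2000))
        f1 = fit_rayleigh_mixture(r, 1, 0.1)
        sigma_mle = np.sqrt(np.sum(r**2) / (2 * r.size))
        assert np.isclose(f1.sigmas[0], sigma_mle, rtol=1e-12)
        f2 = fit_rayleigh_mixture(r, 2, 0.1, seed=0)
        assert f2.loglik >= f1.loglik - 1e-6

    def test_recovery_on_two_state_trajectories(self, two_state_ensemble):
        """Median recovered (p, sigma_slow, sigma_fast) within 10% of truth."""
        recs = []
        for t in two_state_ensemble.trajectories:
            r = np.linalg.norm(t.steps(), axis=1)
            f = fit_rayleigh_mixture(r, 2, 0.1, seed=3)
            if f.k == 2:
                recs.append([f.proportions[1], f.sigmas[0], f.sigmas[1]])
        med = np.median(np.array(recs), axis=0)
        np.testing.assert_allclose(med, [0.5, 0.03, 0.10], rtol=0.10)

    def test_parsimony_prefers_k1_on_pure_rayleigh(self):
        """Pure Rayleigh data selects k=1 in at least 90% of seeded replicates."""
        rng = np.random.default_rng(9)
        wins = 0
        n_rep = 20
        for _ in range(n_rep):
            r = np.hypot(rng.normal(0, 0.08, 400), rng.normal(0, 0.08, 400))
            fits = [fit_rayleigh_mixture(r, k, 0.1, seed=1, n_restarts=4) for k in (1, 2, 3)]
            wins += select_k(fits).k == 1
        assert wins >= 0.9 * n_rep


class TestSelectK:
    def _mk(self, k, aic):
        return RayleighMixtureFit(
            k=k, proportions=np.ones(k) / k, sigmas=np.linspace(0.01, 0.1, k),
            apparent_D=np.ones(k), loglik=0.0, aic=aic, n_steps=100,
        )

    def test_hand_traced_double_stepdown(self):
        fits = [self._mk(k, a) for k, a in zip((1, 2, 3, 4), (100, 97, 96.5, 99))]
        assert select_k(fits).k == 1  # 3 -> 2 (0.5 < 4) -> 1 (3 < 4)

    def test_hand_traced_single_stepdown(self):
        fits = [self._mk(k, a) for k, a in zip((1, 2, 3, 4), (100, 90, 89, 95))]
        assert select_k(fits).k == 2  # 3 -> 2 (1 < 4); 10 >= 4 stops

    def test_no_stepdown_when_gap_large(self):
        fits = [self._mk(k, a) for k, a in zip((1, 2, 3), (120, 100, 110))]
        assert select_k(fits).k == 2


class TestPopulationSummary:
    def test_recovery_of_joint_mode(self, two_state_ensemble):
        fits = []
        for t in two_state_ensemble.trajectories:
            r = np.linalg.norm(t.steps(), axis=1)
            fits.append(fit_rayleigh_mixture(r, 2, 0.1, seed=3))
        summ = population_summary(fits, component="fast", noise_equivalent_D=0.01)
        p_mode, d_mode = summ.mode
        assert abs(p_mode - 0.5) < 0.1
        true_d_fast = 0.10**2 / (2 * 0.1)
        assert abs(np.log10(d_mode) - np.log10(true_d_fast)) < np.log10(1.2)
        slow = population_summary(fits, component="slow", noise_equivalent_D=0.01)
        assert 0.0 <= slow.frac_below_noise_D <= 1.0
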