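"""Scaled radius of gyration, classification, and stratified odds ratios."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from piezospt.mobility import (
    ContingencyStratum,
    classify,
    mantel_haenszel_or,
    scaled_radius_of_gyration,
    weighted_or,
)
from piezospt.trajectory import Trajectory


class TestScaledRadiusOfGyration:
    def test_hand_example(self):
        """Collinear unit steps: Rg = sqrt(2/3), <r> = 1, sRg = 1.0233."""
        t = Trajectory("a", [0, 1, 2], [[0, 0], [1, 0], [2, 0]], 0.1)
        r = scaled_radius_of_gyration(t)
        assert np.isclose(r.Rg, np.sqrt(2.0 / 3.0))
        assert np.isclose(r.mean_step, 1.0)
        assert np.isclose(r.sRg, 1.0233, atol=1e-4)

    def test_iid_gaussian_positions_mean_near_one(self, immobile_ensemble):
        """Noise-only positions give ensemble-mean sRg ~ 1."""
        srg = [scaled_radius_of_gyration(t).sRg for t in immobile_ensemble.trajectories]
        assert abs(np.mean(srg) - 1.0) < 0.02

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(
        st.integers(0, 10_000),
        st.floats(0.1, 50.0),
        st.floats(0.0, 2 * np.pi),
        st.tuples(st.floats(-10, 10), st.floats(-10, 10)),
    )
    def test_similarity_invariance(self, seed, scale, theta, shift):
        """sRg is invariant to translation, rotation, and uniform scaling."""
        rng = np.random.default_rng(seed)
        xy = np.cumsum(rng.normal(0, 0.1, size=(30, 2)), axis=0)
        base = scaled_radius_of_gyration(Trajectory("a", np.arange(30), xy, 0.1)).sRg
        R = np.array([[np.cos(theta), -np.sin(theta)], [np.sin(theta), np.cos(theta)]])
        xy2 = scale * (xy @ R.T) + np.asarray(shift)
        out = scaled_radius_of_gyration(Trajectory("a", np.arange(30), xy2, 0.1)).sRg
        assert np.isclose(base, out, rtol=1e-9)

    def test_steps_skip_gaps(self):
        """The mean step uses consecutive non-gap frames only."""
        xy = np.array([[0, 0], [1, 0], [np.nan, np.nan], [5, 0]], float)
        t = Trajectory("a", np.arange(4), xy, 0.1)
        r = scaled_radius_of_gyration(t)
        assert np.isclose(r.mean_step, 1.0)  # only the 0->1 step; 2->3 spans the gap

    def test_degenerate_all_identical(self):
        t = Trajectory("a", np.arange(5), np.ones((5, 2)), 0.1)
        r = scaled_radius_of_gyration(t)
        assert r.degenerate


class TestClassify:
    def test_boundary_assigned_immobile(self):
        """A trajectory whose sRg equals the threshold exactly is immobile."""
        rng = np.random.default_rng(0)
        trajs = [
            Trajectory(i, np.arange(100), rng.normal(0, 1.0, size=(100, 2)), 0.1)
            for i in range(3)
        ]
        srgs = [scaled_radius_of_gyration(t).sRg for t in trajs]
        results, _ = classify(trajs, srg_threshold=srgs[0])
        assert results[0].label == "immobile"
        for r, s in zip(results[1:], srgs[1:]):
            assert r.label == ("mobile" if s > srgs[0] else "immobile")

    def test_labels_and_session_counts(self):
        rng = np.random.default_rng(1)
        trajs = []
        for i in range(20):
            xy = rng.normal(0, 0.02, size=(50, 2))
            t = Trajectory(i, np.arange(50), xy, 0.1, {"session_id": "s1" if i < 10 else "s2"})
            trajs.append(t)
        results, counts = classify(trajs, srg_threshold=0.0)  # everything mobile
        assert all(r.label == "mobile" for r in results)
        assert counts["s1"]["mobile"] == 10 and counts["s2"]["mobile"] == 10

    def test_two_population_mixing_fraction_recovery(self):
        """Mobile fraction recovers the simulated mixing fraction within 3%."""
        from piezospt.simulate import SimulationConfig, simulate_brownian, simulate_immobile

        n_mob, n_imm = 300, 700
        mob = simulate_brownian(SimulationConfig(n_traj=n_mob, n_points=200, loc_sigma=0.02, seed=41), D=0.1)
        imm = simulate_immobile(SimulationConfig(n_traj=n_imm, n_points=200, loc_sigma=0.02, seed=42))
        trajs = mob.trajectories + imm.trajectories
        results, _ = classify(trajs, srg_threshold=1.04)
        frac = np.mean([r.label == "mobile" for r in results])
        assert abs(frac - n_mob / (n_mob + n_imm)) < 0.03 + 0.05 * n_imm / (n_mob + n_imm)


class TestMantelHaenszel:
    # mobile:immobile counts reported for a cholesterol-depletion (MBCD)
    # treatment and its solvent control, used as a fixed numeric oracle
    MBCD = ContingencyStratum("mbcd", 11097, 5666, 5906, 3670)

    def test_single_stratum_equals_simple_or(self):
        res = mantel_haenszel_or([self.MBCD])
        simple = (11097 * 3670) / (5666 * 5906)
        assert np.isclose(res.common_or, simple)
        assert np.isclose(res.common_or, 1.217, atol=0.001)

    def test_null_stratum_gives_or_one(self):
        s = ContingencyStratum("s", 50, 30, 50, 30)
        assert np.isclose(mantel_haenszel_or([s]).common_or, 1.0)

    def test_replicated_strata_invariance(self):
        one = mantel_haenszel_or([self.MBCD])
        two = mantel_haenszel_or([self.MBCD, self.MBCD])
        assert np.isclose(one.common_or, two.common_or)

    def test_against_statsmodels_oracle(self):
        """MH estimate, RBG CI, and MH test agree with statsmodels StratifiedTable."""
        sm = pytest.importorskip("statsmodels.stats.contingency_tables")
        strata = [
            ContingencyStratum("a", 30, 20, 25, 25),
            ContingencyStratum("b", 40, 10, 35, 20),
            ContingencyStratum("c", 12, 18, 14, 11),
        ]
        tables = [
            np.array([[s.treated_mobile, s.treated_immobile], [s.control_mobile, s.control_immobile]])
            for s in strata
        ]
        st_tab = sm.StratifiedTable(tables)
        res = mantel_haenszel_or(strata)
        assert np.isclose(res.common_or, st_tab.oddsratio_pooled, rtol=1e-10)
        lo, hi = st_tab.oddsratio_pooled_confint(0.05)
        assert np.isclose(res.ci95[0], lo, rtol=1e-6)
        assert np.isclose(res.ci95[1], hi, rtol=1e-6)
        assert np.isclose(res.p_value, st_tab.test_null_odds(correction=False).pvalue, rtol=1e-6)

    def test_counts_validation(self):
        with pytest.raises(ValueError):
            ContingencyStratum("s", -1, 2, 3, 4)
        with pytest.raises(ValueError):
            ContingencyStratum("s", 0, 0, 0, 0)


class TestWeightedOr:
    def test_single_session_reduces_to_simple_or(self):
        res = weighted_or([("s1", 50, 30)], (40, 40))
        assert np.isclose(res.common_or, (50 / 30) / (40 / 40))

    def test_identical_sessions_equal_single(self):
        one = weighted_or([("s1", 50, 30)], (40, 40))
        three = weighted_or([("s1", 50, 30)] * 3, (40, 40))
        assert np.isclose(one.common_or, three.common_or)

    def test_zero_cell_continuity_correction(self):
        res = weighted_or([("s1", 50, 0)], (40, 40))
        assert np.isfinite(res.common_or) and res.common_or > 1

    def test_coverage_under_known_or(self):
        """95% CI covers a true OR of 1.5 in >= 93 of 100 seeded replicates."""
        true_or = 1.5
        p_ctrl = 0.5
        odds_t = true_or * p_ctrl / (1 - p_ctrl)
        p_treat = odds_t / (1 + odds_t)
        rng = np.random.default_rng(99)
        hits = 0
        for _ in range(100):
            sessions = []
            for s in range(5):
                n = 400
                m = rng.binomial(n, p_treat)
                sessions.append((s, m, n - m))
            cm = rng.binomial(2000, p_ctrl)
            res = weighted_or(sessions, (cm, 2000 - cm))
            hits += res.ci95[0] <= true_or <= res.ci95[1]
        assert hits >= 93
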