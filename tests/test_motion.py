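"""Kalman kinematics and motion scores: S_AA, score test, LTM/STM."""

import math

import numpy as np
import pytest

from densetrack.malc import Detection
from densetrack.motion import (
    HypothesisScore,
    KinematicState,
    MotionScoreState,
    ScoringConfig,
    combined_score,
    delta_ltm,
    kf_init,
    kf_predict_update,
    score_test,
    update_saa,
    update_stm,
    velocity_mahalanobis,
)


def det(frame, x, y):
    return Detection(frame_index=frame, centroid=(y, x), detection_id=1)


class TestKalman:
    def test_noiseless_constant_velocity_convergence(self):
        cfg = ScoringConfig(meas_noise=1e-4, process_noise=0.0)
        state = kf_init(det(0, 0.0, 0.0), cfg)
        for t in range(1, 7):
            state = kf_predict_update(state, det(t, 2.0 * t, -1.0 * t), cfg)
        assert np.allclose(state.velocity, [2.0, -1.0], atol=1e-6)
        assert np.allclose(state.position, [12.0, -6.0], atol=1e-6)

    def test_dummy_updates_extrapolate_exactly(self):
        cfg = ScoringConfig()
        state = KinematicState(x=np.array([0.0, 0.0, 3.0, 1.0]), p=np.eye(4))
        for k in range(1, 5):
            state = kf_predict_update(state, None, cfg)
            assert np.allclose(state.position, [3.0 * k, 1.0 * k])

    def test_matches_reference_filter(self, rng):
        # independently coded textbook recursion
        cfg = ScoringConfig(meas_noise=1.3, process_noise=0.7)
        F = np.array([[1, 0, 1, 0], [0, 1, 0, 1], [0, 0, 1, 0], [0, 0, 0, 1]], dtype=float)
        H = np.array([[1, 0, 0, 0], [0, 1, 0, 0]], dtype=float)
        G = np.array([[0.5, 0], [0, 0.5], [1, 0], [0, 1]])
        Q = cfg.process_noise ** 2 * (G @ G.T)
        R = cfg.meas_noise ** 2 * np.eye(2)

        x_ref = np.array([1.0, 2.0, 0.5, -0.2])
        p_ref = np.diag([1.0, 1.0, 4.0, 4.0])
        state = KinematicState(x=x_ref.copy(), p=p_ref.copy())
        for t in range(1, 15):
            z = rng.normal(size=2) * 3 + [t, 2 * t]
            x_pred = F @ x_ref
            p_pred = F @ p_ref @ F.T + Q
            s = H @ p_pred @ H.T + R
            k = p_pred @ H.T @ np.linalg.inv(s)
            x_ref = x_pred + k @ (z - H @ x_pred)
            p_ref = (np.eye(4) - k @ H) @ p_pred
            state = kf_predict_update(state, det(t, z[0], z[1]), cfg)
            assert np.allclose(state.x, x_ref, atol=1e-9)
            assert np.allclose(state.p, p_ref, atol=1e-9)

    def test_non_finite_state_raises(self):
        cfg = ScoringConfig()
        bad = KinematicState(x=np.array([np.nan, 0, 0, 0]), p=np.eye(4))
        with pytest.raises(FloatingPointError):
            kf_predict_update(bad, None, cfg)


class TestVelocityMahalanobis:
    def test_zero_for_matching_velocity(self):
        state = KinematicState(x=np.array([0, 0, 2.0, 3.0]), p=np.eye(4))
        assert velocity_mahalanobis(np.array([2.0, 3.0]), state) == pytest.approx(0.0)

    def test_euclidean_reduction_identity_cov(self):
        state = KinematicState(x=np.array([0, 0, 0.0, 0.0]), p=np.eye(4))
        md = velocity_mahalanobis(np.array([3.0, 4.0]), state)
        assert md == pytest.approx(5.0, abs=1e-6)

    def test_matches_direct_formula(self, rng):
        for _ in range(50):
            a = rng.normal(size=(2, 2))
            sigma = a @ a.T + 0.1 * np.eye(2)
            p = np.eye(4)
            p[2:, 2:] = sigma
            v_pred = rng.normal(size=2)
            v_cand = rng.normal(size=2)
            state = KinematicState(x=np.array([0, 0, *v_pred]), p=p)
            delta = v_cand - v_pred
            expect = math.sqrt(delta @ np.linalg.solve(sigma, delta))
            assert velocity_mahalanobis(v_cand, state) == pytest.approx(expect, rel=1e-5)


class TestSAA:
    def test_first_update_halves(self):
        s = update_saa(MotionScoreState(s_aa=0.0, nc=1), 4.0)
        assert s.s_aa == pytest.approx(2.0)
        assert s.nc == 2

    def test_zero_md_stays_zero(self):
        s = MotionScoreState()
        for _ in range(10):
            s = update_saa(s, 0.0)
        assert s.s_aa == 0.0

    def test_nc_caps_at_tree_depth(self):
        s = MotionScoreState()
        for _ in range(10):
            s = update_saa(s, 1.0, tree_depth=6)
        assert s.nc == 6

    def test_unrolled_geometric_expansion_constant_nc(self, rng):
        nc = 6
        for _ in range(50):
            mds = rng.uniform(0, 5, size=12)
            s = MotionScoreState(s_aa=0.0, nc=nc)
            for md in mds:
                s = update_saa(s, float(md), tree_depth=nc)
            t = len(mds)
            expect = sum(
                (1 / (nc + 1)) * ((nc - 1) / (nc + 1)) ** (t - 1 - l) * mds[l]
                for l in range(t)
            )
            assert abs(s.s_aa - expect) < 1e-9

    def test_recent_terms_weigh_more(self):
        # an impulse arriving later leaves a larger trace
        def run(impulse_at):
            s = MotionScoreState(s_aa=0.0, nc=6)
            for t in range(8):
                s = update_saa(s, 5.0 if t == impulse_at else 0.0)
            return s.s_aa

        assert run(7) > run(3) > run(0)


class TestScoreTest:
    CFG = dict(alpha=20.0, beta=0.8, gamma=10.0, delta=6.0)

    def test_young_track_threshold(self):
        passed, s_st, th = score_test(4.0, MotionScoreState(ns=0), **self.CFG)
        assert th == pytest.approx(16.0)
        assert passed

    def test_late_track_constant_threshold(self):
        _, _, th = score_test(4.0, MotionScoreState(ns=13), **self.CFG)
        assert th == pytest.approx(6.0)

    def test_equality_fails(self):
        st = MotionScoreState(ns=0, s_aa=0.0)
        passed, s_st, th = score_test(16.0, st, **self.CFG)
        assert s_st == pytest.approx(th)
        assert not passed

    def test_threshold_polyline_single_breakpoint(self):
        ths = [score_test(0.0, MotionScoreState(ns=ns), **self.CFG)[2] for ns in range(21)]
        assert all(a >= b for a, b in zip(ths, ths[1:]))
        jumps = [i for i in range(1, 21) if ths[i] == 6.0 and ths[i - 1] != 6.0]
        assert jumps == [10]  # (alpha - Ns) stops exceeding gamma at Ns = 10


class TestLTM:
    def test_dummy_penalty(self):
        cfg = ScoringConfig(p_d=0.9)
        assert delta_ltm(True, 1.0, cfg) == pytest.approx(math.log(0.1))

    def test_initial_score(self):
        cfg = ScoringConfig(lambda_fa=1e-6, lambda_nt=1e-8)
        assert cfg.initial_score == pytest.approx(math.log(0.01))

    def test_zero_increment_at_balance(self):
        cfg = ScoringConfig()
        p = (cfg.lambda_fa + cfg.lambda_nt) / cfg.p_d
        assert delta_ltm(False, p, cfg) == pytest.approx(0.0, abs=1e-12)

    def test_likelihood_floor(self):
        cfg = ScoringConfig()
        assert math.isfinite(delta_ltm(False, 0.0, cfg))


class TestSTM:
    def test_midpoint_zero_increment(self):
        assert update_stm(1.5, 8.0, 16.0) == pytest.approx(1.5)

    def test_hand_value(self):
        assert update_stm(0.0, 4.0, 16.0) == pytest.approx(math.log(3.0))

    def test_floor_caps_and_monotone(self):
        vals = [update_stm(0.0, s, 16.0) for s in (0.0, 1e-5, 1e-3, 0.1, 1.0, 8.0)]
        assert vals[0] == vals[1] == vals[2]
        assert all(a >= b for a, b in zip(vals, vals[1:]))


class TestCombined:
    def test_unit_weights(self):
        assert combined_score(HypothesisScore(2.0, 3.0), 1.0, 1.0) == 5.0

    def test_stm_weight_zero_reduces_to_ltm(self):
        assert combined_score(HypothesisScore(2.0, 99.0), 1.0, 0.0) == 2.0

    def test_birth_state(self):
        cfg = ScoringConfig()
        s = HypothesisScore(cfg.initial_score, 0.0)
        assert combined_score(s, 1.0, 1.0) == pytest.approx(math.log(0.01))

    def test_linear_in_each_component(self):
        base = combined_score(HypothesisScore(1.0, 1.0), 2.0, 3.0)
        assert combined_score(HypothesisScore(2.0, 1.0), 2.0, 3.0) - base == pytest.approx(2.0)
        assert combined_score(HypothesisScore(1.0, 2.0), 2.0, 3.0) - base == pytest.approx(3.0)
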