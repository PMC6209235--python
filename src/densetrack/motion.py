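"""Per-hypothesis kinematics and motion scores.

Each track hypothesis carries a constant-velocity Kalman filter (state
``[x, y, vx, vy]`` in pixels and pixels/frame) plus four scalar scores:

* ``S_AA`` — an autoregressive average of velocity-space Mahalanobis
  discrepancies, updated as ``S_AA <- (S_AA*(NC-1) + MD) / (NC+1)`` with NC
  the (depth-capped) update count.  Unrolled, recent discrepancies carry
  geometrically larger weights, so S_AA is a short-memory smoothness summary.
* ``S_ST = |MD - S_AA|`` — the score-test statistic, compared against a
  two-stage threshold ``th_n`` that starts loose for young tracks and drops
  to a tight constant once a track has sustained long enough.
* ``S_LTM`` — the classical cumulative log-likelihood-ratio track score
  (Gaussian innovation density vs. clutter, with a log(1-P_D) penalty on
  missed frames).
* ``S_STM`` — the accumulated ``log((th_n - S_ST)/S_ST)`` over effective
  (non-dummy) associations, a short-term smoothness likelihood ratio.

The combined hypothesis score is ``w_LTM*S_LTM + w_STM*S_STM``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np

from .malc import Detection

__all__ = [
    "KinematicState",
    "MotionScoreState",
    "HypothesisScore",
    "ScoringConfig",
    "kf_init",
    "kf_predict",
    "kf_update",
    "kf_predict_update",
    "velocity_mahalanobis",
    "candidate_velocity",
    "update_saa",
    "score_test",
    "delta_ltm",
    "update_stm",
    "combined_score",
]

_F = np.array([[1.0, 0, 1, 0], [0, 1, 0, 1], [0, 0, 1, 0], [0, 0, 0, 1]])
_H = np.array([[1.0, 0, 0, 0], [0, 1, 0, 0]])


@dataclass
class ScoringConfig:
    """Score and gate parameters (defaults are the operating point used
    throughout: alpha=20, beta=0.8, gamma=10, delta=6 for the two-stage
    score-test threshold; P_D=0.9; clutter density 1e-6 and new-target
    density 1e-8 per pixel^2 per frame; unit score weights)."""

    alpha: float = 20.0
    beta: float = 0.8
    gamma: float = 10.0
    delta: float = 6.0
    p_d: float = 0.9
    lambda_fa: float = 1e-6
    lambda_nt: float = 1e-8
    w_ltm: float = 1.0
    w_stm: float = 1.0
    meas_noise: float = 1.0       # measurement sigma, px
    process_noise: float = 0.5    # acceleration sigma, px/frame^2
    likelihood_floor: float = 1e-12
    s_st_floor: float = 1e-3
    tree_depth: int = 6

    @property
    def initial_score(self) -> float:
        return math.log(self.lambda_nt / self.lambda_fa)


@dataclass
class KinematicState:
    """Kalman state: position/velocity mean and 4x4 covariance."""

    x: np.ndarray          # [x, y, vx, vy]
    p: np.ndarray          # 4x4 covariance
    last_likelihood: float = 1.0
    predicted_pos: np.ndarray | None = None

    @property
    def position(self) -> np.ndarray:
        return self.x[:2]

    @property
    def velocity(self) -> np.ndarray:
        return self.x[2:]

    def velocity_covariance(self) -> np.ndarray:
        return self.p[2:, 2:]


_Q_CACHE: dict = {}


def _q_matrix(sigma_a: float) -> np.ndarray:
    # discrete white-noise acceleration model, dt = 1
    q = _Q_CACHE.get(sigma_a)
    if q is None:
        G = np.array([[0.5, 0], [0, 0.5], [1, 0], [0, 1]])
        q = _Q_CACHE[sigma_a] = sigma_a ** 2 * (G @ G.T)
    return q


def kf_init(detection: Detection, cfg: ScoringConfig) -> KinematicState:
    """Start a filter at a detection with zero velocity and wide velocity
    uncertainty."""
    x = np.array([detection.position[0], detection.position[1], 0.0, 0.0])
    p = np.diag([cfg.meas_noise ** 2, cfg.meas_noise ** 2, 100.0, 100.0])
    return KinematicState(x=x, p=p)


def kf_predict(state: KinematicState, cfg: ScoringConfig) -> KinematicState:
    """Constant-velocity predict step (dt = 1)."""
    if not np.all(np.isfinite(state.x)):
        raise FloatingPointError("non-finite kinematic state")
    x = _F @ state.x
    p = _F @ state.p @ _F.T + _q_matrix(cfg.process_noise)
    return KinematicState(x=x, p=p, last_likelihood=1.0, predicted_pos=x[:2].copy())


def kf_update(predicted: KinematicState, detection: Detection, cfg: ScoringConfig) -> KinematicState:
    """Position measurement update of a predicted state; also records the
    Gaussian innovation density used by the long-term score."""
    x, p = predicted.x, predicted.p
    z = detection.position
    r2 = cfg.meas_noise ** 2
    # S = H P H' + R is 2x2; invert it in closed form
    s00 = p[0, 0] + r2
    s01 = p[0, 1]
    s11 = p[1, 1] + r2
    det_s = s00 * s11 - s01 * s01
    si00, si01, si11 = s11 / det_s, -s01 / det_s, s00 / det_s
    i0 = z[0] - x[0]
    i1 = z[1] - x[1]
    ph = p[:, :2]
    k = np.empty((4, 2))
    k[:, 0] = ph[:, 0] * si00 + ph[:, 1] * si01
    k[:, 1] = ph[:, 0] * si01 + ph[:, 1] * si11
    x_new = x + k[:, 0] * i0 + k[:, 1] * i1
    p_new = p - k @ ph.T
    p_new = 0.5 * (p_new + p_new.T)
    maha2 = i0 * (si00 * i0 + si01 * i1) + i1 * (si01 * i0 + si11 * i1)
    lik = math.exp(-0.5 * maha2) / (2 * math.pi * math.sqrt(det_s))
    return KinematicState(
        x=x_new, p=p_new, last_likelihood=lik, predicted_pos=predicted.predicted_pos
    )


def kf_predict_update(
    state: KinematicState, detection: Detection | None, cfg: ScoringConfig
) -> KinematicState:
    """One predict step, then a position update if the detection is real; a
    dummy (or None) leaves the prediction as the new state, with the
    covariance grown by the process noise."""
    predicted = kf_predict(state, cfg)
    if detection is None or detection.is_dummy:
        return predicted
    return kf_update(predicted, detection, cfg)


def candidate_velocity(
    det: Detection, last_position: np.ndarray, d_frames: int = 1
) -> np.ndarray:
    """Velocity implied by associating ``det`` to a track whose last updated
    position is ``last_position``, ``d_frames`` frames earlier."""
    return (det.position - last_position) / max(d_frames, 1)


def velocity_mahalanobis(
    v_candidate: np.ndarray, state: KinematicState, jitter: float = 1e-9
) -> float:
    """Mahalanobis distance between a candidate velocity and the filter's
    predicted velocity, under the velocity-block covariance (regularised with
    diagonal jitter if singular)."""
    sigma = state.velocity_covariance() + jitter * np.eye(2)
    delta = np.asarray(v_candidate, dtype=float) - state.velocity
    try:
        sol = np.linalg.solve(sigma, delta)
    except np.linalg.LinAlgError:
        sol = np.linalg.solve(sigma + 1e-6 * np.eye(2), delta)
    return float(math.sqrt(max(delta @ sol, 0.0)))


@dataclass
class MotionScoreState:
    """S_AA and the counters it depends on.

    ``nc`` is the depth-capped update count (starts at 1 so the first
    discrepancy enters with weight 1/2); ``ns`` counts frames since birth
    (dummies included); ``ic`` counts effective (non-dummy) associations.
    """

    s_aa: float = 0.0
    nc: int = 1
    ns: int = 0
    ic: int = 0


def update_saa(prev: MotionScoreState, md: float, tree_depth: int = 6) -> MotionScoreState:
    """Autoregressive S_AA update using the pre-update NC, then NC increments
    (capped at the hypothesis-tree depth)."""
    if md < 0:
        raise ValueError("Mahalanobis distance must be non-negative")
    nc = prev.nc
    s_aa = (prev.s_aa * (nc - 1) + md) / (nc + 1)
    return replace(prev, s_aa=s_aa, nc=min(nc + 1, tree_depth))


def score_test(
    md: float,
    state: MotionScoreState,
    alpha: float,
    beta: float,
    gamma: float,
    delta: float,
) -> tuple[bool, float, float]:
    """Two-stage score test.

    ``s_st = |md - s_aa|`` measures deviation from the track's remembered
    acceleration pattern; the threshold ``th_n = (alpha - Ns)*beta`` while
    ``alpha - Ns > gamma``, else the tight constant ``delta``.  Passing
    requires the strict inequality ``s_st < th_n``.
    """
    s_st = abs(md - state.s_aa)
    th_n = (alpha - state.ns) * beta if (alpha - state.ns) > gamma else delta
    return s_st < th_n, s_st, th_n


def delta_ltm(
    det_is_dummy: bool, likelihood: float, cfg: ScoringConfig
) -> float:
    """Long-term score increment: the log-likelihood ratio of the Gaussian
    innovation density against clutter, or log(1 - P_D) on a missed frame."""
    if det_is_dummy:
        return math.log(1.0 - cfg.p_d)
    p = max(likelihood, cfg.likelihood_floor)
    return math.log(p * cfg.p_d / (cfg.lambda_fa + cfg.lambda_nt))


def update_stm(prev_stm: float, s_st: float, th_n: float, s_st_floor: float = 1e-3) -> float:
    """Short-term score accumulation ``log((th_n - s_st)/s_st)`` with the
    statistic floored before the ratio."""
    s = max(s_st, s_st_floor)
    return prev_stm + math.log((th_n - s) / s)


@dataclass
class HypothesisScore:
    s_ltm: float = 0.0
    s_stm: float = 0.0

    def combined(self, w_ltm: float = 1.0, w_stm: float = 1.0) -> float:
        return w_ltm * self.s_ltm + w_stm * self.s_stm


def combined_score(score: HypothesisScore, w_ltm: float, w_stm: float) -> float:
    return score.combined(w_ltm, w_stm)
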