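"""Track-hypothesis forest: gated growth, birth, death, depth control.

A *track hypothesis* is one candidate detection-per-frame sequence (dummies
standing in for missed frames).  Hypotheses sharing a root detection form a
tree; the forest holds all trees alive at the current frame.  Every frame,
each leaf spawns one child per detection that passes gating (a Euclidean
pre-gate plus the velocity score test once the track is old enough) and one
dummy child; unclaimed detections seed new trees.  Tree depth is bounded by
an N-scan commit: once branching is older than ``depth`` frames the
best-scoring leaf's ancestry wins and disagreeing leaves are dropped.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .malc import Detection
from .motion import (
    HypothesisScore,
    KinematicState,
    MotionScoreState,
    ScoringConfig,
    candidate_velocity,
    delta_ltm,
    kf_init,
    kf_predict,
    kf_update,
    score_test,
    update_saa,
    update_stm,
    velocity_mahalanobis,
)

__all__ = ["TrackerConfig", "TrackHypothesis", "Forest", "extend", "spawn", "terminate", "retain_top"]


@dataclass
class TrackerConfig:
    """Forest management knobs: hypothesis-tree depth, termination rule
    (score drop below peak, or a run of missed frames), the Euclidean
    pre-gate radius, and the retained fraction of terminated hypotheses."""

    depth: int = 6
    delta_term: float = 9.0
    max_dummies: int = 4
    gate_radius: float = 15.0
    retain_fraction: float = 0.2


@dataclass
class TrackHypothesis:
    """One leaf of a hypothesis tree: a full detection sequence with its
    Kalman state and scores.  ``detections[i]`` is the detection at frame
    ``birth_frame + i`` (possibly a dummy)."""

    detections: list
    birth_frame: int
    kin: KinematicState
    motion: MotionScoreState
    score: HypothesisScore
    tree_id: int
    leaf_id: int
    alive: bool = True
    peak_score: float = -math.inf
    consecutive_dummies: int = 0
    traj_id: int | None = None
    last_real_position: np.ndarray | None = None
    last_real_frame: int = -1

    @property
    def last_frame(self) -> int:
        return self.birth_frame + len(self.detections) - 1

    @property
    def n_real(self) -> int:
        return self.motion.ic

    def detection_at(self, frame: int) -> Detection | None:
        i = frame - self.birth_frame
        if 0 <= i < len(self.detections):
            return self.detections[i]
        return None

    def real_detections(self) -> list:
        return [d for d in self.detections if not d.is_dummy]

    def combined(self, scoring: ScoringConfig) -> float:
        return self.score.combined(scoring.w_ltm, scoring.w_stm)


@dataclass
class Forest:
    """All live hypothesis trees at the current frame."""

    scoring: ScoringConfig = field(default_factory=ScoringConfig)
    tracker: TrackerConfig = field(default_factory=TrackerConfig)
    trees: dict = field(default_factory=dict)        # tree_id -> list of leaves
    frame_index: int = -1
    terminated: list = field(default_factory=list)
    _next_tree: int = 0
    _next_leaf: int = 0
    # per-tree frame up to which branching has been committed by N-scan
    _nscan_frame: dict = field(default_factory=dict)

    def live_leaves(self) -> list:
        out = []
        for tid in sorted(self.trees):
            out.extend(self.trees[tid])
        return out

    def new_leaf_id(self) -> int:
        self._next_leaf += 1
        return self._next_leaf - 1


def _gate(
    leaf: TrackHypothesis,
    det: Detection,
    predicted: KinematicState,
    scoring: ScoringConfig,
) -> tuple[bool, float | None, float, float]:
    """Score-test gate for a (leaf, detection) pair that already passed the
    Euclidean pre-gate.

    Returns (passed, md, s_st, th_n).  Young hypotheses (fewer than two real
    detections, hence no defined velocity) pass on the distance gate alone;
    mature ones additionally face the velocity score test.
    """
    if leaf.n_real < 2 or leaf.last_real_position is None:
        return True, None, 0.0, 0.0
    v_cand = candidate_velocity(
        det, leaf.last_real_position, det.frame_index - leaf.last_real_frame
    )
    md = velocity_mahalanobis(v_cand, predicted)
    passed, s_st, th_n = score_test(
        md, leaf.motion, scoring.alpha, scoring.beta, scoring.gamma, scoring.delta
    )
    return passed, md, s_st, th_n


def _make_child(
    forest: Forest,
    leaf: TrackHypothesis,
    det: Detection,
    md: float | None,
    s_st: float,
    th_n: float,
    predicted: KinematicState,
) -> TrackHypothesis:
    sc = forest.scoring
    kin = predicted if det.is_dummy else kf_update(predicted, det, sc)
    m = leaf.motion
    motion = MotionScoreState(m.s_aa, m.nc, m.ns, m.ic)
    score = HypothesisScore(leaf.score.s_ltm, leaf.score.s_stm)
    motion.ns += 1
    if det.is_dummy:
        score.s_ltm += delta_ltm(True, 1.0, sc)
        dummies = leaf.consecutive_dummies + 1
        last_pos, last_frame = leaf.last_real_position, leaf.last_real_frame
    else:
        score.s_ltm += delta_ltm(False, kin.last_likelihood, sc)
        motion.ic += 1
        if md is not None:
            motion = update_saa(motion, md, sc.tree_depth)
            score.s_stm = update_stm(score.s_stm, s_st, th_n, sc.s_st_floor)
        dummies = 0
        last_pos, last_frame = det.position, det.frame_index
    child = TrackHypothesis(
        detections=leaf.detections + [det],
        birth_frame=leaf.birth_frame,
        kin=kin,
        motion=motion,
        score=score,
        tree_id=leaf.tree_id,
        leaf_id=forest.new_leaf_id(),
        peak_score=max(leaf.peak_score, score.combined(sc.w_ltm, sc.w_stm)),
        consecutive_dummies=dummies,
        traj_id=leaf.traj_id,
        last_real_position=last_pos,
        last_real_frame=last_frame,
    )
    return child


def extend(forest: Forest, detections: list) -> Forest:
    """Grow every live leaf by one frame: one child per gated detection plus
    a dummy child; then bound tree depth with the N-scan commit."""
    frame = forest.frame_index + 1
    if any(d.frame_index != frame for d in detections):
        raise ValueError("detections must belong to the next frame")
    claimed = set()
    positions = (
        np.array([d.position for d in detections]) if detections else np.empty((0, 2))
    )
    radius = forest.tracker.gate_radius
    for tid in sorted(forest.trees):
        new_leaves = []
        for leaf in forest.trees[tid]:
            predicted = kf_predict(leaf.kin, forest.scoring)
            if len(detections):
                delta = positions - predicted.predicted_pos
                near = np.nonzero(delta[:, 0] ** 2 + delta[:, 1] ** 2 <= radius ** 2)[0]
            else:
                near = ()
            for di in near:
                det = detections[di]
                ok, md, s_st, th_n = _gate(leaf, det, predicted, forest.scoring)
                if ok:
                    claimed.add(det.detection_id)
                    new_leaves.append(
                        _make_child(forest, leaf, det, md, s_st, th_n, predicted)
                    )
            new_leaves.append(
                _make_child(forest, leaf, Detection.dummy(frame), None, 0.0, 0.0, predicted)
            )
        forest.trees[tid] = new_leaves
        _nscan_commit(forest, tid)
    forest.frame_index = frame
    forest._claimed = claimed
    return forest


def _nscan_commit(forest: Forest, tree_id: int) -> None:
    """Resolve branching older than ``depth`` frames in favour of the
    best-scoring leaf's ancestry."""
    leaves = forest.trees[tree_id]
    if not leaves:
        return
    depth = forest.tracker.depth
    sc = forest.scoring
    start = forest._nscan_frame.setdefault(tree_id, leaves[0].birth_frame)
    while leaves and leaves[0].last_frame - start + 1 > depth:
        best = max(leaves, key=lambda h: (h.combined(sc), -h.leaf_id))
        keep_det = best.detection_at(start)
        keep_id = None if keep_det is None else keep_det.detection_id
        leaves = [
            h
            for h in leaves
            if (h.detection_at(start).detection_id if h.detection_at(start) else None)
            == keep_id
        ]
        start += 1
    forest._nscan_frame[tree_id] = start
    forest.trees[tree_id] = leaves


def spawn(forest: Forest, detections: list) -> Forest:
    """Start a new single-hypothesis tree from every detection that no live
    hypothesis claimed during this frame's extension."""
    claimed = getattr(forest, "_claimed", set())
    sc = forest.scoring
    for det in detections:
        if det.is_dummy or det.detection_id in claimed:
            continue
        tid = forest._next_tree
        forest._next_tree += 1
        leaf = TrackHypothesis(
            detections=[det],
            birth_frame=det.frame_index,
            kin=kf_init(det, sc),
            motion=MotionScoreState(ic=1),
            score=HypothesisScore(s_ltm=sc.initial_score, s_stm=0.0),
            tree_id=tid,
            leaf_id=forest.new_leaf_id(),
            last_real_position=det.position,
            last_real_frame=det.frame_index,
        )
        leaf.peak_score = leaf.combined(sc)
        forest.trees[tid] = [leaf]
        forest._nscan_frame[tid] = det.frame_index
    return forest


def terminate(forest: Forest) -> Forest:
    """Retire leaves whose combined score dropped more than ``delta_term``
    below their peak, or that ran more than ``max_dummies`` consecutive
    missed frames (both strict); empty trees are removed."""
    tr, sc = forest.tracker, forest.scoring
    for tid in sorted(forest.trees):
        kept = []
        for leaf in forest.trees[tid]:
            drop = leaf.peak_score - leaf.combined(sc)
            if leaf.consecutive_dummies > tr.max_dummies or drop > tr.delta_term:
                leaf.alive = False
                forest.terminated.append(leaf)
            else:
                kept.append(leaf)
        if kept:
            forest.trees[tid] = kept
        else:
            del forest.trees[tid]
            forest._nscan_frame.pop(tid, None)
    return forest


def retain_top(
    terminated: list, scoring: ScoringConfig, fraction: float = 0.2
) -> list:
    """Keep the top ``ceil(fraction * n)`` terminated hypotheses by combined
    score; hypotheses tied with the boundary score are all kept."""
    if not terminated:
        return []
    ranked = sorted(
        terminated, key=lambda h: (-h.combined(scoring), h.leaf_id)
    )
    n_keep = math.ceil(fraction * len(ranked))
    cut = ranked[n_keep - 1].combined(scoring)
    return [h for h in ranked if h.combined(scoring) >= cut]
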