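"""End-to-end batch tracking pipeline.

Frames (or precomputed detections) are processed sequentially: MALC
detection, gated hypothesis-tree extension, birth of new trees from
unclaimed detections, termination, and the two pruning stages.  Every
``batch - overlap`` frames the 0-1 selection program is solved over the
trailing ``batch``-frame window and the selected hypotheses' detections in
the front (oldest) part of the window are committed to output trajectories;
committed points are final and are never revised by later batches.  Track
identity across batches follows hypothesis ancestry: a selected hypothesis
that extends a previously committed one inherits its track id.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .config import PipelineConfig
from .hypotheses import Forest, extend, retain_top, spawn, terminate
from .io import Trajectory
from .malc import Detection, GrayFrame, detect_frame
from .pruning import prune_loops, prune_strong
from .selection import build_problem, solve, solve_one_to_one

logger = logging.getLogger(__name__)

__all__ = ["PipelineResult", "run", "run_forest"]


@dataclass
class PipelineResult:
    trajectories: list
    detections_per_frame: list
    leaves_per_frame: list = field(default_factory=list)


def _as_detections(frame_input, frame_index: int, config: PipelineConfig):
    """Accept a GrayFrame / raw 2-D array (detect) or a detection list."""
    if isinstance(frame_input, GrayFrame):
        return detect_frame(frame_input, config.detection)
    if isinstance(frame_input, np.ndarray):
        return detect_frame(GrayFrame(frame_input, frame_index), config.detection)
    return list(frame_input)


def _commit(
    forest: Forest,
    config: PipelineConfig,
    trajectories: dict,
    committed_until: int,
    commit_to: int,
    next_track_id: list,
) -> None:
    """Solve selection over the current window and commit frames
    [committed_until, commit_to) of the selected hypotheses."""
    sc = forest.scoring
    candidates = forest.live_leaves() + retain_top(
        forest.terminated, sc, forest.tracker.retain_fraction
    )
    forest.terminated = []
    if not candidates:
        return
    scores = [h.combined(sc) for h in candidates]
    problem = build_problem(candidates, scores, config.selection)
    if config.selection.association == "one-to-one":
        result = solve_one_to_one(problem)
    else:
        result = solve(problem)
    used_ids: set[int] = set()
    for idx in result.selected:
        hyp = candidates[idx]
        if hyp.traj_id is None or hyp.traj_id in used_ids:
            hyp.traj_id = next_track_id[0]
            next_track_id[0] += 1
        used_ids.add(hyp.traj_id)
        traj = trajectories.setdefault(hyp.traj_id, Trajectory(hyp.traj_id))
        last = traj.points[-1][0] if traj.points else -1
        for det in hyp.detections:
            if det.is_dummy:
                continue
            if committed_until <= det.frame_index < commit_to and det.frame_index > last:
                traj.add(det.frame_index, det.position[0], det.position[1])


def run_forest(frames_or_detections, config: PipelineConfig | None = None) -> PipelineResult:
    """Run the tracker and also report per-frame live-leaf counts (used for
    the pruning ablation)."""
    cfg = config or PipelineConfig()
    forest = Forest(scoring=cfg.scoring, tracker=cfg.tracker)
    trajectories: dict[int, Trajectory] = {}
    next_track_id = [1]
    committed_until = 0
    batch_start = 0
    stride = cfg.pipeline.batch - cfg.pipeline.overlap
    if stride <= 0:
        raise ValueError("batch length must exceed overlap")
    detections_per_frame = []
    leaves_per_frame = []
    n_frames = 0
    for t, frame_input in enumerate(frames_or_detections):
        n_frames = t + 1
        try:
            dets = _as_detections(frame_input, t, cfg)
            dets = [
                d if d.frame_index == t else Detection(t, d.centroid, d.pixel_set, d.detection_id)
                for d in dets
            ]
        except Exception as exc:  # unreadable frame: skip with a dummy step
            logger.warning("frame %d unreadable (%s); treated as empty", t, exc)
            dets = []
        detections_per_frame.append(dets)
        extend(forest, dets)
        spawn(forest, dets)
        terminate(forest)
        if cfg.pruning.stage1:
            prune_strong(forest, cfg.pruning)
        if cfg.pruning.stage2:
            prune_loops(forest, cfg.pruning)
        leaves_per_frame.append(len(forest.live_leaves()))
        if t + 1 - batch_start == cfg.pipeline.batch:
            commit_to = batch_start + stride
            _commit(forest, cfg, trajectories, committed_until, commit_to, next_track_id)
            committed_until = commit_to
            batch_start += stride
        logger.debug("frame %d: %d detections, %d live leaves", t, len(dets), leaves_per_frame[-1])
    if n_frames > committed_until:
        _commit(forest, cfg, trajectories, committed_until, n_frames, next_track_id)
    trajs = [trajectories[tid] for tid in sorted(trajectories) if trajectories[tid].points]
    return PipelineResult(
        trajectories=trajs,
        detections_per_frame=detections_per_frame,
        leaves_per_frame=leaves_per_frame,
    )


def hypothesis_counts(detections_per_frame, config: PipelineConfig | None = None) -> list:
    """Per-frame live-hypothesis counts under the configured pruning
    profile, without running batch selection (which does not affect the
    forest).  Used for pruning-impact ablations."""
    cfg = config or PipelineConfig()
    forest = Forest(scoring=cfg.scoring, tracker=cfg.tracker)
    counts = []
    for dets in detections_per_frame:
        extend(forest, dets)
        spawn(forest, dets)
        terminate(forest)
        if cfg.pruning.stage1:
            prune_strong(forest, cfg.pruning)
        if cfg.pruning.stage2:
            prune_loops(forest, cfg.pruning)
        counts.append(len(forest.live_leaves()))
    return counts


def run(frames_or_detections, config: PipelineConfig | None = None) -> list:
    """Track a sequence of frames (or per-frame detection lists); returns
    the committed trajectories."""
    return run_forest(frames_or_detections, config).trajectories
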