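"""Two-stage hypothesis pruning.

Stage 1 (inter-tree, "strong hypotheses"): when the best-scored and the
most-supported hypotheses through a detection are different hypotheses yet
share more recent detections than the tree depth, one of them is redundant
and the lower-scored one is removed (on a score tie the best-scored one
goes, keeping the better-supported track).

Stage 2 (intra-tree, "loop paths"): two leaves of one tree ending in the
same current-frame detection are two routes between the same endpoints; only
one is kept.  Three keep rules are available.  ``as_printed`` keeps the
*larger* S_AA and ``keep_lower_saa`` the smaller; both are noise-fragile,
because the S_AA gap between the true path and its one-dummy rival is itself
noise-scale, the rival regenerates every frame from the dummy branch, and a
single lost comparison punches a permanent hole in the track.  The default
``best_score`` resolves the loop by the combined hypothesis score, whose
margin per extra real detection (one likelihood-ratio increment minus one
missed-detection penalty) dominates measurement noise, so the
fully-supported path survives deterministically.
"""

from __future__ import annotations

from dataclasses import dataclass

from .hypotheses import Forest, TrackHypothesis

__all__ = ["PruningConfig", "prune_strong", "prune_loops", "shared_detections"]


@dataclass
class PruningConfig:
    """Stage toggles, the loop-pruning keep rule, and the recent window (in
    frames) over which stage 1 counts shared detections.  The window must
    exceed the tree depth for the stage-1 trigger ("shared count exceeds
    depth") to ever fire; default is twice the depth."""

    stage1: bool = True
    stage2: bool = True
    loop_keep: str = "best_score"   # or "as_printed" / "keep_lower_saa"
    strong_window: int = 12


def shared_detections(
    h_i: TrackHypothesis, h_j: TrackHypothesis, first_frame: int, last_frame: int
) -> int:
    """Number of frames in [first_frame, last_frame] where both hypotheses
    hold the same non-dummy detection."""
    count = 0
    for f in range(first_frame, last_frame + 1):
        a, b = h_i.detection_at(f), h_j.detection_at(f)
        if a is not None and b is not None and not a.is_dummy and not b.is_dummy:
            if a.detection_id == b.detection_id:
                count += 1
    return count


def prune_strong(forest: Forest, config: PruningConfig | None = None) -> Forest:
    """Inter-tree stage: for each current-frame detection, compare the
    max-score and max-support hypotheses through it and drop the weaker when
    they share more recent detections than the tree depth."""
    cfg = config or PruningConfig()
    sc = forest.scoring
    depth = forest.tracker.depth
    frame = forest.frame_index
    window_start = frame - cfg.strong_window + 1

    groups: dict[int, list[TrackHypothesis]] = {}
    for leaf in forest.live_leaves():
        det = leaf.detections[-1]
        if not det.is_dummy:
            groups.setdefault(det.detection_id, []).append(leaf)

    removed: set[int] = set()
    for det_id in sorted(groups):
        group = [h for h in groups[det_id] if h.leaf_id not in removed]
        while len(group) >= 2:
            t_ms = max(group, key=lambda h: (h.combined(sc), -h.leaf_id))
            # the max-IC argmax is rarely unique; prefer a representative
            # from another tree so the inter-tree comparison is meaningful.
            # If the unique best-supported hypothesis is the best-scored one
            # there is nothing to arbitrate.
            max_ic = max(h.motion.ic for h in group)
            rivals = [
                h
                for h in group
                if h.motion.ic == max_ic and h.tree_id != t_ms.tree_id
            ]
            if not rivals:
                break
            # run the comparison for every hypothesis through this
            # detection: sweep all cross-tree members that overlap the
            # best-scored one too heavily
            losers = []
            for t_i in sorted(group, key=lambda h: h.leaf_id):
                if t_i is t_ms or t_i.tree_id == t_ms.tree_id:
                    continue
                if shared_detections(t_ms, t_i, window_start, frame) > depth:
                    losers.append(t_ms if t_i.combined(sc) >= t_ms.combined(sc) else t_i)
                    if losers[-1] is t_ms:
                        break
            if not losers:
                break
            for loser in losers:
                removed.add(loser.leaf_id)
            group = [h for h in group if h.leaf_id not in removed]

    if removed:
        for tid in sorted(forest.trees):
            forest.trees[tid] = [
                h for h in forest.trees[tid] if h.leaf_id not in removed
            ]
            if not forest.trees[tid]:
                del forest.trees[tid]
                forest._nscan_frame.pop(tid, None)
    return forest


def prune_loops(forest: Forest, config: PruningConfig | None = None) -> Forest:
    """Intra-tree stage: among same-tree leaves ending in the same
    current-frame detection, keep exactly one, chosen by the configured
    rule (combined score by default, S_AA variants available)."""
    cfg = config or PruningConfig()
    rule = cfg.loop_keep
    if rule not in ("best_score", "as_printed", "keep_lower_saa"):
        raise ValueError(f"unknown loop_keep rule {rule!r}")
    sc = forest.scoring
    for tid in sorted(forest.trees):
        groups: dict[int, list[TrackHypothesis]] = {}
        kept: list[TrackHypothesis] = []
        for leaf in forest.trees[tid]:
            det = leaf.detections[-1]
            if det.is_dummy:
                kept.append(leaf)
            else:
                groups.setdefault(det.detection_id, []).append(leaf)
        for det_id in sorted(groups):
            group = sorted(groups[det_id], key=lambda h: h.leaf_id)
            winner = group[0]
            for challenger in group[1:]:
                if rule == "as_printed":
                    # S_AA(T_i) >= S_AA(T_j) removes T_j
                    if not (winner.motion.s_aa >= challenger.motion.s_aa):
                        winner = challenger
                elif rule == "keep_lower_saa":
                    if challenger.motion.s_aa < winner.motion.s_aa:
                        winner = challenger
                else:  # best_score
                    if challenger.combined(sc) > winner.combined(sc):
                        winner = challenger
            kept.append(winner)
        forest.trees[tid] = sorted(kept, key=lambda h: h.leaf_id)
    return forest
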