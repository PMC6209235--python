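"""Tracking and detection evaluation metrics.

CLEAR-MOT accounting with a distance (not IoU) match rule: a prediction
matches a ground-truth point when their Euclidean distance is at most the
match radius (15 px by default, the same radius used for the output boxes).
Matches persist frame to frame while still within radius; new matches are
made with the Hungarian algorithm on the remaining pairs.  Reported:

* MOTA = 1 - (FN + FP + IDSW) / (number of ground-truth points);
* MOTP = 1 - (mean matched distance) / radius (higher is better);
* IDSW, FN, FP, recall, precision, F-score;
* DR / DR-STD — mean and spread over frames of the per-frame detected
  fraction of ground-truth objects;
* OSPA-T — per-frame optimal sub-pattern assignment distance (order p = 1,
  cutoff c = radius) with a fixed label-error penalty for matched pairs
  whose track identity disagrees with the globally dominant correspondence,
  averaged over frames.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.optimize import linear_sum_assignment

from .io import Trajectory

__all__ = ["EvalReport", "evaluate", "ospa_t"]


@dataclass
class EvalReport:
    dr: float
    dr_std: float
    f_score: float
    mota: float
    motp: float
    idsw: int
    fn: int
    fp: int
    recall: float
    precision: float
    ospa_t: float
    n_truth: int = 0
    n_pred: int = 0


def _points_by_frame(trajs: list) -> dict:
    frames: dict[int, list] = {}
    for traj in trajs:
        for f, x, y in traj.points:
            frames.setdefault(f, []).append((traj.track_id, x, y))
    return frames


def _label_correspondence(truth_frames: dict, pred_frames: dict, radius: float) -> dict:
    """Dominant one-to-one truth-id -> pred-id map by matched-frame counts."""
    votes: dict[tuple, int] = {}
    for f, gts in truth_frames.items():
        preds = pred_frames.get(f, [])
        if not preds:
            continue
        d = np.array(
            [[math.hypot(gx - px, gy - py) for _, px, py in preds] for _, gx, gy in gts]
        )
        d_cost = np.where(d <= radius, d, 1e9)
        ri, ci = linear_sum_assignment(d_cost)
        for i, j in zip(ri, ci):
            if d[i, j] <= radius:
                votes[(gts[i][0], preds[j][0])] = votes.get((gts[i][0], preds[j][0]), 0) + 1
    mapping: dict = {}
    used_pred: set = set()
    for (gid, pid), _cnt in sorted(votes.items(), key=lambda kv: (-kv[1], kv[0])):
        if gid not in mapping and pid not in used_pred:
            mapping[gid] = pid
            used_pred.add(pid)
    return mapping


def ospa_t(
    truth: list,
    pred: list,
    cutoff: float = 15.0,
    order: float = 1.0,
    label_penalty: float | None = None,
) -> float:
    """Mean per-frame OSPA distance with a labelling component.

    The base distance between a truth and a prediction point is capped at
    the cutoff; matched pairs whose prediction id differs from the dominant
    global correspondence of that truth id incur an additional label
    penalty (cutoff/2 by default) inside the cap.  Cardinality mismatches
    cost the full cutoff per unpaired point.
    """
    c = float(cutoff)
    p = float(order)
    alpha = c / 2 if label_penalty is None else float(label_penalty)
    truth_frames = _points_by_frame(truth)
    pred_frames = _points_by_frame(pred)
    mapping = _label_correspondence(truth_frames, pred_frames, c)
    all_frames = sorted(set(truth_frames) | set(pred_frames))
    if not all_frames:
        return 0.0
    per_frame = []
    for f in all_frames:
        gts = truth_frames.get(f, [])
        preds = pred_frames.get(f, [])
        m, n = len(gts), len(preds)
        if m == 0 and n == 0:
            per_frame.append(0.0)
            continue
        if m == 0 or n == 0:
            per_frame.append(c)
            continue
        base = np.array(
            [[math.hypot(gx - px, gy - py) for _, px, py in preds] for _, gx, gy in gts]
        )
        lab = np.array(
            [[0.0 if mapping.get(g[0]) == q[0] else alpha for q in preds] for g in gts]
        )
        d = np.minimum((base ** p + lab ** p) ** (1 / p), c)
        ri, ci = linear_sum_assignment(d ** p)
        cost = float((d[ri, ci] ** p).sum()) + (c ** p) * (max(m, n) - min(m, n))
        per_frame.append((cost / max(m, n)) ** (1 / p))
    return float(np.mean(per_frame))


def evaluate(pred: list, truth: list, radius: float = 15.0) -> EvalReport:
    """CLEAR-MOT evaluation of predicted against ground-truth trajectories."""
    truth_frames = _points_by_frame(truth)
    pred_frames = _points_by_frame(pred)
    all_frames = sorted(set(truth_frames) | set(pred_frames))

    fn = fp = idsw = 0
    n_truth = sum(len(v) for v in truth_frames.values())
    n_pred = sum(len(v) for v in pred_frames.values())
    matched_dist: list[float] = []
    per_frame_dr: list[float] = []
    last_match: dict = {}      # truth id -> pred id
    for f in all_frames:
        gts = truth_frames.get(f, [])
        preds = pred_frames.get(f, [])
        gt_ids = [g[0] for g in gts]
        pr_ids = [q[0] for q in preds]
        pairs: dict[int, int] = {}
        if gts and preds:
            d = np.array(
                [[math.hypot(gx - px, gy - py) for _, px, py in preds] for _, gx, gy in gts]
            )
            # keep persisting matches first (CLEAR-MOT continuity)
            used_g, used_p = set(), set()
            for gi, gid in enumerate(gt_ids):
                pid = last_match.get(gid)
                if pid is not None and pid in pr_ids:
                    pj = pr_ids.index(pid)
                    if d[gi, pj] <= radius and pj not in used_p:
                        pairs[gi] = pj
                        used_g.add(gi)
                        used_p.add(pj)
            free_g = [i for i in range(len(gts)) if i not in used_g]
            free_p = [j for j in range(len(preds)) if j not in used_p]
            if free_g and free_p:
                sub = d[np.ix_(free_g, free_p)]
                cost = np.where(sub <= radius, sub, 1e9)
                ri, ci = linear_sum_assignment(cost)
                for i, j in zip(ri, ci):
                    if sub[i, j] <= radius:
                        pairs[free_g[i]] = free_p[j]
            for gi, pj in pairs.items():
                matched_dist.append(d[gi, pj])
                gid, pid = gt_ids[gi], pr_ids[pj]
                if gid in last_match and last_match[gid] != pid:
                    idsw += 1
                last_match[gid] = pid
        fn += len(gts) - len(pairs)
        fp += len(preds) - len(pairs)
        if gts:
            per_frame_dr.append(len(pairs) / len(gts))

    matched = len(matched_dist)
    recall = matched / n_truth if n_truth else 0.0
    precision = matched / n_pred if n_pred else 0.0
    f_score = (
        2 * recall * precision / (recall + precision) if recall + precision else 0.0
    )
    mota = 1.0 - (fn + fp + idsw) / n_truth if n_truth else math.nan
    motp = 1.0 - float(np.mean(matched_dist)) / radius if matched_dist else 0.0
    return EvalReport(
        dr=float(np.mean(per_frame_dr)) if per_frame_dr else 0.0,
        dr_std=float(np.std(per_frame_dr)) if per_frame_dr else 0.0,
        f_score=f_score,
        mota=mota,
        motp=motp,
        idsw=idsw,
        fn=fn,
        fp=fp,
        recall=recall,
        precision=precision,
        ospa_t=ospa_t(truth, pred, cutoff=radius),
        n_truth=n_truth,
        n_pred=n_pred,
    )
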