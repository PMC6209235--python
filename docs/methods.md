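# Methods

This note documents the models, the numerical choices, and what the
synthetic benchmarks do and do not demonstrate.

## Detection: multi-appearance local contrast (MALC)

**Model.** Small bright objects respond strongly to the square-ring local
contrast `C = I²/MI`, where `MI` averages intensity over the ring between a
centred outer (9 px) and inner (3 px) window. There is deliberately no
minimum-search/max-pool step: pooling dilates objects and manufactures
merged detections, which is precisely the failure mode this detector
targets. Border pixels use the in-image part of the ring; pixels with
`MI = 0` get `C = 0` (they cannot pass a positive threshold, and this avoids
a division by zero on dark backgrounds).

**Multi-threshold trees.** The map is binarised at `n_layers` thresholds
(default 5, odd so the global threshold `mean + K·std` is the middle rung;
spacing defaults to `0.5·std(C)`; non-positive rungs are clamped to 1e−6).
Components are 8-connected; because thresholds ascend on one map, each
layer-(k+1) component nests inside exactly one layer-k component, giving one
tree per lowest-threshold blob.

**Appearance score.** Each node (one object slice at one threshold) is
scored `S = (S_intensity + ε)(S_shape + ε)(N_bubble + 1)` with ε = 1e−6:

* `S_intensity` — population variance of gray levels over the object; a
  correctly isolated object is more homogeneous than a blob-plus-clutter.
* `S_shape` — variance of the distances from edge pixels (object pixels
  with a 4-neighbour outside) to the pixel-coordinate centroid; a clean
  segmentation has a smooth, roundish contour.
* `N_bubble` — holes found by flood-filling the component (4-connected
  background from the bounding-box border); undetected interior pixels
  indicate an over-tight threshold.

The ε floor matters: both variance terms are exactly zero for tiny uniform
or symmetric objects, and without the floor the product degenerates and ties
become ubiquitous. Lower scores are better.

**Per-object threshold selection.** The depth-first pass computes
`S_node = min(S_appearance, Σ S_children)` and marks a node when keeping it
is at least as good as descending (ties keep the parent — the shallower,
fewer-object segmentation). A breadth-first sweep then returns the top-most
marked nodes. The result is the antichain of nodes minimising the summed
score over each tree, verified against exhaustive antichain enumeration on
random trees. Selected components below `min_area` (default 1 px) are
dropped; centroids are arithmetic means of 0-based (row, col) pixel
coordinates.

## Tracking: TOMHT with one-to-many selection

**Kinematics.** Each hypothesis carries a constant-velocity Kalman filter,
state `[x, y, vx, vy]`, dt = 1 frame, measurement noise σ = 1 px, discrete
white-noise acceleration σ = 0.5 px/frame² (all configurable). New
hypotheses start at the detection with zero velocity and velocity variance
100 so the first updates are dominated by data.

**Gating.** A Euclidean pre-gate (radius 15 px, the same radius as the
evaluation match rule) bounds candidate sets; hypotheses with fewer than two
real detections are gated by distance alone since they have no defined
velocity. Mature pairs face the score test: the candidate-implied velocity
`(z − last real position)/Δt` is compared with the filter's predicted
velocity under the velocity-block covariance, giving a Mahalanobis
discrepancy MD; `S_ST = |MD − S_AA|` must stay strictly below the two-stage
threshold `th = (α − Ns)·β` while `α − Ns > γ`, else `δ` (defaults α = 20,
β = 0.8, γ = 10, δ = 6; `Ns` counts frames since birth). The threshold is
loose for young tracks, whose velocity estimates are unstable, and drops to
the tight constant at `Ns = 10`.

**Scores.** `S_AA ← (S_AA·(NC−1) + MD)/(NC+1)` with the update count NC
capped at the tree depth; unrolled this is a geometric average weighting
recent discrepancies most. The long-term score accumulates
`log(p·P_D/(λ_fa+λ_nt))` per association (Gaussian innovation density `p`
floored at 1e−12), `log(1−P_D)` per missed frame, starting from
`log(λ_nt/λ_fa)`; defaults `P_D = 0.9`, `λ_fa = 1e−6`, `λ_nt = 1e−8` per
px² per frame. The short-term score accumulates `log((th − S_ST)/S_ST)`
(`S_ST` floored at 1e−3) on effective associations. The combined score is
the unit-weighted sum of both.

**Forest management.** Every leaf spawns one child per gated detection plus
a dummy child; unclaimed detections seed new trees. Depth is bounded at 6 by
an N-scan commit that resolves the oldest frame in favour of the
best-scoring leaf's ancestry. Leaves terminate when their combined score
falls more than 9 below its running peak, or after more than 4 consecutive
dummies (both strict; the drop threshold fires first under the default score
increments). At each batch boundary the terminated pool is ranked and the
top 20 % (ceiling, boundary ties kept) re-enters selection.

**Pruning.** Stage 1 (inter-tree): for each current-frame detection, if the
best-scored and best-supported (max-IC) hypotheses through it belong to
different trees and overlap in more shared detections than the tree depth
within a recent window (default 12 frames — the window must exceed the
depth or the trigger can never fire), the comparison removes the
lower-scored of each such cross-tree pair. Because IC ties are pervasive,
the best-supported representative is taken from a different tree than the
best-scored one whenever possible; if the unique max-IC hypothesis *is* the
best-scored one, nothing is arbitrated. Stage 2 (intra-tree): two leaves of
one tree ending in the same current-frame detection are redundant routes
between the same endpoints; exactly one is kept. Three keep rules ship:
`as_printed` (larger S_AA wins), `keep_lower_saa`, and the default
`best_score`. The S_AA rules are noise-fragile — the one-dummy rival path
regenerates from the dummy branch every frame, its S_AA differs from the
true path's only at noise scale, and a single lost comparison punches a
permanent hole in the track. The combined score separates the two paths by
one likelihood-ratio increment minus one miss penalty (≈ 13 log-units per
shared-history detection), which measurement noise cannot overturn, so
`best_score` is the default.

**Selection.** Per 40-frame window (stride 20), live leaves plus retained
terminated hypotheses enter the extended 0-1 program: hypothesis costs
`−K·S` (K = 5), pair costs `N_ij·C_IN` (C_IN = 1) for pairs sharing
`0 < N_ij < N_T = 5` detections, and a hard exclusion `ξ_i + ξ_j ≤ 1` at
`N_ij ≥ N_T` — the "infinite cost" branch realised as a constraint for
numerical safety. The linking constraints force each pair variable to be 1
exactly when both members are selected, so sharing is priced linearly, not
forbidden. Solved exactly with HiGHS (`scipy.optimize.milp`); a brute-force
enumerator covers instances up to 20 hypotheses if the solver fails. The
one-to-one variant (every sharing pair hard-excluded) ships for ablations
and coincides with the extended program when `N_T = 1`.

**Commit semantics.** At each boundary the selected hypotheses' detections
in the front half of the window are appended to output trajectories and
frozen; later batches never revise them. Identity is carried by hypothesis
ancestry (children inherit the trajectory id; if two selected branches claim
the same ancestor, the later one gets a fresh id). The final partial batch
commits in full. Output CSVs are MOTChallenge-style with 1-based frames and
radius-15 boxes.

## Synthetic scenes

The generator emulates dense micro-animal footage: Gaussian blobs
(σ = 1.5 px, amplitude 150 on a background of 20 with smoothed clutter and
white noise) moving at 1–3 px/frame with reflective borders, occasional
speed changes (p = 0.05/frame), 2 % missed detections, and scheduled
crossing events in which one object of a pair shadows the other at a
smoothly shrinking offset (closing ~1.5 px/frame, riding at one blob σ for
the merge window). During a merge window the detection stream emits a single
midpoint detection for the pair — the exact merged-detection regime the
one-to-many program addresses. Presets: `larva1` (25 objects, 3 crossings),
`dense` (50 objects, 12 crossings), `blur` (15 % miss rate), `merge-demo`
(10 objects, 5 simultaneous-ish crossings, no misses).
`generate_separated_scene` builds well-separated scenes by construction:
object paths are independent, so a 12× surplus of candidate trajectories is
simulated and a greedy subset with pairwise gaps ≥ 20 px (above the 15 px
gate) is selected deterministically.

What the synthetic benchmarks do **not** show: real larva imagery has
non-Gaussian, elongated, wriggling shapes, correlated background drift,
focus changes, and contact interactions; merged blobs are not exact
midpoints. Passing here demonstrates the algorithmic properties
(threshold-tree resolution of merges, gating, pruning orderings, the value
of one-to-many selection), not field-ready accuracy on any particular
dataset.

## Evaluation

CLEAR-MOT accounting with a 15 px distance match: matches persist while
within radius, remaining pairs match by Hungarian assignment;
`MOTA = 1 − (FN+FP+IDSW)/GT`. MOTP is reported accuracy-style as
`1 − mean matched distance / radius` (higher is better); the complementary
normalised-distance convention is this value subtracted from 1. DR/DR-STD
are the mean and spread over frames of the per-frame detected fraction.
OSPA-T uses order p = 1, cutoff c = 15, and a label penalty of c/2 inside
the cutoff for matched pairs whose predicted identity disagrees with the
dominant global truth↔prediction correspondence; cardinality errors cost the
full cutoff. TF/TCF are not implemented. All parameters are exposed so the
absolute numbers are reproducible.

## Problem sizes and determinism

The shipped checks use: 200 random trees for the segmentation oracle, 300
random programs (≤ 12 hypotheses) against 2ⁿ enumeration, 1000 sequences
for the S_AA identity, a 10-object/60-frame rendered easy scenario, the
merge-demo preset for the association ablation, and the first 30 frames of
the dense preset (two replicate scenes in the acceptance script) for the
pruning ablation — sizes at which every stage, including the intentionally
unpruned forest (~10⁴ leaves), runs comfortably on one core. All randomness
flows from explicit integer seeds; reruns with the same configuration and
seed write byte-identical CSVs.

## Known limitations

* The score test needs two real detections before it constrains anything;
  a clutter detection adjacent to a birth can found a plausible track for a
  few frames until termination catches it.
* Stage-1 pruning depends on crossings to engage; in sparse scenes it is a
  near no-op (by design — there is nothing inter-tree to arbitrate).
* One-to-many selection can keep both members of a pair on one detection
  through long merges; their committed points coincide there, which costs
  MOTP slightly even when identities survive.
* Batch commitment adds a latency of up to one batch; this is inherent to
  selecting over a 40-frame window.
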