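"""Multi-appearance local-contrast (MALC) detection.

Small bright objects on cluttered background are segmented in three stages:

1. A square-ring local-contrast transform turns each grayscale frame into a
   contrast map ``C = I^2 / MI``, where ``MI`` is the mean intensity over the
   ring between an outer and an inner window centred on the pixel.  Unlike the
   classic local-contrast method there is no minimum search / max-pooling
   step, so object edges stay sharp and touching objects are not dilated into
   one another.
2. The map is binarised at several equally spaced thresholds centred on a
   global threshold (mean + K*std of the map).  Connected components of
   adjacent layers nest, which yields one *multi-appearance tree* per
   low-threshold component: children are the components a blob splits into at
   the next, higher threshold.
3. For each tree, a depth-first pass picks the antichain of nodes (one
   threshold per object) minimising the summed appearance score — the product
   of an intensity-variance term, a contour-regularity term and a hole
   ("bubble") penalty.  Merged blobs are thereby resolved at the threshold
   where they separate, while faint lone blobs keep their low threshold.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage import measure

__all__ = [
    "GrayFrame",
    "AppearanceNode",
    "AppearanceForest",
    "Detection",
    "DetectionConfig",
    "contrast_transform",
    "global_threshold",
    "layer_thresholds",
    "build_appearance_forest",
    "appearance_score",
    "select_segmentation",
    "detect_frame",
]

#: floor added to the intensity and shape terms before the product, so that
#: perfectly uniform / symmetric small objects do not collapse the score to 0
SCORE_EPS = 1e-6

#: floor substituted for non-positive layer thresholds
THRESHOLD_FLOOR = 1e-6


@dataclass
class GrayFrame:
    """A single grayscale frame (non-negative intensities)."""

    pixels: np.ndarray
    frame_index: int = 0

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=float)
        if self.pixels.ndim != 2:
            raise ValueError("frame must be 2-D")
        if np.any(self.pixels < 0):
            raise ValueError("intensities must be non-negative")


@dataclass
class ContrastMap:
    """Per-pixel local-contrast response of one frame."""

    values: np.ndarray


@dataclass
class AppearanceNode:
    """One segmented object slice at one threshold layer of a tree."""

    pixel_set: frozenset
    layer: int
    threshold: float
    s_intensity: float = 0.0
    s_shape: float = 0.0
    s_bubble: float = 1.0
    s_appearance: float = 0.0
    children: list = field(default_factory=list)
    marked: bool = False


@dataclass
class AppearanceForest:
    roots: list
    n_layers: int
    thresholds: list


@dataclass(frozen=True)
class Detection:
    """A segmented object instance at one frame.

    ``detection_id`` 0 is reserved for the dummy (missed) detection; real
    detections are numbered from 1 within a frame.  Coordinates are 0-based
    ``(row, col)``; the centroid is the arithmetic mean of the pixel
    coordinates and may be fractional.
    """

    frame_index: int
    centroid: tuple
    pixel_set: frozenset = frozenset()
    detection_id: int = 1
    is_dummy: bool = False

    @staticmethod
    def dummy(frame_index: int) -> "Detection":
        return Detection(frame_index, (math.nan, math.nan), frozenset(), 0, True)

    @property
    def position(self) -> np.ndarray:
        """Centroid as (x, y) = (col, row)."""
        return np.array([self.centroid[1], self.centroid[0]], dtype=float)


@dataclass
class DetectionConfig:
    """Knobs of the MALC detector.

    ``k`` scales the global threshold (mean + k*std of the contrast map);
    3.5 is the best-F value for this detector.  ``n_layers`` binarisation
    layers are spaced ``interval_sigma * std(C)`` apart, centred on the
    global threshold.  Components below ``min_area`` pixels are discarded.
    """

    outer_width: int = 9
    inner_width: int = 3
    k: float = 3.5
    n_layers: int = 5
    interval_sigma: float = 0.5
    min_area: int = 1


def _window_sums(img: np.ndarray, width: int) -> tuple[np.ndarray, np.ndarray]:
    """Sum and pixel count of the centred width x width window clipped to the
    image, for every pixel, via an integral image."""
    pad = width // 2
    ii = np.zeros((img.shape[0] + 1, img.shape[1] + 1))
    np.cumsum(np.cumsum(img, axis=0), axis=1, out=ii[1:, 1:])
    r = np.arange(img.shape[0])
    c = np.arange(img.shape[1])
    r0 = np.clip(r - pad, 0, img.shape[0])
    r1 = np.clip(r + pad + 1, 0, img.shape[0])
    c0 = np.clip(c - pad, 0, img.shape[1])
    c1 = np.clip(c + pad + 1, 0, img.shape[1])
    sums = (
        ii[np.ix_(r1, c1)] - ii[np.ix_(r0, c1)] - ii[np.ix_(r1, c0)] + ii[np.ix_(r0, c0)]
    )
    counts = np.outer(r1 - r0, c1 - c0)
    return sums, counts


def contrast_transform(
    frame: GrayFrame, outer_width: int = 9, inner_width: int = 3
) -> ContrastMap:
    """Square-ring local-contrast transform ``C = I^2 / MI``.

    ``MI`` is the mean intensity over the ring between the centred outer and
    inner windows.  Near borders the in-image part of the ring is used.
    Pixels whose ring mean is 0 get ``C = 0`` (they can never pass a positive
    threshold anyway).
    """
    if outer_width <= inner_width or outer_width % 2 == 0 or inner_width % 2 == 0:
        raise ValueError("window widths must be odd with outer > inner")
    img = frame.pixels
    if min(img.shape) < outer_width:
        raise ValueError(
            f"frame {img.shape} smaller than outer window width {outer_width}"
        )
    outer_sum, outer_cnt = _window_sums(img, outer_width)
    inner_sum, inner_cnt = _window_sums(img, inner_width)
    ring_sum = outer_sum - inner_sum
    ring_cnt = outer_cnt - inner_cnt
    mi = np.divide(ring_sum, ring_cnt, out=np.zeros_like(ring_sum), where=ring_cnt > 0)
    c = np.divide(img * img, mi, out=np.zeros_like(img), where=mi > 0)
    return ContrastMap(values=c)


def global_threshold(cmap: ContrastMap, k: float) -> float:
    """mean(C) + k * std(C) (population standard deviation)."""
    v = cmap.values
    if v.size == 0:
        raise ValueError("empty contrast map")
    return float(v.mean() + k * v.std())


def layer_thresholds(global_thr: float, n_layers: int, interval: float) -> list:
    """Ascending arithmetic threshold ladder centred on the global threshold.

    ``n_layers`` must be odd so the global threshold is the exact middle
    value.  Non-positive entries are clamped to a small positive floor.
    """
    if n_layers < 1 or n_layers % 2 == 0:
        raise ValueError("n_layers must be a positive odd integer")
    if interval <= 0:
        raise ValueError("interval must be positive")
    half = n_layers // 2
    thrs = [global_thr + (i - half) * interval for i in range(n_layers)]
    return [t if t > 0 else THRESHOLD_FLOOR for t in thrs]


def _edge_mask(mask: np.ndarray) -> np.ndarray:
    """Object pixels with at least one 4-neighbour outside the object."""
    eroded = ndimage.binary_erosion(
        mask, structure=ndimage.generate_binary_structure(2, 1), border_value=0
    )
    return mask & ~eroded


def appearance_score(node: AppearanceNode, frame: GrayFrame) -> float:
    """Score a segmented slice; lower means a more object-like segmentation.

    intensity term: population variance of the gray levels over the object;
    shape term: variance of edge-pixel distances to the object centroid;
    bubble term: (number of hole pixels) + 1.  The product uses an epsilon
    floor on the first two terms since both are exactly 0 for tiny
    uniform/symmetric objects.
    """
    coords = np.array(sorted(node.pixel_set))
    rows, cols = coords[:, 0], coords[:, 1]
    intens = frame.pixels[rows, cols]
    s_int = float(np.var(intens))

    r0, r1 = rows.min(), rows.max()
    c0, c1 = cols.min(), cols.max()
    mask = np.zeros((r1 - r0 + 1, c1 - c0 + 1), dtype=bool)
    mask[rows - r0, cols - c0] = True
    edge = _edge_mask(mask)
    er, ec = np.nonzero(edge)
    centroid = coords.mean(axis=0)
    d = np.hypot(er + r0 - centroid[0], ec + c0 - centroid[1])
    s_shape = float(np.var(d)) if d.size else 0.0

    filled = ndimage.binary_fill_holes(mask)
    n_bubble = int(filled.sum() - mask.sum())
    s_bubble = float(n_bubble + 1)

    node.s_intensity = s_int
    node.s_shape = s_shape
    node.s_bubble = s_bubble
    node.s_appearance = (s_int + SCORE_EPS) * (s_shape + SCORE_EPS) * s_bubble
    return node.s_appearance


def build_appearance_forest(
    cmap: ContrastMap, thresholds: list, frame: GrayFrame | None = None
) -> AppearanceForest:
    """Binarise the map at each threshold and link nested components.

    Layer ``k`` mask is ``C >= thresholds[k]`` with 8-connected labelling;
    because the thresholds ascend, every layer-(k+1) component lies inside
    exactly one layer-k component, which becomes its parent.  Appearance
    scores are computed on construction when ``frame`` is given.
    """
    if any(b <= a for a, b in zip(thresholds, thresholds[1:])):
        raise ValueError("thresholds must be strictly ascending")
    c = cmap.values
    prev_nodes: dict[int, AppearanceNode] = {}
    prev_labels = None
    roots: list[AppearanceNode] = []
    for layer, thr in enumerate(thresholds):
        labels = measure.label(c >= thr, connectivity=2)
        nodes: dict[int, AppearanceNode] = {}
        for lab in range(1, labels.max() + 1):
            rr, cc = np.nonzero(labels == lab)
            node = AppearanceNode(
                pixel_set=frozenset(zip(rr.tolist(), cc.tolist())),
                layer=layer,
                threshold=thr,
            )
            if frame is not None:
                appearance_score(node, frame)
            nodes[lab] = node
            if layer == 0:
                roots.append(node)
            else:
                parent_lab = prev_labels[rr[0], cc[0]]
                prev_nodes[parent_lab].children.append(node)
        prev_nodes, prev_labels = nodes, labels
    return AppearanceForest(roots=roots, n_layers=len(thresholds), thresholds=list(thresholds))


def _select_recursive(node: AppearanceNode) -> float:
    """Depth-first pass: returns min(own score, sum over children) and marks
    the node when keeping it is at least as good as descending (ties keep the
    parent — the shallower, fewer-object segmentation)."""
    if not node.children:
        node.marked = True
        return node.s_appearance
    child_sum = sum(_select_recursive(ch) for ch in node.children)
    if child_sum < node.s_appearance:
        node.marked = False
        return child_sum
    node.marked = True
    return node.s_appearance


def select_segmentation(forest: AppearanceForest) -> list:
    """Pick the minimum-total-score antichain of nodes covering each tree.

    After the depth-first scoring pass, a breadth-first sweep keeps only the
    top-most marked nodes (no other marked node between them and the root).
    """
    selected: list[AppearanceNode] = []
    for root in forest.roots:
        _select_recursive(root)
        queue = [root]
        while queue:
            node = queue.pop(0)
            if node.marked:
                selected.append(node)
            else:
                queue.extend(node.children)
    return selected


def detect_frame(frame: GrayFrame, config: DetectionConfig | None = None) -> list:
    """Full MALC pass on one frame: transform, threshold ladder, forest,
    antichain selection; emits one :class:`Detection` per selected node."""
    cfg = config or DetectionConfig()
    cmap = contrast_transform(frame, cfg.outer_width, cfg.inner_width)
    std = float(cmap.values.std())
    if std == 0:
        return []
    gthr = global_threshold(cmap, cfg.k)
    thrs = layer_thresholds(gthr, cfg.n_layers, cfg.interval_sigma * std)
    # clamping can create duplicate floor entries; keep the ascending unique ladder
    uniq = sorted(set(thrs))
    forest = build_appearance_forest(cmap, uniq, frame)
    detections = []
    det_id = 1
    for node in select_segmentation(forest):
        if len(node.pixel_set) < cfg.min_area:
            continue
        coords = np.array(sorted(node.pixel_set), dtype=float)
        centroid = tuple(coords.mean(axis=0))
        detections.append(
            Detection(
                frame_index=frame.frame_index,
                centroid=centroid,
                pixel_set=node.pixel_set,
                detection_id=det_id,
            )
        )
        det_id += 1
    return detections
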