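"""Local-contrast transform, multi-appearance trees and threshold selection."""

import numpy as np
import pytest

from densetrack.malc import (
    AppearanceForest,
    AppearanceNode,
    ContrastMap,
    DetectionConfig,
    GrayFrame,
    appearance_score,
    build_appearance_forest,
    contrast_transform,
    detect_frame,
    global_threshold,
    layer_thresholds,
    select_segmentation,
)


class TestContrastTransform:
    def test_uniform_image_fixed_point(self):
        c = contrast_transform(GrayFrame(np.full((20, 20), 10.0)))
        assert np.allclose(c.values, 10.0)

    def test_single_hot_pixel(self):
        img = np.ones((21, 21))
        img[10, 10] = 100.0
        c = contrast_transform(GrayFrame(img))
        # ring of 72 background pixels has mean 1, so C = 100^2 / 1
        assert c.values[10, 10] == pytest.approx(10000.0)

    def test_zero_image_zero_map(self):
        c = contrast_transform(GrayFrame(np.zeros((15, 15))))
        assert np.all(c.values == 0.0)

    def test_border_pixels_defined(self):
        img = np.full((12, 12), 5.0)
        c = contrast_transform(GrayFrame(img))
        assert np.all(np.isfinite(c.values))
        assert c.values[0, 0] == pytest.approx(5.0)

    def test_frame_smaller_than_window_errors(self):
        with pytest.raises(ValueError):
            contrast_transform(GrayFrame(np.ones((5, 5))))

    def test_even_window_rejected(self):
        with pytest.raises(ValueError):
            contrast_transform(GrayFrame(np.ones((20, 20))), outer_width=8)


class TestGlobalThreshold:
    def test_constant_map(self):
        assert global_threshold(ContrastMap(np.full((4, 4), 7.0)), 3.0) == 7.0

    def test_two_level_map(self):
        vals = np.array([[0.0, 2.0], [2.0, 0.0]])
        assert global_threshold(ContrastMap(vals), 2.0) == pytest.approx(3.0)

    def test_k_zero_is_mean(self):
        vals = np.arange(9, dtype=float).reshape(3, 3)
        assert global_threshold(ContrastMap(vals), 0.0) == pytest.approx(vals.mean())


class TestLayerThresholds:
    def test_centered_ladder(self):
        assert layer_thresholds(10, 3, 2) == [8, 10, 12]

    def test_single_layer(self):
        assert layer_thresholds(10, 1, 1) == [10]

    def test_clamping_non_positive(self):
        thrs = layer_thresholds(1, 5, 1)
        assert thrs[2:] == [1, 2, 3]
        assert thrs[0] > 0 and thrs[1] > 0

    def test_even_layers_rejected(self):
        with pytest.raises(ValueError):
            layer_thresholds(10, 4, 1)


def _blob_map(centers, sigma, shape=(40, 40), amp=10.0):
    yy, xx = np.mgrid[0 : shape[0], 0 : shape[1]]
    img = np.zeros(shape)
    for (r, c) in centers:
        img += amp * np.exp(-((yy - r) ** 2 + (xx - c) ** 2) / (2 * sigma ** 2))
    return img


class TestAppearanceForest:
    def test_single_blob_chain(self):
        cmap = ContrastMap(_blob_map([(20, 20)], 3.0))
        forest = build_appearance_forest(cmap, [1.0, 3.0, 6.0])
        assert len(forest.roots) == 1
        node = forest.roots[0]
        depth = 1
        while node.children:
            assert len(node.children) == 1
            assert node.children[0].pixel_set <= node.pixel_set
            node = node.children[0]
            depth += 1
        assert depth == 3

    def test_merged_blob_splits_at_higher_threshold(self):
        # two peaks fused at a low threshold, separated at a higher one
        cmap = ContrastMap(_blob_map([(20, 14), (20, 26)], 3.0))
        forest = build_appearance_forest(cmap, [1.0, 7.0])
        assert len(forest.roots) == 1
        assert len(forest.roots[0].children) == 2

    def test_blob_below_top_threshold_terminates_branch(self):
        cmap = ContrastMap(_blob_map([(20, 20)], 3.0, amp=5.0))
        forest = build_appearance_forest(cmap, [1.0, 3.0, 100.0])
        node = forest.roots[0]
        assert node.children and not node.children[0].children

    def test_nesting_on_random_maps(self, rng):
        for _ in range(20):
            vals = rng.random((25, 25)) * 10
            thrs = sorted(rng.uniform(1, 9, size=3))
            if len(set(thrs)) < 3:
                continue
            forest = build_appearance_forest(ContrastMap(vals), list(thrs))
            stack = list(forest.roots)
            while stack:
                n = stack.pop()
                for ch in n.children:
                    assert ch.pixel_set <= n.pixel_set
                    assert ch.layer == n.layer + 1
                    stack.append(ch)


class TestAppearanceScore:
    def test_uniform_intensity_object(self):
        img = np.zeros((10, 10))
        pix = {(4, 4), (4, 5), (5, 4), (5, 5)}
        for r, c in pix:
            img[r, c] = 7.0
        node = AppearanceNode(pixel_set=frozenset(pix), layer=0, threshold=1.0)
        appearance_score(node, GrayFrame(img))
        assert node.s_intensity == 0.0
        assert node.s_bubble == 1.0

    def test_two_by_two_square_hand_values(self):
        img = np.zeros((10, 10))
        vals = {(4, 4): 1.0, (4, 5): 1.0, (5, 4): 1.0, (5, 5): 3.0}
        for (r, c), v in vals.items():
            img[r, c] = v
        node = AppearanceNode(pixel_set=frozenset(vals), layer=0, threshold=0.5)
        appearance_score(node, GrayFrame(img))
        assert node.s_intensity == pytest.approx(0.75)
        # all four pixels are edge pixels equidistant from the centroid
        assert node.s_shape == pytest.approx(0.0)

    def test_ring_with_hole_bubble(self):
        pix = {(r, c) for r in range(3) for c in range(3)} - {(1, 1)}
        img = np.zeros((9, 9))
        for r, c in pix:
            img[r + 3, c + 3] = 5.0
        node = AppearanceNode(
            pixel_set=frozenset((r + 3, c + 3) for r, c in pix), layer=0, threshold=1.0
        )
        appearance_score(node, GrayFrame(img))
        assert node.s_bubble == 2.0


def _make_tree(scores_by_path):
    """Build an AppearanceNode tree from {path_tuple: score}; () is the root."""
    nodes = {}
    for path in sorted(scores_by_path, key=len):
        node = AppearanceNode(
            pixel_set=frozenset({path}), layer=len(path), threshold=float(len(path))
        )
        node.s_appearance = scores_by_path[path]
        nodes[path] = node
        if path:
            nodes[path[:-1]].children.append(node)
    return nodes[()]


def _min_antichain_sum(node):
    if not node.children:
        return node.s_appearance
    return min(node.s_appearance, sum(_min_antichain_sum(c) for c in node.children))


def random_forest(rng, max_nodes=15):
    """Random appearance tree with positive scores, as a one-root forest."""
    n = int(rng.integers(1, max_nodes + 1))
    scores = {(): float(rng.uniform(0.1, 10))}
    paths = [()]
    while len(scores) < n:
        parent = paths[int(rng.integers(len(paths)))]
        child = parent + (len([p for p in scores if p[: len(parent)] == parent and len(p) == len(parent) + 1]),)
        if child in scores:
            continue
        scores[child] = float(rng.uniform(0.1, 10))
        paths.append(child)
    root = _make_tree(scores)
    return AppearanceForest(roots=[root], n_layers=max(len(p) for p in scores) + 1, thresholds=[])


class TestSelectSegmentation:
    def test_children_win_when_cheaper(self):
        root = _make_tree({(): 5.0, (0,): 1.0, (1,): 3.0})
        forest = AppearanceForest(roots=[root], n_layers=2, thresholds=[])
        sel = select_segmentation(forest)
        assert sorted(n.s_appearance for n in sel) == [1.0, 3.0]

    def test_parent_wins_on_tie_or_cheaper(self):
        root = _make_tree({(): 2.0, (0,): 1.0, (1,): 3.0})
        forest = AppearanceForest(roots=[root], n_layers=2, thresholds=[])
        sel = select_segmentation(forest)
        assert [n.s_appearance for n in sel] == [2.0]

    def test_matches_exhaustive_antichain_oracle(self, rng):
        for _ in range(200):
            forest = random_forest(rng)
            sel = select_segmentation(forest)
            total = sum(n.s_appearance for n in sel)
            assert total == pytest.approx(_min_antichain_sum(forest.roots[0]))
            # selected nodes form an antichain: no selected node is an
            # ancestor of another (pixel sets here encode paths)
            paths = [next(iter(n.pixel_set)) for n in sel]
            for a in paths:
                for b in paths:
                    assert a == b or a != b[: len(a)]


class TestDetectFrame:
    def test_blank_frame_empty(self):
        assert detect_frame(GrayFrame(np.zeros((30, 30)))) == []

    def test_two_separated_blobs(self):
        img = _blob_map([(10, 10), (30, 32)], 1.5, shape=(44, 44), amp=100.0) + 1.0
        dets = detect_frame(GrayFrame(img), DetectionConfig(k=2.0))
        assert len(dets) == 2
        centers = sorted((d.centroid for d in dets))
        assert abs(centers[0][0] - 10) <= 1 and abs(centers[0][1] - 10) <= 1
        assert abs(centers[1][0] - 30) <= 1 and abs(centers[1][1] - 32) <= 1

    def test_touching_blobs_resolved_by_higher_threshold(self):
        img = _blob_map([(20, 17), (20, 25)], 2.0, shape=(40, 40), amp=100.0) + 1.0
        dets = detect_frame(GrayFrame(img), DetectionConfig(k=1.0))
        assert len(dets) == 2

    def test_disjoint_and_idempotent(self):
        img = _blob_map([(12, 12), (25, 28), (33, 10)], 1.5, shape=(44, 44), amp=80.0) + 1.0
        frame = GrayFrame(img)
        a = detect_frame(frame)
        b = detect_frame(frame)
        assert [d.centroid for d in a] == [d.centroid for d in b]
        seen = set()
        for d in a:
            assert not (seen & d.pixel_set)
            seen |= d.pixel_set
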