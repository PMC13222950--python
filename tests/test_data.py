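"""Synthetic dataset generator, augmentations, split arithmetic, COCO I/O."""

import numpy as np
import pytest

from dsadet.data import (
    CLASS_NAMES,
    AnnotatedImage,
    augment,
    generate_dataset,
    generate_leaf_image,
    read_dataset,
    split_dataset,
    write_dataset,
    xywh_to_xyxy,
    xyxy_to_xywh,
)


class TestSplitArithmetic:
    def test_published_counts_reproduced_exactly(self):
        counts, _ = split_dataset(4778, (5, 1, 2), seed=0)
        assert counts == (2986, 597, 1195)

    @pytest.mark.parametrize("n,want", [(8, (5, 1, 2)), (16, (10, 2, 4)), (80, (50, 10, 20))])
    def test_exact_ratios(self, n, want):
        assert split_dataset(n, (5, 1, 2), seed=1)[0] == want

    @pytest.mark.parametrize("n", [9, 23, 100, 4778])
    def test_counts_sum_and_assignment_consistent(self, n):
        counts, assignment = split_dataset(n, (5, 1, 2), seed=3)
        assert sum(counts) == n == len(assignment)
        got = (assignment.count("train"), assignment.count("val"), assignment.count("test"))
        assert got == counts

    def test_stratified_split_keeps_class_proportions(self):
        n = 200
        labels = [i % 5 for i in range(n)]
        counts, assignment = split_dataset(n, (5, 1, 2), seed=7, labels=labels)
        for c in range(5):
            idx = [i for i in range(n) if labels[i] == c]
            tr = sum(assignment[i] == "train" for i in idx)
            # global ratio 5/8 of 40 = 25; stratification within ±1
            assert abs(tr - len(idx) * counts[0] / n) <= 1

    def test_too_small_dataset_rejected(self):
        with pytest.raises(ValueError):
            split_dataset(7, (5, 1, 2), seed=0)

    def test_seeded_permutation_reproducible(self):
        a = split_dataset(50, (5, 1, 2), seed=9)[1]
        b = split_dataset(50, (5, 1, 2), seed=9)[1]
        c = split_dataset(50, (5, 1, 2), seed=10)[1]
        assert a == b and a != c


class TestGenerator:
    def test_bit_deterministic(self):
        a = generate_leaf_image(2, 11, "medium", size=128)
        b = generate_leaf_image(2, 11, "medium", size=128)
        assert np.array_equal(a.pixels, b.pixels)
        assert a.annotations == b.annotations

    def test_healthy_has_single_leaf_annotation(self):
        img = generate_leaf_image(4, 5, "medium", size=128)
        assert len(img.annotations) == 1
        cid, (x1, y1, x2, y2) = img.annotations[0]
        assert cid == 4
        # leaf box is large: covers a substantial image fraction
        assert (x2 - x1) * (y2 - y1) > 0.2 * 128 * 128

    @pytest.mark.parametrize("class_id", range(4))
    def test_scale_parameterization_bounds(self, class_id):
        S = 256
        for seed in range(3):
            small = generate_leaf_image(class_id, seed, "small", size=S)
            for _, (x1, y1, x2, y2) in small.annotations:
                assert (x2 - x1) * (y2 - y1) < 0.01 * S * S
            large = generate_leaf_image(class_id, seed, "large", size=S)
            for _, (x1, y1, x2, y2) in large.annotations:
                assert (x2 - x1) * (y2 - y1) >= 0.10 * S * S

    def test_invalid_class_rejected(self):
        with pytest.raises(ValueError):
            generate_leaf_image(5, 0, "small")

    def test_boxes_valid_after_any_augmentation(self):
        for op in ("rotation", "hue", "noise"):
            for seed in range(3):
                img = generate_leaf_image(1, seed, "medium", size=128)
                aug = augment(img, op, seed)  # AnnotatedImage validates boxes
                assert isinstance(aug, AnnotatedImage)

    def test_classes_separable_by_color_histogram(self):
        """A linear classifier on coarse RGB histograms separates the five
        procedural classes — the classes are learnable from color alone."""
        from sklearn.linear_model import LogisticRegression
        from sklearn.model_selection import train_test_split
        from sklearn.pipeline import make_pipeline
        from sklearn.preprocessing import StandardScaler

        X, y = [], []
        for cid in range(5):
            for seed in range(100):
                img = generate_leaf_image(cid, seed, "medium", size=96)
                hist = [
                    np.histogram(img.pixels[..., c], bins=8, range=(0, 256))[0]
                    for c in range(3)
                ]
                X.append(np.concatenate(hist) / (96 * 96))
                y.append(cid)
        Xtr, Xte, ytr, yte = train_test_split(
            np.array(X), np.array(y), test_size=0.3, random_state=0, stratify=y
        )
        clf = make_pipeline(StandardScaler(), LogisticRegression(max_iter=2000))
        acc = clf.fit(Xtr, ytr).score(Xte, yte)
        assert acc > 0.8, acc


class TestAugment:
    def test_zero_rotation_is_identity_on_boxes(self):
        img = generate_leaf_image(0, 1, "medium", size=128)
        out = augment(img, "rotation", 0, magnitude=0.0)
        assert [b for _, b in out.annotations] == [b for _, b in img.annotations]

    def test_hue_and_noise_leave_boxes_untouched(self):
        img = generate_leaf_image(1, 1, "medium", size=128)
        for op in ("hue", "noise"):
            out = augment(img, op, 3)
            assert out.annotations == img.annotations
            assert not np.array_equal(out.pixels, img.pixels)

    def test_rotation_box_remap_matches_mask_rotation(self):
        """Rasterize the box, rotate the mask with the image transform,
        re-fit an axis-aligned box: the analytic remap agrees to ~2 px."""
        from skimage import transform as sktf

        S = 160
        box = (30.0, 50.0, 90.0, 100.0)
        for angle in (90.0, 17.0, -33.0):
            mask = np.zeros((S, S))
            mask[int(box[1]) : int(box[3]), int(box[0]) : int(box[2])] = 1.0
            if angle % 90 == 0:
                rot = np.rot90(mask, k=int(angle // 90) % 4, axes=(1, 0))
            else:
                rot = sktf.rotate(mask, -angle, mode="constant")
            ys, xs = np.nonzero(rot > 0.5)
            want = (xs.min(), ys.min(), xs.max() + 1, ys.max() + 1)

            img = AnnotatedImage(
                np.zeros((S, S, 3), dtype=np.uint8), [(0, box)]
            )
            out = augment(img, "rotation", 0, magnitude=angle)
            got = out.annotations[0][1]
            assert max(abs(g - w) for g, w in zip(got, want)) < 2.5, angle

    def test_deterministic_per_seed(self):
        img = generate_leaf_image(3, 2, "medium", size=96)
        a = augment(img, "noise", 5)
        b = augment(img, "noise", 5)
        c = augment(img, "noise", 6)
        assert np.array_equal(a.pixels, b.pixels)
        assert not np.array_equal(a.pixels, c.pixels)


class TestCocoRoundTrip:
    def test_write_then_read_identical(self, tmp_path):
        manifest = generate_dataset(10, seed=4, size=64)
        write_dataset(manifest, str(tmp_path))
        back = read_dataset(str(tmp_path))
        assert back.class_names == tuple(CLASS_NAMES)
        assert len(back.records) == 10
        for a, b in zip(manifest.records, back.records):
            assert np.array_equal(a["image"].pixels, b["image"].pixels)
            got = [(c, tuple(bb)) for c, bb in b["image"].annotations]
            want = [(c, tuple(bb)) for c, bb in a["image"].annotations]
            assert got == want

    def test_empty_split_gives_valid_coco(self, tmp_path):
        manifest = generate_dataset(8, seed=4, size=64)
        for r in manifest.records:
            r["split"] = "train"
        paths = write_dataset(manifest, str(tmp_path))
        import json

        with open(paths["val"]) as fh:
            coco = json.load(fh)
        assert coco["images"] == [] and coco["annotations"] == []
        assert len(coco["categories"]) == 5

    def test_corner_to_corner_box_survives_conversion(self):
        box = (0.0, 0.0, 640.0, 640.0)
        assert xywh_to_xyxy(xyxy_to_xywh(box)) == box
        assert xyxy_to_xywh(box) == (0.0, 0.0, 640.0, 640.0)
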