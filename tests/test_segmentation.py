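import numpy as np
import pytest
from scipy import ndimage as ndi

from cyclicproc.imgmeta_io import ImageMeta, RoundStack
from cyclicproc.segmentation import (LabelMask, SegmentationError,
                                     derive_cytoplasm, expand_labels,
                                     project_dapi, segment_cells,
                                     segment_nuclei)


def _stack_of(dapis):
    stack = RoundStack()
    for r, img in enumerate(dapis, start=1):
        stack.images[(r, "DAPI")] = img
        stack.meta[(r, "DAPI")] = ImageMeta("S", "s", r, "DAPI", "DAPI", 20.0)
    return stack


def _disk_image(shape, centers, radius, value=5000.0, blur=1.5):
    img = np.zeros(shape)
    yy, xx = np.mgrid[0:shape[0], 0:shape[1]]
    for cy, cx in centers:
        img[(yy - cy) ** 2 + (xx - cx) ** 2 <= radius**2] = value
    img = ndi.gaussian_filter(img, blur) + 100.0
    return np.clip(img, 0, 65535).astype(np.uint16)


def expand_oracle(labels, distance):
    """Brute-force nearest-label-within-distance assignment, ties to the
    smaller label id."""
    out = labels.copy()
    fg = np.argwhere(labels > 0)
    for p in np.argwhere(labels == 0):
        d2 = ((fg - p) ** 2).sum(axis=1)
        dmin = d2.min() if len(d2) else np.inf
        if dmin <= distance**2:
            cands = labels[tuple(fg[d2 == dmin].T)]
            out[tuple(p)] = cands.min()
    return out


class TestProjectDapi:
    def test_single_round_is_identity(self):
        img = np.random.default_rng(0).integers(0, 1000, (32, 32)).astype(np.uint16)
        np.testing.assert_array_equal(project_dapi(_stack_of([img])), img)

    def test_zero_round_ignored_by_max(self):
        img = np.random.default_rng(1).integers(1, 1000, (32, 32)).astype(np.uint16)
        proj = project_dapi(_stack_of([img, np.zeros_like(img)]))
        np.testing.assert_array_equal(proj, img)

    def test_disjoint_spots_all_present(self):
        imgs = []
        for c in [(8, 8), (16, 24), (24, 8)]:
            im = np.zeros((32, 32), dtype=np.uint16)
            im[c] = 1000
            imgs.append(im)
        proj = project_dapi(_stack_of(imgs))
        for c in [(8, 8), (16, 24), (24, 8)]:
            assert proj[c] == 1000


class TestSegmentNuclei:
    def test_single_disk_recovered(self):
        img = _disk_image((96, 96), [(48, 48)], radius=9)
        mask = segment_nuclei(img)
        assert mask.n_labels == 1
        truth = np.zeros((96, 96), dtype=bool)
        yy, xx = np.mgrid[0:96, 0:96]
        truth[(yy - 48) ** 2 + (xx - 48) ** 2 <= 81] = True
        covered = (mask.labels > 0) & truth
        assert covered.sum() >= 0.9 * truth.sum()

    def test_touching_disks_split(self):
        img = _disk_image((96, 96), [(48, 39), (48, 57)], radius=9)
        mask = segment_nuclei(img)
        assert mask.n_labels == 2

    def test_blank_image_raises_no_seeds(self):
        with pytest.raises(SegmentationError, match="no seeds"):
            segment_nuclei(np.zeros((64, 64), dtype=np.uint16))

    def test_size_caps_limit_area(self):
        img = _disk_image((96, 96), [(48, 48)], radius=14)
        mask = segment_nuclei(img, size_cap_ck_pos_px2=200,
                              size_cap_ck_neg_px2=100)
        areas = np.bincount(mask.labels.ravel())[1:]
        assert areas.max() <= 100  # default class is CK-negative


class TestExpandLabels:
    def test_distance_zero_is_identity(self):
        labels = np.zeros((16, 16), dtype=np.int32)
        labels[4, 4] = 1
        mask = LabelMask(labels, "nucleus")
        out = expand_labels(mask, 0)
        np.testing.assert_array_equal(out.labels, labels)

    def test_single_pixel_disk_area(self):
        """Expansion of a 1-px label matches the brute-force Euclidean disk
        pixel count."""
        labels = np.zeros((32, 32), dtype=np.int32)
        labels[16, 16] = 1
        out = expand_labels(LabelMask(labels, "nucleus"), 5)
        yy, xx = np.mgrid[0:32, 0:32]
        disk = (yy - 16) ** 2 + (xx - 16) ** 2 <= 25
        assert (out.labels > 0).sum() == disk.sum()
        np.testing.assert_array_equal(out.labels > 0, disk)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_bruteforce_oracle(self, seed):
        rng = np.random.default_rng(seed)
        labels = np.zeros((48, 48), dtype=np.int32)
        for lab in range(1, 6):
            y, x = rng.integers(4, 44, 2)
            labels[y:y + 3, x:x + 3] = lab
        out = expand_labels(LabelMask(labels, "nucleus"), 5)
        np.testing.assert_array_equal(out.labels, expand_oracle(labels, 5))

    def test_two_labels_meet_without_overlap(self):
        labels = np.zeros((32, 32), dtype=np.int32)
        labels[16, 10] = 1
        labels[16, 16] = 2  # 6 px apart, expansion 5 -> fronts meet
        out = expand_labels(LabelMask(labels, "nucleus"), 5)
        np.testing.assert_array_equal(out.labels, expand_oracle(labels, 5))
        # tie pixel at x=13 goes to smaller label
        assert out.labels[16, 13] == 1


class TestSegmentCells:
    def test_all_negative_reduces_to_expansion(self):
        labels = np.zeros((48, 48), dtype=np.int32)
        labels[10:14, 10:14] = 1
        labels[30:34, 30:34] = 2
        nuc = LabelMask(labels, "nucleus")
        membrane = np.zeros((48, 48), dtype=np.uint16)
        out = segment_cells(membrane, nuc, {1: True, 2: True}, expand_px=5)
        np.testing.assert_array_equal(out.labels, expand_labels(nuc, 5).labels)

    def test_membrane_ring_bounds_cell(self):
        """Cell boundary lands within 2 px of the bright ring center-line."""
        shape = (96, 96)
        yy, xx = np.mgrid[0:96, 0:96]
        d = np.sqrt((yy - 48) ** 2 + (xx - 48) ** 2)
        membrane = (3000 * np.exp(-((d - 15) ** 2) / 8)).astype(np.uint16)
        labels = np.zeros(shape, dtype=np.int32)
        labels[d <= 6] = 1
        nuc = LabelMask(labels, "nucleus")
        out = segment_cells(membrane, nuc, {1: False}, max_cell_radius_px=25)
        cell = out.labels == 1
        assert cell[d <= 6].all()
        boundary_r = d[cell].max()
        assert abs(boundary_r - 15) <= 2

    def test_positive_without_membrane_still_contains_nucleus(self):
        labels = np.zeros((64, 64), dtype=np.int32)
        labels[28:36, 28:36] = 1
        nuc = LabelMask(labels, "nucleus")
        membrane = np.zeros((64, 64), dtype=np.uint16)
        out = segment_cells(membrane, nuc, {1: False})
        assert ((out.labels == 1) & (labels == 1)).sum() == (labels == 1).sum()
        assert (out.labels == 1).sum() >= (labels == 1).sum()

    def test_missing_flags_rejected(self):
        labels = np.zeros((16, 16), dtype=np.int32)
        labels[4:8, 4:8] = 1
        with pytest.raises(ValueError, match="flags missing"):
            segment_cells(np.zeros((16, 16), dtype=np.uint16),
                          LabelMask(labels, "nucleus"), {})


class TestDeriveCytoplasm:
    def test_cell_equals_nucleus_gives_empty_cytoplasm(self):
        labels = np.zeros((16, 16), dtype=np.int32)
        labels[4:8, 4:8] = 1
        nuc = LabelMask(labels, "nucleus")
        cell = LabelMask(labels.copy(), "cell")
        cyto = derive_cytoplasm(cell, nuc)
        assert (cyto.labels == 0).all()

    def test_expanded_pixel_cytoplasm_area(self):
        labels = np.zeros((32, 32), dtype=np.int32)
        labels[16, 16] = 1
        nuc = LabelMask(labels, "nucleus")
        cell = expand_labels(nuc, 5)
        cyto = derive_cytoplasm(cell, nuc)
        yy, xx = np.mgrid[0:32, 0:32]
        disk_area = ((yy - 16) ** 2 + (xx - 16) ** 2 <= 25).sum()
        assert (cyto.labels > 0).sum() == disk_area - 1

    def test_containment_violation_lists_labels(self):
        nuc_labels = np.zeros((16, 16), dtype=np.int32)
        nuc_labels[4:8, 4:8] = 1
        cell_labels = np.zeros((16, 16), dtype=np.int32)
        cell_labels[5:9, 5:9] = 1  # does not contain nucleus
        with pytest.raises(ValueError, match=r"\[1\]"):
            derive_cytoplasm(LabelMask(cell_labels, "cell"),
                             LabelMask(nuc_labels, "nucleus"))


class TestMaskAlgebra:
    def test_invariants_on_synthetic_field(self, small_scene):
        """nucleus(k) subset of cell(k); cytoplasm = cell \\ nucleus;
        cytoplasm and nucleus disjoint — on a full synthetic field."""
        stack, truth = small_scene
        nuc = truth.nuclei
        cell = expand_labels(nuc, 5)
        cyto = derive_cytoplasm(cell, nuc)
        n, c, y = nuc.labels, cell.labels, cyto.labels
        assert ((n > 0) & (c != n)).sum() == 0           # containment
        assert ((y > 0) & (n > 0)).sum() == 0            # disjoint
        np.testing.assert_array_equal(np.where(c == n, 0, c), y)
        assert set(nuc.label_ids) == set(cell.label_ids)

    def test_detection_quality_on_synthetic_field(self, small_scene):
        """Object-level F1 at IoU >= 0.5 is >= 0.95 with count error <= 2%
        on a field of non-touching noisy nuclei."""
        stack, truth = small_scene
        pred = segment_nuclei(project_dapi(stack)).labels
        gt = truth.nuclei.labels
        tp, used = 0, set()
        for g in np.unique(gt[gt > 0]):
            gm = gt == g
            labs, cnts = np.unique(pred[gm], return_counts=True)
            best, best_lab = 0.0, 0
            for lab, cnt in zip(labs, cnts):
                if lab == 0:
                    continue
                iou = cnt / (gm.sum() + (pred == lab).sum() - cnt)
                if iou > best:
                    best, best_lab = iou, lab
            if best >= 0.5 and best_lab not in used:
                tp += 1
                used.add(best_lab)
        n_pred = len(np.unique(pred[pred > 0]))
        n_gt = len(np.unique(gt[gt > 0]))
        precision, recall = tp / n_pred, tp / n_gt
        f1 = 2 * precision * recall / (precision + recall)
        assert f1 >= 0.95
        assert abs(n_pred - n_gt) <= 0.02 * n_gt
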