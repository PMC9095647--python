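"""Nucleus / cell / cytoplasm segmentation.

The watershed procedure: a maximum projection of all rounds' DAPI images is
filtered with a white top-hat to isolate nuclear candidates, seeds are
extracted from the top-hat image, nuclear contours come from the Prewitt
gradient magnitude, and a seeded watershed separates touching nuclei.
Nuclei are clipped to a class-specific maximum size — cytokeratin-positive
(epithelial) cells are allowed larger nuclei than cytokeratin-negative ones.

Whole cells are obtained by a watershed on the membrane (Ecad) image seeded
with the nuclei, or — for membrane-negative cells — by expanding each
nucleus five pixels (1.6 µm at 0.325 µm/px) into the background, which
approximates the immune-cell cytoplasm.  The cytoplasm is the cell minus the
nucleus.

Label expansion uses exact Euclidean distances with deterministic
tie-breaking (contested pixels go to the nearest label, ties to the smaller
label id).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage as ndi
from skimage import filters, morphology as skmorph
from skimage.feature import peak_local_max
from skimage.segmentation import watershed

from cyclicproc.imgmeta_io import RoundStack


class SegmentationError(RuntimeError):
    pass


@dataclass
class LabelMask:
    """Integer-labeled raster: 0 = background, k > 0 = object k.

    The three compartments of one scene share a single label space:
    nucleus(k) ⊆ cell(k) and cytoplasm(k) = cell(k) \\ nucleus(k).
    """

    labels: np.ndarray
    compartment: str  # nucleus | cell | cytoplasm
    pixel_size_um: float = 0.325

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.min() < 0:
            raise ValueError("labels must be non-negative")
        if self.compartment not in ("nucleus", "cell", "cytoplasm"):
            raise ValueError(f"unknown compartment {self.compartment!r}")

    @property
    def label_ids(self) -> np.ndarray:
        ids = np.unique(self.labels)
        return ids[ids > 0]

    @property
    def n_labels(self) -> int:
        return len(self.label_ids)


def project_dapi(stack: RoundStack) -> np.ndarray:
    """Pixelwise maximum of the registered DAPI images across rounds.

    The maximum (rather than mean) projection preserves nuclei of cells that
    detach in later rounds, so every cell ever present is segmented.
    """
    dapis = [stack.get(r, "DAPI") for r in stack.rounds
             if (r, "DAPI") in stack.images]
    if not dapis:
        raise ValueError("stack contains no DAPI images")
    shapes = {d.shape for d in dapis}
    if len(shapes) > 1:
        raise ValueError(f"DAPI rasters have mixed shapes {shapes}; register first")
    return np.max(np.stack(dapis), axis=0)


def segment_nuclei(dapi_proj: np.ndarray,
                   tophat_radius_px: int = 15,
                   seed_min_distance_px: int = 5,
                   size_cap_ck_pos_px2: int = 1200,
                   size_cap_ck_neg_px2: int = 600,
                   ck_positive: dict[int, bool] | None = None,
                   smooth_sigma: float = 1.0) -> LabelMask:
    """Watershed nuclear segmentation of a DAPI projection.

    Steps: (i) white top-hat with a disk of ``tophat_radius_px``;
    (ii) seeds = local maxima of the smoothed top-hat above its Otsu
    threshold, at least ``seed_min_distance_px`` apart; (iii) relief =
    Prewitt gradient magnitude; (iv) seeded watershed restricted to the
    Otsu foreground; (v) objects larger than their class's size cap are
    trimmed to the pixels nearest the seed centroid.

    ``ck_positive`` maps seed label id -> cytokeratin positivity; seeds not
    listed are treated as negative.
    """
    if tophat_radius_px <= 0 or seed_min_distance_px <= 0:
        raise ValueError("radii must be positive")
    if size_cap_ck_pos_px2 < size_cap_ck_neg_px2:
        raise ValueError("CK-positive size cap must be >= CK-negative cap")

    img = dapi_proj.astype(float)
    tophat = skmorph.white_tophat(img, footprint=skmorph.disk(tophat_radius_px))
    smoothed = ndi.gaussian_filter(tophat, smooth_sigma)
    if np.ptp(smoothed) == 0:
        raise SegmentationError("no seeds: top-hat image is constant")
    thresh = filters.threshold_otsu(smoothed)
    foreground = smoothed > thresh

    # seeds: maxima of the foreground distance transform (one per convex
    # nuclear candidate; touching nuclei yield one maximum each)
    dist = ndi.distance_transform_edt(foreground)
    peaks = peak_local_max(dist, min_distance=seed_min_distance_px,
                           labels=foreground, exclude_border=False)
    if len(peaks) == 0:
        raise SegmentationError("no seeds found in top-hat image")
    peak_mask = np.zeros(img.shape, dtype=bool)
    peak_mask[tuple(peaks.T)] = True
    # plateau maxima produce peak clusters; merge those within min distance
    seeds, n_seeds = ndi.label(ndi.binary_dilation(
        peak_mask, skmorph.disk(max(1, seed_min_distance_px // 2))))
    if n_seeds == 0:
        raise SegmentationError("no seeds found")

    relief = filters.prewitt(img)
    labels = watershed(relief, markers=seeds, mask=foreground)
    labels = _drop_small(labels, min_size_px2=30)

    labels = _apply_size_caps(labels, seeds,
                              size_cap_ck_pos_px2, size_cap_ck_neg_px2,
                              ck_positive or {})
    return LabelMask(labels.astype(np.int32), "nucleus")


def _drop_small(labels: np.ndarray, min_size_px2: int) -> np.ndarray:
    """Remove noise specks below the minimum plausible nuclear area and
    relabel contiguously."""
    ids, counts = np.unique(labels[labels > 0], return_counts=True)
    keep = ids[counts >= min_size_px2]
    out = np.where(np.isin(labels, keep), labels, 0)
    remap = np.zeros(int(labels.max()) + 1, dtype=labels.dtype)
    remap[keep] = np.arange(1, len(keep) + 1)
    return remap[out]


def _apply_size_caps(labels: np.ndarray, seeds: np.ndarray,
                     cap_pos: int, cap_neg: int,
                     ck_positive: dict[int, bool]) -> np.ndarray:
    """Trim labels exceeding their class's size cap, keeping the pixels
    nearest the seed centroid."""
    out = labels.copy()
    centroids = ndi.center_of_mass(seeds > 0, seeds, np.unique(seeds[seeds > 0]))
    centroid_of = dict(zip(np.unique(seeds[seeds > 0]).tolist(), centroids))
    for lab in np.unique(out[out > 0]):
        cap = cap_pos if ck_positive.get(int(lab), False) else cap_neg
        rr, cc = np.nonzero(out == lab)
        if len(rr) <= cap:
            continue
        cy, cx = centroid_of.get(int(lab), (rr.mean(), cc.mean()))
        d2 = (rr - cy) ** 2 + (cc - cx) ** 2
        drop = np.argsort(d2, kind="stable")[cap:]
        out[rr[drop], cc[drop]] = 0
    return out


def expand_labels(nuclei: LabelMask, distance_px: float = 5.0) -> LabelMask:
    """Grow every label into the background by up to ``distance_px`` (exact
    Euclidean distance).  Contested pixels go to the nearest label; distance
    ties go to the smaller label id.  ``distance_px = 0`` is the identity.
    """
    if distance_px < 0:
        raise ValueError("distance must be >= 0")
    labels = nuclei.labels
    out = labels.copy()
    if distance_px == 0 or nuclei.n_labels == 0:
        return LabelMask(out, "cell", nuclei.pixel_size_um)

    best_dist = np.full(labels.shape, np.inf)
    best_label = np.zeros(labels.shape, dtype=labels.dtype)
    pad = int(np.ceil(distance_px)) + 1
    slices = ndi.find_objects(labels)
    for idx, sl in enumerate(slices):
        if sl is None:
            continue
        lab = idx + 1
        r0 = max(sl[0].start - pad, 0)
        r1 = min(sl[0].stop + pad, labels.shape[0])
        c0 = max(sl[1].start - pad, 0)
        c1 = min(sl[1].stop + pad, labels.shape[1])
        window = (slice(r0, r1), slice(c0, c1))
        dist = ndi.distance_transform_edt(labels[window] != lab)
        # strict < keeps the smaller (earlier) label on exact ties
        upd = dist < best_dist[window]
        best_dist[window][upd] = dist[upd]
        bl = best_label[window]
        bl[upd] = lab
        best_label[window] = bl
    grow = (labels == 0) & (best_dist <= distance_px)
    out[grow] = best_label[grow]
    return LabelMask(out, "cell", nuclei.pixel_size_um)


def segment_cells(membrane_img: np.ndarray, nuclei: LabelMask,
                  membrane_negative: dict[int, bool],
                  expand_px: float = 5.0,
                  max_cell_radius_px: float = 20.0) -> LabelMask:
    """Whole-cell segmentation from a membrane (Ecad) image.

    Membrane-positive nuclei seed a watershed on the membrane intensity
    (basin divides fall on the bright membrane ridge between cells, and a
    background seed placed in low-membrane territory beyond
    ``max_cell_radius_px`` bounds each cell).  Membrane-negative nuclei are
    expanded by ``expand_px``.  Nucleus label ids are preserved.
    """
    if membrane_img.shape != nuclei.labels.shape:
        raise ValueError("membrane image and nuclei mask shapes differ")
    ids = nuclei.label_ids
    missing = [int(i) for i in ids if int(i) not in membrane_negative]
    if missing:
        raise ValueError(f"membrane_negative flags missing for labels {missing}")

    expanded = expand_labels(nuclei, expand_px)
    neg_ids = {i for i in membrane_negative if membrane_negative[i]}
    pos_ids = {int(i) for i in ids} - neg_ids

    out = np.where(np.isin(expanded.labels, sorted(neg_ids)), expanded.labels, 0)

    if pos_ids:
        img = membrane_img.astype(float)
        pos_nuclei = np.where(np.isin(nuclei.labels, sorted(pos_ids)),
                              nuclei.labels, 0)
        dist_to_nucleus = ndi.distance_transform_edt(pos_nuclei == 0)
        if np.ptp(img) > 0:
            mem_thresh = filters.threshold_otsu(img)
        else:
            mem_thresh = np.inf
        bg_seed_id = int(nuclei.labels.max()) + 1
        markers = pos_nuclei.copy()
        background_seed = (dist_to_nucleus > max_cell_radius_px) & (img <= mem_thresh)
        if not background_seed.any():
            background_seed = dist_to_nucleus > max_cell_radius_px
        markers[background_seed] = bg_seed_id
        # watershed climbs the membrane intensity: divides sit on the ridge
        ws = watershed(img, markers=markers)
        ws[ws == bg_seed_id] = 0
        # a positive cell never shrinks below its own nucleus
        keep = (out == 0) & (ws > 0)
        out[keep] = ws[keep]
        nuc_px = pos_nuclei > 0
        out[nuc_px] = pos_nuclei[nuc_px]
    return LabelMask(out.astype(np.int32), "cell", nuclei.pixel_size_um)


def derive_cytoplasm(cell: LabelMask, nuclei: LabelMask) -> LabelMask:
    """Cytoplasm(k) = cell(k) minus nucleus(k); may be empty for a label.

    Raises if any nucleus is not contained in its cell (listing offenders).
    """
    if cell.labels.shape != nuclei.labels.shape:
        raise ValueError("cell and nucleus masks have different shapes")
    nuc = nuclei.labels
    cel = cell.labels
    bad = sorted(np.unique(nuc[(nuc > 0) & (cel != nuc)]).tolist())
    if bad:
        raise ValueError(f"nucleus not contained in cell for labels {bad}")
    extra = sorted(set(nuclei.label_ids.tolist()) - set(cell.label_ids.tolist()))
    if extra:
        raise ValueError(f"nucleus labels absent from cell mask: {extra}")
    cyto = np.where(cel == nuc, 0, cel)
    return LabelMask(cyto, "cytoplasm", cell.pixel_size_um)
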