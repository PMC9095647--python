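"""Per-cell feature extraction.

One row per cell: mean marker intensity in each subcellular compartment
(nucleus, cytoplasm, whole cell), morphology (area, eccentricity, centroid),
and — for downstream analysis — a single ``selected`` intensity per marker
taken from its biologically relevant compartment (e.g. cytoplasm for CK19,
nucleus for Ki67).

Cells whose compartment is empty (e.g. zero-area cytoplasm when the cell
equals its nucleus) get a missing value there, never zero, so background
statistics and normalization are not biased.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import ndimage as ndi
from skimage.measure import regionprops_table

from cyclicproc.imgmeta_io import RoundStack
from cyclicproc.segmentation import LabelMask

COMPARTMENTS = ("nucleus", "cell", "cytoplasm")


def mean_intensity(image: np.ndarray, mask: LabelMask) -> dict[int, float]:
    """Arithmetic mean pixel intensity under each label.

    Labels present in the mask's label space but with no pixels in this
    compartment map to NaN.
    """
    if image.shape != mask.labels.shape:
        raise ValueError(
            f"shape mismatch: image {image.shape} vs mask {mask.labels.shape}")
    ids = mask.label_ids
    if len(ids) == 0:
        return {}
    means = ndi.mean(image.astype(float), labels=mask.labels, index=ids)
    return {int(i): float(m) for i, m in zip(ids, means)}


def morphology(mask: LabelMask) -> pd.DataFrame:
    """Area (px²), ellipse-equivalent eccentricity and centroid per label.

    Eccentricity comes from the second central moments (the ellipse with the
    same moments); centroid is the mean pixel coordinate, returned as
    (x, y) = (col, row).
    """
    props = regionprops_table(
        mask.labels, properties=("label", "area", "eccentricity", "centroid"))
    df = pd.DataFrame(props).rename(columns={
        "label": "cell_id",
        "area": "area_px2",
        "centroid-0": "centroid_y",
        "centroid-1": "centroid_x",
    })
    df["area_px2"] = df["area_px2"].astype(int)
    return df.set_index("cell_id")


def build_cell_table(stack: RoundStack,
                     masks: dict[str, LabelMask],
                     marker_compartment: dict[str, str],
                     slide_id: str = "", scene_id: str = "",
                     core_id: str = "", batch_id: str = "") -> pd.DataFrame:
    """Assemble the per-cell feature table for one scene.

    Parameters
    ----------
    masks
        Compartment name -> :class:`LabelMask`; must contain ``nucleus`` and
        ``cell`` (``cytoplasm`` derived values are NaN if absent).
    marker_compartment
        Marker -> compartment whose mean becomes the marker's
        ``{marker}_selected`` column.  Unmapped markers default to ``cell``
        with a warning.

    Columns: identifiers, morphology, ``{marker}_{compartment}`` means and
    ``{marker}_selected``.
    """
    if "nucleus" not in masks or "cell" not in masks:
        raise ValueError("masks must include 'nucleus' and 'cell'")
    nuc, cel = masks["nucleus"], masks["cell"]
    if set(nuc.label_ids) - set(cel.label_ids):
        raise ValueError("label-space mismatch between nucleus and cell masks")

    cell_morph = morphology(cel)
    nuc_morph = morphology(nuc)

    table = pd.DataFrame(index=cell_morph.index)
    table["slide_id"] = slide_id or next(iter(stack.meta.values())).slide_id
    table["scene_id"] = scene_id or next(iter(stack.meta.values())).scene_id
    table["core_id"] = core_id
    table["batch_id"] = batch_id
    table["centroid_x"] = cell_morph["centroid_x"]
    table["centroid_y"] = cell_morph["centroid_y"]
    table["cell_area_px2"] = cell_morph["area_px2"]
    table["nucleus_area_px2"] = nuc_morph["area_px2"].reindex(table.index)
    table["eccentricity"] = nuc_morph["eccentricity"].reindex(table.index)

    marker_images: dict[str, np.ndarray] = {}
    for key, meta in stack.meta.items():
        if meta.is_blank or meta.channel == "DAPI":
            continue
        marker_images[meta.marker] = stack.images[key]

    for marker, image in sorted(marker_images.items()):
        for comp in COMPARTMENTS:
            if comp not in masks:
                continue
            means = mean_intensity(image, masks[comp])
            col = pd.Series(means, dtype=float).reindex(table.index)
            table[f"{marker}_{comp}"] = col
        comp = marker_compartment.get(marker)
        if comp is None:
            warnings.warn(f"marker {marker!r} has no compartment mapping; "
                          "defaulting to whole-cell mean", stacklevel=2)
            comp = "cell"
        if comp not in COMPARTMENTS:
            raise ValueError(f"unknown compartment {comp!r} for marker {marker!r}")
        table[f"{marker}_selected"] = table[f"{marker}_{comp}"]

    table = table.reset_index().rename(columns={"index": "cell_id"})
    table["cell_id"] = table["cell_id"].astype(int)
    return table
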