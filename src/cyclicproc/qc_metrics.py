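"""Staining-quality and tissue-integrity metrics.

Signal-to-background ratio (SBR) of a marker image is
``(mean intensity of positive pixels − mean intensity of negative pixels) /
mean intensity of negative pixels``.  Positive pixels lie strictly above a
per-marker threshold; background pixels lie at or below it *and* more than a
gap distance (30 px ≈ 10 µm) from any positive pixel, excluding lateral
bleed-through.  Manual artifact-exclusion masks are honoured.

A quantile variant estimates dynamic range and SBR from the 4th and 99.5th
intensity quantiles without a manual threshold.

Tissue retention across quench rounds is scored on per-cell DAPI: each
round's cells are thresholded with the Li minimum-cross-entropy algorithm,
and retention is the fraction of the round-1 population still above the
threshold in that round.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage as ndi
from skimage.filters import threshold_li


@dataclass(frozen=True)
class ThresholdRecord:
    """Per-marker intensity threshold with provenance."""

    marker: str
    value: float
    provenance: str = "manual"  # manual | li | restore | reverse_quantile
    scope: str = "pixel"        # pixel | cell_mean

    def __post_init__(self) -> None:
        if self.value < 0:
            raise ValueError("threshold must be >= 0")
        if self.provenance not in ("manual", "li", "restore", "reverse_quantile"):
            raise ValueError(f"unknown provenance {self.provenance!r}")
        if self.scope not in ("pixel", "cell_mean"):
            raise ValueError(f"unknown scope {self.scope!r}")


@dataclass(frozen=True)
class SbrResult:
    marker: str
    fg_mean: float
    bg_mean: float
    sbr: float
    n_fg_px: int
    n_bg_px: int
    negative_in_tissue: bool = False


def sbr_from_threshold(image: np.ndarray, t: ThresholdRecord,
                       gap_px: float = 30.0,
                       exclusion_mask: np.ndarray | None = None) -> SbrResult:
    """Threshold-based SBR with a Euclidean exclusion gap around foreground.

    Background pixels must be at or below the threshold, strictly more than
    ``gap_px`` (Euclidean) from every foreground pixel, and outside the
    artifact ``exclusion_mask`` (True = excluded).  A marker with no pixel
    above threshold is flagged ``negative_in_tissue`` (not analyzed).
    """
    if gap_px < 0:
        raise ValueError("gap must be >= 0")
    img = image.astype(float)
    fg = img > t.value
    if exclusion_mask is not None:
        if exclusion_mask.shape != image.shape:
            raise ValueError("exclusion mask shape mismatch")
        fg &= ~exclusion_mask

    if not fg.any():
        return SbrResult(t.marker, np.nan, np.nan, np.nan, 0, 0,
                         negative_in_tissue=True)

    dist_to_fg = ndi.distance_transform_edt(~fg)
    bg = (~fg) & (dist_to_fg > gap_px)
    if exclusion_mask is not None:
        bg &= ~exclusion_mask
    if not bg.any():
        raise ValueError("no background pixels beyond the exclusion gap")

    fg_mean = float(img[fg].mean())
    bg_mean = float(img[bg].mean())
    sbr = (fg_mean - bg_mean) / bg_mean
    return SbrResult(t.marker, fg_mean, bg_mean, sbr,
                     int(fg.sum()), int(bg.sum()))


def sbr_from_quantiles(values: np.ndarray, q_low: float = 0.04,
                       q_high: float = 0.995
                       ) -> tuple[tuple[float, float], float]:
    """Quantile-based dynamic range and SBR estimate.

    Returns ``((q_low value, q_high value), (q_high − q_low)/q_low)``.
    The estimate is NaN (flagged by a warning) when the low quantile is 0.
    """
    values = np.asarray(values, dtype=float).ravel()
    if len(values) == 0:
        raise ValueError("no values")
    if len(values) < 100:
        warnings.warn(f"only {len(values)} values; quantile SBR is unstable",
                      stacklevel=2)
    lo = float(np.quantile(values, q_low))
    hi = float(np.quantile(values, q_high))
    if lo == 0:
        warnings.warn("low quantile is 0; SBR estimate undefined", stacklevel=2)
        return (lo, hi), float("nan")
    return (lo, hi), (hi - lo) / lo


def percent_positive(cell_values: np.ndarray, t: ThresholdRecord) -> float:
    """Fraction of cells strictly above the threshold."""
    values = np.asarray(cell_values, dtype=float).ravel()
    if len(values) == 0:
        raise ValueError("no cells")
    return float(np.mean(values > t.value))


def relative_ratio(metric_a: float, metric_b: float) -> float:
    """Ratio a/b, e.g. replicate-to-replicate relative SBR."""
    if metric_b <= 0:
        raise ValueError("denominator metric must be > 0")
    return metric_a / metric_b


def tissue_retention(dapi_by_round: dict[int, np.ndarray],
                     reference_round: int | None = None,
                     pixel_values_by_round: dict[int, np.ndarray] | None = None,
                     ) -> dict[int, float]:
    """Per-round fraction of reference-round cells retained on the slide.

    Cells are tracked by index across rounds (same segmentation mask).  For
    each round a Li minimum-cross-entropy threshold is computed — on the
    round's DAPI image pixels when ``pixel_values_by_round`` is supplied
    (image pixels always contain the slide-background mode, so the threshold
    cleanly splits nuclei from background even in rounds without cell loss),
    otherwise on the round's per-cell DAPI means.  A cell is retained if its
    mean DAPI lies above the threshold.  Retention(r) = retained(r) /
    retained(reference), capped at 1.  Per-round thresholds absorb per-round
    exposure differences.
    """
    if not dapi_by_round:
        raise ValueError("no rounds")
    rounds = sorted(dapi_by_round)
    reference_round = rounds[0] if reference_round is None else reference_round
    if reference_round not in dapi_by_round:
        raise ValueError(f"reference round {reference_round} missing")

    n = len(np.asarray(dapi_by_round[reference_round]).ravel())
    retained: dict[int, np.ndarray] = {}
    for r in rounds:
        vals = np.asarray(dapi_by_round[r], dtype=float).ravel()
        if len(vals) == 0:
            raise ValueError(f"round {r} has no cells")
        if len(vals) != n:
            raise ValueError("cell index differs across rounds")
        if pixel_values_by_round is not None:
            thr_sample = np.asarray(pixel_values_by_round[r], dtype=float).ravel()
        else:
            thr_sample = vals
        retained[r] = vals > _li_threshold(thr_sample)

    ref = retained[reference_round]
    denom = max(int(ref.sum()), 1)
    out = {}
    for r in rounds:
        frac = float((retained[r] & ref).sum()) / denom
        out[r] = min(frac, 1.0)
    return out


def _li_threshold(values: np.ndarray) -> float:
    """Li minimum-cross-entropy threshold of a 1-D intensity sample
    (initial guess = mean intensity)."""
    if np.ptp(values) == 0:
        return float(values[0])
    return float(threshold_li(values, initial_guess=float(values.mean())))


def f1_vs_annotation(annotations: np.ndarray | list[str]
                     ) -> tuple[float, float, float]:
    """Precision, recall and F1 from per-cell TP/FP/FN/TN annotations."""
    ann = np.asarray(annotations, dtype=object)
    valid = {"TP", "FP", "FN", "TN"}
    bad = set(np.unique(ann)) - valid
    if bad:
        raise ValueError(f"unknown annotation labels {sorted(bad)}")
    tp = int((ann == "TP").sum())
    fp = int((ann == "FP").sum())
    fn = int((ann == "FN").sum())
    if tp + fn == 0:
        raise ValueError("annotation contains no positives (TP+FN = 0)")
    precision = tp / (tp + fp) if tp + fp else 0.0
    recall = tp / (tp + fn)
    f1 = (2 * precision * recall / (precision + recall)
          if precision + recall else 0.0)
    return precision, recall, f1


def annotate_cells(cell_values: np.ndarray, threshold: float,
                   truth_positive: np.ndarray) -> np.ndarray:
    """Derive TP/FP/FN/TN annotations by comparing thresholded calls with a
    ground-truth positivity vector."""
    values = np.asarray(cell_values, dtype=float).ravel()
    truth = np.asarray(truth_positive, dtype=bool).ravel()
    if len(values) != len(truth):
        raise ValueError("annotation must cover all cells")
    called = values > threshold
    out = np.where(called & truth, "TP",
          np.where(called & ~truth, "FP",
          np.where(~called & truth, "FN", "TN")))
    return out.astype(object)
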