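"""Autofluorescence (AF) subtraction from blank-channel acquisitions.

Residual tissue autofluorescence after quenching is strongest in the AF488 /
AF555 / AF647 channels and varies across staining rounds.  Two algorithms
remove it using registered blank (unstained) acquisitions:

- *baseline*: one blank per channel, linearly scaled by the ratio of marker
  to blank exposure time, is subtracted from every round.  Best practice is
  to acquire this blank after three or four quench rounds, near the AF
  intensity minimum, which avoids over-subtraction.
- *scaled* (interpolated): blanks acquired early and late in the experiment
  are exposure-scaled and linearly interpolated in round index, modelling a
  linear AF drift over rounds.

DAPI and the AF750 channel pass through uncorrected by default (AF750
autofluorescence is minimal).  Negative differences are clamped to zero
unless a signed float output is requested for diagnostics.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from cyclicproc.imgmeta_io import ImageMeta, RoundStack

#: fluors corrected by default
DEFAULT_CORRECTED_FLUORS = frozenset({"AF488", "AF555", "AF647"})


@dataclass
class BackgroundSet:
    """Registered blank acquisitions for one channel.

    ``early_blank`` at round ``r_e`` is mandatory; ``late_blank`` at round
    ``r_l > r_e`` enables the interpolated (scaled) algorithm.
    """

    early_blank: np.ndarray
    early_meta: ImageMeta
    late_blank: np.ndarray | None = None
    late_meta: ImageMeta | None = None

    def __post_init__(self) -> None:
        if (self.late_blank is None) != (self.late_meta is None):
            raise ValueError("late blank raster and metadata must come together")
        if self.late_meta is not None and \
                self.late_meta.round_index <= self.early_meta.round_index:
            raise ValueError("late blank round must be after early blank round")
        if self.early_meta.round_index == 0:
            warnings.warn(
                "baseline blank is the round-0 (pre-quench) acquisition; "
                "pre-quench autofluorescence is brighter and risks "
                "over-subtraction", stacklevel=2)

    @property
    def r_early(self) -> int:
        return self.early_meta.round_index

    @property
    def r_late(self) -> int | None:
        return None if self.late_meta is None else self.late_meta.round_index


def scale_background(blank: np.ndarray, blank_exposure_ms: float,
                     target_exposure_ms: float) -> np.ndarray:
    """Scale a blank raster linearly to the target exposure time.

    Camera counts are proportional to integration time, so a blank acquired
    at ``blank_exposure_ms`` predicts the AF of a marker image acquired at
    ``target_exposure_ms`` after multiplication by the exposure ratio.
    Returns a real-valued raster (no clipping, no integer cast).
    """
    if blank_exposure_ms <= 0 or target_exposure_ms <= 0:
        raise ValueError("exposure times must be positive")
    return blank.astype(float) * (target_exposure_ms / blank_exposure_ms)


def _finalize(diff: np.ndarray, clamp: bool, dtype) -> np.ndarray:
    if not clamp:
        return diff
    out = np.clip(diff, 0, None)
    if np.issubdtype(dtype, np.integer):
        out = np.clip(np.rint(out), 0, np.iinfo(dtype).max).astype(dtype)
    return out


def subtract_baseline(marker_img: np.ndarray, baseline_blank: np.ndarray,
                      marker_exposure_ms: float, blank_exposure_ms: float,
                      clamp: bool = True) -> np.ndarray:
    """Baseline algorithm: subtract one exposure-scaled blank.

    ``clamp=False`` returns the signed floating-point difference for
    diagnostics; otherwise negatives are clamped to 0 and the result is cast
    back to the marker dtype.
    """
    if marker_img.shape != baseline_blank.shape:
        raise ValueError(
            f"shape mismatch: marker {marker_img.shape} vs blank {baseline_blank.shape}")
    af = scale_background(baseline_blank, blank_exposure_ms, marker_exposure_ms)
    diff = marker_img.astype(float) - af
    return _finalize(diff, clamp, marker_img.dtype)


def subtract_interpolated(marker_img: np.ndarray, round_index: int,
                          bg: BackgroundSet, marker_exposure_ms: float,
                          clamp: bool = True) -> np.ndarray:
    """Scaled algorithm: subtract AF linearly interpolated between blanks.

    Each blank is exposure-scaled to the marker exposure; the AF estimate at
    round ``r`` is ``(1-w)*B_early + w*B_late`` with
    ``w = (r - r_e)/(r_l - r_e)`` clamped to [0, 1] (no extrapolation, which
    risks over-subtraction outside the observed blank rounds).
    """
    if bg.late_blank is None:
        raise ValueError(
            "interpolated subtraction needs a late blank; "
            "use the baseline algorithm with a single blank")
    if marker_img.shape != bg.early_blank.shape:
        raise ValueError("shape mismatch between marker image and blanks")
    b_e = scale_background(bg.early_blank, bg.early_meta.exposure_ms, marker_exposure_ms)
    b_l = scale_background(bg.late_blank, bg.late_meta.exposure_ms, marker_exposure_ms)
    w = (round_index - bg.r_early) / (bg.r_late - bg.r_early)
    w = min(max(w, 0.0), 1.0)
    af = (1.0 - w) * b_e + w * b_l
    diff = marker_img.astype(float) - af
    return _finalize(diff, clamp, marker_img.dtype)


def correct_stack(stack: RoundStack,
                  backgrounds: dict[str, BackgroundSet],
                  algorithm: str = "baseline",
                  corrected_fluors: frozenset[str] = DEFAULT_CORRECTED_FLUORS,
                  clamp: bool = True) -> RoundStack:
    """Apply AF subtraction to every marker acquisition of a registered stack.

    ``backgrounds`` maps channel name (c2..c5) to its :class:`BackgroundSet`.
    Channels whose fluor is outside ``corrected_fluors`` (DAPI and AF750 by
    default) and blank acquisitions pass through unchanged.
    """
    if algorithm not in ("baseline", "scaled"):
        raise ValueError(f"unknown algorithm {algorithm!r}")
    images: dict[tuple[int, str], np.ndarray] = {}
    for key, img in stack.images.items():
        r, channel = key
        meta = stack.meta[key]
        if meta.is_blank or meta.fluor not in corrected_fluors or channel not in backgrounds:
            images[key] = img
            continue
        bg = backgrounds[channel]
        if algorithm == "baseline":
            images[key] = subtract_baseline(
                img, bg.early_blank, meta.exposure_ms,
                bg.early_meta.exposure_ms, clamp=clamp)
        else:
            images[key] = subtract_interpolated(
                img, r, bg, meta.exposure_ms, clamp=clamp)
    return stack.copy_with(images)


def backgrounds_from_stack(stack: RoundStack) -> dict[str, BackgroundSet]:
    """Collect per-channel blank acquisitions of a stack into BackgroundSets.

    The earliest blank per channel becomes the early/baseline blank, the
    latest (if distinct) the late blank.
    """
    per_channel: dict[str, list[tuple[int, str]]] = {}
    for key, meta in stack.meta.items():
        if meta.is_blank and meta.channel != "DAPI":
            per_channel.setdefault(meta.channel, []).append(key)
    out: dict[str, BackgroundSet] = {}
    for channel, keys in per_channel.items():
        keys.sort()
        early = keys[0]
        late = keys[-1] if keys[-1][0] > early[0] else None
        out[channel] = BackgroundSet(
            early_blank=stack.images[early], early_meta=stack.meta[early],
            late_blank=None if late is None else stack.images[late],
            late_meta=None if late is None else stack.meta[late],
        )
    return out
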