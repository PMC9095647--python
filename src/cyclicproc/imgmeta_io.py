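"""Image, mask and cell-table I/O plus experiment metadata.

Images are single-channel unsigned 16-bit grayscale TIFFs, one file per
(round, channel) acquisition of a scene.  All experiment metadata — slide,
scene, staining round, marker, fluorescence channel and camera exposure —
is carried in the filename using the convention

    {slide}_{scene}_R{round}_{marker}_{channel}_{exposure}ms.tif

e.g. ``S1_scene01_R2_CK19_c5_100ms.tif``.  Round 0 denotes a pre-staining
acquisition; marker ``blank`` denotes an unstained autofluorescence
background acquisition (allowed in any round).  The template is configurable
through :func:`parse_filename`'s ``template`` argument.

Cell tables are plain CSV with a header row; ``cell_id`` is mandatory.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
import tifffile

#: channels of the imaging panel; c1 is reserved for DAPI
CHANNELS = ("DAPI", "c2", "c3", "c4", "c5")

#: conventional fluor label per non-DAPI channel
CHANNEL_FLUORS = {"DAPI": "DAPI", "c2": "AF488", "c3": "AF555", "c4": "AF647", "c5": "AF750"}

DEFAULT_PIXEL_SIZE_UM = 0.325  # 20x scan

DEFAULT_TEMPLATE = "{slide}_{scene}_R{round}_{marker}_{channel}_{exposure}ms.tif"

_FILENAME_RE = re.compile(
    r"^(?P<slide>[^_]+)_(?P<scene>[^_]+)_R(?P<round>\d+)_"
    r"(?P<marker>[^_]+)_(?P<channel>DAPI|c[2-5])_(?P<exposure>\d+(?:\.\d+)?)ms\.tiff?$"
)


class FilenameParseError(ValueError):
    """Raised when an image filename does not match the naming convention."""


@dataclass(frozen=True)
class ImageMeta:
    """Metadata of one single-channel acquisition."""

    slide_id: str
    scene_id: str
    round_index: int
    channel: str
    marker: str
    exposure_ms: float
    pixel_size_um: float = DEFAULT_PIXEL_SIZE_UM

    def __post_init__(self) -> None:
        if self.channel not in CHANNELS:
            raise ValueError(f"unknown channel {self.channel!r}; expected one of {CHANNELS}")
        if self.exposure_ms <= 0:
            raise ValueError(f"exposure_ms must be positive, got {self.exposure_ms}")
        if self.round_index < 0:
            raise ValueError(f"round_index must be >= 0, got {self.round_index}")
        if self.pixel_size_um <= 0:
            raise ValueError("pixel_size_um must be positive")

    @property
    def fluor(self) -> str:
        return CHANNEL_FLUORS[self.channel]

    @property
    def is_blank(self) -> bool:
        return self.marker == "blank"


def parse_filename(name: str, template: str = DEFAULT_TEMPLATE,
                   pixel_size_um: float = DEFAULT_PIXEL_SIZE_UM) -> ImageMeta:
    """Parse experiment metadata out of an image filename.

    Parameters
    ----------
    name
        Basename (or path; only the final component is used).
    template
        Filename template.  Only the default template is compiled to a strict
        regex; custom templates are converted field-by-field.

    Raises
    ------
    FilenameParseError
        If the name does not match, naming the first missing field.
    """
    base = Path(name).name
    if template == DEFAULT_TEMPLATE:
        rx = _FILENAME_RE
    else:
        rx = _compile_template(template)
    m = rx.match(base)
    if m is None:
        _diagnose(base, rx)
        raise FilenameParseError(f"filename {base!r} does not match template {template!r}")
    d = m.groupdict()
    return ImageMeta(
        slide_id=d["slide"],
        scene_id=d["scene"],
        round_index=int(d["round"]),
        channel=d["channel"],
        marker=d["marker"],
        exposure_ms=float(d["exposure"]),
        pixel_size_um=pixel_size_um,
    )


def _compile_template(template: str) -> re.Pattern:
    pats = {
        "{slide}": r"(?P<slide>[^_]+)",
        "{scene}": r"(?P<scene>[^_]+)",
        "{round}": r"(?P<round>\d+)",
        "{marker}": r"(?P<marker>[^_]+)",
        "{channel}": r"(?P<channel>DAPI|c[2-5])",
        "{exposure}": r"(?P<exposure>\d+(?:\.\d+)?)",
    }
    out = re.escape(template)
    for k, v in pats.items():
        out = out.replace(re.escape(k), v)
    return re.compile("^" + out + "$")


def _diagnose(base: str, rx: re.Pattern) -> None:
    """Raise a parse error naming the specific missing token where detectable."""
    if not re.search(r"_R\d+_", base):
        raise FilenameParseError(f"filename {base!r}: missing round token '_R<n>_'")
    if not re.search(r"_(DAPI|c[2-5])[_.]", base):
        raise FilenameParseError(f"filename {base!r}: missing channel token")
    if not re.search(r"\d+(\.\d+)?ms\.", base):
        raise FilenameParseError(f"filename {base!r}: missing exposure token '<n>ms'")


def format_filename(meta: ImageMeta, template: str = DEFAULT_TEMPLATE) -> str:
    """Inverse of :func:`parse_filename` (exact round-trip)."""
    exposure = meta.exposure_ms
    exp_str = str(int(exposure)) if float(exposure).is_integer() else str(exposure)
    return template.format(
        slide=meta.slide_id,
        scene=meta.scene_id,
        round=meta.round_index,
        marker=meta.marker,
        channel=meta.channel,
        exposure=exp_str,
    )


@dataclass
class RoundStack:
    """A pile of single-channel rasters keyed by (round_index, channel).

    Before registration the rasters may have unequal shapes (``shape`` is
    ``None``); after registration all rasters share one shape.
    """

    images: dict[tuple[int, str], np.ndarray] = field(default_factory=dict)
    meta: dict[tuple[int, str], ImageMeta] = field(default_factory=dict)

    @property
    def rounds(self) -> list[int]:
        return sorted({r for r, _ in self.images})

    @property
    def shape(self) -> tuple[int, int] | None:
        shapes = {im.shape for im in self.images.values()}
        return shapes.pop() if len(shapes) == 1 else None

    def __len__(self) -> int:
        return len(self.images)

    def channels_in_round(self, round_index: int) -> list[str]:
        return sorted(c for r, c in self.images if r == round_index)

    def get(self, round_index: int, channel: str) -> np.ndarray:
        return self.images[(round_index, channel)]

    def marker_keys(self) -> list[tuple[int, str]]:
        """Keys of non-blank, non-DAPI acquisitions."""
        return sorted(
            k for k, m in self.meta.items() if not m.is_blank and m.channel != "DAPI"
        )

    def copy_with(self, images: Mapping[tuple[int, str], np.ndarray]) -> "RoundStack":
        return RoundStack(images=dict(images), meta=dict(self.meta))


def assemble_stack(files: Iterable[str | Path],
                   template: str = DEFAULT_TEMPLATE,
                   pixel_size_um: float = DEFAULT_PIXEL_SIZE_UM) -> RoundStack:
    """Load image files of one scene into a :class:`RoundStack`.

    The result is independent of file ordering.  Every round must contain a
    DAPI acquisition; duplicate (round, channel) keys and mixed scenes are
    errors.
    """
    entries = []
    for f in files:
        meta = parse_filename(str(f), template=template, pixel_size_um=pixel_size_um)
        entries.append((Path(f), meta))
    if not entries:
        raise ValueError("no input files")
    # canonical ordering makes assembly order-independent
    entries.sort(key=lambda e: (e[1].round_index, e[1].channel, e[0].name))

    scenes = {(m.slide_id, m.scene_id) for _, m in entries}
    if len(scenes) > 1:
        raise ValueError(f"inputs span multiple scenes: {sorted(scenes)}")

    stack = RoundStack()
    for path, meta in entries:
        key = (meta.round_index, meta.channel)
        if key in stack.images:
            raise ValueError(f"duplicate acquisition for round {key[0]}, channel {key[1]}")
        stack.images[key] = read_image(path)
        stack.meta[key] = meta

    for r in stack.rounds:
        if (r, "DAPI") not in stack.images:
            raise ValueError(f"round {r} has no DAPI image")
    return stack


def read_image(path: str | Path) -> np.ndarray:
    """Read a single-channel TIFF raster."""
    arr = tifffile.imread(str(path))
    if arr.ndim != 2:
        raise ValueError(f"{path}: expected a 2-D single-channel raster, got shape {arr.shape}")
    return arr


def write_image(path: str | Path, image: np.ndarray) -> None:
    """Write an uncompressed grayscale TIFF (uint16 for intensity, int32 for labels)."""
    image = np.asarray(image)
    if image.dtype not in (np.uint16, np.int32, np.uint8, np.uint32):
        if np.issubdtype(image.dtype, np.integer):
            image = image.astype(np.int32)
        else:
            image = np.clip(np.rint(image), 0, np.iinfo(np.uint16).max).astype(np.uint16)
    tifffile.imwrite(str(path), image)


MANDATORY_CELL_COLUMNS = ("cell_id",)


def write_cell_table(table: pd.DataFrame, path: str | Path) -> None:
    """Write a cell table as CSV (lossless round-trip at float precision)."""
    if len(table) == 0:
        raise ValueError("refusing to write an empty cell table")
    for col in MANDATORY_CELL_COLUMNS:
        if col not in table.columns:
            raise ValueError(f"cell table lacks mandatory column {col!r}")
    table.to_csv(path, index=False, float_format="%.12g")


def read_cell_table(path: str | Path) -> pd.DataFrame:
    """Read a cell table CSV; validates mandatory columns."""
    table = pd.read_csv(path)
    missing = [c for c in MANDATORY_CELL_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"cell table {path} is missing mandatory columns: {missing}")
    return table
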