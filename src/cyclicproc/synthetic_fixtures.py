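"""Synthetic multi-round image and cell-table generators with ground truth.

Everything downstream of the microscope is testable against these fixtures:

- :func:`simulate_image_experiment` builds a multi-round, multi-channel scene
  of non-overlapping nuclei with per-round registration jitter, tissue loss,
  shot + read noise, and an autofluorescence field (diffuse background plus
  bright curvilinear fibers) whose intensity follows a per-round multiplier
  v(r) — by default declining to a minimum at round 3–4 and rising
  afterwards, the dynamic observed for quenched tissue autofluorescence.
  Blank (unstained) acquisitions are emitted at configurable rounds.
- :func:`simulate_cell_table` builds a per-cell intensity table with planted
  cell types, mutually exclusive marker pairs (exclusive markers are never
  co-high in one cell), known background thresholds, and per-batch
  gain/offset batch effects.

All outputs are fully determined by (config, seed).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage as ndi

from cyclicproc.imgmeta_io import ImageMeta, RoundStack
from cyclicproc.segmentation import LabelMask


def default_af_profile(rounds: tuple[int, ...]) -> dict[int, float]:
    """Piecewise-linear per-round AF multiplier: decline to a minimum at
    round 3–4, then rise (normalized so round 1 = 1)."""
    out = {}
    for r in rounds:
        if r <= 1:
            out[r] = 1.0
        elif r <= 4:
            out[r] = 1.0 - 0.15 * (r - 1)      # down to 0.55 at round 4
        else:
            out[r] = 0.55 + 0.1 * (r - 4)      # recovery in later rounds
    return out


@dataclass
class SimImageConfig:
    """Study conditions for the synthetic multi-round image experiment."""

    shape: tuple[int, int] = (512, 512)
    n_cells: int = 150
    nucleus_radius_px: tuple[float, float] = (6.0, 10.0)
    rounds: tuple[int, ...] = (1, 2, 3)
    channels: tuple[str, ...] = ("c2", "c3")
    markers: dict[tuple[int, str], str] = field(default_factory=dict)
    exposure_ms: dict[str, float] = field(default_factory=dict)
    signal_intensity: float = 3000.0
    dapi_intensity: float = 8000.0
    positive_fraction: float = 0.4
    af_diffuse: float = 300.0
    af_fiber: float = 6000.0
    n_fibers: int = 6
    af_profile: dict[int, float] | None = None
    blank_rounds: tuple[int, ...] = (0,)
    max_shift_px: float = 8.0
    max_rotation_deg: float = 2.0
    retention_schedule: dict[int, float] | None = None
    gaussian_noise_sd: float = 2.0
    poisson_noise: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.markers:
            names = ["CK19", "CD45", "Ki67", "Ecad", "Vim", "CD8", "HER2", "CD4"]
            i = 0
            for r in self.rounds:
                for c in self.channels:
                    self.markers[(r, c)] = names[i % len(names)] + (
                        "" if i < len(names) else f"_{i}")
                    i += 1
        if not self.exposure_ms:
            self.exposure_ms = {"DAPI": 20.0, "c2": 100.0, "c3": 80.0,
                                "c4": 150.0, "c5": 200.0}
        if self.af_profile is None:
            self.af_profile = default_af_profile(
                tuple(sorted(set(self.rounds) | set(self.blank_rounds))))
        if self.retention_schedule is None:
            self.retention_schedule = {r: 1.0 for r in self.rounds}
        fracs = [self.retention_schedule[r] for r in sorted(self.retention_schedule)]
        if any(b > a + 1e-12 for a, b in zip(fracs, fracs[1:])):
            raise ValueError("retention schedule must be non-increasing")
        if any(v <= 0 for v in self.af_profile.values()):
            raise ValueError("AF multipliers must be positive")


@dataclass
class SimImageTruth:
    """Ground truth returned alongside the simulated stack."""

    nuclei: LabelMask
    centers: np.ndarray                      # (n, 2) row, col
    radii: np.ndarray
    positive_cells: dict[str, np.ndarray]    # marker -> bool per cell
    signal: dict[tuple[int, str], np.ndarray]  # clean signal rasters
    af_field: np.ndarray                     # unit AF field (round multiplier applies)
    transforms: dict[int, tuple[float, float, float]]  # round -> (dy, dx, rot_deg)
    retained: dict[int, np.ndarray]          # round -> bool per cell


def _place_nuclei(cfg: SimImageConfig, rng: np.random.Generator
                  ) -> tuple[np.ndarray, np.ndarray]:
    """Rejection-sample non-overlapping nucleus centers (margin 4 px)."""
    h, w = cfg.shape
    rmin, rmax = cfg.nucleus_radius_px
    margin = int(math.ceil(rmax)) + 12
    centers, radii = [], []
    attempts = 0
    while len(centers) < cfg.n_cells:
        attempts += 1
        if attempts > cfg.n_cells * 400:
            raise ValueError(
                f"could not place {cfg.n_cells} non-overlapping nuclei in "
                f"{cfg.shape}")
        r = rng.uniform(rmin, rmax)
        cy = rng.uniform(margin, h - margin)
        cx = rng.uniform(margin, w - margin)
        ok = True
        for (oy, ox), orr in zip(centers, radii):
            if (cy - oy) ** 2 + (cx - ox) ** 2 < (r + orr + 4) ** 2:
                ok = False
                break
        if ok:
            centers.append((cy, cx))
            radii.append(r)
    return np.array(centers), np.array(radii)


def _nucleus_stamp(shape, centers, radii, values) -> np.ndarray:
    """Render soft-edged disks of the given per-cell peak values."""
    h, w = shape
    img = np.zeros(shape, dtype=float)
    yy, xx = np.mgrid[0:h, 0:w]
    for (cy, cx), r, v in zip(centers, radii, values):
        if v == 0:
            continue
        y0, y1 = int(max(cy - r - 4, 0)), int(min(cy + r + 5, h))
        x0, x1 = int(max(cx - r - 4, 0)), int(min(cx + r + 5, w))
        d = np.sqrt((yy[y0:y1, x0:x1] - cy) ** 2 + (xx[y0:y1, x0:x1] - cx) ** 2)
        img[y0:y1, x0:x1] += v / (1.0 + np.exp((d - r) * 2.0))
    return img


def _nucleus_labels(shape, centers, radii) -> np.ndarray:
    h, w = shape
    labels = np.zeros(shape, dtype=np.int32)
    yy, xx = np.mgrid[0:h, 0:w]
    for i, ((cy, cx), r) in enumerate(zip(centers, radii), start=1):
        d2 = (yy - cy) ** 2 + (xx - cx) ** 2
        labels[(d2 <= r**2) & (labels == 0)] = i
    return labels


def _af_field(cfg: SimImageConfig, rng: np.random.Generator) -> np.ndarray:
    """Diffuse smooth field plus bright curvilinear fibers, unit amplitude."""
    h, w = cfg.shape
    diffuse = ndi.gaussian_filter(rng.random((h, w)), 40)
    diffuse = (diffuse - diffuse.min()) / max(np.ptp(diffuse), 1e-12)
    field = cfg.af_diffuse * (0.5 + diffuse)
    fibers = np.zeros((h, w))
    for _ in range(cfg.n_fibers):
        y = rng.uniform(0, h)
        x = rng.uniform(0, w)
        ang = rng.uniform(0, 2 * np.pi)
        for _ in range(rng.integers(100, 300)):
            iy, ix = int(y), int(x)
            if 0 <= iy < h and 0 <= ix < w:
                fibers[iy, ix] = 1.0
            ang += rng.normal(0, 0.15)
            y += math.sin(ang)
            x += math.cos(ang)
    fibers = ndi.gaussian_filter(fibers, 1.5)
    if fibers.max() > 0:
        fibers /= fibers.max()
    return field + cfg.af_fiber * fibers


def _jitter(img: np.ndarray, dy: float, dx: float, rot_deg: float) -> np.ndarray:
    out = img
    if rot_deg != 0:
        out = ndi.rotate(out, rot_deg, reshape=False, order=1, mode="constant")
    if dy != 0 or dx != 0:
        out = ndi.shift(out, (dy, dx), order=1, mode="constant")
    return out


def _to_u16(img: np.ndarray) -> np.ndarray:
    return np.clip(np.rint(img), 0, 65535).astype(np.uint16)


def simulate_image_experiment(cfg: SimImageConfig
                              ) -> tuple[RoundStack, SimImageTruth]:
    """Simulate one scene across rounds; returns the raw (jittered) stack and
    the full ground truth (masks, clean signal, AF field, transforms,
    retention)."""
    rng = np.random.default_rng(cfg.seed)
    centers, radii = _place_nuclei(cfg, rng)
    n = len(centers)
    labels = LabelMask(_nucleus_labels(cfg.shape, centers, radii), "nucleus")
    af_unit = _af_field(cfg, rng)

    all_rounds = sorted(set(cfg.rounds) | set(cfg.blank_rounds))
    # tissue loss: which cells remain at each round (non-increasing sets)
    retained: dict[int, np.ndarray] = {}
    alive = np.ones(n, dtype=bool)
    order = rng.permutation(n)
    for r in all_rounds:
        target = cfg.retention_schedule.get(r, 1.0)
        n_keep = int(round(target * n))
        while alive.sum() > n_keep:
            alive[order[int(alive.sum()) - 1]] = False
        retained[r] = alive.copy()

    positive: dict[str, np.ndarray] = {}
    for marker in set(cfg.markers.values()):
        positive[marker] = rng.random(n) < cfg.positive_fraction

    transforms: dict[int, tuple[float, float, float]] = {}
    for r in all_rounds:
        if r == min(r2 for r2 in cfg.rounds):
            transforms[r] = (0.0, 0.0, 0.0)
        else:
            transforms[r] = (
                float(rng.uniform(-cfg.max_shift_px, cfg.max_shift_px)),
                float(rng.uniform(-cfg.max_shift_px, cfg.max_shift_px)),
                float(rng.uniform(-cfg.max_rotation_deg, cfg.max_rotation_deg)),
            )

    stack = RoundStack()
    signal_truth: dict[tuple[int, str], np.ndarray] = {}

    def add_noise(img: np.ndarray) -> np.ndarray:
        out = img
        if cfg.poisson_noise:
            out = rng.poisson(np.clip(out, 0, None)).astype(float)
        if cfg.gaussian_noise_sd > 0:
            out = out + rng.normal(0, cfg.gaussian_noise_sd, img.shape)
        return out

    slide, scene = "SIM", "scene01"
    for r in all_rounds:
        dy, dx, rot = transforms[r]
        v = cfg.af_profile.get(r, 1.0)
        is_blank_round = r in cfg.blank_rounds and r not in cfg.rounds

        # DAPI: retained nuclei only
        dapi_vals = np.where(retained[r], cfg.dapi_intensity, 0.0)
        dapi = _nucleus_stamp(cfg.shape, centers, radii, dapi_vals) + 100.0
        img = _to_u16(add_noise(_jitter(dapi, dy, dx, rot)))
        stack.images[(r, "DAPI")] = img
        stack.meta[(r, "DAPI")] = ImageMeta(slide, scene, r, "DAPI", "DAPI",
                                            cfg.exposure_ms["DAPI"])
        for c in cfg.channels:
            exposure = cfg.exposure_ms[c]
            exposure_scale = exposure / 100.0
            af = af_unit * v * exposure_scale
            if is_blank_round or (r, c) not in cfg.markers:
                marker = "blank"
                clean = np.zeros(cfg.shape)
            else:
                marker = cfg.markers[(r, c)]
                vals = np.where(positive[marker] & retained[r],
                                cfg.signal_intensity * exposure_scale, 0.0)
                clean = _nucleus_stamp(cfg.shape, centers, radii, vals)
            signal_truth[(r, c)] = clean
            img = _to_u16(add_noise(_jitter(clean + af, dy, dx, rot)))
            stack.images[(r, c)] = img
            stack.meta[(r, c)] = ImageMeta(slide, scene, r, c, marker, exposure)

    truth = SimImageTruth(nuclei=labels, centers=centers, radii=radii,
                          positive_cells=positive, signal=signal_truth,
                          af_field=af_unit, transforms=transforms,
                          retained=retained)
    return stack, truth


# ------------------------------------------------------------- cell tables

@dataclass
class SimTableConfig:
    """Study conditions for the synthetic cell table.

    Defaults mirror the batch-evaluation design: 3 TMA cores × 3 replicate
    batches with 1000 cells each.  Markers come in lineage groups
    (epithelial: CK19, Ecad; immune/stromal: CD45, Vim); a cell expresses
    the markers of its own lineage — co-expressed through a shared per-cell
    staining factor — and only background for the other lineage, so every
    cross-lineage pair is mutually exclusive.  Intensities are lognormal and
    heavy-tailed (signal sigma 0.8 on the log scale, typical of the
    decades-wide dynamic range of immunofluorescence staining); batch
    effects are a per-batch multiplicative gain plus additive offset.
    """

    n_cells_per_group: int = 1000
    cores: tuple[str, ...] = ("core1", "core2", "core3")
    batches: tuple[str, ...] = ("batch1", "batch2", "batch3")
    marker_groups: tuple[tuple[str, ...], ...] = (("CK19", "Ecad"),
                                                  ("CD45", "Vim"))
    lineage_fractions: tuple[float, ...] | None = None
    background_mean: float = 50.0
    background_sigma: float = 0.3   # lognormal sd on log scale
    signal_mean: float = 800.0
    signal_sigma: float = 0.8
    coexpression_noise: float = 0.25  # within-lineage residual log-sd
    batch_gain: dict[str, float] | None = None
    batch_offset: dict[str, float] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.lineage_fractions is None:
            k = len(self.marker_groups)
            self.lineage_fractions = tuple([1.0 / k] * k)
        if abs(sum(self.lineage_fractions) - 1.0) > 1e-9:
            raise ValueError("lineage fractions must sum to 1")
        if self.batch_gain is None:
            gains = [1.0, 1.6, 0.7]
            self.batch_gain = {b: gains[i % 3] for i, b in enumerate(self.batches)}
        if self.batch_offset is None:
            offs = [0.0, 20.0, 10.0]
            self.batch_offset = {b: offs[i % 3] for i, b in enumerate(self.batches)}
        if any(g <= 0 for g in self.batch_gain.values()):
            raise ValueError("batch gains must be positive")

    @property
    def markers(self) -> tuple[str, ...]:
        return tuple(m for grp in self.marker_groups for m in grp)

    @property
    def exclusive_pairs(self) -> tuple[tuple[str, str], ...]:
        out = []
        for i, ga in enumerate(self.marker_groups):
            for gb in self.marker_groups[i + 1:]:
                out.extend((a, b) for a in ga for b in gb)
        return tuple(out)


@dataclass
class SimTableTruth:
    cell_type: np.ndarray                 # lineage index per cell
    thresholds: dict[str, float]          # background thresholds, pre-batch-effect
    batch_gain: dict[str, float]
    batch_offset: dict[str, float]
    exclusive_pairs: tuple[tuple[str, str], ...]

    def threshold_in_batch(self, marker: str, batch: str) -> float:
        """Background threshold after the batch's gain/offset."""
        return (self.thresholds[marker] * self.batch_gain[batch]
                + self.batch_offset[batch])


def simulate_cell_table(cfg: SimTableConfig
                        ) -> tuple[pd.DataFrame, SimTableTruth]:
    """Simulate a per-cell intensity table with planted structure.

    Exclusivity is planted through lineages: a cell is high only in its own
    lineage's markers, so cross-lineage markers are never co-high in one
    cell, while same-lineage markers are strongly co-expressed.  The true
    background threshold per marker is the 99.5th percentile of its
    (pre-batch-effect) background lognormal; in batch ``b`` the effective
    threshold is ``threshold_in_batch(marker, b)``.
    """
    rng = np.random.default_rng(cfg.seed)
    n_lineages = len(cfg.marker_groups)
    lineage_of = {m: g for g, grp in enumerate(cfg.marker_groups) for m in grp}
    rows = []
    types_all = []
    cell_id = 0
    for batch in cfg.batches:
        for core in cfg.cores:
            n = cfg.n_cells_per_group
            ctype = rng.choice(n_lineages, size=n, p=cfg.lineage_fractions)
            types_all.append(ctype)
            # shared per-cell staining factor drives within-lineage co-expression
            factor = rng.lognormal(np.log(cfg.signal_mean), cfg.signal_sigma, n)
            data = {}
            for m in cfg.markers:
                own = ctype == lineage_of[m]
                signal = factor * rng.lognormal(0.0, cfg.coexpression_noise, n)
                background = rng.lognormal(np.log(cfg.background_mean),
                                           cfg.background_sigma, n)
                base = np.where(own, signal, background)
                data[m] = (base * cfg.batch_gain[batch]
                           + cfg.batch_offset[batch])
            df = pd.DataFrame(data)
            df.insert(0, "cell_id", np.arange(cell_id, cell_id + n))
            df.insert(1, "slide_id", batch)
            df.insert(2, "scene_id", "scene01")
            df.insert(3, "core_id", core)
            df.insert(4, "batch_id", batch)
            cell_id += n
            rows.append(df)
    table = pd.concat(rows, ignore_index=True)

    # true background threshold: 99.5th percentile of the background lognormal
    z995 = 2.5758293035489004  # Phi^{-1}(0.995)
    thresholds = {
        m: float(np.exp(np.log(cfg.background_mean)
                        + z995 * cfg.background_sigma))
        for m in cfg.markers
    }
    truth = SimTableTruth(cell_type=np.concatenate(types_all),
                          thresholds=thresholds,
                          batch_gain=dict(cfg.batch_gain),
                          batch_offset=dict(cfg.batch_offset),
                          exclusive_pairs=cfg.exclusive_pairs)
    return table, truth
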