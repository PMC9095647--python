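"""DAPI-based affine registration of cyclic staining rounds.

Each round is aligned to the reference round (round 1 by default, falling
back to the earliest stained round present) by estimating a planar affine
transform between the two DAPI images and applying it to every channel of
the moving round.  Estimation follows the classic keypoint pipeline:
scale/rotation-invariant local features (ORB), descriptor matching, and a
RANSAC consensus affine fit, followed by a sub-pixel translation refinement
via upsampled phase correlation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage import transform as sktransform
from skimage.feature import ORB, match_descriptors
from skimage.measure import ransac
from skimage.registration import phase_cross_correlation

from cyclicproc.imgmeta_io import RoundStack


class RegistrationError(RuntimeError):
    """Raised when a reliable transform cannot be estimated."""


@dataclass(frozen=True)
class AffineTransform:
    """Planar affine transform mapping moving-image coordinates (x, y) into
    the reference frame: ``[x', y'] = [[a, b], [c, d]] @ [x, y] + [tx, ty]``.

    ``residual_rms`` is the RMS keypoint mismatch after the fit, in pixels.
    """

    a: float
    b: float
    c: float
    d: float
    tx: float
    ty: float
    residual_rms: float = 0.0
    n_inliers: int = 0

    def __post_init__(self) -> None:
        if abs(self.a * self.d - self.b * self.c) < 1e-12:
            raise ValueError("singular linear part")
        if self.residual_rms < 0:
            raise ValueError("residual_rms must be >= 0")

    @classmethod
    def identity(cls) -> "AffineTransform":
        return cls(1.0, 0.0, 0.0, 1.0, 0.0, 0.0)

    @property
    def matrix(self) -> np.ndarray:
        """3x3 homogeneous matrix acting on (x, y, 1) column vectors."""
        return np.array(
            [[self.a, self.b, self.tx], [self.c, self.d, self.ty], [0.0, 0.0, 1.0]]
        )

    def apply(self, xy: np.ndarray) -> np.ndarray:
        """Map an (n, 2) array of (x, y) points into the reference frame."""
        xy = np.atleast_2d(np.asarray(xy, dtype=float))
        lin = np.array([[self.a, self.b], [self.c, self.d]])
        return xy @ lin.T + np.array([self.tx, self.ty])

    def inverse(self) -> "AffineTransform":
        inv = np.linalg.inv(self.matrix)
        return AffineTransform(inv[0, 0], inv[0, 1], inv[1, 0], inv[1, 1],
                               inv[0, 2], inv[1, 2],
                               residual_rms=self.residual_rms, n_inliers=self.n_inliers)

    @classmethod
    def from_matrix(cls, m: np.ndarray, residual_rms: float = 0.0,
                    n_inliers: int = 0) -> "AffineTransform":
        return cls(m[0, 0], m[0, 1], m[1, 0], m[1, 1], m[0, 2], m[1, 2],
                   residual_rms=residual_rms, n_inliers=n_inliers)


def _detect(image: np.ndarray, n_keypoints: int) -> tuple[np.ndarray, np.ndarray]:
    orb = ORB(n_keypoints=n_keypoints, fast_threshold=0.05)
    img = image.astype(float)
    rng = np.ptp(img)
    if rng == 0:
        raise RegistrationError("image has zero dynamic range; no features found")
    orb.detect_and_extract(img / rng)
    return orb.keypoints, orb.descriptors


def estimate_affine(reference: np.ndarray, moving: np.ndarray,
                    min_matches: int = 10, n_keypoints: int = 800,
                    inlier_tol_px: float = 2.0,
                    max_residual_rms: float = 5.0,
                    refine_translation: bool = True) -> AffineTransform:
    """Estimate the affine transform taking ``moving`` onto ``reference``.

    ORB keypoints are matched between the two DAPI rasters and an affine
    model is fitted by RANSAC (inlier tolerance ``inlier_tol_px``).  A final
    sub-pixel translation correction is obtained by phase correlation between
    the reference and the warped moving image.

    Raises
    ------
    RegistrationError
        If fewer than ``min_matches`` consistent correspondences are found or
        the post-fit residual exceeds ``max_residual_rms`` pixels.
    """
    if reference.size == 0 or moving.size == 0:
        raise RegistrationError("empty raster")
    if reference.dtype != moving.dtype:
        raise RegistrationError(
            f"bit depth mismatch: {reference.dtype} vs {moving.dtype}")

    try:
        kp_ref, desc_ref = _detect(reference, n_keypoints)
        kp_mov, desc_mov = _detect(moving, n_keypoints)
    except (RuntimeError, RegistrationError) as exc:
        raise RegistrationError(f"feature detection failed: {exc}") from exc

    matches = match_descriptors(desc_mov, desc_ref, cross_check=True)
    if len(matches) < min_matches:
        raise RegistrationError(
            f"only {len(matches)} feature matches, need >= {min_matches}")

    # keypoints are (row, col); transforms act on (x, y) = (col, row)
    src = kp_mov[matches[:, 0]][:, ::-1]
    dst = kp_ref[matches[:, 1]][:, ::-1]

    model, inliers = ransac(
        (src, dst), sktransform.AffineTransform,
        min_samples=3, residual_threshold=inlier_tol_px,
        max_trials=2000, rng=0,
    )
    if model is None or inliers is None or int(inliers.sum()) < min_matches:
        n = 0 if inliers is None else int(inliers.sum())
        raise RegistrationError(
            f"only {n} consistent correspondences after consensus fit, "
            f"need >= {min_matches}")

    n_inliers = int(inliers.sum())
    # least-squares refit on the inlier set
    refit = sktransform.estimate_transform("affine", src[inliers], dst[inliers])
    residuals = np.linalg.norm(refit(src[inliers]) - dst[inliers], axis=1)
    residual_rms = float(np.sqrt(np.mean(residuals**2)))
    if residual_rms > max_residual_rms:
        raise RegistrationError(
            f"registration residual {residual_rms:.2f} px exceeds "
            f"{max_residual_rms} px")

    t = AffineTransform.from_matrix(refit.params, residual_rms=residual_rms,
                                    n_inliers=n_inliers)

    if refine_translation:
        warped = warp(moving, t, reference.shape)
        try:
            shift, _, _ = phase_cross_correlation(
                reference.astype(float), warped.astype(float),
                upsample_factor=20, normalization=None)
        except Exception:
            shift = np.zeros(2)
        # shift is (row, col) displacement of warped relative to reference
        m = t.matrix.copy()
        m[0, 2] += shift[1]
        m[1, 2] += shift[0]
        t = AffineTransform.from_matrix(m, residual_rms=residual_rms,
                                        n_inliers=n_inliers)
    return t


def warp(image: np.ndarray, t: AffineTransform,
         out_shape: tuple[int, int] | None = None) -> np.ndarray:
    """Resample ``image`` into the reference frame under transform ``t``.

    Bilinear interpolation; pixels mapping outside the input are filled with
    0; the input dtype is preserved.
    """
    out_shape = out_shape or image.shape
    inv = np.linalg.inv(t.matrix)  # reference (x,y) -> moving (x,y)
    sk_t = sktransform.AffineTransform(matrix=inv)
    warped = sktransform.warp(
        image.astype(float), sk_t, output_shape=out_shape,
        order=1, mode="constant", cval=0.0, preserve_range=True,
    )
    if np.issubdtype(image.dtype, np.integer):
        info = np.iinfo(image.dtype)
        warped = np.clip(np.rint(warped), info.min, info.max)
    return warped.astype(image.dtype)


def register_stack(stack: RoundStack, reference_round: int | None = None,
                   min_matches: int = 10,
                   ) -> tuple[RoundStack, dict[int, AffineTransform]]:
    """Register every round onto the reference round via its DAPI image.

    The transform estimated on a round's DAPI is applied to all channels of
    that round (channel consistency); the reference round passes through
    unchanged.

    Returns the registered stack and the per-round transforms.
    """
    rounds = stack.rounds
    if not rounds:
        raise ValueError("empty stack")
    if reference_round is None:
        stained = [r for r in rounds if r >= 1]
        reference_round = stained[0] if stained else rounds[0]
    if (reference_round, "DAPI") not in stack.images:
        raise ValueError(f"reference round {reference_round} has no DAPI image")

    ref_dapi = stack.get(reference_round, "DAPI")
    out_shape = ref_dapi.shape

    transforms: dict[int, AffineTransform] = {}
    images: dict[tuple[int, str], np.ndarray] = {}
    for r in rounds:
        if r == reference_round:
            transforms[r] = AffineTransform.identity()
            for c in stack.channels_in_round(r):
                images[(r, c)] = stack.get(r, c)
            continue
        try:
            t = estimate_affine(ref_dapi, stack.get(r, "DAPI"),
                                min_matches=min_matches)
        except RegistrationError as exc:
            raise RegistrationError(f"round {r}: {exc}") from exc
        transforms[r] = t
        for c in stack.channels_in_round(r):
            images[(r, c)] = warp(stack.get(r, c), t, out_shape)
    return stack.copy_with(images), transforms


def transforms_to_csv(transforms: dict[int, AffineTransform], path) -> None:
    """Serialize per-round transforms as CSV (one row per round)."""
    import pandas as pd

    rows = [
        {"round": r, "a": t.a, "b": t.b, "c": t.c, "d": t.d,
         "tx": t.tx, "ty": t.ty, "residual_rms": t.residual_rms,
         "n_inliers": t.n_inliers}
        for r, t in sorted(transforms.items())
    ]
    pd.DataFrame(rows).to_csv(path, index=False)
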