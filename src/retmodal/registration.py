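"""Fundus <-> OCT en-face registration and en-face projection.

The two modalities are related by a planar transform estimated from paired
retinal-vessel intersection landmarks (picked by a human; landmark
*detection* is out of scope).  The en-face image itself is the mean axial
intensity between the photoreceptor inner/outer-segment junction (IS/OS)
and Bruch's membrane (BM), which highlights the vasculature shadowing and
makes the two frames comparable.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage import transform as sktransform

from .io_formats import FundusImage, OctVolume


@dataclass
class LandmarkSet:
    """Point correspondences ((x, y) fundus, (x, y) en-face)."""

    pairs: list

    def __post_init__(self) -> None:
        src = [tuple(p[0]) for p in self.pairs]
        if len(set(src)) != len(src):
            raise ValueError("duplicate source landmarks")

    @property
    def src(self) -> np.ndarray:
        return np.asarray([p[0] for p in self.pairs], dtype=float)

    @property
    def dst(self) -> np.ndarray:
        return np.asarray([p[1] for p in self.pairs], dtype=float)


@dataclass
class TransformModel:
    """Homogeneous 3x3 planar map from fundus (x, y) to en-face (x, y)."""

    matrix: np.ndarray
    kind: str = "similarity"
    residual_rms_px: float = 0.0

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.shape != (3, 3):
            raise ValueError("transform matrix must be 3x3")
        if abs(np.linalg.det(self.matrix)) < 1e-12:
            raise ValueError("transform matrix is singular")

    def apply(self, points: np.ndarray) -> np.ndarray:
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        h = np.column_stack([pts, np.ones(len(pts))])
        out = h @ self.matrix.T
        return out[:, :2] / out[:, 2:3]

    def inverse(self) -> "TransformModel":
        return TransformModel(np.linalg.inv(self.matrix), self.kind, self.residual_rms_px)


def estimate_transform(landmarks: LandmarkSet, kind: str = "similarity") -> TransformModel:
    """Least-squares planar transform from landmark correspondences.

    ``kind`` is ``"similarity"`` (rotation + isotropic scale + translation,
    >= 2 pairs) or ``"affine"`` (>= 3 non-collinear pairs).
    """
    if kind not in ("similarity", "affine"):
        raise ValueError(f"unknown transform kind {kind!r}")
    src, dst = landmarks.src, landmarks.dst
    min_pairs = 2 if kind == "similarity" else 3
    if len(src) < min_pairs:
        raise ValueError(f"{kind} needs >= {min_pairs} landmark pairs, got {len(src)}")
    centered = src - src.mean(axis=0)
    rank = np.linalg.matrix_rank(centered, tol=1e-9 * max(1.0, np.abs(centered).max()))
    if kind == "affine" and rank < 2:
        raise ValueError("landmarks are collinear; affine estimation is degenerate")
    if rank < 1:
        raise ValueError("landmarks are coincident; estimation is degenerate")
    tf = sktransform.estimate_transform(kind, src, dst)
    m = np.asarray(tf.params, dtype=float)
    if not np.all(np.isfinite(m)) or abs(np.linalg.det(m)) < 1e-12:
        raise ValueError("degenerate landmark configuration")
    mapped = tf(src)
    rms = float(np.sqrt(np.mean(np.sum((mapped - dst) ** 2, axis=1))))
    return TransformModel(matrix=m, kind=kind, residual_rms_px=rms)


def project_enface(vol: OctVolume, surfaces) -> np.ndarray:
    """Mean axial intensity over the inclusive [IS/OS, BM] band per column.

    Returns a float image of shape ``(n_ascan, n_bscan)``.
    """
    nz = vol.shape[2]
    lo = np.rint(np.asarray(surfaces.isos, dtype=float)).astype(int)
    hi = np.rint(np.asarray(surfaces.bm, dtype=float)).astype(int)
    bad = (lo < 0) | (hi >= nz) | (lo > hi)
    if bad.any():
        x, y = np.argwhere(bad)[0]
        raise ValueError(f"projection band invalid at column (ascan={x}, bscan={y})")
    data = vol.intensities.astype(np.float64)
    cs = np.concatenate(
        [np.zeros(data.shape[:2] + (1,)), np.cumsum(data, axis=2)], axis=2
    )
    ix, iy = np.meshgrid(
        np.arange(vol.shape[0]), np.arange(vol.shape[1]), indexing="ij"
    )
    band_sum = cs[ix, iy, hi + 1] - cs[ix, iy, lo]
    return band_sum / (hi - lo + 1)


def warp_crop_fundus(
    fundus: FundusImage, t: TransformModel, target_dims: tuple[int, int]
):
    """Resample the fundus onto the en-face grid by inverse bilinear mapping.

    ``t`` maps fundus coordinates to en-face coordinates.  Returns
    ``(warped_rgb, validity_mask)``; pixels whose preimage falls outside
    the fundus are zero-filled and marked invalid.
    """
    nx, ny = target_dims
    inv = t.inverse()
    gx, gy = np.meshgrid(np.arange(nx), np.arange(ny), indexing="ij")
    pts = np.column_stack([gx.ravel(), gy.ravel()]).astype(float)
    src = inv.apply(pts)
    sx = src[:, 0].reshape(nx, ny)
    sy = src[:, 1].reshape(nx, ny)
    h, w = fundus.rgb.shape[:2]
    valid = (sx >= 0) & (sx <= h - 1) & (sy >= 0) & (sy <= w - 1)
    out = np.zeros((nx, ny, fundus.rgb.shape[2]), dtype=np.float64)
    for c in range(fundus.rgb.shape[2]):
        out[:, :, c] = ndimage.map_coordinates(
            fundus.rgb[:, :, c].astype(np.float64),
            [sx, sy],
            order=1,
            mode="constant",
            cval=0.0,
        )
    out[~valid] = 0.0
    return out, valid.astype(np.uint8)


def warp_mask_to_enface(
    mask: np.ndarray, t: TransformModel, target_dims: tuple[int, int]
) -> np.ndarray:
    """Nearest-neighbour warp of a binary fundus-frame mask into the en-face frame."""
    nx, ny = target_dims
    inv = t.inverse()
    gx, gy = np.meshgrid(np.arange(nx), np.arange(ny), indexing="ij")
    src = inv.apply(np.column_stack([gx.ravel(), gy.ravel()]).astype(float))
    warped = ndimage.map_coordinates(
        mask.astype(np.float64),
        [src[:, 0].reshape(nx, ny), src[:, 1].reshape(nx, ny)],
        order=0,
        mode="constant",
        cval=0.0,
    )
    return (warped > 0.5).astype(np.uint8)
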