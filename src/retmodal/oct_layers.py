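"""Retinal layer-boundary segmentation on SD-OCT B-scans.

Hyper-reflective foci share their intensity with the nerve-fiber layer
(NFL) and the photoreceptor outer-segment complex, so focus detection is
confined to a *narrow band* between the NFL lower boundary and the IS/OS
junction.  This module denoises each B-scan with an edge-preserving
bilateral filter, then traces each boundary as the minimum-cost
left-to-right path through a signed vertical-gradient cost image
(dynamic programming with a bounded per-step vertical jump).  Bruch's
membrane (BM) is segmented as well because the en-face projection needs
the IS/OS-to-BM band.

Boundaries are found top-down in stacked search bands - inner limiting
membrane (ILM) first, then NFL-lower below it, IS/OS below that, BM
last - which keeps each DP problem unimodal: within its band every
boundary is the dominant gradient transition of the requested polarity.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .io_formats import OctVolume


@dataclass
class LayerSurfaces:
    """Per-(ascan, bscan) axial depths (voxels) of the three boundaries.

    Invariant: ``0 <= nfl_lower < isos < bm < n_axial`` in every column.
    """

    nfl_lower: np.ndarray
    isos: np.ndarray
    bm: np.ndarray

    def __post_init__(self) -> None:
        self.nfl_lower = np.asarray(self.nfl_lower, dtype=float)
        self.isos = np.asarray(self.isos, dtype=float)
        self.bm = np.asarray(self.bm, dtype=float)
        if not (self.nfl_lower.shape == self.isos.shape == self.bm.shape):
            raise ValueError("surface arrays must share one (ascan, bscan) shape")

    def check_ordering(self, n_axial: int | None = None) -> None:
        ok = (self.nfl_lower < self.isos) & (self.isos < self.bm) & (self.nfl_lower >= 0)
        if n_axial is not None:
            ok &= self.bm < n_axial
        if not ok.all():
            x, y = np.argwhere(~ok)[0]
            raise ValueError(f"surface ordering violated at B-scan {y} (A-scan {x})")


@dataclass
class NarrowBand:
    """3D binary search region between NFL-lower and IS/OS, margins eroded."""

    mask: np.ndarray
    margin_vox: int = 0


@dataclass
class LayerParams:
    """Knobs for the boundary tracer.

    ``max_jump`` bounds the per-A-scan vertical step of a boundary path
    (voxels); ``nfl_band_frac`` is the depth allowance below the ILM that
    is searched for the NFL lower boundary, as a fraction of the axial
    range; ``median_window`` smooths each surface across (ascan, bscan).
    """

    sigma_spatial: float = 2.0
    sigma_range: float = 15.0
    max_jump: int = 2
    nfl_band_frac: float = 0.15
    bottom_margin_frac: float = 0.03
    median_window: int = 5


def bilateral_denoise(
    bscan: np.ndarray,
    sigma_spatial: float = 2.0,
    sigma_range: float = 15.0,
    win_half: int = 2,
) -> np.ndarray:
    """Edge-preserving speckle reduction on a B-scan.

    Classic bilateral filter: each output pixel is the average of its
    (2*win_half+1)^2 neighbourhood weighted by a Gaussian in both spatial
    distance (``sigma_spatial``, pixels) and intensity difference
    (``sigma_range``, gray levels).  The centre pixel always carries
    weight one, so the output is a convex combination of inputs and never
    leaves the input intensity range.
    """
    if sigma_spatial <= 0 or sigma_range <= 0:
        raise ValueError("bilateral filter sigmas must be positive")
    img = np.asarray(bscan, dtype=np.float64)
    if img.ndim != 2:
        raise ValueError("expected a 2D B-scan")
    padded = np.pad(img, win_half, mode="reflect")
    num = np.zeros_like(img)
    den = np.zeros_like(img)
    nx, nz = img.shape
    for dx in range(-win_half, win_half + 1):
        for dz in range(-win_half, win_half + 1):
            shifted = padded[
                win_half + dx : win_half + dx + nx, win_half + dz : win_half + dz + nz
            ]
            w_s = np.exp(-(dx * dx + dz * dz) / (2.0 * sigma_spatial**2))
            w = w_s * np.exp(-((shifted - img) ** 2) / (2.0 * sigma_range**2))
            num += w * shifted
            den += w
    return num / den


def segment_boundary(
    bscan: np.ndarray,
    polarity: str,
    search_band: tuple[int, int],
    max_jump: int = 2,
) -> np.ndarray:
    """Minimum-cost boundary path across a B-scan.

    Cost per pixel is the negative signed vertical gradient for
    ``polarity="dark_to_bright"`` (the path seeks increasing intensity
    with depth) or the positive gradient for ``"bright_to_dark"``.  The
    optimum over all paths with per-step vertical jump <= ``max_jump`` is
    found by dynamic programming; ties break toward the smallest axial
    index.  Returns one axial index per A-scan.
    """
    if polarity not in ("dark_to_bright", "bright_to_dark"):
        raise ValueError(f"unknown polarity {polarity!r}")
    img = np.asarray(bscan, dtype=np.float64)
    nx, nz = img.shape
    z0, z1 = int(search_band[0]), int(search_band[1])
    if z0 > z1 or z0 < 0 or z1 >= nz:
        raise ValueError(f"empty or out-of-range search band ({z0}, {z1})")
    band_h = z1 - z0 + 1
    if band_h <= max_jump:
        raise ValueError(
            f"search band height {band_h} must exceed max_jump {max_jump}"
        )
    grad = np.gradient(img, axis=1)
    cost = -grad if polarity == "dark_to_bright" else grad
    cost = cost[:, z0 : z1 + 1]

    dp = cost[0].copy()
    back = np.zeros((nx, band_h), dtype=np.int32)
    offsets = np.arange(-max_jump, max_jump + 1)
    for x in range(1, nx):
        # stack predecessors ordered by ascending source z so that argmin
        # ties resolve to the smallest axial index
        shifted = np.full((offsets.size, band_h), np.inf)
        for i, off in enumerate(offsets):
            lo = max(0, -off)
            hi = min(band_h, band_h - off)
            shifted[i, lo:hi] = dp[lo + off : hi + off]
        choice = np.argmin(shifted, axis=0)
        back[x] = np.arange(band_h) + offsets[choice]
        dp = shifted[choice, np.arange(band_h)] + cost[x]

    path = np.empty(nx, dtype=np.int64)
    path[-1] = int(np.argmin(dp))
    for x in range(nx - 1, 0, -1):
        path[x - 1] = back[x, path[x]]
    return path + z0


def build_surfaces(vol: OctVolume, params: LayerParams | None = None) -> LayerSurfaces:
    """Segment NFL-lower, IS/OS and BM on every B-scan of a volume.

    Each B-scan is bilaterally denoised, then the four boundaries are
    traced in stacked search bands (each band placed below the surface
    found above it); surfaces are median-filtered across (ascan, bscan)
    and the ordering invariant is enforced.
    """
    params = params or LayerParams()
    data = vol.intensities
    if np.ptp(data) == 0:
        raise ValueError("volume is constant: no gradient evidence for any boundary")
    nx, ny, nz = data.shape
    mj = params.max_jump
    nfl_allow = max(int(round(params.nfl_band_frac * nz)), mj + 2)
    bottom = max(int(round(params.bottom_margin_frac * nz)), 1)

    ilm = np.empty((nx, ny))
    nfl = np.empty((nx, ny))
    isos = np.empty((nx, ny))
    bm = np.empty((nx, ny))
    for y in range(ny):
        den = bilateral_denoise(
            data[:, y, :], params.sigma_spatial, params.sigma_range
        )
        p_ilm = segment_boundary(den, "dark_to_bright", (1, nz - 2), mj)
        lo = int(p_ilm.min()) + 1
        hi = min(int(p_ilm.max()) + nfl_allow, nz - 2)
        p_nfl = segment_boundary(den, "bright_to_dark", (lo, hi), mj)
        lo = min(int(p_nfl.max()) + 3, nz - 2 - bottom - mj)
        p_isos = segment_boundary(den, "dark_to_bright", (lo, nz - 1 - bottom), mj)
        lo = min(int(p_isos.min()) + 2, nz - 2 - mj)
        p_bm = segment_boundary(den, "bright_to_dark", (lo, nz - 2), mj)
        ilm[:, y], nfl[:, y], isos[:, y], bm[:, y] = p_ilm, p_nfl, p_isos, p_bm

    w = params.median_window
    if w > 1:
        size = (w, min(w, ny))
        nfl = ndimage.median_filter(nfl, size=size, mode="nearest")
        isos = ndimage.median_filter(isos, size=size, mode="nearest")
        bm = ndimage.median_filter(bm, size=size, mode="nearest")
    surfaces = LayerSurfaces(nfl_lower=nfl, isos=isos, bm=bm)
    surfaces.check_ordering(nz)
    return surfaces


def build_narrow_band(surfaces: LayerSurfaces, grid_dims, margin_vox: int = 1) -> NarrowBand:
    """Mask of voxels with ``nfl_lower + margin <= z <= isos - margin``."""
    nx, ny, nz = grid_dims
    lo = np.rint(surfaces.nfl_lower).astype(int) + margin_vox
    hi = np.rint(surfaces.isos).astype(int) - margin_vox
    if (lo > hi).any():
        x, y = np.argwhere(lo > hi)[0]
        raise ValueError(
            f"margin {margin_vox} collapses the narrow band at column "
            f"(ascan={x}, bscan={y})"
        )
    z = np.arange(nz)[None, None, :]
    mask = (z >= lo[:, :, None]) & (z <= hi[:, :, None])
    return NarrowBand(mask=mask, margin_vox=margin_vox)
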