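"""Hard-exudate segmentation on (cropped) fundus images.

Exudates are conspicuous bright yellowish deposits, so they are segmented
by *local colour contrast*: at each pixel the mean CIELab vector of a
small centred square (v1) is compared with the mean over the surrounding
square annulus (v2); the per-scale saliency is the Euclidean distance
``C = ||v1 - v2||`` and the final map is the sum of C across scales.
Thresholding the summed map (Otsu by default) and removing small
components yields the exudate mask.  A pair of add/remove correction
masks stands in for the clinician's manual clean-up of pseudo-exudates
such as cotton-wool spots.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage import color as skcolor
from skimage import filters as skfilters


@dataclass
class SaliencyConfig:
    """Scales are inner-square half-widths (px); the annulus adds
    ``neighborhood_width`` px on each side.  ``neighborhood_width=None``
    uses the scale's own half-width."""

    scales: tuple = (2, 4, 8)
    neighborhood_width: int | None = None
    threshold_method: str = "otsu"
    fixed_threshold: float | None = None
    min_area_px: int = 5

    def __post_init__(self) -> None:
        if len(self.scales) == 0:
            raise ValueError("scales must be nonempty")
        if list(self.scales) != sorted(set(self.scales)):
            raise ValueError("scales must be strictly increasing")
        if any(s < 1 for s in self.scales):
            raise ValueError("scales must be >= 1 px")
        if self.neighborhood_width is not None and self.neighborhood_width < 1:
            raise ValueError("neighborhood width must be >= 1 px")
        if self.threshold_method not in ("otsu", "fixed"):
            raise ValueError(f"unknown threshold method {self.threshold_method!r}")
        if self.threshold_method == "fixed" and self.fixed_threshold is None:
            raise ValueError("fixed threshold method needs fixed_threshold")


@dataclass
class SaliencyMap:
    per_scale: list
    total: np.ndarray


def rgb_to_lab(image: np.ndarray) -> np.ndarray:
    """sRGB (0-255) to CIELab (D65)."""
    image = np.asarray(image)
    if image.ndim != 3 or image.shape[2] != 3:
        raise ValueError(f"expected an (nx, ny, 3) RGB image, got shape {image.shape}")
    return skcolor.rgb2lab(np.clip(image, 0, 255) / 255.0)


def _box_mean(channel: np.ndarray, half: int) -> np.ndarray:
    # reflect mode repeats the edge sample, matching np.pad(mode="symmetric")
    return ndimage.uniform_filter(channel, size=2 * half + 1, mode="reflect")


def saliency_at_scale(
    lab_image: np.ndarray, half_width: int, neighborhood_width: int | None = None
) -> np.ndarray:
    """Single-scale local colour contrast ``||v1 - v2||``.

    v1 is the mean Lab vector over the centred ``(2h+1)^2`` square, v2 the
    mean over the surrounding annulus of the given width; borders are
    handled by reflection padding.
    """
    if half_width < 1:
        raise ValueError("half_width must be >= 1")
    w = neighborhood_width if neighborhood_width is not None else half_width
    if w < 1:
        raise ValueError("neighborhood width must be >= 1")
    outer = half_width + w
    nx, ny = lab_image.shape[:2]
    if 2 * outer + 1 > 2 * min(nx, ny):
        raise ValueError(
            f"outer window {2 * outer + 1} exceeds reflect-padded image ({nx}x{ny})"
        )
    inner_n = (2 * half_width + 1) ** 2
    outer_n = (2 * outer + 1) ** 2
    sq = np.zeros((nx, ny))
    for c in range(lab_image.shape[2]):
        ch = lab_image[:, :, c].astype(np.float64)
        v1 = _box_mean(ch, half_width)
        outer_mean = _box_mean(ch, outer)
        v2 = (outer_mean * outer_n - v1 * inner_n) / (outer_n - inner_n)
        sq += (v1 - v2) ** 2
    return np.sqrt(sq)


def saliency_multiscale(lab_image: np.ndarray, config: SaliencyConfig) -> SaliencyMap:
    """Sum of per-scale saliency maps."""
    per_scale = [
        saliency_at_scale(lab_image, s, config.neighborhood_width) for s in config.scales
    ]
    return SaliencyMap(per_scale=per_scale, total=np.sum(per_scale, axis=0))


def segment_he(smap: SaliencyMap, config: SaliencyConfig) -> np.ndarray:
    """Threshold the summed saliency map and drop sub-minimum components."""
    total = smap.total
    if not np.all(np.isfinite(total)):
        raise ValueError("saliency map contains non-finite values")
    if config.threshold_method == "otsu":
        if np.ptp(total) == 0:
            raise ValueError(
                "saliency map is constant; Otsu is undefined - use a fixed threshold"
            )
        thr = skfilters.threshold_otsu(total)
    else:
        thr = config.fixed_threshold
    mask = total >= thr
    if config.min_area_px > 1 and mask.any():
        labels, n = ndimage.label(mask, structure=np.ones((3, 3), dtype=bool))
        sizes = ndimage.sum_labels(mask, labels, index=np.arange(1, n + 1))
        keep = np.flatnonzero(sizes >= config.min_area_px) + 1
        mask = np.isin(labels, keep)
    return mask.astype(np.uint8)


def apply_correction(
    mask: np.ndarray, add_mask: np.ndarray | None = None, remove_mask: np.ndarray | None = None
) -> np.ndarray:
    """(mask | add) & ~remove - the programmatic stand-in for manual review."""
    mask = np.asarray(mask).astype(bool)
    for other, name in ((add_mask, "add"), (remove_mask, "remove")):
        if other is not None and np.asarray(other).shape != mask.shape:
            raise ValueError(
                f"{name} mask shape {np.asarray(other).shape} != mask shape {mask.shape}"
            )
    out = mask.copy()
    if add_mask is not None:
        out |= np.asarray(add_mask).astype(bool)
    if remove_mask is not None:
        out &= ~np.asarray(remove_mask).astype(bool)
    return out.astype(np.uint8)
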