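"""Hyper-reflective focus (HRF) detection inside the narrow band.

Per B-scan, seed pixels are those brighter than mean + k*SD of the band
pixels (a self-adapting threshold: it tracks each B-scan's own intensity
statistics, so no absolute gray-level needs to be chosen).  Seeds are
expanded by region growing - 8-connected breadth-first admission of band
pixels within ``delta`` gray levels of the seed component's mean - and
the per-B-scan masks are linked into 3D lesions by 26-connected
component labelling.  Lesions are split into hard-exudate (HE) and
non-HE foci by their en-face footprint overlap with a registered fundus
HE mask.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .io_formats import OctVolume
from .oct_layers import LayerSurfaces, NarrowBand, build_narrow_band

_STRUCT_2D = np.ones((3, 3), dtype=bool)
_STRUCT_3D = np.ones((3, 3, 3), dtype=bool)


@dataclass
class Lesion:
    """One 3D connected lesion: voxels, centroid and en-face geometry."""

    id: int
    voxels: np.ndarray  # (n, 3) int array of (ascan, bscan, axial)
    centroid: tuple[float, float, float]
    columns: np.ndarray  # (k, 2) unique (ascan, bscan) footprint pixels
    column_counts: np.ndarray  # voxels per footprint column (axial extent)

    @property
    def n_voxels(self) -> int:
        return len(self.voxels)


@dataclass
class LesionSet:
    labels: np.ndarray  # 3D int label volume, 0 = background
    lesions: list

    @property
    def shape(self):
        return self.labels.shape

    def __len__(self) -> int:
        return len(self.lesions)

    def mask(self) -> np.ndarray:
        return (self.labels > 0).astype(np.uint8)


def adaptive_seeds(bscan: np.ndarray, band_mask: np.ndarray, k: float = 2.0) -> np.ndarray:
    """Seed pixels: band pixels with intensity >= band mean + k * band SD."""
    bscan = np.asarray(bscan, dtype=np.float64)
    band = np.asarray(band_mask).astype(bool)
    if bscan.shape != band.shape:
        raise ValueError("B-scan and band mask shapes differ")
    vals = bscan[band]
    if vals.size == 0:
        raise ValueError("narrow band is empty on this B-scan")
    thr = vals.mean() + k * vals.std()
    # strict comparison: a perfectly homogeneous band has nothing standing out
    return (band & (bscan > thr)).astype(np.uint8)


def region_grow(
    bscan: np.ndarray, seeds: np.ndarray, band_mask: np.ndarray, delta: float = 10.0
) -> np.ndarray:
    """Grow seed components over 8-connectivity within the band.

    A pixel is admitted iff it lies in the band and its intensity is
    >= (mean intensity of its seed component) - delta.  Implemented as a
    flood fill from each seed component over its admissible set, which is
    equivalent to the breadth-first formulation.
    """
    bscan = np.asarray(bscan, dtype=np.float64)
    seeds = np.asarray(seeds).astype(bool)
    band = np.asarray(band_mask).astype(bool)
    if not (bscan.shape == seeds.shape == band.shape):
        raise ValueError("B-scan, seed and band shapes differ")
    if (seeds & ~band).any():
        raise ValueError("seeds must lie inside the narrow band")
    out = np.zeros_like(seeds, dtype=bool)
    seed_labels, n_seed = ndimage.label(seeds, structure=_STRUCT_2D)
    for sid in range(1, n_seed + 1):
        comp = seed_labels == sid
        thr = bscan[comp].mean() - delta
        # seeds stay in unconditionally; expansion admits band pixels
        # bright enough relative to the seed-component mean
        admissible = (band & (bscan >= thr)) | comp
        grown_labels, _ = ndimage.label(admissible, structure=_STRUCT_2D)
        ids = np.unique(grown_labels[comp])
        ids = ids[ids > 0]
        out |= np.isin(grown_labels, ids)
    return out.astype(np.uint8)


def link_3d(per_bscan_masks) -> LesionSet:
    """Stack per-B-scan masks and label 26-connected 3D lesions."""
    masks = [np.asarray(m).astype(bool) for m in per_bscan_masks]
    shapes = {m.shape for m in masks}
    if len(shapes) != 1:
        raise ValueError(f"inconsistent B-scan mask shapes: {sorted(shapes)}")
    nx, nz = masks[0].shape
    vol_mask = np.stack(masks, axis=1)  # (ascan, bscan, axial)
    labels, n = ndimage.label(vol_mask, structure=_STRUCT_3D)
    return _lesions_from_labels(labels, n)


def _lesions_from_labels(labels: np.ndarray, n: int) -> LesionSet:
    lesions = []
    for lid in range(1, n + 1):
        vox = np.argwhere(labels == lid)
        centroid = tuple(vox.mean(axis=0))
        cols, counts = np.unique(vox[:, :2], axis=0, return_counts=True)
        lesions.append(
            Lesion(id=lid, voxels=vox, centroid=centroid, columns=cols, column_counts=counts)
        )
    return LesionSet(labels=labels, lesions=lesions)


def filter_min_size(lesions: LesionSet, min_voxels: int = 3) -> LesionSet:
    """Drop lesions smaller than ``min_voxels`` (speckle suppression); relabel."""
    keep = [l for l in lesions.lesions if l.n_voxels >= min_voxels]
    labels = np.zeros_like(lesions.labels)
    out = []
    for new_id, les in enumerate(keep, start=1):
        labels[tuple(les.voxels.T)] = new_id
        out.append(
            Lesion(
                id=new_id,
                voxels=les.voxels,
                centroid=les.centroid,
                columns=les.columns,
                column_counts=les.column_counts,
            )
        )
    return LesionSet(labels=labels, lesions=out)


def detect_hrf(
    vol: OctVolume,
    surfaces: LayerSurfaces,
    k: float = 2.0,
    delta: float = 10.0,
    margin_vox: int = 2,
    min_voxels: int = 3,
    seed_min_px: int = 2,
    band: NarrowBand | None = None,
) -> LesionSet:
    """Full HRF detection for a volume: band -> seeds -> growth -> 3D link.

    ``margin_vox`` defaults to 2 here (band margin 1 plus one guard voxel
    against layer-surface estimation error); ``seed_min_px`` drops seed
    components smaller than that many pixels before growth, suppressing
    isolated speckle seeds.
    """
    if band is None:
        band = build_narrow_band(surfaces, vol.shape, margin_vox)
    masks = []
    for y in range(vol.shape[1]):
        bscan = vol.intensities[:, y, :]
        band2d = band.mask[:, y, :]
        if not band2d.any():
            masks.append(np.zeros_like(band2d, dtype=np.uint8))
            continue
        seeds = adaptive_seeds(bscan, band2d, k)
        if seed_min_px > 1 and seeds.any():
            slab, ns = ndimage.label(seeds, structure=_STRUCT_2D)
            sizes = ndimage.sum_labels(seeds, slab, index=np.arange(1, ns + 1))
            keep = np.flatnonzero(sizes >= seed_min_px) + 1
            seeds = np.isin(slab, keep).astype(np.uint8)
        masks.append(region_grow(bscan, seeds, band2d, delta))
    lesions = link_3d(masks)
    return filter_min_size(lesions, min_voxels)


def height_map(lesions: LesionSet, axial_pitch_um: float) -> np.ndarray:
    """Topographic lesion thickness map: voxels per column x axial pitch (um)."""
    nx, ny, _ = lesions.shape
    out = np.zeros((nx, ny), dtype=np.float64)
    for les in lesions.lesions:
        out[les.columns[:, 0], les.columns[:, 1]] += les.column_counts * axial_pitch_um
    return out


def split_by_he(
    lesions: LesionSet, he_mask_enface: np.ndarray, min_overlap_frac: float = 0.5
):
    """Partition lesions into (HE, non-HE focus) sets by footprint overlap.

    A lesion is an HE iff the fraction of its en-face footprint covered by
    the registered fundus HE mask is >= ``min_overlap_frac``.
    """
    he_mask = np.asarray(he_mask_enface).astype(bool)
    if he_mask.shape != lesions.shape[:2]:
        raise ValueError(
            f"HE mask frame {he_mask.shape} != en-face frame {lesions.shape[:2]}"
        )
    he_ids, focus_ids = [], []
    for les in lesions.lesions:
        inside = he_mask[les.columns[:, 0], les.columns[:, 1]].sum()
        frac = inside / len(les.columns)
        (he_ids if frac >= min_overlap_frac else focus_ids).append(les.id)
    return _subset(lesions, he_ids), _subset(lesions, focus_ids)


def _subset(lesions: LesionSet, ids) -> LesionSet:
    ids = set(ids)
    labels = np.zeros_like(lesions.labels)
    out = []
    for new_id, les in enumerate((l for l in lesions.lesions if l.id in ids), start=1):
        labels[tuple(les.voxels.T)] = new_id
        out.append(
            Lesion(
                id=new_id,
                voxels=les.voxels,
                centroid=les.centroid,
                columns=les.columns,
                column_counts=les.column_counts,
            )
        )
    return LesionSet(labels=labels, lesions=out)
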