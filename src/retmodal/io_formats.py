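"""Readers and writers for every artifact the pipeline touches.

Conventions used throughout the package:

* OCT volumes are arrays indexed ``[ascan, bscan, axial]`` (x, y, z); the
  axial index increases with depth (vitreous -> choroid).  Intensities are
  8-bit (0-255).
* 2D images (en-face projections, fundus photographs, masks) are arrays
  indexed ``[x, y]``; a point coordinate ``(x, y)`` addresses ``arr[x, y]``.
* Volumes go to disk as multi-page TIFF (one page per B-scan) with a JSON
  sidecar carrying the physical geometry; masks are stored 8-bit {0, 255}
  on disk and normalised to {0, 1} in memory.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
from PIL import Image

FEATURE_COLUMNS = [
    "eye_id",
    "label",
    "avg_area_mm2",
    "amount",
    "avg_distance_um",
    "avg_altitude_um",
    "avg_reflectivity",
]


@dataclass
class OctVolume:
    """An SD-OCT volume with explicit physical voxel pitch.

    ``intensities`` has shape ``(n_ascan, n_bscan, n_axial)`` and dtype
    uint8; ``voxel_pitch_um`` is the per-axis pitch in micrometres.
    """

    intensities: np.ndarray
    voxel_pitch_um: tuple[float, float, float]
    eye_id: str = ""
    fovea: tuple[int, int] | None = None
    label: str | None = None

    def __post_init__(self) -> None:
        self.intensities = np.asarray(self.intensities)
        if self.intensities.ndim != 3:
            raise ValueError("OctVolume expects a 3D (ascan, bscan, axial) array")
        if any(p <= 0 for p in self.voxel_pitch_um):
            raise ValueError(f"voxel pitch must be positive, got {self.voxel_pitch_um}")
        lo, hi = float(self.intensities.min(initial=0)), float(self.intensities.max(initial=0))
        if lo < 0 or hi > 255:
            raise ValueError(f"intensities outside [0, 255]: min {lo}, max {hi}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.intensities.shape


@dataclass
class FundusImage:
    """An RGB fundus photograph, array shape ``(nx, ny, 3)``."""

    rgb: np.ndarray
    pixel_pitch_um: tuple[float, float] = (1.0, 1.0)
    eye_id: str = ""

    def __post_init__(self) -> None:
        self.rgb = np.asarray(self.rgb)
        if self.rgb.ndim != 3 or self.rgb.shape[2] != 3:
            raise ValueError("FundusImage expects an (nx, ny, 3) RGB array")
        if self.rgb.min(initial=0) < 0:
            raise ValueError("negative pixel values")


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(".json")


def write_volume(vol: OctVolume, path: str | Path) -> None:
    """Write a volume as a multi-page TIFF (pages = B-scans) + JSON sidecar."""
    path = Path(path)
    pages = np.ascontiguousarray(np.transpose(vol.intensities, (1, 0, 2)))
    tifffile.imwrite(path, pages.astype(np.uint8))
    meta = {
        "dims": list(vol.shape),
        "voxel_pitch_um": list(vol.voxel_pitch_um),
        "eye_id": vol.eye_id,
        "fovea": list(vol.fovea) if vol.fovea is not None else None,
        "label": vol.label,
    }
    _sidecar_path(path).write_text(json.dumps(meta, indent=1))


def read_volume(path: str | Path) -> OctVolume:
    """Read a volume written by :func:`write_volume`; round-trip is exact."""
    path = Path(path)
    sidecar = _sidecar_path(path)
    if not sidecar.exists():
        raise FileNotFoundError(f"missing JSON sidecar {sidecar} for volume {path}")
    meta = json.loads(sidecar.read_text())
    pages = tifffile.imread(path)
    if pages.ndim == 2:
        pages = pages[None]
    dims = tuple(meta["dims"])
    if pages.shape != (dims[1], dims[0], dims[2]):
        raise ValueError(
            f"TIFF stack shape {pages.shape} does not match sidecar dims {dims} "
            f"(expected {(dims[1], dims[0], dims[2])} pages x rows x cols)"
        )
    return OctVolume(
        intensities=np.transpose(pages, (1, 0, 2)),
        voxel_pitch_um=tuple(meta["voxel_pitch_um"]),
        eye_id=meta.get("eye_id", ""),
        fovea=tuple(meta["fovea"]) if meta.get("fovea") else None,
        label=meta.get("label"),
    )


def write_mask(mask: np.ndarray, path: str | Path) -> None:
    """Write a binary mask: PNG for 2D, multi-page TIFF for 3D. Stored {0,255}."""
    path = Path(path)
    mask = np.asarray(mask)
    vals = np.unique(mask)
    if not np.all(np.isin(vals, (0, 1))):
        raise ValueError(f"mask is not binary; values present: {vals.tolist()}")
    disk = (mask.astype(np.uint8)) * 255
    if mask.ndim == 2:
        Image.fromarray(disk).save(path)
    elif mask.ndim == 3:
        tifffile.imwrite(path, np.ascontiguousarray(np.transpose(disk, (1, 0, 2))))
    else:
        raise ValueError("mask must be 2D or 3D")


def read_mask(path: str | Path) -> np.ndarray:
    """Read a mask back to a {0,1} uint8 array."""
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        disk = tifffile.imread(path)
        if disk.ndim == 3:
            disk = np.transpose(disk, (1, 0, 2))
    else:
        disk = np.asarray(Image.open(path))
    vals = np.unique(disk)
    bad = vals[~np.isin(vals, (0, 1, 255))]
    if bad.size:
        raise ValueError(f"mask file {path} has non-binary values: {bad.tolist()}")
    return (disk > 0).astype(np.uint8)


def write_fundus(img: FundusImage, path: str | Path) -> None:
    Image.fromarray(np.clip(img.rgb, 0, 255).astype(np.uint8)).save(Path(path))


def read_fundus(path: str | Path, pixel_pitch_um=(1.0, 1.0), eye_id: str = "") -> FundusImage:
    rgb = np.asarray(Image.open(path).convert("RGB"))
    return FundusImage(rgb=rgb, pixel_pitch_um=pixel_pitch_um, eye_id=eye_id)


def write_feature_table(rows, path: str | Path) -> None:
    """Write per-eye feature rows to CSV with a fixed header.

    Each row is a mapping carrying eye_id, label and the five lesion
    features; a missing field is an error.
    """
    records = []
    for i, row in enumerate(rows):
        missing = [c for c in FEATURE_COLUMNS if c not in row]
        if missing:
            raise ValueError(f"feature row {i} missing fields {missing}")
        records.append({c: row[c] for c in FEATURE_COLUMNS})
    df = pd.DataFrame(records, columns=FEATURE_COLUMNS)
    df.to_csv(path, index=False)


def read_feature_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in FEATURE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"feature table {path} missing columns {missing}")
    return df


def write_landmarks(pairs, path: str | Path) -> None:
    """Write landmark correspondences as CSV (x_fundus,y_fundus,x_enface,y_enface)."""
    df = pd.DataFrame(
        [(fx, fy, ex, ey) for (fx, fy), (ex, ey) in pairs],
        columns=["x_fundus", "y_fundus", "x_enface", "y_enface"],
    )
    df.to_csv(path, index=False)


def read_landmarks(path: str | Path):
    df = pd.read_csv(path)
    need = ["x_fundus", "y_fundus", "x_enface", "y_enface"]
    missing = [c for c in need if c not in df.columns]
    if missing:
        raise ValueError(f"landmark file {path} missing columns {missing}")
    return [((r.x_fundus, r.y_fundus), (r.x_enface, r.y_enface)) for r in df.itertuples()]
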