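"""Per-eye lesion features and HE agreement statistics.

Five features summarise an eye's lesion load: mean en-face footprint area
(mm^2), lesion count, mean en-face centroid distance to the fovea (um),
mean axial extent over lesion columns (um, "altitude"), and mean lesion
voxel intensity (0-255 reflectivity).  Agreement between hard-exudate
areas measured on fundus photography and on OCT is quantified per
severity group by Pearson correlation and an ordinary least-squares fit.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .hrf_seg import LesionSet
from .io_formats import OctVolume

FEATURE_NAMES = [
    "avg_area_mm2",
    "amount",
    "avg_distance_um",
    "avg_altitude_um",
    "avg_reflectivity",
]


@dataclass
class EyeFeatures:
    eye_id: str
    label: str
    avg_area_mm2: float
    amount: int
    avg_distance_um: float
    avg_altitude_um: float
    avg_reflectivity: float
    defined: bool = True  # False when amount == 0 and the means are NaN

    def as_row(self) -> dict:
        return {
            "eye_id": self.eye_id,
            "label": self.label,
            "avg_area_mm2": self.avg_area_mm2,
            "amount": self.amount,
            "avg_distance_um": self.avg_distance_um,
            "avg_altitude_um": self.avg_altitude_um,
            "avg_reflectivity": self.avg_reflectivity,
        }


def compute_eye_features(
    lesions: LesionSet,
    vol: OctVolume,
    fovea: tuple[int, int],
    eye_id: str = "",
    label: str = "",
) -> EyeFeatures:
    """Aggregate the five lesion features for one eye.

    Per lesion: area = footprint pixel count x lateral pitches; altitude =
    mean per-column axial extent x axial pitch; distance = lateral
    Euclidean distance (um) from the en-face centroid to the fovea.
    Eye-level values are means over lesions; with no lesions the means
    are NaN and ``defined`` is False.
    """
    nx, ny, _ = vol.shape
    fx, fy = fovea
    if not (0 <= fx < nx and 0 <= fy < ny):
        raise ValueError(f"fovea {fovea} outside the en-face grid {(nx, ny)}")
    px, py, pz = vol.voxel_pitch_um
    if len(lesions) == 0:
        return EyeFeatures(eye_id, label, np.nan, 0, np.nan, np.nan, np.nan, defined=False)
    areas, dists, alts, refls = [], [], [], []
    for les in lesions.lesions:
        areas.append(len(les.columns) * px * py / 1e6)
        alts.append(les.column_counts.mean() * pz)
        cx, cy = les.centroid[0], les.centroid[1]
        dists.append(float(np.hypot((cx - fx) * px, (cy - fy) * py)))
        vox = les.voxels
        refls.append(float(vol.intensities[vox[:, 0], vox[:, 1], vox[:, 2]].mean()))
    return EyeFeatures(
        eye_id=eye_id,
        label=label,
        avg_area_mm2=float(np.mean(areas)),
        amount=len(lesions),
        avg_distance_um=float(np.mean(dists)),
        avg_altitude_um=float(np.mean(alts)),
        avg_reflectivity=float(np.mean(refls)),
    )


def normalize_features(matrix: np.ndarray, names=None, on_constant: str = "raise") -> np.ndarray:
    """Cohort-wide per-feature min-max scaling to [0, 1].

    A zero-range feature is an error by default; ``on_constant="zero"``
    maps it to all zeros instead (useful when a lesion group is absent
    in every eye of a cohort).
    """
    X = np.asarray(matrix, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2:
        raise ValueError("need a 2D matrix with >= 2 eyes")
    lo, hi = X.min(axis=0), X.max(axis=0)
    rng = hi - lo
    flat = rng <= 0
    if flat.any():
        if on_constant == "zero":
            rng = np.where(flat, 1.0, rng)
            out = (X - lo) / rng
            out[:, flat] = 0.0
            return out
        j = int(np.flatnonzero(flat)[0])
        name = names[j] if names is not None else f"column {j}"
        raise ValueError(f"feature {name} has zero range; cannot normalize")
    return (X - lo) / rng


def pearson_with_p(x, y):
    """Pearson r with two-sided p (t on n-2 df) and the OLS fit of y on x."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("need paired samples with n >= 3")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("zero variance input")
    r, p = sps.pearsonr(x, y)
    fit = sps.linregress(x, y)
    return float(r), float(p), float(fit.slope), float(fit.intercept)


def agreement_report(table: pd.DataFrame) -> pd.DataFrame:
    """Per-severity-group agreement between fundus and OCT HE areas.

    ``table`` needs columns eye_id, label, cfp_area, oct_area.  Groups
    with fewer than 3 eyes are skipped with a warning.  Returns one row
    per group: n, r, p, slope, intercept.
    """
    need = {"eye_id", "label", "cfp_area", "oct_area"}
    missing = need - set(table.columns)
    if missing:
        raise ValueError(f"agreement table missing columns {sorted(missing)}")
    rows = []
    for label, grp in table.groupby("label", sort=True):
        if len(grp) < 3:
            warnings.warn(f"group {label!r} has n={len(grp)} < 3; skipped")
            continue
        try:
            r, p, slope, intercept = pearson_with_p(grp["cfp_area"], grp["oct_area"])
        except ValueError as exc:
            warnings.warn(f"group {label!r} skipped: {exc}")
            continue
        rows.append(
            {"label": label, "n": len(grp), "r": r, "p": p, "slope": slope,
             "intercept": intercept}
        )
    return pd.DataFrame(rows, columns=["label", "n", "r", "p", "slope", "intercept"])
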