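"""Synthetic paired SD-OCT / fundus phantoms with full ground truth.

The OCT phantom is a layered slab model of the macula: five boundary
surfaces (ILM, NFL lower boundary, OPL/ONL border, IS/OS, Bruch's
membrane) with gentle smooth undulation separate slabs of distinct mean
reflectivity, degraded by multiplicative Gamma speckle.  Bright
ellipsoidal foci - the hyper-reflective foci of diabetic retinopathy -
are inserted near the OPL/ONL border, inside the NFL-lower-to-IS/OS
band.  A subset of foci (the larger, axially taller ones) is designated
as fundus-visible hard exudates; the paired fundus photograph shows
these as yellowish blobs, plus dark vessel lines whose intersections
serve as registration landmarks, related to the OCT en-face frame by a
known similarity transform.

Everything is deterministic given the config seed, and every ground
truth (layer surfaces, focus masks, transform, landmarks, fovea,
severity label) is returned alongside the images.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage.draw import line as skline

from .io_formats import FundusImage, OctVolume
from .oct_layers import LayerSurfaces
from .registration import LandmarkSet, TransformModel

_STRUCT_3D = np.ones((3, 3, 3), dtype=bool)

# slab mean intensities (0-255), vitreous -> choroid; the NFL-lower to
# IS/OS band is kept at one level so the only bright structures inside
# the focus search band are the foci themselves
_INT_VITREOUS = 20.0
_INT_NFL = 120.0
_INT_INNER = 45.0
_INT_ISOS_BM = 130.0
_INT_CHOROID = 30.0

# fundus palette: exudates are conspicuous bright-yellow deposits; vessels
# are kept low-contrast so they act as registration landmarks without
# rivalling exudate saliency (the clinical pseudo-lesion problem is
# exercised separately through the correction-mask interface)
_RGB_RETINA = (185.0, 95.0, 45.0)
_RGB_VESSEL = (165.0, 82.0, 42.0)
_RGB_EXUDATE = (255.0, 240.0, 160.0)
_FUNDUS_NOISE_SD = 1.5


@dataclass(frozen=True)
class PhantomConfig:
    """Study-condition knobs for one synthetic eye.

    ``layer_depths_um`` are the nominal depths of (ILM, NFL-lower,
    OPL/ONL, IS/OS, BM); ``foci_radius_range_um`` bounds the lateral
    semi-axis of a focus; hard-exudate-destined foci draw from the upper
    half of that range and are elongated axially by
    ``he_axial_aspect`` (plain foci by ``axial_aspect``).
    """

    grid_dims: tuple = (512, 128, 1024)
    extent_mm: tuple = (6.0, 6.0, 2.0)
    n_foci: int = 8
    n_exudates: int = 3
    foci_radius_range_um: tuple = (50.0, 90.0)
    foci_intensity: float = 95.0
    axial_aspect: float = 1.0
    he_axial_aspect: float = 1.6
    layer_depths_um: tuple = (200.0, 330.0, 650.0, 800.0, 880.0)
    surface_wobble_um: float = 20.0
    speckle_sigma: float = 0.1
    fundus_dims: tuple = (700, 200)
    rotation_deg: float = 3.0
    scale: float | None = None
    translation: tuple | None = None
    vessel_width_px: int = 2
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if any(d <= 0 for d in self.grid_dims) or any(e <= 0 for e in self.extent_mm):
            raise ValueError("grid dims and extents must be positive")
        if self.n_foci < 0 or self.n_exudates < 0:
            raise ValueError("counts must be nonnegative")
        if self.n_exudates > self.n_foci:
            raise ValueError("n_exudates cannot exceed n_foci")
        if list(self.layer_depths_um) != sorted(self.layer_depths_um):
            raise ValueError("layer depths must be strictly increasing")
        if len(set(self.layer_depths_um)) != len(self.layer_depths_um):
            raise ValueError("layer depths must be strictly increasing")
        rmin, rmax = self.foci_radius_range_um
        if not (0 < rmin <= rmax):
            raise ValueError("invalid focus radius range")
        if self.speckle_sigma < 0:
            raise ValueError("speckle sigma must be nonnegative")
        # the tallest possible focus must fit inside the narrow band
        ilm, nfl, opl, isos, bm = self.layer_depths_um
        max_rz = rmax * max(self.axial_aspect, self.he_axial_aspect)
        pz = self.voxel_pitch_um[2]
        band = (isos - nfl) - 2 * self.surface_wobble_um - 8 * pz
        if 2 * max_rz >= band:
            raise ValueError(
                f"focus axial extent {2 * max_rz:.0f} um exceeds the narrow band "
                f"({band:.0f} um usable); reject config"
            )
        if bm >= self.extent_mm[2] * 1000:
            raise ValueError("BM depth outside the axial extent")

    @property
    def voxel_pitch_um(self) -> tuple[float, float, float]:
        return tuple(
            1000.0 * e / n for e, n in zip(self.extent_mm, self.grid_dims)
        )

    @property
    def effective_scale(self) -> float:
        """Fundus->en-face scale; ``None`` picks the smallest scale whose
        fundus frame still covers the whole en-face frame (40 px slack
        for the rotation)."""
        if self.scale is not None:
            return self.scale
        nx, ny, _ = self.grid_dims
        fx, fy = self.fundus_dims
        return max(nx / max(fx - 40, 1), ny / max(fy - 40, 1))


@dataclass
class FundusPhantom:
    fundus: FundusImage
    he_mask: np.ndarray  # fundus frame, {0,1}
    vessel_mask: np.ndarray
    landmarks: LandmarkSet
    clipped_he_ids: list


@dataclass
class PhantomCase:
    """One synthetic eye with every ground truth the pipeline can check."""

    eye_id: str
    oct: OctVolume
    fundus: FundusImage
    truth_layers: LayerSurfaces
    truth_foci_mask: np.ndarray
    truth_foci_labels: np.ndarray
    truth_he_focus_ids: list
    truth_he_mask_fundus: np.ndarray
    truth_he_mask_enface: np.ndarray
    truth_vessel_mask: np.ndarray
    truth_transform: TransformModel
    landmarks: LandmarkSet
    fovea: tuple[int, int]
    severity_label: str
    config: PhantomConfig
    clipped_he_ids: list = field(default_factory=list)


def _smooth_field(shape, amp, rng):
    """Low-frequency undulation shared by all surfaces (voxel units)."""
    nx, ny = shape
    fx, fy = rng.uniform(0.5, 1.5, size=2)
    px_, py_ = rng.uniform(0, 2 * np.pi, size=2)
    x = np.linspace(0, 2 * np.pi, nx)[:, None]
    y = np.linspace(0, 2 * np.pi, ny)[None, :]
    return amp * np.sin(fx * x + px_) * np.cos(fy * y + py_)


def make_truth_transform(config: PhantomConfig) -> TransformModel:
    """The known fundus -> en-face similarity from the config parameters."""
    th = math.radians(config.rotation_deg)
    s = config.effective_scale
    r = s * np.array([[math.cos(th), -math.sin(th)], [math.sin(th), math.cos(th)]])
    if config.translation is not None:
        t = np.asarray(config.translation, dtype=float)
    else:  # centre the fundus frame on the en-face frame
        nx, ny, _ = config.grid_dims
        fc = np.array([(config.fundus_dims[0] - 1) / 2, (config.fundus_dims[1] - 1) / 2])
        ec = np.array([(nx - 1) / 2, (ny - 1) / 2])
        t = ec - r @ fc
    m = np.eye(3)
    m[:2, :2] = r
    m[:2, 2] = t
    return TransformModel(matrix=m, kind="similarity", residual_rms_px=0.0)


def generate_oct_phantom(config: PhantomConfig):
    """Layered OCT volume with inserted foci.

    Returns ``(OctVolume, LayerSurfaces, foci_mask)``; the binary mask
    marks exactly the inserted focus voxels.  Deterministic given the
    config seed.
    """
    vol, surfaces, labels, _ = _generate_oct(config)
    return vol, surfaces, (labels > 0).astype(np.uint8)


def _generate_oct(config: PhantomConfig):
    rng = np.random.default_rng([config.rng_seed, 0])
    nx, ny, nz = config.grid_dims
    px, py, pz = config.voxel_pitch_um
    wobble_vox = config.surface_wobble_um / pz
    base = _smooth_field((nx, ny), wobble_vox, rng)
    depths = [d / pz + base + _smooth_field((nx, ny), 0.5, rng)
              for d in config.layer_depths_um]
    ilm, nfl, opl, isos, bm = depths

    z = np.arange(nz)[None, None, :]
    volume = np.full((nx, ny, nz), _INT_VITREOUS)
    for surf, level in [
        (ilm, _INT_NFL),
        (nfl, _INT_INNER),
        (isos, _INT_ISOS_BM),
        (bm, _INT_CHOROID),
    ]:
        volume = np.where(z >= np.rint(surf)[:, :, None], level, volume)

    labels, foci = _place_foci(config, rng, nfl, opl, isos)
    for f in foci:
        volume[labels == f["id"]] = config.foci_intensity

    if config.speckle_sigma > 0:
        shape = 1.0 / config.speckle_sigma**2
        volume = volume * rng.gamma(shape, 1.0 / shape, size=volume.shape)
    volume = np.clip(np.rint(volume), 0, 255).astype(np.uint8)
    vol = OctVolume(
        intensities=volume, voxel_pitch_um=(px, py, pz), eye_id="", fovea=None
    )
    surfaces = LayerSurfaces(nfl_lower=nfl, isos=isos, bm=bm)
    return vol, surfaces, labels, foci


def _place_foci(config: PhantomConfig, rng, nfl, opl, isos):
    """Sample non-touching ellipsoidal foci centred near the OPL/ONL border.

    The first ``n_exudates`` foci are hard-exudate-destined: lateral
    radius from the upper half of the range and a taller axial aspect.
    Centres sit on voxel centres; bounding boxes (plus a 2-voxel margin)
    are kept disjoint along at least one axis so the truth mask has
    exactly ``n_foci`` 26-connected components.
    """
    nx, ny, nz = config.grid_dims
    px, py, pz = config.voxel_pitch_um
    rmin, rmax = config.foci_radius_range_um
    rmid = 0.5 * (rmin + rmax)
    labels = np.zeros((nx, ny, nz), dtype=np.int32)
    foci = []
    boxes = []
    for fid in range(1, config.n_foci + 1):
        he = fid <= config.n_exudates
        r_um = rng.uniform(rmid, rmax) if he else rng.uniform(rmin, rmax)
        aspect = config.he_axial_aspect if he else config.axial_aspect
        rx, ry, rz = r_um / px, r_um / py, aspect * r_um / pz
        placed = False
        for _ in range(2000):
            cx = int(rng.integers(int(np.ceil(rx)) + 1, nx - int(np.ceil(rx)) - 1))
            cy = int(rng.integers(0, ny))
            lo = float(nfl[cx, cy]) + rz + 3
            hi = float(isos[cx, cy]) - rz - 3
            if lo > hi:
                raise ValueError("focus radius exceeds the narrow-band thickness")
            cz = int(np.rint(np.clip(opl[cx, cy] + rng.uniform(-4, 4), lo, hi)))
            box = (
                cx - int(np.ceil(rx)) - 2, cx + int(np.ceil(rx)) + 2,
                cy - int(np.ceil(ry)) - 2, cy + int(np.ceil(ry)) + 2,
                cz - int(np.ceil(rz)) - 2, cz + int(np.ceil(rz)) + 2,
            )
            if all(_boxes_separated(box, b) for b in boxes):
                placed = True
                break
        if not placed:
            raise ValueError(
                f"could not place focus {fid}; grid too crowded for n_foci={config.n_foci}"
            )
        boxes.append(box)
        x0, x1 = max(0, box[0]), min(nx, box[1] + 1)
        y0, y1 = max(0, box[2]), min(ny, box[3] + 1)
        z0, z1 = max(0, box[4]), min(nz, box[5] + 1)
        xs, ys, zs = np.meshgrid(
            np.arange(x0, x1), np.arange(y0, y1), np.arange(z0, z1), indexing="ij"
        )
        inside = (
            ((xs - cx) / max(rx, 0.5)) ** 2
            + ((ys - cy) / max(ry, 0.5)) ** 2
            + ((zs - cz) / max(rz, 0.5)) ** 2
        ) <= 1.0
        labels[x0:x1, y0:y1, z0:z1][inside] = fid
        foci.append(
            {"id": fid, "center": (cx, cy, cz), "r_um": r_um, "aspect": aspect, "he": he}
        )
    return labels, foci


def _boxes_separated(a, b) -> bool:
    # disjoint along at least one axis, with the margin already baked in
    for ax in range(3):
        if a[2 * ax + 1] < b[2 * ax] or b[2 * ax + 1] < a[2 * ax]:
            return True
    return False


def select_he_foci(labels: np.ndarray, n_exudates: int):
    """Pick the ``n_exudates`` axially tallest foci as hard-exudate-destined.

    Returns ``(ids, enface_label_mask)`` where the 2D mask carries each
    selected focus's en-face footprint under its label id.
    """
    ids = np.unique(labels)
    ids = ids[ids > 0]
    extents = []
    for lid in ids:
        zs = np.argwhere(labels == lid)[:, 2]
        extents.append((zs.max() - zs.min() + 1, int(lid)))
    extents.sort(reverse=True)
    chosen = sorted(lid for _, lid in extents[:n_exudates])
    enface = np.zeros(labels.shape[:2], dtype=np.int32)
    for lid in chosen:
        footprint = (labels == lid).any(axis=2)
        enface[footprint] = lid
    return chosen, enface


def generate_fundus_phantom(
    config: PhantomConfig, truth_transform: TransformModel, he_subset: np.ndarray
) -> FundusPhantom:
    """Paired fundus photograph: exudate blobs at the transform preimages
    of the selected focus footprints, dark vessel lines, and >= 4 exact
    vessel-intersection landmarks.

    ``he_subset`` is a 2D en-face labelled mask of the HE-destined focus
    footprints.  Blobs whose preimage falls (partly) outside the fundus
    frame are clipped and their ids reported in ``clipped_he_ids``.
    """
    rng = np.random.default_rng([config.rng_seed, 1])
    fx, fy = config.fundus_dims
    he_subset = np.asarray(he_subset)

    # preimage of the footprint mask: sample the en-face labels at t(p)
    gx, gy = np.meshgrid(np.arange(fx), np.arange(fy), indexing="ij")
    pts = np.column_stack([gx.ravel(), gy.ravel()]).astype(float)
    mapped = truth_transform.apply(pts)
    mx = np.rint(mapped[:, 0]).reshape(fx, fy).astype(int)
    my = np.rint(mapped[:, 1]).reshape(fx, fy).astype(int)
    nx, ny = he_subset.shape
    in_frame = (mx >= 0) & (mx < nx) & (my >= 0) & (my < ny)
    he_labels_fundus = np.zeros((fx, fy), dtype=np.int32)
    he_labels_fundus[in_frame] = he_subset[mx[in_frame], my[in_frame]]
    he_mask = (he_labels_fundus > 0).astype(np.uint8)

    clipped = []
    for lid in np.unique(he_subset[he_subset > 0]):
        n_src = int((he_subset == lid).sum())
        # expected preimage pixel count is n_src / det(scale part)
        n_dst = int((he_labels_fundus == lid).sum())
        expected = n_src / abs(np.linalg.det(truth_transform.matrix[:2, :2]))
        if n_dst < 0.5 * expected:
            clipped.append(int(lid))

    rgb = np.zeros((fx, fy, 3), dtype=np.float64)
    rgb[:] = _RGB_RETINA
    vessel_mask, landmarks_fundus = _draw_vessels(rgb, config, rng)
    rgb[he_mask > 0] = _RGB_EXUDATE
    rgb += rng.normal(0, _FUNDUS_NOISE_SD, size=rgb.shape)
    rgb = np.clip(np.rint(rgb), 0, 255).astype(np.uint8)

    pairs = [
        (tuple(p), tuple(truth_transform.apply([p])[0])) for p in landmarks_fundus
    ]
    return FundusPhantom(
        fundus=FundusImage(rgb=rgb),
        he_mask=he_mask,
        vessel_mask=vessel_mask,
        landmarks=LandmarkSet(pairs=pairs),
        clipped_he_ids=clipped,
    )


def _draw_vessels(rgb: np.ndarray, config: PhantomConfig, rng):
    """Two x-running and two y-running dark lines; returns the vessel mask
    and the four exact line-intersection points (fundus frame)."""
    fx, fy = rgb.shape[:2]
    mask = np.zeros((fx, fy), dtype=bool)
    # family A runs along x (endpoints on the x-borders), family B along y
    a_lines, b_lines = [], []
    for frac in rng.uniform(0.25, 0.45), rng.uniform(0.6, 0.8):
        y0 = frac * (fy - 1) + rng.uniform(-3, 3)
        y1 = frac * (fy - 1) + rng.uniform(-3, 3)
        a_lines.append(((0.0, y0), (fx - 1.0, y1)))
    for frac in rng.uniform(0.25, 0.45), rng.uniform(0.6, 0.8):
        x0 = frac * (fx - 1) + rng.uniform(-3, 3)
        x1 = frac * (fx - 1) + rng.uniform(-3, 3)
        b_lines.append(((x0, 0.0), (x1, fy - 1.0)))
    for (p0, p1) in a_lines + b_lines:
        rr, cc = skline(
            int(round(p0[0])), int(round(p0[1])), int(round(p1[0])), int(round(p1[1]))
        )
        mask[rr, cc] = True
    if config.vessel_width_px > 1:
        mask = ndimage.binary_dilation(
            mask, iterations=config.vessel_width_px - 1
        )
    rgb[mask] = _RGB_VESSEL

    points = []
    for a in a_lines:
        for b in b_lines:
            points.append(_line_intersection(a, b))
    return mask.astype(np.uint8), points


def _line_intersection(a, b):
    (x1, y1), (x2, y2) = a
    (x3, y3), (x4, y4) = b
    d = (x1 - x2) * (y3 - y4) - (y1 - y2) * (x3 - x4)
    px_ = ((x1 * y2 - y1 * x2) * (x3 - x4) - (x1 - x2) * (x3 * y4 - y3 * x4)) / d
    py_ = ((x1 * y2 - y1 * x2) * (y3 - y4) - (y1 - y2) * (x3 * y4 - y3 * x4)) / d
    return (px_, py_)


def generate_case(config: PhantomConfig, eye_id: str = "", label: str = "") -> PhantomCase:
    """Assemble one fully ground-truthed synthetic eye."""
    vol, surfaces, labels, foci = _generate_oct(config)
    vol.eye_id = eye_id
    vol.label = label or None
    he_ids, he_enface = select_he_foci(labels, config.n_exudates)
    t = make_truth_transform(config)
    fp = generate_fundus_phantom(config, t, he_enface)
    fp.fundus.eye_id = eye_id
    rng = np.random.default_rng([config.rng_seed, 2])
    nx, ny, _ = config.grid_dims
    fovea = (
        int(nx // 2 + rng.integers(-nx // 16, nx // 16 + 1)),
        int(ny // 2 + rng.integers(-max(ny // 16, 1), max(ny // 16, 1) + 1)),
    )
    vol.fovea = fovea
    return PhantomCase(
        eye_id=eye_id,
        oct=vol,
        fundus=fp.fundus,
        truth_layers=surfaces,
        truth_foci_mask=(labels > 0).astype(np.uint8),
        truth_foci_labels=labels,
        truth_he_focus_ids=he_ids,
        truth_he_mask_fundus=fp.he_mask,
        truth_he_mask_enface=(he_enface > 0).astype(np.uint8),
        truth_vessel_mask=fp.vessel_mask,
        truth_transform=t,
        landmarks=fp.landmarks,
        fovea=fovea,
        severity_label=label,
        config=config,
        clipped_he_ids=fp.clipped_he_ids,
    )


def synthetic_agreement_pairs(cohort, slope: float, noise_frac: float = 0.03, rng_seed: int = 0):
    """Paired per-eye hard-exudate area measurements with a controlled
    linear relation: the fundus-side area is each case's ground-truth HE
    area, the OCT-side area is ``slope`` times that plus small Gaussian
    noise (``noise_frac`` of the mean area).  Used to exercise the
    agreement statistics with a known answer.
    """
    import pandas as pd

    rng = np.random.default_rng([rng_seed, 11])
    rows = []
    for case in cohort:
        s = case.truth_transform.matrix[:2, :2]
        px, py, _ = case.config.voxel_pitch_um
        pix_area_mm2 = abs(np.linalg.det(s)) * px * py / 1e6
        cfp = float(case.truth_he_mask_fundus.sum()) * pix_area_mm2
        rows.append({"eye_id": case.eye_id, "label": case.severity_label, "cfp_area": cfp})
    df = pd.DataFrame(rows)
    sd = noise_frac * df["cfp_area"].mean()
    df["oct_area"] = slope * df["cfp_area"] + rng.normal(0, sd, len(df))
    return df


@dataclass(frozen=True)
class CohortRanges:
    """Per-severity sampling ranges (inclusive) for the cohort generator.

    PDR eyes carry more foci and more fundus-visible exudates than NPDR
    eyes, matching the direction of the clinical severity contrast.
    """

    npdr_foci: tuple = (4, 7)
    pdr_foci: tuple = (9, 14)
    npdr_exudates: tuple = (1, 3)
    pdr_exudates: tuple = (4, 7)
    grid_dims: tuple = (128, 32, 256)


def generate_cohort(
    n_npdr: int,
    n_pdr: int,
    config_ranges: CohortRanges | None = None,
    rng_seed: int = 0,
) -> list:
    """A labelled cohort of synthetic eyes with per-case derived seeds."""
    if n_npdr < 0 or n_pdr < 0:
        raise ValueError("cohort sizes must be nonnegative")
    ranges = config_ranges or CohortRanges()
    rng = np.random.default_rng([rng_seed, 7])
    cases = []
    specs = [("NPDR", ranges.npdr_foci, ranges.npdr_exudates)] * n_npdr + [
        ("PDR", ranges.pdr_foci, ranges.pdr_exudates)
    ] * n_pdr
    for i, (label, foci_rng, exu_rng) in enumerate(specs):
        n_foci = int(rng.integers(foci_rng[0], foci_rng[1] + 1))
        n_exu = min(int(rng.integers(exu_rng[0], exu_rng[1] + 1)), n_foci)
        seed = int(rng.integers(0, 2**31 - 1))
        cfg = PhantomConfig(
            grid_dims=ranges.grid_dims,
            n_foci=n_foci,
            n_exudates=n_exu,
            rng_seed=seed,
        )
        cases.append(generate_case(cfg, eye_id=f"eye{i:03d}", label=label))
    return cases
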