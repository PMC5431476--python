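"""End-to-end orchestration: phantom cohort -> registration -> HE
segmentation -> layer segmentation -> HRF detection -> features ->
agreement statistics -> severity classification.

A run is configured by a JSON-serialisable dict, is deterministic given
its seed, and writes per-stage artifacts plus a manifest (seed,
parameters, per-stage timings, artifact checksums) under the output
directory.
"""

from __future__ import annotations

import hashlib
import json
import time
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage

from . import classify, features_stats, he_seg, hrf_seg, io_formats, oct_layers
from . import phantom as ph
from . import registration as reg

DEFAULT_CONFIG = {
    "out_dir": "retmodal_run",
    "seed": 0,
    "cohort": {"n_npdr": 14, "n_pdr": 19, "grid_dims": [128, 32, 256]},
    "registration": {"kind": "similarity"},
    "he_seg": {
        "scales": [2, 4, 8],
        "threshold": "fixed",
        "fixed_threshold": 25.0,
        "min_area_px": 5,
        "use_vessel_correction": True,
    },
    "hrf": {"k": 4.0, "delta": 10.0, "margin_vox": 2, "min_voxels": 3},
    "split": {"min_overlap_frac": 0.5},
    "svm": {
        "c_grid": [0.0625, 1.0, 16.0],
        "g_grid": [0.0625, 1.0, 16.0],
        "inner_folds": 3,
    },
    "write_volumes": False,
}

_REQUIRED = {
    "out_dir": str,
    "seed": int,
    "cohort": dict,
    "he_seg": dict,
    "hrf": dict,
    "svm": dict,
}


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name and eye id."""

    def __init__(self, stage: str, eye_id: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed on eye {eye_id!r}: {cause}")
        self.stage = stage
        self.eye_id = eye_id
        self.cause = cause


def merge_config(overrides: dict | None = None) -> dict:
    cfg = json.loads(json.dumps(DEFAULT_CONFIG))
    for key, val in (overrides or {}).items():
        if isinstance(val, dict) and isinstance(cfg.get(key), dict):
            cfg[key].update(val)
        else:
            cfg[key] = val
    return cfg


def validate_config(config: dict) -> list:
    """All schema violations at once; an empty list means valid."""
    issues = []
    for key, typ in _REQUIRED.items():
        if key not in config:
            issues.append(f"missing required field {key!r}")
        elif not isinstance(config[key], typ):
            issues.append(f"field {key!r} must be {typ.__name__}")
    cohort = config.get("cohort", {})
    if isinstance(cohort, dict):
        for k in ("n_npdr", "n_pdr"):
            if not isinstance(cohort.get(k), int) or cohort.get(k, -1) < 0:
                issues.append(f"cohort.{k} must be a nonnegative integer")
        dims = cohort.get("grid_dims")
        if not (isinstance(dims, (list, tuple)) and len(dims) == 3 and all(
            isinstance(d, int) and d > 0 for d in dims
        )):
            issues.append("cohort.grid_dims must be three positive integers")
    hs = config.get("he_seg", {})
    if isinstance(hs, dict):
        scales = hs.get("scales")
        if not (isinstance(scales, (list, tuple)) and scales and all(
            isinstance(s, int) and s >= 1 for s in scales
        ) and list(scales) == sorted(set(scales))):
            issues.append("he_seg.scales must be strictly increasing positive ints")
    svm = config.get("svm", {})
    if isinstance(svm, dict):
        for grid in ("c_grid", "g_grid"):
            g = svm.get(grid)
            if not (isinstance(g, (list, tuple)) and g and all(
                isinstance(v, (int, float)) and v > 0 for v in g
            )):
                issues.append(f"svm.{grid} must be a nonempty list of positive numbers")
    return issues


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def process_eye(case: ph.PhantomCase, config: dict) -> dict:
    """All per-eye stages for one phantom case; returns per-eye results."""
    eye = case.eye_id
    try:
        t_est = reg.estimate_transform(
            case.landmarks, config["registration"]["kind"]
        )
    except Exception as exc:  # noqa: BLE001 - rethrown with context
        raise StageError("registration", eye, exc) from exc

    try:
        surfaces = oct_layers.build_surfaces(case.oct)
        enface = reg.project_enface(case.oct, surfaces)
    except Exception as exc:
        raise StageError("layers", eye, exc) from exc

    nx, ny, _ = case.oct.shape
    try:
        cropped, validity = reg.warp_crop_fundus(case.fundus, t_est, (nx, ny))
        hs = config["he_seg"]
        sal_cfg = he_seg.SaliencyConfig(
            scales=tuple(hs["scales"]),
            threshold_method=hs.get("threshold", "otsu"),
            fixed_threshold=hs.get("fixed_threshold"),
            min_area_px=hs["min_area_px"],
        )
        smap = he_seg.saliency_multiscale(
            he_seg.rgb_to_lab(case.fundus.rgb), sal_cfg
        )
        he_mask_fundus = he_seg.segment_he(smap, sal_cfg)
        if hs.get("use_vessel_correction", True):
            # stand-in for the clinician's pseudo-exudate removal
            vessels = ndimage.binary_dilation(
                case.truth_vessel_mask.astype(bool), iterations=1
            )
            he_mask_fundus = he_seg.apply_correction(
                he_mask_fundus, remove_mask=vessels.astype(np.uint8)
            )
        he_mask_enface = reg.warp_mask_to_enface(he_mask_fundus, t_est, (nx, ny))
    except Exception as exc:
        raise StageError("he_seg", eye, exc) from exc

    try:
        hrf_cfg = config["hrf"]
        lesions = hrf_seg.detect_hrf(
            case.oct,
            surfaces,
            k=hrf_cfg["k"],
            delta=hrf_cfg["delta"],
            margin_vox=hrf_cfg["margin_vox"],
            min_voxels=hrf_cfg["min_voxels"],
        )
        hmap = hrf_seg.height_map(lesions, case.oct.voxel_pitch_um[2])
        he_lesions, focus_lesions = hrf_seg.split_by_he(
            lesions, he_mask_enface, config["split"]["min_overlap_frac"]
        )
    except Exception as exc:
        raise StageError("hrf", eye, exc) from exc

    try:
        groups = {
            "HEs": he_lesions,
            "HRF_excl_HE": focus_lesions,
            "HRF_incl_HE": lesions,
        }
        feats = {
            name: features_stats.compute_eye_features(
                ls, case.oct, case.fovea, eye_id=eye, label=case.severity_label
            )
            for name, ls in groups.items()
        }
    except Exception as exc:
        raise StageError("features", eye, exc) from exc

    px, py, _ = case.oct.voxel_pitch_um
    s = case.truth_transform.matrix[:2, :2]
    fundus_px_area_mm2 = abs(np.linalg.det(s)) * px * py / 1e6
    cfp_area = float(he_mask_fundus.sum()) * fundus_px_area_mm2
    oct_area = sum(
        len(l.columns) for l in he_lesions.lesions
    ) * px * py / 1e6
    return {
        "eye_id": eye,
        "label": case.severity_label,
        "transform": t_est,
        "surfaces": surfaces,
        "enface": enface,
        "cropped": cropped,
        "he_mask_fundus": he_mask_fundus,
        "he_mask_enface": he_mask_enface,
        "lesions": lesions,
        "he_lesions": he_lesions,
        "focus_lesions": focus_lesions,
        "height_map": hmap,
        "features": feats,
        "cfp_area": cfp_area,
        "oct_area": oct_area,
    }


def _feature_matrix(rows):
    """(X, y) from EyeFeatures; undefined means are zero lesion load."""
    X = np.array(
        [
            [
                0.0 if not f.defined else f.avg_area_mm2,
                float(f.amount),
                0.0 if not f.defined else f.avg_distance_um,
                0.0 if not f.defined else f.avg_altitude_um,
                0.0 if not f.defined else f.avg_reflectivity,
            ]
            for f in rows
        ]
    )
    y = np.array([f.label for f in rows])
    return X, y


def run_end_to_end(config: dict | None = None) -> dict:
    """Execute every stage on a phantom cohort and write the report bundle."""
    config = merge_config(config)
    issues = validate_config(config)
    if issues:
        raise ValueError("invalid run config: " + "; ".join(issues))
    out = Path(config["out_dir"])
    out.mkdir(parents=True, exist_ok=True)
    timings = {}

    t0 = time.time()
    cohort_cfg = config["cohort"]
    ranges = ph.CohortRanges(grid_dims=tuple(cohort_cfg["grid_dims"]))
    cases = ph.generate_cohort(
        cohort_cfg["n_npdr"], cohort_cfg["n_pdr"], ranges, rng_seed=config["seed"]
    )
    timings["phantom"] = time.time() - t0

    t0 = time.time()
    results = [process_eye(case, config) for case in cases]
    timings["per_eye_stages"] = time.time() - t0

    # feature tables per lesion group
    t0 = time.time()
    artifacts = []
    tables = {}
    for group in ("HEs", "HRF_excl_HE", "HRF_incl_HE"):
        rows = [r["features"][group] for r in results]
        path = out / f"features_{group}.csv"
        io_formats.write_feature_table([f.as_row() for f in rows], path)
        artifacts.append(path)
        tables[group] = rows

    agree_tbl = pd.DataFrame(
        [
            {"eye_id": r["eye_id"], "label": r["label"],
             "cfp_area": r["cfp_area"], "oct_area": r["oct_area"]}
            for r in results
        ]
    )
    agree_path = out / "agreement_pairs.csv"
    agree_tbl.to_csv(agree_path, index=False)
    artifacts.append(agree_path)
    report = features_stats.agreement_report(agree_tbl)
    report_path = out / "agreement_report.csv"
    report.to_csv(report_path, index=False)
    artifacts.append(report_path)
    timings["statistics"] = time.time() - t0

    t0 = time.time()
    svm_cfg = classify.SvmConfig(
        c_grid=tuple(config["svm"]["c_grid"]),
        g_grid=tuple(config["svm"]["g_grid"]),
        inner_folds=config["svm"]["inner_folds"],
    )
    feature_tables = {}
    for group, rows in tables.items():
        X, y = _feature_matrix(rows)
        Xn = features_stats.normalize_features(
            X, features_stats.FEATURE_NAMES, on_constant="zero"
        )
        feature_tables[group] = (Xn, y)
    severity = classify.severity_report(feature_tables, svm_cfg)
    sev_path = out / "severity_report.csv"
    severity.to_csv(sev_path, index=False)
    (out / "severity_report.txt").write_text(classify.format_report(severity))
    artifacts.extend([sev_path, out / "severity_report.txt"])
    timings["classification"] = time.time() - t0

    if config.get("write_volumes"):
        for case in cases:
            vol_path = out / f"{case.eye_id}.tif"
            io_formats.write_volume(case.oct, vol_path)
            artifacts.append(vol_path)

    manifest = {
        "seed": config["seed"],
        "config": config,
        "n_eyes": len(cases),
        "eyes": [
            {"eye_id": c.eye_id, "label": c.severity_label} for c in cases
        ],
        "timings_s": {k: round(v, 3) for k, v in timings.items()},
        "artifacts": {str(p.relative_to(out)): _sha256(p) for p in artifacts},
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return manifest
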