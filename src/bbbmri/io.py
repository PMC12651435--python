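"""NIfTI / CSV input-output with validation.

Volumes travel as NIfTI-1 files whose affine encodes the voxel size (world
units mm); label and mask volumes are integer NIfTI.  Tables are UTF-8 CSV.
Studies are directories with one file per modality (``T1w.nii``,
``DWI.nii``, ``FLAIR.nii``, optionally ``T1w_post.nii``), a ``VOI.nii``
mask and ``prob_GM/WM/CSF.nii`` class probabilities.
"""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .types import MODALITIES, GroundTruth, MultimodalStudy

AFFINE_TOL = 1e-4

EVENT_COLUMNS = ("kind", "onset_hours", "duration_min")


def _nifti(path: Path) -> nib.Nifti1Image:
    return nib.load(str(path))


def write_volume(path: Path, data: np.ndarray, voxel_size, dtype=None) -> None:
    affine = np.diag(list(voxel_size) + [1.0])
    arr = np.asarray(data)
    if dtype is not None:
        arr = arr.astype(dtype)
    elif arr.dtype == bool:
        arr = arr.astype(np.uint8)
    nib.save(nib.Nifti1Image(arr, affine), str(path))


def write_study(study: MultimodalStudy, directory: Path,
                truth: GroundTruth | None = None) -> None:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    vs = study.voxel_size
    for name, vol in study.modalities.items():
        write_volume(directory / f"{name}.nii", vol, vs)
    if study.voi is not None:
        write_volume(directory / "VOI.nii", study.voi, vs)
    if study.class_probabilities is not None:
        for cls, vol in study.class_probabilities.items():
            write_volume(directory / f"prob_{cls}.nii", vol, vs)
    if truth is not None:
        write_volume(directory / "truth_labels.nii", truth.label_volume, vs, np.int16)
        write_volume(directory / "truth_bbbd.nii", truth.bbbd_mask, vs)
        write_volume(directory / "truth_enhancement.nii", truth.enhancement_truth, vs)
        for name, mask in truth.roi_masks.items():
            write_volume(directory / f"roi_{name}.nii", mask, vs)
        meta = {"roi_names": sorted(truth.roi_masks), "voxel_size": list(vs)}
        (directory / "truth_meta.json").write_text(json.dumps(meta, indent=2))


def read_study(directory: Path, required: tuple[str, ...] = MODALITIES
               ) -> MultimodalStudy:
    """Load a study directory; all volumes must share grid and affine."""
    directory = Path(directory)
    imgs: dict[str, nib.Nifti1Image] = {}
    for name in required:
        path = directory / f"{name}.nii"
        if not path.exists():
            raise FileNotFoundError(f"missing modality {name!r}: {path}")
        imgs[name] = _nifti(path)
    for name in ("T1w_post",):
        path = directory / f"{name}.nii"
        if path.exists():
            imgs[name] = _nifti(path)
    ref_name = required[0]
    ref = imgs[ref_name]
    for name, img in imgs.items():
        if img.shape != ref.shape:
            raise ValueError(f"grid mismatch: {name} {img.shape} != {ref_name} {ref.shape}")
        if np.max(np.abs(img.affine - ref.affine)) > AFFINE_TOL:
            raise ValueError(f"affine mismatch beyond {AFFINE_TOL}: {directory / name}.nii")
    voxel_size = tuple(float(v) for v in nib.affines.voxel_sizes(ref.affine))
    voi = None
    voi_path = directory / "VOI.nii"
    if voi_path.exists():
        voi = np.asarray(_nifti(voi_path).dataobj).astype(bool)
    probs = None
    if all((directory / f"prob_{c}.nii").exists() for c in ("GM", "WM", "CSF")):
        probs = {c: np.asarray(_nifti(directory / f"prob_{c}.nii").dataobj, dtype=float)
                 for c in ("GM", "WM", "CSF")}
    modalities = {name: np.asarray(img.dataobj, dtype=float) for name, img in imgs.items()}
    return MultimodalStudy(modalities=modalities, voxel_size=voxel_size, voi=voi,
                           class_probabilities=probs, subject_id=directory.name)


def read_truth(directory: Path) -> GroundTruth:
    directory = Path(directory)
    labels = np.asarray(_nifti(directory / "truth_labels.nii").dataobj).astype(np.int16)
    bbbd = np.asarray(_nifti(directory / "truth_bbbd.nii").dataobj).astype(bool)
    enh = np.asarray(_nifti(directory / "truth_enhancement.nii").dataobj, dtype=float)
    meta = json.loads((directory / "truth_meta.json").read_text())
    rois = {name: np.asarray(_nifti(directory / f"roi_{name}.nii").dataobj).astype(bool)
            for name in meta["roi_names"]}
    return GroundTruth(label_volume=labels, bbbd_mask=bbbd,
                       enhancement_truth=enh, roi_masks=rois)


def write_templates(templates, directory: Path, voxel_size) -> None:
    from .preprocessing import TemplateSet  # noqa: F401  (type only)

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for m in templates.modalities:
        write_volume(directory / f"template_mean_{m}.nii", templates.mean[m], voxel_size)
        write_volume(directory / f"template_var_{m}.nii", templates.variance[m], voxel_size)
    write_volume(directory / "template_voi.nii", templates.voi, voxel_size)
    meta = {"n_controls": templates.n_controls, "modalities": list(templates.modalities),
            "variance_floor": templates.variance_floor}
    (directory / "template_meta.json").write_text(json.dumps(meta, indent=2))


def read_templates(directory: Path):
    from .preprocessing import TemplateSet

    directory = Path(directory)
    meta = json.loads((directory / "template_meta.json").read_text())
    mods = tuple(meta["modalities"])
    mean = {m: np.asarray(_nifti(directory / f"template_mean_{m}.nii").dataobj, float)
            for m in mods}
    var = {m: np.asarray(_nifti(directory / f"template_var_{m}.nii").dataobj, float)
           for m in mods}
    voi = np.asarray(_nifti(directory / "template_voi.nii").dataobj).astype(bool)
    return TemplateSet(mean=mean, variance=var, voi=voi,
                       n_controls=meta["n_controls"],
                       variance_floor=meta["variance_floor"], modalities=mods)


# -- tables ------------------------------------------------------------------

COHORT_RANGES = {"WFNS": (1, 5), "MRS_Day14": (0, 6)}


def read_cohort(csv_path: Path, outcome: str = "outcome"
                ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Cohort CSV with typed columns and row-level range validation.

    Returns ``(table, flags)`` where ``flags`` lists (row, column, value) for
    out-of-range entries (e.g. WFNS outside 1..5).  Unknown columns error.
    """
    from .synthetic import PREDICTOR_NAMES

    df = pd.read_csv(csv_path)
    if df.empty:
        raise ValueError(f"empty cohort file: {csv_path}")
    known = set(PREDICTOR_NAMES) | {outcome, "patient_id"}
    unknown = [c for c in df.columns if c not in known]
    if unknown:
        raise ValueError(f"unknown cohort columns: {unknown}")
    flags = []
    for col, (lo, hi) in COHORT_RANGES.items():
        if col not in df.columns:
            continue
        vals = df[col]
        bad = vals.notna() & ((vals < lo) | (vals > hi))
        flags.extend((int(i), col, float(vals[i])) for i in df.index[bad])
    flags_df = pd.DataFrame(flags, columns=["row", "column", "value"])
    return df, flags_df


def read_events(csv_path: Path) -> pd.DataFrame:
    df = pd.read_csv(csv_path)
    missing = set(EVENT_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"event file {csv_path} lacks columns {sorted(missing)}")
    return df
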