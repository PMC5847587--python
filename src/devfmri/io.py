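"""File-format glue: the plain-text pipeline inputs and outputs.

Timecourses travel as long TSV (subject_id, roi, tr, value; 1-based TRs),
motion as TSV (subject_id, tr, composite_motion_mm), metadata and ROI
tables as CSV, events as CSV, permutation results as JSON. An optional
NIfTI reader extracts sphere-ROI voxel timecourses from a 4D image.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .acquisition import AcquisitionParams
from .prep import ArtifactMask, InputError, RoiTimecourseSet

_FLOAT_FMT = "%.10g"


def write_timecourses(
    path: Path | str, sets: list[RoiTimecourseSet]
) -> None:
    frames = []
    for ts in sets:
        n_rois, n_trs = ts.values.shape
        frames.append(
            pd.DataFrame(
                {
                    "subject_id": np.repeat(ts.subject_id, n_rois * n_trs),
                    "roi": np.repeat(ts.roi_names, n_trs),
                    "tr": np.tile(np.arange(1, n_trs + 1), n_rois),
                    "value": ts.values.ravel(),
                }
            )
        )
    pd.concat(frames, ignore_index=True).to_csv(
        path, sep="\t", index=False, float_format=_FLOAT_FMT
    )


def read_timecourses(
    path: Path | str,
    acq: AcquisitionParams,
    masks: dict[str, ArtifactMask] | None = None,
) -> list[RoiTimecourseSet]:
    df = pd.read_csv(path, sep="\t")
    out = []
    for sid, sub in df.groupby("subject_id", sort=False):
        wide = sub.pivot(index="roi", columns="tr", values="value")
        rois = sub["roi"].drop_duplicates().tolist()
        wide = wide.loc[rois, sorted(wide.columns)]
        values = wide.to_numpy()
        if masks is not None and sid in masks:
            mask = masks[sid]
        else:
            mask = ArtifactMask(np.isnan(values).any(axis=0))
        out.append(
            RoiTimecourseSet(
                subject_id=str(sid),
                values=values,
                roi_names=rois,
                mask=mask,
                acq=acq,
            )
        )
    return out


def write_motion(path: Path | str, motion: dict[str, np.ndarray]) -> None:
    frames = [
        pd.DataFrame(
            {
                "subject_id": sid,
                "tr": np.arange(1, len(m) + 1),
                "composite_motion_mm": m,
            }
        )
        for sid, m in motion.items()
    ]
    pd.concat(frames, ignore_index=True).to_csv(
        path, sep="\t", index=False, float_format=_FLOAT_FMT
    )


def read_motion(path: Path | str) -> dict[str, np.ndarray]:
    df = pd.read_csv(path, sep="\t")
    return {
        str(sid): sub.sort_values("tr")["composite_motion_mm"].to_numpy()
        for sid, sub in df.groupby("subject_id", sort=False)
    }


def extract_sphere_timecourses(
    image_path: Path | str, roi_table: pd.DataFrame
) -> tuple[np.ndarray, list[str]]:
    """Voxel timecourses from a 4D NIfTI for every sphere ROI.

    Voxels within ``radius_mm`` of each ROI's MNI center (world-to-voxel
    via the image affine) are extracted; returns a (n_voxels, n_volumes)
    matrix and the per-row ROI labels, ready for
    :func:`devfmri.prep.prepare_roi_timecourses`.
    """
    try:
        import nibabel as nib
    except ImportError as exc:  # pragma: no cover
        raise ImportError(
            "NIfTI input needs nibabel (pip install devfmri[nifti])"
        ) from exc
    img = nib.load(str(image_path))
    data = np.asanyarray(img.dataobj)
    if data.ndim != 4:
        raise InputError("expected a 4-D functional image")
    inv = np.linalg.inv(img.affine)
    shape = data.shape[:3]
    grid = np.array(
        np.meshgrid(*[np.arange(s) for s in shape], indexing="ij")
    ).reshape(3, -1)
    world = (
        img.affine[:3, :3] @ grid + img.affine[:3, 3:4]
    )  # mm coordinates of every voxel center
    rows, labels = [], []
    for _, roi in roi_table.iterrows():
        center = np.array([roi["x"], roi["y"], roi["z"]])[:, None]
        dist = np.linalg.norm(world - center, axis=0)
        idx = np.flatnonzero(dist <= roi["radius_mm"])
        if idx.size == 0:
            raise InputError(f"ROI {roi['name']}: no voxels inside sphere")
        flat = data.reshape(-1, data.shape[3])
        rows.append(flat[idx])
        labels.extend([roi["name"]] * idx.size)
    return np.vstack(rows), labels
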