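"""NIfTI I/O, ROI extraction and gray-level discretization.

Volumes are exchanged as one ``.nii.gz`` per modality plus one label-mask
``.nii.gz`` per subject, tied together by a cohort manifest CSV with one row
per subject (columns: ``subject_id``, one path column per modality, ``mask``).

Conventions: voxel indices are 0-based, axial slices run along the third
array axis, and voxel spacing is read from the NIfTI affine diagonal.
"""
from __future__ import annotations

import logging
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import nibabel as nib
import numpy as np
import pandas as pd

from ._types import (
    MODALITIES,
    REGION_CODES,
    DiscretizationConfig,
    MultiparametricSample,
    RoiInstance,
    RoiSlice,
)

logger = logging.getLogger(__name__)

#: Defaults below which an ROI (3D) or a plane (2D) is too small for texture.
MIN_REGION_VOXELS = 10
MIN_SLICE_VOXELS = 5


# ---------------------------------------------------------------------------
# NIfTI round trip
# ---------------------------------------------------------------------------

def save_sample(sample: MultiparametricSample, out_dir: str | Path) -> dict[str, str]:
    """Write one subject's volumes + mask; returns a manifest row (paths)."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    affine = np.diag(list(sample.voxel_spacing) + [1.0])
    row: dict[str, str] = {"subject_id": sample.subject_id}
    for mod, vol in sample.modalities.items():
        path = out_dir / f"{sample.subject_id}_{mod}.nii.gz"
        nib.save(nib.Nifti1Image(np.asarray(vol, dtype=np.float64), affine), path)
        row[mod] = str(path)
    mask_path = out_dir / f"{sample.subject_id}_mask.nii.gz"
    nib.save(nib.Nifti1Image(sample.label_mask.astype(np.uint8), affine), mask_path)
    row["mask"] = str(mask_path)
    return row


def save_cohort(
    samples: Iterable[MultiparametricSample], out_dir: str | Path
) -> Path:
    """Write every subject plus a manifest CSV; returns the manifest path."""
    out_dir = Path(out_dir)
    rows = [save_sample(s, out_dir) for s in samples]
    manifest = out_dir / "cohort_manifest.csv"
    pd.DataFrame(rows).to_csv(manifest, index=False)
    return manifest


def _spacing_from_affine(img: nib.Nifti1Image) -> tuple[float, float, float]:
    zooms = img.header.get_zooms()[:3]
    return tuple(float(z) for z in zooms)


def load_sample(
    manifest_row: Mapping[str, str],
    modalities: Sequence[str] = MODALITIES,
    allow_missing: bool = False,
) -> MultiparametricSample:
    """Load one subject from a manifest row.

    With ``allow_missing`` (degraded mode, e.g. cohorts acquired without an
    ADC map) absent modality columns are tolerated as long as at least one
    modality remains; otherwise a missing modality is an error.
    """
    present: dict[str, np.ndarray] = {}
    spacings: list[tuple[float, float, float]] = []
    for mod in modalities:
        path = manifest_row.get(mod)
        if path is None or (isinstance(path, float) and np.isnan(path)) or path == "":
            if allow_missing:
                logger.warning(
                    "subject %s: modality %s missing, continuing in degraded mode",
                    manifest_row.get("subject_id", "?"), mod,
                )
                continue
            raise ValueError(f"modality {mod} missing for subject "
                             f"{manifest_row.get('subject_id', '?')}")
        img = nib.load(path)
        present[mod] = np.asarray(img.dataobj, dtype=np.float64)
        spacings.append(_spacing_from_affine(img))
    if not present:
        raise ValueError("no modality volume could be loaded")
    mask_img = nib.load(manifest_row["mask"])
    mask = np.asarray(mask_img.dataobj).astype(np.int64)
    spacings.append(_spacing_from_affine(mask_img))
    if any(not np.allclose(s, spacings[0], rtol=1e-5) for s in spacings):
        raise ValueError(f"voxel spacings disagree across files: {spacings}")
    return MultiparametricSample(
        subject_id=str(manifest_row["subject_id"]),
        modalities=present,
        label_mask=mask,
        voxel_spacing=spacings[0],
    )


def load_cohort(
    manifest_path: str | Path,
    modalities: Sequence[str] = MODALITIES,
    allow_missing: bool = False,
) -> list[MultiparametricSample]:
    df = pd.read_csv(manifest_path)
    return [
        load_sample(row, modalities=modalities, allow_missing=allow_missing)
        for row in df.to_dict(orient="records")
    ]


# ---------------------------------------------------------------------------
# ROI extraction
# ---------------------------------------------------------------------------

def extract_rois(
    sample: MultiparametricSample,
    min_voxels: int = MIN_REGION_VOXELS,
    min_slice_voxels: int = MIN_SLICE_VOXELS,
) -> list[RoiInstance]:
    """Split a sample into per-subregion ROI instances.

    Regions smaller than ``min_voxels`` are skipped with a warning; axial
    planes with fewer than ``min_slice_voxels`` in-region voxels are dropped
    from the slice decomposition (texture on a handful of pixels is noise).
    """
    instances: list[RoiInstance] = []
    for code, region in REGION_CODES.items():
        region_mask = sample.label_mask == code
        n = int(region_mask.sum())
        if n == 0:
            continue
        if n < min_voxels:
            logger.warning(
                "subject %s: region %s has only %d voxels (< %d), skipped",
                sample.subject_id, region, n, min_voxels,
            )
            continue
        idx = np.nonzero(region_mask)
        lo = [int(i.min()) for i in idx]
        hi = [int(i.max()) + 1 for i in idx]
        box = tuple(slice(l, h) for l, h in zip(lo, hi))
        mask3d = region_mask[box]
        values = {
            mod: vol[region_mask].astype(np.float64)
            for mod, vol in sample.modalities.items()
        }
        slices: list[RoiSlice] = []
        for z in range(mask3d.shape[2]):
            plane_mask = mask3d[:, :, z]
            if int(plane_mask.sum()) < min_slice_voxels:
                continue
            images = {
                mod: np.where(plane_mask, vol[box][:, :, z], 0.0)
                for mod, vol in sample.modalities.items()
            }
            slices.append(RoiSlice(z_index=lo[2] + z, mask=plane_mask, images=images))
        if not slices:
            logger.warning(
                "subject %s: region %s has no axial plane with >= %d voxels, skipped",
                sample.subject_id, region, min_slice_voxels,
            )
            continue
        instances.append(
            RoiInstance(
                subject_id=sample.subject_id,
                region_label=region,
                mask3d=mask3d,
                modality_values=values,
                slices=slices,
                voxel_spacing=sample.voxel_spacing,
            )
        )
    return instances


# ---------------------------------------------------------------------------
# Discretization
# ---------------------------------------------------------------------------

def discretize(
    values: np.ndarray, cfg: DiscretizationConfig = DiscretizationConfig()
) -> np.ndarray:
    """Fixed-bin-count discretization onto integer levels 1..n_levels.

    The ROI minimum maps to level 1 and the maximum to ``n_levels``; a
    constant patch maps entirely to level 1.  Monotone: input ordering is
    preserved in the output levels.
    """
    v = np.asarray(values, dtype=np.float64)
    if v.size == 0:
        raise ValueError("cannot discretize an empty patch")
    vmin, vmax = float(v.min()), float(v.max())
    if vmax == vmin:
        return np.ones(v.shape, dtype=np.int64)
    levels = np.floor((v - vmin) / (vmax - vmin) * cfg.n_levels).astype(np.int64) + 1
    return np.clip(levels, 1, cfg.n_levels)
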