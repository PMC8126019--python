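"""Assembly of the full radiomics vector for one ROI instance.

Per modality the vector holds a fixed 329-feature block:

    16 first-order + 16 LBP-histogram + 8 shape + 22 GLCM + 11 GLRLM
    + 256 SIFT  =  329

With the standard four modalities (T1CE, T2W, FLAIR, ADC) this gives 1316
named features per (subject, subregion) ROI, decomposing as 128 intensity
histogram (64 first-order + 64 LBP), 32 geometry, 132 texture (88 GLCM +
44 GLRLM) and 1024 SIFT values.  Shape is recomputed per modality block
(the mask is shared, so the four shape sub-blocks coincide numerically) to
keep the per-modality block layout uniform.  Feature names are
``{modality}_{family}_{feature}`` and form the normative registry.
"""
from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .._types import MODALITIES, DiscretizationConfig, RoiInstance
from ..io import extract_rois
from .firstorder import FIRSTORDER_NAMES, firstorder_features
from .lbp import LBP_NAMES, lbp_features
from .shape import SHAPE_NAMES, shape_features
from .sift import SIFT_NAMES, sift_features
from .texture import (
    GLCM_NAMES,
    GLRLM_NAMES,
    compute_texture_matrices,
    glcm_features,
    glrlm_features,
)

logger = logging.getLogger(__name__)

#: family -> feature names within one modality block, in registry order
FAMILIES: dict[str, tuple[str, ...]] = {
    "firstorder": FIRSTORDER_NAMES,
    "lbp": LBP_NAMES,
    "shape": SHAPE_NAMES,
    "glcm": GLCM_NAMES,
    "glrlm": GLRLM_NAMES,
    "sift": SIFT_NAMES,
}

BLOCK_SIZE = sum(len(v) for v in FAMILIES.values())  # 329


def feature_names(modalities: Sequence[str] = MODALITIES) -> list[str]:
    """The full ordered feature-name registry for the given modalities."""
    return [
        f"{mod}_{family}_{name}"
        for mod in modalities
        for family, names in FAMILIES.items()
        for name in names
    ]


def export_registry(path: str | Path, modalities: Sequence[str] = MODALITIES) -> None:
    """Write the name registry (with modality/family/feature tags) as JSON."""
    entries = [
        {"name": f"{mod}_{family}_{name}", "modality": mod,
         "family": family, "feature": name}
        for mod in modalities
        for family, names in FAMILIES.items()
        for name in names
    ]
    Path(path).write_text(json.dumps(entries, indent=1))


@dataclass
class FeatureVector:
    """Ordered, named feature record for one (subject, subregion) ROI."""

    instance_ref: tuple[str, str]
    names: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if len(self.names) != self.values.size:
            raise ValueError("names and values disagree in length")
        if len(set(self.names)) != len(self.names):
            raise ValueError("feature names are not unique")
        if not np.all(np.isfinite(self.values)):
            bad = [n for n, v in zip(self.names, self.values) if not np.isfinite(v)]
            raise ValueError(
                f"{self.instance_ref}: non-finite feature values for {bad[:5]}"
            )

    def as_dict(self) -> dict[str, float]:
        return dict(zip(self.names, self.values.tolist()))


def extract_all(
    roi: RoiInstance, cfg: DiscretizationConfig = DiscretizationConfig()
) -> FeatureVector:
    """Compute the full per-modality feature blocks for one ROI instance."""
    names: list[str] = []
    values: list[float] = []
    context = f"{roi.subject_id}/{roi.region_label}"
    for mod in roi.modality_names:
        try:
            block = _modality_block(roi, mod, cfg)
        except Exception as err:
            raise RuntimeError(f"feature extraction failed for {context}, "
                               f"modality {mod}") from err
        for family, family_names in FAMILIES.items():
            feats = block[family]
            for name in family_names:
                names.append(f"{mod}_{family}_{name}")
                values.append(feats[name])
    return FeatureVector(
        instance_ref=(roi.subject_id, roi.region_label),
        names=names,
        values=np.asarray(values),
    )


def _modality_block(
    roi: RoiInstance, mod: str, cfg: DiscretizationConfig
) -> dict[str, dict[str, float]]:
    voxels = roi.modality_values[mod]
    slice_masks = [s.mask for s in roi.slices]
    slice_images = [s.images[mod] for s in roi.slices]

    # one ROI-wide discretization, applied consistently to every slice
    lo, hi = float(voxels.min()), float(voxels.max())
    if hi > lo:
        def to_levels(img: np.ndarray) -> np.ndarray:
            lev = np.floor((img - lo) / (hi - lo) * cfg.n_levels).astype(np.int64) + 1
            return np.clip(lev, 1, cfg.n_levels)
    else:
        def to_levels(img: np.ndarray) -> np.ndarray:
            return np.ones(img.shape, dtype=np.int64)
    slice_levels = [np.where(m, to_levels(img), 0) for img, m in
                    zip(slice_images, slice_masks)]

    matrices = compute_texture_matrices(slice_levels, slice_masks, cfg.n_levels)
    return {
        "firstorder": firstorder_features(voxels, cfg),
        "lbp": lbp_features(slice_levels, slice_masks),
        "shape": shape_features(roi.mask3d, roi.voxel_spacing),
        "glcm": glcm_features(matrices),
        "glrlm": glrlm_features(matrices),
        "sift": sift_features(slice_images, slice_masks,
                              context=f"{roi.subject_id}/{roi.region_label}/{mod}"),
    }


def extract_cohort_features(
    samples: Iterable,
    cfg: DiscretizationConfig = DiscretizationConfig(),
    min_voxels: int = 10,
) -> pd.DataFrame:
    """Feature table: one row per ROI, columns subject_id, region_label, features."""
    rows = []
    expected_names: list[str] | None = None
    for sample in samples:
        for roi in extract_rois(sample, min_voxels=min_voxels):
            fv = extract_all(roi, cfg)
            if expected_names is None:
                expected_names = fv.names
            elif fv.names != expected_names:
                raise ValueError(
                    f"{fv.instance_ref}: feature registry differs across ROIs "
                    "(mixed modality sets?)"
                )
            rows.append(
                {"subject_id": roi.subject_id, "region_label": roi.region_label,
                 **fv.as_dict()}
            )
    return pd.DataFrame(rows)
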