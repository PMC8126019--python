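"""Shared domain containers for multiparametric tumor-subregion analysis.

The pipeline works on co-registered multiparametric MR volumes (contrast
enhanced T1, T2-weighted, T2-FLAIR and ADC maps) together with an integer
label mask that codes four tumor subregions:

    1 = necrosis, 2 = solid (enhancing) part, 3 = peritumoral tissue,
    4 = peritumoral edema, 0 = background.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

#: Canonical modality order used everywhere a feature vector is assembled.
MODALITIES: tuple[str, ...] = ("T1CE", "T2W", "FLAIR", "ADC")

#: Label code -> subregion name, in anatomical (inside-out) order.
REGION_CODES: dict[int, str] = {
    1: "necrosis",
    2: "solid",
    3: "peritumoral",
    4: "edema",
}
REGION_NAMES: tuple[str, ...] = tuple(REGION_CODES.values())
NAME_TO_CODE: dict[str, int] = {v: k for k, v in REGION_CODES.items()}


@dataclass
class MultiparametricSample:
    """One subject: co-registered modality volumes plus a 4-class label mask."""

    subject_id: str
    modalities: Mapping[str, np.ndarray]
    label_mask: np.ndarray
    voxel_spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)

    def __post_init__(self) -> None:
        if not self.modalities:
            raise ValueError("sample must carry at least one modality volume")
        shapes = {m: v.shape for m, v in self.modalities.items()}
        if len(set(shapes.values())) != 1:
            raise ValueError(f"modality volumes disagree in shape: {shapes}")
        ref_shape = next(iter(shapes.values()))
        if self.label_mask.shape != ref_shape:
            raise ValueError(
                f"label mask shape {self.label_mask.shape} does not match "
                f"modality shape {ref_shape}"
            )
        codes = set(np.unique(self.label_mask).tolist())
        unknown = codes - ({0} | set(REGION_CODES))
        if unknown:
            raise ValueError(f"label mask contains unknown region codes {sorted(unknown)}")
        if len(self.voxel_spacing) != 3 or any(s <= 0 for s in self.voxel_spacing):
            raise ValueError(f"voxel spacing must be three positive floats, got {self.voxel_spacing}")

    @property
    def shape(self) -> tuple[int, ...]:
        return self.label_mask.shape

    @property
    def present_regions(self) -> list[str]:
        codes = np.unique(self.label_mask)
        return [REGION_CODES[int(c)] for c in codes if int(c) in REGION_CODES]


@dataclass
class RoiSlice:
    """One axial plane of an ROI: cropped modality patches plus the in-plane mask."""

    z_index: int
    mask: np.ndarray                       # 2D bool
    images: Mapping[str, np.ndarray]       # modality -> 2D float patch (cropped)

    @property
    def n_voxels(self) -> int:
        return int(self.mask.sum())


@dataclass
class RoiInstance:
    """One (subject, subregion) extraction unit.

    ``mask3d`` is the region's binary mask cropped to its bounding box; the
    axial ``slices`` are the in-plane decomposition used for the 2D texture
    and keypoint features.  ``modality_values`` holds the flattened masked
    voxel values per modality in a fixed scan order.
    """

    subject_id: str
    region_label: str
    mask3d: np.ndarray
    modality_values: Mapping[str, np.ndarray]
    slices: Sequence[RoiSlice]
    voxel_spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)

    def __post_init__(self) -> None:
        if self.region_label not in NAME_TO_CODE:
            raise ValueError(f"unknown region label {self.region_label!r}")
        n = int(self.mask3d.sum())
        for mod, vals in self.modality_values.items():
            if vals.shape != (n,):
                raise ValueError(
                    f"{self.subject_id}/{self.region_label}: modality {mod} has "
                    f"{vals.shape} values for {n} masked voxels"
                )
        if len(self.slices) == 0:
            raise ValueError(
                f"{self.subject_id}/{self.region_label}: ROI has no usable axial slice"
            )

    @property
    def modality_names(self) -> tuple[str, ...]:
        return tuple(self.modality_values)

    @property
    def n_voxels(self) -> int:
        return int(self.mask3d.sum())


@dataclass(frozen=True)
class DiscretizationConfig:
    """Fixed-bin-count gray-level discretization over the ROI's [min, max]."""

    n_levels: int = 64

    def __post_init__(self) -> None:
        if self.n_levels < 2:
            raise ValueError("need at least 2 gray levels")
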