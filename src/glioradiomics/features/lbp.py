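"""Local-binary-pattern histogram features on the axial slice decomposition.

LBP codes use the rotation-invariant uniform variant with P=8 samples on a
radius-1 circle, which yields 10 possible codes (0..8 for uniform patterns,
9 for non-uniform ones).  Codes are computed per slice on the discretized
patch (edge-replicated by one pixel so every masked pixel has a full
neighborhood), pooled over all slices at the masked positions, and summarized by the same 16
statistics as the first-order family, under ``LBP_``-prefixed names.
"""
from __future__ import annotations

import numpy as np
from skimage.feature import local_binary_pattern

from .firstorder import FIRSTORDER_NAMES, firstorder_features

LBP_P = 8
LBP_R = 1.0
#: number of distinct rotation-invariant uniform codes for P=8
LBP_N_CODES = LBP_P + 2

LBP_NAMES: tuple[str, ...] = tuple(f"LBP_{n}" for n in FIRSTORDER_NAMES)

MIN_SLICE_PIXELS = 9


def lbp_codes_for_slice(image: np.ndarray, mask: np.ndarray) -> np.ndarray:
    """Pooled LBP codes at the masked pixels of one 2D patch."""
    image = np.asarray(image)
    if not np.issubdtype(image.dtype, np.integer):
        # exact comparisons on floats are fine here, but skimage warns; the
        # pipeline always passes discretized integer levels
        image = image.astype(np.float64)
    padded = np.pad(image, 1, mode="edge")
    codes = local_binary_pattern(padded, LBP_P, LBP_R, method="uniform")
    return codes[1:-1, 1:-1][mask]


def lbp_features(
    slice_images: list[np.ndarray], slice_masks: list[np.ndarray]
) -> dict[str, float]:
    """The 16 summary statistics of the pooled LBP code histogram."""
    usable = [
        (img, m) for img, m in zip(slice_images, slice_masks) if m.sum() >= MIN_SLICE_PIXELS
    ]
    if not usable:
        raise ValueError("LBP requires at least one slice with >= 9 in-region pixels")
    pooled = np.concatenate([lbp_codes_for_slice(img, m) for img, m in usable])
    stats = firstorder_features(pooled)
    return {f"LBP_{k}": v for k, v in stats.items()}
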