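"""Scale-invariant feature transform (SIFT) descriptor aggregation.

Keypoints are detected per axial slice on the ROI patch (background inside
the bounding box is zero; intensities are rescaled to [0, 1] using the
ROI-wide range).  Descriptors whose keypoint falls inside the region mask
are pooled over all slices and summarized by the element-wise mean and
population standard deviation of the 128-dimensional descriptors, giving a
fixed, deterministic 256-value block.  An ROI without any keypoint (e.g. a
flat region) yields the zero vector and a logged warning.
"""
from __future__ import annotations

import logging

import numpy as np
from skimage.feature import SIFT

logger = logging.getLogger(__name__)

N_SIFT = 256

SIFT_NAMES: tuple[str, ...] = tuple(
    [f"SIFT_Mean_{i:03d}" for i in range(128)]
    + [f"SIFT_Std_{i:03d}" for i in range(128)]
)


def sift_descriptors_for_slice(image: np.ndarray, mask: np.ndarray) -> np.ndarray:
    """Descriptors (k x 128) of the keypoints lying inside the slice mask."""
    image = np.asarray(image, dtype=np.float64)
    if min(image.shape) < 8:  # too small for the SIFT scale space
        return np.empty((0, 128), dtype=np.float64)
    detector = SIFT()
    try:
        detector.detect_and_extract(image)
    except (RuntimeError, IndexError, ValueError):
        # no features found (flat slice) or patch too small for an octave
        return np.empty((0, 128), dtype=np.float64)
    kp = detector.keypoints  # (k, 2) row/col
    rows = np.clip(kp[:, 0], 0, mask.shape[0] - 1)
    cols = np.clip(kp[:, 1], 0, mask.shape[1] - 1)
    inside = mask[rows, cols]
    return detector.descriptors[inside].astype(np.float64)


def sift_features(
    slice_images: list[np.ndarray],
    slice_masks: list[np.ndarray],
    context: str = "",
) -> dict[str, float]:
    """Element-wise mean and sd of pooled in-region SIFT descriptors."""
    if not slice_images:
        raise ValueError("SIFT aggregation needs at least one slice")
    lo = min(float(np.min(img[m])) for img, m in zip(slice_images, slice_masks) if m.any())
    hi = max(float(np.max(img[m])) for img, m in zip(slice_images, slice_masks) if m.any())
    scale = hi - lo
    pooled: list[np.ndarray] = []
    for img, m in zip(slice_images, slice_masks):
        patch = np.where(m, (img - lo) / scale if scale > 0 else 0.0, 0.0)
        d = sift_descriptors_for_slice(patch, m)
        if d.size:
            pooled.append(d)
    if not pooled:
        logger.warning("no SIFT keypoint found%s; emitting zero descriptor block",
                       f" ({context})" if context else "")
        values = np.zeros(N_SIFT)
    else:
        d = np.vstack(pooled)
        values = np.concatenate([d.mean(axis=0), d.std(axis=0)])
    return dict(zip(SIFT_NAMES, values.tolist()))
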