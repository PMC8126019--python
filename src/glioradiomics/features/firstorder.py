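"""First-order (intensity histogram) statistics of a masked voxel set."""
from __future__ import annotations

import numpy as np
from scipy import stats

from .._types import DiscretizationConfig
from ..io import discretize

#: The 16 first-order statistics, in registry order.
FIRSTORDER_NAMES: tuple[str, ...] = (
    "Mean", "Median", "Minimum", "Maximum", "Range",
    "Variance", "StandardDeviation", "Skewness", "Kurtosis",
    "Energy", "Entropy", "Uniformity", "RootMeanSquare",
    "MeanAbsoluteDeviation", "Percentile10", "Percentile90",
)


def firstorder_features(
    values: np.ndarray, cfg: DiscretizationConfig = DiscretizationConfig()
) -> dict[str, float]:
    """The 16 first-order statistics of a 1D array of masked voxel values.

    Variance uses the population convention; skewness and (excess) kurtosis
    are set to 0 for zero-variance patches.  Entropy (bits) and uniformity
    are computed on the fixed-bin-count discretized histogram.
    """
    v = np.asarray(values, dtype=np.float64).ravel()
    if v.size == 0:
        raise ValueError("first-order statistics of an empty patch are undefined")
    mean = float(v.mean())
    if v.max() == v.min():  # constant patch: zero-variance conventions
        var, sd, skew, kurt = 0.0, 0.0, 0.0, 0.0
    else:
        var = float(v.var())
        sd = float(np.sqrt(var))
        skew = float(stats.skew(v, bias=True))
        kurt = float(stats.kurtosis(v, fisher=True, bias=True))
    levels = discretize(v, cfg)
    counts = np.bincount(levels)[1:]  # drop the empty 0 bin
    p = counts[counts > 0] / v.size
    entropy = float(-(p * np.log2(p)).sum())
    uniformity = float((p ** 2).sum())
    return {
        "Mean": mean,
        "Median": float(np.median(v)),
        "Minimum": float(v.min()),
        "Maximum": float(v.max()),
        "Range": float(v.max() - v.min()),
        "Variance": var,
        "StandardDeviation": sd,
        "Skewness": skew,
        "Kurtosis": kurt,
        "Energy": float((v ** 2).sum()),
        "Entropy": entropy,
        "Uniformity": uniformity,
        "RootMeanSquare": float(np.sqrt((v ** 2).mean())),
        "MeanAbsoluteDeviation": float(np.abs(v - mean).mean()),
        "Percentile10": float(np.percentile(v, 10)),
        "Percentile90": float(np.percentile(v, 90)),
    }
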