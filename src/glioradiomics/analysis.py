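"""Feature ranking by random-forest importance and correlation structure.

Importance scores (IS) are mean-impurity-decrease importances of forests
fitted on the whole feature table, averaged over several seeds to damp the
seed-to-seed jitter of tree construction; scores are normalized to sum to
one.  The top-k features (default k = 20) are then correlated pairwise and
against the subregion label, encoded ordinally 1-4 in the anatomical order
necrosis -> solid -> peritumoral -> edema, with either Pearson's r or
Spearman's rank coefficient.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from ._types import NAME_TO_CODE
from .classify import ClassifierSpec, make_estimator

logger = logging.getLogger(__name__)

LABEL_COLUMN = "region_label_code"


@dataclass
class ImportanceRanking:
    """Normalized importance scores with a deterministic rank order."""

    names: list[str]
    scores: np.ndarray          # aligned with names (registry order)
    order: np.ndarray           # indices sorted by descending score
    top_k: list[str]

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "name": [self.names[i] for i in self.order],
                "importance": self.scores[self.order],
                "rank": np.arange(1, len(self.order) + 1),
            }
        )


def rank_importance(
    features: pd.DataFrame,
    spec: ClassifierSpec | None = None,
    n_seeds: int = 10,
    top_k: int = 20,
) -> ImportanceRanking:
    """Rank features by seed-averaged random-forest impurity importance.

    Ties are broken by feature-registry (column) order, so ranks are
    reproducible.
    """
    if spec is None:
        spec = ClassifierSpec(family="random_forest")
    if spec.family != "random_forest":
        raise ValueError("importance ranking is defined for the random forest")
    meta = [c for c in ("subject_id", "region_label") if c in features.columns]
    X = features.drop(columns=meta).to_numpy(dtype=np.float64)
    y = features["region_label"].to_numpy()
    names = [c for c in features.columns if c not in meta]

    scores = np.zeros(X.shape[1])
    for s in range(n_seeds):
        fold_spec = ClassifierSpec(
            family="random_forest", params=spec.params, seed=spec.seed + s
        )
        model = make_estimator(fold_spec, n_features=X.shape[1])
        model.fit(X, y)
        scores += model.named_steps["clf"].feature_importances_
    scores /= n_seeds
    total = scores.sum()
    if total > 0:
        scores = scores / total
    order = np.lexsort((np.arange(len(scores)), -scores))
    return ImportanceRanking(
        names=names,
        scores=scores,
        order=order,
        top_k=[names[i] for i in order[:top_k]],
    )


@dataclass
class CorrelationMatrix:
    """Symmetric correlation matrix over selected features plus the label."""

    method: str
    columns: list[str]
    values: np.ndarray
    zero_variance_flags: list[str] = field(default_factory=list)

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.columns, columns=self.columns)


def correlation_matrix(
    features: pd.DataFrame,
    columns: list[str],
    method: str = "pearson",
) -> CorrelationMatrix:
    """Pairwise correlations of selected features and the encoded label.

    Zero-variance columns get coefficient 0 against everything (flagged);
    the diagonal stays 1.
    """
    if method not in ("pearson", "spearman"):
        raise ValueError("method must be 'pearson' or 'spearman'")
    if len(features) < 3:
        raise ValueError("need at least 3 samples for a correlation analysis")
    data = features[columns].copy()
    data[LABEL_COLUMN] = features["region_label"].map(NAME_TO_CODE)
    cols = list(data.columns)
    arr = data.to_numpy(dtype=np.float64)

    flags = [c for c, v in zip(cols, arr.T) if np.ptp(v) == 0]
    n = len(cols)
    out = np.eye(n)
    for a in range(n):
        for b in range(a + 1, n):
            if cols[a] in flags or cols[b] in flags:
                r = 0.0
            elif method == "pearson":
                r = float(stats.pearsonr(arr[:, a], arr[:, b]).statistic)
            else:
                r = float(stats.spearmanr(arr[:, a], arr[:, b]).statistic)
            out[a, b] = out[b, a] = r
    if flags:
        logger.warning("zero-variance columns in correlation analysis: %s", flags)
    return CorrelationMatrix(
        method=method, columns=cols, values=out, zero_variance_flags=flags
    )


def plot_heatmap(matrix: CorrelationMatrix, path: str | Path) -> None:
    """Render a correlation matrix as a heatmap PNG (pure presentation)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(10, 8))
    im = ax.imshow(matrix.values, vmin=-1, vmax=1, cmap="RdBu_r")
    ax.set_xticks(range(len(matrix.columns)))
    ax.set_yticks(range(len(matrix.columns)))
    ax.set_xticklabels(matrix.columns, rotation=90, fontsize=6)
    ax.set_yticklabels(matrix.columns, fontsize=6)
    fig.colorbar(im, ax=ax, label=f"{matrix.method} correlation")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
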