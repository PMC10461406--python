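"""Screen quality metrics: precision-recall against labeled gene sets,
replicate correlations with hierarchical clustering, and PCA of profiles."""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

__all__ = [
    "precision_recall",
    "recall_at_precision",
    "replicate_correlation",
    "pca_profiles",
]


def precision_recall(scores: pd.Series, positives: set[str],
                     negatives: set[str]) -> pd.DataFrame:
    """Precision-recall curve over labeled genes, ascending-score threshold.

    More negative scores mean stronger depletion, so the sweep calls the
    most-depleted labeled genes first. Unlabeled genes are ignored; tied
    scores enter together. Columns: threshold, n_called, tp, fp, precision,
    recall.
    """
    overlap = positives & negatives
    if overlap:
        raise ValueError(f"labels overlap: {sorted(overlap)[:5]}")
    labeled = scores[scores.index.isin(positives | negatives)].dropna()
    if labeled.empty or not (set(labeled.index) & positives) \
            or not (set(labeled.index) & negatives):
        raise ValueError("need at least one scored positive and one scored "
                         "negative gene")
    labeled = labeled.sort_values(kind="mergesort")
    is_pos = labeled.index.isin(positives)
    n_pos = int(is_pos.sum())
    tp = np.cumsum(is_pos)
    called = np.arange(1, len(labeled) + 1)
    # group ties: keep only the last row of each tied block
    vals = labeled.to_numpy()
    last = np.r_[vals[1:] != vals[:-1], True]
    df = pd.DataFrame({
        "threshold": vals[last],
        "n_called": called[last],
        "tp": tp[last],
    })
    df["fp"] = df["n_called"] - df["tp"]
    df["precision"] = df["tp"] / df["n_called"]
    df["recall"] = df["tp"] / n_pos
    return df


def recall_at_precision(scores: pd.Series, positives: set[str],
                        negatives: set[str],
                        min_precision: float = 0.95) -> float:
    """Recall at the most permissive threshold keeping precision >= target."""
    curve = precision_recall(scores, positives, negatives)
    ok = curve[curve["precision"] >= min_precision]
    return float(ok["recall"].max()) if len(ok) else 0.0


def replicate_correlation(lfc: pd.DataFrame,
                          ) -> tuple[pd.DataFrame, np.ndarray, list[str]]:
    """Pairwise Pearson correlations between profiles plus average-linkage
    clustering on 1 - r.

    ``lfc`` is guides x profiles; rows with any missing value are dropped
    (intersecting guides). Returns (correlation matrix, linkage matrix,
    deterministic leaf order).
    """
    if lfc.shape[1] < 2:
        raise ValueError("need >= 2 profiles")
    shared = lfc.dropna()
    if len(shared) < 3:
        raise ValueError(f"only {len(shared)} shared guides (< 3)")
    corr = shared.corr(method="pearson")
    dist = np.clip(1.0 - corr.to_numpy(), 0.0, None)
    np.fill_diagonal(dist, 0.0)
    link = hierarchy.average(squareform(dist, checks=False))
    order = hierarchy.leaves_list(link)
    labels = [corr.columns[i] for i in order]
    return corr, link, labels


def pca_profiles(values: pd.DataFrame, n_components: int = 2,
                 ) -> tuple[pd.DataFrame, np.ndarray]:
    """Centered PCA of sample profiles.

    ``values`` is guides x samples; each sample is a point in guide space.
    Returns (sample coordinates for the leading components, explained
    variance fractions). The sign convention makes each component's
    largest-magnitude loading positive.
    """
    X = values.to_numpy(dtype=float).T  # samples x guides
    X = X - X.mean(axis=0, keepdims=True)
    if np.allclose(X, 0):
        raise ValueError("constant matrix has no principal components")
    u, s, vt = np.linalg.svd(X, full_matrices=False)
    n_components = min(n_components, len(s))
    for k in range(n_components):
        j = np.argmax(np.abs(vt[k]))
        if vt[k, j] < 0:
            vt[k] *= -1.0
            u[:, k] *= -1.0
    coords = pd.DataFrame(
        u[:, :n_components] * s[:n_components],
        index=values.columns,
        columns=[f"PC{k + 1}" for k in range(n_components)])
    evr = (s ** 2) / (s ** 2).sum()
    return coords, evr[:n_components]
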