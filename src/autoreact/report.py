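"""Visual-summary computations: PCA, column standardization, clustering.

These produce the *data* behind the figures — component scores and
variance fractions, standardized matrices, dendrogram leaf orders and
merge heights, and 95% concentration ellipses — rather than rendered
graphics, so they can be tested and re-plotted with any front end.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist

__all__ = [
    "PcaResult",
    "ClusterOrdering",
    "pca",
    "standardize_columns",
    "hclust_complete",
    "concentration_ellipse",
]


@dataclass
class PcaResult:
    scores: pd.DataFrame  # samples x components
    variance_fraction: np.ndarray
    loadings: np.ndarray  # analytes x components


@dataclass
class ClusterOrdering:
    order: list  # leaf labels in dendrogram order
    heights: np.ndarray  # non-decreasing merge heights
    linkage: np.ndarray  # scipy linkage matrix


def pca(matrix: pd.DataFrame, center: bool = True, scale: bool = False) -> PcaResult:
    """Principal components by singular value decomposition.

    Columns are centered by default and optionally scaled to unit sample
    SD.  ``variance_fraction[i]`` is sigma_i^2 over the total.
    """
    X = matrix.to_numpy(float)
    if X.shape[0] < 2:
        raise ValueError("PCA needs at least 2 samples")
    if center:
        X = X - X.mean(axis=0)
    if scale:
        sd = X.std(axis=0, ddof=1)
        if (sd == 0).any():
            raise ValueError("cannot scale zero-variance columns")
        X = X / sd
    if not np.any(X):
        raise ValueError("matrix has no variance")
    U, s, Vt = np.linalg.svd(X, full_matrices=False)
    var = s**2
    frac = var / var.sum()
    scores = U * s
    comps = [f"PC{i + 1}" for i in range(scores.shape[1])]
    return PcaResult(
        scores=pd.DataFrame(scores, index=matrix.index, columns=comps),
        variance_fraction=frac,
        loadings=Vt.T,
    )


def standardize_columns(matrix: pd.DataFrame) -> pd.DataFrame:
    """Center each column to mean 0 and sample SD 1; zero-SD columns are
    dropped with a warning."""
    sd = matrix.std(axis=0, ddof=1)
    bad = sd[sd == 0].index
    if len(bad):
        warnings.warn(f"dropping {len(bad)} zero-variance column(s)")
        matrix = matrix.drop(columns=bad)
        sd = sd.drop(bad)
    return (matrix - matrix.mean(axis=0)) / sd


def hclust_complete(matrix: pd.DataFrame, axis: int = 0) -> ClusterOrdering:
    """Complete-linkage agglomerative clustering on Euclidean distances.

    ``axis=0`` clusters rows, ``axis=1`` columns.  scipy's linkage breaks
    distance ties by the smallest cluster indices, which keeps the result
    deterministic; identical items merge first at height 0.
    """
    data = matrix.to_numpy(float) if axis == 0 else matrix.to_numpy(float).T
    labels = list(matrix.index if axis == 0 else matrix.columns)
    if data.shape[0] < 2:
        raise ValueError("need at least 2 items to cluster")
    Z = hierarchy.linkage(pdist(data, metric="euclidean"), method="complete")
    order = [labels[i] for i in hierarchy.leaves_list(Z)]
    return ClusterOrdering(order=order, heights=Z[:, 2].copy(), linkage=Z)


def concentration_ellipse(scores_2d: np.ndarray, level: float = 0.95) -> dict:
    """Gaussian concentration ellipse of 2-D scores.

    Returns center, semi-axis lengths and orientation (radians) scaled by
    the chi-square(2) quantile of ``level`` — the ellipse expected to
    contain that fraction of points under normality.
    """
    pts = np.asarray(scores_2d, float)
    if pts.ndim != 2 or pts.shape[1] != 2 or pts.shape[0] < 3:
        raise ValueError("need an (n >= 3) x 2 score matrix")
    center = pts.mean(axis=0)
    cov = np.cov(pts, rowvar=False)
    evals, evecs = np.linalg.eigh(cov)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    r = stats.chi2.ppf(level, df=2)
    return {
        "center": center,
        "semi_axes": np.sqrt(np.maximum(evals, 0.0) * r),
        "angle": float(np.arctan2(evecs[1, 0], evecs[0, 0])),
        "level": level,
    }
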