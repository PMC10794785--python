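"""Repeat-array copy number from read depth, and karyotype PCA.

Two loosely coupled capabilities live here. The first estimates the copy
number of a tandem repeat array (the Yq heterochromatin proxy) from
windowed depth of coverage: depths are GC-corrected by bin-median scaling
fit on a single-copy region, then the mean repeat depth is normalized by
the mean single-copy depth, so the result is invariant to overall
sequencing depth. The second places samples in expression space: a
variance-stabilizing log transform, linear batch removal, PCA over a gene
subset (e.g. the shared X- and Y-responsive genes), 95% confidence
ellipses around karyotype-group centroids, and nearest-centroid
classification of structural-variant samples.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "PCAResult",
    "GroupEllipse",
    "gc_correct",
    "normalized_repeat_depth",
    "vst_log",
    "remove_batch",
    "pca_project",
    "centroid_ellipses",
    "classify_variant",
    "reference_centroids",
]


def gc_correct(profile: pd.DataFrame, n_bins: int = 10) -> pd.DataFrame:
    """Bin-median GC correction of windowed depths.

    Equal-width GC bins are laid over the single-copy windows' GC range;
    each bin's scaling factor is (global single-copy median depth) / (bin
    median depth), fit on single-copy windows only and applied to every
    window (repeat windows included, clipped into the fitted bin range).
    A profile with all-zero single-copy depth is returned unchanged.
    """
    single = profile[profile["region"] == "single_copy"]
    if single.empty:
        raise ValueError("profile has no single_copy windows to fit the GC model on")
    global_med = float(single["depth"].median())
    out = profile.copy()
    if global_med == 0:
        return out
    lo, hi = single["gc"].min(), single["gc"].max()
    if hi <= lo:
        return out  # uniform GC: identity correction
    edges = np.linspace(lo, hi, n_bins + 1)
    sbin = np.clip(np.digitize(single["gc"], edges[1:-1]), 0, n_bins - 1)
    factors = np.ones(n_bins)
    for b in range(n_bins):
        med = single.loc[sbin == b, "depth"].median()
        if np.isfinite(med) and med > 0:
            factors[b] = global_med / med
    allbin = np.clip(np.digitize(out["gc"], edges[1:-1]), 0, n_bins - 1)
    out["depth"] = out["depth"].to_numpy() * factors[allbin]
    return out


def normalized_repeat_depth(profile: pd.DataFrame) -> float:
    """Mean repeat-region depth over mean single-copy depth.

    The ratio proxies repeat copy number: more repeat units attract
    proportionally more reads, while the single-copy denominator cancels
    the sample's sequencing depth.
    """
    rep = profile.loc[profile["region"] == "repeat", "depth"]
    sc = profile.loc[profile["region"] == "single_copy", "depth"]
    if sc.empty or rep.empty:
        raise ValueError("profile needs both repeat and single_copy windows")
    denom = float(sc.mean())
    if denom == 0:
        raise ValueError("single-copy mean depth is zero; ratio undefined")
    return float(rep.mean()) / denom


def vst_log(normalized_counts) -> pd.DataFrame:
    """Variance-stabilizing log transform log2(x + 1) of normalized counts."""
    m = pd.DataFrame(normalized_counts)
    if (m.to_numpy() < 0).any():
        raise ValueError("normalized counts must be non-negative")
    return np.log2(m + 1.0)


def remove_batch(matrix: pd.DataFrame, batch_labels: pd.Series) -> pd.DataFrame:
    """Subtract per-gene batch means, re-adding the grand mean.

    ``matrix`` is genes x samples; a single batch leaves the matrix
    unchanged (with a warning), matching the no-op contract.
    """
    batches = pd.Series(batch_labels).loc[matrix.columns]
    if batches.nunique() < 2:
        warnings.warn("only one batch present; remove_batch is the identity", stacklevel=2)
        return matrix.copy()
    grand = matrix.mean(axis=1)
    out = matrix.copy()
    for b, cols in matrix.columns.to_series().groupby(batches):
        out[cols] = matrix[cols].sub(matrix[cols].mean(axis=1), axis=0).add(grand, axis=0)
    return out


@dataclass
class PCAResult:
    scores: pd.DataFrame       # samples x k
    loadings: pd.DataFrame     # genes x k, orthonormal columns
    explained_variance_ratio: np.ndarray


def pca_project(matrix: pd.DataFrame, gene_subset=None, k: int = 2) -> PCAResult:
    """Centered PCA of samples over a gene subset, with deterministic signs.

    ``matrix`` is genes x samples (expression space); samples are the
    observations. Component signs are fixed so the largest-magnitude
    loading of each component is positive, making results reproducible up
    to exact arithmetic.
    """
    sub = matrix if gene_subset is None else matrix.loc[pd.Index(gene_subset)]
    X = sub.to_numpy(dtype=float).T  # samples x genes
    if min(X.shape) < k or X.shape[0] < k + 1:
        raise ValueError("not enough samples/genes for the requested number of components")
    Xc = X - X.mean(axis=0, keepdims=True)
    if np.allclose(Xc, 0):
        raise ValueError("matrix is constant across samples; PCA undefined")
    U, S, Vt = np.linalg.svd(Xc, full_matrices=False)
    U, S, Vt = U[:, :k], S[:k], Vt[:k]
    for j in range(k):
        i = np.argmax(np.abs(Vt[j]))
        if Vt[j, i] < 0:
            Vt[j] *= -1
            U[:, j] *= -1
    total_var = (Xc**2).sum()
    evr = S**2 / total_var if total_var > 0 else np.zeros(k)
    comp = [f"PC{j + 1}" for j in range(k)]
    return PCAResult(
        scores=pd.DataFrame(U * S, index=sub.columns, columns=comp),
        loadings=pd.DataFrame(Vt.T, index=sub.index, columns=comp),
        explained_variance_ratio=evr,
    )


@dataclass
class GroupEllipse:
    group: str
    center: tuple[float, float]
    semi_axes: tuple[float, float]
    angle: float  # radians, orientation of the major axis
    n: int


def centroid_ellipses(
    scores: pd.DataFrame,
    groups: pd.Series,
    level: float = 0.95,
    min_n: int = 3,
) -> list[GroupEllipse]:
    """95% confidence ellipses around group centroids in 2-D score space.

    The ellipse is built from the covariance of the centroid (group score
    covariance divided by n) scaled by the chi-square quantile with 2
    degrees of freedom; groups with fewer than ``min_n`` samples get no
    ellipse.
    """
    if scores.shape[1] < 2:
        raise ValueError("scores must have at least 2 components")
    q = stats.chi2.ppf(level, df=2)
    groups = pd.Series(groups).loc[scores.index]
    out = []
    for g, idx in scores.index.to_series().groupby(groups):
        pts = scores.loc[idx].iloc[:, :2].to_numpy()
        n = len(pts)
        if n < min_n:
            continue
        center = pts.mean(axis=0)
        cov_mean = np.cov(pts.T, ddof=1) / n
        evals, evecs = np.linalg.eigh(cov_mean)
        order = np.argsort(evals)[::-1]
        evals, evecs = evals[order], evecs[:, order]
        semi = np.sqrt(np.maximum(evals, 0.0) * q)
        angle = float(np.arctan2(evecs[1, 0], evecs[0, 0]))
        out.append(GroupEllipse(str(g), tuple(center), (float(semi[0]), float(semi[1])), angle, n))
    return out


def classify_variant(scores: pd.DataFrame, reference_centroids: pd.DataFrame) -> pd.DataFrame:
    """Nearest-centroid karyotype label for each sample in 2-D score space.

    ``reference_centroids`` is label x (PC1, PC2). Ties go to the
    lexicographically first label and are flagged.
    """
    if len(reference_centroids) < 2:
        raise ValueError("need at least 2 reference centroids")
    cent = reference_centroids.sort_index()
    pts = scores.iloc[:, :2].to_numpy()
    d = np.linalg.norm(pts[:, None, :] - cent.to_numpy()[None, :, :], axis=2)
    best = d.argmin(axis=1)
    tie = (d == d.min(axis=1, keepdims=True)).sum(axis=1) > 1
    return pd.DataFrame(
        {
            "label": cent.index.to_numpy()[best],
            "distance": d.min(axis=1),
            "tie": tie,
        },
        index=scores.index,
    )


def reference_centroids(scores: pd.DataFrame, groups: pd.Series) -> pd.DataFrame:
    """Mean 2-D score per group, for use as classification references."""
    groups = pd.Series(groups).loc[scores.index]
    return scores.iloc[:, :2].groupby(groups).mean()
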