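"""Population structure: informative-SNP subsetting, PCA, k-means with AIC.

The analysis mirrors the structure workflow of the study: restrict to SNPs
where at least one stock carries the minor allele at frequency > 0.1, run a
PCA on the pool-by-SNP frequency matrix, then cluster the leading principal
components with best-of-restarts k-means over k = 1..10, scoring each k with
a spherical-Gaussian AIC

    AIC(k) = n d ln(W_k / (n d)) + 2 k d

(n samples, d dimensions, W_k total within-cluster sum of squares) and
choosing k by the elbow (maximum second difference of the AIC curve).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans
from sklearn.decomposition import PCA

__all__ = [
    "ClusterResult",
    "select_informative_snps",
    "pca",
    "kmeans_aic",
    "choose_k_elbow",
    "cluster_stocks",
]

logger = logging.getLogger(__name__)

_W_FLOOR = 1e-12  # keeps ln(W) finite when every point sits on its centroid


@dataclass
class ClusterResult:
    """Outcome of the PCA + k-means/AIC structure analysis."""

    aic: dict[int, float]
    chosen_k: int
    labels: np.ndarray  # cluster assignment per sample, values in 0..k-1
    coords: pd.DataFrame  # PC coordinates used for clustering
    explained_variance_ratio: np.ndarray
    n_pcs_used: int


def select_informative_snps(
    stock_freq: pd.DataFrame,
    sample_freq: pd.DataFrame | None = None,
    min_freq: float = 0.1,
) -> pd.DataFrame:
    """Keep SNP columns where any stock's minor-allele frequency exceeds
    ``min_freq`` (strictly).

    ``stock_freq`` is stocks x SNPs; the mask is applied to ``sample_freq``
    (samples x SNPs, e.g. per-pool frequencies) when given, else to
    ``stock_freq`` itself.  Frequencies are folded to the minor allele
    before thresholding.  All-missing columns are dropped.
    """
    folded = np.minimum(stock_freq, 1.0 - stock_freq)
    keep = (folded > min_freq).any(axis=0)
    target = sample_freq if sample_freq is not None else stock_freq
    out = target.loc[:, keep[keep].index]
    return out.dropna(axis=1, how="all")


def pca(
    matrix: pd.DataFrame, n_components: int | None = None
) -> tuple[pd.DataFrame, np.ndarray]:
    """PCA of a samples-x-SNPs frequency matrix.

    Missing entries are mean-imputed per SNP column; columns are centered;
    the decomposition is a full SVD.  Returns (coordinates, explained
    variance fractions), fractions non-increasing and summing to <= 1.
    """
    if matrix.shape[0] < 2:
        raise ValueError("PCA needs at least 2 samples")
    if matrix.shape[1] < 2:
        raise ValueError("PCA needs at least 2 SNPs")
    X = matrix.to_numpy(dtype=float)
    col_mean = np.nanmean(X, axis=0)
    nan_mask = np.isnan(X)
    X[nan_mask] = np.take(col_mean, np.nonzero(nan_mask)[1])
    n_components = n_components or min(X.shape[0] - 1, X.shape[1])
    model = PCA(n_components=n_components, svd_solver="full")
    coords = model.fit_transform(X)
    cols = [f"PC{i + 1}" for i in range(coords.shape[1])]
    return (
        pd.DataFrame(coords, index=matrix.index, columns=cols),
        model.explained_variance_ratio_,
    )


def kmeans_aic(
    pcs: np.ndarray | pd.DataFrame,
    k_range: range | list[int] = range(1, 11),
    restarts: int = 25,
    seed: int = 0,
) -> tuple[dict[int, float], dict[int, np.ndarray]]:
    """Best-of-restarts k-means AIC over a range of cluster counts.

    Returns (AIC per k, labels per k).  Values of k exceeding the sample
    count are skipped with a warning.  Deterministic under a fixed seed.
    """
    X = np.asarray(pcs, dtype=float)
    if not np.isfinite(X).all():
        raise ValueError("PC coordinates must be finite")
    if restarts < 1:
        raise ValueError("restarts must be >= 1")
    n, d = X.shape
    aic: dict[int, float] = {}
    labels: dict[int, np.ndarray] = {}
    for k in k_range:
        if k > n:
            warnings.warn(f"k={k} exceeds sample count {n}; skipped", stacklevel=2)
            continue
        if k == 1:
            centroid = X.mean(axis=0)
            W = float(((X - centroid) ** 2).sum())
            lab = np.zeros(n, dtype=int)
        else:
            km = KMeans(
                n_clusters=k, n_init=restarts, random_state=seed
            ).fit(X)
            W = float(km.inertia_)
            lab = km.labels_
        W = max(W, _W_FLOOR)
        aic[k] = n * d * np.log(W / (n * d)) + 2.0 * k * d
        labels[k] = lab
    return aic, labels


def choose_k_elbow(aic: dict[int, float]) -> int:
    """Elbow choice: k maximizing the second difference
    AIC(k-1) - 2 AIC(k) + AIC(k+1) over consecutive k; ties break to the
    smallest k.  With fewer than 3 consecutive points, falls back to the
    AIC minimum with a warning."""
    ks = sorted(aic)
    interior = [k for k in ks if (k - 1 in aic and k + 1 in aic)]
    if not interior:
        warnings.warn(
            "fewer than 3 consecutive AIC points; choosing argmin AIC",
            stacklevel=2,
        )
        return min(ks, key=lambda k: aic[k])
    second_diff = {k: aic[k - 1] - 2.0 * aic[k] + aic[k + 1] for k in interior}
    best = max(second_diff.values())
    return min(k for k in interior if second_diff[k] == best)


def cluster_stocks(
    freq_matrix: pd.DataFrame,
    stock_freq: pd.DataFrame | None = None,
    min_freq: float = 0.1,
    k_range: range = range(1, 11),
    restarts: int = 25,
    seed: int = 0,
    n_pcs: int | None = None,
    variance_target: float = 0.9,
) -> ClusterResult:
    """Full structure pipeline: subset SNPs, PCA, k-means/AIC, elbow.

    ``n_pcs`` fixes the number of leading components fed to the clustering;
    by default the smallest number covering ``variance_target`` of the
    variance is used.
    """
    if stock_freq is not None:
        freq_matrix = select_informative_snps(
            stock_freq, freq_matrix, min_freq=min_freq
        )
    coords, evr = pca(freq_matrix)
    if n_pcs is None:
        cum = np.cumsum(evr)
        n_pcs = int(np.searchsorted(cum, variance_target) + 1)
        n_pcs = min(n_pcs, coords.shape[1])
    used = coords.iloc[:, :n_pcs]
    aic, labels = kmeans_aic(used, k_range=k_range, restarts=restarts, seed=seed)
    k = choose_k_elbow(aic)
    logger.info("structure: %d PCs, chosen k=%d", n_pcs, k)
    return ClusterResult(
        aic=aic,
        chosen_k=k,
        labels=labels[k],
        coords=coords,
        explained_variance_ratio=evr,
        n_pcs_used=n_pcs,
    )
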