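"""Exploratory structure: correlations, PCA, 2-D projections, clustering.

These stages wrap established algorithms (scikit-learn PCA / KMeans /
DBSCAN / t-SNE and umap-learn) behind a deterministic, seed-threaded
surface: Pearson correlation matrix of the 10 streams, correlation PCA
with a fixed sign convention, UMAP (n_neighbors=15, min_dist=0.1) and
t-SNE projections of latent codes, and clustering of the projected
coordinates.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.cluster import DBSCAN, KMeans
from sklearn.decomposition import PCA
from sklearn.manifold import TSNE

from .autoencoders import LatentCodes
from .session_io import CohortMatrix, DegenerateFeatureError
from .streams import STREAM_NAMES

__all__ = [
    "PcaResult",
    "Projection2D",
    "ClusterLabels",
    "correlation_matrix",
    "pca_decomposition",
    "project_2d",
    "cluster_labels",
]


@dataclass
class PcaResult:
    """Correlation-PCA loadings and explained variance."""

    loadings: pd.DataFrame  # components x streams
    explained_ratio: np.ndarray
    cumulative_ratio: np.ndarray
    mean_: np.ndarray = field(repr=False, default=None)

    def n_components_for(self, fraction: float) -> int:
        """Smallest number of components explaining >= fraction of variance."""
        return int(np.searchsorted(self.cumulative_ratio, fraction) + 1)


@dataclass
class Projection2D:
    method: str
    coords: np.ndarray
    params: dict
    seed: int

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, float)
        if self.coords.ndim != 2 or self.coords.shape[1] != 2:
            raise ValueError("projection must be N x 2")


@dataclass
class ClusterLabels:
    method: str
    labels: np.ndarray
    params: dict

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, int)


def _matrix(m) -> np.ndarray:
    if isinstance(m, CohortMatrix):
        return m.values
    if isinstance(m, LatentCodes):
        return m.codes
    return np.asarray(m, float)


def correlation_matrix(m) -> pd.DataFrame:
    """Pearson correlation matrix of the 10 streams across sessions."""
    X = _matrix(m)
    if X.shape[0] < 3:
        raise ValueError("need at least 3 sessions for a correlation matrix")
    sd = X.std(axis=0)
    if np.any(sd <= 0):
        names = [STREAM_NAMES[j] for j in np.flatnonzero(sd <= 0)]
        raise DegenerateFeatureError(
            f"degenerate feature(s) with zero dispersion: {', '.join(names)}"
        )
    R = np.corrcoef(X, rowvar=False)
    return pd.DataFrame(R, index=STREAM_NAMES, columns=STREAM_NAMES)


def pca_decomposition(m) -> PcaResult:
    """Full PCA of the standardized cohort matrix (correlation PCA).

    The sign of each component is fixed by making its largest-magnitude
    loading positive, so loadings are reproducible across runs.
    """
    X = _matrix(m)
    if isinstance(m, CohortMatrix) and not m.standardized:
        raise ValueError("PCA expects the standardized cohort matrix")
    n_comp = min(X.shape)
    pca = PCA(n_components=n_comp, svd_solver="full")
    pca.fit(X)
    comps = pca.components_.copy()
    for i in range(comps.shape[0]):
        j = np.argmax(np.abs(comps[i]))
        if comps[i, j] < 0:
            comps[i] = -comps[i]
    loadings = pd.DataFrame(
        comps,
        index=[f"PC{i + 1}" for i in range(n_comp)],
        columns=STREAM_NAMES[: X.shape[1]],
    )
    ratio = pca.explained_variance_ratio_
    return PcaResult(
        loadings=loadings,
        explained_ratio=ratio,
        cumulative_ratio=np.cumsum(ratio),
        mean_=pca.mean_,
    )


def project_2d(codes, method: str = "umap", seed: int = 0, **params) -> Projection2D:
    """Project codes to 2-D with UMAP (default) or t-SNE, seeded.

    UMAP defaults: ``n_neighbors=15, min_dist=0.1``; t-SNE perplexity
    defaults to 30 clamped to (N-1)/3 for small cohorts.
    """
    X = _matrix(codes)
    n = X.shape[0]
    if method == "umap":
        import umap  # deferred: numba compilation is slow at import

        opts = {"n_neighbors": 15, "min_dist": 0.1, "n_components": 2}
        opts.update(params)
        if n <= opts["n_neighbors"]:
            raise ValueError(
                f"UMAP requires N > n_neighbors ({opts['n_neighbors']}), got N={n}"
            )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            reducer = umap.UMAP(random_state=seed, **opts)
            coords = reducer.fit_transform(X)
        return Projection2D("umap", coords, opts, seed)
    if method == "tsne":
        opts = {"perplexity": min(30.0, max(1.0, (n - 1) / 3.0)), "init": "pca"}
        opts.update(params)
        if n < 4:
            raise ValueError("t-SNE needs at least 4 sessions")
        tsne = TSNE(n_components=2, random_state=seed, **opts)
        coords = tsne.fit_transform(X)
        return Projection2D("tsne", coords, opts, seed)
    raise ValueError(f"unknown projection method: {method!r}")


def cluster_labels(coords, method: str = "kmeans", seed: int = 0, **params) -> ClusterLabels:
    """Cluster 2-D coordinates with seeded KMeans (k=3) or DBSCAN.

    DBSCAN runs on z-scored coordinates so that its ``eps`` (default
    0.5) is expressed in standardized projection units; -1 labels noise.
    """
    X = coords.coords if isinstance(coords, Projection2D) else np.asarray(coords, float)
    if method == "kmeans":
        opts = {"n_clusters": 3}
        opts.update(params)
        km = KMeans(random_state=seed, n_init=10, **opts)
        labels = km.fit_predict(X)
        return ClusterLabels("kmeans", labels, opts)
    if method == "dbscan":
        opts = {"eps": 0.5, "min_samples": 5}
        opts.update(params)
        sd = X.std(axis=0)
        sd[sd == 0] = 1.0
        Xs = (X - X.mean(axis=0)) / sd
        db = DBSCAN(**opts)
        labels = db.fit_predict(Xs)
        return ClusterLabels("dbscan", labels, opts)
    raise ValueError(f"unknown clustering method: {method!r}")
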