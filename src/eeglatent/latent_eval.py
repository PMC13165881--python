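"""Latent-space quality, stability and anomaly metrics.

Given per-session latent codes z_i and their 2-D projections u_i, this
module computes the monitoring metric suite: mean squared reconstruction
error, total latent variance Var(Z), per-group intra dispersion
D_intra(G) (mean squared distance to the group centroid) and pairwise
inter-group separation D_inter(G_a, G_b) (Euclidean distance between
centroids — note the deliberate squared/unsquared scale difference,
preserved as defined), the k-nearest-neighbour consistency score
Cons(k) between latent space and projection, and percentile-threshold
anomaly flagging on reconstruction errors.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist

from .autoencoders import LatentCodes

__all__ = [
    "GroupDispersion",
    "ConsistencyScore",
    "AnomalyConfig",
    "latent_summary",
    "group_dispersion",
    "knn_consistency",
    "flag_anomalies",
    "metrics_report",
]


@dataclass
class GroupDispersion:
    """Intra-group dispersion and pairwise centroid separation.

    ``intra`` maps group label -> D_intra (squared-distance units);
    ``inter`` is a symmetric DataFrame of centroid distances (distance
    units) with zero diagonal.
    """

    intra: dict[str, float]
    inter: pd.DataFrame
    grouping: str

    def min_inter(self) -> float:
        vals = self.inter.values[np.triu_indices(len(self.inter), k=1)]
        return float(vals.min())

    def max_intra(self) -> float:
        return float(max(self.intra.values()))

    def is_stable(self) -> bool:
        """Separation test on a common (squared) scale.

        True when the smallest squared centroid separation exceeds the
        largest within-group dispersion.
        """
        return self.min_inter() ** 2 > self.max_intra()


@dataclass
class ConsistencyScore:
    k: int
    score: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.score <= 1.0:
            raise ValueError("consistency score must lie in [0, 1]")


@dataclass
class AnomalyConfig:
    """Percentile rule for reconstruction-error anomaly flagging."""

    percentile: float = 95.0

    def __post_init__(self) -> None:
        if not 0.0 < self.percentile < 100.0:
            raise ValueError("percentile must lie strictly between 0 and 100")


def _codes_array(codes) -> np.ndarray:
    if isinstance(codes, LatentCodes):
        return codes.codes
    return np.asarray(codes, float)


def latent_summary(codes, errors) -> dict[str, float]:
    """Reconstruction MSE and total latent variance.

    ``l_rec = mean_i E_i^2`` (E_i are per-session reconstruction-error
    norms) and ``var_z = mean_i ||z_i - z_bar||^2``.
    """
    z = _codes_array(codes)
    errors = np.asarray(errors, float)
    if len(errors) != len(z):
        raise ValueError("errors must align with codes")
    centered = z - z.mean(axis=0)
    return {
        "l_rec": float(np.mean(errors**2)),
        "var_z": float(np.mean(np.sum(centered**2, axis=1))),
    }


def group_dispersion(codes, groups, grouping: str = "group") -> GroupDispersion:
    """D_intra per group and pairwise centroid D_inter.

    ``groups`` is a per-session label sequence; every group must be
    non-empty (guaranteed by construction) and labels are reported in
    first-appearance order.
    """
    z = _codes_array(codes)
    groups = [str(g) for g in groups]
    if len(groups) != len(z):
        raise ValueError("group labels must align with codes")
    order: list[str] = []
    for g in groups:
        if g not in order:
            order.append(g)
    intra: dict[str, float] = {}
    centroids: dict[str, np.ndarray] = {}
    arr = np.asarray(groups)
    for g in order:
        members = z[arr == g]
        if len(members) == 0:
            raise ValueError(f"empty group: {g}")
        c = members.mean(axis=0)
        centroids[g] = c
        intra[g] = float(np.mean(np.sum((members - c) ** 2, axis=1)))
    inter = pd.DataFrame(0.0, index=order, columns=order)
    for i, a in enumerate(order):
        for b in order[i + 1:]:
            d = float(np.linalg.norm(centroids[a] - centroids[b]))
            inter.loc[a, b] = inter.loc[b, a] = d
    return GroupDispersion(intra=intra, inter=inter, grouping=grouping)


def _knn_sets(points: np.ndarray, k: int) -> np.ndarray:
    """Index matrix of each point's k nearest neighbours (self excluded).

    Ties are broken by lower index (stable sort over distances).
    """
    D = cdist(points, points)
    np.fill_diagonal(D, np.inf)
    order = np.argsort(D, axis=1, kind="stable")
    return order[:, :k]


def knn_consistency(z, u, k: int) -> ConsistencyScore:
    """Neighbourhood preservation between latent space and projection.

    ``Cons(k) = mean_i |N_k(z_i) ∩ N_k(u_i)| / k`` with Euclidean
    neighbourhoods in both spaces, excluding the point itself.
    """
    z = _codes_array(z)
    u = _codes_array(u)
    if len(z) != len(u):
        raise ValueError("z and u must have the same number of points")
    n = len(z)
    if not 1 <= k <= n - 1:
        raise ValueError(f"k must lie in [1, {n - 1}], got {k}")
    nz = _knn_sets(z, k)
    nu = _knn_sets(u, k)
    overlap = [
        len(set(nz[i]).intersection(nu[i])) / k for i in range(n)
    ]
    return ConsistencyScore(k=k, score=float(np.mean(overlap)))


def flag_anomalies(errors, cfg: AnomalyConfig | None = None):
    """Flag sessions whose reconstruction error exceeds a percentile cut.

    The threshold epsilon is the ``cfg.percentile``-th percentile
    (linear interpolation) of the supplied errors; a session is flagged
    iff its error is strictly greater than epsilon.  Returns
    ``(mask, epsilon)``.
    """
    cfg = cfg or AnomalyConfig()
    errors = np.asarray(errors, float)
    if errors.ndim != 1 or len(errors) < 2:
        raise ValueError("need at least two reconstruction errors")
    eps = float(np.percentile(errors, cfg.percentile))
    return errors > eps, eps


def metrics_report(codes, errors, projection=None, k: int = 10,
                   groupings: dict[str, list] | None = None) -> dict:
    """Bundle the metric suite into one JSON-serializable report."""
    report: dict = dict(latent_summary(codes, errors))
    if projection is not None:
        n = len(_codes_array(codes))
        k_eff = min(k, n - 1)
        report[f"knn_consistency_k{k_eff}"] = knn_consistency(codes, projection, k_eff).score
    mask, eps = flag_anomalies(errors)
    report["anomaly_threshold"] = eps
    report["n_anomalous"] = int(mask.sum())
    if groupings:
        for name, labels in groupings.items():
            gd = group_dispersion(codes, labels, grouping=name)
            report[f"d_intra_{name}"] = gd.intra
            report[f"d_inter_{name}"] = {
                f"{a}|{b}": float(gd.inter.loc[a, b])
                for i, a in enumerate(gd.inter.index)
                for b in gd.inter.columns[i + 1:]
            }
            report[f"stable_{name}"] = bool(gd.is_stable())
    return report
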