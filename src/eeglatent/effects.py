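"""Pairwise multivariate phase-effect sizes.

For each pair of therapy moments the module fits a two-group one-way
MANOVA on the (standardized) rhythm-band features and reports the
partial eta-squared as the Pillai trace V = tr(H (H + E)^{-1}) — for two
groups the statistic has s = 1, so V itself is the partial eta-squared.
Precision comes from a stratified (within-group) percentile bootstrap,
and interpretability from per-band contribution shares, defined as each
band's percentage of the total between-group sum of squares on
standardized features.

``PhaseEffectModel`` follows the statsmodels idiom: construct from a
cohort, ``fit()`` returns a results object with a ``summary()`` table
and per-pair :class:`PhaseEffect` records.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .session_io import CohortMatrix, zscore_matrix
from .streams import BAND_NAMES, MOMENTS, Moment, STREAM_NAMES

__all__ = [
    "PhaseEffect",
    "SingularCovarianceError",
    "pairwise_eta_squared",
    "bootstrap_ci",
    "band_contributions",
    "PhaseEffectModel",
    "PhaseEffectResults",
]

_IDX = {name: j for j, name in enumerate(STREAM_NAMES)}


class SingularCovarianceError(ValueError):
    """Within-group covariance is singular; reduce the feature set."""


@dataclass
class PhaseEffect:
    """Effect of one pairwise phase contrast."""

    pair: tuple[Moment, Moment]
    eta_sq: float
    ci95: tuple[float, float] | None
    contributions: dict[str, float] | None
    n_a: int
    n_b: int

    def __post_init__(self) -> None:
        if not 0.0 <= self.eta_sq <= 1.0:
            raise ValueError("eta squared must lie in [0, 1]")
        if self.contributions is not None:
            total = sum(self.contributions.values())
            if abs(total - 100.0) > 1e-6:
                raise ValueError("contributions must sum to 100")


def _standardized(m: CohortMatrix) -> CohortMatrix:
    return m if m.standardized else zscore_matrix(m)


def _group_arrays(m: CohortMatrix, pair, feature_set):
    a, b = (Moment.parse(p) if not isinstance(p, Moment) else p for p in pair)
    idx = [_IDX[f] for f in feature_set]
    moments = m.labels["moment"].map(
        lambda v: v if isinstance(v, Moment) else Moment.parse(str(v))
    )
    Xa = m.values[np.asarray(moments == a)][:, idx]
    Xb = m.values[np.asarray(moments == b)][:, idx]
    if len(Xa) < 2 or len(Xb) < 2:
        raise ValueError(
            f"empty group: need >= 2 sessions per moment, got "
            f"{a.value}={len(Xa)}, {b.value}={len(Xb)}"
        )
    return Xa, Xb, (a, b)


def _pillai(Xa: np.ndarray, Xb: np.ndarray) -> float:
    """Pillai trace of the two-group MANOVA (equals partial eta-squared)."""
    grand = np.vstack([Xa, Xb]).mean(axis=0)
    H = np.zeros((Xa.shape[1],) * 2)
    E = np.zeros_like(H)
    for X in (Xa, Xb):
        mean = X.mean(axis=0)
        dm = mean - grand
        H += len(X) * np.outer(dm, dm)
        C = X - mean
        E += C.T @ C
    T = H + E
    # Guard against singular total scatter before solving.
    cond = np.linalg.cond(T)
    if not np.isfinite(cond) or cond > 1e12:
        raise SingularCovarianceError(
            "within-group covariance is singular; reduce the feature set"
        )
    V = float(np.trace(np.linalg.solve(T, H)))
    return min(max(V, 0.0), 1.0)


def pairwise_eta_squared(m: CohortMatrix, pair, feature_set=BAND_NAMES) -> float:
    """Multivariate partial eta-squared between two therapy moments.

    Two-group one-way MANOVA on the selected standardized features; the
    Pillai trace is returned (s = 1 for two groups, so the trace equals
    the partial eta-squared).  Default feature set: the 8 rhythm bands.
    """
    m = _standardized(m)
    Xa, Xb, _ = _group_arrays(m, pair, feature_set)
    return _pillai(Xa, Xb)


def bootstrap_ci(m: CohortMatrix, pair, B: int = 2000, level: float = 0.95,
                 seed: int = 0, feature_set=BAND_NAMES) -> tuple[float, float]:
    """Stratified percentile bootstrap interval for the eta-squared.

    Sessions are resampled with replacement within each group; a
    degenerate resample (singular covariance) is redrawn.
    """
    if B < 200:
        raise ValueError("B must be >= 200 for a stable percentile interval")
    m = _standardized(m)
    Xa, Xb, _ = _group_arrays(m, pair, feature_set)
    rng = np.random.default_rng(seed)
    stats = np.empty(B)
    n_redrawn = 0
    for i in range(B):
        for _attempt in range(100):
            ia = rng.integers(0, len(Xa), len(Xa))
            ib = rng.integers(0, len(Xb), len(Xb))
            try:
                stats[i] = _pillai(Xa[ia], Xb[ib])
                break
            except SingularCovarianceError:
                n_redrawn += 1
        else:
            raise SingularCovarianceError(
                "bootstrap resamples persistently singular"
            )
    alpha = (1.0 - level) / 2.0
    lo, hi = np.percentile(stats, [100 * alpha, 100 * (1 - alpha)])
    return float(lo), float(hi)


def band_contributions(m: CohortMatrix, pair, feature_set=BAND_NAMES) -> dict[str, float]:
    """Per-band percentage shares of the between-group signal.

    ``contribution_b = 100 * SSB_b / sum_b' SSB_b'`` with SSB computed
    per feature on the standardized matrix.
    """
    m = _standardized(m)
    Xa, Xb, _ = _group_arrays(m, pair, feature_set)
    grand = np.vstack([Xa, Xb]).mean(axis=0)
    ssb = (
        len(Xa) * (Xa.mean(axis=0) - grand) ** 2
        + len(Xb) * (Xb.mean(axis=0) - grand) ** 2
    )
    total = ssb.sum()
    if total <= 1e-12:  # exactly-equal group means up to float round-off
        raise ValueError("no between-group signal: all per-band SSB are zero")
    shares = 100.0 * ssb / total
    return {f: float(s) for f, s in zip(feature_set, shares)}


class PhaseEffectModel:
    """Pairwise phase-effect analysis over a cohort matrix."""

    def __init__(self, cohort: CohortMatrix, feature_set=BAND_NAMES):
        self.cohort = _standardized(cohort)
        self.feature_set = tuple(feature_set)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, feature_set=BAND_NAMES):
        """Build from a flat table with label columns + stream columns."""
        labels = pd.DataFrame(
            {
                "patient_id": df["patient_id"].astype(int),
                "moment": df["moment"].map(Moment.parse),
                "date": df.get("date"),
            }
        )
        values = df[list(STREAM_NAMES)].to_numpy(float)
        return cls(CohortMatrix(values=values, labels=labels), feature_set)

    def fit(self, bootstrap: int | None = 2000, level: float = 0.95,
            seed: int = 0) -> "PhaseEffectResults":
        counts = self.cohort.labels["moment"].value_counts()
        missing = [m.value for m in MOMENTS if counts.get(m, 0) < 2]
        if missing:
            raise ValueError(
                f"empty group: moment(s) with fewer than 2 sessions: "
                f"{', '.join(missing)}"
            )
        pairs = [
            (MOMENTS[0], MOMENTS[1]),
            (MOMENTS[0], MOMENTS[2]),
            (MOMENTS[1], MOMENTS[2]),
        ]
        effects = []
        for i, pair in enumerate(pairs):
            eta = pairwise_eta_squared(self.cohort, pair, self.feature_set)
            ci = None
            if bootstrap:
                ci = bootstrap_ci(
                    self.cohort, pair, B=bootstrap, level=level,
                    seed=seed + i, feature_set=self.feature_set,
                )
            contrib = band_contributions(self.cohort, pair, self.feature_set)
            moments = self.cohort.labels["moment"]
            n_a = int((moments == pair[0]).sum())
            n_b = int((moments == pair[1]).sum())
            effects.append(PhaseEffect(pair, eta, ci, contrib, n_a, n_b))
        return PhaseEffectResults(self, effects)


class PhaseEffectResults:
    def __init__(self, model: PhaseEffectModel, effects: list[PhaseEffect]):
        self.model = model
        self.effects = effects

    def __getitem__(self, pair) -> PhaseEffect:
        key = tuple(Moment.parse(p) if not isinstance(p, Moment) else p for p in pair)
        for e in self.effects:
            if e.pair == key:
                return e
        raise KeyError(pair)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for e in self.effects:
            row = {
                "pair": f"{e.pair[0].value} vs {e.pair[1].value}",
                "n_a": e.n_a,
                "n_b": e.n_b,
                "eta_sq": e.eta_sq,
            }
            if e.ci95 is not None:
                row["ci_lo"], row["ci_hi"] = e.ci95
            if e.contributions:
                for band, pct in e.contributions.items():
                    row[f"pct_{band}"] = pct
            rows.append(row)
        return pd.DataFrame(rows)

    def summary(self) -> str:
        lines = [
            "Pairwise multivariate phase effects (Pillai partial eta-squared)",
            "=" * 66,
        ]
        for e in self.effects:
            ci = (
                f"  95% CI [{e.ci95[0]:.4f}, {e.ci95[1]:.4f}]" if e.ci95 else ""
            )
            lines.append(
                f"{e.pair[0].value:>6} vs {e.pair[1].value:<6} "
                f"(n={e.n_a}/{e.n_b})  eta_sq = {e.eta_sq:.4f}{ci}"
            )
            if e.contributions:
                top = sorted(e.contributions.items(), key=lambda kv: -kv[1])[:3]
                lines.append(
                    "        top contributions: "
                    + ", ".join(f"{b} {p:.2f}%" for b, p in top)
                )
        return "\n".join(lines)

    def to_json(self) -> dict:
        return {
            f"{e.pair[0].value}_vs_{e.pair[1].value}": {
                "eta_sq": e.eta_sq,
                "ci95": list(e.ci95) if e.ci95 else None,
                "contributions_pct": e.contributions,
                "n": [e.n_a, e.n_b],
            }
            for e in self.effects
        }
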