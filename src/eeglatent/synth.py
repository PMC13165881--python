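"""Synthetic cohort generator.

Emulates the statistical structure the downstream analysis assumes: one
text recording per session over 10 streams, three therapy moments,
additive per-patient baseline offsets, phase-dependent mean shifts
concentrated in configurable rhythm bands, strong positive correlation
between adjacent sub-bands and weak negative correlation of the
attention/meditation indices with band powers.

The session model, in standardized units, is

    x = patient_offset + shift[moment] + noise_sd * F @ eps,

with ``F`` a symmetric factor of the target band-correlation matrix,
``eps`` i.i.d. standard normal, and patient offsets drawn through the
same factor (scaled by ``patient_sd``) so that between-subject variance
preserves the planted spectral correlations.  Raw stream values are
``baseline + scale * x`` per stream.

Because every patient contributes sessions to every moment, patient
offsets cancel exactly from group-mean contrasts; this keeps the
expected two-group effect size available in closed form
(:func:`oracle_eta_squared`), which serves as the generator's ground
truth in recovery checks.
"""

from __future__ import annotations

import datetime as _dt
import zipfile
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .session_io import CohortMatrix
from .streams import BAND_NAMES, MOMENTS, Moment, N_STREAMS, STREAM_NAMES

__all__ = [
    "PhaseEffectProfile",
    "CohortConfig",
    "default_band_corr",
    "default_profile",
    "null_profile",
    "sample_cohort",
    "write_archive",
    "oracle_eta_squared",
    "phase_stability_threshold",
]

_IDX = {name: j for j, name in enumerate(STREAM_NAMES)}

#: Plausible raw per-stream levels (band powers in headset units,
#: attention/meditation on their 0-100 scale) and the raw spread that one
#: standardized unit maps to.
DEFAULT_BASELINE = np.array(
    [620.0, 410.0, 160.0, 130.0, 95.0, 70.0, 48.0, 36.0, 54.0, 58.0]
)
DEFAULT_SCALE = np.array(
    [90.0, 60.0, 25.0, 20.0, 15.0, 11.0, 8.0, 6.0, 12.0, 12.0]
)


def default_band_corr() -> np.ndarray:
    """Target 10 x 10 correlation matrix of the streams.

    Adjacent low/high sub-bands of the same rhythm correlate at 0.7,
    the alpha/beta/gamma block at 0.3 otherwise, the slow rhythms
    (delta, theta) at 0.4 with each other and 0.2 with the rest of the
    spectrum, and the attention/meditation indices weakly negatively
    (-0.1) with every band and mildly (0.2) with each other.
    """
    R = np.full((N_STREAMS, N_STREAMS), 0.0)
    bands = range(8)
    fast = range(2, 8)  # alpha/beta/gamma
    for i in bands:
        for j in bands:
            if i == j:
                continue
            if i in fast and j in fast:
                R[i, j] = 0.3
    for lo, hi in ((2, 3), (4, 5), (6, 7)):  # same-rhythm sub-band pairs
        R[lo, hi] = R[hi, lo] = 0.7
    R[0, 1] = R[1, 0] = 0.4  # delta-theta
    for i in (0, 1):
        for j in fast:
            R[i, j] = R[j, i] = 0.2
    for i in (8, 9):  # attention / meditation
        for j in bands:
            R[i, j] = R[j, i] = -0.1
    R[8, 9] = R[9, 8] = 0.2
    np.fill_diagonal(R, 1.0)
    return R


@dataclass
class PhaseEffectProfile:
    """Per-moment mean shift over the 10 streams, in standardized units.

    The reference moment carries the zero vector by definition.
    """

    shifts: dict[Moment, np.ndarray]
    reference: Moment = Moment.BEFORE

    def __post_init__(self) -> None:
        self.shifts = {m: np.asarray(v, dtype=float) for m, v in self.shifts.items()}
        for m in MOMENTS:
            if m not in self.shifts:
                raise ValueError(f"profile missing moment {m.value}")
            if self.shifts[m].shape != (N_STREAMS,):
                raise ValueError("each shift vector must have length 10")
        if np.any(self.shifts[self.reference] != 0):
            raise ValueError("reference moment shift must be the zero vector")

    def shift(self, moment: Moment) -> np.ndarray:
        return self.shifts[moment]


def _shift_from_shares(shares: dict[str, float], amplitude: float) -> np.ndarray:
    """Build a shift whose squared components follow the given band shares.

    ``shares`` maps stream names to percentages of the between-group
    signal; unmentioned rhythm bands split the remainder equally, the
    cognitive indices stay at zero.
    """
    total = sum(shares.values())
    if total > 100.0 + 1e-9:
        raise ValueError("shares exceed 100%")
    rest = [b for b in BAND_NAMES if b not in shares]
    fill = (100.0 - total) / len(rest) if rest else 0.0
    v = np.zeros(N_STREAMS)
    for name, pct in shares.items():
        v[_IDX[name]] = np.sqrt(pct / 100.0)
    for name in rest:
        v[_IDX[name]] = np.sqrt(fill / 100.0)
    return amplitude * v


# Between-group contribution shares (percent) emulating the band-specific
# phase effects the analysis is designed to resolve: the During contrast is
# delta-dominant, the After contrast spreads over theta/low-gamma/high-beta.
_DURING_SHARES = {
    "delta": 75.13,
    "gamma_low": 8.54,
    "theta": 4.94,
    "gamma_high": 4.01,
    "beta_high": 3.61,
}
_AFTER_SHARES = {
    "theta": 25.17,
    "gamma_low": 24.72,
    "beta_high": 19.26,
    "delta": 13.90,
    "gamma_high": 8.88,
}

#: Shift amplitudes (standardized units).  Chosen so the planted structure
#: is recoverable at simulated cohort sizes of a few hundred sessions per
#: phase: the dominant-band gap must exceed the sampling noise of per-band
#: group-mean contrasts (sd ~ sqrt(2/n)).
DURING_AMPLITUDE = 0.8
AFTER_AMPLITUDE = 0.6


def default_profile() -> PhaseEffectProfile:
    """Default planted phase effects (Before is the reference)."""
    return PhaseEffectProfile(
        shifts={
            Moment.BEFORE: np.zeros(N_STREAMS),
            Moment.DURING: _shift_from_shares(_DURING_SHARES, DURING_AMPLITUDE),
            Moment.AFTER: _shift_from_shares(_AFTER_SHARES, AFTER_AMPLITUDE),
        }
    )


def null_profile() -> PhaseEffectProfile:
    """Profile with no phase effect at all (null behaviour)."""
    return PhaseEffectProfile(shifts={m: np.zeros(N_STREAMS) for m in MOMENTS})


@dataclass
class CohortConfig:
    """Study-condition parameters of the synthetic cohort.

    ``sessions_per_phase`` is the session count per (patient, moment);
    either a single int or a (before, during, after) triple.  Defaults
    emulate a six-patient corpus with a heavier baseline block.
    """

    n_patients: int = 6
    sessions_per_phase: int | tuple[int, int, int] = (6, 5, 5)
    patient_sd: float = 0.3
    noise_sd: float = 1.0
    band_corr: np.ndarray | None = None
    profile: PhaseEffectProfile | None = None
    samples_per_session: int = 40
    jitter_sd: float | None = None  # standardized units; default noise_sd / 4
    baseline: np.ndarray | None = None
    scale: np.ndarray | None = None
    start_year: int = 2022
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_patients < 1:
            raise ValueError("n_patients must be >= 1")
        if isinstance(self.sessions_per_phase, int):
            self.sessions_per_phase = (self.sessions_per_phase,) * 3
        self.sessions_per_phase = tuple(int(c) for c in self.sessions_per_phase)
        if len(self.sessions_per_phase) != 3 or min(self.sessions_per_phase) < 1:
            raise ValueError("sessions_per_phase must be a positive int or triple")
        if self.noise_sd < 0 or self.patient_sd < 0:
            raise ValueError("dispersion parameters must be non-negative")
        self.band_corr = (
            default_band_corr() if self.band_corr is None else np.asarray(self.band_corr, float)
        )
        if self.band_corr.shape != (N_STREAMS, N_STREAMS):
            raise ValueError("band_corr must be 10 x 10")
        if not np.allclose(self.band_corr, self.band_corr.T, atol=1e-12):
            raise ValueError("band_corr must be symmetric")
        if not np.allclose(np.diag(self.band_corr), 1.0, atol=1e-12):
            raise ValueError("band_corr must have unit diagonal")
        if self.profile is None:
            self.profile = default_profile()
        self.baseline = (
            DEFAULT_BASELINE.copy() if self.baseline is None else np.asarray(self.baseline, float)
        )
        self.scale = DEFAULT_SCALE.copy() if self.scale is None else np.asarray(self.scale, float)
        if self.jitter_sd is None:
            self.jitter_sd = self.noise_sd / 4.0

    @property
    def n_sessions(self) -> int:
        return self.n_patients * sum(self.sessions_per_phase)

    def counts_by_moment(self) -> dict[Moment, int]:
        return {
            m: self.n_patients * c for m, c in zip(MOMENTS, self.sessions_per_phase)
        }


def _corr_factor(corr: np.ndarray) -> np.ndarray:
    """Symmetric square-root factor of a correlation matrix (PSD-checked)."""
    w, V = np.linalg.eigh(corr)
    if w.min() < -1e-10:
        raise ValueError(
            f"band_corr is not positive semi-definite (min eigenvalue {w.min():.3e})"
        )
    return V @ np.diag(np.sqrt(np.clip(w, 0.0, None))) @ V.T


def _rngs(seed: int, n: int) -> list[np.random.Generator]:
    return [np.random.default_rng(s) for s in np.random.SeedSequence(seed).spawn(n)]


def sample_cohort(cfg: CohortConfig) -> CohortMatrix:
    """Draw a raw labelled cohort matrix under the generative model."""
    F = _corr_factor(cfg.band_corr)
    rng = _rngs(cfg.seed, 2)[0]
    rows = []
    labels = {"patient_id": [], "moment": [], "date": []}
    start = _dt.date(cfg.start_year, 1, 1)
    for p in range(1, cfg.n_patients + 1):
        offset = cfg.patient_sd * (F @ rng.standard_normal(N_STREAMS))
        for mi, (moment, count) in enumerate(zip(MOMENTS, cfg.sessions_per_phase)):
            shift = cfg.profile.shift(moment)
            for s in range(count):
                noise = cfg.noise_sd * (F @ rng.standard_normal(N_STREAMS))
                x_std = offset + shift + noise
                rows.append(cfg.baseline + cfg.scale * x_std)
                labels["patient_id"].append(p)
                labels["moment"].append(moment)
                labels["date"].append(start + _dt.timedelta(days=mi * 37 + s * 200))
    return CohortMatrix(values=np.array(rows), labels=pd.DataFrame(labels))


def _member_name(patient_id: int, moment: Moment, date: _dt.date) -> str:
    return f"Patient{patient_id}_{moment.value}_{date.isoformat()}.txt"


def write_archive(cohort: CohortMatrix, cfg: CohortConfig, out_path: str | Path) -> Path:
    """Write a cohort as a ZIP of per-session text recordings.

    Each member holds ``samples_per_session`` rows equal to the session
    feature vector plus per-row Gaussian jitter of sd ``jitter_sd``
    (standardized units, mapped through the per-stream scale), so that
    parsing and re-summarizing the archive recovers the features to
    within sampling error of the jitter.
    """
    out_path = Path(out_path)
    rng = _rngs(cfg.seed, 2)[1]
    names_seen: set[str] = set()
    with zipfile.ZipFile(out_path, "w", zipfile.ZIP_DEFLATED) as zf:
        for i in range(cohort.n_sessions):
            lab = cohort.labels.iloc[i]
            name = _member_name(int(lab["patient_id"]), lab["moment"], lab["date"])
            if name in names_seen:
                raise ValueError(f"duplicate session identity: {name}")
            names_seen.add(name)
            jitter = cfg.jitter_sd * rng.standard_normal(
                (cfg.samples_per_session, N_STREAMS)
            )
            data = cohort.values[i] + cfg.scale * jitter
            lines = ["\t".join(STREAM_NAMES)]
            for row in data:
                lines.append("\t".join(f"{v:.17g}" for v in row))
            zf.writestr(name, "\n".join(lines) + "\n")
    return out_path


def phase_stability_threshold(cfg: CohortConfig) -> float:
    """Noise level below which the phase geometry is predictably stable.

    Works in the standardized feature space.  With session counts
    ``w_m`` per moment, each column's total variance is
    ``noise^2 + patient_sd^2 + shift_var_b`` (shift variance taken over
    the weighted moment mix), so after z-scoring the expected
    within-phase dispersion is ``sum_b (noise^2 + patient_sd^2) / tot_b``
    and the squared centroid separation of moments (a, b) is
    ``sum_b (shift_a_b - shift_b_b)^2 / tot_b``.  The returned value is
    the largest noise_sd at which the smallest pairwise separation still
    exceeds the within-phase dispersion (bisection; 0.0 if no planted
    separation exists).
    """
    counts = np.array(cfg.sessions_per_phase, float)
    w = counts / counts.sum()
    shifts = np.stack([cfg.profile.shift(m) for m in MOMENTS])
    mean_shift = w @ shifts
    shift_var = w @ (shifts - mean_shift) ** 2

    def margin(noise_sd: float) -> float:
        tot = noise_sd**2 + cfg.patient_sd**2 + shift_var
        intra = np.sum((noise_sd**2 + cfg.patient_sd**2) / tot)
        inter2 = [
            np.sum((shifts[i] - shifts[j]) ** 2 / tot)
            for i in range(3)
            for j in range(i + 1, 3)
        ]
        return min(inter2) - intra

    # z-scored zero-shift columns keep unit variance for any noise_sd > 0,
    # so evaluate the noiseless limit just above zero
    lo, hi = 1e-9, 10.0
    if margin(lo) <= 0:
        return 0.0
    for _ in range(80):
        mid = (lo + hi) / 2
        if margin(mid) > 0:
            lo = mid
        else:
            hi = mid
    return lo


def oracle_eta_squared(
    cfg: CohortConfig,
    pair: tuple[Moment, Moment],
    feature_set: tuple[str, ...] = BAND_NAMES,
) -> float:
    """Expected two-group Pillai effect size under the generating model.

    Plug-in value obtained from the expected between- and within-group
    SSCP matrices: with shift difference d, per-group per-patient counts
    m_a, m_b, P patients and n_g = P * m_g sessions per group,

        E[H] = (n_a n_b / N) d d' + sigma_n^2 Sigma
        E[E] = (N - 2) sigma_n^2 Sigma
               + (m_a + m_b)(P - 1) sigma_p^2 Sigma

    (patient offsets cancel exactly from the group-mean contrast because
    every patient appears in both groups with equal weight, but they do
    inflate within-group scatter).  The reported value is
    tr(E[H] (E[H] + E[E])^{-1}), which also accounts for the estimator's
    small-sample bias to first order.
    """
    idx = [_IDX[name] for name in feature_set]
    S = cfg.band_corr[np.ix_(idx, idx)]
    counts = dict(zip(MOMENTS, cfg.sessions_per_phase))
    a, b = pair
    m_a, m_b = counts[a], counts[b]
    P = cfg.n_patients
    n_a, n_b = P * m_a, P * m_b
    N = n_a + n_b
    d = (cfg.profile.shift(a) - cfg.profile.shift(b))[idx]
    sn2, sp2 = cfg.noise_sd**2, cfg.patient_sd**2
    H = (n_a * n_b / N) * np.outer(d, d) + sn2 * S
    E = (N - 2) * sn2 * S + (m_a + m_b) * (P - 1) * sp2 * S
    return float(np.trace(np.linalg.solve(H + E, H)))
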