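"""End-to-end orchestration: ingest/simulate -> normalize -> train ->
metrics -> projection/clustering -> phase effects.

A single :class:`PipelineConfig` (buildable from YAML/JSON) drives the
whole analysis.  One global seed is fanned out to every stochastic stage
through named substreams, so a run is reproducible bit-for-bit from its
manifest.  Every artifact is written under the output directory and the
run report lists paths plus headline metrics.
"""

from __future__ import annotations

import json
import logging
import platform
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .autoencoders import (
    TaeConfig,
    TransformerAutoencoder,
    VaeConfig,
    VariationalAutoencoder,
)
from .effects import PhaseEffectModel
from .latent_eval import metrics_report
from .manifold import cluster_labels, correlation_matrix, pca_decomposition, project_2d
from .session_io import (
    CohortMatrix,
    cohort_to_csv,
    read_cohort,
    write_manifest,
    zscore_matrix,
)
from .streams import BAND_NAMES
from .synth import CohortConfig, sample_cohort, write_archive

__all__ = ["PipelineConfig", "PipelineStageError", "run_pipeline"]

log = logging.getLogger("eeglatent")

_STAGES = ("ingest", "normalize", "explore", "train", "evaluate", "project", "effects")


class PipelineStageError(RuntimeError):
    """A pipeline stage failed; carries the stage name and an error code."""

    def __init__(self, stage: str, code: str, message: str):
        super().__init__(f"[{stage}:{code}] {message}")
        self.stage = stage
        self.code = code


@dataclass
class PipelineConfig:
    """Full pipeline configuration (exactly one input mode)."""

    archive: str | None = None
    synthetic: CohortConfig | None = None
    models: str = "both"  # vae | tae | both
    out_dir: str = "eeglatent_run"
    seed: int = 0
    vae: VaeConfig = field(default_factory=VaeConfig)
    tae: TaeConfig = field(default_factory=TaeConfig)
    projection_method: str = "umap"
    knn_k: int = 10
    bootstrap: int = 2000
    anomaly_percentile: float = 95.0
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        if (self.archive is None) == (self.synthetic is None):
            raise ValueError(
                "exactly one input mode required: archive path or synthetic config"
            )
        if self.models not in ("vae", "tae", "both"):
            raise ValueError("models must be vae, tae or both")

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        if d.get("synthetic") is not None and not isinstance(d["synthetic"], CohortConfig):
            syn = dict(d["synthetic"])
            if isinstance(syn.get("profile"), dict):
                from .streams import Moment as _M
                from .synth import PhaseEffectProfile

                syn["profile"] = PhaseEffectProfile(
                    shifts={_M.parse(k): np.asarray(v) for k, v in syn["profile"].items()}
                )
            for key in ("band_corr", "baseline", "scale"):
                if syn.get(key) is not None:
                    syn[key] = np.asarray(syn[key], float)
            if isinstance(syn.get("sessions_per_phase"), list):
                syn["sessions_per_phase"] = tuple(syn["sessions_per_phase"])
            d["synthetic"] = CohortConfig(**syn)
        if not isinstance(d.get("vae", VaeConfig()), VaeConfig):
            d["vae"] = VaeConfig(**d["vae"])
        if not isinstance(d.get("tae", TaeConfig()), TaeConfig):
            d["tae"] = TaeConfig(**d["tae"])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def echo(self) -> dict:
        d = asdict(self)
        if self.synthetic is not None:
            syn = d["synthetic"]
            for key in ("band_corr", "baseline", "scale"):
                if syn.get(key) is not None:
                    syn[key] = np.asarray(syn[key]).tolist()
            syn["profile"] = {
                m.value: v.tolist() for m, v in self.synthetic.profile.shifts.items()
            }
        return d


def _stage_seeds(seed: int) -> dict[str, int]:
    """Fan the global seed out to named per-stage substreams."""
    names = ("synth", "vae", "tae", "projection", "clustering", "effects")
    children = np.random.SeedSequence(seed).spawn(len(names))
    return {
        name: int(child.generate_state(1)[0] % (2**31))
        for name, child in zip(names, children)
    }


def _run_stage(stage: str, fn, *args, **kwargs):
    try:
        return fn(*args, **kwargs)
    except PipelineStageError:
        raise
    except Exception as exc:  # abort with stage name + machine-readable code
        code = type(exc).__name__
        raise PipelineStageError(stage, code, str(exc)) from exc


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Execute the full analysis; returns the run report."""
    logging.basicConfig(level=getattr(logging, cfg.log_level.upper(), logging.INFO))
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seeds = _stage_seeds(cfg.seed)
    artifacts: dict[str, str] = {}
    headline: dict = {}

    # -- ingest ----------------------------------------------------------
    def ingest():
        if cfg.archive is not None:
            log.info("ingesting archive %s", cfg.archive)
            return read_cohort(cfg.archive)
        syn = cfg.synthetic
        syn = CohortConfig(**{**asdict_shallow(syn), "seed": seeds["synth"]})
        log.info("simulating cohort: %d sessions", syn.n_sessions)
        cohort = sample_cohort(syn)
        archive_path = out / "synthetic_archive.zip"
        write_archive(cohort, syn, archive_path)
        artifacts["synthetic_archive"] = str(archive_path)
        cohort, manifest = read_cohort(archive_path)
        return cohort, manifest

    cohort, manifest = _run_stage("ingest", ingest)
    cohort_path = out / "cohort_raw.csv"
    cohort_to_csv(cohort, cohort_path)
    artifacts["cohort_raw"] = str(cohort_path)
    headline["n_sessions"] = cohort.n_sessions
    headline["by_moment"] = manifest["by_moment"]

    # -- normalize -------------------------------------------------------
    std = _run_stage("normalize", zscore_matrix, cohort)
    std_path = out / "cohort_standardized.csv"
    cohort_to_csv(std, std_path)
    artifacts["cohort_standardized"] = str(std_path)
    manifest = dict(
        manifest,
        norm_stats={k: v.tolist() for k, v in std.norm_stats.items()},
    )
    manifest_path = out / "manifest.json"
    write_manifest(manifest, manifest_path)
    artifacts["manifest"] = str(manifest_path)

    # -- exploratory -----------------------------------------------------
    def explore():
        corr = correlation_matrix(cohort)
        corr.to_csv(out / "correlation_matrix.csv")
        pca = pca_decomposition(std)
        pca.loadings.to_csv(out / "pca_loadings.csv")
        pd.DataFrame(
            {
                "explained_ratio": pca.explained_ratio,
                "cumulative_ratio": pca.cumulative_ratio,
            },
            index=pca.loadings.index,
        ).to_csv(out / "pca_variance.csv")
        return pca

    pca = _run_stage("explore", explore)
    artifacts["correlation_matrix"] = str(out / "correlation_matrix.csv")
    artifacts["pca_loadings"] = str(out / "pca_loadings.csv")
    artifacts["pca_variance"] = str(out / "pca_variance.csv")
    headline["cumulative_variance_7pc"] = float(pca.cumulative_ratio[min(6, len(pca.cumulative_ratio) - 1)])

    # -- train / evaluate / project per model ----------------------------
    kinds = ("vae", "tae") if cfg.models == "both" else (cfg.models,)
    metrics_all: dict[str, dict] = {}
    for kind in kinds:
        def train_model(kind=kind):
            if kind == "vae":
                mcfg = VaeConfig(**{**asdict(cfg.vae), "seed": seeds["vae"]})
                return VariationalAutoencoder(std, mcfg).fit()
            mcfg = TaeConfig(**{**asdict(cfg.tae), "seed": seeds["tae"]})
            return TransformerAutoencoder(std, mcfg).fit()

        res = _run_stage("train", train_model)
        res.trace.to_csv(out / f"trace_{kind}.csv", index=False)
        artifacts[f"trace_{kind}"] = str(out / f"trace_{kind}.csv")

        def evaluate(res=res, kind=kind):
            errors = res.reconstruction_errors()
            try:
                proj = project_2d(
                    res.codes, method=cfg.projection_method, seed=seeds["projection"]
                )
            except ValueError as exc:
                # cohort too small to project; keep going without a 2-D view
                log.warning("skipping projection: %s", exc)
                proj = None
            frame = res.codes.to_frame()
            if proj is not None:
                res.codes.projection = proj.coords
                km = cluster_labels(proj, method="kmeans", seed=seeds["clustering"])
                db = cluster_labels(proj, method="dbscan")
                frame = res.codes.to_frame()
                frame["kmeans"] = km.labels
                frame["dbscan"] = db.labels
            frame.to_csv(out / f"latent_{kind}.csv", index=False)
            groupings = {
                "moment": list(std.moments()),
                "patient": list(std.labels["patient_id"].astype(str)),
            }
            report = metrics_report(
                res.codes, errors,
                projection=proj.coords if proj is not None else None,
                k=cfg.knn_k, groupings=groupings,
            )
            report["final_loss"] = res.final_loss()
            return report

        report = _run_stage("evaluate", evaluate)
        artifacts[f"latent_{kind}"] = str(out / f"latent_{kind}.csv")
        metrics_all[kind] = report
        headline[f"{kind}_final_loss"] = report["final_loss"]
        for key, val in report.items():
            if key.startswith("knn_consistency"):
                headline[f"{kind}_{key}"] = val

    metrics_path = out / "metrics.json"
    with open(metrics_path, "w") as fh:
        json.dump(metrics_all, fh, indent=2, sort_keys=True)
    artifacts["metrics"] = str(metrics_path)

    # -- phase effects ---------------------------------------------------
    def effects():
        model = PhaseEffectModel(std, feature_set=BAND_NAMES)
        return model.fit(bootstrap=cfg.bootstrap or None, seed=seeds["effects"])

    eff = _run_stage("effects", effects)
    with open(out / "effects.json", "w") as fh:
        json.dump(eff.to_json(), fh, indent=2)
    eff.to_frame().to_csv(out / "effects.csv", index=False)
    artifacts["effects"] = str(out / "effects.json")
    for e in eff.effects:
        headline[f"eta_sq_{e.pair[0].value.lower()}_vs_{e.pair[1].value.lower()}"] = e.eta_sq

    # -- run manifest ----------------------------------------------------
    run_manifest = {
        "config": cfg.echo(),
        "seed": cfg.seed,
        "stage_seeds": seeds,
        "versions": {
            "eeglatent": __version__,
            "python": platform.python_version(),
            "numpy": np.__version__,
            "pandas": pd.__version__,
        },
        "artifacts": artifacts,
        "headline": headline,
    }
    with open(out / "run_manifest.json", "w") as fh:
        json.dump(run_manifest, fh, indent=2, default=str)
    return run_manifest


def asdict_shallow(cfg: CohortConfig) -> dict:
    """CohortConfig -> kwargs dict preserving composite fields as objects."""
    return {
        "n_patients": cfg.n_patients,
        "sessions_per_phase": cfg.sessions_per_phase,
        "patient_sd": cfg.patient_sd,
        "noise_sd": cfg.noise_sd,
        "band_corr": cfg.band_corr,
        "profile": cfg.profile,
        "samples_per_session": cfg.samples_per_session,
        "jitter_sd": cfg.jitter_sd,
        "baseline": cfg.baseline,
        "scale": cfg.scale,
        "start_year": cfg.start_year,
        "seed": cfg.seed,
    }
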