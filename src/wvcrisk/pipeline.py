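"""End-to-end orchestration: scene -> submodels -> collision model -> risk map.

The pipeline mirrors the framework's flow: fit the occurrence submodel
to presence/background points, fit the traffic volume and speed
forests to observed counts and limits, predict all three quantities to
every road segment, build a collision/background segment dataset from
reported collision points, fit the structured cloglog GLM (and the
flat "alternative" GLM on raw covariates for comparison), validate on
an independent collision draw, and export the per-segment risk map.
"""

from __future__ import annotations

import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as wio
from ._rng import substream
from .occurrence import correlation_prune, fit_occurrence, predict_occurrence_raster
from .risk import (
    CollisionModelFit,
    fit_alternative_glm,
    fit_collision_glm,
    roc_auc,
)
from .spatial import (
    assign_records_to_segments,
    draw_background_segments,
    filter_records_by_accuracy,
)
from .synthetic import (
    SceneConfig,
    SyntheticScene,
    TruthParameters,
    draw_collision_records,
    generate_scene,
    simulate_collisions,
)
from .traffic import fit_speed_model, fit_volume_model, predict_traffic

__all__ = ["PipelineConfig", "RunManifest", "run_pipeline", "validate_holdout", "export_risk_map",
           "build_collision_dataset", "attach_submodel_predictions"]

RAW_COVARIATE_PREDICTORS = ["KMTODEV", "KMTOHWY", "POPDENS", "RDCLASS", "RDDENS"]


@dataclass
class PipelineConfig:
    """Configuration of a full synthetic-mode run."""

    scene: SceneConfig = field(default_factory=SceneConfig)
    truth: TruthParameters = field(default_factory=TruthParameters)
    n_presence: int = 900
    n_background: int = 10_000
    background_ratio: float = 2.0
    accuracy_threshold: float = 300.0
    occurrence_prune_threshold: float = 0.75
    traffic_prune_threshold: float = 0.7
    occurrence_params: dict = field(
        default_factory=lambda: {"max_trees": 500, "cv_folds": 5}
    )
    term_order: list[str] = field(default_factory=lambda: ["ln_O", "ln_V", "ln_S"])
    holdout_seed_offset: int = 104729  # distinct collision draw for validation
    output_dir: str | None = None

    def __post_init__(self) -> None:
        if not (0 < self.occurrence_prune_threshold <= 1):
            raise ValueError("occurrence prune threshold must lie in (0, 1]")
        if not (0 < self.traffic_prune_threshold <= 1):
            raise ValueError("traffic prune threshold must lie in (0, 1]")
        if self.accuracy_threshold <= 0:
            raise ValueError("accuracy_threshold must be positive")
        if self.background_ratio < 0:
            raise ValueError("background_ratio must be non-negative")


@dataclass
class RunManifest:
    """Reproducibility record of one pipeline run."""

    config: dict
    version: str
    metrics: dict
    outputs: list[str]
    timings: dict

    def comparable(self) -> dict:
        """Everything except wall-clock timings, for reproducibility checks."""
        return {"config": self.config, "metrics": self.metrics, "outputs": self.outputs}


def _sample_covariates(rasters, xs, ys) -> pd.DataFrame:
    return pd.DataFrame({name: r.sample_points(xs, ys) for name, r in rasters.items()})


def _occurrence_training_table(scene: SyntheticScene, prune_threshold: float):
    pres = _sample_covariates(scene.rasters, scene.presences["x"], scene.presences["y"])
    back = _sample_covariates(scene.rasters, scene.background["x"], scene.background["y"])
    table = pd.concat([pres, back], ignore_index=True)
    labels = np.concatenate([np.ones(len(pres)), np.zeros(len(back))])
    keep = ~table.isna().any(axis=1)
    table, labels = table[keep.to_numpy()], labels[keep.to_numpy()]
    pruned, dropped = correlation_prune(table, threshold=prune_threshold)
    pruned = pruned.copy()
    pruned["label"] = labels
    return pruned, dropped


def attach_submodel_predictions(
    scene: SyntheticScene,
    occ_raster,
    vol_fit,
    spd_fit,
) -> pd.DataFrame:
    """Segment table with predicted EGK (exposure), TVOL and TSPD columns."""
    table = scene.segment_table.copy()
    occ = occ_raster.sample_points(table["mid_x"].to_numpy(), table["mid_y"].to_numpy())
    table["EGK"] = np.clip(occ, 1e-6, 1.0)
    table["TVOL"] = predict_traffic(vol_fit, table)
    table["TSPD"] = predict_traffic(spd_fit, table)
    return table


def build_collision_dataset(
    scene: SyntheticScene,
    table: pd.DataFrame,
    records,
    accuracy_threshold: float,
    background_ratio: float,
    seed: int,
) -> pd.DataFrame:
    """Collision-coded + background segments with modelling covariates.

    Reported collision points are screened by positional accuracy,
    snapped to the nearest segment (ties to the lowest id) and collapsed
    to a binary code; background segments are a uniform draw, disjoint
    from the collision set, of ``background_ratio`` times its size.
    """
    kept = filter_records_by_accuracy(records, accuracy_threshold)
    _, collision_ids = assign_records_to_segments(kept, scene.segments)
    background_ids = draw_background_segments(
        scene.segments, collision_ids, ratio=background_ratio, seed=substream(seed, "background")
    )
    ids = list(collision_ids) + list(background_ids)
    data = table.set_index("segment_id").loc[ids].reset_index()
    data["Y"] = np.concatenate(
        [np.ones(len(collision_ids), dtype=int), np.zeros(len(background_ids), dtype=int)]
    )
    # raw covariates at midpoints for the alternative (flat) model
    cov = _sample_covariates(scene.rasters, data["mid_x"].to_numpy(), data["mid_y"].to_numpy())
    for c in cov.columns:
        data[c] = cov[c].to_numpy()
    data["O"] = data["EGK"]
    data["V"] = data["TVOL"]
    data["S"] = data["TSPD"]
    return data


def validate_holdout(
    fit: CollisionModelFit, holdout: pd.DataFrame, n_bins: int = 10
) -> tuple[float, pd.DataFrame]:
    """ROC AUC plus decile calibration on an independent record set.

    Calibration bins the hold-out segments into deciles of predicted
    probability and compares mean predicted p with the observed
    collision frequency in each bin.
    """
    if len(holdout) == 0:
        raise ValueError("hold-out dataset is empty")
    y = holdout["Y"].to_numpy()
    if len(np.unique(y)) < 2:
        raise ValueError("hold-out dataset has a single outcome class; AUC undefined")
    X = pd.DataFrame(
        {"ln_O": np.log(np.clip(holdout["O"], 1e-6, None)),
         "ln_V": np.log(holdout["V"]),
         "ln_S": np.log(holdout["S"])}
    )
    if fit.terms != list(X.columns):  # alternative model: raw covariates
        X = holdout[fit.terms].astype(float)
    p = fit.predict(X)
    auc = roc_auc(p, y)
    order = np.argsort(np.argsort(p, kind="mergesort"), kind="mergesort")
    bins = np.minimum((order * n_bins) // len(p), n_bins - 1)
    calib = pd.DataFrame({"bin": bins, "p": p, "y": y}).groupby("bin").agg(
        mean_predicted=("p", "mean"), observed_frequency=("y", "mean"), n=("y", "size")
    )
    return auc, calib.reset_index()


def export_risk_map(
    scene: SyntheticScene, table: pd.DataFrame, fit: CollisionModelFit, out_dir: Path
) -> list[str]:
    """Predicted relative collision probability for every segment.

    Writes ``risk_map.geojson`` (LineString features with p, O, V, S
    properties) and ``risk_map.csv``.
    """
    X = pd.DataFrame(
        {"ln_O": np.log(np.clip(table["EGK"], 1e-6, None)),
         "ln_V": np.log(table["TVOL"]),
         "ln_S": np.log(table["TSPD"])}
    )
    p = fit.predict(X)
    out = table[["segment_id", "road_class", "cell_id", "length", "EGK", "TVOL", "TSPD"]].copy()
    out["risk_p"] = p
    out.to_csv(out_dir / "risk_map.csv", index=False)
    extra = {
        row.segment_id: {
            "risk_p": row.risk_p, "EGK": row.EGK, "TVOL": row.TVOL, "TSPD": row.TSPD
        }
        for row in out.itertuples()
    }
    wio.segments_to_geojson(scene.segments, out_dir / "risk_map.geojson", extra=extra)
    return ["risk_map.csv", "risk_map.geojson"]


def run_pipeline(config: PipelineConfig) -> tuple[RunManifest, dict]:
    """Execute the full framework on a synthetic scene.

    Returns the manifest and a dict of in-memory artifacts (scene, fits,
    datasets) for programmatic use.  With ``config.output_dir`` set, the
    scene, fit summaries, and risk map are also written to disk.
    """
    timings: dict[str, float] = {}
    metrics: dict[str, object] = {}
    outputs: list[str] = []
    out_dir = Path(config.output_dir) if config.output_dir else None
    if out_dir:
        out_dir.mkdir(parents=True, exist_ok=True)

    def stage(name):
        class _T:
            def __enter__(self):
                self.t0 = time.perf_counter()

            def __exit__(self, exc_type, exc, tb):
                timings[name] = time.perf_counter() - self.t0
                if exc is not None:
                    raise RuntimeError(f"pipeline stage '{name}' failed: {exc}") from exc

        return _T()

    with stage("scene"):
        scene = generate_scene(
            config.scene,
            config.truth,
            n_presence=config.n_presence,
            n_background=config.n_background,
        )

    with stage("occurrence"):
        occ_table, occ_dropped = _occurrence_training_table(
            scene, config.occurrence_prune_threshold
        )
        occ_fit = fit_occurrence(occ_table, seed=config.scene.seed, **config.occurrence_params)
        occ_raster = predict_occurrence_raster(occ_fit, scene.rasters)
        metrics["occurrence"] = {
            "n_trees": occ_fit.n_trees,
            "deviance_explained_pct": occ_fit.deviance_explained,
            "cv_auc": occ_fit.cv_auc_mean,
            "cv_auc_sd": occ_fit.cv_auc_sd,
            "dropped_covariates": occ_dropped,
            "contributions_pct": occ_fit.contributions.round(4).to_dict(),
        }

    with stage("traffic"):
        vol_fit = fit_volume_model(
            scene.traffic_obs, seed=config.scene.seed,
            prune_threshold=config.traffic_prune_threshold,
        )
        spd_fit = fit_speed_model(scene.traffic_obs, seed=config.scene.seed)
        metrics["traffic_volume"] = {
            "pct_variance_explained": vol_fit.pct_variance_explained,
            "importance_pct": vol_fit.importance.round(4).to_dict(),
            "dropped_predictors": vol_fit.dropped_predictors,
        }
        metrics["traffic_speed"] = {
            "pct_variance_explained": spd_fit.pct_variance_explained,
            "importance_pct": spd_fit.importance.round(4).to_dict(),
        }

    with stage("dataset"):
        table = attach_submodel_predictions(scene, occ_raster, vol_fit, spd_fit)
        train_data = build_collision_dataset(
            scene, table, scene.collision_records,
            config.accuracy_threshold, config.background_ratio, config.scene.seed,
        )

    with stage("collision_glm"):
        fit = fit_collision_glm(train_data, term_order=config.term_order)
        cov_names = list(scene.rasters.keys()) + RAW_COVARIATE_PREDICTORS
        alt_fit = fit_alternative_glm(train_data, covariates=cov_names)
        metrics["collision"] = {
            "coefficients": fit.coefficients["coef"].round(6).to_dict(),
            "deviance_explained_pct": fit.deviance_explained,
            "aic": fit.aic,
            "anova_shares": fit.anova.round(6).to_dict(),
        }
        metrics["alternative_collision"] = {
            "deviance_explained_pct": alt_fit.deviance_explained,
            "aic": alt_fit.aic,
        }

    with stage("validation"):
        holdout_seed = config.scene.seed + config.holdout_seed_offset
        holdout_outcomes = simulate_collisions(
            scene.segment_table, config.truth.risk_coefs, holdout_seed
        )
        holdout_records = draw_collision_records(scene.segments, holdout_outcomes, holdout_seed)
        holdout_data = build_collision_dataset(
            scene, table, holdout_records,
            config.accuracy_threshold, config.background_ratio, holdout_seed,
        )
        auc, calibration = validate_holdout(fit, holdout_data)
        alt_auc, _ = validate_holdout(alt_fit, holdout_data)
        fit.holdout_roc = auc
        alt_fit.holdout_roc = alt_auc
        metrics["validation"] = {
            "holdout_auc": auc,
            "alternative_holdout_auc": alt_auc,
            "n_holdout": int(len(holdout_data)),
        }

    with stage("export"):
        if out_dir:
            outputs += list(wio.write_scene(scene, out_dir / "scene")["files"])
            wio.write_json(metrics, out_dir / "metrics.json")
            outputs.append("metrics.json")
            train_data.to_csv(out_dir / "collision_dataset.csv", index=False)
            holdout_data.to_csv(out_dir / "holdout_dataset.csv", index=False)
            outputs += ["collision_dataset.csv", "holdout_dataset.csv"]
            outputs += export_risk_map(scene, table, fit, out_dir)

    manifest = RunManifest(
        config=wio._jsonable(config),
        version="0.1.0",
        metrics=wio._jsonable(metrics),
        outputs=outputs,
        timings=timings,
    )
    if out_dir:
        wio.write_json(
            {**manifest.comparable(), "timings": timings, "version": manifest.version},
            out_dir / "run_manifest.json",
        )
    artifacts = {
        "scene": scene,
        "occurrence_fit": occ_fit,
        "occurrence_raster": occ_raster,
        "volume_fit": vol_fit,
        "speed_fit": spd_fit,
        "segment_table": table,
        "train_data": train_data,
        "holdout_data": holdout_data,
        "collision_fit": fit,
        "alternative_fit": alt_fit,
        "calibration": calibration,
    }
    return manifest, artifacts
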