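"""End-to-end pipeline: simulate/load -> preprocess -> band selection ->
indices -> classify -> evaluate (-> map).

One :class:`RunConfig` seed fans out to per-stage seeds through a stable
derivation (CRC32 of the stage name), so any stage can be re-run in
isolation and reproduce its in-pipeline behaviour.  By default all fitted
statistics (z-score, correlation pruning, RFE, PCA, index normalisation)
use the training rows only; ``pooled_normalization=True`` fits the normalisation on
the whole dataset instead, reproducing the common preprocess-then-split
ordering at the cost of mild leakage.
"""

from __future__ import annotations

import hashlib
import json
import logging
import zlib
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from . import classify as cl
from .analysis import build_stress_map, export_geojson
from .errors import ContractError, ParameterError
from .feature_select import BandRanking, correlation_matrix, pca_fit, pca_transform, prune_redundant, rfe_select
from .indices import (
    MLVI_DEFINITION,
    formulate_index,
    hvsi_series,
    interpret_mlvi,
    mlvi,
    ndvi_series,
    ndwi_series,
)
from .metrics import MetricsReport, evaluate_predictions
from .nn import CNNConfig
from .preprocess import smooth_library, zscore_apply, zscore_fit
from .spectra_io import SpectralLibrary
from .synth import SynthConfig, generate_library

logger = logging.getLogger(__name__)

FEATURE_MODES = ("rfe+indices", "rfe", "indices", "pca", "ndvi")


def derive_seed(seed: int, stage: str) -> int:
    """Per-stage seed derived from the global seed and the stage name."""
    return (int(seed) * 1000003 + zlib.crc32(stage.encode())) % (2**31)


@dataclass
class RunConfig:
    """All pipeline stage parameters plus the single global seed."""

    seed: int = 0
    # preprocessing
    sg_half_width: int = 5          # Savitzky-Golay window 2m+1 = 11 bands
    sg_polyorder: int = 2
    # band selection
    prune_threshold: Optional[float] = None  # e.g. 0.95 to drop near-duplicate bands first
    k_rfe: int = 10
    k_pca: int = 30
    rfe_estimator: str = "forest"
    # features and models
    feature_mode: str = "rfe+indices"
    models: tuple = ("cnn", "lda", "svm")
    cnn: CNNConfig = field(default_factory=CNNConfig)
    split_fractions: tuple = (0.70, 0.15, 0.15)
    use_generated_index: bool = False  # MLVI bands from the RFE ranking (vs fixed 854/1649/2133)
    pooled_normalization: bool = False

    def __post_init__(self) -> None:
        if self.feature_mode not in FEATURE_MODES:
            raise ParameterError(f"feature_mode must be one of {FEATURE_MODES}")

    def config_hash(self) -> str:
        payload = asdict(self)
        payload["models"] = list(self.models)
        payload["split_fractions"] = list(self.split_fractions)
        return hashlib.sha256(json.dumps(payload, sort_keys=True).encode()).hexdigest()[:16]


@dataclass
class PipelineResult:
    config: RunConfig
    config_hash: str
    library: SpectralLibrary
    split: cl.SplitAssignment
    retained_wavelengths: list
    ranking: Optional[BandRanking]
    index_definition: object
    features: cl.FeatureMatrix
    models: dict                    # kind -> ClassifierModel
    reports: dict                   # kind -> MetricsReport
    index_values: pd.DataFrame


def run_pipeline(
    config: RunConfig,
    library: Optional[SpectralLibrary] = None,
    synth: Optional[SynthConfig] = None,
    outdir: Optional[str] = None,
) -> PipelineResult:
    """Execute the full pipeline and (optionally) write artifacts to ``outdir``."""
    if library is None:
        synth = synth or SynthConfig(seed=derive_seed(config.seed, "simulate"))
        logger.info("simulate: generating synthetic library (seed %d)", synth.seed)
        library = generate_library(synth)
    if library.labels is None:
        raise ContractError("pipeline requires a labeled library (band selection and training)")
    labels = library.labels
    n_classes = config.cnn.n_classes

    split = cl.stratified_split(
        labels, fractions=config.split_fractions, seed=derive_seed(config.seed, "split")
    )
    logger.info(
        "split: %d train / %d val / %d test",
        split.train.size, split.validation.size, split.test.size,
    )

    smoothed = smooth_library(library, config.sg_half_width, config.sg_polyorder)
    fit_rows = None if config.pooled_normalization else split.train
    stats = zscore_fit(smoothed, fit_rows)
    zlib_all = zscore_apply(smoothed, stats, zero_variance="zero")
    logger.info("preprocess: %d samples x %d bands smoothed and z-scored",
                zlib_all.n_samples, zlib_all.n_bands)

    fit_idx = np.arange(library.n_samples) if config.pooled_normalization else split.train
    train_z = zlib_all.subset_samples(fit_idx)
    if config.prune_threshold is not None:
        cm = correlation_matrix(train_z)
        retained = prune_redundant(cm, config.prune_threshold)
        logger.info("prune: %d of %d bands retained (|r| <= %.2f)",
                    len(retained), zlib_all.n_bands, config.prune_threshold)
        pruned_train = train_z.subset_bands(
            [train_z.band_index(w, tolerance=0.5) for w in retained]
        )
    else:
        retained = [float(w) for w in zlib_all.wavelengths]
        pruned_train = train_z

    ranking = None
    if config.feature_mode in ("rfe+indices", "rfe") or config.use_generated_index:
        k = min(config.k_rfe, pruned_train.n_bands)
        ranking = rfe_select(
            pruned_train,
            labels[fit_idx],
            estimator=config.rfe_estimator,
            k=k,
            seed=derive_seed(config.seed, "rfe"),
        )
        logger.info("rfe: selected %s nm", np.sort(ranking.wavelengths).astype(int).tolist())

    if config.use_generated_index and ranking is not None and ranking.wavelengths.size >= 3:
        index_def = formulate_index(ranking)
    else:
        index_def = MLVI_DEFINITION
    # indices are physical band ratios: computed on smoothed raw reflectance
    mlvi_vals = index_def.evaluate(smoothed).values
    hvsi_vals = hvsi_series(smoothed).values
    ndvi_vals = ndvi_series(smoothed).values
    ndwi_vals = ndwi_series(smoothed).values
    index_values = pd.DataFrame(
        {
            "sample_id": library.sample_ids,
            "mlvi": mlvi_vals,
            "h_vsi": hvsi_vals,
            "ndvi": ndvi_vals,
            "ndwi": ndwi_vals,
            "category": interpret_mlvi(mlvi_vals),
        }
    )

    features = _build_features(
        config, zlib_all, smoothed, ranking, split, fit_idx,
        mlvi_vals, hvsi_vals, ndvi_vals,
    )

    models, reports = {}, {}
    for kind in config.models:
        if kind == "cnn":
            cnn_cfg = CNNConfig(**{**asdict(config.cnn), "seed": derive_seed(config.seed, "cnn")})
            model = cl.train_cnn(features, labels, split, cnn_cfg)
        elif kind == "lda":
            model = cl.train_lda(features, labels, split, n_classes=n_classes)
        elif kind == "svm":
            model = cl.train_svm(
                features, labels, split, seed=derive_seed(config.seed, "svm"),
                n_classes=n_classes,
            )
        else:
            raise ParameterError(f"unknown model kind {kind!r}")
        test_features = cl.FeatureMatrix(
            values=features.values[split.test], mode=features.mode,
            feature_names=features.feature_names,
        )
        proba, pred = cl.predict(model, test_features)
        reports[kind] = evaluate_predictions(labels[split.test], pred, n_classes, proba)
        models[kind] = model
        logger.info("%s: test accuracy %.3f, MCC %.3f",
                    kind, reports[kind].accuracy, reports[kind].mcc)

    result = PipelineResult(
        config=config,
        config_hash=config.config_hash(),
        library=library,
        split=split,
        retained_wavelengths=retained,
        ranking=ranking,
        index_definition=index_def,
        features=features,
        models=models,
        reports=reports,
        index_values=index_values,
    )
    if outdir is not None:
        _write_artifacts(result, Path(outdir))
    return result


def _zscore_columns(x: np.ndarray, fit_idx: np.ndarray):
    mu = x[fit_idx].mean(axis=0)
    sd = np.maximum(x[fit_idx].std(axis=0), 1e-12)
    return (x - mu) / sd


def _build_features(
    config, zlib_all, smoothed, ranking, split, fit_idx, mlvi_vals, hvsi_vals, ndvi_vals
) -> cl.FeatureMatrix:
    mode = config.feature_mode
    index_block = _zscore_columns(np.column_stack([mlvi_vals, hvsi_vals]), fit_idx)
    if mode in ("rfe+indices", "rfe"):
        wl = np.sort(ranking.wavelengths)
        cols = [zlib_all.band_index(w, tolerance=0.5) for w in wl]
        band_block = zlib_all.reflectance[:, cols]
        names = [f"X{int(w)}" for w in wl]
        if mode == "rfe":
            return cl.FeatureMatrix(values=band_block, mode=mode, feature_names=names)
        return cl.FeatureMatrix(
            values=np.column_stack([band_block, index_block]),
            mode=mode,
            feature_names=names + ["mlvi", "h_vsi"],
        )
    if mode == "indices":
        return cl.FeatureMatrix(values=index_block, mode=mode, feature_names=["mlvi", "h_vsi"])
    if mode == "pca":
        k = min(config.k_pca, fit_idx.size, zlib_all.n_bands)
        model = pca_fit(zlib_all.subset_samples(fit_idx), k=k)
        scores = pca_transform(model, zlib_all)
        return cl.FeatureMatrix(
            values=scores, mode=mode, feature_names=[f"pc{i + 1}" for i in range(k)]
        )
    # ndvi: single-value sequence
    return cl.FeatureMatrix(
        values=_zscore_columns(ndvi_vals[:, None], fit_idx), mode=mode, feature_names=["ndvi"]
    )


def _write_artifacts(result: PipelineResult, outdir: Path) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    stamp = {"config_hash": result.config_hash, "seed": result.config.seed}
    metrics = {
        kind: {**report.to_dict(), **stamp} for kind, report in result.reports.items()
    }
    (outdir / "metrics.json").write_text(json.dumps(metrics, indent=1))
    if result.ranking is not None:
        ranking = {
            "wavelengths_nm": result.ranking.wavelengths.tolist(),
            "scores": result.ranking.scores.tolist(),
            "elimination_order": result.ranking.elimination_order,
            **stamp,
        }
        (outdir / "ranking.json").write_text(json.dumps(ranking, indent=1))
    result.index_values.to_csv(outdir / "indices.csv", index=False)
    if "cnn" in result.models:
        net = result.models["cnn"].model
        np.savez(outdir / "cnn_model.npz", **net.params)
        sidecar = {
            "kind": "cnn",
            "feature_mode": result.features.mode,
            "classes": list(range(result.models["cnn"].n_classes)),
            "cnn_config": asdict(result.config.cnn),
            **stamp,
        }
        (outdir / "cnn_model.json").write_text(json.dumps(sidecar, indent=1))
        hist = result.models["cnn"].history
        pd.DataFrame(
            {
                "epoch": hist.epoch,
                "train_loss": hist.train_loss,
                "train_accuracy": hist.train_accuracy,
                "val_loss": hist.val_loss,
                "val_accuracy": hist.val_accuracy,
                "learning_rate": hist.learning_rate,
            }
        ).to_csv(outdir / "cnn_history.csv", index=False)
    md = result.library.metadata
    if md is not None and {"latitude", "longitude"} <= set(md.columns):
        series = mlvi(result.library)
        stress_map = build_stress_map(result.library, series)
        export_geojson(stress_map, outdir / "stress_map.geojson")
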