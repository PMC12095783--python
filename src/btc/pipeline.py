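"""End-to-end orchestration: phantoms -> enhancement -> segmentation ->
ROIs -> features -> ensemble cross-validation -> metric report.

A single master seed fans out to per-stage seeds through a documented
hash (:func:`stage_seed`), so any stage can be re-run independently and
two runs with the same (config, seed) produce identical artifacts.
Each run writes a manifest recording the config hash, per-stage
timings, derived seeds, package version, and every artifact path.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
import zlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .enhance import AGSWParams, StructuringElement, agsw_filter, morphological_cleanup
from .ensemble import CVResult, EnsembleConfig, cross_validate
from .features import (
    FeatureNetConfig,
    extract_features,
    train_feature_extractor,
)
from .metrics import evaluate_confusion, load_reference_confusion, round4
from .phantom import (
    CLASS_NAMES,
    augment_dataset,
    generate_dataset,
    min_max_normalize,
)
from .segment import SegNetConfig, extract_roi, predict_mask, train_segmenter

logger = logging.getLogger(__name__)

#: Published per-class metric table for the reference confusion matrix
#: (rows: accuracy, sensitivity, specificity, precision, F1), used by
#: ``reproduce_reference`` to verify the metrics module cell for cell.
REFERENCE_METRICS = {
    "meningioma": {"accuracy": 0.9951, "sensitivity": 0.9944,
                   "specificity": 0.9953, "precision": 0.9846, "f1": 0.9895},
    "glioma": {"accuracy": 0.9967, "sensitivity": 0.9937,
               "specificity": 0.9994, "precision": 0.9993, "f1": 0.9965},
    "pituitary": {"accuracy": 0.9984, "sensitivity": 0.9978,
                  "specificity": 0.9986, "precision": 0.9968, "f1": 0.9973},
}
REFERENCE_MACRO_ACCURACY = 0.9967
REFERENCE_FOLD_ACCURACY = 0.9951
REFERENCE_N_CORRECT = 3049
REFERENCE_N_MISCLASSIFIED = 15


def stage_seed(master_seed: int, stage: str) -> int:
    """Per-stage seed: CRC-32 of the stage name mixed into the master
    seed through a SeedSequence; always below 2^31."""
    ss = np.random.SeedSequence([int(master_seed), zlib.crc32(stage.encode())])
    return int(ss.generate_state(1, dtype=np.uint32)[0] % 2**31)


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

@dataclass
class PhantomStageConfig:
    n_per_class: int = 100
    image_size: int = 64
    noise_sd: float = 0.02
    inhomogeneity_strength: float = 0.15
    augment: bool = False
    rotation_angles: tuple[float, ...] = (90.0, 180.0, 270.0)


@dataclass
class EnhanceStageConfig:
    enabled: bool = True
    radius: int = 4
    orientations: tuple[float, ...] = (0.0, 45.0, 90.0, 135.0)
    sigma_major: float = 2.0
    sigma_minor: float = 0.8
    epsilon: float = 1e-3
    loss_form: str = "standard"
    guidance_lambda: float = 0.3
    se_shape: str = "disk"
    se_radius: int = 3

    def agsw_params(self) -> AGSWParams:
        return AGSWParams(
            radius=self.radius, orientations=tuple(self.orientations),
            sigma_major=self.sigma_major, sigma_minor=self.sigma_minor,
            epsilon=self.epsilon, loss_form=self.loss_form,
            guidance_lambda=self.guidance_lambda,
        )

    def structuring_element(self) -> StructuringElement:
        return StructuringElement(shape=self.se_shape, radius=self.se_radius)


@dataclass
class SegmentStageConfig:
    n_train: int = 60
    depth: int = 3
    base_channels: int = 8
    se_reduction: int = 4
    batch_size: int = 4
    epochs: int = 15
    train_fraction: float = 0.70
    roi_margin: int = 4
    roi_size: int = 64


@dataclass
class FeatureStageConfig:
    n_representation: int = 60
    epochs: int = 15
    batch_size: int = 32
    learning_rate: float = 0.003
    dropout: float = 0.5


@dataclass
class EnsembleStageConfig:
    rf_trees: int = 200
    svm_kernel: str = "rbf"
    svm_c: float = 1.0
    knn_k: int = 5
    knn_weights: str = "distance"

    def ensemble_config(self, seed: int) -> EnsembleConfig:
        return EnsembleConfig(
            rf_trees=self.rf_trees, svm_kernel=self.svm_kernel,
            svm_c=self.svm_c, knn_k=self.knn_k,
            knn_weights=self.knn_weights, seed=seed,
        )


@dataclass
class MetricsStageConfig:
    cv_folds: int = 5


@dataclass
class PipelineConfig:
    """Nested per-stage blocks plus the master seed and output settings."""

    phantom: PhantomStageConfig = field(default_factory=PhantomStageConfig)
    enhance: EnhanceStageConfig = field(default_factory=EnhanceStageConfig)
    segment: SegmentStageConfig = field(default_factory=SegmentStageConfig)
    features: FeatureStageConfig = field(default_factory=FeatureStageConfig)
    ensemble: EnsembleStageConfig = field(default_factory=EnsembleStageConfig)
    metrics: MetricsStageConfig = field(default_factory=MetricsStageConfig)
    seed: int = 0
    output_dir: str = "btc_run"
    verbosity: str = "info"

    @classmethod
    def from_dict(cls, data: dict) -> "PipelineConfig":
        """Build from a nested dict, rejecting unknown keys anywhere."""
        blocks = {f.name: f for f in dataclasses.fields(cls)}
        unknown = set(data) - set(blocks)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        kwargs: dict[str, Any] = {}
        for name, value in data.items():
            f = blocks[name]
            if dataclasses.is_dataclass(f.type) or name in (
                "phantom", "enhance", "segment", "features", "ensemble", "metrics"
            ):
                sub_cls = {
                    "phantom": PhantomStageConfig,
                    "enhance": EnhanceStageConfig,
                    "segment": SegmentStageConfig,
                    "features": FeatureStageConfig,
                    "ensemble": EnsembleStageConfig,
                    "metrics": MetricsStageConfig,
                }[name]
                sub_fields = {sf.name for sf in dataclasses.fields(sub_cls)}
                sub_unknown = set(value) - sub_fields
                if sub_unknown:
                    raise ValueError(
                        f"unknown keys in config block {name!r}: "
                        f"{sorted(sub_unknown)}"
                    )
                value = {
                    k: tuple(v) if isinstance(v, list) else v
                    for k, v in value.items()
                }
                kwargs[name] = sub_cls(**value)
            else:
                kwargs[name] = value
        return cls(**kwargs)

    def to_dict(self) -> dict:
        def clean(obj):
            if dataclasses.is_dataclass(obj):
                return {k: clean(v) for k, v in dataclasses.asdict(obj).items()}
            if isinstance(obj, tuple):
                return [clean(v) for v in obj]
            return obj

        return clean(self)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as f:
            data = yaml.safe_load(f) or {}
        return cls.from_dict(data)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as f:
            yaml.safe_dump(self.to_dict(), f, sort_keys=False)

    def config_hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:16]


@dataclass
class RunManifest:
    """Reproducibility record of one pipeline run."""

    config_hash: str
    seed: int
    stage_seeds: dict[str, int]
    stage_timings: dict[str, float]
    artifacts: dict[str, str]
    version: str = __version__

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as f:
            json.dump(dataclasses.asdict(self), f, indent=2)


# ---------------------------------------------------------------------------
# pipeline
# ---------------------------------------------------------------------------

def _preprocess(img_pixels: np.ndarray, cfg: EnhanceStageConfig) -> np.ndarray:
    """Normalize, AGSW-enhance and morphologically clean one image."""
    pixels = min_max_normalize(img_pixels)
    if not cfg.enabled:
        return pixels
    z, _ = agsw_filter(pixels, cfg.agsw_params())
    _, masked = morphological_cleanup(
        np.clip(z, 0.0, 1.0), cfg.structuring_element()
    )
    return masked


def run_pipeline(config: PipelineConfig, output_dir: str | Path | None = None
                 ) -> tuple[RunManifest, CVResult]:
    """Execute the full pipeline and return (manifest, CV result).

    Stages: generate evaluation phantoms -> normalize (+ optional
    augmentation) -> enhance + cleanup -> train segmenter on a separate
    phantom sample -> predict masks and crop ROIs -> train the feature
    extractor on another separate sample -> extract feature vectors ->
    soft-voting ensemble under stratified k-fold CV -> metric report.
    """
    out = Path(output_dir or config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    timings: dict[str, float] = {}
    seeds = {name: stage_seed(config.seed, name)
             for name in ("phantom", "segment_data", "segment", "features_data",
                          "features", "ensemble")}
    artifacts: dict[str, str] = {}

    def timed(name: str):
        class _Timer:
            def __enter__(self_inner):
                self_inner.t0 = time.perf_counter()
                logger.info("stage %s: start (seed=%d)", name,
                            seeds.get(name, config.seed))

            def __exit__(self_inner, exc_type, exc, tb):
                timings[name] = round(time.perf_counter() - self_inner.t0, 3)
                if exc_type is not None:
                    logger.error("stage %s failed: %s", name, exc)
                    return False
                logger.info("stage %s: done in %.2fs", name, timings[name])

        return _Timer()

    pc = config.phantom
    with timed("phantom"):
        dataset = generate_dataset(
            n_per_class=pc.n_per_class, image_size=pc.image_size,
            seed=seeds["phantom"], noise_sd=pc.noise_sd,
            inhomogeneity_strength=pc.inhomogeneity_strength,
        )
        if pc.augment:
            dataset = augment_dataset(dataset, angles=pc.rotation_angles,
                                      seed=seeds["phantom"])

    with timed("enhance"):
        processed = [_preprocess(img.pixels, config.enhance) for img in dataset]

    sc = config.segment
    with timed("segment_train"):
        seg_train = generate_dataset(
            n_per_class=max(1, sc.n_train // 3), image_size=pc.image_size,
            seed=seeds["segment_data"], noise_sd=pc.noise_sd,
            inhomogeneity_strength=pc.inhomogeneity_strength,
        )
        for img in seg_train:
            img.pixels = _preprocess(img.pixels, config.enhance)
        seg_config = SegNetConfig(
            depth=sc.depth, base_channels=sc.base_channels,
            se_reduction=sc.se_reduction, batch_size=sc.batch_size,
            epochs=sc.epochs, train_fraction=sc.train_fraction,
            seed=seeds["segment"], roi_margin=sc.roi_margin,
            roi_size=sc.roi_size,
        )
        segmenter, seg_history = train_segmenter(seg_train, seg_config)
        hist_path = out / "segmenter_history.json"
        hist_path.write_text(json.dumps(seg_history, indent=2))
        artifacts["segmenter_history"] = str(hist_path)

    with timed("rois"):
        rois = []
        for img, pixels in zip(dataset, processed):
            pred = predict_mask(segmenter, _with_pixels(img, pixels))
            rois.append(
                extract_roi(_with_pixels(img, pixels), pred,
                            margin=sc.roi_margin, out_size=sc.roi_size)
            )

    fc = config.features
    with timed("features_train"):
        rep_set = generate_dataset(
            n_per_class=max(1, fc.n_representation // 3),
            image_size=pc.image_size, seed=seeds["features_data"],
            noise_sd=pc.noise_sd,
            inhomogeneity_strength=pc.inhomogeneity_strength,
        )
        rep_rois = []
        for img in rep_set:
            pixels = _preprocess(img.pixels, config.enhance)
            pred = predict_mask(segmenter, _with_pixels(img, pixels))
            rep_rois.append(
                extract_roi(_with_pixels(img, pixels), pred,
                            margin=sc.roi_margin, out_size=sc.roi_size)
            )
        feat_config = FeatureNetConfig(
            input_size=sc.roi_size, seed=seeds["features"],
            epochs=fc.epochs, batch_size=fc.batch_size,
            learning_rate=fc.learning_rate, dropout=fc.dropout,
        )
        extractor, feat_history = train_feature_extractor(
            rep_rois, CLASS_NAMES, feat_config
        )

    with timed("features_extract"):
        feature_matrix = extract_features(rois, extractor)
        labels = np.array([r.label for r in rois])
        groups = np.array([
            r.provenance.get("source_index", i) for i, r in enumerate(rois)
        ])
        is_original = np.array([
            r.provenance.get("augmentation", "original") == "original"
            for r in rois
        ])
        df = pd.DataFrame(feature_matrix)
        df.insert(0, "label", labels)
        feat_path = out / "features.csv"
        df.to_csv(feat_path, index=False)
        artifacts["features"] = str(feat_path)

    with timed("ensemble_cv"):
        result = cross_validate(
            feature_matrix, labels, k=config.metrics.cv_folds,
            cfg=config.ensemble.ensemble_config(seeds["ensemble"]),
            class_order=CLASS_NAMES,
            groups=groups if pc.augment else None,
            is_original=is_original if pc.augment else None,
        )
        report = {
            "mean": result.mean_metrics,
            "folds": [r.as_dict() for r in result.fold_reports],
            "segmenter_final_test_dice": seg_history[-1]["test_dice"],
        }
        report_path = out / "report.json"
        report_path.write_text(json.dumps(report, indent=2))
        artifacts["report"] = str(report_path)

    config_path = out / "config.yaml"
    config.to_yaml(config_path)
    artifacts["config"] = str(config_path)
    manifest = RunManifest(
        config_hash=config.config_hash(), seed=config.seed,
        stage_seeds=seeds, stage_timings=timings, artifacts=artifacts,
    )
    manifest_path = out / "manifest.json"
    manifest.to_json(manifest_path)
    return manifest, result


def _with_pixels(img, pixels):
    from .phantom import LabeledImage

    return LabeledImage(pixels=pixels, label=img.label, mask=img.mask,
                        provenance=dict(img.provenance))


# ---------------------------------------------------------------------------
# reference reproduction
# ---------------------------------------------------------------------------

def reproduce_reference(path: str | Path | None = None) -> tuple[bool, str]:
    """Evaluate the shipped reference confusion matrix and compare every
    metric cell (4 dp, half-up) with the published table.

    Returns (all_match, human-readable diff table).
    """
    cm = load_reference_confusion(path)
    report = evaluate_confusion(cm)
    lines = []
    ok = True
    for name, expected in REFERENCE_METRICS.items():
        got = report.per_class[name]
        for key, exp_val in expected.items():
            got_val = round4(got[key])
            match = got_val == exp_val
            ok &= match
            lines.append(
                f"{name:<12} {key:<12} computed={got_val:.4f} "
                f"published={exp_val:.4f} {'OK' if match else 'MISMATCH'}"
            )
    checks = [
        ("macro accuracy", round4(report.macro["accuracy"]),
         REFERENCE_MACRO_ACCURACY),
        ("fold accuracy", round4(report.fold_accuracy),
         REFERENCE_FOLD_ACCURACY),
        ("n correct", cm.trace, REFERENCE_N_CORRECT),
        ("n misclassified", cm.total - cm.trace, REFERENCE_N_MISCLASSIFIED),
    ]
    for label, got_val, exp_val in checks:
        match = got_val == exp_val
        ok &= match
        lines.append(f"{label:<25} computed={got_val} published={exp_val} "
                     f"{'OK' if match else 'MISMATCH'}")
    return ok, "\n".join(lines)
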