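"""End-to-end orchestration: scene -> segmentation -> masking -> stratified
sampling -> classification -> evaluation.

Everything is seeded through one global seed, and the run report is a plain
JSON-serializable dictionary so identical configurations reproduce identical
reports byte for byte.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field, replace

import numpy as np
import pandas as pd

from . import auto_sampling, classification, evaluation, scene_synthesis, segmentation, stratification
from .auto_sampling import CandidateFilter, Prototype
from .classification import ClassifierSpec, VEGETATION
from .mab_model import MabTable, SamplingParams, default_mab_table
from .scene_synthesis import CULTIVATED_NAME, NODATA, SceneBundle, SceneParams
from .segmentation import SegmentationParams

__all__ = [
    "PipelineConfig",
    "PipelineResult",
    "PipelineStageError",
    "run_pipeline",
    "raster_confusion",
]


class PipelineStageError(RuntimeError):
    """A pipeline stage failed; carries the stage name for the run report."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass(frozen=True)
class PipelineConfig:
    scene: SceneParams = SceneParams()
    # layer 1: coarse, non-vegetation extraction; layer 2: fine, sampling
    seg_layer1: SegmentationParams = SegmentationParams(scale=120.0)
    seg_layer2: SegmentationParams = SegmentationParams(scale=10.0)
    # the synthetic geometry yields wider objects than real imagery, so the
    # default elongation cut is looser than the CandidateFilter default
    filter: CandidateFilter = CandidateFilter(min_area=25, max_length_width=12.0)
    sampling: SamplingParams = SamplingParams()
    classifier_kind: str = "rf"
    classifier_params: dict = field(
        default_factory=lambda: {
            "n_estimators": 20, "max_depth": 19, "min_samples_leaf": 2, "max_features": 8,
        }
    )
    clustering_algorithm: str = "kmeans"
    tune: bool = False
    n_validation: int = 1000
    seed: int = 0

    def config_hash(self) -> str:
        blob = json.dumps(
            {
                "scene": asdict(self.scene),
                "seg1": asdict(self.seg_layer1),
                "seg2": asdict(self.seg_layer2),
                "filter": asdict(self.filter),
                "sampling": asdict(self.sampling),
                "classifier": [self.classifier_kind, self.classifier_params],
                "algorithm": self.clustering_algorithm,
                "tune": self.tune,
                "n_validation": self.n_validation,
                "seed": self.seed,
            },
            sort_keys=True,
            default=str,
        )
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


@dataclass
class PipelineResult:
    config: PipelineConfig
    scene: SceneBundle
    layer1: segmentation.ObjectMap
    layer2: segmentation.ObjectMap
    features1: pd.DataFrame
    features2: pd.DataFrame
    veg_mask2: pd.Series
    belt_raster: stratification.BeltRaster
    object_belts: dict[int, int]
    sample_db: dict
    labels: pd.Series
    pred_raster: np.ndarray
    report: dict


def raster_confusion(
    pred: np.ndarray, ref: np.ndarray, classes
) -> evaluation.ConfusionMatrix:
    """Vectorized full-raster confusion over pixels valid in the reference."""
    valid = ref != NODATA
    n_cls = len(classes)
    p = pred[valid].astype(np.int64)
    r = ref[valid].astype(np.int64)
    counts = np.bincount(p * n_cls + r, minlength=n_cls * n_cls).reshape(n_cls, n_cls)
    return evaluation.ConfusionMatrix(counts=counts, classes=tuple(classes))


def _prototypes(scene: SceneBundle) -> dict[str, Prototype]:
    return {
        name: auto_sampling.prototype_from_signature(sig)
        for name, sig in scene.signatures.items()
    }


def run_pipeline(
    config: PipelineConfig = PipelineConfig(),
    scene: SceneBundle | None = None,
    table: MabTable | None = None,
) -> PipelineResult:
    """Run every stage on a (possibly pre-built) scene and assemble the report."""
    from contextlib import contextmanager

    @contextmanager
    def guard(stage: str):
        try:
            yield
        except PipelineStageError:
            raise
        except Exception as exc:
            raise PipelineStageError(stage, exc) from exc

    table = table or default_mab_table()
    seed = config.seed
    if scene is None:
        with guard("scene_synthesis"):
            scene = scene_synthesis.generate_scene(
                replace(config.scene, seed=seed), table=table
            )
    class_names = scene.class_names

    # --- segmentation: one merge run, snapshots at both layer scales -------
    with guard("segmentation"):
        stack = segmentation.build_stack(scene.image, scene.dsm)
        same_shape = (
            config.seg_layer1.shape_factor == config.seg_layer2.shape_factor
            and config.seg_layer1.compactness == config.seg_layer2.compactness
            and config.seg_layer1.band_weights == config.seg_layer2.band_weights
        )
        s2, s1 = sorted([config.seg_layer2.scale, config.seg_layer1.scale])
        if same_shape:
            layer2, layer1 = segmentation.segment_multi(
                stack, config.seg_layer2, [s2, s1]
            )
        else:  # different heterogeneity settings need independent merge runs
            layer2 = segmentation.segment(stack, config.seg_layer2)
            layer1 = segmentation.segment(stack, config.seg_layer1)
        features2 = segmentation.compute_features(layer2, scene.image, scene.dsm)
        features1 = segmentation.compute_features(layer1, scene.image, scene.dsm)

    # --- layer 1: fuzzy non-vegetation mask, inherited to layer 2 ----------
    with guard("layer1_classification"):
        layer1_labels = classification.classify_layer1(features1)
        veg_mask2 = classification.inherit_classes(layer1_labels, layer1, layer2)
        veg_ids = set(int(i) for i in veg_mask2.index[veg_mask2 == VEGETATION])

    # --- stratification ----------------------------------------------------
    with guard("stratification"):
        slope_mask = stratification.split_slopes(scene.dsm)
        belt_raster = stratification.build_constraint_raster(
            scene.dsm, slope_mask, table
        )
        object_belts = stratification.assign_objects(layer2, belt_raster)

    # --- automatic sampling ------------------------------------------------
    with guard("sampling"):
        prototypes = _prototypes(scene)
        sample_db = auto_sampling.build_sample_db(
            features2,
            object_belts,
            belt_raster,
            table,
            prototypes,
            veg_object_ids=veg_ids,
            filt=config.filter,
            params=config.sampling,
            algorithm=config.clustering_algorithm,
            seed=seed,
        )

    # --- classification ----------------------------------------------------
    with guard("classification"):
        basal_ids = {
            bid
            for bid, belt in enumerate(belt_raster.belts)
            if belt.formation == table.basal_formation
        }
        cultivated_ids = [
            oid for oid, bid in object_belts.items() if bid in basal_ids and oid in veg_ids
        ]
        fixed = pd.Series(CULTIVATED_NAME, index=pd.Index(cultivated_ids, name="object_id"))

        feature_names = [c for c in segmentation.ALL_FEATURES if c in features2.columns]
        spec = ClassifierSpec(
            kind=config.classifier_kind,
            params=dict(config.classifier_params),
            feature_names=feature_names,
            seed=seed,
        )
        train_db = {k: v for k, v in sample_db.items() if v.corrected is not None}
        if config.tune and train_db:
            tr_ids, tr_labels = [], []
            for res in train_db.values():
                tr_ids.extend(res.corrected.object_ids)
                tr_labels.extend([res.corrected.formation] * len(res.corrected.object_ids))
            ranked, selected = classification.rank_features(
                features2.loc[tr_ids], np.asarray(tr_labels), seed=seed,
                feature_names=feature_names,
            )
            spec = classification.tune_classifier(
                config.classifier_kind, features2.loc[tr_ids], np.asarray(tr_labels),
                seed=seed, feature_names=selected,
            )
        labels = classification.train_classify(
            spec,
            train_db,
            features2,
            veg_mask2,
            fixed_labels=fixed,
            target_n=config.sampling.target_n,
            seed=seed,
        )

    # --- rasterize predictions and evaluate --------------------------------
    with guard("evaluation"):
        name_to_id = {n: i for i, n in enumerate(class_names)}
        label_ids = labels.map(name_to_id).to_numpy(np.int64)
        pred_raster = label_ids[layer2.labels]

        cm = raster_confusion(pred_raster, scene.truth, class_names)
        oa = evaluation.overall_accuracy(cm)
        kap = evaluation.kappa(cm)
        valid = scene.truth != NODATA
        n_points = min(config.n_validation, int(valid.sum()))
        vcm, error_points = evaluation.validation_points(
            pred_raster, scene.truth, n_points, seed, class_names, valid_mask=valid
        )

    corrected_sets = [r.corrected for r in sample_db.values() if r.corrected is not None]
    stage_acc = {}
    for stage in ("initial", "purified", "corrected"):
        accs = {}
        for key, res in sample_db.items():
            sset = getattr(res, stage)
            if sset is not None and len(sset.object_ids):
                accs["|".join(key)] = evaluation.sample_accuracy(
                    sset, scene.truth, layer2, class_names
                )
        stage_acc[stage] = accs
    sar = (
        evaluation.sample_accuracy_report(corrected_sets, scene.truth, layer2, class_names)
        if corrected_sets
        else {}
    )

    report = {
        "config_hash": config.config_hash(),
        "seed": seed,
        "n_layer1_objects": layer1.n_objects,
        "n_layer2_objects": layer2.n_objects,
        "n_vegetation_objects": len(veg_ids),
        "sample_counts": {
            "|".join(k): {
                "candidates": len(v.candidates),
                "initial": len(v.initial) if v.initial else 0,
                "purified": len(v.purified) if v.purified else 0,
                "corrected": len(v.corrected) if v.corrected else 0,
                "error": v.error,
            }
            for k, v in sample_db.items()
        },
        "sample_accuracy_by_stage": stage_acc,
        "sample_accuracy_report": {
            k: v for k, v in sar.items() if k != "per_formation"
        } | ({"per_formation": {"|".join(k): v for k, v in sar["per_formation"].items()}} if sar else {}),
        "overall_accuracy": oa,
        "kappa": kap,
        "user_accuracy": {c: evaluation.user_accuracy(cm, c) for c in class_names if cm.row_totals[name_to_id[c]] > 0},
        "producer_accuracy": {c: evaluation.producer_accuracy(cm, c) for c in class_names if cm.col_totals[name_to_id[c]] > 0},
        "validation": {
            "n_points": n_points,
            "n_errors": len(error_points),
            "overall_accuracy": evaluation.overall_accuracy(vcm),
        },
        "classifier": {"kind": spec.kind, "params": spec.params,
                       "features": spec.feature_names},
    }
    return PipelineResult(
        config=config,
        scene=scene,
        layer1=layer1,
        layer2=layer2,
        features1=features1,
        features2=features2,
        veg_mask2=veg_mask2,
        belt_raster=belt_raster,
        object_belts=object_belts,
        sample_db=sample_db,
        labels=labels,
        pred_raster=pred_raster,
        report=report,
    )
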