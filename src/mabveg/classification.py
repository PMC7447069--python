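"""Object-based classification: fuzzy non-vegetation masking, class
inheritance between segmentation layers, feature selection, and RF/KNN
training and scene-wide labelling.

Layer 1 (coarse) separates vegetation from non-vegetation with fuzzy
membership rules (NDVI*100, brightness, DSM combined with fuzzy AND);
Layer 2 (fine) inherits that attribute and its vegetation objects are then
classified into formations.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import f1_score
from sklearn.model_selection import StratifiedKFold
from sklearn.neighbors import KNeighborsClassifier

from .segmentation import ALL_FEATURES, ObjectMap

__all__ = [
    "MembershipRule",
    "default_layer1_rules",
    "membership",
    "classify_layer1",
    "inherit_classes",
    "rank_features",
    "f1",
    "tune_classifier",
    "ClassifierSpec",
    "make_classifier",
    "draw_training_samples",
    "train_classify",
    "DEFAULT_RF_GRID",
    "DEFAULT_KNN_GRID",
]

VEGETATION = "vegetation"
NON_VEGETATION = "non-vegetation"


@dataclass(frozen=True)
class MembershipRule:
    """Fuzzy membership: 1 at ``full_value``'s side, 0 past ``zero_value``.

    Between the two endpoints the membership follows a cosine ramp (a smooth
    Z/S shape); ``full_value < zero_value`` gives a decreasing rule,
    ``full_value > zero_value`` an increasing one.
    """

    variable: str  # e.g. ndvi100, brightness, dsm
    full_value: float
    zero_value: float

    def __post_init__(self) -> None:
        if self.full_value == self.zero_value:
            raise ValueError("full_value and zero_value must differ")


def membership(value: float | np.ndarray, rule: MembershipRule) -> np.ndarray:
    """Evaluate a fuzzy membership rule; vectorized over ``value``."""
    x = np.asarray(value, float)
    a, b = rule.full_value, rule.zero_value
    t = np.clip((x - a) / (b - a), 0.0, 1.0)  # 0 at full side, 1 at zero side
    return 0.5 * (1.0 + np.cos(np.pi * t))


def default_layer1_rules() -> dict[str, MembershipRule]:
    """Non-vegetation membership rules calibrated to the synthetic scenes.

    The NDVI*100 endpoints (-2, 1) follow the fuzzy non-vegetation rule;
    brightness/DSM endpoints are config defaults: non-vegetation is bright
    and sits at low altitude, which keeps shadows and alpine snow (bright but
    high) out of the mask.
    """
    return {
        "ndvi100": MembershipRule("ndvi100", full_value=-2.0, zero_value=1.0),
        "brightness": MembershipRule("brightness", full_value=105.0, zero_value=80.0),
        "dsm": MembershipRule("dsm", full_value=800.0, zero_value=1500.0),
    }


def classify_layer1(
    features: pd.DataFrame,
    rules: dict[str, MembershipRule] | None = None,
    cutoff: float = 0.5,
) -> pd.Series:
    """Vegetation / non-vegetation labels for Layer-1 objects.

    Combined non-vegetation membership is the minimum (fuzzy AND) of the
    NDVI*100, brightness and DSM memberships; an object is non-vegetation
    iff the combined membership >= cutoff.
    """
    rules = rules or default_layer1_rules()
    for key in ("ndvi100", "brightness", "dsm"):
        if key not in rules:
            raise KeyError(f"missing membership rule for {key!r}")
    for col in ("ndvi", "brightness", "dsm_mean"):
        if col not in features.columns:
            raise KeyError(f"feature table lacks column {col!r}")
    m = np.minimum.reduce(
        [
            membership(features["ndvi"].to_numpy() * 100.0, rules["ndvi100"]),
            membership(features["brightness"].to_numpy(), rules["brightness"]),
            membership(features["dsm_mean"].to_numpy(), rules["dsm"]),
        ]
    )
    labels = np.where(m >= cutoff, NON_VEGETATION, VEGETATION)
    return pd.Series(labels, index=features.index, name="layer1_class")


def inherit_classes(
    layer1_labels: pd.Series, layer1_objects: ObjectMap, layer2_objects: ObjectMap
) -> pd.Series:
    """Each Layer-2 object inherits the majority Layer-1 label over its pixels.

    Exact 50/50 ties go to vegetation so the object still reaches the
    formation classifier.
    """
    if layer1_objects.labels.shape != layer2_objects.labels.shape:
        raise ValueError("object maps must share one grid")
    l1 = layer1_objects.labels.ravel()
    l2 = layer2_objects.labels.ravel()
    is_nonveg = (layer1_labels.loc[l1].to_numpy() == NON_VEGETATION)
    n2 = layer2_objects.n_objects
    nonveg_px = np.bincount(l2, weights=is_nonveg.astype(float), minlength=n2)
    total_px = np.bincount(l2, minlength=n2)
    labels = np.where(nonveg_px > total_px / 2.0, NON_VEGETATION, VEGETATION)
    return pd.Series(labels, index=pd.RangeIndex(n2, name="object_id"),
                     name="layer2_inherited")


def rank_features(
    samples: pd.DataFrame,
    labels: pd.Series | np.ndarray,
    seed: int = 0,
    feature_names: list[str] | None = None,
    top_k: int = 8,
    cum_threshold: float = 0.95,
) -> tuple[list[tuple[str, float]], list[str]]:
    """Impurity importances from a default random forest, plus the selection.

    Returns (ranked (feature, importance) list summing to 1, selected names),
    where the selection keeps the top min(top_k, smallest k reaching the
    cumulative-importance threshold) features.
    """
    names = feature_names or [c for c in ALL_FEATURES if c in samples.columns]
    y = np.asarray(labels)
    if len(np.unique(y)) < 2:
        raise ValueError("need at least 2 classes to rank features")
    x = samples[names].to_numpy(float)
    x = np.nan_to_num(x, nan=0.0)
    rf = RandomForestClassifier(random_state=seed)
    rf.fit(x, y)
    imp = rf.feature_importances_
    total = imp.sum()
    if total > 0:
        imp = imp / total
    order = np.argsort(-imp, kind="stable")
    ranked = [(names[i], float(imp[i])) for i in order]
    cum = np.cumsum([v for _, v in ranked])
    k_cum = int(np.searchsorted(cum, cum_threshold) + 1)
    k = min(top_k, max(1, k_cum))
    return ranked, [name for name, _ in ranked[:k]]


def f1(precision: float, recall: float) -> float:
    """Harmonic mean of precision and recall; 0 when both are 0."""
    if precision + recall == 0:
        return 0.0
    return 2.0 * precision * recall / (precision + recall)


DEFAULT_RF_GRID = [
    {"n_estimators": 20, "max_depth": 19, "min_samples_leaf": 2, "max_features": 8},
    {"n_estimators": 100, "max_depth": None, "min_samples_leaf": 1, "max_features": "sqrt"},
    {"n_estimators": 50, "max_depth": 10, "min_samples_leaf": 2, "max_features": "sqrt"},
]

DEFAULT_KNN_GRID = [
    {"n_neighbors": 9, "weights": "uniform", "p": 2},
    {"n_neighbors": 5, "weights": "uniform", "p": 2},
    {"n_neighbors": 9, "weights": "distance", "p": 2},
]


@dataclass
class ClassifierSpec:
    """A tuned classifier choice: kind, grid, winning parameters, features."""

    kind: str  # rf | knn
    grid: list = field(default_factory=list)
    params: dict = field(default_factory=dict)
    feature_names: list[str] = field(default_factory=list)
    seed: int = 0
    cv_score: float = float("nan")

    def __post_init__(self) -> None:
        if self.kind not in ("rf", "knn"):
            raise ValueError("kind must be 'rf' or 'knn'")


def make_classifier(spec: ClassifierSpec):
    params = dict(spec.params)
    if spec.kind == "rf":
        mf = params.get("max_features")
        if isinstance(mf, int) and spec.feature_names:
            params["max_features"] = min(mf, len(spec.feature_names))
        return RandomForestClassifier(random_state=spec.seed, **params)
    return KNeighborsClassifier(**params)


def tune_classifier(
    kind: str,
    samples: pd.DataFrame,
    labels,
    grid: list[dict] | None = None,
    folds: int = 5,
    seed: int = 0,
    feature_names: list[str] | None = None,
) -> ClassifierSpec:
    """Grid search maximizing cross-validated macro-F1; ties keep grid order."""
    grid = grid if grid is not None else (DEFAULT_RF_GRID if kind == "rf" else DEFAULT_KNN_GRID)
    if not grid:
        raise ValueError("grid must be non-empty")
    if folds < 2:
        raise ValueError("folds must be >= 2")
    names = feature_names or [c for c in ALL_FEATURES if c in samples.columns]
    x = np.nan_to_num(samples[names].to_numpy(float), nan=0.0)
    y = np.asarray(labels)
    _, counts = np.unique(y, return_counts=True)
    if counts.min() < folds:
        raise ValueError(
            f"every class needs >= folds={folds} samples (smallest has {counts.min()})"
        )
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    best_i, best_score = 0, -np.inf
    for i, params in enumerate(grid):
        spec = ClassifierSpec(kind=kind, params=params, feature_names=names, seed=seed)
        scores = []
        for tr, te in skf.split(x, y):
            clf = make_classifier(spec)
            clf.fit(x[tr], y[tr])
            scores.append(f1_score(y[te], clf.predict(x[te]), average="macro"))
        score = float(np.mean(scores))
        if score > best_score:
            best_i, best_score = i, score
    return ClassifierSpec(
        kind=kind, grid=list(grid), params=dict(grid[best_i]),
        feature_names=names, seed=seed, cv_score=best_score,
    )


def draw_training_samples(
    sample_db: dict, target_n: int = 120, seed: int = 0
) -> tuple[list[int], list[str]]:
    """Seeded draw of up to ``target_n`` corrected samples per formation."""
    rng = np.random.default_rng(seed)
    train_ids: list[int] = []
    train_labels: list[str] = []
    for key in sorted(sample_db, key=str):
        res = sample_db[key]
        sset = res.corrected if hasattr(res, "corrected") else res
        if sset is None or not getattr(sset, "object_ids", ()):
            continue
        ids = np.asarray(sset.object_ids)
        if len(ids) > target_n:
            ids = rng.choice(ids, size=target_n, replace=False)
        train_ids.extend(int(i) for i in ids)
        train_labels.extend([sset.formation] * len(ids))
    return train_ids, train_labels


def train_classify(
    spec: ClassifierSpec,
    sample_db: dict,
    features: pd.DataFrame,
    veg_mask: pd.Series,
    fixed_labels: pd.Series | None = None,
    target_n: int = 120,
    seed: int = 0,
) -> pd.Series:
    """Train on up to ``target_n`` corrected samples per formation and label
    every vegetation object; non-vegetation (and any ``fixed_labels``, e.g.
    cultivated objects from the basal belt) pass through unchanged.
    """
    veg_ids = [int(i) for i in veg_mask.index[veg_mask == VEGETATION]]
    if not veg_ids:
        raise ValueError("vegetation mask is empty: nothing to classify")
    train_ids, train_labels = draw_training_samples(sample_db, target_n, seed)
    if not train_ids:
        raise ValueError("sample database is empty")

    names = spec.feature_names or [c for c in ALL_FEATURES if c in features.columns]
    xtr = np.nan_to_num(features.loc[train_ids, names].to_numpy(float), nan=0.0)
    clf = make_classifier(
        ClassifierSpec(spec.kind, spec.grid, spec.params, names, seed=seed)
    )
    clf.fit(xtr, np.asarray(train_labels))

    out = pd.Series(NON_VEGETATION, index=features.index, name="class", dtype=object)
    if fixed_labels is not None:
        out.loc[fixed_labels.index] = fixed_labels
    pred_ids = veg_ids
    if fixed_labels is not None:
        fixed = set(int(i) for i in fixed_labels.index)
        pred_ids = [i for i in veg_ids if i not in fixed]
    if pred_ids:
        xte = np.nan_to_num(features.loc[pred_ids, names].to_numpy(float), nan=0.0)
        out.loc[pred_ids] = clf.predict(xte)
    return out
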