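"""Accuracy assessment: confusion matrices, OA/UA/PA, kappa, sample accuracy.

Orientation convention (fixed, matches the packaged worked-example tables):
**rows are predicted classes, columns are reference classes**, so user
accuracy is row-wise and producer accuracy is column-wise.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "ConfusionMatrix",
    "confusion",
    "overall_accuracy",
    "user_accuracy",
    "producer_accuracy",
    "kappa",
    "sample_accuracy",
    "sample_accuracy_report",
    "majority_truth",
    "validation_points",
    "load_confusion_csv",
    "packaged_confusion",
    "packaged_table3",
    "round_half_up",
]


def round_half_up(value: float, ndigits: int) -> float:
    """Decimal half-up rounding used for report display."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(value)).quantize(q, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class ConfusionMatrix:
    """Square count matrix; rows = predicted, columns = reference."""

    counts: np.ndarray
    classes: tuple[str, ...]

    def __post_init__(self) -> None:
        c = np.asarray(self.counts)
        if c.ndim != 2 or c.shape[0] != c.shape[1]:
            raise ValueError("counts must be square")
        if c.shape[0] != len(self.classes):
            raise ValueError("class list must match matrix size")
        if np.any(c < 0) or not np.issubdtype(c.dtype, np.integer):
            raise ValueError("counts must be non-negative integers")

    @property
    def n(self) -> int:
        return int(self.counts.sum())

    @property
    def row_totals(self) -> np.ndarray:
        return self.counts.sum(axis=1)

    @property
    def col_totals(self) -> np.ndarray:
        return self.counts.sum(axis=0)

    @property
    def p_o(self) -> float:
        return float(np.trace(self.counts) / self.n)

    @property
    def p_e(self) -> float:
        return float((self.row_totals * self.col_totals).sum() / self.n**2)

    def index_of(self, cls: str) -> int:
        try:
            return self.classes.index(cls)
        except ValueError:
            raise KeyError(f"unknown class {cls!r}") from None

    def to_frame(self, marginals: bool = True) -> pd.DataFrame:
        df = pd.DataFrame(self.counts, index=list(self.classes), columns=list(self.classes))
        if marginals:
            df["Total"] = self.row_totals
            df.loc["Total"] = list(self.col_totals) + [self.n]
        return df


def confusion(pred, ref, classes) -> ConfusionMatrix:
    """Count matrix from paired predicted/reference label sequences."""
    pred = list(pred)
    ref = list(ref)
    if len(pred) != len(ref):
        raise ValueError("pred and ref must have equal length")
    if not pred:
        raise ValueError("empty label sequences")
    classes = tuple(classes)
    index = {c: i for i, c in enumerate(classes)}
    counts = np.zeros((len(classes), len(classes)), dtype=np.int64)
    for p, r in zip(pred, ref):
        if p not in index:
            raise ValueError(f"predicted label {p!r} not in class list")
        if r not in index:
            raise ValueError(f"reference label {r!r} not in class list")
        counts[index[p], index[r]] += 1
    return ConfusionMatrix(counts=counts, classes=classes)


def overall_accuracy(m: ConfusionMatrix) -> float:
    """trace / N."""
    if m.n == 0:
        raise ValueError("empty confusion matrix")
    return m.p_o


def user_accuracy(m: ConfusionMatrix, cls: str) -> float:
    """Diagonal / row total (commission); NaN flag on an empty row."""
    i = m.index_of(cls)
    total = m.row_totals[i]
    if total == 0:
        return float("nan")
    return float(m.counts[i, i] / total)


def producer_accuracy(m: ConfusionMatrix, cls: str) -> float:
    """Diagonal / column total (omission); NaN flag on an empty column."""
    i = m.index_of(cls)
    total = m.col_totals[i]
    if total == 0:
        return float("nan")
    return float(m.counts[i, i] / total)


def kappa(m: ConfusionMatrix) -> float:
    """(p_o - p_e) / (1 - p_e); degenerate p_e = 1 gives 1 iff p_o = 1."""
    if m.n == 0:
        raise ValueError("empty confusion matrix")
    p_o, p_e = m.p_o, m.p_e
    if p_e == 1.0:
        return 1.0 if p_o == 1.0 else float("nan")
    return (p_o - p_e) / (1.0 - p_e)


# ---------------------------------------------------------------------------
# sample accuracy
# ---------------------------------------------------------------------------


def majority_truth(objects, truth: np.ndarray) -> np.ndarray:
    """Majority ground-truth class id per object (ties: smaller id)."""
    lab = objects.labels.ravel()
    t = truth.ravel().astype(np.int64)
    n_cls = int(t.max()) + 1
    counts = np.bincount(lab * n_cls + t, minlength=objects.n_objects * n_cls)
    return np.argmax(counts.reshape(objects.n_objects, n_cls), axis=1)


def sample_accuracy(samples, truth: np.ndarray, objects, class_names) -> float:
    """Fraction of sample objects whose majority truth matches the formation."""
    if len(samples.object_ids) == 0:
        raise ValueError("empty sample set")
    maj = majority_truth(objects, truth)
    target = list(class_names).index(samples.formation)
    ids = np.asarray(samples.object_ids)
    return float((maj[ids] == target).mean())


def sample_accuracy_report(
    sample_sets, truth: np.ndarray, objects, class_names
) -> dict:
    """Per-formation accuracies plus slope / west-middle-east / overall means.

    Regions are equal-width vertical thirds of the raster; an object belongs
    to the third containing its centroid column.
    """
    maj = majority_truth(objects, truth)
    lab = objects.labels.ravel()
    cols = np.tile(np.arange(objects.labels.shape[1]), objects.labels.shape[0])
    colsum = np.bincount(lab, weights=cols, minlength=objects.n_objects)
    npx = np.bincount(lab, minlength=objects.n_objects)
    centroid_col = colsum / npx
    width = objects.labels.shape[1]
    region_of = np.minimum((centroid_col / (width / 3)).astype(int), 2)
    region_names = ("west", "middle", "east")

    per_formation = {}
    rows = []
    for sset in sample_sets:
        if len(sset.object_ids) == 0:
            continue
        ids = np.asarray(sset.object_ids)
        target = list(class_names).index(sset.formation)
        correct = maj[ids] == target
        per_formation[(sset.slope, sset.formation)] = float(correct.mean())
        for oid, ok in zip(ids, correct):
            rows.append((sset.slope, region_names[region_of[oid]], bool(ok)))
    df = pd.DataFrame(rows, columns=["slope", "region", "correct"])
    report = {
        "per_formation": per_formation,
        "overall": float(df["correct"].mean()) if len(df) else float("nan"),
        "n_samples": int(len(df)),
        "by_slope": df.groupby("slope")["correct"].mean().to_dict(),
        "by_region": df.groupby("region")["correct"].mean().to_dict(),
        "counts_by_region": df.groupby("region")["correct"].size().to_dict(),
    }
    return report


def validation_points(
    pred_raster: np.ndarray,
    ref_raster: np.ndarray,
    n: int,
    seed: int,
    classes,
    valid_mask: np.ndarray | None = None,
) -> tuple[ConfusionMatrix, list[tuple[int, int]]]:
    """Confusion over n seeded uniform random valid pixels + error coordinates."""
    if pred_raster.shape != ref_raster.shape:
        raise ValueError("rasters are not co-registered")
    if n < 1:
        raise ValueError("n must be >= 1")
    valid = np.ones(pred_raster.shape, bool) if valid_mask is None else valid_mask
    flat_idx = np.flatnonzero(valid.ravel())
    if len(flat_idx) < n:
        raise ValueError(f"only {len(flat_idx)} valid pixels for {n} points")
    rng = np.random.default_rng(seed)
    pick = rng.choice(flat_idx, size=n, replace=False)
    rr, cc = np.unravel_index(pick, pred_raster.shape)
    classes = tuple(classes)
    pred = [classes[i] for i in pred_raster[rr, cc]]
    ref = [classes[i] for i in ref_raster[rr, cc]]
    m = confusion(pred, ref, classes)
    errors = [
        (int(r), int(c)) for r, c, p, q in zip(rr, cc, pred, ref) if p != q
    ]
    return m, errors


# ---------------------------------------------------------------------------
# worked-example table I/O
# ---------------------------------------------------------------------------


def load_confusion_csv(path: str | Path) -> ConfusionMatrix:
    """Read a predicted-by-reference count matrix CSV (first column = predicted)."""
    df = pd.read_csv(path, index_col=0)
    classes = tuple(str(c) for c in df.columns)
    if tuple(str(i) for i in df.index) != classes:
        raise ValueError(f"{path}: row and column class lists differ")
    return ConfusionMatrix(counts=df.to_numpy(np.int64), classes=classes)


def packaged_confusion(which: str) -> ConfusionMatrix:
    """The packaged RF ('rf') or KNN ('knn') worked-example matrix."""
    fname = {"rf": "table4.csv", "knn": "table5.csv"}[which]
    ref = importlib.resources.files("mabveg.data") / fname
    with importlib.resources.as_file(ref) as path:
        return load_confusion_csv(path)


def packaged_table3() -> pd.DataFrame:
    """The packaged clustering-algorithm comparison fixture."""
    ref = importlib.resources.files("mabveg.data") / "table3.csv"
    with importlib.resources.as_file(ref) as path:
        return pd.read_csv(path, index_col=0)
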