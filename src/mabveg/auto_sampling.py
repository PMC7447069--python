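"""Belt-stratified automatic sample selection.

Within each altitudinal belt the candidate objects are filtered (area and
length/width), clustered (k = 3 x nearby formations), the most suitable of
the largest clusters is taken as the initial sample set, outliers are removed
with the 3-sigma (Pauta) rule on object brightness, and the set is then
corrected by iterative 2-way clustering that repeatedly keeps the category
nearer a per-formation prototype until the two categories look alike, the
set is down to the target size, or the iteration cap is hit.

The "compared with the image" judgement of the manual workflow is automated
by explicit prototypes: expected clustering-feature vectors per formation,
derived from the synthetic generator's signatures or supplied by the user.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .mab_model import MabTable, SamplingParams, cluster_count, formations_near
from .scene_synthesis import SpectralSignature
from .segmentation import CLUSTER_FEATURES
from .stratification import BeltRaster

__all__ = [
    "CLUSTER_ALGORITHMS",
    "CandidateFilter",
    "SampleSet",
    "Prototype",
    "SamplingFailure",
    "filter_candidates",
    "standardize",
    "cluster_candidates",
    "select_initial_category",
    "pauta_purify",
    "iterative_correct",
    "prototype_from_signature",
    "sample_belt",
    "build_sample_db",
    "compare_algorithms",
    "mean_row",
]

CLUSTER_ALGORITHMS = (
    "kmeans",
    "spectral",
    "gaussian_mixture",
    "agglomerative",
    "dbscan",
    "meanshift",
)


class SamplingFailure(RuntimeError):
    """Sample selection failed for a formation (too few objects survive)."""


@dataclass(frozen=True)
class CandidateFilter:
    """Fragment filter: drop small or overly elongated objects."""

    min_area: int = 25
    max_length_width: float = 5.0

    def __post_init__(self) -> None:
        if self.min_area < 1:
            raise ValueError("min_area must be >= 1")
        if self.max_length_width < 1:
            raise ValueError("max_length_width must be >= 1")


@dataclass(frozen=True)
class Prototype:
    """Expected clustering-feature values for one formation."""

    formation: str
    values: tuple[float, ...]  # aligned with CLUSTER_FEATURES

    def __post_init__(self) -> None:
        if len(self.values) != len(CLUSTER_FEATURES):
            raise ValueError(f"prototype needs {len(CLUSTER_FEATURES)} values")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("prototype values must be finite")


@dataclass(frozen=True)
class SampleSet:
    """Selected sample objects of one formation on one slope, with provenance."""

    formation: str
    slope: str
    object_ids: tuple[int, ...]
    stage: str  # initial -> purified -> corrected
    brightness: tuple[float, ...]
    audit: tuple = ()

    STAGES = ("initial", "purified", "corrected")

    def __post_init__(self) -> None:
        if self.stage not in self.STAGES:
            raise ValueError(f"unknown stage {self.stage!r}")
        if len(self.object_ids) != len(set(self.object_ids)):
            raise ValueError("object ids must be unique")
        if len(self.brightness) != len(self.object_ids):
            raise ValueError("brightness must align with object_ids")

    def __len__(self) -> int:
        return len(self.object_ids)

    @property
    def mu(self) -> float:
        return float(np.mean(self.brightness)) if self.brightness else float("nan")

    @property
    def sigma(self) -> float:
        return float(np.std(self.brightness)) if self.brightness else float("nan")

    def advance(self, stage: str, keep_ids: tuple[int, ...], brightness, audit=()) -> "SampleSet":
        order = self.STAGES
        if order.index(stage) != order.index(self.stage) + 1:
            raise ValueError(f"illegal stage transition {self.stage} -> {stage}")
        return replace(
            self,
            stage=stage,
            object_ids=tuple(keep_ids),
            brightness=tuple(brightness),
            audit=self.audit + tuple(audit),
        )


def filter_candidates(
    features: pd.DataFrame, belt_members, filt: CandidateFilter
) -> list[int]:
    """Retain belt members with area >= min_area and length/width <= max."""
    members = [int(m) for m in belt_members]
    missing = set(members) - set(features.index)
    if missing:
        raise KeyError(f"belt members missing from feature table: {sorted(missing)[:5]}")
    sub = features.loc[members]
    keep = sub[(sub["area"] >= filt.min_area) & (sub["length_width"] <= filt.max_length_width)]
    if len(keep) == 0 and members:
        warnings.warn("candidate filter removed every object in the belt", stacklevel=2)
    return [int(i) for i in keep.index]


def standardize(matrix: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Column z-score; zero-variance columns keep sd 1 so they map to 0."""
    x = np.asarray(matrix, float)
    mean = x.mean(axis=0)
    sd = x.std(axis=0)
    sd = np.where(sd > 0, sd, 1.0)
    return (x - mean) / sd, mean, sd


def cluster_candidates(
    features: np.ndarray, k: int, algorithm: str = "kmeans", seed: int = 0
) -> np.ndarray:
    """Cluster standardized candidate features; returns one label per row.

    ``k`` is ignored by dbscan/meanshift, which use their own documented
    heuristics (4-NN distance knee; quantile bandwidth estimate).
    """
    x = np.asarray(features, float)
    n = len(x)
    if algorithm not in CLUSTER_ALGORITHMS:
        raise ValueError(f"unknown algorithm {algorithm!r}")
    if algorithm in ("kmeans", "spectral", "gaussian_mixture", "agglomerative"):
        if k < 1:
            raise ValueError("k must be >= 1")
        if k > n:
            raise ValueError(f"k={k} exceeds candidate count {n}")

    if algorithm == "kmeans":
        from sklearn.cluster import KMeans

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # duplicate points give convergence chatter
            return KMeans(n_clusters=k, n_init=10, random_state=seed).fit_predict(x)
    if algorithm == "spectral":
        from sklearn.cluster import SpectralClustering

        if k == 1:
            return np.zeros(n, int)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            return SpectralClustering(
                n_clusters=k,
                random_state=seed,
                assign_labels="discretize",
                affinity="nearest_neighbors",
                n_neighbors=min(10, n),
            ).fit_predict(x)
    if algorithm == "gaussian_mixture":
        from sklearn.mixture import GaussianMixture

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            return GaussianMixture(
                n_components=k, random_state=seed, reg_covar=1e-4
            ).fit_predict(x)
    if algorithm == "agglomerative":
        from sklearn.cluster import AgglomerativeClustering

        return AgglomerativeClustering(n_clusters=k).fit_predict(x)
    if algorithm == "dbscan":
        from sklearn.cluster import DBSCAN
        from sklearn.neighbors import NearestNeighbors

        nn = min(4, n - 1) if n > 1 else 1
        if nn < 1:
            return np.zeros(n, int)
        d, _ = NearestNeighbors(n_neighbors=nn + 1).fit(x).kneighbors(x)
        kth = np.sort(d[:, -1])
        eps = float(kth[int(0.9 * (len(kth) - 1))])  # knee proxy: 90th percentile
        return DBSCAN(eps=max(eps, 1e-6), min_samples=min(5, n)).fit_predict(x)
    # meanshift
    from sklearn.cluster import MeanShift, estimate_bandwidth

    bw = estimate_bandwidth(x, quantile=0.2, random_state=seed)
    return MeanShift(bandwidth=max(float(bw), 1e-6)).fit_predict(x)


def _cluster_ranking(labels: np.ndarray) -> list[tuple[int, int]]:
    """(cluster label, size), size-descending, ties to the smaller label."""
    uniq, counts = np.unique(labels[labels >= 0], return_counts=True)
    order = np.lexsort((uniq, -counts))
    return [(int(uniq[i]), int(counts[i])) for i in order]


def select_initial_category(
    labels: np.ndarray,
    features_std: np.ndarray,
    prototype_std: np.ndarray,
    candidate_ids,
    brightness,
    formation: str,
    slope: str,
    top_m: int = 5,
) -> SampleSet:
    """Among the ``top_m`` largest clusters, keep the one nearest the prototype.

    ``features_std`` and ``prototype_std`` must live in the same z-scored
    space.  The size/distance ranking is recorded in the audit trail.
    """
    ranking = _cluster_ranking(labels)
    if not ranking:
        raise ValueError("clustering produced no clusters")
    candidate_ids = np.asarray(list(candidate_ids))
    brightness = np.asarray(list(brightness), float)
    best_label, best_dist = None, np.inf
    audit_rows = []
    for cl, size in ranking[:top_m]:
        centroid = features_std[labels == cl].mean(axis=0)
        dist = float(np.linalg.norm(centroid - prototype_std))
        audit_rows.append({"cluster": cl, "size": size, "proto_dist": dist})
        if dist < best_dist:
            best_label, best_dist = cl, dist
    keep = labels == best_label
    return SampleSet(
        formation=formation,
        slope=slope,
        object_ids=tuple(int(i) for i in candidate_ids[keep]),
        stage="initial",
        brightness=tuple(float(b) for b in brightness[keep]),
        audit=(("initial_ranking", tuple((r["cluster"], r["size"], r["proto_dist"]) for r in audit_rows)),),
    )


def pauta_purify(samples: SampleSet) -> SampleSet:
    """3-sigma rule on brightness: keep |x_i - mu| <= 3 sigma (pooled mu, sigma).

    sigma = 0 keeps everything; fewer than 2 samples are returned unchanged
    with a warning.
    """
    if samples.stage != "initial":
        raise ValueError("pauta_purify expects an initial-stage sample set")
    x = np.asarray(samples.brightness, float)
    if len(x) < 2:
        warnings.warn("fewer than 2 samples: purification skipped", stacklevel=2)
        return samples.advance("purified", samples.object_ids, samples.brightness,
                               audit=(("pauta", {"skipped": True}),))
    mu = x.mean()
    sigma = x.std()  # population sd
    keep = np.abs(x - mu) <= 3.0 * sigma if sigma > 0 else np.ones(len(x), bool)
    ids = np.asarray(samples.object_ids)[keep]
    return samples.advance(
        "purified",
        tuple(int(i) for i in ids),
        tuple(float(v) for v in x[keep]),
        audit=(("pauta", {"mu": float(mu), "sigma": float(sigma),
                          "removed": int((~keep).sum())}),),
    )


def iterative_correct(
    samples: SampleSet,
    features_std: np.ndarray,
    prototype_std: np.ndarray,
    params: SamplingParams = SamplingParams(),
    seed: int = 0,
) -> SampleSet:
    """Iterative 2-means correction: keep the nearer-to-prototype category.

    Stops when (a) the standardized inter-centroid distance drops below
    ``params.balance_tol`` (the two categories look alike), (b) the kept set
    is down to ``params.target_n``, or (c) ``params.max_iter`` passes.
    ``features_std`` rows align with ``samples.object_ids``.
    """
    if samples.stage != "purified":
        raise ValueError("iterative_correct expects a purified-stage sample set")
    from sklearn.cluster import KMeans

    ids = np.asarray(samples.object_ids)
    bright = np.asarray(samples.brightness, float)
    x = np.asarray(features_std, float)
    if len(x) != len(ids):
        raise ValueError("features_std must align with the sample set")
    log = []
    for it in range(params.max_iter):
        if len(ids) < 2:
            break
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            km = KMeans(n_clusters=2, n_init=10, random_state=seed + it).fit(x)
        c0, c1 = km.cluster_centers_
        dist = float(np.linalg.norm(c0 - c1))
        if dist < params.balance_tol:
            log.append({"iter": it, "centroid_dist": dist, "action": "stop_balanced"})
            break
        d0 = float(np.linalg.norm(c0 - prototype_std))
        d1 = float(np.linalg.norm(c1 - prototype_std))
        keep_label = 0 if d0 <= d1 else 1
        keep = km.labels_ == keep_label
        if keep.sum() < params.min_keep:
            raise SamplingFailure(
                f"{samples.formation} ({samples.slope}): correction left "
                f"{int(keep.sum())} < min_keep={params.min_keep} samples"
            )
        ids, bright, x = ids[keep], bright[keep], x[keep]
        log.append(
            {"iter": it, "centroid_dist": dist, "kept": int(keep.sum()),
             "action": "keep_nearer"}
        )
        if len(ids) <= params.target_n:
            log.append({"iter": it, "action": "stop_target_n", "size": len(ids)})
            break
    return samples.advance(
        "corrected",
        tuple(int(i) for i in ids),
        tuple(float(b) for b in bright),
        audit=(("correction_log", tuple(tuple(sorted(d.items())) for d in log)),),
    )


def prototype_from_signature(sig: SpectralSignature) -> Prototype:
    """Expected clustering-feature vector implied by a spectral signature."""
    m = sig.effective_means()
    blue, green, red, nir = m
    brightness = float(m.mean())
    ndvi = float((nir - red) / (nir + red)) if nir + red > 0 else 0.0
    dvi = float(nir - red)
    rvi = float(nir / red) if red > 0 else 0.0
    max_diff = float((m.max() - m.min()) / brightness) if brightness > 0 else 0.0
    return Prototype(
        formation=sig.formation,
        values=(float(blue), float(green), float(red), float(nir),
                brightness, ndvi, dvi, rvi, max_diff),
    )


@dataclass
class BeltSampleResult:
    """All stages of sample selection for one (slope, formation) belt."""

    formation: str
    slope: str
    candidates: tuple[int, ...]
    initial: SampleSet | None = None
    purified: SampleSet | None = None
    corrected: SampleSet | None = None
    error: str | None = None


def _belt_feature_matrix(features: pd.DataFrame, ids) -> np.ndarray:
    sub = features.loc[list(ids), CLUSTER_FEATURES].astype(float)
    # undefined RVI (red mean 0) enters clustering as 0, flagged upstream
    return np.nan_to_num(sub.to_numpy(), nan=0.0)


def sample_belt(
    features: pd.DataFrame,
    belt_member_ids,
    prototype: Prototype,
    slope: str,
    k: int,
    filt: CandidateFilter = CandidateFilter(),
    params: SamplingParams = SamplingParams(),
    algorithm: str = "kmeans",
    seed: int = 0,
) -> BeltSampleResult:
    """Full per-belt chain: filter -> cluster -> select -> purify -> correct."""
    res = BeltSampleResult(formation=prototype.formation, slope=slope,
                           candidates=())
    cand = filter_candidates(features, belt_member_ids, filt)
    res.candidates = tuple(cand)
    if len(cand) < max(k, params.min_keep):
        res.error = f"only {len(cand)} candidates after filtering (k={k})"
        return res
    mat = _belt_feature_matrix(features, cand)
    x, mean, sd = standardize(mat)
    proto_std = (np.asarray(prototype.values) - mean) / sd
    try:
        labels = cluster_candidates(x, k, algorithm, seed)
        res.initial = select_initial_category(
            labels, x, proto_std, cand,
            features.loc[cand, "brightness"].to_numpy(),
            prototype.formation, slope, top_m=params.top_m,
        )
        res.purified = pauta_purify(res.initial)
        pur_pos = [cand.index(i) for i in res.purified.object_ids]
        res.corrected = iterative_correct(
            res.purified, x[pur_pos], proto_std, params, seed
        )
    except (SamplingFailure, ValueError) as exc:
        res.error = str(exc)
    return res


def build_sample_db(
    features: pd.DataFrame,
    object_belts: dict[int, int],
    belt_raster: BeltRaster,
    table: MabTable,
    prototypes: dict[str, Prototype],
    veg_object_ids=None,
    filt: CandidateFilter = CandidateFilter(),
    params: SamplingParams = SamplingParams(),
    algorithm: str = "kmeans",
    seed: int = 0,
) -> dict[tuple[str, str], BeltSampleResult]:
    """Corrected sample sets for every vegetation formation on every slope.

    ``object_belts`` maps object id -> belt id (from
    :func:`mabveg.stratification.assign_objects`); objects not classified as
    vegetation can be excluded via ``veg_object_ids``.  Formations that fail
    are recorded with their error, and the run continues.
    """
    members_by_belt: dict[int, list[int]] = {}
    for oid, bid in object_belts.items():
        if veg_object_ids is not None and oid not in veg_object_ids:
            continue
        members_by_belt.setdefault(bid, []).append(oid)

    out: dict[tuple[str, str], BeltSampleResult] = {}
    rng = np.random.default_rng(seed)
    for bid, belt in enumerate(belt_raster.belts):
        if belt.formation == table.basal_formation:
            continue
        proto = prototypes.get(belt.formation)
        if proto is None:
            raise KeyError(f"no prototype for formation {belt.formation!r}")
        near = formations_near(
            table, belt.slope, belt.alt_lo, belt.alt_hi, params.near_delta
        )
        k = cluster_count(len(near), params)
        members = sorted(members_by_belt.get(bid, []))
        res = sample_belt(
            features, members, proto, belt.slope, k,
            filt=filt, params=params, algorithm=algorithm,
            seed=int(rng.integers(2**31)),
        )
        if not members:
            res.error = res.error or "belt contains no vegetation objects"
        out[(belt.slope, belt.formation)] = res
    return out


def mean_row(values) -> float:
    """Column mean used by the algorithm-comparison report (NaNs skipped)."""
    arr = np.asarray(list(values), float)
    arr = arr[~np.isnan(arr)]
    if len(arr) == 0:
        return float("nan")
    return float(arr.mean())


def compare_algorithms(
    features: pd.DataFrame,
    object_belts: dict[int, int],
    belt_raster: BeltRaster,
    table: MabTable,
    prototypes: dict[str, Prototype],
    truth_accuracy,  # callable(SampleSet) -> float
    algorithms=CLUSTER_ALGORITHMS,
    seeds=(0,),
    veg_object_ids=None,
    filt: CandidateFilter = CandidateFilter(),
    params: SamplingParams = SamplingParams(),
) -> pd.DataFrame:
    """First-pass sample accuracy per formation per clustering algorithm.

    One column per algorithm, one row per (slope, formation), plus a final
    ``Mean`` row of column means over available cells, averaged over seeds.
    """
    if not seeds:
        raise ValueError("at least one seed required")
    members_by_belt: dict[int, list[int]] = {}
    for oid, bid in object_belts.items():
        if veg_object_ids is not None and oid not in veg_object_ids:
            continue
        members_by_belt.setdefault(bid, []).append(oid)

    rows: dict[tuple[str, str], dict[str, list[float]]] = {}
    for bid, belt in enumerate(belt_raster.belts):
        if belt.formation == table.basal_formation:
            continue
        proto = prototypes[belt.formation]
        near = formations_near(table, belt.slope, belt.alt_lo, belt.alt_hi, params.near_delta)
        k = cluster_count(len(near), params)
        members = sorted(members_by_belt.get(bid, []))
        cand = filter_candidates(features, members, filt) if members else []
        key = (belt.slope, belt.formation)
        rows.setdefault(key, {a: [] for a in algorithms})
        if len(cand) < max(k, 2):
            continue
        mat = _belt_feature_matrix(features, cand)
        x, mean, sd = standardize(mat)
        proto_std = (np.asarray(proto.values) - mean) / sd
        bright = features.loc[cand, "brightness"].to_numpy()
        for alg in algorithms:
            for s in seeds:
                try:
                    labels = cluster_candidates(x, k, alg, s)
                    init = select_initial_category(
                        labels, x, proto_std, cand, bright,
                        belt.formation, belt.slope, top_m=params.top_m,
                    )
                    rows[key][alg].append(truth_accuracy(init))
                except (ValueError, SamplingFailure):
                    pass  # recorded as missing

    index = pd.MultiIndex.from_tuples(sorted(rows), names=["slope", "formation"])
    data = {
        alg: [mean_row(rows[key][alg]) if rows[key][alg] else np.nan for key in sorted(rows)]
        for alg in algorithms
    }
    df = pd.DataFrame(data, index=index)
    df.loc[("", "Mean"), :] = [mean_row(df[alg].dropna()) for alg in algorithms]
    return df
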