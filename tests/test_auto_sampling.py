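import numpy as np
import pandas as pd
import pytest

from mabveg import auto_sampling as asmp
from mabveg import evaluation as ev
from mabveg import stratification as st
from mabveg.auto_sampling import (
    CandidateFilter,
    Prototype,
    SampleSet,
    SamplingFailure,
    build_sample_db,
    cluster_candidates,
    compare_algorithms,
    filter_candidates,
    iterative_correct,
    mean_row,
    pauta_purify,
    prototype_from_signature,
    select_initial_category,
    standardize,
)
from mabveg.mab_model import SamplingParams
from mabveg.segmentation import CLUSTER_FEATURES

N_FEAT = len(CLUSTER_FEATURES)


def make_set(brightness, stage="initial", formation="f", slope="north", ids=None):
    ids = tuple(range(len(brightness))) if ids is None else tuple(ids)
    return SampleSet(
        formation=formation, slope=slope, object_ids=ids, stage=stage,
        brightness=tuple(float(b) for b in brightness),
    )


class TestCandidateFilter:
    def _features(self, rows):
        return pd.DataFrame(rows, columns=["area", "length_width"]).assign(
            brightness=50.0
        )

    def test_area_threshold_excludes_below(self):
        f = self._features([[24, 1.0], [25, 1.0]])
        assert filter_candidates(f, [0, 1], CandidateFilter(min_area=25)) == [1]

    def test_ratio_boundary_retained(self):
        f = self._features([[30, 5.0], [30, 5.01]])
        got = filter_candidates(f, [0, 1], CandidateFilter(max_length_width=5))
        assert got == [0]

    def test_identity_filter(self):
        f = self._features([[1, 1.0], [2, 99.0]])
        got = filter_candidates(f, [0, 1], CandidateFilter(1, np.inf))
        assert got == [0, 1]

    def test_empty_result_warns_not_raises(self):
        f = self._features([[1, 1.0]])
        with pytest.warns(UserWarning):
            got = filter_candidates(f, [0], CandidateFilter(min_area=100))
        assert got == []

    def test_unknown_member_rejected(self):
        f = self._features([[30, 1.0]])
        with pytest.raises(KeyError):
            filter_candidates(f, [0, 7], CandidateFilter())

    def test_invalid_filter(self):
        with pytest.raises(ValueError):
            CandidateFilter(min_area=0)
        with pytest.raises(ValueError):
            CandidateFilter(max_length_width=0.5)


class TestStandardize:
    def test_zscore_columns(self, rng):
        x = rng.normal(5, 3, (200, 4))
        z, mean, sd = standardize(x)
        assert np.allclose(z.mean(axis=0), 0, atol=1e-9)
        assert np.allclose(z.std(axis=0), 1, atol=1e-9)

    def test_constant_column_maps_to_zero(self):
        x = np.column_stack([np.ones(5), np.arange(5.0)])
        z, _, _ = standardize(x)
        assert np.all(z[:, 0] == 0)


class TestClusterCandidates:
    def _blobs(self, rng, n=60, sep=10.0):
        a = rng.normal(0, 1, (n, 6))
        b = rng.normal(sep, 1, (n, 6))
        x = np.vstack([a, b])
        return x, np.repeat([0, 1], n)

    def test_k1_all_equal(self, rng):
        labels = cluster_candidates(rng.normal(0, 1, (20, 3)), 1, "kmeans", 0)
        assert len(set(labels)) == 1

    def test_blobs_match_bruteforce_nearest_centroid(self, rng):
        x, truth = self._blobs(rng)
        labels = cluster_candidates(x, 2, "kmeans", 0)
        # oracle: recompute the implied centroids, then brute-force assign
        c = np.stack([x[labels == v].mean(axis=0) for v in (0, 1)])
        oracle = np.argmin(
            ((x[:, None, :] - c[None, :, :]) ** 2).sum(-1), axis=1
        )
        assert np.array_equal(labels, oracle)
        # and the partition equals blob membership exactly
        assert len(set(zip(labels.tolist(), truth.tolist()))) == 2

    @pytest.mark.parametrize("alg", asmp.CLUSTER_ALGORITHMS)
    def test_every_algorithm_separates_blobs(self, alg, rng):
        x, truth = self._blobs(rng, n=40)
        labels = cluster_candidates(x, 2, alg, 0)
        # each blob must be label-pure; dbscan may flag boundary points noise
        blob_labels = []
        for blob in (0, 1):
            core = labels[truth == blob]
            core = core[core >= 0]
            assert len(core) > 0
            assert len(set(core.tolist())) == 1
            blob_labels.append(core[0])
        assert blob_labels[0] != blob_labels[1]

    def test_same_seed_identical(self, rng):
        x, _ = self._blobs(rng)
        a = cluster_candidates(x, 2, "kmeans", 5)
        b = cluster_candidates(x, 2, "kmeans", 5)
        assert np.array_equal(a, b)

    def test_k_exceeding_candidates_rejected(self, rng):
        with pytest.raises(ValueError):
            cluster_candidates(rng.normal(0, 1, (4, 3)), 5, "kmeans", 0)

    def test_unknown_algorithm_rejected(self, rng):
        with pytest.raises(ValueError):
            cluster_candidates(rng.normal(0, 1, (4, 3)), 2, "xmeans", 0)


class TestSelectInitial:
    def test_prototype_beats_size(self):
        # cluster 0: 50 members far from prototype; cluster 1: 30 members at it
        x = np.vstack([np.full((50, N_FEAT), 5.0), np.zeros((30, N_FEAT))])
        labels = np.repeat([0, 1], [50, 30])
        got = select_initial_category(
            labels, x, np.zeros(N_FEAT), range(80), np.ones(80), "f", "north", top_m=5
        )
        assert set(got.object_ids) == set(range(50, 80))
        assert got.stage == "initial"

    def test_top_m_1_degenerates_to_largest(self):
        x = np.vstack([np.full((50, N_FEAT), 5.0), np.zeros((30, N_FEAT))])
        labels = np.repeat([0, 1], [50, 30])
        got = select_initial_category(
            labels, x, np.zeros(N_FEAT), range(80), np.ones(80), "f", "north", top_m=1
        )
        assert set(got.object_ids) == set(range(50))

    def test_huge_cluster_at_prototype_wins(self):
        x = np.vstack([np.zeros((60, N_FEAT)), np.full((5, N_FEAT), 8.0)])
        labels = np.repeat([0, 1], [60, 5])
        got = select_initial_category(
            labels, x, np.zeros(N_FEAT), range(65), np.ones(65), "f", "north"
        )
        assert len(got) == 60

    def test_audit_records_ranking(self):
        x = np.zeros((10, N_FEAT))
        labels = np.repeat([0, 1], [6, 4])
        got = select_initial_category(
            labels, x, np.zeros(N_FEAT), range(10), np.ones(10), "f", "north"
        )
        key, ranking = got.audit[0]
        assert key == "initial_ranking"
        assert [r[1] for r in ranking] == [6, 4]  # sizes, descending


class TestPauta:
    def test_constant_brightness_all_retained(self):
        got = pauta_purify(make_set([10, 10, 10, 10]))
        assert len(got) == 4
        assert got.stage == "purified"

    def test_nine_zeros_and_hundred_all_retained(self):
        # mu = 10, population sigma = 30 exactly; |100-10| = 90 <= 3*30
        got = pauta_purify(make_set([0] * 9 + [100]))
        assert len(got) == 10

    def test_far_outlier_removed(self):
        vals = [10.0] * 30 + [10000.0]
        got = pauta_purify(make_set(vals))
        assert len(got) == 30
        assert 30 not in got.object_ids

    def test_montecarlo_retention_at_three_sigma(self):
        fracs = []
        for seed in range(5):
            x = np.random.default_rng(seed).standard_normal(10_000)
            got = pauta_purify(make_set(x))
            fracs.append(len(got) / 10_000)
        assert abs(np.mean(fracs) - 0.997) < 0.002

    def test_single_sample_warns_unchanged(self):
        with pytest.warns(UserWarning):
            got = pauta_purify(make_set([5.0]))
        assert len(got) == 1
        assert got.stage == "purified"

    def test_wrong_stage_rejected(self):
        with pytest.raises(ValueError):
            pauta_purify(make_set([1, 2], stage="purified"))

    def test_second_pass_removes_no_more_than_first(self, rng):
        for seed in range(20):
            x = np.random.default_rng(seed).standard_normal(500)
            first = pauta_purify(make_set(x))
            removed_first = 500 - len(first)
            again = pauta_purify(make_set(first.brightness, ids=first.object_ids))
            removed_second = len(first) - len(again)
            assert removed_second <= removed_first


class TestIterativeCorrect:
    def test_homogeneous_set_unchanged(self):
        s = make_set([10.0] * 100, stage="purified")
        x = np.zeros((100, N_FEAT))
        got = iterative_correct(s, x, np.zeros(N_FEAT))
        assert got.object_ids == s.object_ids
        assert got.stage == "corrected"
        log = dict(got.audit)["correction_log"]
        assert dict(log[0])["action"] == "stop_balanced"

    def test_contaminants_removed_first_iteration(self):
        x = np.vstack([np.zeros((150, N_FEAT)), np.full((50, N_FEAT), 10.0)])
        s = make_set([10.0] * 200, stage="purified")
        got = iterative_correct(s, x, np.zeros(N_FEAT))
        assert set(got.object_ids) == set(range(150))  # purity 1.0

    def test_never_grows_and_terminates(self, rng):
        x = rng.normal(0, 1, (300, N_FEAT))
        s = make_set(rng.normal(50, 5, 300), stage="purified")
        got = iterative_correct(s, x, np.zeros(N_FEAT), SamplingParams(target_n=20))
        assert len(got) <= 300
        log = dict(got.audit)["correction_log"]
        assert len(log) <= 2 * SamplingParams().max_iter

    def test_min_keep_failure(self):
        x = np.vstack([np.zeros((6, N_FEAT)), np.full((6, N_FEAT), 10.0)])
        s = make_set([1.0] * 12, stage="purified")
        with pytest.raises(SamplingFailure):
            iterative_correct(s, x, np.zeros(N_FEAT), SamplingParams(min_keep=10))

    def test_wrong_stage_rejected(self):
        with pytest.raises(ValueError):
            iterative_correct(make_set([1, 2]), np.zeros((2, N_FEAT)), np.zeros(N_FEAT))

    def test_stage_chain_is_enforced(self):
        s = make_set([1.0, 2.0])
        with pytest.raises(ValueError):
            s.advance("corrected", s.object_ids, s.brightness)  # skips purified


class TestPrototypes:
    def test_from_signature_matches_hand_computation(self, table):
        from mabveg.scene_synthesis import SpectralSignature

        sig = SpectralSignature("x", (40.0, 50.0, 60.0, 120.0))
        p = prototype_from_signature(sig)
        vals = dict(zip(CLUSTER_FEATURES, p.values))
        assert vals["brightness"] == pytest.approx(67.5)
        assert vals["ndvi"] == pytest.approx(1 / 3)
        assert vals["rvi"] == pytest.approx(2.0)
        assert vals["max_diff"] == pytest.approx(80 / 67.5)

    def test_prototype_validation(self):
        with pytest.raises(ValueError):
            Prototype("x", (1.0, 2.0))
        with pytest.raises(ValueError):
            Prototype("x", tuple([np.nan] * N_FEAT))


@pytest.fixture(scope="module")
def scene_db(small_scene, small_segmented, small_stratified, table):
    om, feats = small_segmented
    _, br = small_stratified
    belts_of = st.assign_objects(om, br)
    protos = {
        n: prototype_from_signature(s) for n, s in small_scene.signatures.items()
    }
    db = build_sample_db(
        feats, belts_of, br, table, protos,
        filt=CandidateFilter(min_area=4, max_length_width=25),
        params=SamplingParams(target_n=10, min_keep=3, balance_tol=0.3),
        seed=0,
    )
    return om, feats, br, belts_of, protos, db


class TestBuildSampleDb:
    def test_liaotungensis_only_on_north(self, scene_db):
        *_, db = scene_db
        keys = set(db)
        assert ("north", "Quercus liaotungensis forest") in keys
        assert ("south", "Quercus liaotungensis forest") not in keys
        assert all(k[1] != "Basal zone" for k in keys)
        assert len(keys) == 15  # 8 north + 7 south vegetation formations

    def test_subset_chain(self, scene_db):
        *_, db = scene_db
        checked = 0
        for res in db.values():
            if res.corrected is None:
                continue
            cand = set(res.candidates)
            ini = set(res.initial.object_ids)
            pur = set(res.purified.object_ids)
            cor = set(res.corrected.object_ids)
            assert cor <= pur <= ini <= cand
            checked += 1
        assert checked >= 8

    def test_deterministic(self, small_scene, small_segmented, small_stratified, table):
        om, feats = small_segmented
        _, br = small_stratified
        belts_of = st.assign_objects(om, br)
        protos = {
            n: prototype_from_signature(s) for n, s in small_scene.signatures.items()
        }
        kwargs = dict(
            filt=CandidateFilter(min_area=4, max_length_width=25),
            params=SamplingParams(target_n=10, min_keep=3), seed=42,
        )
        a = build_sample_db(feats, belts_of, br, table, protos, **kwargs)
        b = build_sample_db(feats, belts_of, br, table, protos, **kwargs)
        for key in a:
            ca, cb = a[key].corrected, b[key].corrected
            assert (ca is None) == (cb is None)
            if ca is not None:
                assert ca.object_ids == cb.object_ids

    def test_missing_prototype_rejected(self, scene_db, table):
        om, feats, br, belts_of, protos, _ = scene_db
        with pytest.raises(KeyError):
            build_sample_db(feats, belts_of, br, table, {}, seed=0)


class TestCompareAlgorithms:
    def test_report_shape_and_mean_row(self, scene_db, small_scene, table):
        om, feats, br, belts_of, protos, _ = scene_db
        maj = ev.majority_truth(om, small_scene.truth)
        names = list(small_scene.class_names)

        def acc(sset):
            return float(
                (maj[list(sset.object_ids)] == names.index(sset.formation)).mean()
            )

        algs = ("kmeans", "gaussian_mixture")
        df = compare_algorithms(
            feats, belts_of, br, table, protos, acc, algorithms=algs, seeds=(0,),
            filt=CandidateFilter(min_area=4, max_length_width=25),
        )
        assert list(df.columns) == list(algs)
        assert df.index[-1] == ("", "Mean")
        for alg in algs:
            col = df[alg].iloc[:-1].dropna()
            assert df[alg].iloc[-1] == pytest.approx(mean_row(col))

    def test_requires_a_seed(self, scene_db, table):
        om, feats, br, belts_of, protos, _ = scene_db
        with pytest.raises(ValueError):
            compare_algorithms(feats, belts_of, br, table, protos,
                               lambda s: 1.0, seeds=())


class TestMeanRow:
    def test_printed_kmeans_column(self):
        col = [0.82, 0.86, 0.84, 0.94, 0.79, 0.84, 0.96, 0.88, 0.89]
        assert round(mean_row(col), 2) == 0.87

    def test_nan_skipped(self):
        assert mean_row([1.0, np.nan, 0.0]) == pytest.approx(0.5)
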