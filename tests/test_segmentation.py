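"""Outlier initialisation, EM mixture, region growing and morphology."""

import numpy as np
import pytest

from bbbmri import preprocessing, segmentation, synthetic
from bbbmri.preprocessing import TemplateSet
from bbbmri.types import Tissue


def _tiny_template(shape, mean=0.0, var=1.0):
    voi = np.ones(shape, dtype=bool)
    return TemplateSet(mean={"T1w": np.full(shape, mean)},
                       variance={"T1w": np.full(shape, var)},
                       voi=voi, n_controls=2, modalities=("T1w",))


class TestMahalanobis:
    @pytest.mark.parametrize("z,mean,var,expected", [
        (3.0, 0.0, 1.0, 3.0),     # unit template variance
        (6.0, 0.0, 4.0, 3.0),     # deviation 6 at variance 4
        (1.5, 1.5, 2.0, 0.0),     # patient equals template mean
    ])
    def test_scaled_absolute_deviation(self, z, mean, var, expected):
        shape = (2, 2, 1)
        zvol = preprocessing.ZScoreVolume(values=np.full(shape, z),
                                          voi=np.ones(shape, bool),
                                          mu=0.0, sigma=1.0, trim_fraction=0.0)
        d = segmentation.mahalanobis_distance(zvol, _tiny_template(shape, mean, var), "T1w")
        np.testing.assert_allclose(d, expected)

    def test_grid_mismatch_error(self):
        zvol = preprocessing.ZScoreVolume(values=np.zeros((2, 2, 1)),
                                          voi=np.ones((2, 2, 1), bool),
                                          mu=0.0, sigma=1.0, trim_fraction=0.0)
        with pytest.raises(ValueError, match="grid"):
            segmentation.mahalanobis_distance(zvol, _tiny_template((3, 3, 1)), "T1w")


class TestInitialLesion:
    def test_threshold_union_semantics(self):
        shape = (1, 3, 1)
        voi = np.ones(shape, bool)
        below = {m: np.full(shape, 2.9) for m in "abc"}
        assert segmentation.initial_lesion(below, voi).sum() == 0
        one_at = {"a": np.array([[[3.0]], [[0.0]], [[0.0]]]).reshape(shape),
                  "b": np.zeros(shape), "c": np.zeros(shape)}
        flagged = segmentation.initial_lesion(one_at, voi)
        assert flagged[0, 0, 0] and flagged.sum() == 1
        assert segmentation.initial_lesion({"a": np.zeros(shape)}, voi).sum() == 0


def brute_force_two_partition(values):
    """Minimal within-cluster SSE over all sorted 1-D 2-partitions."""
    v = np.sort(values)
    best, best_cut = np.inf, 1
    for cut in range(1, len(v)):
        lo, hi = v[:cut], v[cut:]
        sse = ((lo - lo.mean()) ** 2).sum() + ((hi - hi.mean()) ** 2).sum()
        if sse < best:
            best, best_cut = sse, cut
    return set(v[:best_cut]), set(v[best_cut:])


class TestDwiSplit:
    def test_perfectly_separated(self):
        mask = np.ones((4, 1, 1), bool)
        dwi = np.array([1.0, 1.0, 9.0, 9.0]).reshape(4, 1, 1)
        labels = segmentation.split_lesion_by_dwi(mask, dwi)
        assert set(labels[dwi == 9.0]) == {Tissue.ABT_HYPER}
        assert set(labels[dwi == 1.0]) == {Tissue.ABT_ISO}

    def test_degenerate_lesion_warns_iso(self):
        mask = np.zeros((3, 3, 1), bool)
        mask[1, 1, 0] = True
        with pytest.warns(UserWarning, match="iso"):
            labels = segmentation.split_lesion_by_dwi(mask, np.ones((3, 3, 1)))
        assert labels[1, 1, 0] == Tissue.ABT_ISO

    @pytest.mark.parametrize("values", [
        [1.0, 2.0, 8.0, 9.0, 10.0],
        [0.0, 0.5, 1.0, 5.0, 5.5, 6.0, 20.0],
        [2.0, 3.0, 4.0, 100.0],
    ])
    def test_matches_brute_force_partition(self, values):
        values = np.array(values)
        mask = np.ones((len(values), 1, 1), bool)
        labels = segmentation.split_lesion_by_dwi(mask, values.reshape(-1, 1, 1))
        lo_set, hi_set = brute_force_two_partition(values)
        got_hi = set(values[labels.ravel() == Tissue.ABT_HYPER])
        assert got_hi == hi_set


class TestPcaReduce:
    def test_perfect_correlation_single_component(self, rng):
        x = rng.normal(size=500)
        X = np.column_stack([x, 2 * x])
        X = (X - X.mean(0)) / X.std(0)
        scores = segmentation.pca_reduce(X)
        assert scores.shape == (500, 1)

    def test_independent_columns_all_kept(self, rng):
        X = rng.normal(size=(2000, 3))
        X = (X - X.mean(0)) / X.std(0)
        assert segmentation.pca_reduce(X).shape == (2000, 3)

    def test_threshold_zero_keeps_all(self, rng):
        X = rng.normal(size=(100, 3))
        assert segmentation.pca_reduce(X, 0.0).shape == (100, 3)

    def test_rank_zero_error(self):
        with pytest.raises(ValueError, match="rank"):
            segmentation.pca_reduce(np.zeros((10, 2)))


class TestEmGmm:
    def test_k1_closed_form(self, rng):
        X = rng.normal(size=(200, 2))
        state = segmentation.em_gmm(X, np.zeros(200, int), K=1, max_iter=2,
                                    covariance_floor=0.0)
        np.testing.assert_allclose(state.means[0], X.mean(axis=0), atol=1e-9)
        np.testing.assert_allclose(state.covariances[0],
                                   np.cov(X, rowvar=False, ddof=0), atol=1e-9)

    def test_separated_clusters_recovered(self, rng):
        a = rng.normal([0, 0], 1.0, size=(400, 2))
        b = rng.normal([8, 8], 1.0, size=(400, 2))
        X = np.vstack([a, b])
        init = np.repeat([0, 1], 400)
        state = segmentation.em_gmm(X, init, K=2)
        means = state.means[np.argsort(state.means[:, 0])]
        np.testing.assert_allclose(means[0], [0, 0], atol=0.1)
        np.testing.assert_allclose(means[1], [8, 8], atol=0.1)

    def test_loglik_monotone_and_posteriors_normalised(self, rng):
        X = rng.normal(size=(300, 2)) + np.repeat([[0], [3]], 150, axis=0)
        state = segmentation.em_gmm(X, (np.arange(300) % 3), K=3)
        ll = np.array(state.log_likelihood)
        assert np.all(np.diff(ll) >= -1e-9 * np.abs(ll[:-1]))
        np.testing.assert_allclose(state.gamma.sum(axis=1), 1.0, atol=1e-12)
        assert state.weights.sum() == pytest.approx(1.0)

    def test_empty_class_error_names_class(self, rng):
        X = rng.normal(size=(50, 2))
        with pytest.raises(ValueError, match="class 1"):
            segmentation.em_gmm(X, np.zeros(50, int), K=3)

    def test_agrees_with_reference_mixture(self, rng):
        """Independent cross-check: same data/K, sklearn's EM converges to the
        same log-likelihood and means on well-separated data."""
        from sklearn.mixture import GaussianMixture

        a = rng.normal([0, 0], 1.0, size=(300, 2))
        b = rng.normal([6, -4], 1.5, size=(300, 2))
        X = np.vstack([a, b])
        init = np.repeat([0, 1], 300)
        state = segmentation.em_gmm(X, init, K=2, tol=1e-9, max_iter=300)
        ref = GaussianMixture(2, covariance_type="full", tol=1e-9, max_iter=300,
                              reg_covar=1e-6, random_state=0, n_init=3).fit(X)
        ours = state.means[np.argsort(state.means[:, 0])]
        theirs = ref.means_[np.argsort(ref.means_[:, 0])]
        np.testing.assert_allclose(ours, theirs, atol=0.05)
        assert state.log_likelihood[-1] / len(X) == pytest.approx(
            ref.score(X), abs=1e-3)


class TestMapLabels:
    def test_examples(self):
        gamma = np.array([[0.1, 0.2, 0.7, 0.0, 0.0],
                          [0.5, 0.5, 0.0, 0.0, 0.0]])
        labels = segmentation.map_labels(gamma)
        assert labels[0] == 2          # maximum posterior
        assert labels[1] == 0          # tie breaks to the lowest class index

    def test_one_hot_identity(self, rng):
        idx = rng.integers(0, 5, size=40)
        gamma = np.eye(5)[idx]
        np.testing.assert_array_equal(segmentation.map_labels(gamma), idx)


def brute_force_region_grow(labels, gamma_vol, voi, margin=0.1, thr=0.5):
    """Exhaustive synchronous iteration over in-slice 8-neighbourhoods."""
    labels = labels.copy()
    nx, ny, nz = labels.shape
    while True:
        grew = []
        abt = np.isin(labels, (4, 5))
        for x in range(nx):
            for y in range(ny):
                for z in range(nz):
                    if labels[x, y, z] not in (1, 2, 3) or not voi[x, y, z]:
                        continue
                    neigh = any(abt[i, j, z]
                                for i in range(max(0, x - 1), min(nx, x + 2))
                                for j in range(max(0, y - 1), min(ny, y + 2))
                                if (i, j) != (x, y))
                    if not neigh:
                        continue
                    g = gamma_vol[x, y, z]
                    if (g.max() - g[3] < margin or g.max() - g[4] < margin
                            or g[3] + g[4] >= thr):
                        grew.append((x, y, z))
        if not grew:
            return labels
        for x, y, z in grew:
            g = gamma_vol[x, y, z]
            labels[x, y, z] = 4 if g[3] >= g[4] else 5


class TestRegionGrow:
    def _seeded(self, shape=(5, 5, 1)):
        labels = np.full(shape, Tissue.GM, dtype=np.int16)
        labels[2, 2, 0] = Tissue.ABT_HYPER
        gamma = np.zeros(shape + (5,))
        gamma[..., 0] = 1.0
        gamma[2, 2, 0] = [0, 0, 0, 1, 0]
        return labels, gamma

    def test_sum_boundary_inclusive(self):
        labels, gamma = self._seeded()
        gamma[2, 3, 0] = [0.5, 0, 0, 0.25, 0.25]   # gamma4+gamma5 == 0.5
        grown = segmentation.region_grow_abt(labels, gamma, np.ones_like(labels, bool))
        assert grown[2, 3, 0] in (Tissue.ABT_HYPER, Tissue.ABT_ISO)

    def test_margin_strictly_less(self):
        labels, gamma = self._seeded()
        gamma[2, 3, 0] = [0.55, 0, 0, 0.45, 0.0]   # gap exactly 0.10: excluded
        grown = segmentation.region_grow_abt(labels, gamma, np.ones_like(labels, bool))
        assert grown[2, 3, 0] == Tissue.GM
        gamma[2, 3, 0] = [0.549, 0, 0, 0.451, 0.0]  # gap 0.098 < 0.1: included
        grown = segmentation.region_grow_abt(labels, gamma, np.ones_like(labels, bool))
        assert grown[2, 3, 0] == Tissue.ABT_HYPER

    def test_matches_exhaustive_oracle(self, rng):
        shape = (7, 7, 2)
        labels = np.full(shape, Tissue.GM, dtype=np.int16)
        labels[3, 3, 0] = Tissue.ABT_HYPER
        labels[1, 5, 1] = Tissue.ABT_ISO
        raw = rng.dirichlet(np.ones(5) * 0.7, size=shape)
        gamma = raw
        voi = np.ones(shape, bool)
        got = segmentation.region_grow_abt(labels.copy(), gamma, voi)
        want = brute_force_region_grow(labels.copy(), gamma, voi)
        np.testing.assert_array_equal(got, want)

    def test_no_cross_slice_growth(self):
        labels, gamma = self._seeded((5, 5, 2))
        gamma[2, 2, 1] = [0.2, 0, 0, 0.8, 0]  # would qualify, but other slice
        grown = segmentation.region_grow_abt(labels, gamma, np.ones_like(labels, bool))
        assert grown[2, 2, 1] == Tissue.GM


class TestMorphRefine:
    def test_small_component_volume_rule(self):
        mask = np.zeros((10, 10, 4), bool)
        mask[1, 1:3, 1] = True            # 2 voxels = 2 mm^3 at unit voxels
        mask[5, 5:8, 1] = True            # 3 voxels = 3 mm^3
        out = segmentation.remove_small_components(mask, (1, 1, 1), 3.0)
        assert not out[1, 1:3, 1].any()
        assert out[5, 5:8, 1].all()

    def test_removal_idempotent(self, rng):
        mask = rng.random((12, 12, 5)) > 0.7
        once = segmentation.remove_small_components(mask, (1, 1, 2.0), 3.0)
        twice = segmentation.remove_small_components(once, (1, 1, 2.0), 3.0)
        np.testing.assert_array_equal(once, twice)

    def test_enclosed_hole_filled_by_area(self):
        # 2x2 mm pixels: a 3-pixel hole (12 mm^2) enclosed by ABT is filled
        mask = np.zeros((9, 9, 1), bool)
        mask[1:8, 1:8, 0] = True
        mask[3, 3:6, 0] = False
        out = segmentation.morph_refine(mask, (2.0, 2.0, 5.0))
        assert out[3, 3:6, 0].all()
        # a 5-pixel hole (20 mm^2) stays open
        mask2 = np.zeros((11, 11, 1), bool)
        mask2[1:10, 1:10, 0] = True
        mask2[4:5, 3:8, 0] = False
        out2 = segmentation.morph_refine(mask2, (2.0, 2.0, 5.0), closing_radius_px=0)
        assert not out2[4, 3:8, 0].any()

    def test_empty_mask_passthrough(self):
        mask = np.zeros((6, 6, 2), bool)
        out = segmentation.morph_refine(mask, (1, 1, 1))
        assert not out.any()


class TestSegmentStudy:
    def test_lesion_dice(self, segmented, patient_bundle):
        _, truth = patient_bundle
        abt, t = segmented.abt_mask, truth.abt_mask
        dice = 2 * np.sum(abt & t) / (abt.sum() + t.sum())
        assert dice >= 0.80

    def test_hyper_subdivision_dominates(self, segmented, patient_bundle):
        _, truth = patient_bundle  # default lesion is DWI-hyperintense
        sub = segmented.abt_subdivision[segmented.abt_mask]
        assert (sub == Tissue.ABT_HYPER).mean() > 0.5

    def test_lesion_free_false_positive_bound(self, control_templates):
        spec = synthetic.PhantomSpec(seed=8, lesion_blobs=[], bbbd_blobs=[])
        study, _ = synthetic.generate_patient_study(spec)
        res = segmentation.segment_study(study, control_templates)
        assert res.abt_mask.sum() / res.voi.sum() <= 0.01

    def test_deterministic(self, patient_bundle, control_templates, segmented):
        study, _ = patient_bundle
        again = segmentation.segment_study(study, control_templates)
        np.testing.assert_array_equal(again.labels, segmented.labels)
        np.testing.assert_array_equal(again.abt_mask, segmented.abt_mask)

    def test_provenance_log_lists_stages(self, segmented):
        stages = [s["stage"] for s in segmented.log["stages"]]
        assert stages == ["zscore", "outliers", "pca", "em",
                          "region_grow", "morphology"]
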