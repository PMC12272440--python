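"""K-means label generation, unlabeled margin, balanced sampling."""

import numpy as np
import pytest
from scipy import ndimage

from dermapa.core_io import TissueMask, VoxelGeometry
from dermapa.labeling import (BACKGROUND, HEALTHY, NONHEALTHY, UNLABELED,
                              LabelMap, SpectralKMeansLabeler, TrainingSet,
                              apply_margin, cluster_pixels, sample_balanced)
from dermapa.phantom import generate_phantom
from dermapa.preprocess import apply_mask, segment_background
from tests.conftest import tiny_spec


@pytest.fixture(scope="module")
def clustered_noiseless():
    spec = tiny_spec(noise_sigma=0.0, additive_floor=0.0, rim_mm=0.0, contrast=5.0)
    pa, us, truth = generate_phantom(spec)
    mask = segment_background(us)
    pa = apply_mask(pa, mask)
    labels = cluster_pixels(pa, mask, seed=0)
    return spec, pa, mask, truth, labels


class TestClustering:
    def test_noiseless_high_contrast_matches_truth_everywhere(self, clustered_noiseless):
        _, _, mask, truth, labels = clustered_noiseless
        pred_tumor = labels.labels == NONHEALTHY
        np.testing.assert_array_equal(pred_tumor, truth.tumor_mask & mask.mask)
        pred_healthy = labels.labels == HEALTHY
        np.testing.assert_array_equal(pred_healthy, mask.mask & ~truth.tumor_mask)

    def test_background_exactly_where_mask_is_false(self, clustered_noiseless):
        _, _, mask, _, labels = clustered_noiseless
        np.testing.assert_array_equal(labels.labels == BACKGROUND, ~mask.mask)

    def test_volume_pooled_clustering_keeps_tumor_free_slices_clean(self):
        # tumor confined to the first slices; the far slice must contain no
        # non-healthy label because clustering pools the whole volume
        spec = tiny_spec(shape=(4, 40, 64), noise_sigma=0.0, additive_floor=0.0,
                         rim_mm=0.0, tumor_center_mm=(0.25, 1.9),
                         tumor_half_axes_mm=(0.6, 0.5, 1.0))
        pa, us, truth = generate_phantom(spec)
        assert not truth.tumor_mask[3].any()
        mask = segment_background(us)
        labels = cluster_pixels(apply_mask(pa, mask), mask, seed=1)
        assert (labels.labels[3] == NONHEALTHY).sum() == 0
        assert (labels.labels[0] == NONHEALTHY).sum() > 0

    def test_cluster_naming_invariant_to_seed(self, clustered_noiseless):
        _, pa, mask, _, labels = clustered_noiseless
        for seed in (1, 2, 3):
            again = cluster_pixels(pa, mask, seed=seed)
            np.testing.assert_array_equal(again.labels, labels.labels)

    def test_higher_intensity_cluster_named_nonhealthy(self):
        rng = np.random.default_rng(0)
        bright = 5.0 + 0.01 * rng.random((50, 10))
        dim = 1.0 + 0.01 * rng.random((200, 10))
        X = np.vstack([bright, dim])
        est = SpectralKMeansLabeler(random_state=0).fit(X)
        assert est.labels_[:50].all() and not est.labels_[50:].any()
        assert est.cluster_centers_[1].sum() > est.cluster_centers_[0].sum()

    def test_identical_spectra_degeneracy_rejected(self):
        with pytest.raises(ValueError, match="identical"):
            SpectralKMeansLabeler().fit(np.ones((100, 5)))


class TestMargin:
    def test_single_pixel_margin_relabels_exactly_80(self):
        # 0.5 mm margin, isotropic 0.1 mm pixels: lattice points at
        # 0 < d <= 5 px number exactly 80
        g = VoxelGeometry(slice_spacing_mm=0.5, axial_mm=0.1, lateral_mm=0.1)
        labels = np.full((1, 21, 21), HEALTHY, dtype=np.int8)
        labels[0, 10, 10] = NONHEALTHY
        out = apply_margin(LabelMap(labels), 0.5, g)
        assert (out.labels == UNLABELED).sum() == 80
        assert (out.labels == NONHEALTHY).sum() == 1

    def test_zero_margin_is_identity(self, clustered_noiseless):
        _, pa, _, _, labels = clustered_noiseless
        out = apply_margin(labels, 0.0, pa.geometry)
        np.testing.assert_array_equal(out.labels, labels.labels)

    def test_margin_larger_than_plane_unlabels_all_healthy(self):
        g = VoxelGeometry(0.5, 0.1, 0.1)
        labels = np.full((1, 10, 10), HEALTHY, dtype=np.int8)
        labels[0, 5, 5] = NONHEALTHY
        out = apply_margin(LabelMap(labels), 100.0, g)
        assert (out.labels == HEALTHY).sum() == 0
        assert (out.labels == NONHEALTHY).sum() == 1

    def test_nonhealthy_never_eroded(self, clustered_noiseless):
        _, pa, _, _, labels = clustered_noiseless
        out = apply_margin(labels, 0.5, pa.geometry)
        np.testing.assert_array_equal(out.labels == NONHEALTHY,
                                      labels.labels == NONHEALTHY)

    def test_post_margin_separation_distance_oracle(self, clustered_noiseless):
        # distance-transform oracle: after the margin no healthy pixel may
        # lie within margin_mm of a non-healthy pixel, in-plane
        _, pa, _, _, labels = clustered_noiseless
        margin = 0.5
        out = apply_margin(labels, margin, pa.geometry)
        g = pa.geometry
        for s in range(out.labels.shape[0]):
            sl = out.labels[s]
            if not (sl == NONHEALTHY).any():
                continue
            d = ndimage.distance_transform_edt(
                sl != NONHEALTHY, sampling=(g.axial_mm, g.lateral_mm))
            assert d[sl == HEALTHY].min() > margin

    def test_depth_only_margin_mode(self):
        g = VoxelGeometry(0.5, 0.1, 0.1)
        labels = np.full((1, 21, 21), HEALTHY, dtype=np.int8)
        labels[0, 10, 10] = NONHEALTHY
        out = apply_margin(LabelMap(labels), 0.5, g, in_plane=False)
        unl = np.argwhere(out.labels == UNLABELED)
        assert len(unl) == 10  # 5 above + 5 below, same column only
        assert (unl[:, 2] == 10).all()


class TestBalancedSampling:
    def test_default_n_is_minority_class_size(self):
        rng = np.random.default_rng(0)
        labels = np.full((1, 100, 104), HEALTHY, dtype=np.int8)
        idx = rng.choice(100 * 104, size=400, replace=False)
        labels.ravel()[idx] = NONHEALTHY
        pa_data = rng.random((1, 100, 104, 5))
        from dermapa.core_io import PAVolume, build_spectral_axis
        pa = PAVolume(pa_data, VoxelGeometry(), build_spectral_axis(680, 700, 5))
        ts = sample_balanced(LabelMap(labels), pa, seed=0)
        assert ts.n_per_class == 400
        assert len(ts.spectra) == 800

    def test_same_seed_identical_provenance(self, clustered_noiseless):
        _, pa, _, _, labels = clustered_noiseless
        a = sample_balanced(labels, pa, n_per_class=50, seed=9)
        b = sample_balanced(labels, pa, n_per_class=50, seed=9)
        np.testing.assert_array_equal(a.provenance, b.provenance)
        c = sample_balanced(labels, pa, n_per_class=50, seed=10)
        assert not np.array_equal(a.provenance, c.provenance)

    def test_provenance_audit_never_samples_unlabeled_or_background(self, clustered_noiseless):
        _, pa, _, _, labels = clustered_noiseless
        margined = apply_margin(labels, 0.5, pa.geometry)
        ts = sample_balanced(margined, pa, n_per_class=100, seed=4)
        flat = margined.labels.ravel()
        sampled_labels = flat[ts.provenance]
        assert set(np.unique(sampled_labels)) <= {HEALTHY, NONHEALTHY}
        # spectra traceable to their pixels
        spectra_flat = pa.data.reshape(-1, pa.data.shape[3])
        np.testing.assert_array_equal(ts.spectra, spectra_flat[ts.provenance])
        # label codes agree with the map
        np.testing.assert_array_equal(ts.labels == 1, sampled_labels == NONHEALTHY)

    def test_oversized_request_rejected_with_counts(self, clustered_noiseless):
        _, pa, _, _, labels = clustered_noiseless
        n_tumor = int((labels.labels == NONHEALTHY).sum())
        with pytest.raises(ValueError, match="class sizes"):
            sample_balanced(labels, pa, n_per_class=n_tumor + 1, seed=0)

    def test_exact_balance_enforced_by_container(self):
        with pytest.raises(ValueError, match="balanced"):
            TrainingSet(spectra=np.zeros((3, 5)), labels=np.array([0, 1, 1]),
                        provenance=np.arange(3), seed=0)

    def test_mean_training_spectra_ordered_at_shortest_wavelength(self, clustered_noiseless):
        _, pa, _, _, labels = clustered_noiseless
        ts = sample_balanced(labels, pa, n_per_class=200, seed=1)
        tumor_mean = ts.spectra[ts.labels == 1].mean(axis=0)
        healthy_mean = ts.spectra[ts.labels == 0].mean(axis=0)
        assert tumor_mean[0] > healthy_mean[0]
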