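import numpy as np
import pytest

from strokeflow.edema import (edema_threshold, fit_background_gaussian,
                              quantify_edema)
from strokeflow.phantom import generate_contralesional_mri

from conftest import make_hemisphere_labels, make_volume


def _hemisphere_volume(values_right, shape=(24, 20, 16), values_left=None,
                       voxel_size_mm=0.5, ventricle_box=None):
    labels = make_hemisphere_labels(shape=shape, voxel_size_mm=voxel_size_mm,
                                    ventricle_box=ventricle_box)
    vals = np.empty(shape)
    right = labels.hemisphere_mask("right")
    vals[right] = np.resize(values_right, int(right.sum()))
    left = labels.hemisphere_mask("left")
    if values_left is None:
        vals[left] = np.resize(values_right, int(left.sum()))
    else:
        vals[left] = np.resize(values_left, int(left.sum()))
    return make_volume(vals, voxel_size_mm=voxel_size_mm, modality="MRI"), labels


class TestGaussianFit:
    def test_recovers_generator_parameters(self):
        rng = np.random.default_rng(0)
        draws = rng.normal(100, 10, size=10 ** 5)
        vol, labels = _hemisphere_volume(draws, shape=(50, 64, 64))
        fit = fit_background_gaussian(vol, labels)
        assert fit.mu == pytest.approx(100, rel=0.01)
        assert fit.sigma == pytest.approx(10, rel=0.01)

    def test_bright_component_does_not_capture_fit(self):
        # ~2.4% bright CSF component must not drag the parenchymal fit
        rng = np.random.default_rng(1)
        n = 10 ** 5
        draws = rng.normal(100, 10, size=n)
        bright = rng.random(n) < 0.024
        draws[bright] = rng.normal(200, 10, size=bright.sum())
        vol, labels = _hemisphere_volume(draws, shape=(50, 64, 64))
        fit = fit_background_gaussian(vol, labels)
        assert fit.mu == pytest.approx(100, rel=0.02)
        assert fit.sigma == pytest.approx(10, rel=0.15)

    def test_constant_hemisphere_rejected(self):
        vol, labels = _hemisphere_volume(np.full(10 ** 4, 50.0))
        with pytest.raises(ValueError, match="degenerate"):
            fit_background_gaussian(vol, labels)

    def test_too_few_voxels_rejected(self):
        vol, labels = _hemisphere_volume(np.random.default_rng(0).normal(size=10 ** 4),
                                         shape=(8, 8, 8))
        with pytest.raises(ValueError, match="finite voxels"):
            fit_background_gaussian(vol, labels)


class TestThreshold:
    def test_formula(self):
        rng = np.random.default_rng(2)
        vol, labels = _hemisphere_volume(rng.normal(100, 10, 10 ** 5),
                                         shape=(50, 64, 64))
        fit = fit_background_gaussian(vol, labels)
        thr = edema_threshold(fit)
        assert thr == pytest.approx(fit.mu + 2 * fit.sigma)
        assert edema_threshold(fit, literal_subtraction=True) == pytest.approx(
            fit.mu - 2 * fit.sigma)

    def test_pure_gaussian_excluded_fraction_is_phi2(self):
        rng = np.random.default_rng(3)
        vol, labels = _hemisphere_volume(rng.normal(100, 10, 2 * 10 ** 5),
                                         shape=(64, 80, 80))
        res = quantify_edema(vol, labels)
        # Phi(2) = 0.97725
        assert res.excluded_fraction_contra == pytest.approx(0.97725, abs=0.004)

    def test_affine_intensity_equivariance(self):
        rng = np.random.default_rng(4)
        base = rng.normal(100, 10, 10 ** 5)
        vol, labels = _hemisphere_volume(base, shape=(50, 64, 64))
        fit = fit_background_gaussian(vol, labels)
        res = quantify_edema(vol, labels, fit=fit)
        vol2, _ = _hemisphere_volume(3.0 * base + 50.0, shape=(50, 64, 64))
        fit2 = fit_background_gaussian(vol2, labels)
        res2 = quantify_edema(vol2, labels, fit=fit2)
        assert fit2.mu == pytest.approx(3 * fit.mu + 50, rel=0.01)
        assert fit2.sigma == pytest.approx(3 * fit.sigma, rel=0.02)
        assert res2.raw_edema_volume_mm3 == pytest.approx(
            res.raw_edema_volume_mm3, rel=0.05)

    def test_raising_threshold_never_increases_raw_volume(self):
        rng = np.random.default_rng(5)
        vol, labels = _hemisphere_volume(rng.normal(100, 10, 10 ** 5),
                                         shape=(50, 64, 64))
        fit = fit_background_gaussian(vol, labels)
        vols = [quantify_edema(vol, labels, fit=fit, k_sd=k).raw_edema_volume_mm3
                for k in (1.0, 1.5, 2.0, 2.5, 3.0)]
        assert vols == sorted(vols, reverse=True)


class TestQuantify:
    def _blob_phantom(self, blob_mm3=40.0, swelling_voxels=0, seed=6):
        """Equal hemispheres, truncated parenchymal noise, one bright blob.

        Truncation at 1.6 SD keeps every parenchymal voxel below the fitted
        mu + 2 sigma threshold, so the blob is the only supra-threshold
        tissue and the corrected volume has a sharp ground truth.
        """
        from scipy import stats
        rng = np.random.default_rng(seed)
        shape, vx = (40, 40, 32), 0.5
        labels = make_hemisphere_labels(shape=shape, voxel_size_mm=vx)
        noise = stats.truncnorm.rvs(-1.6, 1.6, scale=10, size=shape,
                                    random_state=rng)
        vals = 100.0 + noise
        n_blob = int(round(blob_mm3 / vx ** 3))
        left_idx = np.argwhere(labels.hemisphere_mask("left"))
        blob_idx = left_idx[:n_blob]
        vals[tuple(blob_idx.T)] = 200.0
        if swelling_voxels:
            # emulate a swollen ipsilesional hemisphere: drop voxels contra
            right_idx = np.argwhere(labels.hemisphere_mask("right"))
            vals[tuple(right_idx[:swelling_voxels].T)] = np.nan
        return make_volume(vals, voxel_size_mm=vx, modality="MRI"), labels, vx

    def test_designed_blob_recovered(self):
        vol, labels, vx = self._blob_phantom(blob_mm3=40.0)
        res = quantify_edema(vol, labels)
        assert res.ventricle_label_missing
        assert res.ventricle_volume_mm3 == 0.0
        assert res.corrected_infarct_volume_mm3 == pytest.approx(40.0, abs=vx ** 3)

    def test_swelling_excess_subtracted(self):
        n_sw = 80  # 10 mm^3 at 0.5 mm voxels
        vol, labels, vx = self._blob_phantom(blob_mm3=40.0, swelling_voxels=n_sw)
        res = quantify_edema(vol, labels)
        assert res.swelling_excess_mm3 == pytest.approx(n_sw * vx ** 3)
        assert res.corrected_infarct_volume_mm3 == pytest.approx(
            res.raw_edema_volume_mm3 - res.ventricle_volume_mm3 - n_sw * vx ** 3)

    def test_ventricle_subtraction_uses_contralesional_label(self):
        rng = np.random.default_rng(7)
        shape, vx = (40, 40, 32), 0.5
        box = (slice(30, 34), slice(10, 14), slice(10, 14))  # right hemisphere
        labels = make_hemisphere_labels(shape=shape, voxel_size_mm=vx,
                                        ventricle_box=box)
        vals = 100.0 + np.clip(rng.normal(0, 10, shape), -15, 15)
        vals[box] = 200.0
        vol = make_volume(vals, voxel_size_mm=vx, modality="MRI")
        res = quantify_edema(vol, labels)
        assert not res.ventricle_label_missing
        assert res.ventricle_volume_mm3 == pytest.approx(4 ** 3 * vx ** 3)

    def test_lesion_free_null_case(self):
        rng = np.random.default_rng(8)
        shape = (40, 40, 32)
        labels = make_hemisphere_labels(shape=shape, voxel_size_mm=0.5)
        vol = make_volume(100 + rng.normal(0, 10, shape), voxel_size_mm=0.5,
                          modality="MRI")
        res = quantify_edema(vol, labels)
        # corrected volume is at most the 2.3% Gaussian-tail false-positive volume
        ipsi_mm3 = labels.hemisphere_mask("left").sum() * 0.5 ** 3
        assert res.corrected_infarct_volume_mm3 <= 0.03 * ipsi_mm3
        assert not res.clamped


def test_synthetic_hemisphere_generator_mixture():
    vol, labels = generate_contralesional_mri(seed=0, shape=(40, 40, 40))
    vals = vol.values[np.isfinite(vol.values)]
    assert labels.ventricle_mask.mean() == pytest.approx(0.024, abs=0.001)
    assert np.mean(vals > 150) == pytest.approx(0.024, abs=0.005)
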