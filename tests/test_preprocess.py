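"""Resampling, Z-score normalization and fixed-bin-width discretization."""

import numpy as np
import pytest

from otoradiomics.preprocess import discretize, resample_isotropic, znormalize
from otoradiomics.volume import ImageVolume, SegMask


def _ball_mask(shape, spacing, radius_mm):
    ax = [(np.arange(n) - (n - 1) / 2.0) * s for n, s in zip(shape, spacing)]
    x, y, z = np.meshgrid(*ax, indexing="ij")
    return (x**2 + y**2 + z**2 <= radius_mm**2).astype(np.uint8)


def test_resample_identity_when_already_isotropic():
    rng = np.random.default_rng(0)
    data = rng.normal(size=(20, 20, 20))
    img = ImageVolume(data, (0.5, 0.5, 0.5))
    mask = SegMask(_ball_mask((20, 20, 20), (0.5, 0.5, 0.5), 3.0), (0.5, 0.5, 0.5))
    out_img, out_mask = resample_isotropic(img, mask, 0.5)
    assert out_img.spacing == (0.5, 0.5, 0.5)
    np.testing.assert_allclose(out_img.data, data, atol=1e-6)
    np.testing.assert_array_equal(out_mask.data, mask.data)


def test_resample_constant_image_stays_constant():
    img = ImageVolume(np.full((12, 15, 10), 7.0), (1.0, 0.8, 2.0))
    mask = SegMask(_ball_mask((12, 15, 10), (1.0, 0.8, 2.0), 3.0), (1.0, 0.8, 2.0))
    out_img, _ = resample_isotropic(img, mask, 0.5)
    np.testing.assert_allclose(out_img.data, 7.0, atol=1e-6)


def test_resample_ball_preserves_volume():
    """A 5 mm ball sampled at 1.0 mm, resampled to 0.5 mm: the mask volume
    should match the analytic sphere volume within 5%."""
    shape, spacing = (24, 24, 24), (1.0, 1.0, 1.0)
    mask = SegMask(_ball_mask(shape, spacing, 5.0), spacing)
    img = ImageVolume(np.zeros(shape), spacing)
    _, out_mask = resample_isotropic(img, mask, 0.5)
    vol = out_mask.voxel_count * 0.125
    assert vol == pytest.approx(4.0 / 3.0 * np.pi * 125.0, rel=0.05)


def test_resample_empty_result_raises():
    shape, spacing = (20, 20, 20), (0.2, 0.2, 0.2)
    mask = np.zeros(shape, dtype=np.uint8)
    mask[5, 5, 5] = 1  # single 0.2 mm voxel, 1 mm off the coarse grid, vanishes
    with pytest.raises(ValueError, match="ROI lost"):
        resample_isotropic(ImageVolume(np.zeros(shape), spacing), SegMask(mask, spacing), 2.0)


def test_znormalize_definition_and_idempotence():
    rng = np.random.default_rng(1)
    img = ImageVolume(rng.normal(5, 3, size=(10, 10, 10)), (1, 1, 1))
    out = znormalize(img)
    assert out.data.mean() == pytest.approx(0.0, abs=1e-9)
    assert out.data.std() == pytest.approx(1.0, abs=1e-9)
    again = znormalize(out)
    np.testing.assert_allclose(again.data, out.data, atol=1e-12)


def test_znormalize_two_voxel_toy():
    """{10, 20} -> {-1, +1} under the population-SD convention."""
    img = ImageVolume(np.array([10.0, 20.0]).reshape(2, 1, 1), (1, 1, 1))
    out = znormalize(img)
    np.testing.assert_allclose(out.data.ravel(), [-1.0, 1.0])


def test_znormalize_constant_image_raises():
    with pytest.raises(ValueError, match="zero-variance"):
        znormalize(ImageVolume(np.full((4, 4, 4), 3.0), (1, 1, 1)))


@pytest.mark.parametrize(
    "values,expected_labels,expected_ng",
    [
        ([0.0, 0.4, 0.5, 1.2], [1, 1, 2, 3], 3),
        ([-1.0, -0.6, 0.3], [1, 1, 3], 3),
        ([2.0, 2.0, 2.0], [1, 1, 1], 1),
    ],
)
def test_discretize_hand_examples(values, expected_labels, expected_ng):
    data = np.array(values).reshape(-1, 1, 1)
    mask = np.ones(data.shape, dtype=np.uint8)
    disc = discretize(ImageVolume(data, (1, 1, 1)), SegMask(mask, (1, 1, 1)), 0.5)
    assert disc.n_levels == expected_ng
    assert list(disc.labels.ravel()) == expected_labels


def test_discretize_shift_invariance():
    rng = np.random.default_rng(3)
    data = rng.normal(size=(6, 6, 6))
    mask = (rng.random((6, 6, 6)) > 0.4).astype(np.uint8)
    mask.flat[0] = 1
    a = discretize(data, mask, 0.5)
    b = discretize(data + 17.3, mask, 0.5)
    np.testing.assert_array_equal(a.labels, b.labels)
    assert a.n_levels == b.n_levels


def test_discretize_bad_bin_width():
    with pytest.raises(ValueError):
        discretize(np.zeros((2, 2, 2)), np.ones((2, 2, 2)), 0.0)


def test_origin_shift_changes_nothing():
    """Translating the whole grid in world space alters no output values."""
    rng = np.random.default_rng(4)
    data = rng.normal(size=(14, 14, 14))
    mask = _ball_mask((14, 14, 14), (1, 1, 1), 4.0)
    out1 = resample_isotropic(
        ImageVolume(data, (1, 1, 1), (0, 0, 0)), SegMask(mask, (1, 1, 1), (0, 0, 0)), 0.5
    )
    out2 = resample_isotropic(
        ImageVolume(data, (1, 1, 1), (50, -20, 3)), SegMask(mask, (1, 1, 1), (50, -20, 3)), 0.5
    )
    np.testing.assert_allclose(out1[0].data, out2[0].data, atol=1e-9)
    np.testing.assert_array_equal(out1[1].data, out2[1].data)
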