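"""Texture-matrix engine vs brute-force enumeration oracles, plus
hand-computed and degenerate cases."""

import numpy as np
import pytest

from otoradiomics.features import texture as tx
from otoradiomics.preprocess import DiscretizedROI

from _oracles import glcm_pairs, gldm_table, glrlm_runs, glszm_zones, ngtdm_ns
from conftest import make_disc, random_label_grid

N_RANDOM_GRIDS = 120


@pytest.fixture(scope="module")
def random_grids():
    rng = np.random.default_rng(2024)
    return [random_label_grid(rng) for _ in range(N_RANDOM_GRIDS)]


def test_glcm_matches_bruteforce_on_random_grids(random_grids):
    for labels, ng in random_grids:
        disc = make_disc(labels, ng)
        mats = tx.glcm_matrices(disc)
        for k, d in enumerate(tx.DIRECTIONS_13):
            expected = glcm_pairs(labels, d, ng)
            np.testing.assert_allclose(mats[k], expected, atol=1e-12)


def test_glrlm_matches_bruteforce_on_random_grids(random_grids):
    for labels, ng in random_grids:
        disc = make_disc(labels, ng)
        mats = tx.glrlm_matrices(disc)
        for k, d in enumerate(tx.DIRECTIONS_13):
            expected = glrlm_runs(labels, d, ng)
            assert mats[k].shape == expected.shape, (labels.shape, d)
            np.testing.assert_allclose(mats[k], expected)


def test_glszm_matches_bruteforce_on_random_grids(random_grids):
    for labels, ng in random_grids:
        disc = make_disc(labels, ng)
        np.testing.assert_allclose(tx.glszm_matrix(disc), glszm_zones(labels, ng))


def test_gldm_and_ngtdm_match_bruteforce(random_grids):
    for labels, ng in random_grids[:40]:
        disc = make_disc(labels, ng)
        np.testing.assert_allclose(tx.gldm_matrix(disc), gldm_table(labels, ng))
        n, s, nv = tx.ngtdm_table(disc)
        n_o, s_o, nv_o = ngtdm_ns(labels, ng)
        assert nv == nv_o
        np.testing.assert_allclose(n, n_o)
        np.testing.assert_allclose(s, s_o, atol=1e-9)


def test_glrlm_weighted_total_equals_voxel_count(random_grids):
    """Sum_j j * P(i, j) must equal the ROI voxel count for every direction."""
    for labels, ng in random_grids[:30]:
        n_vox = int((labels > 0).sum())
        for mat in tx.glrlm_matrices(make_disc(labels, ng)):
            lengths = np.arange(1, mat.shape[1] + 1)
            assert int((mat * lengths).sum()) == n_vox


def test_glcm_two_band_slab_hand_example():
    """2x2x1 labels [[1,1],[2,2]]: along the in-plane horizontal direction the
    co-occurrences are {(1,1):1, (2,2):1}, giving zero contrast."""
    labels = np.array([[1, 1], [2, 2]]).reshape(2, 2, 1)
    disc = make_disc(labels)
    d = (0, 1, 0)  # within-row neighbor
    k = tx.DIRECTIONS_13.index(d)
    mats = tx.glcm_matrices(disc)
    np.testing.assert_allclose(mats[k], np.array([[0.5, 0.0], [0.0, 0.5]]))
    assert tx._glcm_features_single(mats[k])["contrast"] == 0.0


def test_glcm_checkerboard_contrast_one():
    """4x4x1 checkerboard of labels {1,2}: horizontal neighbors always differ
    by one level, so directional contrast is exactly 1."""
    base = np.indices((4, 4)).sum(axis=0) % 2 + 1
    labels = base.reshape(4, 4, 1)
    disc = make_disc(labels)
    for d in ((1, 0, 0), (0, 1, 0)):
        k = tx.DIRECTIONS_13.index(d)
        p = tx.glcm_matrices(disc)[k]
        assert tx._glcm_features_single(p)["contrast"] == pytest.approx(1.0)


def test_constant_roi_degenerate_values():
    """A flat 3x3x3 ROI: single run of 3 per direction line, a single zone of
    27 voxels, GLCM energy 1 / entropy 0 / contrast 0, NGTDM coarseness at
    its capped degenerate value."""
    disc = make_disc(np.ones((3, 3, 3), dtype=int))
    glcm = tx.glcm_features(disc)
    assert glcm["joint_energy"] == pytest.approx(1.0)
    assert glcm["joint_entropy"] == pytest.approx(0.0, abs=1e-12)
    assert glcm["contrast"] == 0.0

    for mat in tx.glrlm_matrices(disc):
        # every maximal line is one run; runs of length 3 exist along each
        # direction's central lines
        lengths = np.arange(1, mat.shape[1] + 1)
        assert (mat * lengths).sum() == 27

    szm = tx.glszm_matrix(disc)
    assert szm.shape == (1, 27)
    assert szm[0, -1] == 1  # a single zone of size 27

    assert tx.ngtdm_features(disc)["coarseness"] == 1e6


def test_glrlm_all_distinct_line():
    """All-distinct labels along a line: every voxel is its own run."""
    labels = np.arange(1, 6).reshape(5, 1, 1)
    disc = make_disc(labels)
    k = tx.DIRECTIONS_13.index((1, 0, 0))
    mat = tx.glrlm_matrices(disc)[k]
    assert mat.shape == (5, 1)
    np.testing.assert_allclose(mat[:, 0], 1.0)
    feats = tx.glrlm_features(disc)
    assert feats["RLN"] >= 1.0  # 5 runs of length 1 in the x direction


def test_single_voxel_roi_is_finite():
    disc = make_disc(np.pad(np.ones((1, 1, 1), dtype=int), 1))
    for fn in (tx.glcm_features, tx.glrlm_features, tx.glszm_features,
               tx.gldm_features, tx.ngtdm_features):
        vals = fn(disc)
        assert all(np.isfinite(v) for v in vals.values()), fn.__name__
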