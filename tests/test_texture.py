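"""GLCM/GLRLM construction and statistics against brute-force enumeration."""
import numpy as np
import pytest

from glioradiomics.features import (
    DIRECTIONS,
    GLCM_NAMES,
    GLRLM_NAMES,
    compute_texture_matrices,
    glcm_features,
    glcm_features_single,
    glrlm_features,
    glrlm_features_single,
)

from oracles import (
    naive_glcm,
    naive_glcm_features,
    naive_glrlm,
    naive_glrlm_features,
)

N_LEVELS = 4


def random_case(seed, shape=(6, 6), masked=True):
    rng = np.random.default_rng(seed)
    levels = rng.integers(1, N_LEVELS + 1, size=shape)
    if masked and seed % 2:
        mask = rng.random(shape) < 0.8
        mask[shape[0] // 2, shape[1] // 2] = True
    else:
        mask = np.ones(shape, dtype=bool)
    return np.where(mask, levels, 0), mask


@pytest.mark.parametrize("seed", range(100))
def test_glcm_matches_pair_enumeration(seed):
    levels, mask = random_case(seed)
    tm = compute_texture_matrices([levels], [mask], N_LEVELS)
    tm.validate()
    for d, offset in enumerate(DIRECTIONS):
        expected_matrix = naive_glcm([levels], [mask], offset, N_LEVELS)
        assert np.allclose(tm.glcm_by_direction[d], expected_matrix, atol=1e-12)
        got = glcm_features_single(tm.glcm_by_direction[d])
        expected = naive_glcm_features(expected_matrix)
        for name in GLCM_NAMES:
            assert got[name] == pytest.approx(expected[name], abs=1e-10), name


@pytest.mark.parametrize("seed", range(100))
def test_glrlm_matches_run_enumeration(seed):
    levels, mask = random_case(seed)
    tm = compute_texture_matrices([levels], [mask], N_LEVELS)
    for d, offset in enumerate(DIRECTIONS):
        expected_matrix = naive_glrlm([levels], [mask], offset, N_LEVELS,
                                      tm.glrlm_by_direction[d].shape[1])
        assert np.array_equal(tm.glrlm_by_direction[d], expected_matrix)
        got = glrlm_features_single(tm.glrlm_by_direction[d], tm.n_pixels)
        expected = naive_glrlm_features(expected_matrix, tm.n_pixels)
        for name in GLRLM_NAMES:
            assert got[name] == pytest.approx(expected[name], abs=1e-10), name


def test_multislice_pooling_matches_enumeration():
    rng = np.random.default_rng(7)
    slices, masks = [], []
    for _ in range(3):
        levels, mask = rng.integers(1, N_LEVELS + 1, (5, 7)), rng.random((5, 7)) < 0.8
        mask[2, 3] = True
        slices.append(np.where(mask, levels, 0))
        masks.append(mask)
    tm = compute_texture_matrices(slices, masks, N_LEVELS)
    tm.validate()
    for d, offset in enumerate(DIRECTIONS):
        assert np.allclose(
            tm.glcm_by_direction[d], naive_glcm(slices, masks, offset, N_LEVELS),
            atol=1e-12,
        )
        assert np.array_equal(
            tm.glrlm_by_direction[d],
            naive_glrlm(slices, masks, offset, N_LEVELS,
                        tm.glrlm_by_direction[d].shape[1]),
        )


def test_worked_four_by_four_example():
    """2x2 blocks of levels 1/2 over 3/4; 0-degree pairs counted by hand."""
    img = np.array([[1, 1, 2, 2], [1, 1, 2, 2], [3, 3, 4, 4], [3, 3, 4, 4]])
    mask = np.ones((4, 4), dtype=bool)
    tm = compute_texture_matrices([img], [mask], 4)
    horizontal = tm.glcm_by_direction[0]
    # 12 ordered horizontal pairs, symmetrized to 24: (1,1)x2,(2,2)x2,(1,2)x2,
    # (3,3)x2,(4,4)x2,(3,4)x2 -> symmetric counts 4 on diagonals, 2+2 off.
    expected = np.array(
        [[4, 2, 0, 0], [2, 4, 0, 0], [0, 0, 4, 2], [0, 0, 2, 4]], dtype=float
    ) / 24.0
    assert np.allclose(horizontal, expected)
    feats = glcm_features_single(horizontal)
    oracle = naive_glcm_features(expected)
    for name in GLCM_NAMES:
        assert feats[name] == pytest.approx(oracle[name], abs=1e-10)

    runs = tm.glrlm_by_direction[0]
    # each row contributes two runs of length 2 -> every level has 2 runs of 2
    expected_runs = np.zeros((4, 4))
    expected_runs[:, 1] = 2
    assert np.array_equal(runs, expected_runs)


def test_checkerboard_correlation_is_minus_one():
    img = (np.indices((6, 6)).sum(axis=0) % 2) + 1  # strict two-level board
    mask = np.ones((6, 6), dtype=bool)
    tm = compute_texture_matrices([img], [mask], 2)
    feats = glcm_features_single(tm.glcm_by_direction[0])  # 0-degree offset
    assert feats["Correlation"] == pytest.approx(-1.0, abs=1e-12)
    assert feats["Contrast"] == pytest.approx(1.0)


def test_constant_patch_single_cell_glcm():
    img = np.ones((5, 5), dtype=int)
    mask = np.ones((5, 5), dtype=bool)
    tm = compute_texture_matrices([img], [mask], 1)
    feats = glcm_features(tm)
    assert feats["Contrast"] == 0.0
    assert feats["Energy"] == 1.0
    assert feats["Entropy"] == 0.0
    assert feats["Homogeneity1"] == 1.0
    assert feats["Correlation"] == 0.0  # zero-variance convention


def test_rotating_a_slice_preserves_direction_averaged_features():
    rng = np.random.default_rng(3)
    img = rng.integers(1, 5, (7, 7))
    mask = np.ones((7, 7), dtype=bool)
    a = compute_texture_matrices([img], [mask], N_LEVELS)
    b = compute_texture_matrices([np.rot90(img).copy()], [mask], N_LEVELS)
    fa, fb = glcm_features(a), glcm_features(b)
    for name in GLCM_NAMES:
        assert fa[name] == pytest.approx(fb[name], abs=1e-10), name
    ra, rb = glrlm_features(a), glrlm_features(b)
    for name in GLRLM_NAMES:
        assert ra[name] == pytest.approx(rb[name], abs=1e-10), name


def test_constant_row_run_closed_form():
    n = 9
    img = np.ones((1, n), dtype=int)
    mask = np.ones((1, n), dtype=bool)
    tm = compute_texture_matrices([img], [mask], 1)
    feats = glrlm_features_single(tm.glrlm_by_direction[0], tm.n_pixels)
    assert feats["LongRunEmphasis"] == pytest.approx(n ** 2)
    assert feats["RunPercentage"] == pytest.approx(1.0 / n)


def test_alternating_row_all_unit_runs():
    img = np.array([[1, 2] * 5])
    mask = np.ones_like(img, dtype=bool)
    tm = compute_texture_matrices([img], [mask], 2)
    feats = glrlm_features_single(tm.glrlm_by_direction[0], tm.n_pixels)
    assert feats["ShortRunEmphasis"] == pytest.approx(1.0)
    assert feats["RunPercentage"] == pytest.approx(1.0)


def test_mass_conservation_invariant():
    levels, mask = random_case(12)
    tm = compute_texture_matrices([levels], [mask], N_LEVELS)
    lengths = np.arange(1, tm.glrlm_by_direction[0].shape[1] + 1)
    for r in tm.glrlm_by_direction:
        assert int((r * lengths).sum()) == int(mask.sum())
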