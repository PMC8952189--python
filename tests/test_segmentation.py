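"""Intensity mixture, MGRF/ICM labeling and connectivity filtering."""

import itertools

import numpy as np
import pytest

from octadr.segmentation import (
    MgrfParams,
    filter_connectivity,
    fit_intensity_model,
    mgrf_energy,
    segment_mgrf,
    segment_vessels,
)
from octadr.synthetic import generate_phantom, ndr_spec


def test_em_recovers_bimodal_parameters(rng):
    n = 100_000
    x = np.concatenate(
        [rng.normal(0.2, 0.05, n // 2), rng.normal(0.8, 0.05, n // 2)]
    ).reshape(250, -1)
    m = fit_intensity_model(x)
    # component 0 is the vessel (higher-mean) class
    np.testing.assert_allclose(m.means, [0.8, 0.2], atol=0.02)
    np.testing.assert_allclose(m.weights, [0.5, 0.5], atol=0.05)
    assert abs(m.weights.sum() - 1.0) < 1e-9
    diffs = np.diff(m.log_likelihoods)
    assert np.all(diffs >= -1e-9)


def test_em_agrees_with_sklearn_oracle(rng):
    from sklearn.mixture import GaussianMixture

    x = np.concatenate([rng.normal(0.3, 0.06, 4000), rng.normal(0.75, 0.08, 6000)])
    ours = fit_intensity_model(x.reshape(100, 100))
    gm = GaussianMixture(2, random_state=0, n_init=3).fit(x[:, None])
    sk_means = np.sort(gm.means_.ravel())[::-1]
    np.testing.assert_allclose(ours.means, sk_means, atol=0.02)


def test_em_converged_parameters_are_a_fixed_point(rng):
    x = np.concatenate([rng.normal(0.25, 0.05, 5000), rng.normal(0.7, 0.05, 5000)]).reshape(100, 100)
    m = fit_intensity_model(x, tol=1e-9)
    m2 = fit_intensity_model(x, init=(m.means, m.variances, m.weights), max_iters=2)
    assert abs(m2.log_likelihoods[-1] - m2.log_likelihoods[0]) < 1e-6


def test_em_rejects_constant_image():
    with pytest.raises(ValueError):
        fit_intensity_model(np.full((32, 32), 0.5))


def test_gamma_zero_equals_maximum_likelihood(phantom128):
    mix = fit_intensity_model(phantom128.image)
    mask = segment_mgrf(phantom128.image, MgrfParams(gamma=0.0), mixture=mix)
    logd = mix.class_log_density(phantom128.image)
    ml = (logd[0] > logd[1]).astype(np.uint8)  # vessel wins where more likely
    np.testing.assert_array_equal(mask, ml)


def test_icm_energy_monotone(phantom128):
    _, energies = segment_mgrf(phantom128.image, MgrfParams(gamma=1.5), return_energy=True)
    assert len(energies) >= 2
    assert all(energies[i + 1] <= energies[i] + 1e-9 for i in range(len(energies) - 1))


def test_icm_smooths_salt_and_pepper_init(rng):
    """Isolated flipped labels revert to the neighborhood majority."""
    img = generate_phantom(ndr_spec(64, seed=4)).image
    mix = fit_intensity_model(img)
    params = MgrfParams(gamma=2.0, max_icm_iters=1)
    ml = segment_mgrf(img, MgrfParams(gamma=0.0), mixture=mix)
    corrupt = ml.copy()
    flips = rng.random(corrupt.shape) < 0.02
    corrupt[flips] = 1 - corrupt[flips]
    out, energies = segment_mgrf(
        img, params, mixture=mix, init_labels=corrupt, return_energy=True
    )
    assert energies[-1] <= energies[0]
    # strongly isolated pixels (all 8 neighbors disagree) must flip
    inner = np.ones_like(corrupt, dtype=bool)
    inner[0, :] = inner[-1, :] = inner[:, 0] = inner[:, -1] = False
    for i, j in zip(*np.nonzero(flips & inner)):
        nb = corrupt[i - 1 : i + 2, j - 1 : j + 2].sum() - corrupt[i, j]
        if corrupt[i, j] == 1 and nb == 0:
            assert out[i, j] == 0
        if corrupt[i, j] == 0 and nb == 8:
            assert out[i, j] == 1


def _exhaustive_optimum(unary, gamma):
    """Global Potts-energy minimum over all 2^(h*w) labelings."""
    h, w = unary.shape[1:]
    best_e, best_l = np.inf, None
    for bits in itertools.product((0, 1), repeat=h * w):
        lab = np.asarray(bits, dtype=np.int64).reshape(h, w)
        e = mgrf_energy(lab, unary, gamma, 8)
        if e < best_e:
            best_e, best_l = e, lab
    return best_e, best_l


def test_icm_respects_exhaustive_optimum(rng):
    """ICM is a local minimizer: never below the global optimum, and a
    fixed point when started from it."""
    from octadr.segmentation import GaussianMixture1D

    img = np.clip(rng.normal(0.5, 0.25, (4, 4)), 0.01, 0.99)
    img[0, :2] = 0.9  # plant a bright blob
    mix = GaussianMixture1D(
        means=np.array([0.8, 0.3]),
        variances=np.array([0.02, 0.02]),
        weights=np.array([0.5, 0.5]),
        log_likelihoods=np.zeros(1),
    )
    logd = mix.class_log_density(img)
    unary = np.stack([-logd[1], -logd[0]])
    gamma = 1.0
    best_e, best_l = _exhaustive_optimum(unary, gamma)
    _, energies = segment_mgrf(img, MgrfParams(gamma=gamma), mixture=mix, return_energy=True)
    assert energies[-1] >= best_e - 1e-9
    out, e2 = segment_mgrf(
        img, MgrfParams(gamma=gamma), mixture=mix, init_labels=best_l, return_energy=True
    )
    np.testing.assert_allclose(e2[-1], best_e, rtol=1e-12)
    np.testing.assert_array_equal(out, best_l)


def test_connectivity_filter_thresholds_components():
    mask = np.zeros((20, 40), dtype=np.uint8)
    mask[2:4, 2:4] = 1  # 4 px blob... make it 3px
    mask[3, 3] = 0
    mask[10:20, 10:20] = 1  # 100 px blob
    out = filter_connectivity(mask, 20)
    assert out[10:20, 10:20].all()
    assert out[:5, :5].sum() == 0
    assert np.all(out <= mask)  # subset property


def test_connectivity_filter_edge_cases(rng):
    zero = np.zeros((8, 8), dtype=np.uint8)
    np.testing.assert_array_equal(filter_connectivity(zero, 5), zero)
    m = (rng.random((16, 16)) < 0.4).astype(np.uint8)
    np.testing.assert_array_equal(filter_connectivity(m, 1), m)
    with pytest.raises(ValueError):
        filter_connectivity(np.array([[0, 2]]), 1)


def test_segmentation_dice_on_phantom(phantom128):
    mask = segment_vessels(phantom128.image)
    t = phantom128.truth_mask
    dice = 2 * np.sum(mask * t) / (mask.sum() + t.sum())
    assert dice >= 0.85
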