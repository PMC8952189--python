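"""Architecture census, loss, augmentation group and training behaviour."""

import numpy as np
import pytest
from scipy import stats

from octadr.classifier import (
    DIHEDRAL_SIZE,
    ArchitectureSpec,
    TrainConfig,
    apply_dihedral,
    augment,
    build_architecture,
    cross_entropy_loss,
    train_phase,
)


def _weights_by_name(plan, prefix):
    return [li.weights for li in plan if li.name.split(". ")[-1].startswith(prefix)]


def test_census_for_1024_input():
    plan = build_architecture(ArchitectureSpec(input_side=1024))
    assert _weights_by_name(plan, "Conv") == [432, 4608, 18432, 73728]
    concat = next(li for li in plan if "Concat" in li.name)
    assert concat.out_shape == (492032,)
    fc = _weights_by_name(plan, "Full")
    assert fc[0] == 62980096 and fc[1] == 16384
    conv1 = next(li for li in plan if li.name == "1. Conv")
    assert conv1.out_shape == (1022, 1022, 16)


def test_minimal_census():
    plan = build_architecture(
        ArchitectureSpec(input_side=16, in_channels=1, conv_filters=(1,), kernel=1,
                         fc_widths=(), n_classes=1)
    )
    conv = next(li for li in plan if "Conv" in li.name)
    assert conv.weights == 1


def test_flatten_oracle_for_512():
    """Independent shape propagation: four (s-2)//2 steps, squared, x128."""
    s = 512
    for _ in range(4):
        s = (s - 2) // 2
    expected = s * s * 128
    plan = build_architecture(ArchitectureSpec(input_side=512))
    concat = next(li for li in plan if "Concat" in li.name)
    assert concat.out_shape == (expected,) == (115200,)


def test_too_small_input_names_failing_block():
    with pytest.raises(ValueError, match="block"):
        build_architecture(ArchitectureSpec(input_side=32))


def test_two_convs_per_block_variant():
    plan = build_architecture(ArchitectureSpec(input_side=1024, convs_per_block=2))
    assert len(_weights_by_name(plan, "Conv")) == 8


def test_cross_entropy_examples():
    assert cross_entropy_loss(np.eye(2), np.eye(2)) == pytest.approx(0.0, abs=1e-9)
    uniform = np.full((4, 2), 0.5)
    truth = np.eye(2)[[0, 1, 0, 1]]
    assert cross_entropy_loss(truth, uniform) == pytest.approx(np.log(2))
    assert cross_entropy_loss(
        np.array([[1.0, 0.0]]), np.array([[0.8, 0.2]])
    ) == pytest.approx(-np.log(0.8))
    with pytest.raises(ValueError):
        cross_entropy_loss(np.eye(2), np.eye(3))
    with pytest.raises(ValueError):
        cross_entropy_loss(np.array([[0.5, 0.5]]), np.array([[0.5, 0.5]]))


def test_loss_nonnegative_random(rng):
    for _ in range(50):
        p = rng.dirichlet((1, 1), size=6)
        y = np.eye(2)[rng.integers(0, 2, 6)]
        assert cross_entropy_loss(y, p) >= 0.0


def test_rot90_four_times_is_identity(rng):
    a = rng.random((8, 8, 3))
    b = a
    for _ in range(4):
        b = apply_dihedral(b, 1)
    np.testing.assert_array_equal(a, b)


def test_augment_preserves_pixel_multiset_and_label_geometry(rng):
    a = rng.random((10, 10, 3))
    for k in range(8):
        b = apply_dihedral(a, k)
        for c in range(3):
            np.testing.assert_array_equal(
                np.sort(a[..., c].ravel()), np.sort(b[..., c].ravel())
            )


def test_dihedral_closure():
    """Composing any two allowed transforms equals some single transform."""
    probe = np.arange(9.0).reshape(3, 3)
    tables = [apply_dihedral(probe, k) for k in range(8)]
    for i in range(8):
        for j in range(8):
            composed = apply_dihedral(apply_dihedral(probe, i), j)
            assert any(np.array_equal(composed, t) for t in tables)


def test_augment_seeded_and_uniform():
    a = np.arange(16.0).reshape(4, 4)
    np.testing.assert_array_equal(augment(a, 5), augment(a, 5))
    rng = np.random.default_rng(0)
    counts = np.zeros(8)
    probe = np.arange(16.0).reshape(4, 4)
    tables = [apply_dihedral(probe, k) for k in range(8)]
    for _ in range(10_000):
        out = augment(probe, rng)
        counts[next(i for i, t in enumerate(tables) if np.array_equal(out, t))] += 1
    chi2 = ((counts - 1250.0) ** 2 / 1250.0).sum()
    assert chi2 < stats.chi2.ppf(0.99, df=7)


def test_augment_rejects_non_square():
    with pytest.raises(ValueError):
        apply_dihedral(np.zeros((4, 6)), 1)


def _toy_dataset(n=24, side=20, seed=0):
    """Class 1 images are brighter: trivially separable."""
    rng = np.random.default_rng(seed)
    y = np.array(["NDR", "DR"] * (n // 2))
    x = rng.normal(0.3, 0.05, (n, side, side, 3))
    x[y == "DR"] += 0.4
    return np.clip(x, 0, 1), y


def test_training_is_deterministic_and_learns():
    x, y = _toy_dataset()
    spec = ArchitectureSpec(input_side=20, conv_filters=(8, 16), dropout_rate=0.0)
    cfg = TrainConfig(epochs=12, batch_size=8, seed=3, dropout_rate=0.0, augmentation=True)
    t1 = train_phase(x, y, spec, cfg)
    t2 = train_phase(x, y, spec, cfg)
    assert t1.curves == t2.curves
    for k in t1.model.params:
        np.testing.assert_array_equal(t1.model.params[k], t2.model.params[k])
    assert t1.curves["train_acc"][-1] >= 0.9
    assert t1.curves["train_loss"][-1] < t1.curves["train_loss"][0]


def test_prediction_rows_sum_to_one():
    x, y = _toy_dataset(n=8)
    spec = ArchitectureSpec(input_side=20, conv_filters=(8,), dropout_rate=0.2)
    t = train_phase(x, y, spec, TrainConfig(epochs=1, batch_size=4, seed=0))
    p = t.predict_proba(x)
    np.testing.assert_allclose(p.sum(axis=1), 1.0, atol=1e-6)


def test_single_class_manifest_rejected():
    x, _ = _toy_dataset(n=8)
    with pytest.raises(ValueError):
        train_phase(x, np.array(["DR"] * 8),
                    ArchitectureSpec(input_side=20, conv_filters=(8,)), TrainConfig(epochs=1))


def test_shape_mismatch_rejected():
    x, y = _toy_dataset(n=8, side=20)
    with pytest.raises(ValueError):
        train_phase(x, y, ArchitectureSpec(input_side=24, conv_filters=(8,)),
                    TrainConfig(epochs=1))
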