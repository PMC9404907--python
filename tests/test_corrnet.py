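import numpy as np
import pytest

from retireg import (NetworkConfig, build_model, forward_grid, load_checkpoint,
                     save_checkpoint)


def expected_parameter_count(f, depth, k):
    """Analytic count: conv weights+bias plus batch-norm gamma/beta per
    non-final convolution, transposed convs, and the 1x1 two-channel head."""
    total = 0

    def conv(c_in, c_out, ksize=k):
        return ksize * ksize * c_in * c_out + c_out + 2 * c_out  # w + b + bn

    total += conv(2, f) + conv(f, f)
    for lv in range(1, depth + 1):
        c_in, c_out = f * 2 ** (lv - 1), f * 2**lv
        total += conv(c_in, c_out) + conv(c_out, c_out)
    for lv in range(depth, 0, -1):
        c_hi, c_lo = f * 2**lv, f * 2 ** (lv - 1)
        total += 2 * 2 * c_hi * c_lo + c_lo            # transposed conv
        total += conv(2 * c_lo, c_lo) + conv(c_lo, c_lo)
    total += 1 * 1 * f * 2 + 2                          # head, no bn
    return total


def test_forward_output_shape_and_zero_start(rng):
    model = build_model(NetworkConfig(base_filters=8, depth=2, input_size=64), seed=3)
    x = rng.random((1, 64, 64, 2))
    out = model.forward(x, training=False)
    assert out.shape == (1, 64, 64, 2)
    # zero-initialized head: a fresh model starts at the identity transform
    np.testing.assert_array_equal(out, 0.0)


def test_same_seed_same_weights():
    cfg = NetworkConfig(base_filters=4, depth=2, input_size=16)
    a, b = build_model(cfg, seed=11), build_model(cfg, seed=11)
    for la, lb in zip(a.layers, b.layers):
        for key in la.params:
            np.testing.assert_array_equal(la.params[key], lb.params[key])


def test_different_seed_different_weights():
    cfg = NetworkConfig(base_filters=4, depth=2, input_size=16)
    a, b = build_model(cfg, seed=1), build_model(cfg, seed=2)
    assert any(not np.array_equal(la.params[k], lb.params[k])
               for la, lb in zip(a.layers, b.layers) for k in la.params if k == "w")


def test_indivisible_input_size_rejected():
    with pytest.raises(ValueError):
        NetworkConfig(base_filters=4, depth=2, input_size=50)


@pytest.mark.parametrize("f,depth", [(4, 1), (4, 2), (8, 2)])
def test_parameter_count_formula(f, depth):
    size = 16 * 2**depth
    model = build_model(NetworkConfig(base_filters=f, depth=depth, input_size=size), seed=0)
    assert model.parameter_count() == expected_parameter_count(f, depth, 3)


def test_fully_convolutional_shape_consistency(rng):
    """The same weights process any input size divisible by 2^depth."""
    model = build_model(NetworkConfig(base_filters=4, depth=2, input_size=16), seed=5)
    for size in (16, 32):
        out = model.forward(rng.random((1, size, size, 2)), training=False)
        assert out.shape == (1, size, size, 2)


def test_forward_grid_shape_and_mismatch(rng, phantom64):
    from retireg import segment_vessels
    model = build_model(NetworkConfig(base_filters=4, depth=2, input_size=64), seed=0)
    vm = segment_vessels(phantom64.pixels)
    grid = forward_grid(model, vm, vm)
    assert grid.shape == (64, 64, 2)
    with pytest.raises(ValueError):
        forward_grid(model, vm.soft, rng.random((32, 32)))


def test_backprop_matches_finite_differences(rng):
    """Gradient of a scalar loss w.r.t. one input pixel agrees with
    central differences on a 16x16 model."""
    model = build_model(NetworkConfig(base_filters=4, depth=2, input_size=16), seed=9)
    # randomize the head so the output is a non-trivial function of the input
    model.head.params["w"] = rng.normal(0, 0.1, model.head.params["w"].shape)
    x = rng.random((1, 16, 16, 2))
    w = rng.random((1, 16, 16, 2))  # fixed projection -> scalar loss

    def scalar_loss(inp):
        return float((model.forward(inp, training=True) * w).sum())

    model.forward(x, training=True)
    analytic = model.backward(w)
    eps = 1e-6
    for _ in range(6):
        idx = (0, rng.integers(16), rng.integers(16), rng.integers(2))
        xp, xm = x.copy(), x.copy()
        xp[idx] += eps
        xm[idx] -= eps
        fd = (scalar_loss(xp) - scalar_loss(xm)) / (2 * eps)
        assert analytic[idx] == pytest.approx(fd, rel=1e-3, abs=1e-8)


def test_checkpoint_roundtrip_bit_exact(tmp_path, rng):
    model = build_model(NetworkConfig(base_filters=4, depth=2, input_size=16), seed=2)
    model.head.params["w"] = rng.normal(0, 0.1, model.head.params["w"].shape)
    model.training_curve = [0.1, 0.5, 0.9]
    path = tmp_path / "ckpt.npz"
    save_checkpoint(model, str(path))
    loaded = load_checkpoint(str(path))
    assert loaded.config == model.config
    assert loaded.training_curve == model.training_curve
    for la, lb in zip(model.layers, loaded.layers):
        for key in la.params:
            np.testing.assert_array_equal(la.params[key], lb.params[key])
    x = rng.random((1, 16, 16, 2))
    np.testing.assert_array_equal(model.forward(x, training=False),
                                  loaded.forward(x, training=False))
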