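import numpy as np
import pytest

from retireg import SSIMParams, dice, evaluate_all, gain_coefficient, mse, ssim


# --- MSE -------------------------------------------------------------

def test_mse_identical_is_zero(rng):
    img = rng.random((16, 16))
    assert mse(img, img) == 0.0


def test_mse_zeros_vs_ones_is_one():
    assert mse(np.zeros((7, 9)), np.ones((7, 9))) == 1.0


def test_mse_hand_example():
    ref = np.array([[0.0, 0.5], [1.0, 0.0]])
    warp = np.array([[0.0, 0.0], [0.5, 0.0]])
    assert mse(ref, warp) == pytest.approx(0.125)


def test_mse_symmetric_nonnegative(rng):
    a, b = rng.random((12, 12)), rng.random((12, 12))
    assert mse(a, b) == mse(b, a) >= 0.0


# --- SSIM ------------------------------------------------------------

def brute_force_windowed_ssim(a, b, params):
    """Per-window oracle: explicit Gaussian-weighted moments in each fully
    interior window, the SSIM expression per window, then a plain average."""
    rad = (params.window_size - 1) // 2
    x = np.arange(-rad, rad + 1)
    g1 = np.exp(-0.5 * (x / params.sigma) ** 2)
    g1 /= g1.sum()
    kernel = np.outer(g1, g1)
    h, w = a.shape
    vals = []
    for r in range(rad, h - rad):
        for c in range(rad, w - rad):
            wa = a[r - rad:r + rad + 1, c - rad:c + rad + 1]
            wb = b[r - rad:r + rad + 1, c - rad:c + rad + 1]
            mu_a = (kernel * wa).sum()
            mu_b = (kernel * wb).sum()
            var_a = (kernel * wa * wa).sum() - mu_a**2
            var_b = (kernel * wb * wb).sum() - mu_b**2
            cov = (kernel * wa * wb).sum() - mu_a * mu_b
            vals.append((2 * mu_a * mu_b + params.c1) * (2 * cov + params.c2)
                        / ((mu_a**2 + mu_b**2 + params.c1)
                           * (var_a + var_b + params.c2)))
    return float(np.mean(vals))


def test_ssim_self_is_one_both_modes(phantom64):
    img = phantom64.pixels
    assert ssim(img, img) == pytest.approx(1.0, abs=1e-12)
    assert ssim(img, img, SSIMParams(mode="global")) == pytest.approx(1.0, abs=1e-12)


def test_ssim_global_negation_matches_direct_formula(rng):
    img = np.clip(0.5 + 0.3 * rng.standard_normal((32, 32)), 0, 1)
    inv = 1.0 - img
    params = SSIMParams(mode="global")
    mu_r, mu_w = img.mean(), inv.mean()
    cov = ((img - mu_r) * (inv - mu_w)).mean()
    expected = ((2 * mu_r * mu_w + params.c1) * (2 * cov + params.c2)
                / ((mu_r**2 + mu_w**2 + params.c1) * (img.var() + inv.var() + params.c2)))
    got = ssim(img, inv, params)
    assert got == pytest.approx(expected, abs=1e-12)
    assert got < 1.0  # anti-correlated structure scores poorly


def test_ssim_windowed_matches_brute_force_oracle(rng):
    params = SSIMParams()
    for _ in range(3):
        a, b = rng.random((32, 32)), rng.random((32, 32))
        ours = ssim(a, b, params)
        oracle = brute_force_windowed_ssim(a, b, params)
        assert ours == pytest.approx(oracle, abs=1e-8)


def test_ssim_below_one_for_different_images(rng):
    a = rng.random((24, 24))
    b = np.clip(a + 0.2 * rng.standard_normal(a.shape), 0, 1)
    assert ssim(a, b) < 1.0


# --- Dice ------------------------------------------------------------

def test_dice_identical_nonempty_is_one(rng):
    mask = rng.random((16, 16)) < 0.3
    mask[0, 0] = True
    assert dice(mask, mask) == 1.0


def test_dice_disjoint_is_zero():
    a = np.zeros((8, 8), dtype=bool)
    b = np.zeros((8, 8), dtype=bool)
    a[0, 0] = b[5, 5] = True
    assert dice(a, b) == 0.0


def test_dice_hand_example():
    """|A| = 4, |B| = 4, |A ∩ B| = 2 -> 2*2/8 = 0.5."""
    a = np.zeros((4, 4), dtype=bool); a[0] = True                 # |A|=4
    b = np.zeros((4, 4), dtype=bool); b[0, 0] = b[0, 1] = True    # overlap 2
    b[2, 0] = b[2, 1] = True                                      # |B|=4
    assert dice(a, b) == pytest.approx(0.5)


def test_dice_both_empty_is_one():
    empty = np.zeros((6, 6), dtype=bool)
    assert dice(empty, empty) == 1.0


def test_dice_symmetric_and_monotone(rng):
    a = rng.random((16, 16)) < 0.4
    b = rng.random((16, 16)) < 0.4
    assert dice(a, b) == dice(b, a)
    # growing the intersection with |A|,|B| fixed raises Dice
    a2, b2 = a.copy(), b.copy()
    only_a = a2 & ~b2
    only_b = b2 & ~a2
    if only_a.any() and only_b.any():
        ra, ca = np.argwhere(only_a)[0]
        rb, cb = np.argwhere(only_b)[0]
        a2[ra, ca] = False
        a2[rb, cb] = True  # same |A|, one more overlap
        assert dice(a2, b2) > dice(a, b)


# --- Gain coefficient ------------------------------------------------

def _triple(rng):
    ref = rng.random((8, 8)) < 0.5
    mov = rng.random((8, 8)) < 0.5
    if not (ref & mov).any():
        ref[0, 0] = mov[0, 0] = True
    return ref, mov


def test_gc_is_one_when_warp_equals_mov(rng):
    ref, mov = _triple(rng)
    assert gain_coefficient(ref, mov, mov) == 1.0


def test_gc_doubles_with_doubled_overlap():
    ref = np.zeros((8, 8), dtype=bool); ref[0:4, 0] = True
    mov = np.zeros((8, 8), dtype=bool); mov[0:2, 0] = True        # overlap 2
    warp = np.zeros((8, 8), dtype=bool); warp[0:4, 0] = True      # overlap 4
    assert gain_coefficient(ref, mov, warp) == 2.0


def test_gc_empty_warp_is_zero(rng):
    ref, mov = _triple(rng)
    assert gain_coefficient(ref, mov, np.zeros((8, 8), dtype=bool)) == 0.0


def test_gc_empty_baseline_raises():
    ref = np.zeros((8, 8), dtype=bool); ref[0, 0] = True
    mov = np.zeros((8, 8), dtype=bool); mov[7, 7] = True
    with pytest.raises(ZeroDivisionError):
        gain_coefficient(ref, mov, ref)


# --- combined report --------------------------------------------------

def test_evaluate_all_perfect_triple(rng):
    mask = rng.random((32, 32)) < 0.3
    mask[0, 0] = True
    rep = evaluate_all(mask, mask, mask)
    assert rep.mse == 0.0
    assert rep.ssim == pytest.approx(1.0, abs=1e-12)
    assert rep.dice == 1.0
    assert rep.gc == 1.0


def test_evaluate_all_matches_individual_metrics(rng):
    ref = rng.random((32, 32)) < 0.3
    mov = rng.random((32, 32)) < 0.3
    warp = rng.random((32, 32)) < 0.3
    ref[0, 0] = mov[0, 0] = True
    rep = evaluate_all(ref, mov, warp)
    assert rep.mse == mse(ref.astype(float), warp.astype(float))
    assert rep.ssim == ssim(ref.astype(float), warp.astype(float))
    assert rep.dice == dice(ref, warp)
    assert rep.gc == gain_coefficient(ref, mov, warp)
    assert all(np.isfinite(v) for v in rep.as_dict().values())
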