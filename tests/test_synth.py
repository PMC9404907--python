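import numpy as np
import pytest

from retireg import (DeformationSpec, DegradeSpec, PhantomSpec, dice, make_pair,
                     segment_vessels, smooth_deformation, vessel_phantom)
from retireg.stn import bilinear_warp, identity_grid
from retireg.metrics import mse


def test_phantom_deterministic_per_seed():
    spec = PhantomSpec(size=64, seed=5)
    np.testing.assert_array_equal(vessel_phantom(spec).pixels,
                                  vessel_phantom(spec).pixels)


def test_phantom_intensities_in_unit_interval():
    img = vessel_phantom(PhantomSpec(size=64, seed=1))
    assert img.pixels.min() >= 0.0 and img.pixels.max() <= 1.0


def test_phantom_vessel_fraction_reasonable():
    """Dark vessel strokes cover a plausible fraction of the raster."""
    fracs = []
    for seed in range(5):
        img = vessel_phantom(PhantomSpec(size=64, n_trees=2, branch_depth=3,
                                         vessel_width=(1.0, 3.0), seed=seed))
        vm = segment_vessels(img.pixels)
        fracs.append((vm.soft > 0.3).mean())
    assert 0.02 <= np.mean(fracs) <= 0.25


def test_zero_amplitude_deformation_is_zero_field():
    field = smooth_deformation(DeformationSpec(amplitude=0.0, smoothness=5, seed=0), 32, 32)
    np.testing.assert_array_equal(field, 0.0)


def test_deformation_max_magnitude_equals_amplitude():
    for amp in (0.5, 2.0, 6.0):
        field = smooth_deformation(DeformationSpec(amplitude=amp, smoothness=6, seed=3), 48, 48)
        mags = np.hypot(field[..., 0], field[..., 1])
        assert mags.max() == pytest.approx(amp, abs=1e-6)
        assert np.abs(field.mean(axis=(0, 1))).max() < amp  # zero-mean-ish by construction


def test_deformation_correlation_length_grows_with_smoothness():
    """Rank test over three smoothness settings: smoother fields have
    slower-decaying spatial autocorrelation."""
    def lag_correlation(field, lag=4):
        f = field[..., 0] - field[..., 0].mean()
        num = (f[:, :-lag] * f[:, lag:]).mean()
        return num / f.var()

    corrs = [lag_correlation(smooth_deformation(
        DeformationSpec(amplitude=3, smoothness=s, seed=11), 64, 64)) for s in (2, 6, 14)]
    assert corrs[0] < corrs[1] < corrs[2]


def test_make_pair_zero_deformation_identity():
    """No deformation, no degradation, no acquisition grain: the pair
    members are pixel-identical."""
    i_ref, i_mov, grid = make_pair(PhantomSpec(size=64, seed=2),
                                   DeformationSpec(amplitude=0.0, smoothness=4, seed=0),
                                   grain_strength=0.0)
    np.testing.assert_array_equal(i_ref.pixels, i_mov.pixels)
    np.testing.assert_array_equal(grid, 0.0)


def test_make_pair_acquisition_grain_independent():
    """With grain enabled, reference and mover differ even at zero
    deformation (two acquisitions never share sensor noise)."""
    i_ref, i_mov, _ = make_pair(PhantomSpec(size=64, seed=2),
                                DeformationSpec(amplitude=0.0, smoothness=4, seed=0))
    assert np.abs(i_ref.pixels - i_mov.pixels).max() > 0.01


def test_segmentation_overlap_decays_with_amplitude():
    """Dice between segmented reference and mover drops as the true
    deformation grows."""
    dices = []
    for amp in (0.0, 4.0, 8.0):
        i_ref, i_mov, _ = make_pair(
            PhantomSpec(size=64, n_trees=2, branch_depth=3, vessel_width=(1.0, 3.0), seed=4),
            DeformationSpec(amplitude=amp, smoothness=8, seed=9))
        dices.append(dice(segment_vessels(i_ref.pixels), segment_vessels(i_mov.pixels)))
    assert dices[0] > dices[1] > dices[2]


def test_small_warp_approximately_invertible():
    """For small smooth fields, warping back with the negated field
    recovers the original within a small MSE (checked on a band-limited
    image so interpolation error does not mask the field inversion)."""
    from scipy.ndimage import gaussian_filter
    ref = gaussian_filter(vessel_phantom(PhantomSpec(size=64, seed=6)).pixels, 1.5)
    grid = smooth_deformation(DeformationSpec(amplitude=1.0, smoothness=10, seed=12), 64, 64)
    moved = bilinear_warp(ref, identity_grid(64, 64) + grid)
    back = bilinear_warp(moved, identity_grid(64, 64) - grid)
    assert mse(back, ref) < 1e-3


def test_degradations_darken_and_blur():
    spec = PhantomSpec(size=64, seed=8)
    dspec = DeformationSpec(amplitude=0.0, smoothness=4, seed=0)
    _, clean, _ = make_pair(spec, dspec)
    _, degraded, _ = make_pair(spec, dspec, DegradeSpec(blur_sigma=1.0, dim_factor=0.7,
                                                        n_occlusions=1, seed=3))
    assert degraded.pixels.mean() < clean.pixels.mean()
    # blur reduces high-frequency energy
    hf = lambda im: np.abs(np.diff(im, axis=0)).mean()
    assert hf(degraded.pixels) < hf(clean.pixels)
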