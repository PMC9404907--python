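"""Synthetic fundus phantoms, ground-truth deformations and degradations.

Generates everything the registration pipeline needs for training and
testing without any external dataset: dark branching vessel trees on a
bright circular fundus background, smooth random displacement fields of
bounded amplitude, and quality degradations (blur, dimming, smooth
occlusion blobs) emulating poor acquisitions. All generation is
deterministic per seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
from scipy import ndimage

from .images import FundusImage, VesselMap
from .stn import bilinear_warp, identity_grid
from .vesselseg import segment_vessels
from .preprocess import extract_structure_channel

__all__ = ["PhantomSpec", "DeformationSpec", "DegradeSpec", "vessel_phantom",
           "smooth_deformation", "make_pair", "make_dataset", "training_suite"]


@dataclass(frozen=True)
class PhantomSpec:
    """Vessel-tree phantom parameters (size in pixels, counts >= 1).

    ``texture_strength``/``texture_scale`` control the correlated
    background grain (choroidal texture plus sensor noise) present in
    every real fundus photograph; its segmentation speckle is what the
    connected-component refinement stage exists to remove.
    """

    size: int = 512
    n_trees: int = 3
    branch_depth: int = 4
    vessel_width: tuple[float, float] = (1.5, 5.0)
    texture_strength: float = 0.03
    texture_scale: float = 1.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.size < 32:
            raise ValueError("phantom size must be >= 32")
        if self.n_trees < 1 or self.branch_depth < 1:
            raise ValueError("counts must be >= 1")


@dataclass(frozen=True)
class DeformationSpec:
    """Smooth random displacement field: max |d| = amplitude (pixels),
    Gaussian correlation length = smoothness (pixels)."""

    amplitude: float = 4.0
    smoothness: float = 12.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.amplitude < 0:
            raise ValueError("amplitude must be >= 0")
        if self.smoothness <= 0:
            raise ValueError("smoothness must be > 0")


@dataclass(frozen=True)
class DegradeSpec:
    """Low-quality acquisition model: blur, dark lighting, occlusions."""

    blur_sigma: float = 0.0
    dim_factor: float = 1.0
    n_occlusions: int = 0
    occlusion_strength: float = 0.5
    noise_sigma: float = 0.0
    seed: int = 0


def _walk_branch(rng, pos, heading, length, step, curl):
    """Curvy polyline of pixel samples from a random walk."""
    pts = []
    n_steps = max(2, int(length / step))
    for _ in range(n_steps):
        heading += rng.normal(0.0, curl)
        pos = pos + step * np.array([np.sin(heading), np.cos(heading)])
        pts.append((pos.copy(), heading))
    return pts


def vessel_phantom(spec: PhantomSpec) -> FundusImage:
    """Dark branching vessel trees on a bright circular retina disc.

    Trees emanate from a synthetic optic-disc location with recursively
    splitting, curving branches whose width shrinks with depth; strokes
    are rendered with an anti-aliased soft edge via a distance
    transform. Deterministic per ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed)
    s = spec.size
    yy, xx = np.mgrid[0:s, 0:s]
    center = (s - 1) / 2.0
    rad = np.hypot(yy - center, xx - center) / (0.48 * s)
    fundus_mask = rad <= 1.0
    background = np.where(fundus_mask, 0.82 - 0.12 * rad**2, 0.04)
    if spec.texture_strength > 0:
        grain = ndimage.gaussian_filter(rng.normal(size=(s, s)), spec.texture_scale,
                                        mode="reflect")
        grain /= grain.std()
        background = background + spec.texture_strength * grain * fundus_mask

    w_lo, w_hi = spec.vessel_width
    depth0 = spec.branch_depth
    # centerline pixels grouped by stroke width (one distance transform each)
    width_levels = [w_hi * (0.72**d) for d in range(depth0)]
    width_levels = [max(w, w_lo) for w in width_levels]
    centerlines = [np.zeros((s, s), dtype=bool) for _ in width_levels]

    disc = np.array([center + rng.normal(0, 0.05 * s),
                     center + 0.3 * s * rng.choice([-1, 1])])

    def draw(pos, heading, depth):
        if depth >= depth0:
            return
        length = s * (0.28 * 0.8**depth) * rng.uniform(0.7, 1.3)
        pts = _walk_branch(rng, pos, heading, length, step=0.5, curl=0.06)
        mask = centerlines[depth]
        for p, _ in pts:
            r, c = int(round(p[0])), int(round(p[1]))
            if 0 <= r < s and 0 <= c < s:
                mask[r, c] = True
        end_pos, end_heading = pts[-1]
        spread = rng.uniform(0.3, 0.8)
        for sgn in (-1, 1):
            draw(end_pos, end_heading + sgn * spread * rng.uniform(0.6, 1.4), depth + 1)

    for _ in range(spec.n_trees):
        heading = rng.uniform(0, 2 * np.pi)
        draw(disc.copy(), heading, 0)

    vessel = np.zeros((s, s))
    for mask, width in zip(centerlines, width_levels):
        if not mask.any():
            continue
        dist = ndimage.distance_transform_edt(~mask)
        vessel = np.maximum(vessel, np.clip(width / 2 + 0.5 - dist, 0.0, 1.0))
    vessel *= fundus_mask
    pixels = background * (1.0 - 0.6 * vessel)
    return FundusImage(pixels=np.clip(pixels, 0.0, 1.0))


def smooth_deformation(spec: DeformationSpec, height: int, width: int) -> np.ndarray:
    """Zero-mean smooth random displacement field, shape (H, W, 2).

    Two independent white-noise fields are Gaussian-smoothed at the
    requested correlation length and rescaled so the maximum
    displacement magnitude equals ``spec.amplitude`` exactly.
    """
    if spec.amplitude == 0.0:
        return np.zeros((height, width, 2))
    rng = np.random.default_rng(spec.seed)
    field_ = np.stack([
        ndimage.gaussian_filter(rng.normal(size=(height, width)), spec.smoothness,
                                mode="reflect")
        for _ in range(2)
    ], axis=-1)
    field_ -= field_.mean(axis=(0, 1), keepdims=True)
    mag = np.hypot(field_[..., 0], field_[..., 1]).max()
    if mag == 0.0:  # degenerate draw; keep the zero field
        return field_
    return field_ * (spec.amplitude / mag)


def _occlusion_field(rng, shape, n_blobs, strength):
    """Smooth multiplicative shading field with n dark blobs."""
    h, w = shape
    shade = np.ones(shape)
    for _ in range(n_blobs):
        cy, cx = rng.uniform(0.2 * h, 0.8 * h), rng.uniform(0.2 * w, 0.8 * w)
        sig = rng.uniform(0.06, 0.14) * min(h, w)
        yy, xx = np.mgrid[0:h, 0:w]
        blob = np.exp(-((yy - cy) ** 2 + (xx - cx) ** 2) / (2 * sig**2))
        shade *= 1.0 - strength * blob
    return shade


def _degrade(pixels: np.ndarray, spec: DegradeSpec) -> np.ndarray:
    rng = np.random.default_rng(spec.seed)
    out = pixels
    if spec.blur_sigma > 0:
        out = ndimage.gaussian_filter(out, spec.blur_sigma, mode="reflect")
    if spec.n_occlusions > 0:
        out = out * _occlusion_field(rng, out.shape, spec.n_occlusions,
                                     spec.occlusion_strength)
    if spec.dim_factor != 1.0:
        out = out * spec.dim_factor
    if spec.noise_sigma > 0:
        out = out + rng.normal(0.0, spec.noise_sigma, size=out.shape)
    return np.clip(out, 0.0, 1.0)


def _acquisition_grain(shape, scale, strength, seed):
    g = ndimage.gaussian_filter(np.random.default_rng(seed).normal(size=shape),
                                scale, mode="reflect")
    return strength * g / g.std()


def make_pair(phantom_spec: PhantomSpec, deform_spec: DeformationSpec,
              degrade: DegradeSpec | None = None,
              grain_strength: float = 0.04, grain_scale: float = 1.5):
    """Build a registration test pair with known ground truth.

    The reference is a phantom; the moving image is the phantom resampled
    through the true displacement field (``I_mov(p) = I_ref(p + d(p))``)
    and then optionally degraded. Each image additionally receives its
    own independent correlated sensor grain (two separate acquisitions
    of the same anatomy never share their noise), controlled by
    ``grain_strength``. Returns ``(i_ref, i_mov, true_grid)`` where
    ``true_grid`` is the (H, W, 2) displacement used.
    """
    scene = vessel_phantom(phantom_spec)
    s = phantom_spec.size
    true_grid = smooth_deformation(deform_spec, s, s)
    moved = bilinear_warp(scene.pixels, identity_grid(s, s) + true_grid)
    ref_px, mov_px = scene.pixels, moved
    if grain_strength > 0:
        base = phantom_spec.seed * 2 + deform_spec.seed * 3
        ref_px = ref_px + _acquisition_grain((s, s), grain_scale, grain_strength,
                                             (base + 1) % 2**31)
        mov_px = mov_px + _acquisition_grain((s, s), grain_scale, grain_strength,
                                             (base + 2) % 2**31)
    mov_px = np.clip(mov_px, 0.0, 1.0)
    if degrade is not None:
        mov_px = _degrade(mov_px, degrade)
    return (FundusImage(pixels=np.clip(ref_px, 0.0, 1.0)),
            FundusImage(pixels=mov_px), true_grid)


#: Desk-scale study suite: seeds and specs for the reproducible training set.
#: Phantom density is matched to real fundus vasculature (vessels cover
#: well under the segmentation's kept fraction, so the tree segments as a
#: few large connected components).
SUITE_SIZE = 64
SUITE_AMPLITUDE = 4.0
SUITE_SMOOTHNESS = 8.0
SUITE_N_TREES = 2
SUITE_BRANCH_DEPTH = 3
SUITE_VESSEL_WIDTH = (2.0, 4.0)


def make_dataset(n_pairs: int, size: int = SUITE_SIZE, amplitude: float = SUITE_AMPLITUDE,
                 smoothness: float = SUITE_SMOOTHNESS, seed: int = 0,
                 degrade: bool = True, n_trees: int = SUITE_N_TREES,
                 branch_depth: int = SUITE_BRANCH_DEPTH,
                 vessel_width: tuple[float, float] = SUITE_VESSEL_WIDTH):
    """A reproducible list of synthetic registration pairs.

    Every other pair receives Dataset-1-style degradations on its moving
    image — blur, global dimming, one occlusion blob and sensor noise —
    emulating a poor-quality acquisition paired with a clean reference.
    """
    pairs = []
    for i in range(n_pairs):
        pspec = PhantomSpec(size=size, n_trees=n_trees, branch_depth=branch_depth,
                            vessel_width=vessel_width, seed=seed * 10_000 + i)
        dspec = DeformationSpec(amplitude=amplitude, smoothness=smoothness,
                                seed=seed * 10_000 + 5000 + i)
        gspec = None
        if degrade and i % 2 == 1:
            gspec = DegradeSpec(blur_sigma=0.6, dim_factor=0.85, n_occlusions=1,
                                occlusion_strength=0.4, noise_sigma=0.03,
                                seed=seed * 10_000 + 7000 + i)
        i_ref, i_mov, grid = make_pair(pspec, dspec, gspec)
        pairs.append({"i_ref": i_ref, "i_mov": i_mov, "true_grid": grid,
                      "phantom_spec": pspec, "deform_spec": dspec,
                      "degrade_spec": gspec})
    return pairs


def training_suite(n_pairs: int = 16, seed: int = 0, size: int = SUITE_SIZE,
                   **segment_kwargs):
    """Segmented (B_ref, B_mov) vessel-map pairs ready for the trainer."""
    dataset = make_dataset(n_pairs, size=size, seed=seed)
    out = []
    for item in dataset:
        b_ref = segment_vessels(extract_structure_channel(item["i_ref"]), **segment_kwargs)
        b_mov = segment_vessels(extract_structure_channel(item["i_mov"]), **segment_kwargs)
        out.append((b_ref, b_mov))
    return out


def manifest(n_pairs: int = 16, seed: int = 0, size: int = SUITE_SIZE) -> list[dict]:
    """JSON-serializable record of the specs/seeds behind ``make_dataset``."""
    entries = []
    for item in make_dataset(n_pairs, size=size, seed=seed):
        entries.append({
            "phantom_spec": asdict(item["phantom_spec"]),
            "deform_spec": asdict(item["deform_spec"]),
            "degrade_spec": asdict(item["degrade_spec"]) if item["degrade_spec"] else None,
        })
    return entries
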