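"""Shared fixtures and pipeline helpers for the test suite."""

from __future__ import annotations

import numpy as np
import pytest

from histotract.image_prep import RasterImage
from histotract.phantoms import make_angle_field_volume
from histotract.structure_tensor import ScalarMap, analyze
from histotract.tensor_volume import (MaskImage, build_brain_mask, build_seed_mask,
                                      downsample_mask, downsample_tensor,
                                      embed_pseudo_tensor)
from histotract.tracking import TrackingConfig, track_all


def circular_dev(theta_map, truth_deg):
    """Signed angular deviation (degrees), wrapped to [-90, 90)."""
    return (np.asarray(theta_map) - truth_deg + 90.0) % 180.0 - 90.0


def uniform_volume(shape, theta_deg=0.0, lam=(2.0, 0.5)):
    """Uniform-orientation tensor volume of a given (H, W) shape."""
    return make_angle_field_volume(np.full(shape, float(theta_deg)), lam)


def full_fa(shape, value=0.5):
    return ScalarMap(np.full(shape, value), "fa2d")


def full_mask(shape):
    return MaskImage(np.ones(shape, dtype=bool))


def run_pipeline_on_image(img, tissue=None, factor=4, percentile=95.0,
                          sigma=5.0, track_cfg=None, seed_subsample=1):
    """Image -> coarse tensors/FA/masks -> streamlines (the tracking chain).

    ``tissue`` overrides brain-mask construction with a known truth mask;
    ``seed_subsample`` keeps every n-th seed to bound runtime on large seed
    sets without changing any tracking parameter.
    """
    st, ef, coh, fa = analyze(img, sigma_window=sigma)
    tv = embed_pseudo_tensor(st)
    if tissue is None:
        brain = build_brain_mask(img)
    else:
        brain = MaskImage(np.asarray(tissue, dtype=bool), "brain")
    tv_c, fa_c = downsample_tensor(tv, fa, factor)
    brain_c = downsample_mask(brain, factor)
    seeds = build_seed_mask(fa_c, brain_c, percentile)
    if seed_subsample > 1:
        idx = np.argwhere(seeds.values)
        keep = np.zeros_like(seeds.values)
        for r, c in idx[::seed_subsample]:
            keep[r, c] = True
        seeds = MaskImage(keep, "seed")
    cfg = track_cfg or TrackingConfig(rng_seed=0)
    ss = track_all(tv_c, fa_c, brain_c, seeds, cfg)
    return ss, tv_c, fa_c, brain_c, seeds


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def random_image(rng):
    """32x32 random 8-bit test image."""
    return RasterImage(rng.integers(0, 256, (32, 32)).astype(np.uint8))
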