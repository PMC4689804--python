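"""Synthetic histology-like phantoms with known orientation ground truth.

Each generator emulates the appearance of an inverted immunostained section
— bright fiber textures on a dark background — with a fully known truth:
the per-pixel fiber orientation (NaN where no directional texture exists),
a region label map and a tissue mask.  Stripe textures are sinusoidal
(band-limited) so that gradient estimators behave well down to a stripe
period of 4 px; "perpendicularly cut" fibers are modeled as a dense dot
field, the in-plane appearance of axon bundles crossing the section plane.

All generators are bit-reproducible under a fixed RNG seed, and every
phantom ships its ground truth so tests compare pipeline output against
construction parameters, never magic numbers.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .image_prep import RasterImage

#: angle convention matches structure_tensor: x along columns, y along rows
#: (down), theta in degrees reduced to [-90, 90)


@dataclass
class PhantomTruth:
    """Ground truth shipped with every phantom."""

    orientation: np.ndarray         # degrees in [-90, 90), NaN where undefined
    labels: np.ndarray              # integer region labels, 0 = background
    tissue: np.ndarray              # boolean tissue mask
    spec: dict = field(default_factory=dict)


def _grid(shape):
    h, w = shape
    yy, xx = np.mgrid[0:h, 0:w].astype(np.float64)
    return xx, yy


def _stripes(xx, yy, theta_deg, period):
    """Sinusoidal stripe field in [0, 1] whose *fiber* direction is theta.

    Wavefront normal is perpendicular to the fiber direction, so intensity
    is constant along fibers and oscillates across them.
    """
    th = np.radians(theta_deg)
    # unit normal to the fiber direction (cos th, sin th)
    phase = (-np.sin(th) * xx + np.cos(th) * yy) * (2.0 * np.pi / period)
    return 0.5 + 0.5 * np.cos(phase)


def _finalize(img_f, noise_sd, rng):
    if noise_sd > 0:
        img_f = img_f + rng.normal(0.0, noise_sd, img_f.shape)
    return np.clip(np.floor(img_f + 0.5), 0, 255).astype(np.uint8)


def make_stripe_phantom(theta_deg: float, size: int = 128, period: float = 12.0,
                        noise_sd: float = 0.0, seed: int = 0,
                        contrast: float = 120.0, mean: float = 128.0
                        ) -> tuple[RasterImage, PhantomTruth]:
    """Full-canvas sinusoidal stripe phantom with fiber orientation theta."""
    if period < 4:
        raise ValueError("stripe period must be >= 4 px (sampling)")
    rng = np.random.default_rng(seed)
    xx, yy = _grid((size, size))
    img_f = mean + contrast * (_stripes(xx, yy, theta_deg, period) - 0.5)
    img = RasterImage(_finalize(img_f, noise_sd, rng), pixel_size_um=0.92,
                      magnification_label="10X")
    theta_red = (theta_deg + 90.0) % 180.0 - 90.0
    truth = PhantomTruth(
        orientation=np.full((size, size), theta_red),
        labels=np.ones((size, size), dtype=np.int32),
        tissue=np.ones((size, size), dtype=bool),
        spec={"kind": "stripe", "theta_deg": theta_deg, "size": size,
              "period": period, "noise_sd": noise_sd, "seed": seed})
    return img, truth


def make_arc_phantom(center=None, r_inner: float = 60.0, r_outer: float = 100.0,
                     size: int = 256, period: float = 12.0, noise_sd: float = 0.0,
                     seed: int = 0, contrast: float = 120.0, mean: float = 128.0,
                     background: float = 8.0) -> tuple[RasterImage, PhantomTruth]:
    """Annular bundle of tangentially oriented fibers around a dark "ventricle".

    The texture is a concentric sinusoid (rings), whose gradient is radial and
    whose fiber direction is therefore everywhere tangential — the geometry of
    a C-shaped periventricular bundle.
    """
    if not r_inner < r_outer:
        raise ValueError("r_inner must be below r_outer")
    if center is None:
        center = (size / 2.0, size / 2.0)
    cx, cy = center
    if cx - r_outer < 0 and cx + r_outer > size and cy - r_outer < 0 and cy + r_outer > size:
        raise ValueError("annulus geometry exceeds the canvas entirely")
    rng = np.random.default_rng(seed)
    xx, yy = _grid((size, size))
    r = np.hypot(xx - cx, yy - cy)
    annulus = (r >= r_inner) & (r <= r_outer)
    rings = 0.5 + 0.5 * np.cos(2.0 * np.pi * r / period)
    img_f = np.where(annulus, mean + contrast * (rings - 0.5), background)
    # tangent direction at (x, y): perpendicular to the radius
    theta = np.degrees(np.arctan2(xx - cx, -(yy - cy)))  # tangent = (-dy, dx)
    theta = (theta + 90.0) % 180.0 - 90.0
    orientation = np.where(annulus, theta, np.nan)
    truth = PhantomTruth(
        orientation=orientation,
        labels=annulus.astype(np.int32),
        tissue=annulus.copy(),
        spec={"kind": "arc", "center": [cx, cy], "r_inner": r_inner,
              "r_outer": r_outer, "size": size, "period": period,
              "noise_sd": noise_sd, "seed": seed})
    img = RasterImage(_finalize(img_f, noise_sd, rng), pixel_size_um=0.92,
                      magnification_label="10X")
    return img, truth


def _dot_field(shape, density, radius, rng, value=1.0):
    """Jittered dot texture: bright discs scattered with ~Poisson-disk spacing."""
    h, w = shape
    out = np.zeros(shape)
    spacing = max(2 * radius + 1, int(round(1.0 / np.sqrt(max(density, 1e-6)))))
    xx, yy = _grid((2 * radius + 1, 2 * radius + 1))
    stamp = (np.hypot(xx - radius, yy - radius) <= radius).astype(np.float64) * value
    for gy in range(0, h, spacing):
        for gx in range(0, w, spacing):
            if rng.random() > min(1.0, density * spacing**2):
                continue
            cx = int(gx + rng.integers(0, spacing))
            cy = int(gy + rng.integers(0, spacing))
            if cx >= w or cy >= h:
                continue
            y0, y1 = max(cy - radius, 0), min(cy + radius + 1, h)
            x0, x1 = max(cx - radius, 0), min(cx + radius + 1, w)
            sy0, sx0 = y0 - (cy - radius), x0 - (cx - radius)
            out[y0:y1, x0:x1] = np.maximum(
                out[y0:y1, x0:x1],
                stamp[sy0:sy0 + (y1 - y0), sx0:sx0 + (x1 - x0)])
    return out


LAYER_LABELS = {"VZ": 1, "IZ": 2, "SP": 3, "CP": 4}


def make_layered_wall_phantom(size: tuple = (256, 256),
                              layer_fractions: tuple = (0.2, 0.35, 0.2, 0.25),
                              crossing_fraction: float = 0.3,
                              period: float = 12.0, noise_sd: float = 5.0,
                              seed: int = 0) -> tuple[RasterImage, PhantomTruth]:
    """Laminar phantom of the fetal telencephalic wall.

    Rows from the bottom (ventricular surface) upward:

    * VZ — dim, directionless speckle (low stain uptake, no organization);
    * IZ — bright tangential (horizontal) stripes with a configurable
      admixture of radial (vertical) crossing fibers;
    * SP — low-contrast diffuse crossing texture (low anisotropy);
    * CP — radial (vertical) stripes (strong radial organization).

    ``layer_fractions`` are the (VZ, IZ, SP, CP) height fractions.
    """
    h, w = size
    rng = np.random.default_rng(seed)
    xx, yy = _grid((h, w))
    fr = np.asarray(layer_fractions, dtype=np.float64)
    fr = fr / fr.sum()
    # bottom of image = ventricular surface: VZ occupies the last rows,
    # so the top-down layer order is CP, SP, IZ, VZ
    cp_h = int(round(fr[3] * h))
    sp_h = int(round(fr[2] * h))
    iz_h = int(round(fr[1] * h))
    rows = {
        "CP": (0, cp_h),
        "SP": (cp_h, cp_h + sp_h),
        "IZ": (cp_h + sp_h, cp_h + sp_h + iz_h),
        "VZ": (cp_h + sp_h + iz_h, h),
    }
    img_f = np.zeros((h, w))
    labels = np.zeros((h, w), dtype=np.int32)
    orientation = np.full((h, w), np.nan)
    tangential = _stripes(xx, yy, 0.0, period)      # fibers along x
    radial = _stripes(xx, yy, -90.0, period)        # fibers along y

    y0, y1 = rows["CP"]
    img_f[y0:y1] = 120 + 110 * (radial[y0:y1] - 0.5)
    orientation[y0:y1] = -90.0
    labels[y0:y1] = LAYER_LABELS["CP"]

    y0, y1 = rows["SP"]
    # diffuse equal crossing at low contrast: weakly oriented by construction
    sp_tex = 0.5 * tangential[y0:y1] + 0.5 * radial[y0:y1]
    img_f[y0:y1] = 110 + 30 * (sp_tex - 0.5) + rng.normal(0, 6, (y1 - y0, w))
    labels[y0:y1] = LAYER_LABELS["SP"]

    y0, y1 = rows["IZ"]
    iz_tex = ((1.0 - crossing_fraction) * tangential[y0:y1]
              + crossing_fraction * radial[y0:y1])
    img_f[y0:y1] = 150 + 100 * (iz_tex - 0.5)
    orientation[y0:y1] = 0.0       # dominant tangential population
    labels[y0:y1] = LAYER_LABELS["IZ"]

    y0, y1 = rows["VZ"]
    img_f[y0:y1] = 40 + rng.normal(0, 8, (y1 - y0, w))
    labels[y0:y1] = LAYER_LABELS["VZ"]

    img = RasterImage(_finalize(img_f, noise_sd, rng), pixel_size_um=0.92,
                      magnification_label="10X")
    truth = PhantomTruth(
        orientation=orientation, labels=labels,
        tissue=np.ones((h, w), dtype=bool),
        spec={"kind": "layered_wall", "size": list(size),
              "layer_fractions": list(fr), "crossing_fraction": crossing_fraction,
              "period": period, "noise_sd": noise_sd, "seed": seed,
              "labels": LAYER_LABELS})
    return img, truth


def make_perpendicular_phantom(size: tuple = (256, 256), dot_density: float = 0.06,
                               dot_radius: int = 2, period: float = 12.0,
                               noise_sd: float = 0.0, seed: int = 0,
                               background: float = 20.0
                               ) -> tuple[RasterImage, PhantomTruth]:
    """Punctate region (fibers cut across the plane) beside in-plane stripes.

    The left half is a bright dot field — high staining intensity but
    near-zero in-plane coherency; the right half carries horizontal in-plane
    fibers.  Labels: 1 = punctate, 2 = stripes.
    """
    if not 0 < dot_density < 1:
        raise ValueError("dot_density must lie in (0, 1)")
    h, w = size
    rng = np.random.default_rng(seed)
    xx, yy = _grid((h, w))
    half = w // 2
    img_f = np.full((h, w), background)
    dots = _dot_field((h, half), dot_density, dot_radius, rng)
    img_f[:, :half] = background + (235.0 - background) * dots
    stripes = _stripes(xx[:, half:], yy[:, half:], 0.0, period)
    img_f[:, half:] = 128 + 120 * (stripes - 0.5)
    labels = np.zeros((h, w), dtype=np.int32)
    labels[:, :half] = 1
    labels[:, half:] = 2
    orientation = np.full((h, w), np.nan)
    orientation[:, half:] = 0.0
    img = RasterImage(_finalize(img_f, noise_sd, rng), pixel_size_um=0.92,
                      magnification_label="10X")
    truth = PhantomTruth(
        orientation=orientation, labels=labels,
        tissue=np.ones((h, w), dtype=bool),
        spec={"kind": "perpendicular", "size": list(size),
              "dot_density": dot_density, "dot_radius": dot_radius,
              "period": period, "noise_sd": noise_sd, "seed": seed})
    return img, truth


def make_crossing_phantom(theta1: float, theta2: float, mix_fraction: float = 0.5,
                          size: int = 128, period: float = 12.0,
                          noise_sd: float = 0.0, seed: int = 0,
                          contrast: float = 120.0) -> tuple[RasterImage, PhantomTruth]:
    """Two superimposed stripe fields simulating within-voxel fiber crossing.

    ``mix_fraction`` is the weight of the theta2 population (0 = pure theta1).
    Truth records both angles and the dominant one.
    """
    if (theta1 - theta2) % 180.0 == 0.0:
        raise ValueError("crossing angles must differ modulo 180")
    rng = np.random.default_rng(seed)
    xx, yy = _grid((size, size))
    s1 = _stripes(xx, yy, theta1, period)
    s2 = _stripes(xx, yy, theta2, period)
    tex = (1.0 - mix_fraction) * s1 + mix_fraction * s2
    img_f = 128 + contrast * (tex - 0.5)
    dominant = theta1 if mix_fraction <= 0.5 else theta2
    dominant = (dominant + 90.0) % 180.0 - 90.0
    img = RasterImage(_finalize(img_f, noise_sd, rng), pixel_size_um=0.92,
                      magnification_label="10X")
    truth = PhantomTruth(
        orientation=np.full((size, size), dominant),
        labels=np.ones((size, size), dtype=np.int32),
        tissue=np.ones((size, size), dtype=bool),
        spec={"kind": "crossing", "theta1": theta1, "theta2": theta2,
              "mix_fraction": mix_fraction, "dominant": dominant,
              "size": size, "period": period, "noise_sd": noise_sd, "seed": seed})
    return img, truth


PHANTOM_MAKERS = {
    "stripe": make_stripe_phantom,
    "arc": make_arc_phantom,
    "layered": make_layered_wall_phantom,
    "perpendicular": make_perpendicular_phantom,
    "crossing": make_crossing_phantom,
}


def save_phantom(img: RasterImage, truth: PhantomTruth, out_dir) -> dict:
    """Write a phantom and its truth: image PNG, orientation float TIFF,
    label PNG and the JSON spec.  Returns the path map."""
    import tifffile
    from PIL import Image

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "image": out / "phantom.png",
        "orientation": out / "orientation_truth.tif",
        "labels": out / "labels.png",
        "spec": out / "phantom_spec.json",
    }
    Image.fromarray(img.pixels).save(paths["image"])
    tifffile.imwrite(paths["orientation"], truth.orientation.astype(np.float32))
    Image.fromarray(truth.labels.astype(np.uint8)).save(paths["labels"])
    paths["spec"].write_text(json.dumps(truth.spec, indent=2) + "\n")
    return {k: str(v) for k, v in paths.items()}


def make_angle_field_volume(theta_deg_map, lam=(2.0, 0.5)):
    """Pseudo-tensor volume with prescribed per-voxel fiber angles.

    Builds tensors ``lam[0] * u u^T + lam[1] * I`` with ``u`` the unit vector
    at ``theta_deg_map`` degrees (NaN entries become isotropic voxels), in the
    tracking convention (principal eigenvector along the fiber).  Useful for
    constructing exact tracking scenarios without going through an image.
    """
    from .tensor_volume import TensorVolume

    th = np.radians(np.asarray(theta_deg_map, dtype=np.float64))
    ok = np.isfinite(th)
    ux = np.where(ok, np.cos(th), 0.0)
    uy = np.where(ok, np.sin(th), 0.0)
    d = np.zeros(th.shape + (6,))
    d[..., 0] = lam[0] * ux * ux + lam[1] * ok
    d[..., 1] = lam[0] * ux * uy
    d[..., 3] = lam[0] * uy * uy + lam[1] * ok
    # isotropic stand-in for undefined orientation: equal in-plane eigenvalues
    iso = ~ok
    d[iso, 0] = d[iso, 3] = lam[1]
    return TensorVolume(d=d)
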