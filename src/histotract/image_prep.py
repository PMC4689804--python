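"""Reading and preprocessing of digitalized histological section images.

Two preprocessing dialects are supported, reflecting the two downstream
consumers of the section image:

* ``"hsb"``   — grayscale conversion followed by inversion, so that strongly
  stained (dark) axonal fibers become bright textures on a dark background.
  This is the input to orientation/coherency mapping and HSB rendering.
* ``"tract"`` — red-channel extraction, contrast-limited adaptive histogram
  equalization (CLAHE) and linear range normalization.  This is the input to
  the tractography substrate (pseudo-tensor volume, masks, seeds).

Native scans are assumed to be acquired at 40X with a pixel size of 0.23 um;
down-sampling by integer factors (2, 4, 8) yields the 20X/10X/5X working
magnifications.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from PIL import Image
from skimage import exposure

logger = logging.getLogger(__name__)

#: pixel edge length of the native 40X scan, in micrometers
NATIVE_PIXEL_SIZE_UM = 0.23

#: magnification label -> down-sample factor from the native 40X scan
MAGNIFICATION_FACTORS = {"40X": 1, "20X": 2, "10X": 4, "5X": 8}


@dataclass
class RasterImage:
    """A 2D section image (single channel or RGB) with physical metadata.

    Attributes
    ----------
    pixels : ndarray
        ``(H, W)`` or ``(H, W, 3)`` array of 8-bit intensities in [0, 255].
    pixel_size_um : float
        Physical edge length of one pixel, micrometers.
    magnification_label : str
        Free-text magnification tag, e.g. ``"10X"``.
    """

    pixels: np.ndarray
    pixel_size_um: float = NATIVE_PIXEL_SIZE_UM
    magnification_label: str = "40X"

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim not in (2, 3):
            raise ValueError(f"expected 2D or 3-channel image, got ndim={self.pixels.ndim}")
        if self.pixels.ndim == 3 and self.pixels.shape[2] != 3:
            raise ValueError(f"color images must have 3 channels, got {self.pixels.shape[2]}")
        if self.pixels.size == 0:
            raise ValueError("zero-area image")
        lo, hi = float(self.pixels.min()), float(self.pixels.max())
        if lo < 0 or hi > 255:
            raise ValueError(f"intensities out of 8-bit range: [{lo}, {hi}]")
        if not self.pixel_size_um > 0:
            raise ValueError(f"pixel_size_um must be positive, got {self.pixel_size_um}")

    @property
    def shape(self) -> tuple:
        return self.pixels.shape

    @property
    def n_channels(self) -> int:
        return 1 if self.pixels.ndim == 2 else self.pixels.shape[2]


@dataclass
class PrepConfig:
    """Preprocessing parameters.

    ``channel`` selects the component converted to grayscale (the red channel
    for the tractography dialect; ``"luminance"`` applies Rec. 601 weights
    0.299 R + 0.587 G + 0.114 B).  ``clip_limit`` and ``tile_grid`` are the
    CLAHE parameters (normalized clip limit; tiles across the image).
    ``out_range`` is the target interval of the final linear rescale.
    """

    channel: str = "red"
    invert: bool = False
    equalize: bool = True
    clip_limit: float = 0.01
    tile_grid: tuple = (8, 8)
    out_range: tuple = (0, 255)

    def __post_init__(self) -> None:
        if self.channel not in ("red", "green", "blue", "luminance"):
            raise ValueError(f"unknown channel {self.channel!r}")
        if not self.clip_limit > 0:
            raise ValueError("clip_limit must be > 0")
        if any(int(t) < 1 for t in self.tile_grid):
            raise ValueError("tile_grid entries must be >= 1")
        lo, hi = self.out_range
        if not lo < hi:
            raise ValueError("out_range lower bound must be below upper bound")


def read_image(path, pixel_size_um: float | None = None,
               downsample_factor: int = 1,
               magnification_label: str = "40X") -> RasterImage:
    """Read a TIFF/PNG/JPEG section image from disk.

    If ``pixel_size_um`` is not given it defaults to the native scan
    resolution (0.23 um) multiplied by ``downsample_factor``, matching the
    magnification-level bookkeeping of slide scanners.
    """
    path = Path(path)
    try:
        with Image.open(path) as im:
            im.load()
            if im.mode not in ("L", "RGB"):
                im = im.convert("RGB" if im.mode in ("RGBA", "P", "CMYK") else "L")
            pixels = np.asarray(im)
    except FileNotFoundError:
        raise
    except Exception as exc:  # PIL raises a zoo of decode errors
        raise OSError(f"cannot read image file {path}: {exc}") from exc
    if pixels.size == 0:
        raise ValueError(f"zero-area image: {path}")
    if pixels.shape[0] < 16 or pixels.shape[1] < 16:
        raise ValueError(f"section image too small ({pixels.shape[0]}x"
                         f"{pixels.shape[1]}); minimum is 16x16")
    if pixel_size_um is None:
        pixel_size_um = NATIVE_PIXEL_SIZE_UM * downsample_factor
    return RasterImage(pixels=pixels, pixel_size_um=pixel_size_um,
                       magnification_label=magnification_label)


def write_image(img: RasterImage, path) -> None:
    """Write an 8-bit PNG/TIFF intermediate."""
    Image.fromarray(img.pixels.astype(np.uint8)).save(Path(path))


_CHANNEL_INDEX = {"red": 0, "green": 1, "blue": 2}


def extract_grayscale(img: RasterImage, cfg: PrepConfig) -> RasterImage:
    """Reduce a color image to a single 8-bit channel.

    ``channel in {red, green, blue}`` picks that component; ``luminance``
    applies the Rec. 601 weighted sum.  A grayscale input is passed through
    unchanged (with a warning if a color channel was requested).
    """
    if img.n_channels == 1:
        if cfg.channel != "luminance":
            logger.warning("channel %r requested from grayscale input; no-op", cfg.channel)
        return img
    px = img.pixels.astype(np.float64)
    if cfg.channel == "luminance":
        gray = px[..., 0] * 0.299 + px[..., 1] * 0.587 + px[..., 2] * 0.114
    else:
        gray = px[..., _CHANNEL_INDEX[cfg.channel]]
    gray = np.clip(np.floor(gray + 0.5), 0, 255).astype(np.uint8)
    return RasterImage(gray, img.pixel_size_um, img.magnification_label)


def invert(img: RasterImage) -> RasterImage:
    """8-bit inversion, ``out = 255 - in``.  Involutive."""
    if img.n_channels != 1:
        raise ValueError("invert expects a single-channel image")
    out = 255 - img.pixels.astype(np.uint8)
    return RasterImage(out, img.pixel_size_um, img.magnification_label)


def _block_mean(a: np.ndarray, factor: int) -> np.ndarray:
    """Block-mean reduction with edge truncation; output dims = ceil(n/f)."""
    h, w = a.shape
    rows = np.add.reduceat(a, np.arange(0, h, factor), axis=0)
    both = np.add.reduceat(rows, np.arange(0, w, factor), axis=1)
    # per-block pixel counts (partial edge blocks average over fewer pixels)
    rc = np.minimum(np.arange(0, h, factor) + factor, h) - np.arange(0, h, factor)
    cc = np.minimum(np.arange(0, w, factor) + factor, w) - np.arange(0, w, factor)
    return both / np.outer(rc, cc)


def downsample(img: RasterImage, factor: int) -> RasterImage:
    """Block-mean down-sampling by an integer factor.

    Mean-preserving on exact blocks; partial edge blocks average over the
    pixels actually present.  ``pixel_size_um`` is scaled by ``factor``.
    """
    factor = int(factor)
    if factor < 1:
        raise ValueError(f"downsample factor must be >= 1, got {factor}")
    if factor == 1:
        return img
    a = img.pixels.astype(np.float64)
    if a.ndim == 2:
        out = _block_mean(a, factor)
    else:
        out = np.stack([_block_mean(a[..., c], factor) for c in range(a.shape[2])], axis=-1)
    out = np.clip(np.floor(out + 0.5), 0, 255).astype(np.uint8)
    return RasterImage(out, img.pixel_size_um * factor, img.magnification_label)


def equalize_normalize(img: RasterImage, cfg: PrepConfig) -> RasterImage:
    """CLAHE followed by linear range normalization.

    CLAHE (when ``cfg.equalize``) uses ``cfg.clip_limit`` and ``cfg.tile_grid``;
    the result is then linearly rescaled so min -> out_range lower and
    max -> out_range upper.  Constant images pass through unchanged because
    the rescale is undefined for them.
    """
    if img.n_channels != 1:
        raise ValueError("equalize_normalize expects a single-channel image")
    a = img.pixels.astype(np.float64)
    if a.max() == a.min():
        logger.warning("constant image: equalization/normalization skipped")
        return img
    if cfg.equalize:
        h, w = a.shape
        ty, tx = (int(t) for t in cfg.tile_grid)
        kernel = (max(1, h // ty), max(1, w // tx))
        eq = exposure.equalize_adapthist(a / 255.0, kernel_size=kernel,
                                         clip_limit=cfg.clip_limit)
    else:
        eq = a / 255.0
    lo, hi = cfg.out_range
    mn, mx = eq.min(), eq.max()
    out = lo + (eq - mn) * (hi - lo) / (mx - mn)
    out = np.clip(np.floor(out + 0.5), lo, hi).astype(np.uint8)
    return RasterImage(out, img.pixel_size_um, img.magnification_label)


def preprocess(img: RasterImage, dialect: str = "hsb",
               cfg: PrepConfig | None = None,
               downsample_factor: int = 1) -> RasterImage:
    """Run one of the two preprocessing chains end to end.

    ``"hsb"``: grayscale (luminance) -> invert.
    ``"tract"``: red channel -> CLAHE -> normalize to ``out_range``.
    Down-sampling, when requested, is applied first in both dialects.
    """
    if dialect not in ("hsb", "tract"):
        raise ValueError(f"unknown preprocessing dialect {dialect!r}")
    if cfg is None:
        cfg = PrepConfig(channel="luminance" if dialect == "hsb" else "red")
    if downsample_factor > 1:
        img = downsample(img, downsample_factor)
    logger.info("preprocess dialect=%s channel=%s", dialect, cfg.channel)
    if dialect == "hsb":
        g = extract_grayscale(img, cfg)
        return invert(g)
    g = extract_grayscale(img, cfg)
    if cfg.invert:
        g = invert(g)
    return equalize_normalize(g, cfg)
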