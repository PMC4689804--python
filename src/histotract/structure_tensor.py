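"""2D structure-tensor analysis: orientation, coherency, FA and HSB rendering.

The structure tensor at a pixel is the Gaussian-windowed outer product of
intensity gradients,

    G = w_sigma * (grad I grad I^T),   grad I = (Ix, Iy),

whose *major* eigenvector points across the stained fibers (along the
intensity gradient) and whose *minor* eigenvector points along them.  All
orientation outputs of this module therefore report the direction of the
minor eigenvector: that is the fiber orientation.

Angle convention
----------------
Image coordinates: x runs along columns (rightward), y along rows
(downward).  ``theta_fiber`` is ``atan2(e_y, e_x)`` of the minor eigenvector,
in degrees, reduced to [-90, 90).  Positive angles therefore rotate from +x
toward +y (clockwise on screen); the same convention is used by the phantom
generators, the hue mapping and the streamline colors, so recovered and
ground-truth angles are directly comparable.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage.color import hsv2rgb

from .image_prep import RasterImage

#: default Gaussian window scale, pixels (slide-scan analysis default)
DEFAULT_SIGMA_WINDOW = 5.0

#: relative eigenvalue-gap threshold below which a pixel counts as isotropic
ISOTROPIC_TOL = 1e-12


@dataclass
class STField:
    """Per-pixel structure-tensor components on the image grid."""

    gxx: np.ndarray
    gxy: np.ndarray
    gyy: np.ndarray
    sigma_window: float = DEFAULT_SIGMA_WINDOW
    gradient_kernel: str = "cubic_spline"

    @property
    def shape(self) -> tuple:
        return self.gxx.shape

    def validate(self) -> None:
        tr = self.gxx + self.gyy
        eps = 1e-9 * np.maximum(tr, 0) ** 2 + 1e-30
        if (self.gxx < -eps).any() or (self.gyy < -eps).any():
            raise ValueError("negative diagonal structure-tensor component")
        if (self.gxy**2 > self.gxx * self.gyy + eps).any():
            raise ValueError("structure tensor not positive semidefinite")


@dataclass
class EigenField:
    """Ordered eigen-decomposition of an :class:`STField`.

    ``lambda1 >= lambda2 >= 0``; ``e1``/``e2`` are unit eigenvector fields of
    shape ``(H, W, 2)`` in (x, y) components; ``theta_fiber`` is the fiber
    orientation (direction of the minor eigenvector ``e2``) in degrees,
    reduced to [-90, 90).
    """

    lambda1: np.ndarray
    lambda2: np.ndarray
    e1: np.ndarray
    e2: np.ndarray
    theta_fiber: np.ndarray

    @property
    def shape(self) -> tuple:
        return self.lambda1.shape


@dataclass
class ScalarMap:
    """A per-pixel real-valued map with a semantic tag."""

    values: np.ndarray
    kind: str = "intensity"


@dataclass
class HSBRender:
    """8-bit hue/saturation/brightness channels of an orientation render."""

    hue: np.ndarray
    saturation: np.ndarray
    brightness: np.ndarray

    def to_rgb(self) -> np.ndarray:
        """Convert to an 8-bit RGB array (HSB == HSV)."""
        hsv = np.stack([self.hue, self.saturation, self.brightness], axis=-1) / 255.0
        return np.clip(np.floor(hsv2rgb(hsv) * 255.0 + 0.5), 0, 255).astype(np.uint8)


def _gradient(image: np.ndarray, kernel: str) -> tuple[np.ndarray, np.ndarray]:
    """Per-axis first derivative: cubic-spline or central-difference.

    The cubic-spline gradient prefilters the image into cubic B-spline
    coefficients and differentiates the spline at the sample points, which
    reduces to correlating the coefficients with [-1/2, 0, 1/2].
    """
    if kernel == "cubic_spline":
        base = ndimage.spline_filter(image, order=3, mode="mirror")
    elif kernel == "central_difference":
        base = image
    else:
        raise ValueError(f"unknown gradient kernel {kernel!r}")
    d = np.array([0.5, 0.0, -0.5])  # correlate -> (f[i+1] - f[i-1]) / 2
    ix = ndimage.correlate1d(base, d[::-1], axis=1, mode="mirror")
    iy = ndimage.correlate1d(base, d[::-1], axis=0, mode="mirror")
    return ix, iy


def compute_structure_tensor(img, sigma_window: float = DEFAULT_SIGMA_WINDOW,
                             gradient_kernel: str = "cubic_spline") -> STField:
    """Compute the Gaussian-windowed structure tensor of a section image.

    Parameters
    ----------
    img : RasterImage or 2D ndarray
        Single-channel image.
    sigma_window : float
        Standard deviation of the Gaussian window, pixels.
    gradient_kernel : {"cubic_spline", "central_difference"}
        Derivative estimator.

    Boundaries are handled by reflection throughout.
    """
    a = img.pixels if isinstance(img, RasterImage) else np.asarray(img)
    if a.ndim != 2:
        raise ValueError("structure tensor requires a single-channel image")
    if not np.isfinite(a).all():
        raise ValueError("image contains non-finite pixels")
    if not sigma_window > 0:
        raise ValueError("sigma_window must be positive")
    a = a.astype(np.float64)
    ix, iy = _gradient(a, gradient_kernel)

    def w(f):
        return ndimage.gaussian_filter(f, sigma_window, mode="reflect")

    st = STField(gxx=w(ix * ix), gxy=w(ix * iy), gyy=w(iy * iy),
                 sigma_window=sigma_window, gradient_kernel=gradient_kernel)
    # clamp tiny negative round-off on the diagonals
    np.maximum(st.gxx, 0.0, out=st.gxx)
    np.maximum(st.gyy, 0.0, out=st.gyy)
    # zero out pure floating-point dust (e.g. the spline prefilter leaves
    # ~eps-scale gradients on constant images); the floor scales with the
    # squared intensity, so derived maps stay scale-invariant
    floor = (64.0 * np.finfo(np.float64).eps * max(np.abs(a).max(), 1.0)) ** 2
    dust = (st.gxx + st.gyy) <= floor
    st.gxx[dust] = st.gxy[dust] = st.gyy[dust] = 0.0
    return st


def fiber_angle_deg(vx, vy):
    """Angle of a direction (vx, vy) in degrees, reduced to [-90, 90)."""
    th = np.degrees(np.arctan2(vy, vx))
    return (th + 90.0) % 180.0 - 90.0


def eigen_decompose(st: STField) -> EigenField:
    """Closed-form eigen-decomposition of the 2x2 symmetric tensor field.

    Isotropic pixels (eigenvalue gap below ``ISOTROPIC_TOL * trace``) get the
    conventional tie-break ``theta_fiber = 0`` with ``e2 = (1, 0)``.
    """
    gxx, gxy, gyy = st.gxx, st.gxy, st.gyy
    tr = gxx + gyy
    half_gap = np.sqrt(((gxx - gyy) * 0.5) ** 2 + gxy**2)
    lam1 = tr * 0.5 + half_gap
    lam2 = np.maximum(tr * 0.5 - half_gap, 0.0)

    # major eigenvector: (gxy, lam1-gxx); diagonal tensors (gxy == 0) take
    # the axis of the larger diagonal entry directly
    off = np.abs(gxy) > 0
    v1x = np.where(off, gxy, (gxx >= gyy).astype(np.float64))
    v1y = np.where(off, lam1 - gxx, (gxx < gyy).astype(np.float64))
    norm = np.hypot(v1x, v1y)
    iso = (lam1 - lam2) <= ISOTROPIC_TOL * np.maximum(tr, 0) + 1e-300
    safe = np.where(norm > 0, norm, 1.0)
    e1 = np.stack([np.where(iso, 0.0, v1x / safe),
                   np.where(iso, 1.0, v1y / safe)], axis=-1)
    # minor eigenvector: rotate e1 by 90 degrees
    e2 = np.stack([-e1[..., 1], e1[..., 0]], axis=-1)
    # fix sign so e2 points into the canonical half-plane (not required by
    # the angle reduction, but keeps the field deterministic)
    flip = e2[..., 0] < 0
    e2[flip] = -e2[flip]
    theta = np.where(iso, 0.0, fiber_angle_deg(e2[..., 0], e2[..., 1]))
    return EigenField(lambda1=lam1, lambda2=lam2, e1=e1, e2=e2, theta_fiber=theta)


def coherency(ef: EigenField) -> ScalarMap:
    """Coherency C = (lam1 - lam2) / (lam1 + lam2); zero where the trace is zero."""
    tr = ef.lambda1 + ef.lambda2
    with np.errstate(invalid="ignore", divide="ignore"):
        c = np.where(tr > 0, (ef.lambda1 - ef.lambda2) / np.where(tr > 0, tr, 1.0), 0.0)
    return ScalarMap(values=c, kind="coherency")


def fa2d(ef: EigenField, denominator: str = "budde") -> ScalarMap:
    """Two-dimensional fractional anisotropy of the tensor eigenvalues.

    FA_2d = sqrt( ((l1-m)^2 + (l2-m)^2) / (l1^2 + l2^2) ),  m = (l1+l2)/2,

    which ranges over [0, 1/sqrt(2)]: 0 for isotropic texture, 1/sqrt(2) in
    the rank-1 limit.  ``denominator="sum"`` replaces the denominator with
    (l1+l2)^2, a monotone variant with range [0, 1/2].
    """
    l1, l2 = ef.lambda1, ef.lambda2
    m = (l1 + l2) * 0.5
    num = (l1 - m) ** 2 + (l2 - m) ** 2
    if denominator == "budde":
        den = l1**2 + l2**2
    elif denominator == "sum":
        den = (l1 + l2) ** 2
    else:
        raise ValueError(f"unknown FA denominator {denominator!r}")
    with np.errstate(invalid="ignore", divide="ignore"):
        fa = np.sqrt(np.where(den > 0, num / np.where(den > 0, den, 1.0), 0.0))
    return ScalarMap(values=fa, kind="fa2d")


def hue_byte_from_theta(theta_deg):
    """Map an orientation in [-90, 90) to an 8-bit hue, round-half-up."""
    return np.floor((np.asarray(theta_deg, dtype=np.float64) + 90.0) / 180.0 * 255.0
                    + 0.5).astype(np.uint8)


def orientation_rgb(theta_deg) -> np.ndarray:
    """Fully saturated hue-wheel color for an orientation (streamline colors)."""
    h = hue_byte_from_theta(theta_deg) / 255.0
    hsv = np.stack([h, np.ones_like(h), np.ones_like(h)], axis=-1)
    return np.clip(np.floor(hsv2rgb(np.atleast_3d(hsv).reshape(-1, 1, 3)) * 255.0 + 0.5),
                   0, 255).astype(np.uint8).reshape(np.shape(h) + (3,))


def render_hsb(ef: EigenField, intensity: ScalarMap) -> HSBRender:
    """Compose the orientation render: hue = orientation, saturation =
    coherency, brightness = staining intensity."""
    if intensity.values.shape != ef.shape:
        raise ValueError("intensity map dimensions do not match the eigen field")
    hue = hue_byte_from_theta(ef.theta_fiber)
    sat = np.clip(np.floor(coherency(ef).values * 255.0 + 0.5), 0, 255).astype(np.uint8)
    bright = np.clip(np.floor(np.asarray(intensity.values, dtype=np.float64) + 0.5),
                     0, 255).astype(np.uint8)
    return HSBRender(hue=hue, saturation=sat, brightness=bright)


def analyze(img, sigma_window: float = DEFAULT_SIGMA_WINDOW,
            gradient_kernel: str = "cubic_spline",
            fa_denominator: str = "budde"):
    """Convenience pipeline: image -> (STField, EigenField, coherency, fa2d)."""
    st = compute_structure_tensor(img, sigma_window, gradient_kernel)
    ef = eigen_decompose(st)
    return st, ef, coherency(ef), fa2d(ef, fa_denominator)
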