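"""Pseudo-3D tensor embedding, masks and NIfTI export.

The 2D structure tensor G is generalized to a 3x3 "pseudo-diffusion" tensor
by zeroing every z component, so that standard diffusion-tractography
machinery can run on a single histological section.  Because deterministic
tracking follows the *principal* eigenvector while the structure tensor's
principal eigenvector points across fibers, the default embedding swaps the
two in-plane eigenvalues,

    T = (lam1 + lam2) * I2 - G,

which keeps the eigenvectors and exchanges the eigenvalues, so the embedded
tensor's principal eigenvector lies along fibers.  The literal embedding of
the raw G is retained as a documented mode (``track_convention=False``).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
from scipy import ndimage
from skimage.filters import threshold_otsu
from skimage.morphology import closing, disk

from .image_prep import RasterImage, _block_mean
from .structure_tensor import EigenField, STField, ScalarMap, eigen_decompose, fa2d

logger = logging.getLogger(__name__)

#: component order of the 6 unique tensor entries (upper triangle, row-major)
COMPONENT_ORDER = ("dxx", "dxy", "dxz", "dyy", "dyz", "dzz")


@dataclass
class TensorVolume:
    """Per-voxel pseudo-diffusion tensors on an X x Y x 1 grid.

    ``d`` has shape ``(H, W, 6)`` with components ordered as
    :data:`COMPONENT_ORDER`; all z components (dxz, dyz, dzz) are zero.
    """

    d: np.ndarray
    voxel_size: float = 1.0
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.d = np.asarray(self.d, dtype=np.float64)
        if self.d.ndim != 3 or self.d.shape[2] != 6:
            raise ValueError(f"expected (H, W, 6) tensor array, got {self.d.shape}")

    @property
    def shape(self) -> tuple:
        return self.d.shape[:2]

    def inplane(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """The in-plane 2x2 block as (dxx, dxy, dyy) component maps."""
        return self.d[..., 0], self.d[..., 1], self.d[..., 3]

    def validate(self) -> None:
        if np.abs(self.d[..., [2, 4, 5]]).max(initial=0.0) > 0:
            raise ValueError("z components of the pseudo tensor must be zero")
        dxx, dxy, dyy = self.inplane()
        tr = dxx + dyy
        eps = 1e-9 * np.maximum(tr, 0) ** 2 + 1e-30
        if (dxx < -eps).any() or (dyy < -eps).any() or (dxy**2 > dxx * dyy + eps).any():
            raise ValueError("in-plane tensor block not positive semidefinite")


@dataclass
class MaskImage:
    """Boolean pixel mask with a semantic tag (brain tissue or seeds)."""

    values: np.ndarray
    kind: str = "brain"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=bool)

    @property
    def shape(self) -> tuple:
        return self.values.shape

    def count(self) -> int:
        return int(self.values.sum())


def embed_pseudo_tensor(st: STField, track_convention: bool = True,
                        voxel_size: float = 1.0) -> TensorVolume:
    """Embed a 2D structure-tensor field as pseudo-3D diffusion tensors.

    With ``track_convention`` (default) the in-plane block is the
    eigen-swapped tensor ``(lam1+lam2) I - G`` so the principal eigenvector
    points along fibers; with it off the raw G is embedded literally.
    """
    h, w = st.shape
    d = np.zeros((h, w, 6), dtype=np.float64)
    if track_convention:
        tr = st.gxx + st.gyy
        d[..., 0] = tr - st.gxx   # swapped: dxx = gyy
        d[..., 1] = -st.gxy
        d[..., 3] = tr - st.gyy   # swapped: dyy = gxx
    else:
        d[..., 0] = st.gxx
        d[..., 1] = st.gxy
        d[..., 3] = st.gyy
    return TensorVolume(d=d, voxel_size=voxel_size,
                        provenance={"track_convention": bool(track_convention),
                                    "sigma_window": st.sigma_window,
                                    "gradient_kernel": st.gradient_kernel})


def tensor_eigen(tv: TensorVolume) -> EigenField:
    """Eigen-decomposition of the in-plane 2x2 block of a tensor volume."""
    dxx, dxy, dyy = tv.inplane()
    return eigen_decompose(STField(gxx=dxx, gxy=dxy, gyy=dyy))


def tensor_fa(tv: TensorVolume, denominator: str = "budde") -> ScalarMap:
    """FA_2d recomputed from the tensor volume's in-plane eigenvalues."""
    return fa2d(tensor_eigen(tv), denominator)


def downsample_tensor(tv: TensorVolume, fa: ScalarMap | None, factor: int
                      ) -> tuple[TensorVolume, ScalarMap]:
    """Block-mean down-sampling of the tensor field.

    Tensors average linearly, so each of the six components is block-meaned
    independently; FA is then *recomputed* from the averaged tensors rather
    than averaged directly (direct FA averaging is biased wherever fibers
    cross within a block).  The ``fa`` argument is accepted for interface
    symmetry and ignored in favor of recomputation.
    """
    factor = int(factor)
    if factor < 1:
        raise ValueError(f"downsample factor must be >= 1, got {factor}")
    if factor == 1:
        out = tv
    else:
        comps = [_block_mean(tv.d[..., c], factor) for c in range(6)]
        out = TensorVolume(d=np.stack(comps, axis=-1),
                           voxel_size=tv.voxel_size * factor,
                           provenance={**tv.provenance, "downsample_factor": factor})
    return out, tensor_fa(out)


def downsample_mask(mask: MaskImage, factor: int) -> MaskImage:
    """Majority (>= 0.5 occupancy) block reduction of a boolean mask."""
    factor = int(factor)
    if factor < 1:
        raise ValueError("downsample factor must be >= 1")
    if factor == 1:
        return mask
    frac = _block_mean(mask.values.astype(np.float64), factor)
    return MaskImage(values=frac >= 0.5, kind=mask.kind)


def build_brain_mask(img, close_radius: int = 5, otsu: bool = True,
                     fill_holes: bool = True, largest_only: bool = True) -> MaskImage:
    """Separate tissue foreground from slide background.

    Recipe: Otsu threshold -> morphological closing (disk radius
    ``close_radius``) -> hole filling -> largest connected component.  Each
    step can be toggled for diagnosis; all are on by default.
    """
    a = img.pixels if isinstance(img, RasterImage) else np.asarray(img)
    a = a.astype(np.float64)
    if otsu:
        if a.max() == a.min():
            raise ValueError("no tissue detected: image is constant")
        mask = a > threshold_otsu(a)
    else:
        mask = a > 0
    if not mask.any():
        raise ValueError("no tissue detected: empty foreground")
    if close_radius > 0:
        mask = closing(mask, disk(close_radius)).astype(bool)
    if fill_holes:
        mask = ndimage.binary_fill_holes(mask)
    if largest_only:
        labels, n = ndimage.label(mask)
        if n == 0:
            raise ValueError("no tissue detected: empty foreground")
        sizes = ndimage.sum_labels(np.ones_like(labels), labels, np.arange(1, n + 1))
        mask = labels == (1 + int(np.argmax(sizes)))
    logger.info("brain mask: %d foreground pixels", int(mask.sum()))
    return MaskImage(values=mask, kind="brain")


def nearest_rank_percentile(values: np.ndarray, percentile: float) -> float:
    """Nearest-rank percentile: the k-th smallest value, k = ceil(p/100 * n)."""
    v = np.sort(np.asarray(values).ravel())
    n = v.size
    if n == 0:
        raise ValueError("empty sample")
    if percentile <= 0:
        return float(v[0])
    k = int(np.ceil(percentile / 100.0 * n))
    return float(v[min(max(k, 1), n) - 1])


def build_seed_mask(fa: ScalarMap, brain: MaskImage, percentile: float = 95.0
                    ) -> MaskImage:
    """High-pass threshold of in-mask FA at its nearest-rank percentile.

    Default ``percentile=95`` keeps the top 5% of FA values inside the brain
    mask — the high-anisotropy white matter used to initiate tracking.
    """
    if fa.values.shape != brain.shape:
        raise ValueError("FA map and brain mask dimensions differ")
    if not brain.values.any():
        raise ValueError("empty brain mask")
    inmask = fa.values[brain.values]
    thr = nearest_rank_percentile(inmask, percentile)
    seeds = brain.values & (fa.values >= thr)
    logger.info("seed mask: %d seeds (P%.4g = %.4g)", int(seeds.sum()), percentile, thr)
    return MaskImage(values=seeds, kind="seed")


def _nifti_affine(voxel_size: float) -> np.ndarray:
    aff = np.diag([voxel_size, voxel_size, voxel_size, 1.0])
    return aff


def write_nifti_tensor(tv: TensorVolume, path) -> Path:
    """Write the tensor volume as a 4D NIfTI-1 file of dims [X, Y, 1, 6].

    The six volumes are the upper-triangle components in the order
    (dxx, dxy, dxz, dyy, dyz, dzz); the affine is the identity scaled by the
    voxel size with the origin at the image corner (x = column, y = row).
    """
    path = Path(path)
    h, w = tv.shape
    # image rows are y, columns are x; NIfTI wants x fastest
    data = np.transpose(tv.d, (1, 0, 2))[:, :, np.newaxis, :]  # (X, Y, 1, 6)
    img = nib.Nifti1Image(np.ascontiguousarray(data), _nifti_affine(tv.voxel_size))
    img.header.set_zooms((tv.voxel_size,) * 3 + (1.0,))
    try:
        nib.save(img, path)
    except Exception as exc:
        raise OSError(f"cannot write NIfTI tensor file {path}: {exc}") from exc
    return path


def read_nifti_tensor(path) -> TensorVolume:
    """Read back a tensor volume written by :func:`write_nifti_tensor`."""
    img = nib.load(str(path))
    data = np.asarray(img.dataobj, dtype=np.float64)
    if data.ndim != 4 or data.shape[2] != 1 or data.shape[3] != 6:
        raise ValueError(f"expected [X, Y, 1, 6] tensor NIfTI, got dims {data.shape}")
    d = np.transpose(data[:, :, 0, :], (1, 0, 2))
    voxel = float(img.header.get_zooms()[0])
    return TensorVolume(d=d, voxel_size=voxel, provenance={"source": str(path)})


def write_nifti_mask(mask: MaskImage, path, voxel_size: float = 1.0) -> Path:
    path = Path(path)
    data = mask.values.T[:, :, np.newaxis].astype(np.uint8)
    nib.save(nib.Nifti1Image(np.ascontiguousarray(data), _nifti_affine(voxel_size)), path)
    return path
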