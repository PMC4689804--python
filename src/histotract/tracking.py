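"""Deterministic streamline tractography on the pseudo-tensor grid.

Tracking integrates the principal-eigenvector field of the (eigen-swapped)
pseudo tensor with a classical fourth-order Runge-Kutta scheme.  The tensor
at a continuous position is obtained by *probabilistic nearest-neighbor*
interpolation: one of the four surrounding grid voxels is drawn with
probability equal to its bilinear weight, and that voxel's tensor (and FA,
for the stopping rule) is used.  Repeating the tracking from the same seed
therefore yields a family of slightly different streamlines whose spread
reflects local orientation uncertainty.

Stopping rules: exit of the brain mask or grid, FA at or below the floor,
turning angle between consecutive steps at or above the curve threshold,
step-count cap, or a locally isotropic/zero tensor.

Coordinates are coarse-grid pixel units, (x, y) with x along columns and y
along rows; grid nodes sit at integer coordinates (voxel centers).
"""

from __future__ import annotations

import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from .structure_tensor import ScalarMap, fiber_angle_deg, orientation_rgb
from .tensor_volume import MaskImage, TensorVolume

logger = logging.getLogger(__name__)

TERMINATION_REASONS = ("mask_exit", "low_fa", "high_curvature", "max_steps", "zero_tensor")


class OutOfDomain(Exception):
    """Continuous position outside the tensor grid."""


@dataclass
class TrackingConfig:
    """Parameters of the deterministic tracker.

    Defaults follow the histology-tractography protocol: 2-pixel steps, a
    75 degree curve threshold, an FA floor of 0.1 and 10 stochastic
    iterations per seed voxel.  ``max_steps`` and ``min_points`` bound the
    streamline length (per launch direction and total, respectively).
    """

    step_px: float = 2.0
    curve_threshold_deg: float = 75.0
    fa_min: float = 0.1
    iterations_per_seed: int = 10
    max_steps: int = 2000
    min_points: int = 5
    rng_seed: int = 0
    bidirectional: bool = True

    def __post_init__(self) -> None:
        if not self.step_px > 0:
            raise ValueError("step_px must be positive")
        if not 0 < self.curve_threshold_deg < 180:
            raise ValueError("curve_threshold_deg must lie in (0, 180)")
        if not 0 <= self.fa_min < 1:
            raise ValueError("fa_min must lie in [0, 1)")
        if self.iterations_per_seed < 1:
            raise ValueError("iterations_per_seed must be >= 1")


@dataclass
class Streamline:
    """An ordered polyline in coarse-grid coordinates with per-point colors."""

    points: np.ndarray              # (N, 2) float, (x, y)
    colors: np.ndarray              # (N, 3) uint8
    termination_reason: tuple       # (reverse-end reason, forward-end reason)
    seed_index: int = -1

    def __len__(self) -> int:
        return len(self.points)

    @property
    def length(self) -> float:
        return float(np.linalg.norm(np.diff(self.points, axis=0), axis=1).sum())


@dataclass
class StreamlineSet:
    streamlines: list
    config: TrackingConfig
    seeds: np.ndarray = field(default_factory=lambda: np.zeros((0, 2)))

    def __len__(self) -> int:
        return len(self.streamlines)

    def summary(self) -> dict:
        """Aggregate statistics for provenance/QC JSON."""
        hist = {r: 0 for r in TERMINATION_REASONS}
        for sl in self.streamlines:
            for reason in sl.termination_reason:
                hist[reason] += 1
        lengths = [sl.length for sl in self.streamlines]
        return {
            "streamline_count": len(self.streamlines),
            "mean_length_px": float(np.mean(lengths)) if lengths else 0.0,
            "total_points": int(sum(len(sl) for sl in self.streamlines)),
            "termination_reasons": hist,
            "config": asdict(self.config),
            "seed_count": int(len(self.seeds)),
        }


def interpolate_tensor(tv: TensorVolume, pos, rng) -> tuple[np.ndarray, tuple]:
    """Probabilistic nearest-neighbor draw of a voxel tensor at ``pos``.

    One of the <= 4 voxels surrounding the continuous position ``(x, y)`` is
    selected with probability equal to its bilinear weight; returns the
    selected voxel's in-plane 2x2 tensor and its ``(row, col)`` index.
    Positions outside the grid raise :class:`OutOfDomain`.
    """
    x, y = float(pos[0]), float(pos[1])
    h, w = tv.shape
    if not (0.0 <= x <= w - 1 and 0.0 <= y <= h - 1):
        raise OutOfDomain(f"position ({x:.3f}, {y:.3f}) outside grid {w}x{h}")
    x0, y0 = int(np.floor(x)), int(np.floor(y))
    fx, fy = x - x0, y - y0
    # bilinear weights of (x0,y0), (x0+1,y0), (x0,y0+1), (x0+1,y0+1)
    u = rng.random()
    if u < (1 - fx) * (1 - fy):
        ix, iy = x0, y0
    elif u < (1 - fy):
        ix, iy = x0 + 1, y0
    elif u < (1 - fy) + fy * (1 - fx):
        ix, iy = x0, y0 + 1
    else:
        ix, iy = x0 + 1, y0 + 1
    ix, iy = min(ix, w - 1), min(iy, h - 1)
    d = tv.d[iy, ix]
    return np.array([[d[0], d[1]], [d[1], d[3]]]), (iy, ix)


#: eigenvalue-gap tolerance (relative to trace) below which a tensor counts
#: as isotropic for direction extraction
_DIR_TOL = 1e-9


def principal_direction(tensor: np.ndarray, prev_dir=None):
    """In-plane principal eigenvector, sign-aligned to the previous direction.

    Returns a unit 2-vector, or ``None`` for a zero/isotropic tensor (the
    ``zero_tensor`` termination signal).  Without a previous direction the
    sign is chosen toward positive x, ties toward positive y.
    """
    gxx, gxy, gyy = tensor[0, 0], tensor[0, 1], tensor[1, 1]
    tr = gxx + gyy
    half_gap = np.hypot((gxx - gyy) * 0.5, gxy)
    if tr <= 0 or 2.0 * half_gap <= _DIR_TOL * tr:
        return None
    lam1 = tr * 0.5 + half_gap
    if abs(gxy) > 0:
        v = np.array([gxy, lam1 - gxx])
    else:
        v = np.array([1.0, 0.0]) if gxx >= gyy else np.array([0.0, 1.0])
    v = v / np.linalg.norm(v)
    if prev_dir is not None:
        if float(np.dot(v, prev_dir)) < 0:
            v = -v
    elif v[0] < 0 or (v[0] == 0 and v[1] < 0):
        v = -v
    return v


class _Termination(Exception):
    def __init__(self, reason: str):
        self.reason = reason


def _field_dir(tv, fa_vals, pos, ref_dir, cfg, rng, brain=None):
    """Direction of the tensor field at ``pos``, sign-aligned to ``ref_dir``.

    Raises _Termination on leaving the grid or brain mask (checked first:
    the mask rule takes precedence over all others), low FA, isotropy, or a
    stage turn at or beyond the curve threshold (sharp orientation
    discontinuities must not be smeared through the RK averaging)."""
    if brain is not None and not _in_mask(brain, pos):
        raise _Termination("mask_exit")
    try:
        tensor, idx = interpolate_tensor(tv, pos, rng)
    except OutOfDomain:
        raise _Termination("mask_exit")
    if fa_vals is not None and fa_vals[idx] <= cfg.fa_min:
        raise _Termination("low_fa")
    v = principal_direction(tensor, ref_dir)
    if v is None:
        raise _Termination("zero_tensor")
    if ref_dir is not None:
        ang = np.degrees(np.arccos(np.clip(float(np.dot(v, ref_dir)), -1.0, 1.0)))
        if ang >= cfg.curve_threshold_deg:
            raise _Termination("high_curvature")
    return v, idx


def rk4_step(tv: TensorVolume, pos, direction, cfg: TrackingConfig, rng,
             fa_vals=None, brain=None):
    """One classical 4-stage Runge-Kutta step through the direction field.

    Each stage direction is sign-aligned to the incoming step direction
    (tensor fields carry axial, not polar, orientations).  The combined RK
    increment is renormalized so the step has length exactly ``cfg.step_px``.
    """
    h = cfg.step_px
    k1, _ = _field_dir(tv, fa_vals, pos, direction, cfg, rng, brain)
    k2, _ = _field_dir(tv, fa_vals, pos + 0.5 * h * k1, direction, cfg, rng, brain)
    k3, _ = _field_dir(tv, fa_vals, pos + 0.5 * h * k2, direction, cfg, rng, brain)
    k4, _ = _field_dir(tv, fa_vals, pos + h * k3, direction, cfg, rng, brain)
    v = k1 + 2.0 * k2 + 2.0 * k3 + k4
    n = np.linalg.norm(v)
    if n == 0:
        raise _Termination("high_curvature")
    return pos + h * (v / n)


def _in_mask(brain: MaskImage, pos) -> bool:
    h, w = brain.shape
    ix, iy = int(round(pos[0])), int(round(pos[1]))
    if not (0 <= ix < w and 0 <= iy < h):
        return False
    return bool(brain.values[iy, ix])


def _track_one_direction(tv, fa_vals, brain, seed_pos, launch_dir, cfg, rng):
    """March from the seed along one launch direction; returns (points, reason)."""
    pts = [np.asarray(seed_pos, dtype=np.float64)]
    direction = launch_dir
    prev_seg = None
    for _ in range(cfg.max_steps):
        try:
            nxt = rk4_step(tv, pts[-1], direction, cfg, rng, fa_vals, brain)
        except _Termination as t:
            return pts, t.reason
        seg = nxt - pts[-1]
        if prev_seg is not None:
            cosang = float(np.dot(seg, prev_seg)) / (
                np.linalg.norm(seg) * np.linalg.norm(prev_seg))
            ang = np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0)))
            if ang >= cfg.curve_threshold_deg:
                return pts, "high_curvature"
        if not _in_mask(brain, nxt):
            return pts, "mask_exit"
        # FA stopping uses the voxel drawn by the probabilistic interpolation
        # at the accepted new position (consistent with the tracking substrate)
        try:
            tensor, idx = interpolate_tensor(tv, nxt, rng)
        except OutOfDomain:
            return pts, "mask_exit"
        if fa_vals is not None and fa_vals[idx] <= cfg.fa_min:
            pts.append(nxt)
            return pts, "low_fa"
        pts.append(nxt)
        nd = principal_direction(tensor, seg / np.linalg.norm(seg))
        if nd is None:
            return pts, "zero_tensor"
        direction = nd
        prev_seg = seg
    return pts, "max_steps"


def _colorize(points: np.ndarray) -> np.ndarray:
    """Per-point RGB from local segment orientation (hue wheel)."""
    if len(points) < 2:
        return np.full((len(points), 3), 255, dtype=np.uint8)
    segs = np.diff(points, axis=0)
    theta = fiber_angle_deg(segs[:, 0], segs[:, 1])
    theta_pts = np.concatenate([[theta[0]], theta])  # first point takes first segment
    return orientation_rgb(theta_pts)


def track_seed(tv: TensorVolume, fa: ScalarMap, brain: MaskImage, seed_pos,
               cfg: TrackingConfig, rng) -> list:
    """Track ``cfg.iterations_per_seed`` streamlines from one seed voxel.

    Each iteration launches from the seed center bidirectionally (two
    antiparallel launches joined at the seed) unless ``cfg.bidirectional``
    is off.  Streamlines shorter than ``cfg.min_points`` are discarded.
    """
    seed_pos = np.asarray(seed_pos, dtype=np.float64)
    if not _in_mask(brain, seed_pos):
        raise ValueError(f"seed {tuple(seed_pos)} lies outside the brain mask")
    fa_vals = fa.values if fa is not None else None
    out = []
    for _ in range(cfg.iterations_per_seed):
        try:
            tensor, _ = interpolate_tensor(tv, seed_pos, rng)
        except OutOfDomain:
            continue
        d0 = principal_direction(tensor, None)
        if d0 is None:
            continue
        fwd_pts, fwd_reason = _track_one_direction(tv, fa_vals, brain, seed_pos, d0, cfg, rng)
        if cfg.bidirectional:
            bwd_pts, bwd_reason = _track_one_direction(tv, fa_vals, brain, seed_pos, -d0, cfg, rng)
        else:
            bwd_pts, bwd_reason = [seed_pos], fwd_reason
        pts = np.array(bwd_pts[::-1] + fwd_pts[1:])
        if len(pts) < cfg.min_points:
            continue
        out.append(Streamline(points=pts, colors=_colorize(pts),
                              termination_reason=(bwd_reason, fwd_reason)))
    return out


def track_all(tv: TensorVolume, fa: ScalarMap, brain: MaskImage,
              seeds: MaskImage, cfg: TrackingConfig) -> StreamlineSet:
    """Track every voxel of the seed mask with a per-seed RNG substream.

    Substream ``i`` is seeded from ``(cfg.rng_seed, i)`` so results are
    independent of execution order and bit-reproducible for a fixed seed.
    """
    seed_rc = np.argwhere(seeds.values)  # (row, col)
    streamlines = []
    seed_xy = seed_rc[:, ::-1].astype(np.float64)
    for i, (x, y) in enumerate(seed_xy):
        rng = np.random.default_rng([int(cfg.rng_seed), i])
        for sl in track_seed(tv, fa, brain, (x, y), cfg, rng):
            sl.seed_index = i
            streamlines.append(sl)
    logger.info("tracked %d streamlines from %d seeds", len(streamlines), len(seed_xy))
    return StreamlineSet(streamlines=streamlines, config=cfg, seeds=seed_xy)


# ---------------------------------------------------------------------------
# legacy ASCII VTK polydata I/O

def write_vtk(ss: StreamlineSet, path) -> Path:
    """Write streamlines as legacy ASCII VTK polydata.

    POINTS (z = 0), LINES connectivity, and a per-point 3-component
    unsigned-char array ``eigvec_color`` holding the orientation hue-wheel
    color of the local principal eigenvector.
    """
    path = Path(path)
    if len(ss) == 0:
        logger.warning("writing empty streamline set to %s", path)
    npts = sum(len(sl) for sl in ss.streamlines)
    lines = []
    lines.append("# vtk DataFile Version 3.0")
    lines.append("histotract streamlines")
    lines.append("ASCII")
    lines.append("DATASET POLYDATA")
    lines.append(f"POINTS {npts} float")
    for sl in ss.streamlines:
        for x, y in sl.points:
            lines.append(f"{x:.6f} {y:.6f} 0.000000")
    total_ints = sum(len(sl) + 1 for sl in ss.streamlines)
    lines.append(f"LINES {len(ss)} {total_ints}")
    offset = 0
    for sl in ss.streamlines:
        idx = " ".join(str(offset + j) for j in range(len(sl)))
        lines.append(f"{len(sl)} {idx}")
        offset += len(sl)
    lines.append(f"POINT_DATA {npts}")
    lines.append("COLOR_SCALARS eigvec_color 3")
    for sl in ss.streamlines:
        for r, g, b in sl.colors:
            lines.append(f"{r / 255.0:.6f} {g / 255.0:.6f} {b / 255.0:.6f}")
    try:
        path.write_text("\n".join(lines) + "\n")
    except OSError as exc:
        raise OSError(f"cannot write VTK file {path}: {exc}") from exc
    return path


def read_vtk_polylines(path) -> tuple[np.ndarray, list, np.ndarray]:
    """Parse a legacy ASCII VTK polydata file written by :func:`write_vtk`.

    Returns (points (N,3), list of index lists, colors (N,3) uint8).
    Intended for round-trip verification, not as a general VTK reader.
    """
    text = Path(path).read_text().split("\n")
    i = 0
    points, polylines, colors = np.zeros((0, 3)), [], np.zeros((0, 3), dtype=np.uint8)
    while i < len(text):
        line = text[i].strip()
        if line.startswith("POINTS"):
            n = int(line.split()[1])
            vals = []
            i += 1
            while len(vals) < 3 * n:
                vals.extend(float(t) for t in text[i].split())
                i += 1
            points = np.array(vals).reshape(n, 3)
            continue
        if line.startswith("LINES"):
            nlines = int(line.split()[1])
            i += 1
            for _ in range(nlines):
                toks = [int(t) for t in text[i].split()]
                polylines.append(toks[1:1 + toks[0]])
                i += 1
            continue
        if line.startswith("COLOR_SCALARS"):
            n = points.shape[0]
            vals = []
            i += 1
            while len(vals) < 3 * n:
                vals.extend(float(t) for t in text[i].split())
                i += 1
            colors = np.clip(np.floor(np.array(vals).reshape(n, 3) * 255.0 + 0.5),
                             0, 255).astype(np.uint8)
            continue
        i += 1
    return points, polylines, colors


def arc_subtended_deg(points: np.ndarray, center) -> float:
    """Unwrapped angle (degrees) a polyline subtends around ``center``.

    Used to quantify how far a streamline follows a curved bundle.
    """
    cx, cy = center
    ang = np.unwrap(np.arctan2(points[:, 1] - cy, points[:, 0] - cx))
    return float(np.degrees(abs(ang[-1] - ang[0])))
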