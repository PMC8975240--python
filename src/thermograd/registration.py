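"""Planar (projective) registration between the IR and color cameras.

The two cameras view an approximately planar scene (a child lying in a PICU
bed, or a flat calibration board), so a single 3x3 homography maps IR pixel
coordinates onto color-frame coordinates.  The homography is estimated from
point correspondences — in practice the inner corners of a dual-emissivity
checkerboard, whose aluminium squares appear cold/dark to the IR sensor
while the printed pattern is seen by the color camera.

Coordinate convention (used throughout the package): pixel centers at
integer coordinates, origin (0, 0) at the top-left, x rightward, y downward.

Estimation is a Hartley-normalized direct linear transform (DLT) solved by
SVD, with an optional random-sample-consensus mode for outlying
correspondences.  Warping and sub-pixel corner refinement are delegated to
scikit-image.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage.feature import corner_subpix, peak_local_max
from skimage.transform import ProjectiveTransform, warp

from .errors import (
    BoardDetectionError,
    DegenerateGeometryError,
    DomainError,
    InsufficientDataError,
    SingularTransformError,
)


@dataclass
class PlanarTransform:
    """3x3 projective mapping from ``src_space`` pixels to ``dst_space`` pixels.

    The matrix is normalized so its bottom-right element equals 1 whenever
    that element is nonzero.  ``rmse`` carries the reprojection RMSE of the
    correspondences the transform was estimated from, if any.
    """

    matrix: np.ndarray
    src_space: str = "ir"
    dst_space: str = "rgb"
    rmse: float | None = None

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        if m.shape != (3, 3):
            raise DomainError("transform matrix must be 3x3")
        if abs(np.linalg.det(m)) < 1e-12 * max(1.0, np.abs(m).max() ** 3):
            raise SingularTransformError("transform matrix is singular")
        if m[2, 2] != 0:
            m = m / m[2, 2]
        self.matrix = m

    def apply(self, points) -> np.ndarray:
        """Map (n, 2) src-space points to dst space."""
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        h = self.matrix @ np.vstack([pts.T, np.ones(len(pts))])
        return (h[:2] / h[2]).T

    def inverse(self) -> "PlanarTransform":
        return PlanarTransform(np.linalg.inv(self.matrix),
                               src_space=self.dst_space, dst_space=self.src_space)

    def compose(self, other: "PlanarTransform") -> "PlanarTransform":
        """Return the transform applying ``other`` first, then ``self``."""
        return PlanarTransform(self.matrix @ other.matrix,
                               src_space=other.src_space, dst_space=self.dst_space)

    @classmethod
    def identity(cls, space: str = "ir") -> "PlanarTransform":
        return cls(np.eye(3), src_space=space, dst_space=space)

    # -- JSON round trip ----------------------------------------------------
    def to_json(self, path: str | Path) -> None:
        payload = {
            "matrix": self.matrix.tolist(),
            "src_space": self.src_space,
            "dst_space": self.dst_space,
            "reprojection_rmse": self.rmse,
        }
        Path(path).write_text(json.dumps(payload, indent=2) + "\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "PlanarTransform":
        payload = json.loads(Path(path).read_text())
        return cls(np.asarray(payload["matrix"], dtype=float),
                   src_space=payload.get("src_space", "ir"),
                   dst_space=payload.get("dst_space", "rgb"),
                   rmse=payload.get("reprojection_rmse"))


@dataclass
class CorrespondenceSet:
    """Paired pixel coordinates in two frames, (n, 2) each, (x, y) order."""

    src_points: np.ndarray
    dst_points: np.ndarray

    def __post_init__(self) -> None:
        src = np.atleast_2d(np.asarray(self.src_points, dtype=float))
        dst = np.atleast_2d(np.asarray(self.dst_points, dtype=float))
        if src.shape != dst.shape or src.ndim != 2 or src.shape[1] != 2:
            raise DomainError("src and dst must be (n, 2) arrays of equal length")
        if len(src) != len(np.unique(src, axis=0)):
            raise DomainError("duplicate src points")
        self.src_points, self.dst_points = src, dst

    def __len__(self) -> int:
        return len(self.src_points)

    def to_csv(self, path: str | Path) -> None:
        pd.DataFrame({
            "src_x": self.src_points[:, 0], "src_y": self.src_points[:, 1],
            "dst_x": self.dst_points[:, 0], "dst_y": self.dst_points[:, 1],
        }).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path) -> "CorrespondenceSet":
        df = pd.read_csv(path)
        return cls(df[["src_x", "src_y"]].to_numpy(),
                   df[["dst_x", "dst_y"]].to_numpy())


# ---------------------------------------------------------------------------
# Homography estimation

def _hartley_normalization(pts: np.ndarray) -> np.ndarray:
    """Similarity transform bringing points to zero centroid, mean norm sqrt(2)."""
    centroid = pts.mean(axis=0)
    dist = np.sqrt(((pts - centroid) ** 2).sum(axis=1)).mean()
    scale = np.sqrt(2) / dist if dist > 0 else 1.0
    return np.array([[scale, 0, -scale * centroid[0]],
                     [0, scale, -scale * centroid[1]],
                     [0, 0, 1.0]])


def _dlt(src: np.ndarray, dst: np.ndarray) -> np.ndarray:
    """Normalized DLT homography from exact/overdetermined correspondences."""
    t_src = _hartley_normalization(src)
    t_dst = _hartley_normalization(dst)
    sh = (t_src @ np.vstack([src.T, np.ones(len(src))]))
    dh = (t_dst @ np.vstack([dst.T, np.ones(len(dst))]))
    sx, sy = sh[0] / sh[2], sh[1] / sh[2]
    dx, dy = dh[0] / dh[2], dh[1] / dh[2]
    zeros = np.zeros_like(sx)
    ones = np.ones_like(sx)
    rows_x = np.stack([-sx, -sy, -ones, zeros, zeros, zeros,
                       dx * sx, dx * sy, dx], axis=1)
    rows_y = np.stack([zeros, zeros, zeros, -sx, -sy, -ones,
                       dy * sx, dy * sy, dy], axis=1)
    a = np.concatenate([rows_x, rows_y])
    _, s, vt = np.linalg.svd(a)
    if s[-2] < 1e-9 * s[0]:
        raise DegenerateGeometryError(
            "correspondences are rank-deficient (collinear configuration)")
    h_norm = vt[-1].reshape(3, 3)
    h = np.linalg.inv(t_dst) @ h_norm @ t_src
    if abs(np.linalg.det(h)) < 1e-12:
        raise DegenerateGeometryError("estimated homography is singular")
    return h / h[2, 2] if h[2, 2] != 0 else h


def estimate_planar_transform(
    correspondences: CorrespondenceSet,
    src_space: str = "ir",
    dst_space: str = "rgb",
    robust: bool = False,
    inlier_threshold_px: float = 2.0,
    n_trials: int = 500,
    seed: int = 0,
) -> PlanarTransform:
    """Least-squares projective fit from >= 4 point correspondences.

    Plain Hartley-normalized DLT by default; with ``robust=True`` a seeded
    random-minimal-sample consensus (4-point samples, reprojection-distance
    inlier test) precedes a final least-squares fit on the inliers.  The
    reprojection RMSE of the fitted pairs is stored on the result.
    """
    if len(correspondences) < 4:
        raise InsufficientDataError(
            f"need >= 4 correspondences, got {len(correspondences)}")
    src, dst = correspondences.src_points, correspondences.dst_points

    if robust:
        rng = np.random.default_rng(seed)
        best_inliers = None
        for _ in range(n_trials):
            pick = rng.choice(len(src), size=4, replace=False)
            try:
                h = _dlt(src[pick], dst[pick])
            except DegenerateGeometryError:
                continue
            proj = PlanarTransform(h).apply(src)
            err = np.sqrt(((proj - dst) ** 2).sum(axis=1))
            inliers = err < inlier_threshold_px
            if best_inliers is None or inliers.sum() > best_inliers.sum():
                best_inliers = inliers
        if best_inliers is None or best_inliers.sum() < 4:
            raise DegenerateGeometryError("consensus search found no valid model")
        src, dst = src[best_inliers], dst[best_inliers]

    matrix = _dlt(src, dst)
    transform = PlanarTransform(matrix, src_space=src_space, dst_space=dst_space)
    transform.rmse = reprojection_rmse(
        transform, CorrespondenceSet(src, dst))
    return transform


def reprojection_rmse(transform: PlanarTransform,
                      correspondences: CorrespondenceSet) -> float:
    """RMS Euclidean distance between mapped src points and dst points."""
    if len(correspondences) == 0:
        raise DomainError("empty correspondence set")
    proj = transform.apply(correspondences.src_points)
    return float(np.sqrt(((proj - correspondences.dst_points) ** 2)
                         .sum(axis=1).mean()))


# ---------------------------------------------------------------------------
# Warping and overlay

_ORDERS = {"nearest": 0, "bilinear": 1}


def warp_frame(frame, transform: PlanarTransform, out_shape: tuple[int, int],
               interpolation: str = "bilinear", fill: float = 0.0) -> np.ndarray:
    """Warp a 2-D grid from src space into dst space.

    Each output pixel is sampled from the source at the inverse-mapped
    location; locations outside the source get ``fill``.
    """
    if interpolation not in _ORDERS:
        raise ValueError(f"interpolation must be one of {sorted(_ORDERS)}")
    frame = np.asarray(frame, dtype=float)
    inv = np.linalg.inv(transform.matrix)  # dst -> src, (x, y) homogeneous
    return warp(frame, ProjectiveTransform(matrix=inv),
                output_shape=out_shape, order=_ORDERS[interpolation],
                cval=fill, mode="constant", preserve_range=True)


def compose_overlay(color: np.ndarray, warped_temps, opacity: float,
                    cmap: str = "inferno",
                    t_range: tuple[float, float] | None = None) -> np.ndarray:
    """Alpha-blend a colormapped temperature layer over an RGB frame.

    ``color`` is (h, w, 3) float in [0, 1] or uint8; the return value matches
    the input convention.  ``opacity`` 0 returns the color frame unchanged,
    1 returns the pure colormapped thermal layer.
    """
    if not 0.0 <= opacity <= 1.0:
        raise DomainError("opacity must lie in [0, 1]")
    temps = np.asarray(getattr(warped_temps, "celsius", warped_temps), dtype=float)
    color = np.asarray(color)
    if color.ndim != 3 or color.shape[2] != 3 or color.shape[:2] != temps.shape:
        raise DomainError("color and temperature layers must share (h, w)")
    as_uint8 = color.dtype == np.uint8
    base = color.astype(float) / 255.0 if as_uint8 else color.astype(float)
    if opacity == 0.0:
        return color.copy()
    import matplotlib
    lo, hi = t_range if t_range is not None else (np.nanmin(temps), np.nanmax(temps))
    span = hi - lo if hi > lo else 1.0
    layer = matplotlib.colormaps[cmap]((temps - lo) / span)[..., :3]
    out = (1.0 - opacity) * base + opacity * layer
    return (np.round(out * 255).astype(np.uint8)) if as_uint8 else out


# ---------------------------------------------------------------------------
# Checkerboard corner detection

def detect_checkerboard_corners(image: np.ndarray,
                                inner_grid: tuple[int, int],
                                min_separation_px: float | None = None,
                                refine_window_px: int = 9) -> np.ndarray:
    """Locate the inner corners of a full checkerboard, ordered row-major.

    Inner corners of a checkerboard are saddle points of image intensity;
    they are localized with a determinant-of-Hessian saddle response, picked
    as the ``rows * cols`` strongest peaks, refined to sub-pixel precision
    (Foerstner), and ordered into a row-major grid anchored at the extreme
    corner nearest the image origin.  Ordering uses point geometry only, so
    it is identical for a color rendering and a contrast-inverted thermal
    rendering of the same board pose.

    Returns an (rows*cols, 2) array of (x, y) corner coordinates.
    """
    rows, cols = inner_grid
    if rows < 2 or cols < 2:
        raise DomainError("inner grid must be at least 2x2")
    n = rows * cols
    img = np.asarray(image, dtype=float)
    if img.ndim == 3:
        img = img.mean(axis=2)
    span = np.ptp(img)
    if span < 1e-9:
        raise BoardDetectionError("image is uniform; no board visible")
    img = (img - img.min()) / span

    sm = ndimage.gaussian_filter(img, 1.2)
    gxx = ndimage.sobel(ndimage.sobel(sm, axis=1), axis=1)
    gyy = ndimage.sobel(ndimage.sobel(sm, axis=0), axis=0)
    gxy = ndimage.sobel(ndimage.sobel(sm, axis=1), axis=0)
    saddle = gxy ** 2 - gxx * gyy  # > 0 where the Hessian is indefinite

    min_dist = 3 if min_separation_px is None else max(1, int(min_separation_px))
    peaks = peak_local_max(saddle, min_distance=min_dist, num_peaks=n,
                           exclude_border=2, threshold_rel=0.1)
    if len(peaks) < n:
        raise BoardDetectionError(
            f"found only {len(peaks)} of {n} corners; board absent, partially "
            f"visible, or too small")

    refined = corner_subpix(img, peaks.astype(float),
                            window_size=refine_window_px)
    failed = np.isnan(refined).any(axis=1)
    refined[failed] = peaks[failed]
    points = refined[:, ::-1]  # (row, col) -> (x, y)
    return _order_corner_grid(points, rows, cols)


def _order_corner_grid(points: np.ndarray, rows: int, cols: int) -> np.ndarray:
    """Order scattered corner detections into a row-major grid.

    The four extreme detections anchor a homography from the unit inner-corner
    grid; every detection is then snapped to its nearest grid node.  The
    anchor corner (grid origin) is the extreme point with the smallest x + y,
    which resolves the board's 180-degree ambiguity deterministically.
    """
    s = points.sum(axis=1)
    d = points[:, 0] - points[:, 1]
    extremes = np.array([points[np.argmin(s)], points[np.argmax(d)],
                         points[np.argmax(s)], points[np.argmin(d)]])
    unit = np.array([[0, 0], [cols - 1, 0], [cols - 1, rows - 1],
                     [0, rows - 1]], dtype=float)
    h = _dlt(unit, extremes)
    h_inv = np.linalg.inv(h)
    hp = h_inv @ np.vstack([points.T, np.ones(len(points))])
    uv = (hp[:2] / hp[2]).T
    ij = np.round(uv).astype(int)
    grid = np.full((rows, cols, 2), np.nan)
    for (u, v), p in zip(ij, points):
        if 0 <= u < cols and 0 <= v < rows and np.isnan(grid[v, u]).all():
            grid[v, u] = p
    if np.isnan(grid).any():
        missing = int(np.isnan(grid[..., 0]).sum())
        raise BoardDetectionError(
            f"grid assembly failed: {missing} node(s) unassigned "
            f"(detections off-grid or duplicated)")
    return grid.reshape(-1, 2)
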