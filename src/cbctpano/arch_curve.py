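"""Dental arch curve creation from the axial MIP.

Stage order: k-means++ bone segmentation, spatial-quadrangle isolation of
the dental arch, least-squares parabola fit in a PCA-rotated frame,
symmetric control-point selection, Hermite cubic spline (Catmull-Rom
tangents), and uniform arc-length sampling of perpendicular lines.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy.interpolate import CubicHermiteSpline


class ArchExtractionError(RuntimeError):
    pass


# ---------------------------------------------------------------------------
# k-means helper (shared with per-section tooth segmentation)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class LabelThreshold:
    """Result of 1-D intensity clustering: sorted centers + bone threshold."""

    k: int
    cluster_centers: tuple[float, ...]
    threshold: float
    seed: int


def kmeans_intensity(values: np.ndarray, k: int, seed: int) -> tuple[np.ndarray, np.ndarray]:
    """1-D k-means++ (seeded init, Lloyd to convergence) on raw intensities.

    Returns ``(labels, sorted_centers)`` where labels index the sorted
    centers (0 = darkest cluster).  ``k`` is reduced with a warning when the
    data has fewer distinct values.
    """
    from sklearn.cluster import KMeans

    values = np.asarray(values, dtype=float).ravel()
    n_distinct = np.unique(values).size
    if n_distinct < 2:
        raise ArchExtractionError("cannot cluster an image with a single intensity value")
    if n_distinct < k:
        warnings.warn(f"only {n_distinct} distinct values; reducing k from {k}")
        k = n_distinct
    km = KMeans(n_clusters=k, init="k-means++", n_init=1, random_state=seed)
    raw_labels = km.fit_predict(values[:, None])
    centers = km.cluster_centers_.ravel()
    order = np.argsort(centers)
    remap = np.empty_like(order)
    remap[order] = np.arange(k)
    return remap[raw_labels], centers[order]


def segment_bone(mip, k: int = 5, seed: int = 0,
                 top_clusters: int | str = "auto", merge_ratio: float = 0.8):
    """Segment the bone area (dental arch + jaws) in the MIP image.

    Pixels assigned to the highest-center intensity cluster(s) form the
    bone mask.  ``top_clusters`` may be an integer count or ``"auto"``, in
    which case every cluster whose center is at least ``merge_ratio`` of
    the top center is included — enamel and dense cortical bone are close
    in intensity and can land in separate clusters on clean data but in a
    single cluster on noisy data.  Returns ``(mask, LabelThreshold)``.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    data = np.asarray(mip.data, dtype=float)
    labels, centers = kmeans_intensity(data, k, seed)
    k_eff = centers.size
    if top_clusters == "auto":
        n_top = int(np.sum(centers >= merge_ratio * centers[-1]))
    else:
        n_top = int(top_clusters)
    n_top = min(max(n_top, 1), k_eff - 1)
    cut = k_eff - n_top
    mask = (labels >= cut).reshape(data.shape)
    if not mask.any():
        raise ArchExtractionError("empty bone mask")
    threshold = float((centers[cut - 1] + centers[cut]) / 2.0)
    return mask, LabelThreshold(k=k_eff, cluster_centers=tuple(float(c) for c in centers),
                                threshold=threshold, seed=seed)


# ---------------------------------------------------------------------------
# spatial quadrangle
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Quadrangle:
    """Axis-aligned rectangle about the bone centroid covering >= p of the mask."""

    center: tuple[float, float]
    half_extents: tuple[float, float]
    covered_fraction: float

    def contains(self, xy: np.ndarray) -> np.ndarray:
        cx, cy = self.center
        hx, hy = self.half_extents
        xy = np.asarray(xy, dtype=float)
        return (np.abs(xy[..., 0] - cx) <= hx) & (np.abs(xy[..., 1] - cy) <= hy)


def spatial_quadrangle(mask: np.ndarray, p: float = 0.75) -> Quadrangle:
    """Smallest centroid-anchored rectangle covering >= p of the mask pixels.

    The rectangle grows from zero with its aspect ratio fixed to the mask's
    per-axis standard-deviation ratio, so it adapts to the arch footprint.
    """
    if not (0.0 < p < 1.0):
        raise ValueError("p must be in (0, 1)")
    pts = np.argwhere(mask).astype(float)
    if pts.size == 0:
        raise ArchExtractionError("empty mask")
    center = pts.mean(axis=0)
    std = pts.std(axis=0)
    std = np.where(std < 0.5, 0.5, std)  # degenerate flat masks still grow
    offsets = np.abs(pts - center)
    # scale t such that the box t*std covers each point: per-point minimum t
    t_needed = np.max(offsets / std, axis=1)
    t_sorted = np.sort(t_needed)
    idx = int(np.ceil(p * len(t_sorted))) - 1
    t = float(t_sorted[max(idx, 0)])
    covered = float(np.mean(t_needed <= t))
    return Quadrangle(center=(float(center[0]), float(center[1])),
                      half_extents=(float(t * std[0]), float(t * std[1])),
                      covered_fraction=covered)


def isolate_arch(mask: np.ndarray, quad: Quadrangle) -> np.ndarray:
    """Logical AND of the bone mask with the quadrangle interior."""
    pts = np.argwhere(mask)
    keep = quad.contains(pts)
    out = np.zeros_like(mask)
    out[tuple(pts[keep].T)] = True
    if not out.any():
        raise ArchExtractionError("no dental arch found (quadrangle disjoint from mask)")
    return out


# ---------------------------------------------------------------------------
# parabola fit
# ---------------------------------------------------------------------------

@dataclass
class Parabola:
    """y = a x^2 + b x + c in a PCA-rotated, centroid-centered frame."""

    coeffs: tuple[float, float, float]
    rotation: float          # radians; rotated frame -> original frame
    center: tuple[float, float]  # rotation pivot (mask centroid), original coords

    def _rot(self):
        c, s = np.cos(self.rotation), np.sin(self.rotation)
        return np.array([[c, -s], [s, c]])

    def to_rotated(self, xy: np.ndarray) -> np.ndarray:
        xy = np.atleast_2d(np.asarray(xy, dtype=float))
        return (xy - np.asarray(self.center)) @ self._rot()

    def to_original(self, xy_rot: np.ndarray) -> np.ndarray:
        xy_rot = np.atleast_2d(np.asarray(xy_rot, dtype=float))
        return xy_rot @ self._rot().T + np.asarray(self.center)

    def y_rot(self, x_rot: np.ndarray) -> np.ndarray:
        a, b, c = self.coeffs
        x_rot = np.asarray(x_rot, dtype=float)
        return a * x_rot**2 + b * x_rot + c

    @property
    def apex_rot(self) -> tuple[float, float]:
        a, b, c = self.coeffs
        x = -b / (2 * a)
        return (x, a * x**2 + b * x + c)

    def apex(self) -> np.ndarray:
        """Apex position in original image coordinates."""
        return self.to_original(np.asarray(self.apex_rot))[0]


def fit_parabola(mask: np.ndarray, image_shape: Optional[tuple[int, int]] = None) -> Parabola:
    """Least-squares parabola through all mask pixel coordinates.

    The fit is performed in a frame rotated so the mask's minor principal
    axis (the arch's axis of symmetry) is vertical, which makes the method
    orientation-invariant.
    """
    pts = np.argwhere(mask).astype(float)
    if pts.shape[0] < 3:
        raise ArchExtractionError("need >= 3 pixels to fit a parabola")
    center = pts.mean(axis=0)
    cov = np.cov((pts - center).T)
    evals, evecs = np.linalg.eigh(cov)
    if evals[0] < 1e-9:
        raise ArchExtractionError("degenerate (collinear) mask; cannot fit a parabola")
    major = evecs[:, np.argmax(evals)]  # arch width direction -> rotated x
    rotation = float(np.arctan2(major[1], major[0]))
    rot = np.array([[np.cos(rotation), -np.sin(rotation)],
                    [np.sin(rotation), np.cos(rotation)]])
    pr = (pts - center) @ rot
    x, y = pr[:, 0], pr[:, 1]
    A = np.column_stack([x**2, x, np.ones_like(x)])
    coeffs, *_ = np.linalg.lstsq(A, y, rcond=None)
    # refine toward the geometric (perpendicular-distance) least-squares fit
    # with Sampson weights: the plain vertical-residual fit lets the steep
    # arch arms dominate and biases the apex on wide masks
    for _ in range(3):
        w = 1.0 / (1.0 + (2 * coeffs[0] * x + coeffs[1]) ** 2)
        Aw = A * w[:, None]
        coeffs, *_ = np.linalg.lstsq(Aw.T @ A, Aw.T @ y, rcond=None)
    a, b, c = (float(v) for v in coeffs)
    if abs(a) < 1e-12:
        raise ArchExtractionError("degenerate fit: leading coefficient is zero")
    pb = Parabola(coeffs=(a, b, c), rotation=rotation,
                  center=(float(center[0]), float(center[1])))
    if image_shape is not None:
        ax, ay = pb.apex()
        if not (0 <= ax < image_shape[0] and 0 <= ay < image_shape[1]):
            warnings.warn("parabola apex falls outside the image bounds")
    return pb


# ---------------------------------------------------------------------------
# control points + Hermite spline
# ---------------------------------------------------------------------------

def _parabola_arclength_rot(pb: Parabola, x_from: float, x_to) -> np.ndarray:
    a, b, _ = pb.coeffs
    xs = np.linspace(x_from, x_to, 513, axis=-1)
    return np.trapezoid(np.sqrt(1.0 + (2 * a * xs + b) ** 2), xs, axis=-1)


def select_control_points(pb: Parabola, mask: np.ndarray, n: int = 7) -> np.ndarray:
    """n (odd) points on the parabola, uniform in arc length about the apex.

    The middle point is the apex; the end points sit at the arc positions of
    the extreme mask pixels projected onto the parabola (the larger of the
    two half-spans, so the whole mask extent is spanned).
    """
    if n % 2 == 0 or n < 3:
        raise ValueError("n must be odd and >= 3")
    pts = np.argwhere(mask).astype(float)
    xr = pb.to_rotated(pts)[:, 0]
    x_apex = pb.apex_rot[0]
    s_lo = float(_parabola_arclength_rot(pb, x_apex, float(xr.min())))
    s_hi = float(_parabola_arclength_rot(pb, x_apex, float(xr.max())))
    s_half = max(abs(s_lo), abs(s_hi))
    if s_half < 1.0:
        raise ArchExtractionError("mask extent too small for control-point selection")
    min_gap = 2.0  # px of arc length between consecutive control points
    while n > 3 and 2 * s_half / (n - 1) < min_gap:
        warnings.warn(f"mask extent {2 * s_half:.1f}px too small for {n} control points; reducing")
        n -= 2
    s_targets = np.linspace(-s_half, s_half, n)
    # invert s(x) by dense sampling
    span = 1.5 * max(abs(float(xr.min()) - x_apex), abs(float(xr.max()) - x_apex)) + 1.0
    xs = np.linspace(x_apex - span, x_apex + span, 4001)
    ss = _parabola_arclength_rot(pb, x_apex, xs)
    x_ctrl = np.interp(s_targets, ss, xs)
    ctrl_rot = np.column_stack([x_ctrl, pb.y_rot(x_ctrl)])
    return pb.to_original(ctrl_rot)


@dataclass
class ArchCurve:
    """Piecewise cubic Hermite interpolant of the arch control points.

    Parameterized by ``t`` in ``[0, n_ctrl - 1]``; ``arclength_table`` maps a
    dense grid of ``t`` to cumulative chord length, enabling arc-length
    lookups in both directions.
    """

    control_points: np.ndarray          # (n, 2)
    tangents: np.ndarray                # (n, 2)
    _spline: CubicHermiteSpline = field(repr=False)
    t_dense: np.ndarray = field(repr=False)
    arclength_table: np.ndarray = field(repr=False)

    @property
    def total_length(self) -> float:
        return float(self.arclength_table[-1])

    def evaluate(self, t) -> np.ndarray:
        return np.asarray(self._spline(t))

    def tangent(self, t) -> np.ndarray:
        d = np.asarray(self._spline.derivative()(t))
        return d / np.linalg.norm(d, axis=-1, keepdims=True)

    def t_at_arclength(self, s) -> np.ndarray:
        return np.interp(s, self.arclength_table, self.t_dense)

    def point_at_arclength(self, s) -> np.ndarray:
        return self.evaluate(self.t_at_arclength(s))

    def interior_centroid(self) -> np.ndarray:
        return self.control_points.mean(axis=0)


def build_hermite_spline(ctrl: np.ndarray, samples_per_segment: int = 200) -> ArchCurve:
    """Hermite cubic spline through the control points.

    Tangents are central finite differences of neighboring control points
    (Catmull-Rom), one-sided at the ends; the cumulative arc-length table is
    built by dense chord-length sampling.
    """
    ctrl = np.asarray(ctrl, dtype=float)
    if ctrl.ndim != 2 or ctrl.shape[1] != 2 or ctrl.shape[0] < 3:
        raise ValueError("need >= 3 control points of dimension 2")
    if np.any(np.all(np.abs(np.diff(ctrl, axis=0)) < 1e-12, axis=1)):
        raise ValueError("duplicate consecutive control points")
    n = ctrl.shape[0]
    tangents = np.empty_like(ctrl)
    tangents[1:-1] = (ctrl[2:] - ctrl[:-2]) / 2.0
    tangents[0] = ctrl[1] - ctrl[0]
    tangents[-1] = ctrl[-1] - ctrl[-2]
    t_knots = np.arange(n, dtype=float)
    spline = CubicHermiteSpline(t_knots, ctrl, tangents, axis=0)
    t_dense = np.linspace(0.0, n - 1.0, (n - 1) * samples_per_segment + 1)
    pts = spline(t_dense)
    seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
    table = np.concatenate([[0.0], np.cumsum(seg)])
    if np.any(np.diff(table) <= 0):
        # collapse strictly-equal entries (possible only for coincident samples)
        table = np.maximum.accumulate(table + np.arange(table.size) * 1e-12)
    return ArchCurve(control_points=ctrl, tangents=tangents, _spline=spline,
                     t_dense=t_dense, arclength_table=table)


# ---------------------------------------------------------------------------
# perpendicular lines
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class NormalLine:
    """A line perpendicular to the arch curve at a given arc position."""

    foot: tuple[float, float]
    direction: tuple[float, float]   # unit vector, outward (convex side)
    half_length: float
    arc_position: float

    @property
    def foot_xy(self) -> np.ndarray:
        return np.asarray(self.foot)

    @property
    def dir_xy(self) -> np.ndarray:
        return np.asarray(self.direction)


def sample_perpendicular_lines(curve: ArchCurve, step_px: float,
                               half_length_px: float) -> list[NormalLine]:
    """Normal lines at uniform arc-length intervals along the curve.

    All normals share one rotation sense of the tangent, chosen so they
    point outward, away from the arch's concave side (the control-point
    centroid); this keeps the orientation consistent along the curve.
    """
    if step_px <= 0 or half_length_px <= 0:
        raise ValueError("step_px and half_length_px must be positive")
    L = curve.total_length
    if step_px > L:
        warnings.warn("step larger than curve length; returning a single mid-curve line")
        s_values = np.array([L / 2.0])
    else:
        n_steps = int(np.floor(L / step_px + 1e-9))
        s_values = np.arange(n_steps + 1) * step_px
        if L - s_values[-1] > 1e-6 * L:
            s_values = np.append(s_values, L)
    ts = curve.t_at_arclength(s_values)
    feet = curve.evaluate(ts)
    tans = curve.tangent(ts)
    # rotate tangent +90deg; flip globally if that points toward the centroid
    normals = np.column_stack([-tans[:, 1], tans[:, 0]])
    centroid = curve.interior_centroid()
    mid = len(s_values) // 2
    if np.dot(normals[mid], feet[mid] - centroid) < 0:
        normals = -normals
    return [
        NormalLine(foot=(float(f[0]), float(f[1])),
                   direction=(float(d[0]), float(d[1])),
                   half_length=float(half_length_px),
                   arc_position=float(s))
        for f, d, s in zip(feet, normals, s_values)
    ]
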