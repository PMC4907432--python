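"""Ground-truth metrics for phantom experiments.

Everything here compares pipeline outputs against the closed-form phantom
truth: arch-curve recovery, surface-to-axis distances, per-tooth tissue
coverage in developed radiographs, slab-thickness sweeps and
mandibular-canal detectability.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .arch_curve import ArchCurve
from .phantom import PhantomTruth, ToothTruth
from .surface import PanoramicSurface
from .synthesis import DevelopedImage


# ---------------------------------------------------------------------------
# geometric distances
# ---------------------------------------------------------------------------

def arch_to_tooth_distance(curve: ArchCurve, truth: PhantomTruth,
                           n_samples: int = 2000) -> float:
    """Mean distance from the true tooth centers (axial projection) to the curve."""
    ts = np.linspace(0, curve.control_points.shape[0] - 1, n_samples)
    pts = curve.evaluate(ts)  # (n, 2)
    centers = np.asarray([t.center[:2] for t in truth.teeth])
    d = np.linalg.norm(centers[:, None, :] - pts[None, :, :], axis=2).min(axis=1)
    return float(d.mean())


def point_to_mesh_distance(points: np.ndarray, vertices: np.ndarray,
                           triangles: np.ndarray) -> np.ndarray:
    """Exact point-to-triangle-mesh distances (vectorized per point chunk).

    For each point: distance to the triangle plane if the projection falls
    inside the triangle, else the minimum distance to the three edges.
    """
    points = np.asarray(points, dtype=float)
    tri = vertices[triangles]                       # (m, 3, 3)
    a, b, c = tri[:, 0], tri[:, 1], tri[:, 2]
    ab, ac = b - a, c - a
    n = np.cross(ab, ac)
    nn = np.einsum("ij,ij->i", n, n)
    nn = np.where(nn < 1e-30, 1e-30, nn)
    out = np.empty(points.shape[0])
    for start in range(0, points.shape[0], 64):
        P = points[start:start + 64]                # (p, 3)
        ap = P[:, None, :] - a[None, :, :]          # (p, m, 3)
        dist_plane = np.einsum("pmi,mi->pm", ap, n) / np.sqrt(nn)[None, :]
        # barycentric coordinates of the in-plane projection
        d00 = np.einsum("ij,ij->i", ab, ab)
        d01 = np.einsum("ij,ij->i", ab, ac)
        d11 = np.einsum("ij,ij->i", ac, ac)
        d20 = np.einsum("pmi,mi->pm", ap, ab)
        d21 = np.einsum("pmi,mi->pm", ap, ac)
        denom = d00 * d11 - d01 * d01
        denom = np.where(np.abs(denom) < 1e-30, 1e-30, denom)
        v = (d11 * d20 - d01 * d21) / denom
        w = (d00 * d21 - d01 * d20) / denom
        inside = (v >= 0) & (w >= 0) & (v + w <= 1)
        d_seg = np.minimum.reduce([
            _point_segment_distance(P, a, b),
            _point_segment_distance(P, b, c),
            _point_segment_distance(P, a, c),
        ])
        d_all = np.where(inside, np.abs(dist_plane), d_seg)
        out[start:start + 64] = d_all.min(axis=1)
    return out


def _point_segment_distance(P: np.ndarray, s0: np.ndarray, s1: np.ndarray) -> np.ndarray:
    """Distances from points (p,3) to segments (m,3)-(m,3), result (p,m)."""
    d = s1 - s0
    dd = np.einsum("ij,ij->i", d, d)
    dd = np.where(dd < 1e-30, 1e-30, dd)
    ap = P[:, None, :] - s0[None, :, :]
    t = np.clip(np.einsum("pmi,mi->pm", ap, d) / dd[None, :], 0.0, 1.0)
    closest = s0[None, :, :] + t[..., None] * d[None, :, :]
    return np.linalg.norm(P[:, None, :] - closest, axis=2)


def surface_to_truth_distances(surf: PanoramicSurface, truth_points: np.ndarray) -> np.ndarray:
    """Distance from each true long-axis sample point to the surface mesh."""
    verts = surf.grid.reshape(-1, 3)
    return point_to_mesh_distance(truth_points, verts, surf.triangles())


def long_axis_fit_deviation(curve_samples: np.ndarray, tooth: ToothTruth,
                            line_foot: np.ndarray, line_dir: np.ndarray) -> float:
    """Max |fitted u(z) - true axis u(z)| over the tooth's z-extent.

    The true axis is intersected with the section plane by projecting it
    onto the line direction (the axis of a tilted tooth lies in the section
    plane through its arch position up to curvature effects).
    """
    z0 = tooth.center[2] - tooth.half_length * abs(tooth.axis[2])
    z1 = tooth.center[2] + tooth.half_length * abs(tooth.axis[2])
    zs = np.arange(int(np.ceil(z0)), int(np.floor(z1)) + 1)
    if zs.size == 0:
        return 0.0
    # parametrize the axis by z (axis[2] != 0 for realistic tilts)
    t = (zs - tooth.center[2]) / tooth.axis[2]
    axis_pts = tooth.center[None, :2] + t[:, None] * tooth.axis[None, :2]
    u_true = (axis_pts - line_foot[None, :]) @ line_dir
    u_fit = curve_samples[zs]
    return float(np.max(np.abs(u_fit - u_true)))


# ---------------------------------------------------------------------------
# developed-image coverage
# ---------------------------------------------------------------------------

def _tooth_arc_position(curve: ArchCurve, center_xy: np.ndarray) -> float:
    """Arc length along the curve of the point nearest to a tooth center."""
    pts = curve.evaluate(curve.t_dense)
    i = int(np.argmin(np.linalg.norm(pts - center_xy[None, :], axis=1)))
    return float(curve.arclength_table[i])


def tooth_column(dev: DevelopedImage, curve: ArchCurve,
                 center_xy: np.ndarray,
                 surf: PanoramicSurface | None = None) -> int:
    """Developed-image column corresponding to a tooth's arch position."""
    s = _tooth_arc_position(curve, center_xy)
    if dev.provenance == "surface":
        if surf is None:
            raise ValueError("surface image requires the PanoramicSurface for mapping")
        w = float(np.interp(s, surf.arc_positions, dev.w_coords))
    else:
        w = s
    return int(np.clip(round(w), 0, dev.data.shape[0] - 1))


@dataclass
class ToothCoverage:
    tooth_id: str
    enamel_hit: bool
    pulp_fraction: float


def coverage_report(dev: DevelopedImage, curve: ArchCurve, truth: PhantomTruth,
                    surf: PanoramicSurface | None = None,
                    pulp_core_fraction: float = 0.6) -> list[ToothCoverage]:
    """Per-tooth tissue visibility in a developed radiograph.

    *Enamel*: some pixel within +-1 of the truth-mapped (w, h) cell at the
    crown-cap rows reaches at least (dentine+enamel)/2.
    *Pulp*: fraction of interior pulp-core rows (central
    ``pulp_core_fraction`` of the axis) whose truth-mapped pixel lies in the
    pulp intensity band, away from both dentine and soft tissue.
    """
    I = truth.intensities
    cfg = truth.config
    enamel_thr = (I["dentine"] + I["enamel"]) / 2.0
    pulp_lo = (I["soft_tissue"] + I["pulp"]) / 2.0
    pulp_hi = (I["pulp"] + I["dentine"]) / 2.0
    r = cfg.crown_radius_px
    r_dent = r - cfg.enamel_thickness_mm / cfg.spacing_mm
    data = dev.data
    nz = data.shape[1]
    out = []
    for t in truth.teeth:
        col = tooth_column(dev, curve, t.center[:2], surf)
        cols = slice(max(col - 1, 0), min(col + 2, data.shape[0]))
        # crown cap: on-axis enamel lies between the dentine and enamel radii
        delta = (r_dent + r) / 2.0
        cap = t.crown_end + t.axis * delta
        row = int(np.clip(round(cap[2]), 0, nz - 1))
        rows = slice(max(row - 1, 0), min(row + 2, nz))
        enamel_hit = bool(np.max(data[cols, rows]) >= enamel_thr)
        # interior pulp core rows
        hl = t.half_length * pulp_core_fraction
        z0 = t.center[2] - hl * abs(t.axis[2])
        z1 = t.center[2] + hl * abs(t.axis[2])
        zs = np.arange(int(np.ceil(z0)), int(np.floor(z1)) + 1)
        zs = zs[(zs >= 0) & (zs < nz)]
        if zs.size == 0:
            out.append(ToothCoverage(t.tooth_id, enamel_hit, 0.0))
            continue
        vals = data[cols, :][:, zs]
        hit = ((vals > pulp_lo) & (vals < pulp_hi)).any(axis=0)
        out.append(ToothCoverage(t.tooth_id, enamel_hit, float(hit.mean())))
    return out


def full_dentition_covered(report: list[ToothCoverage],
                           pulp_threshold: float = 0.7,
                           require_pulp: bool = True) -> bool:
    ok = all(c.enamel_hit for c in report)
    if require_pulp:
        ok = ok and all(c.pulp_fraction >= pulp_threshold for c in report)
    return ok


def min_slab_for_enamel_coverage(render_fn, max_n: int = 41) -> int:
    """Smallest odd slab thickness whose max-aggregated render shows every
    tooth's crown enamel.  ``render_fn(n) -> list[ToothCoverage]``.
    Returns ``max_n + 2`` if no tested thickness achieves coverage."""
    for n in range(1, max_n + 1, 2):
        if full_dentition_covered(render_fn(n), require_pulp=False):
            return n
    return max_n + 2


# ---------------------------------------------------------------------------
# mandibular canal detectability
# ---------------------------------------------------------------------------

def canal_detection_fraction(dev: DevelopedImage, curve: ArchCurve,
                             truth: PhantomTruth,
                             surf: PanoramicSurface | None = None,
                             window: int = 4, locate_tol: int = 2) -> float:
    """Fraction of canal-path columns showing a local intensity minimum.

    For each polyline sample of the true canal, the corresponding developed
    column's profile over rows ``canal_z +- window`` must dip by more than
    5% of the bone/soft-tissue contrast, with the minimum within
    ``locate_tol`` rows of the true canal row.
    """
    if truth.canal_polyline.size == 0:
        raise ValueError("phantom has no canal")
    I = truth.intensities
    dip_thr = 0.05 * (I["jaw_bone"] - I["soft_tissue"])
    data = dev.data
    nz = data.shape[1]
    detected = []
    for p in truth.canal_polyline[::4]:
        col = tooth_column(dev, curve, p[:2], surf)
        zc = int(round(p[2]))
        lo, hi = max(zc - window, 0), min(zc + window + 1, nz)
        profile = data[col, lo:hi]
        if profile.size < 3:
            continue
        dip = float(np.median(profile) - profile.min())
        zmin = lo + int(np.argmin(profile))
        detected.append(dip > dip_thr and abs(zmin - zc) <= locate_tol)
    return float(np.mean(detected)) if detected else 0.0


# ---------------------------------------------------------------------------
# image comparison
# ---------------------------------------------------------------------------

def mean_abs_difference(a: np.ndarray, b: np.ndarray) -> float:
    """Mean absolute difference over the common (cropped) extent."""
    w = min(a.shape[0], b.shape[0])
    h = min(a.shape[1], b.shape[1])
    return float(np.mean(np.abs(a[:w, :h].astype(float) - b[:w, :h].astype(float))))
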