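"""Panoramic curved-surface extraction.

For each normal line of the dental arch curve an oblique sagittal section
is resampled from the volume; teeth are segmented per section by intensity
clustering; a single polynomial long-axis curve u(z) (default quintic) is
fitted through the combined upper+lower tooth mask; the per-section curves
are assembled into a triangle-strip surface whose per-vertex normals come
from local PCA plane fits.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.ndimage import map_coordinates

from .arch_curve import NormalLine, kmeans_intensity
from .volume_io import Volume


class SurfaceError(RuntimeError):
    pass


# ---------------------------------------------------------------------------
# sections
# ---------------------------------------------------------------------------

@dataclass
class SectionImage:
    """Oblique sagittal resampling of the volume along one normal line.

    ``data[iu, iz]``: ``iu`` indexes position along the line
    (``u = iu - half_length``), ``iz`` is the axial slice index.
    """

    data: np.ndarray
    line: NormalLine
    interpolation: str = "bilinear"

    @property
    def half_length(self) -> int:
        return (self.data.shape[0] - 1) // 2

    def u_of_index(self, iu) -> np.ndarray:
        return np.asarray(iu, dtype=float) - self.half_length


def extract_section(vol: Volume, line: NormalLine) -> SectionImage:
    """Resample the volume on the vertical plane through a normal line.

    Sample positions are ``foot + u * direction`` for integer
    ``u in [-half_length, +half_length]`` at every axial slice; in-plane
    interpolation is bilinear, and positions outside the volume take the
    volume's minimum intensity.
    """
    H = int(round(line.half_length))
    us = np.arange(-H, H + 1, dtype=float)
    foot = line.foot_xy
    d = line.dir_xy
    xs = foot[0] + us * d[0]
    ys = foot[1] + us * d[1]
    nz = vol.n_slices
    zs = np.arange(nz, dtype=float)
    cx = np.repeat(xs, nz)
    cy = np.repeat(ys, nz)
    cz = np.tile(zs, us.size)
    fill = float(vol.data.min())
    samples = map_coordinates(vol.data, np.stack([cx, cy, cz]), order=1,
                              mode="constant", cval=fill)
    return SectionImage(data=samples.reshape(us.size, nz), line=line)


def segment_teeth_section(sec: SectionImage, k: int = 4, seed: int = 0,
                          min_area: int = 10) -> np.ndarray:
    """Tooth mask of a section: top k-means++ intensity cluster, despeckled.

    Small connected components (< ``min_area`` px) are removed before
    fitting — least squares on salt noise is catastrophic.  A constant (or
    near-constant) section yields an empty mask, handled downstream by the
    fit fallback.
    """
    from skimage.measure import label

    if k < 2:
        raise ValueError("k must be >= 2")
    data = sec.data
    if np.unique(data).size < 2:
        return np.zeros_like(data, dtype=bool)
    labels, centers = kmeans_intensity(data, k, seed)
    mask = (labels == centers.size - 1).reshape(data.shape)
    if mask.any() and min_area > 1:
        comp = label(mask, connectivity=2)
        counts = np.bincount(comp.ravel())
        small = np.flatnonzero(counts < min_area)
        mask &= ~np.isin(comp, small[small > 0])
    return mask


# ---------------------------------------------------------------------------
# long axial curves
# ---------------------------------------------------------------------------

@dataclass
class LongAxialCurve:
    """Polynomial u(z) describing the tooth long axes in one section."""

    coefficients: Optional[np.ndarray]  # np.polyfit order (highest first), None if fallback
    z_range: tuple[int, int]
    samples: np.ndarray                 # u per axial slice, clamped outside z_range
    source: str                         # fitted | interpolated | fallback_vertical


def fit_long_axial_curve(mask: np.ndarray, degree: int = 5,
                         n_slices: Optional[int] = None,
                         half_length: Optional[int] = None) -> LongAxialCurve:
    """Least-squares polynomial u(z) through the section's tooth pixels.

    The single curve spans both the upper and the lower tooth of the
    section; the bite gap contributes no pixels and the polynomial bridges
    it.  Outside the fitted z-range the curve is clamped to its boundary
    value, which keeps the top/bottom margins free of polynomial blow-up.
    Falls back to a vertical line at u=0 when the mask spans fewer than
    ``degree + 1`` distinct slices.
    """
    if not (1 <= degree <= 7):
        raise ValueError("degree must be in 1..7")
    mask = np.asarray(mask, dtype=bool)
    nz = n_slices or mask.shape[1]
    H = half_length if half_length is not None else (mask.shape[0] - 1) // 2
    iu, iz = np.nonzero(mask)
    zs_all = np.arange(nz, dtype=float)
    if np.unique(iz).size < degree + 1:
        return LongAxialCurve(coefficients=None, z_range=(0, nz - 1),
                              samples=np.zeros(nz), source="fallback_vertical")
    u = iu.astype(float) - H
    z = iz.astype(float)
    coeffs = np.polyfit(z, u, degree)
    z_lo, z_hi = int(iz.min()), int(iz.max())
    zc = np.clip(zs_all, z_lo, z_hi)
    samples = np.clip(np.polyval(coeffs, zc), -H, H)
    return LongAxialCurve(coefficients=coeffs, z_range=(z_lo, z_hi),
                          samples=samples, source="fitted")


# ---------------------------------------------------------------------------
# surface assembly
# ---------------------------------------------------------------------------

@dataclass
class PanoramicSurface:
    """Grid of 3D surface points: one column per arch section, one row per slice."""

    grid: np.ndarray              # (n_sections, n_slices, 3) voxel coords
    validity: np.ndarray          # (n_sections, n_slices) bool
    arc_positions: np.ndarray     # (n_sections,)
    outward_dirs: np.ndarray      # (n_sections, 2) axial outward unit normals
    column_sources: list[str]
    normals: Optional[np.ndarray] = None  # (n_sections, n_slices, 3), unit

    @property
    def n_sections(self) -> int:
        return self.grid.shape[0]

    @property
    def n_slices(self) -> int:
        return self.grid.shape[1]

    def triangles(self) -> np.ndarray:
        """Triangle-strip connectivity between adjacent columns, as triangles."""
        ns, nz = self.grid.shape[:2]
        idx = np.arange(ns * nz).reshape(ns, nz)
        a = idx[:-1, :-1].ravel()
        b = idx[1:, :-1].ravel()
        c = idx[:-1, 1:].ravel()
        d = idx[1:, 1:].ravel()
        return np.concatenate([np.stack([a, b, c], axis=1),
                               np.stack([b, d, c], axis=1)], axis=0)

    def to_mesh(self):
        """Export as a trimesh.Trimesh (vertices + normals + triangles)."""
        import trimesh

        verts = self.grid.reshape(-1, 3)
        mesh = trimesh.Trimesh(vertices=verts, faces=self.triangles(), process=False)
        if self.normals is not None:
            mesh.vertex_normals = self.normals.reshape(-1, 3)
        return mesh


def build_surface(curves: Sequence[LongAxialCurve], lines: Sequence[NormalLine],
                  n_slices: int) -> PanoramicSurface:
    """Map per-section curves back to 3D and assemble the surface grid.

    Vertex ``(i, j) = foot_i + u_i(z_j) * direction_i`` at slice ``z_j``.
    Columns whose fit fell back are replaced by linear interpolation (in
    arc length) of the u(z) samples of the nearest fitted neighbors; at the
    ends the nearest fitted column is extended.
    """
    if len(curves) != len(lines) or len(curves) < 2:
        raise ValueError("need equally many curves and lines (>= 2)")
    n = len(curves)
    fitted = [i for i, c in enumerate(curves) if c.source == "fitted"]
    if not fitted:
        raise SurfaceError("no teeth found: every section fit fell back")
    s = np.asarray([ln.arc_position for ln in lines])
    u_cols = np.stack([c.samples for c in curves])  # (n, nz)
    sources = [c.source for c in curves]
    fitted_arr = np.asarray(fitted)
    for i in range(n):
        if sources[i] != "fitted":
            lo = fitted_arr[fitted_arr < i]
            hi = fitted_arr[fitted_arr > i]
            if lo.size and hi.size:
                i0, i1 = lo[-1], hi[0]
                w = (s[i] - s[i0]) / (s[i1] - s[i0])
                u_cols[i] = (1 - w) * u_cols[i0] + w * u_cols[i1]
            else:
                u_cols[i] = u_cols[i0 := (lo[-1] if lo.size else hi[0])]
            sources[i] = "interpolated"
    feet = np.asarray([ln.foot for ln in lines])       # (n, 2)
    dirs = np.asarray([ln.direction for ln in lines])  # (n, 2)
    zs = np.arange(n_slices, dtype=float)
    grid = np.empty((n, n_slices, 3))
    grid[:, :, 0] = feet[:, 0:1] + u_cols * dirs[:, 0:1]
    grid[:, :, 1] = feet[:, 1:2] + u_cols * dirs[:, 1:2]
    grid[:, :, 2] = zs[None, :]
    validity = np.ones((n, n_slices), dtype=bool)
    return PanoramicSurface(grid=grid, validity=validity, arc_positions=s,
                            outward_dirs=dirs, column_sources=sources)


def estimate_normals(surf: PanoramicSurface, k_neighbors: int = 9) -> PanoramicSurface:
    """Per-vertex normals by PCA plane fits over local vertex neighborhoods.

    The neighborhood of a vertex is the k nearest vertices in the surface's
    own sampling metric, i.e. a square grid window around it (3x3 for the
    default k = 9); windows are shifted inward at the grid border.  Plain
    Euclidean k-nearest-neighbor search would collapse onto single columns
    when the arch sampling step exceeds the slice spacing.  The normal is
    the eigenvector of the neighborhood covariance with the smallest
    eigenvalue, oriented to agree with the generating line's outward axial
    direction (positive dot product); degenerate (collinear) neighborhoods
    fall back to that outward direction lifted to 3D.
    """
    if k_neighbors < 3:
        raise ValueError("k_neighbors must be >= 3")
    ns, nz = surf.grid.shape[:2]
    half_i = max(int(round(np.sqrt(k_neighbors))) // 2, 1)
    # windows are kept physically near-isotropic: columns are arc-step px
    # apart while rows are one slice apart, so the row half-width scales
    # with the sampling step (plane fits on anisotropic clouds would pick
    # the slice direction as the smallest-variance axis)
    step = float(np.mean(np.diff(surf.arc_positions))) if ns > 1 else 1.0
    half_j = max(int(round(half_i * step)), half_i)
    side_i, side_j = 2 * half_i + 1, 2 * half_j + 1
    # shifted-inward window anchors keep every neighborhood a full window
    i0 = np.clip(np.arange(ns) - half_i, 0, max(ns - side_i, 0))
    j0 = np.clip(np.arange(nz) - half_j, 0, max(nz - side_j, 0))
    ii = i0[:, None, None, None] + np.arange(min(side_i, ns))[None, None, :, None]
    jj = j0[None, :, None, None] + np.arange(min(side_j, nz))[None, None, None, :]
    neigh = surf.grid[ii, jj]                         # (ns, nz, si, sj, 3)
    neigh = neigh.reshape(ns * nz, -1, 3)
    centered = neigh - neigh.mean(axis=1, keepdims=True)
    cov = np.einsum("nki,nkj->nij", centered, centered) / neigh.shape[1]
    evals, evecs = np.linalg.eigh(cov)
    normals = evecs[:, :, 0]                          # smallest eigenvalue first
    # orientation: agree with the outward 2D normal of the generating line
    out3 = np.zeros((ns, nz, 3))
    out3[:, :, :2] = surf.outward_dirs[:, None, :]
    out3 = out3.reshape(-1, 3)
    dots = np.einsum("ni,ni->n", normals, out3)
    normals = np.where(dots[:, None] < 0, -normals, normals)
    degenerate = (evals[:, 1] < 1e-12) | (np.abs(dots) < 1e-12)
    if degenerate.any():
        warnings.warn(f"{int(degenerate.sum())} degenerate normal neighborhoods; "
                      "falling back to the lines' outward directions")
        normals[degenerate] = out3[degenerate]
    normals /= np.linalg.norm(normals, axis=1, keepdims=True)
    surf.normals = normals.reshape(ns, nz, 3)
    return surf
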