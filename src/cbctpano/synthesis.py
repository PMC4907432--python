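"""Panoramic radiograph synthesis by isometric development of the surface.

The surface columns, joined at a reference transverse row, form a 3D
piecewise-linear polyline.  Straightening it by the arc-length rule gives
each column an abscissa ``w_i = sum_{j<=i} L_j`` (cumulative segment
length); the ordinate is the axial slice index, ``h_j = z_j``.  Sampling
the volume on the surface at the developed pixel grid yields the
single-slice panoramic radiograph; averaging samples at offsets along the
surface normals yields thickened radiographs.  A vertical extrusion of the
arch curve (the classical "cylinder method") is provided as baseline.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy.ndimage import map_coordinates

from .arch_curve import ArchCurve
from .surface import PanoramicSurface
from .volume_io import Image2D, Volume


@dataclass
class DevelopedImage:
    """A developed (unrolled) panoramic radiograph.

    ``data[w, h]``: ``w`` runs along the straightened arch, ``h`` is the
    axial slice index.  ``w_coords`` holds the per-column abscissae of the
    source surface columns on the developed axis.
    """

    data: np.ndarray
    w_coords: np.ndarray
    thickness_slices: int
    provenance: str  # surface | cylinder
    spacing: tuple[float, float] = (1.0, 1.0)

    def to_image(self) -> Image2D:
        return Image2D(data=self.data, spacing=np.asarray(self.spacing),
                       provenance="panoramic")


def develop_surface(surf: PanoramicSurface,
                    reference_row: str = "mid") -> tuple[np.ndarray, np.ndarray]:
    """Develop the surface isometrically: per-column w, per-row h.

    ``reference_row`` picks the transverse row whose polyline is
    straightened: ``mid`` (mid-height row) or ``per_row_mean`` (segment
    lengths averaged over all rows).  ``w_0 = 0`` and consecutive gaps equal
    the 3D distance between the corresponding surface points.
    """
    nz = surf.n_slices
    if reference_row == "mid":
        poly = surf.grid[:, nz // 2, :]
        seg = np.linalg.norm(np.diff(poly, axis=0), axis=1)
    elif reference_row == "per_row_mean":
        seg = np.linalg.norm(np.diff(surf.grid, axis=0), axis=2).mean(axis=1)
    else:
        raise ValueError(f"unknown reference_row {reference_row!r}")
    w = np.concatenate([[0.0], np.cumsum(seg)])
    h = np.arange(nz, dtype=float)
    return w, h


def _interp_columns(grid: np.ndarray, w_coords: np.ndarray,
                    w_pixels: np.ndarray) -> np.ndarray:
    """Linear interpolation of per-column quantities at developed abscissae.

    ``grid`` is (n_cols, n_rows, d); returns (len(w_pixels), n_rows, d).
    """
    idx = np.clip(np.searchsorted(w_coords, w_pixels, side="right") - 1,
                  0, len(w_coords) - 2)
    denom = w_coords[idx + 1] - w_coords[idx]
    denom = np.where(denom <= 0, 1.0, denom)
    alpha = np.clip((w_pixels - w_coords[idx]) / denom, 0.0, 1.0)
    return (1 - alpha[:, None, None]) * grid[idx] + alpha[:, None, None] * grid[idx + 1]


def _sample_volume(vol: Volume, coords: np.ndarray) -> np.ndarray:
    """Trilinear sampling; out-of-volume positions take the volume minimum."""
    flat = coords.reshape(-1, 3)
    vals = map_coordinates(vol.data, flat.T, order=1, mode="constant",
                           cval=float(vol.data.min()))
    return vals.reshape(coords.shape[:-1])


def render_single_slice(vol: Volume, surf: PanoramicSurface,
                        w_coords: np.ndarray, h_coords: np.ndarray) -> DevelopedImage:
    """Synthesize the single-slice panoramic radiograph.

    The image has one row per axial slice and a width equal to the number
    of pixels the straightened polyline passes through; each pixel inverts
    the development (linear interpolation in w between surface columns) and
    samples the volume trilinearly at the resulting 3D point.
    """
    width = int(round(w_coords[-1])) + 1
    w_pixels = np.arange(width, dtype=float)
    coords = _interp_columns(surf.grid, w_coords, w_pixels)  # (W, nz, 3)
    data = _sample_volume(vol, coords)
    return DevelopedImage(data=data, w_coords=w_coords.copy(), thickness_slices=1,
                          provenance="surface",
                          spacing=(float(vol.spacing[0]), float(vol.spacing[2])))


def render_thickened(vol: Volume, surf: PanoramicSurface, w_coords: np.ndarray,
                     h_coords: np.ndarray, n_slices: int,
                     aggregate: str = "mean") -> DevelopedImage:
    """Thickened panoramic radiograph along the surface normals.

    Pixel value aggregates (mean by default, max optionally) the volume
    sampled at ``surface_point + t * normal`` for integer voxel offsets
    ``t in {-(n-1)/2 .. +(n-1)/2}``.  ``n_slices = 1`` reduces exactly to
    :func:`render_single_slice`.
    """
    if n_slices < 1 or n_slices % 2 == 0:
        raise ValueError("n_slices must be odd and >= 1")
    if aggregate not in ("mean", "max"):
        raise ValueError("aggregate must be mean|max")
    if n_slices == 1:
        out = render_single_slice(vol, surf, w_coords, h_coords)
        return DevelopedImage(data=out.data, w_coords=out.w_coords, thickness_slices=1,
                              provenance="surface", spacing=out.spacing)
    if surf.normals is None:
        raise ValueError("surface normals not estimated; call estimate_normals first")
    width = int(round(w_coords[-1])) + 1
    w_pixels = np.arange(width, dtype=float)
    coords = _interp_columns(surf.grid, w_coords, w_pixels)
    normals = _interp_columns(surf.normals, w_coords, w_pixels)
    normals /= np.maximum(np.linalg.norm(normals, axis=-1, keepdims=True), 1e-12)
    half = (n_slices - 1) // 2
    acc = None
    for t in range(-half, half + 1):
        sample = _sample_volume(vol, coords + t * normals)
        if acc is None:
            acc = sample if aggregate == "max" else sample.astype(np.float64)
        elif aggregate == "max":
            acc = np.maximum(acc, sample)
        else:
            acc += sample
    data = acc if aggregate == "max" else acc / n_slices
    return DevelopedImage(data=data, w_coords=w_coords.copy(),
                          thickness_slices=n_slices, provenance="surface",
                          spacing=(float(vol.spacing[0]), float(vol.spacing[2])))


def render_cylinder_baseline(vol: Volume, curve: ArchCurve, n_slices: int = 1,
                             aggregate: str = "mean",
                             n_z: Optional[int] = None) -> DevelopedImage:
    """Baseline: vertical extrusion of the arch curve ("cylinder method").

    Pixel ``(w, h)`` samples the volume at the arch-curve point at arc
    length ``w`` on slice ``h``; thickening offsets run along the curve's
    2D outward normal (horizontal) and are averaged (or max-aggregated).
    """
    if n_slices < 1 or n_slices % 2 == 0:
        raise ValueError("n_slices must be odd and >= 1")
    nz = n_z or vol.n_slices
    width = int(round(curve.total_length)) + 1
    w_pixels = np.linspace(0.0, curve.total_length, width)
    ts = curve.t_at_arclength(w_pixels)
    feet = curve.evaluate(ts)                      # (W, 2)
    tans = curve.tangent(ts)
    normals = np.column_stack([-tans[:, 1], tans[:, 0]])
    centroid = curve.interior_centroid()
    if np.dot(normals[len(normals) // 2], feet[len(feet) // 2] - centroid) < 0:
        normals = -normals
    zs = np.arange(nz, dtype=float)
    half = (n_slices - 1) // 2
    acc = None
    for t in range(-half, half + 1):
        xy = feet + t * normals
        coords = np.empty((width, nz, 3))
        coords[:, :, 0] = xy[:, 0:1]
        coords[:, :, 1] = xy[:, 1:2]
        coords[:, :, 2] = zs[None, :]
        sample = _sample_volume(vol, coords)
        if acc is None:
            acc = sample if aggregate == "max" else sample.astype(np.float64)
        elif aggregate == "max":
            acc = np.maximum(acc, sample)
        else:
            acc += sample
    data = acc if aggregate == "max" else acc / n_slices
    return DevelopedImage(data=data, w_coords=w_pixels, thickness_slices=n_slices,
                          provenance="cylinder",
                          spacing=(float(vol.spacing[0]), float(vol.spacing[2])))
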