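"""Volume and image I/O for the panoramic synthesis pipeline.

Conventions
-----------
Voxel indices are 0-based. ``Volume.data`` is indexed ``(x, y, z)`` where
``(x, y)`` span the axial plane and ``z`` is the axial slice index,
increasing from mandible (bottom) to maxilla (top).  Physical position of a
voxel is ``origin + index * spacing`` (mm).  Intensities are used raw
(scanner units); windowing is applied only when saving display images.
"""
from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np


class VolumeFormatError(RuntimeError):
    """Raised when an input volume cannot be read or fails validation."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass
class Volume:
    """A 3D scalar grid with voxel spacing, indexed (x, y, z)."""

    data: np.ndarray
    spacing: np.ndarray  # mm per voxel, one value per axis
    origin: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        self.spacing = np.asarray(self.spacing, dtype=float)
        self.origin = np.asarray(self.origin, dtype=float)
        if self.data.ndim != 3:
            raise VolumeFormatError(f"volume must be 3D, got shape {self.data.shape}")
        if any(s < 2 for s in self.data.shape):
            raise VolumeFormatError(f"all dimensions must be >= 2, got {self.data.shape}")
        if self.spacing.shape != (3,) or np.any(self.spacing <= 0):
            raise VolumeFormatError(f"spacing must be 3 positive values, got {self.spacing}")
        if not np.isfinite(self.data).all():
            idx = tuple(int(i) for i in np.argwhere(~np.isfinite(self.data))[0])
            raise VolumeFormatError(f"non-finite intensity at voxel index {idx}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]

    @property
    def n_slices(self) -> int:
        return self.data.shape[2]


@dataclass
class Image2D:
    """A 2D scalar grid with pixel spacing and a provenance tag."""

    data: np.ndarray
    spacing: np.ndarray  # mm per pixel, two values
    provenance: str = ""  # mip | section | panoramic | ...

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        self.spacing = np.asarray(self.spacing, dtype=float)
        if self.data.ndim != 2:
            raise VolumeFormatError(f"image must be 2D, got shape {self.data.shape}")
        if not np.isfinite(self.data).all():
            raise VolumeFormatError("image contains non-finite values")


@dataclass(frozen=True)
class WindowSetting:
    """Display window (width/level) in intensity units."""

    width: float
    level: float

    def __post_init__(self) -> None:
        if self.width <= 0:
            raise ValueError("window width must be > 0")


# ---------------------------------------------------------------------------
# loading
# ---------------------------------------------------------------------------

def _load_nifti(path: Path) -> Volume:
    import nibabel as nib

    img = nib.load(str(path))
    data = np.asarray(img.get_fdata(), dtype=np.float32)
    zooms = img.header.get_zooms()[:3]
    if not all(z > 0 for z in zooms):
        raise VolumeFormatError(f"missing or invalid spacing metadata in {path}")
    origin = np.asarray(img.affine[:3, 3], dtype=float)
    return Volume(data=data, spacing=np.asarray(zooms, dtype=float), origin=origin)


def _load_dicom_dir(path: Path) -> Volume:
    import pydicom

    files = sorted(p for p in path.iterdir() if p.suffix.lower() in {".dcm", ".ima"} or p.suffix == "")
    datasets = []
    for f in files:
        if not f.is_file():
            continue
        try:
            datasets.append(pydicom.dcmread(str(f)))
        except Exception:
            continue
    if not datasets:
        raise VolumeFormatError(f"no readable DICOM slices in {path}")

    def slice_z(ds):
        if hasattr(ds, "ImagePositionPatient"):
            return float(ds.ImagePositionPatient[2])
        return float(getattr(ds, "InstanceNumber", 0))

    datasets.sort(key=slice_z)
    first = datasets[0]
    if not hasattr(first, "PixelSpacing"):
        raise VolumeFormatError("DICOM series lacks PixelSpacing metadata")
    row_sp, col_sp = (float(v) for v in first.PixelSpacing)
    if len(datasets) > 1:
        gap = abs(slice_z(datasets[1]) - slice_z(datasets[0]))
        if gap == 0:
            gap = float(getattr(first, "SliceThickness", row_sp))
    else:
        gap = float(getattr(first, "SliceThickness", row_sp))
    if abs(row_sp - col_sp) > 1e-9:
        warnings.warn("anisotropic in-plane DICOM spacing; proceeding with per-axis values")
    # pixel_array is (row, col) = (y, x); stack slices as last axis, put x first
    stack = np.stack([ds.pixel_array for ds in datasets], axis=-1)
    data = np.transpose(stack, (1, 0, 2)).astype(np.float32)
    origin = np.zeros(3)
    if hasattr(first, "ImagePositionPatient"):
        origin = np.asarray([float(v) for v in first.ImagePositionPatient])
    return Volume(data=data, spacing=np.array([col_sp, row_sp, gap]), origin=origin)


def _load_raw(path: Path, sidecar: Optional[Path]) -> Volume:
    import yaml

    sidecar = sidecar or path.with_suffix(path.suffix + ".yaml")
    if not sidecar.exists():
        raise VolumeFormatError(f"raw volume requires a YAML sidecar; {sidecar} not found")
    meta = yaml.safe_load(sidecar.read_text())
    try:
        dims = tuple(int(v) for v in meta["dims"])  # (nx, ny, nz)
        dtype = np.dtype(meta["dtype"])
        spacing = np.asarray([float(v) for v in meta["spacing"]])
    except KeyError as e:
        raise VolumeFormatError(f"raw sidecar missing key: {e}") from e
    raw = np.fromfile(str(path), dtype=dtype)
    if raw.size != int(np.prod(dims)):
        raise VolumeFormatError(
            f"raw file has {raw.size} voxels, sidecar dims imply {int(np.prod(dims))}"
        )
    # x fastest-varying on disk
    data = raw.reshape(dims[::-1]).transpose(2, 1, 0).astype(np.float32)
    origin = np.asarray(meta.get("origin", [0.0, 0.0, 0.0]), dtype=float)
    return Volume(data=data, spacing=spacing, origin=origin)


def load_volume(path: str | Path, format_hint: Optional[str] = None,
                sidecar: Optional[str | Path] = None) -> Volume:
    """Load a CBCT volume from NIfTI, a DICOM series directory, or raw binary.

    Parameters
    ----------
    path:
        File (NIfTI, raw) or directory (DICOM series).
    format_hint:
        One of ``{"nifti", "dicom_dir", "raw"}``; inferred from the path when
        omitted.
    sidecar:
        YAML sidecar path for raw volumes (defaults to ``<path>.yaml``).
    """
    path = Path(path)
    if not path.exists():
        raise VolumeFormatError(f"input path does not exist: {path}")
    if format_hint is None:
        if path.is_dir():
            format_hint = "dicom_dir"
        elif path.suffix in {".nii", ".gz"} or path.name.endswith(".nii.gz"):
            format_hint = "nifti"
        elif path.suffix in {".raw", ".bin"}:
            format_hint = "raw"
        else:
            raise VolumeFormatError(f"cannot infer format of {path}; pass format_hint")
    if format_hint == "nifti":
        vol = _load_nifti(path)
    elif format_hint == "dicom_dir":
        vol = _load_dicom_dir(path)
    elif format_hint == "raw":
        vol = _load_raw(path, Path(sidecar) if sidecar else None)
    else:
        raise VolumeFormatError(f"unknown format hint {format_hint!r}")
    if abs(vol.spacing[0] - vol.spacing[1]) > 1e-6 * max(vol.spacing[:2]):
        warnings.warn(f"anisotropic axial spacing {vol.spacing[:2]}; pipeline assumes near-isotropic")
    return vol


def save_volume(vol: Volume, path: str | Path) -> None:
    """Write a volume as NIfTI with spacing and origin in the affine."""
    import nibabel as nib

    affine = np.eye(4)
    affine[0, 0], affine[1, 1], affine[2, 2] = vol.spacing
    affine[:3, 3] = vol.origin
    nib.save(nib.Nifti1Image(np.asarray(vol.data, dtype=np.float32), affine), str(path))


# ---------------------------------------------------------------------------
# MIP / windowing / image output
# ---------------------------------------------------------------------------

def mip_axial(vol: Volume, z_band: Optional[tuple[float, float]] = None) -> Image2D:
    """Axial maximum intensity projection.

    Each output pixel keeps the maximum gray value along the ray through the
    same in-plane location in all axial slices.  ``z_band`` optionally
    restricts the projection to a fractional slice band ``(z_min, z_max)``
    with ``0 <= z_min < z_max <= 1``; the default projects the full range.
    """
    data = vol.data
    if z_band is not None:
        lo, hi = z_band
        if not (0.0 <= lo < hi <= 1.0):
            raise ValueError(f"invalid z band {z_band}")
        nz = data.shape[2]
        i0, i1 = int(np.floor(lo * nz)), max(int(np.ceil(hi * nz)), int(np.floor(lo * nz)) + 1)
        data = data[:, :, i0:i1]
    return Image2D(data=data.max(axis=2), spacing=vol.spacing[:2].copy(), provenance="mip")


def apply_window(img: Image2D, w: WindowSetting) -> Image2D:
    """Map ``[level - width/2, level + width/2]`` linearly to [0, 1], clipped.

    Display-only: never used inside the pipeline math.
    """
    lo = w.level - w.width / 2.0
    out = np.clip((img.data.astype(float) - lo) / w.width, 0.0, 1.0)
    return Image2D(data=out, spacing=img.spacing.copy(), provenance=img.provenance)


def save_image(img: Image2D, path: str | Path, bit_depth: int = 16) -> None:
    """Write an image as 8- or 16-bit PNG/TIFF with a JSON rescale sidecar.

    The full intensity range is rescaled linearly to the integer range; the
    sidecar records ``vmin``/``vmax`` so original values are recoverable up
    to quantization.
    """
    import imageio.v3 as iio

    if bit_depth not in (8, 16):
        raise ValueError("bit_depth must be 8 or 16")
    path = Path(path)
    data = np.asarray(img.data, dtype=float)
    vmin, vmax = float(data.min()), float(data.max())
    span = vmax - vmin if vmax > vmin else 1.0
    maxval = 255 if bit_depth == 8 else 65535
    scaled = np.round((data - vmin) / span * maxval)
    arr = scaled.astype(np.uint8 if bit_depth == 8 else np.uint16)
    # images are indexed (x, y) internally; write row-major (y, x) for viewers
    iio.imwrite(path, arr.T)
    sidecar = {
        "vmin": vmin,
        "vmax": vmax,
        "bit_depth": bit_depth,
        "provenance": img.provenance,
        "spacing_mm": [float(s) for s in img.spacing],
    }
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(sidecar, indent=2))


def load_image(path: str | Path) -> Image2D:
    """Read back an image written by :func:`save_image`, undoing the rescale."""
    import imageio.v3 as iio

    path = Path(path)
    arr = np.asarray(iio.imread(path)).T.astype(float)
    sidecar_path = path.with_suffix(path.suffix + ".json")
    if sidecar_path.exists():
        meta = json.loads(sidecar_path.read_text())
        maxval = 255 if meta["bit_depth"] == 8 else 65535
        arr = arr / maxval * (meta["vmax"] - meta["vmin"]) + meta["vmin"]
        return Image2D(data=arr, spacing=np.asarray(meta["spacing_mm"]),
                       provenance=meta.get("provenance", ""))
    return Image2D(data=arr, spacing=np.ones(2), provenance="")
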