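"""Synthetic dental CBCT phantom with closed-form ground truth.

The phantom emulates the features the pipeline depends on: a parabolic
dental arch of discrete teeth with enamel/dentine/pulp layering, tilted
tooth long axes (strongest at the incisors, fading to zero at the molars),
a wider jaw-bone band behind the teeth, soft tissue inside a head outline,
an optional mandibular-canal tube, and seeded Gaussian noise.

Teeth are capsules (cylinder + hemispherical caps) so every ground-truth
quantity — centers, long axes, arch coefficients, canal centerline — is
available in closed form for parameter-recovery tests.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path
from typing import Optional

import numpy as np

from .volume_io import Volume


class PhantomError(ValueError):
    pass


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

@dataclass
class PhantomConfig:
    """Geometry, intensities and noise of the synthetic jaw.

    The dental arch is ``y = a x^2 + b x + c`` in axial voxel coordinates,
    opening toward +y (posterior); teeth centers sit on this parabola.
    ``incisor_tilt_deg``/``molar_tilt_deg`` set the labial tilt of the tooth
    long axes, interpolated linearly in arc length from the apex outward;
    upper incisors are proclined more than lower ones and the maxillary arch
    sits ``overjet_mm`` labial of the mandibular one, as in normal occlusion.
    """

    dims: tuple[int, int, int] = (160, 160, 160)
    spacing_mm: float = 0.3
    arch_coeffs: Optional[tuple[float, float, float]] = None  # default from dims
    arch_half_span_px: Optional[float] = None  # x half-extent of dentition
    n_teeth_per_jaw: int = 10
    crown_radius_mm: float = 1.8
    tooth_length_mm: float = 12.0
    enamel_thickness_mm: float = 0.6
    pulp_radius_mm: float = 0.6
    incisor_tilt_deg: float = 15.0
    molar_tilt_deg: float = 0.0
    lower_tilt_scale: float = 2.0 / 3.0  # mandibular tilt relative to maxillary
    overjet_mm: float = 0.6
    bite: str = "open"  # open | closed
    bite_gap_mm: float = 3.0
    # intensities (scanner units): soft < jaw <= dentine < enamel, pulp < dentine
    soft_tissue: float = 100.0
    jaw_bone: float = 2000.0
    dentine: float = 2000.0
    enamel: float = 2800.0
    pulp: float = 800.0
    ramus_bone: float = 2600.0  # dense posterior cortical bone (rami)
    jaw_half_mm: float = 4.5  # half-width of the bone bands around each arch
    include_rami: bool = True
    jaw_apex_offset_px: float = 12.0  # x-overshoot of the rami past the arch ends
    jaw_extra_span_px: float = 10.0   # posterior (y) offset of the rami
    canal: bool = False
    canal_radius_mm: float = 0.6
    canal_offset_px: float = 7.0   # lingual offset from the lower root line; the
                                   # extracted surface at canal depth runs ~3 px
                                   # labial of that line, so the tube sits about
                                   # 10 voxels lingual of the panoramic surface
    implant: bool = False
    implant_intensity: float = 6000.0
    noise_sigma: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        nx, ny, nz = self.dims
        if self.arch_coeffs is None:
            # apex at (nx/2, ny/4), rising 0.44*ny over a 0.31*nx half-span
            half = 0.3125 * nx
            a = (0.4375 * ny) / half**2
            x0, y0 = nx / 2.0, ny / 4.0
            self.arch_coeffs = (a, -2 * a * x0, a * x0**2 + y0)
        if self.arch_half_span_px is None:
            self.arch_half_span_px = 0.3125 * nx
        if not (self.soft_tissue < self.jaw_bone <= self.dentine < self.enamel):
            raise PhantomError("require soft_tissue < jaw_bone <= dentine < enamel")
        if not (self.pulp < self.dentine):
            raise PhantomError("require pulp < dentine")
        if not (self.jaw_bone <= self.ramus_bone < self.enamel):
            raise PhantomError("require jaw_bone <= ramus_bone < enamel")
        if self.enamel <= max(self.soft_tissue, self.jaw_bone, self.dentine, self.pulp):
            raise PhantomError("enamel must be the strict maximum tissue intensity")
        if self.bite not in ("open", "closed"):
            raise PhantomError(f"bite must be open|closed, got {self.bite!r}")
        if self.n_teeth_per_jaw < 1:
            raise PhantomError("need at least one tooth per jaw")

    # voxel-unit helpers
    @property
    def crown_radius_px(self) -> float:
        return self.crown_radius_mm / self.spacing_mm

    @property
    def tooth_length_px(self) -> float:
        return self.tooth_length_mm / self.spacing_mm

    @property
    def bite_gap_px(self) -> float:
        """Axial gap between opposing crown-axis endpoints.

        Closed bite: the hemispherical crown caps (radius r past the axis
        endpoints) interdigitate with their tips overlapping 2 voxels in z,
        so the endpoints remain 2r - 2 apart and enamel shells stay disjoint.
        """
        if self.bite == "closed":
            return 2.0 * self.crown_radius_px - 2.0
        return self.bite_gap_mm / self.spacing_mm

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PhantomConfig":
        import yaml

        raw = yaml.safe_load(Path(path).read_text()) or {}
        if "dims" in raw:
            raw["dims"] = tuple(int(v) for v in raw["dims"])
        if raw.get("arch_coeffs") is not None:
            raw["arch_coeffs"] = tuple(float(v) for v in raw["arch_coeffs"])
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> None:
        import yaml

        d = asdict(self)
        d["dims"] = list(self.dims)
        if d["arch_coeffs"] is not None:
            d["arch_coeffs"] = [float(v) for v in d["arch_coeffs"]]
        Path(path).write_text(yaml.safe_dump(d, sort_keys=False))


# ---------------------------------------------------------------------------
# ground truth
# ---------------------------------------------------------------------------

@dataclass
class ToothTruth:
    tooth_id: str
    center: np.ndarray       # (x, y, z) voxel coords, midpoint of the axis
    axis: np.ndarray         # unit vector, root -> crown
    half_length: float       # half the axis segment length, px
    crown_radius: float      # px
    tilt_deg: float
    arc_position: float      # signed arc length from the arch apex, px
    jaw: str                 # upper | lower

    @property
    def crown_end(self) -> np.ndarray:
        return self.center + self.axis * self.half_length

    @property
    def root_end(self) -> np.ndarray:
        return self.center - self.axis * self.half_length


@dataclass
class PhantomTruth:
    arch_coeffs: tuple[float, float, float]
    teeth: list[ToothTruth]
    canal_polyline: np.ndarray  # (n, 3) or empty
    bite_gap_px: float
    intensities: dict[str, float]
    config: PhantomConfig

    def teeth_of(self, jaw: str) -> list[ToothTruth]:
        return [t for t in self.teeth if t.jaw == jaw]

    def to_json(self, path: str | Path) -> None:
        payload = {
            "arch_coeffs": [float(v) for v in self.arch_coeffs],
            "bite_gap_px": float(self.bite_gap_px),
            "intensities": self.intensities,
            "canal_polyline": np.asarray(self.canal_polyline).tolist(),
            "teeth": [
                {
                    "tooth_id": t.tooth_id,
                    "center": t.center.tolist(),
                    "axis": t.axis.tolist(),
                    "half_length": float(t.half_length),
                    "crown_radius": float(t.crown_radius),
                    "tilt_deg": float(t.tilt_deg),
                    "arc_position": float(t.arc_position),
                    "jaw": t.jaw,
                }
                for t in self.teeth
            ],
            "config": _config_dict(self.config),
        }
        Path(path).write_text(json.dumps(payload, indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "PhantomTruth":
        d = json.loads(Path(path).read_text())
        cfg_d = d["config"]
        cfg_d["dims"] = tuple(cfg_d["dims"])
        if cfg_d.get("arch_coeffs") is not None:
            cfg_d["arch_coeffs"] = tuple(cfg_d["arch_coeffs"])
        cfg = PhantomConfig(**cfg_d)
        teeth = [
            ToothTruth(
                tooth_id=t["tooth_id"],
                center=np.asarray(t["center"], dtype=float),
                axis=np.asarray(t["axis"], dtype=float),
                half_length=t["half_length"],
                crown_radius=t["crown_radius"],
                tilt_deg=t["tilt_deg"],
                arc_position=t["arc_position"],
                jaw=t["jaw"],
            )
            for t in d["teeth"]
        ]
        return cls(
            arch_coeffs=tuple(d["arch_coeffs"]),
            teeth=teeth,
            canal_polyline=np.asarray(d["canal_polyline"], dtype=float).reshape(-1, 3),
            bite_gap_px=d["bite_gap_px"],
            intensities=d["intensities"],
            config=cfg,
        )


def _config_dict(cfg: PhantomConfig) -> dict:
    d = asdict(cfg)
    d["dims"] = list(cfg.dims)
    if d["arch_coeffs"] is not None:
        d["arch_coeffs"] = [float(v) for v in d["arch_coeffs"]]
    return d


# ---------------------------------------------------------------------------
# arch geometry helpers
# ---------------------------------------------------------------------------

def _parabola_xy(coeffs, x):
    a, b, c = coeffs
    return np.stack([np.asarray(x, dtype=float),
                     a * np.asarray(x, dtype=float) ** 2 + b * np.asarray(x) + c], axis=-1)


def _parabola_arclength(coeffs, x0, x):
    """Signed arc length along the parabola from x0 to x (vectorized)."""
    a, b, _ = coeffs
    xs = np.linspace(x0, x, 257, axis=-1)
    dy = 2 * a * xs + b
    integrand = np.sqrt(1.0 + dy**2)
    return np.trapezoid(integrand, xs, axis=-1)


def _x_at_arclength(coeffs, x0, s_targets, x_range):
    """Invert arc length -> x by dense sampling + interpolation."""
    xs = np.linspace(x_range[0], x_range[1], 4001)
    ss = _parabola_arclength(coeffs, x0, xs)
    order = np.argsort(ss)
    return np.interp(s_targets, ss[order], xs[order])


def _outward_normal(coeffs, x):
    """Unit axial normal pointing labially (away from the concave side)."""
    a, b, _ = coeffs
    t = np.stack([np.ones_like(np.asarray(x, dtype=float)), 2 * a * np.asarray(x) + b], axis=-1)
    t /= np.linalg.norm(t, axis=-1, keepdims=True)
    # parabola opens toward +y; the concave interior is at +y of the curve
    n = np.stack([t[..., 1], -t[..., 0]], axis=-1)
    apex_x = -b / (2 * a)
    sign = np.where(n[..., 1] <= 0, 1.0, -1.0)  # at apex, outward is -y
    # choose orientation continuously: outward has negative y at apex,
    # and generally points away from the axis of symmetry's +y side
    n = n * sign[..., None]
    return n


# ---------------------------------------------------------------------------
# generation
# ---------------------------------------------------------------------------

def _plan_teeth(cfg: PhantomConfig) -> list[ToothTruth]:
    a, b, c = cfg.arch_coeffs
    apex_x = -b / (2 * a)
    half_span = cfg.arch_half_span_px
    s_max = float(_parabola_arclength(cfg.arch_coeffs, apex_x, apex_x + half_span))
    n = cfg.n_teeth_per_jaw
    # tooth centers evenly spaced in arc length, symmetric about the apex
    s_positions = np.linspace(-s_max, s_max, n) if n > 1 else np.array([0.0])
    nz = cfg.dims[2]
    z_mid = nz / 2.0
    gap = cfg.bite_gap_px
    L = cfg.tooth_length_px
    teeth: list[ToothTruth] = []
    for jaw in ("upper", "lower"):
        coeffs = cfg.arch_coeffs
        if jaw == "upper" and cfg.overjet_mm:
            # maxillary arch sits labial of the mandibular one: shift the
            # parabola toward -y by the overjet (exact offset curve is not
            # needed at these magnitudes)
            coeffs = (a, b, c - cfg.overjet_mm / cfg.spacing_mm)
        s_jaw = s_positions
        if cfg.bite == "closed" and jaw == "upper" and n > 1:
            s_jaw = s_positions + (s_positions[1] - s_positions[0]) / 2.0
        xs = _x_at_arclength(coeffs, apex_x, s_jaw,
                             (apex_x - half_span - 20, apex_x + half_span + 20))
        xy = _parabola_xy(coeffs, xs)
        out = _outward_normal(coeffs, xs)
        for i, (s, p, o) in enumerate(zip(s_jaw, xy, out)):
            frac = min(abs(s) / s_max, 1.0) if s_max > 0 else 0.0
            tilt = cfg.incisor_tilt_deg + (cfg.molar_tilt_deg - cfg.incisor_tilt_deg) * frac
            if jaw == "lower":
                tilt *= cfg.lower_tilt_scale
            th = np.deg2rad(tilt)
            zsign = -1.0 if jaw == "upper" else 1.0  # crown points toward the bite plane
            axis = np.array([o[0] * np.sin(th), o[1] * np.sin(th), zsign * np.cos(th)])
            axis /= np.linalg.norm(axis)
            # crown tip sits gap/2 from the mid-plane
            cz = z_mid + (-zsign) * (gap / 2.0 + (L / 2.0) * np.cos(th))
            center = np.array([p[0], p[1], cz])
            teeth.append(
                ToothTruth(
                    tooth_id=f"{'U' if jaw == 'upper' else 'L'}{i + 1:02d}",
                    center=center,
                    axis=axis,
                    half_length=L / 2.0,
                    crown_radius=cfg.crown_radius_px,
                    tilt_deg=float(tilt),
                    arc_position=float(s),
                    jaw=jaw,
                )
            )
    return teeth


def _paint_capsule(data, seg_a, seg_b, shells):
    """Paint concentric capsule shells around segment a->b.

    ``shells`` is a list of (radius_px, value) from outermost to innermost.
    Returns False if the capsule's bounding box leaves the volume.
    """
    r_max = max(r for r, _ in shells)
    lo = np.floor(np.minimum(seg_a, seg_b) - r_max).astype(int)
    hi = np.ceil(np.maximum(seg_a, seg_b) + r_max).astype(int) + 1
    if np.any(lo < 0) or np.any(hi > np.asarray(data.shape)):
        return False
    xs, ys, zs = (np.arange(lo[i], hi[i]) for i in range(3))
    gx, gy, gz = np.meshgrid(xs, ys, zs, indexing="ij")
    pts = np.stack([gx, gy, gz], axis=-1).astype(float)
    ab = seg_b - seg_a
    denom = float(ab @ ab)
    t = np.clip(((pts - seg_a) @ ab) / denom, 0.0, 1.0) if denom > 0 else np.zeros(pts.shape[:-1])
    closest = seg_a + t[..., None] * ab
    dist = np.linalg.norm(pts - closest, axis=-1)
    sub = data[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]]
    for radius, value in shells:
        sub[dist <= radius] = value
    return True


def _distance_to_parabola_map(coeffs, nx, ny, x_range):
    """Per-axial-pixel distance to a parabola segment (min over dense samples)."""
    xs = np.linspace(x_range[0], x_range[1], 600)
    curve = _parabola_xy(coeffs, xs)  # (600, 2)
    gx, gy = np.meshgrid(np.arange(nx), np.arange(ny), indexing="ij")
    pix = np.stack([gx, gy], axis=-1).astype(np.float32).reshape(-1, 2)
    d = np.full(pix.shape[0], np.inf, dtype=np.float32)
    for chunk in np.array_split(np.arange(curve.shape[0]), 12):
        diffs = pix[:, None, :] - curve[None, chunk, :].astype(np.float32)
        d = np.minimum(d, np.sqrt((diffs**2).sum(-1)).min(axis=1))
    return d.reshape(nx, ny)


def jaw_footprints(cfg: PhantomConfig) -> tuple[np.ndarray, np.ndarray]:
    """Axial footprints (2D bool masks) of the jaw body band and the rami wings.

    The jaw body follows the dental arch (it hosts the roots and the
    mandibular canal); the wings are two elongated rami posterior of and
    labial to the arch ends — the jaw-only structures the spatial
    quadrangle is meant to cut away.
    """
    nx, ny, _ = cfg.dims
    a, b, c = cfg.arch_coeffs
    apex_x = -b / (2 * a)
    half_span = cfg.arch_half_span_px
    jaw_half = cfg.jaw_half_mm / cfg.spacing_mm
    d_arch = _distance_to_parabola_map(cfg.arch_coeffs, nx, ny,
                                       (apex_x - half_span, apex_x + half_span))
    apex_y = a * apex_x**2 + b * apex_x + c
    end_y = a * half_span**2 + apex_y
    gx, gy = np.meshgrid(np.arange(nx), np.arange(ny), indexing="ij")
    wing2d = np.zeros((nx, ny), dtype=bool)
    if not cfg.include_rami:
        return d_arch <= jaw_half, wing2d
    rx, ry = 5.0, 10.0  # ramus semi-axes, px
    for side in (-1.0, 1.0):
        cx = apex_x + side * (half_span + cfg.jaw_apex_offset_px)
        cy = end_y + cfg.jaw_extra_span_px
        wing2d |= ((gx - cx) / rx) ** 2 + ((gy - cy) / ry) ** 2 <= 1.0
    return d_arch <= jaw_half, wing2d


def generate_phantom(cfg: PhantomConfig) -> tuple[Volume, PhantomTruth]:
    """Render the phantom volume and return it with its ground truth.

    Deterministic for a fixed config; the seed only drives the additive
    Gaussian noise, so zero-noise phantoms are identical across seeds.
    """
    nx, ny, nz = cfg.dims
    data = np.zeros((nx, ny, nz), dtype=np.float32)

    # head outline: soft tissue inside an axial ellipse, air outside
    gx, gy = np.meshgrid(np.arange(nx), np.arange(ny), indexing="ij")
    cx, cy = nx / 2.0, ny * 0.52
    ellipse = ((gx - cx) / (0.47 * nx)) ** 2 + ((gy - cy) / (0.45 * ny)) ** 2 <= 1.0
    data[ellipse, :] = cfg.soft_tissue

    teeth = _plan_teeth(cfg)
    a, b, c = cfg.arch_coeffs
    apex_x = -b / (2 * a)
    half_span = cfg.arch_half_span_px

    # jaw bone: a trabecular band centered on the dental arch (hosting the
    # roots and the canal) plus two dense cortical rami posterior of the
    # arch ends; the rami share the MIP's top intensity clusters with the
    # enamel, so only the spatial quadrangle can reject them
    body2d, wing2d = jaw_footprints(cfg)

    z_mid = nz / 2.0
    gap = cfg.bite_gap_px
    L = cfg.tooth_length_px
    canal_poly = np.empty((0, 3))
    canal_z = None
    root_top = z_mid + gap / 2.0 + 0.35 * L   # start of upper root zone
    if cfg.canal:
        # safely below the deepest root caps so the single-slice image shows
        # uniform bone at the canal rows
        canal_z = float(np.floor(z_mid - gap / 2.0 - L - 12.0))
    upper_band = (np.arange(nz) >= root_top) & (np.arange(nz) <= z_mid + gap / 2.0 + L + 6)
    lower_lo = (canal_z - 8.0) if canal_z is not None else z_mid - gap / 2.0 - L - 6
    lower_band = (np.arange(nz) >= lower_lo) & (np.arange(nz) <= z_mid - gap / 2.0 - 0.35 * L)
    zband = upper_band | lower_band
    data[:, :, zband] = np.where(body2d[:, :, None], cfg.jaw_bone, data[:, :, zband])
    data[:, :, zband] = np.where(wing2d[:, :, None], cfg.ramus_bone, data[:, :, zband])

    # mandibular canal: a low-intensity tube inside the lower bone band.
    # Real canals run in the posterior jaw body and end at the mental
    # foramina, so the tube spans the molar/premolar segments on each side,
    # at a fixed lingual offset from the lower root line
    if cfg.canal:
        branches = []
        for side in (-1.0, 1.0):
            xs = np.sort(apex_x + side * np.linspace(0.35 * half_span, half_span, 100))
            xy = _parabola_xy(cfg.arch_coeffs, xs)
            out = _outward_normal(cfg.arch_coeffs, xs)
            # roots of the lower teeth tilt lingually by (L/2)·sin(tilt);
            # the canal sits canal_offset_px further lingual of that line
            s_here = _parabola_arclength(cfg.arch_coeffs, apex_x, xs)
            s_max = float(_parabola_arclength(cfg.arch_coeffs, apex_x,
                                              apex_x + half_span))
            frac = np.minimum(np.abs(s_here) / s_max, 1.0)
            tilt = np.deg2rad((cfg.incisor_tilt_deg
                               + (cfg.molar_tilt_deg - cfg.incisor_tilt_deg) * frac)
                              * cfg.lower_tilt_scale)
            root_off = -(L / 2.0) * np.sin(tilt)
            off = root_off - cfg.canal_offset_px
            pts = xy + off[:, None] * out
            branch = np.column_stack([pts, np.full(len(pts), canal_z)])
            branches.append(branch)
            r_canal = cfg.canal_radius_mm / cfg.spacing_mm
            for p0, p1 in zip(branch[:-1], branch[1:]):
                _paint_capsule(data, p0, p1, [(r_canal, cfg.soft_tissue)])
        canal_poly = np.concatenate(branches, axis=0)

    # teeth: concentric capsule shells, enamel outermost
    r = cfg.crown_radius_px
    r_dent = r - cfg.enamel_thickness_mm / cfg.spacing_mm
    r_pulp = cfg.pulp_radius_mm / cfg.spacing_mm
    bad: list[str] = []
    implant_id = None
    if cfg.implant:
        mid = cfg.n_teeth_per_jaw // 4  # a premolar-ish position
        implant_id = f"U{mid + 1:02d}"
    for t in teeth:
        if t.tooth_id == implant_id:
            shells = [(r, cfg.implant_intensity)]
        else:
            shells = [(r, cfg.enamel), (r_dent, cfg.dentine), (r_pulp, cfg.pulp)]
        ok = _paint_capsule(data, t.root_end, t.crown_end, shells)
        if not ok:
            bad.append(t.tooth_id)
    if bad:
        raise PhantomError(f"teeth overlap the volume boundary: {', '.join(bad)}")

    if cfg.noise_sigma > 0:
        rng = np.random.default_rng(cfg.seed)
        data = data + rng.normal(0.0, cfg.noise_sigma, size=data.shape).astype(np.float32)

    vol = Volume(data=data, spacing=np.full(3, cfg.spacing_mm))
    truth = PhantomTruth(
        arch_coeffs=cfg.arch_coeffs,
        teeth=teeth,
        canal_polyline=canal_poly,
        bite_gap_px=cfg.bite_gap_px,
        intensities={
            "background": 0.0,
            "soft_tissue": cfg.soft_tissue,
            "jaw_bone": cfg.jaw_bone,
            "ramus_bone": cfg.ramus_bone,
            "dentine": cfg.dentine,
            "enamel": cfg.enamel,
            "pulp": cfg.pulp,
        },
        config=cfg,
    )
    return vol, truth


def truth_surface_points(truth: PhantomTruth, samples_per_tooth: int) -> np.ndarray:
    """Points along each tooth's true long axis (root end to crown end).

    These are the targets the extracted panoramic surface must pass near.
    """
    if samples_per_tooth < 2:
        raise ValueError("samples_per_tooth must be >= 2")
    pts = []
    for t in truth.teeth:
        fracs = np.linspace(0.0, 1.0, samples_per_tooth)
        seg = t.root_end[None, :] + fracs[:, None] * (t.crown_end - t.root_end)[None, :]
        pts.append(seg)
    return np.concatenate(pts, axis=0)
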