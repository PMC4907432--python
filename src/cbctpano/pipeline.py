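"""End-to-end orchestration: arch curve -> surface -> panoramic radiograph.

``run_pipeline`` is the library entry point; the ``pano`` command-line
interface is a thin wrapper around it.  Every run can write a
self-describing artifact set (resolved config, curve JSON, surface PLY,
radiograph PNGs with rescale sidecars, structured per-step log), so a run
is reproducible from its output directory alone.
"""
from __future__ import annotations

import json
import time
from dataclasses import dataclass, asdict, field
from pathlib import Path
from typing import Optional

import numpy as np

from . import arch_curve as ac
from . import surface as sf
from . import synthesis as syn
from .volume_io import Image2D, Volume, WindowSetting, apply_window, mip_axial, save_image


@dataclass
class PipelineConfig:
    """All tunable parameters of the three pipeline steps."""

    # step 1: arch curve
    k_mip: int = 5
    p: float = 0.75
    use_quadrangle: bool = True
    bone_top_clusters: int | str = "auto"
    n_control_points: int = 7
    step_px: float = 10.0
    half_length_px: float = 50.0
    z_band: Optional[tuple[float, float]] = None
    # step 2: surface
    k_section: int = 4
    min_area: int = 10
    degree: int = 5
    k_neighbors: int = 9
    # step 3: synthesis
    reference_row: str = "mid"
    thickened_slices: Optional[int] = None
    aggregate: str = "mean"
    render_cylinder: bool = False
    # misc
    seed: int = 0
    window_width: Optional[float] = None
    window_level: Optional[float] = None

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        import yaml

        raw = yaml.safe_load(Path(path).read_text()) or {}
        if raw.get("z_band") is not None:
            raw["z_band"] = tuple(float(v) for v in raw["z_band"])
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> None:
        import yaml

        d = asdict(self)
        if d["z_band"] is not None:
            d["z_band"] = list(d["z_band"])
        Path(path).write_text(yaml.safe_dump(d, sort_keys=False))


@dataclass
class PipelineResult:
    mip: Image2D
    bone_mask: np.ndarray
    quadrangle: Optional[ac.Quadrangle]
    parabola: ac.Parabola
    control_points: np.ndarray
    curve: ac.ArchCurve
    lines: list[ac.NormalLine]
    curves: list[sf.LongAxialCurve]
    surface: sf.PanoramicSurface
    w_coords: np.ndarray
    h_coords: np.ndarray
    panoramic: syn.DevelopedImage
    thickened: Optional[syn.DevelopedImage]
    cylinder: Optional[syn.DevelopedImage]
    timings: dict = field(default_factory=dict)
    counts: dict = field(default_factory=dict)


def extract_arch(vol: Volume, cfg: PipelineConfig):
    """Step 1: MIP, bone segmentation, arch isolation, parabola, spline."""
    mip = mip_axial(vol, z_band=cfg.z_band)
    mask, thr = ac.segment_bone(mip, k=cfg.k_mip, seed=cfg.seed,
                                top_clusters=cfg.bone_top_clusters)
    quad = None
    arch_mask = mask
    if cfg.use_quadrangle:
        quad = ac.spatial_quadrangle(mask, p=cfg.p)
        arch_mask = ac.isolate_arch(mask, quad)
    pb = ac.fit_parabola(arch_mask, image_shape=mip.data.shape)
    ctrl = ac.select_control_points(pb, arch_mask, n=cfg.n_control_points)
    curve = ac.build_hermite_spline(ctrl)
    return mip, mask, quad, arch_mask, pb, ctrl, curve


def run_pipeline(vol: Volume, cfg: Optional[PipelineConfig] = None,
                 outdir: Optional[str | Path] = None) -> PipelineResult:
    """Run the three synthesis steps on a volume.

    When ``outdir`` is given, all artifacts (overlay, curve JSON, surface
    PLY, radiographs, resolved config, log) are written there.
    """
    cfg = cfg or PipelineConfig()
    timings: dict[str, float] = {}
    counts: dict[str, int] = {}

    t0 = time.perf_counter()
    mip, mask, quad, arch_mask, pb, ctrl, curve = extract_arch(vol, cfg)
    lines = ac.sample_perpendicular_lines(curve, cfg.step_px, cfg.half_length_px)
    timings["step1_arch_curve"] = time.perf_counter() - t0

    t0 = time.perf_counter()
    curves = []
    for i, line in enumerate(lines):
        sec = sf.extract_section(vol, line)
        m = sf.segment_teeth_section(sec, k=cfg.k_section, seed=cfg.seed + 1 + i,
                                     min_area=cfg.min_area)
        curves.append(sf.fit_long_axial_curve(m, degree=cfg.degree,
                                              n_slices=vol.n_slices,
                                              half_length=sec.half_length))
    surf = sf.build_surface(curves, lines, n_slices=vol.n_slices)
    surf = sf.estimate_normals(surf, k_neighbors=cfg.k_neighbors)
    timings["step2_surface"] = time.perf_counter() - t0
    counts["sections_processed"] = len(lines)
    counts["columns_fitted"] = sum(c.source == "fitted" for c in curves)
    counts["columns_interpolated"] = sum(s == "interpolated" for s in surf.column_sources)

    t0 = time.perf_counter()
    w, h = syn.develop_surface(surf, reference_row=cfg.reference_row)
    pano = syn.render_single_slice(vol, surf, w, h)
    thick = None
    if cfg.thickened_slices and cfg.thickened_slices > 1:
        thick = syn.render_thickened(vol, surf, w, h, cfg.thickened_slices,
                                     aggregate=cfg.aggregate)
    cyl = None
    if cfg.render_cylinder:
        cyl = syn.render_cylinder_baseline(vol, curve, n_slices=1)
    timings["step3_synthesis"] = time.perf_counter() - t0

    result = PipelineResult(mip=mip, bone_mask=mask, quadrangle=quad, parabola=pb,
                            control_points=ctrl, curve=curve, lines=lines,
                            curves=curves, surface=surf, w_coords=w, h_coords=h,
                            panoramic=pano, thickened=thick, cylinder=cyl,
                            timings=timings, counts=counts)
    if outdir is not None:
        write_artifacts(result, cfg, Path(outdir))
    return result


def write_artifacts(res: PipelineResult, cfg: PipelineConfig, outdir: Path) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cfg.to_yaml(outdir / "config.yaml")

    win = None
    if cfg.window_width and cfg.window_level is not None:
        win = WindowSetting(width=cfg.window_width, level=cfg.window_level)
    _write_overlay(res, outdir / "mip_overlay.png", win)

    curve_json = {
        "control_points": res.control_points.tolist(),
        "tangents": res.curve.tangents.tolist(),
        "parabola": {"coeffs": list(res.parabola.coeffs),
                     "rotation": res.parabola.rotation,
                     "center": list(res.parabola.center)},
        "total_arc_length_px": res.curve.total_length,
    }
    (outdir / "arch_curve.json").write_text(json.dumps(curve_json, indent=2))

    res.surface.to_mesh().export(outdir / "surface.ply")

    save_image(res.panoramic.to_image(), outdir / "panoramic_single.png", bit_depth=16)
    if res.thickened is not None:
        save_image(res.thickened.to_image(), outdir / "panoramic_thickened.png", bit_depth=16)
    if res.cylinder is not None:
        save_image(res.cylinder.to_image(), outdir / "panoramic_cylinder.png", bit_depth=16)

    log = {"timings_s": res.timings, "counts": res.counts, "seed": cfg.seed}
    (outdir / "pipeline_log.json").write_text(json.dumps(log, indent=2))


def _write_overlay(res: PipelineResult, path: Path, win: Optional[WindowSetting]) -> None:
    """MIP image with the fitted arch curve and control points drawn on top."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    img = res.mip
    if win is not None:
        img = apply_window(img, win)
    fig, ax = plt.subplots(figsize=(6, 6))
    ax.imshow(img.data.T, cmap="gray", origin="lower")
    ts = np.linspace(0, res.control_points.shape[0] - 1, 500)
    pts = res.curve.evaluate(ts)
    ax.plot(pts[:, 0], pts[:, 1], "-", color="lime", linewidth=1.5)
    ax.plot(res.control_points[:, 0], res.control_points[:, 1], "o",
            color="red", markersize=3)
    if res.quadrangle is not None:
        cx, cy = res.quadrangle.center
        hx, hy = res.quadrangle.half_extents
        ax.add_patch(plt.Rectangle((cx - hx, cy - hy), 2 * hx, 2 * hy,
                                   fill=False, edgecolor="yellow", linewidth=1))
    ax.set_axis_off()
    fig.savefig(path, dpi=120, bbox_inches="tight")
    plt.close(fig)
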