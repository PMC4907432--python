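"""Shared phantom/pipeline fixtures.

Phantom generation and full pipeline runs are the expensive pieces, so the
standard study phantoms are session-scoped and shared across test modules.
"""
from __future__ import annotations

import warnings

import numpy as np
import pytest

from cbctpano import PhantomConfig, generate_phantom
from cbctpano.pipeline import PipelineConfig, run_pipeline

warnings.filterwarnings("ignore", category=UserWarning)


def degenerate_phantom_config() -> PhantomConfig:
    """Tilt-free degenerate phantom: the closest realizable instance of the
    limit in which the panoramic surface coincides with the cylinder sheet.

    Gentle arch (so 10-px section sampling resolves the curvature:
    kappa * step^2 / 8 << 1 voxel), homogeneous vertical teeth (no internal
    layering), no overjet, no rami.
    """
    a = 0.012
    return PhantomConfig(
        arch_coeffs=(a, -2 * a * 80, a * 6400 + 55),
        n_teeth_per_jaw=8,
        incisor_tilt_deg=0.0,
        molar_tilt_deg=0.0,
        overjet_mm=0.0,
        include_rami=False,
        enamel_thickness_mm=1.8,
        pulp_radius_mm=0.003,
    )


def idealized_pipeline_config(**kw) -> PipelineConfig:
    """Pipeline configuration for degenerate-limit checks: enamel-only bone
    mask, no spatial quadrangle, fine spline."""
    base = dict(bone_top_clusters=1, use_quadrangle=False, n_control_points=17)
    base.update(kw)
    return PipelineConfig(**base)


@pytest.fixture(scope="session")
def default_phantom():
    """The standard study phantom: 160^3, 10 teeth/jaw, 15 deg incisor tilt."""
    return generate_phantom(PhantomConfig())


@pytest.fixture(scope="session")
def default_result(default_phantom):
    vol, _ = default_phantom
    return run_pipeline(vol, PipelineConfig(render_cylinder=True))


@pytest.fixture(scope="session")
def canal_phantom():
    return generate_phantom(PhantomConfig(canal=True))


@pytest.fixture(scope="session")
def canal_result(canal_phantom):
    vol, _ = canal_phantom
    return run_pipeline(vol, PipelineConfig())


@pytest.fixture(scope="session")
def degenerate_phantom():
    return generate_phantom(degenerate_phantom_config())


@pytest.fixture(scope="session")
def small_phantom():
    """Cheaper phantom for unit tests that only need plausible anatomy."""
    return generate_phantom(PhantomConfig(dims=(112, 112, 112), n_teeth_per_jaw=7))


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
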