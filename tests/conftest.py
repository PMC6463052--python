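"""Shared fixtures: small phantoms and canonical geometries."""

from __future__ import annotations

import numpy as np
import pytest

from oftflow import geometry, phantom
from oftflow.segment import Contour


def circle_contour(radius: float, cx: float = 0.0, cy: float = 0.0,
                   n: int = 64, slice_index: int = 0,
                   phase_index: int = 0) -> Contour:
    th = np.arange(n) * 2 * np.pi / n
    verts = np.column_stack([cx + radius * np.cos(th), cy + radius * np.sin(th)])
    return Contour(vertices=verts, slice_index=slice_index,
                   phase_index=phase_index)


def cylinder_series(radius: float = 0.2, n_slices: int = 51,
                    spacing: float = 0.02) -> geometry.CrossSectionSeries:
    contours = [[circle_contour(radius, slice_index=k)] for k in range(n_slices)]
    return geometry.CrossSectionSeries(contours=contours,
                                       slice_spacing_mm=spacing)


@pytest.fixture(scope="session")
def small_phantom_config() -> phantom.PhantomConfig:
    """Compact phantom: quick to generate, retains all dynamics."""
    return phantom.PhantomConfig(
        n_slices=9,
        image_depth_px=48,
        image_width_px=48,
        speckle_noise_sd=0.0,
    )


@pytest.fixture(scope="session")
def small_phantom(small_phantom_config) -> phantom.PhantomDataset:
    return phantom.generate_phantom(small_phantom_config, seed=11)


@pytest.fixture(scope="session")
def cylinder_mesh() -> geometry.TubeMesh:
    """Straight cylinder r=0.2 mm, body length 1 mm, with extensions."""
    series = cylinder_series()
    return geometry.build_mesh(
        series, 0, target_axial_layers=12,
        target_circumferential_divisions=16, radial_layers=3,
        extension_length_factor=1.0,
    )
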