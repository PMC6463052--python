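"""Lumen (and wall) contour extraction from synchronized cross-sections.

A radial edge detector adequate for star-convex lumens: rays are cast
from a seed point inside the dark lumen, the inner wall edge is placed
at the maximum positive intensity gradient along each ray, the radius
function is median-filtered over angle and smoothed periodically, and
the result is emitted as a closed counterclockwise polygon in physical
(mm) coordinates.  A second pass beyond the inner edge locates the
outer (myocardial) boundary at the strongest negative gradient so that
wall-area maps can be produced.

Fully coapted (zero-lumen) configurations are flagged rather than
contoured: when the median detected radius falls below a pixel
threshold the contour is marked ``is_closed_lumen`` and carries no
polygon.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import map_coordinates, median_filter


class SegmentationError(RuntimeError):
    """Raised when no reliable lumen boundary can be found."""


@dataclass
class SegmentParams:
    """Tunables of the radial edge detector (pixel units unless noted)."""

    n_angles: int = 64
    n_vertices: int = 64
    max_radius_px: float | None = None  # default: half the smaller image side
    radial_step_px: float = 0.25
    min_gradient: float = 0.05          # per-pixel intensity rise to accept an edge
    closure_radius_px: float = 3.0      # median radius below this -> closed lumen
    median_window: int = 5              # circular median filter width over angle
    smooth_window: int = 7              # circular boxcar width for final smoothing
    max_failed_ray_fraction: float = 0.25
    wall_search_px: float = 12.0        # extra reach for the outer (wall) edge


@dataclass
class Contour:
    """Closed lumen (or wall) polygon for one slice at one phase.

    ``vertices`` are ordered counterclockwise in the (x, y) = (width,
    depth) plane, in mm; vertex 0 lies at angle 0 (image +x axis) so
    that vertices correspond across slices and phases.
    """

    vertices: np.ndarray  # (n, 2) in mm; empty when is_closed_lumen
    slice_index: int = 0
    phase_index: int = 0
    is_closed_lumen: bool = False
    seed_point_mm: np.ndarray = field(default_factory=lambda: np.zeros(2))
    layer: str = "lumen"

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, dtype=float).reshape(-1, 2)
        if not self.is_closed_lumen and len(self.vertices) < 8:
            raise ValueError("open contour needs at least 8 vertices")


def _circular_smooth(values: np.ndarray, window: int) -> np.ndarray:
    if window <= 1:
        return values
    kernel = np.ones(window) / window
    padded = np.concatenate([values[-window:], values, values[:window]])
    sm = np.convolve(padded, kernel, mode="same")
    return sm[window:-window]


def _radial_profiles(
    image: np.ndarray, seed_rc: np.ndarray, angles: np.ndarray, radii: np.ndarray
) -> np.ndarray:
    """Sample image intensity along rays; (n_angles, n_radii)."""
    rows = seed_rc[0] + radii[None, :] * np.sin(angles)[:, None]
    cols = seed_rc[1] + radii[None, :] * np.cos(angles)[:, None]
    return map_coordinates(image, [rows, cols], order=1, mode="nearest")


def _edge_radii(
    profiles: np.ndarray, radii: np.ndarray, min_gradient: float, step: float
) -> tuple[np.ndarray, np.ndarray]:
    """Per-ray radius of maximum positive gradient and a validity mask."""
    grad = np.gradient(profiles, axis=1) / step
    idx = np.argmax(grad, axis=1)
    strength = grad[np.arange(len(idx)), idx]
    ok = strength >= min_gradient
    # sub-pixel refinement of the gradient peak
    r = radii[idx].astype(float)
    interior = (idx > 0) & (idx < len(radii) - 1)
    g0 = grad[np.arange(len(idx)), np.maximum(idx - 1, 0)]
    g2 = grad[np.arange(len(idx)), np.minimum(idx + 1, len(radii) - 1)]
    denom = g0 - 2 * strength + g2
    delta = np.where((denom < 0) & interior, 0.5 * (g0 - g2) / denom, 0.0)
    return r + np.clip(delta, -1.0, 1.0) * step, ok


def segment_lumen(
    image: np.ndarray,
    seed_point: tuple[float, float],
    pixel_size_mm: float,
    params: SegmentParams | None = None,
    slice_index: int = 0,
    phase_index: int = 0,
) -> Contour:
    """Extract the inner (endocardial) lumen contour around a seed point.

    ``seed_point`` is (row, col) in pixels, inside the dark lumen.
    Raises :class:`SegmentationError` when the seed sits on bright
    tissue or too many rays find no edge; returns a contour flagged
    ``is_closed_lumen`` (no polygon) when the lumen is coapted.
    """
    p = params or SegmentParams()
    image = np.asarray(image, dtype=float)
    seed_rc = np.asarray(seed_point, dtype=float)
    if not (0 <= seed_rc[0] < image.shape[0] and 0 <= seed_rc[1] < image.shape[1]):
        raise SegmentationError("seed point outside image")
    lo, hi = np.percentile(image, [5, 95])
    bright = lo + 0.6 * (hi - lo)
    seed_val = map_coordinates(image, [[seed_rc[0]], [seed_rc[1]]], order=1)[0]
    if seed_val > bright:
        # Either the lumen is fully coapted (wall tissue fills the
        # neighborhood) or the seed was misplaced onto bright tissue of
        # an open section.  Probe a closure-radius disk to distinguish.
        rr = np.arange(-p.closure_radius_px, p.closure_radius_px + 1)
        patch = map_coordinates(
            image,
            [seed_rc[0] + rr[:, None] + 0 * rr[None, :],
             seed_rc[1] + 0 * rr[:, None] + rr[None, :]],
            order=1, mode="nearest",
        )
        if patch.min() > bright - 0.2 * (hi - lo):
            return Contour(
                vertices=np.empty((0, 2)),
                slice_index=slice_index,
                phase_index=phase_index,
                is_closed_lumen=True,
                seed_point_mm=seed_rc[::-1] * pixel_size_mm,
            )
        raise SegmentationError("seed point lies on bright tissue, not lumen")

    max_r = p.max_radius_px or (min(image.shape) / 2.0 - 1.0)
    angles = np.arange(p.n_angles) * 2.0 * np.pi / p.n_angles
    radii = np.arange(0.0, max_r, p.radial_step_px)
    profiles = _radial_profiles(image, seed_rc, angles, radii)
    edge_r, ok = _edge_radii(profiles, radii, p.min_gradient, p.radial_step_px)
    if (~ok).mean() > p.max_failed_ray_fraction:
        raise SegmentationError(
            f"no wall edge on {(~ok).mean():.0%} of rays (limit "
            f"{p.max_failed_ray_fraction:.0%})"
        )
    edge_r = np.where(ok, edge_r, np.median(edge_r[ok]))
    edge_r = median_filter(edge_r, size=p.median_window, mode="wrap")
    edge_r = _circular_smooth(edge_r, p.smooth_window)

    seed_mm = seed_rc[::-1] * pixel_size_mm  # (x, y)
    if np.median(edge_r) < p.closure_radius_px:
        return Contour(
            vertices=np.empty((0, 2)),
            slice_index=slice_index,
            phase_index=phase_index,
            is_closed_lumen=True,
            seed_point_mm=seed_mm,
        )

    out_angles = np.arange(p.n_vertices) * 2.0 * np.pi / p.n_vertices
    r_out = np.interp(out_angles, angles, edge_r, period=2.0 * np.pi)
    x = (seed_rc[1] + r_out * np.cos(out_angles)) * pixel_size_mm
    y = (seed_rc[0] + r_out * np.sin(out_angles)) * pixel_size_mm
    verts = np.column_stack([x, y])
    if _shoelace(verts) < 0:
        verts = verts[::-1]
    return Contour(
        vertices=verts,
        slice_index=slice_index,
        phase_index=phase_index,
        seed_point_mm=seed_mm,
    )


def segment_wall(
    image: np.ndarray,
    lumen: Contour,
    seed_point: tuple[float, float],
    pixel_size_mm: float,
    params: SegmentParams | None = None,
) -> Contour:
    """Outer (myocardial) contour: strongest negative gradient beyond the
    lumen edge along each ray (wall -> background transition)."""
    p = params or SegmentParams()
    image = np.asarray(image, dtype=float)
    seed_rc = np.asarray(seed_point, dtype=float)
    angles = np.arange(p.n_vertices) * 2.0 * np.pi / p.n_vertices
    if lumen.is_closed_lumen:
        inner_r = np.zeros(p.n_vertices)
    else:
        rel = lumen.vertices / pixel_size_mm - seed_rc[::-1]
        inner_r = np.interp(
            angles,
            np.mod(np.arctan2(rel[:, 1], rel[:, 0]), 2 * np.pi),
            np.hypot(rel[:, 0], rel[:, 1]),
            period=2.0 * np.pi,
        )
    max_r = inner_r.max() + p.wall_search_px
    radii = np.arange(0.0, max_r, p.radial_step_px)
    profiles = _radial_profiles(image, seed_rc, angles, radii)
    grad = np.gradient(profiles, axis=1) / p.radial_step_px
    # only look beyond the inner edge (plus half the radial step)
    beyond = radii[None, :] < (inner_r[:, None] + 2 * p.radial_step_px)
    grad = np.where(beyond, np.inf, grad)
    idx = np.argmin(grad, axis=1)
    outer_r = radii[idx]
    outer_r = median_filter(outer_r, size=p.median_window, mode="wrap")
    outer_r = _circular_smooth(outer_r, p.smooth_window)
    outer_r = np.maximum(outer_r, inner_r + p.radial_step_px)
    x = (seed_rc[1] + outer_r * np.cos(angles)) * pixel_size_mm
    y = (seed_rc[0] + outer_r * np.sin(angles)) * pixel_size_mm
    verts = np.column_stack([x, y])
    if _shoelace(verts) < 0:
        verts = verts[::-1]
    return Contour(
        vertices=verts,
        slice_index=lumen.slice_index,
        phase_index=lumen.phase_index,
        seed_point_mm=seed_rc[::-1] * pixel_size_mm,
        layer="wall",
    )


def _shoelace(verts: np.ndarray) -> float:
    x, y = verts[:, 0], verts[:, 1]
    return 0.5 * float(np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y))


def segment_stack(
    volume: np.ndarray,
    pixel_size_mm: float,
    params: SegmentParams | None = None,
    seed_point: tuple[float, float] | None = None,
    layer: str = "lumen",
) -> list[list[Contour]]:
    """Segment every (phase, slice) plane of a synchronized volume.

    ``volume`` has shape (n_phases, depth, width, n_slices).  The seed
    defaults to the image center and tracks the previous phase's
    centroid per slice.  Slices whose lumen is coapted at a phase yield
    closed-flagged contours; segmentation failures propagate.
    Returns ``contours[slice][phase]``.
    """
    p = params or SegmentParams()
    n_phases, depth, width, n_slices = volume.shape
    default_seed = np.array([depth / 2.0, width / 2.0]) if seed_point is None else np.asarray(seed_point, float)
    out: list[list[Contour]] = []
    for k in range(n_slices):
        per_phase: list[Contour] = []
        seed = default_seed.copy()
        for t in range(n_phases):
            c = segment_lumen(
                volume[t, :, :, k], tuple(seed), pixel_size_mm, p,
                slice_index=k, phase_index=t,
            )
            if layer == "wall":
                c = segment_wall(volume[t, :, :, k], c, tuple(seed), pixel_size_mm, p)
            if not c.is_closed_lumen:
                centroid_px = c.vertices.mean(axis=0) / pixel_size_mm
                seed = 0.5 * default_seed + 0.5 * centroid_px[::-1]
            per_phase.append(c)
        out.append(per_phase)
    return out
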