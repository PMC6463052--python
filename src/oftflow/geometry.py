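"""Contour stacks to areas, volumes, centerlines, area-motion matrices
and simulation-ready hexahedral tube meshes.

The mesh generator lofts cross-sectional contours along the tube axis
into a structured all-hex mesh with an O-grid (butterfly) core: a
central square block mapped smoothly onto half the local radius plus a
ring of radial layers out to the wall, so cells stay well-shaped at the
centerline.  Inlet and outlet are artificially extended with straight
segments (the end contour tapers smoothly to its own area-preserving
circle) to establish parabolic flow; extension cells are tagged so
post-simulation analyses can exclude them.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .segment import Contour, _shoelace


class MeshError(RuntimeError):
    """Raised when a valid mesh cannot be built (closed slice, tangle)."""


# ---------------------------------------------------------------------------
# contour measures
# ---------------------------------------------------------------------------


def contour_area(c: Contour) -> float:
    """Polygon area (mm^2) by the shoelace formula; 0 for closed lumens."""
    if c.is_closed_lumen or len(c.vertices) == 0:
        return 0.0
    area = _shoelace(c.vertices)
    if area < 0:
        raise ValueError("contour is clockwise; expected counterclockwise")
    if _self_intersects(c.vertices):
        raise ValueError("self-intersecting polygon")
    return float(area)


def _self_intersects(verts: np.ndarray) -> bool:
    """Cheap star-convexity check around the centroid (our contours are
    radial by construction): angles must be strictly monotone mod 2*pi."""
    rel = verts - verts.mean(axis=0)
    ang = np.unwrap(np.arctan2(rel[:, 1], rel[:, 0]))
    d = np.diff(ang)
    return not (np.all(d > 0) or np.all(d < 0))


def contour_centroid(c: Contour) -> np.ndarray:
    """Area centroid of the polygon (mm); seed point for closed lumens."""
    if c.is_closed_lumen or len(c.vertices) == 0:
        return np.asarray(c.seed_point_mm, dtype=float)
    x, y = c.vertices[:, 0], c.vertices[:, 1]
    xn, yn = np.roll(x, -1), np.roll(y, -1)
    cross = x * yn - xn * y
    a = 0.5 * np.sum(cross)
    cx = np.sum((x + xn) * cross) / (6.0 * a)
    cy = np.sum((y + yn) * cross) / (6.0 * a)
    return np.array([cx, cy])


@dataclass
class CrossSectionSeries:
    """Grid of contours over [n_slices x n_phases] with derived measures."""

    contours: list[list[Contour]]  # [slice][phase]
    slice_spacing_mm: float

    def __post_init__(self) -> None:
        if self.slice_spacing_mm <= 0:
            raise ValueError("slice spacing must be positive")
        n_phases = {len(row) for row in self.contours}
        if len(n_phases) != 1:
            raise ValueError("incomplete contour grid")

    @property
    def n_slices(self) -> int:
        return len(self.contours)

    @property
    def n_phases(self) -> int:
        return len(self.contours[0])

    @property
    def areas(self) -> np.ndarray:
        """(n_slices, n_phases) areas in mm^2; closed slices carry 0."""
        return np.array(
            [[contour_area(c) for c in row] for row in self.contours]
        )

    @property
    def centroids(self) -> np.ndarray:
        """(n_slices, n_phases, 2) in-plane centroids in mm."""
        return np.array(
            [[contour_centroid(c) for c in row] for row in self.contours]
        )

    def centerline_points(self, phase: int) -> np.ndarray:
        """3-D centroid polyline at one phase: (n_slices, 3) mm."""
        cen = self.centroids[:, phase, :]
        z = np.arange(self.n_slices) * self.slice_spacing_mm
        return np.column_stack([cen, z])

    def closed_mask(self) -> np.ndarray:
        return np.array(
            [[c.is_closed_lumen for c in row] for row in self.contours]
        )


def slab_volume(series: CrossSectionSeries, phase: int) -> float:
    """Lumen volume (mm^3) at one phase by area-slab stacking.

    Each cross-section area is multiplied by the mean of the
    centerpoint distances to its two neighbors (half-gaps at the
    ends), so the estimate works even for phases with closed slices
    that cannot be meshed.
    """
    if series.n_slices < 2:
        raise ValueError("need at least two slices")
    pts = series.centerline_points(phase)
    areas = series.areas[:, phase]
    gaps = np.linalg.norm(np.diff(pts, axis=0), axis=1)
    weights = np.empty(series.n_slices)
    weights[0] = 0.5 * gaps[0]
    weights[-1] = 0.5 * gaps[-1]
    weights[1:-1] = 0.5 * (gaps[:-1] + gaps[1:])
    return float(np.sum(areas * weights))


def centerline_length(series: CrossSectionSeries, phase: int | None = None) -> float:
    """Length (mm) of the centroid polyline.

    By convention measured at a closed configuration of the lumen: if
    ``phase`` is None the phase of minimum total lumen volume is used.
    """
    if phase is None:
        volumes = [slab_volume(series, t) for t in range(series.n_phases)]
        phase = int(np.argmin(volumes))
    pts = series.centerline_points(phase)
    return float(np.sum(np.linalg.norm(np.diff(pts, axis=0), axis=1)))


@dataclass
class AreaMotionMatrix:
    """Cross-sectional areas on a (slice x phase) grid, inlet at row 0.

    Rendered with time horizontal and normalized tube length vertical
    (inlet at the bottom).  ``phase_lag_slope`` is the fitted slope of
    the per-slice phase of maximum area versus normalized length, in
    cycles per tube length (the traveling-wave lag).
    """

    values: np.ndarray  # (n_slices, n_phases), mm^2
    layer: str = "lumen"
    max_phase_per_slice: np.ndarray | None = None
    phase_lag_slope: float | None = None

    def __post_init__(self) -> None:
        if np.any(self.values < 0):
            raise ValueError("areas must be non-negative")


def area_motion(series: CrossSectionSeries, layer: str = "lumen") -> AreaMotionMatrix:
    """Area-motion matrix plus traveling-wave diagnostics.

    The per-slice phase of maximum area is refined by parabolic
    interpolation of the circular argmax, unwrapped along the slice
    axis, and fitted with a straight line whose slope estimates the
    inlet->outlet phase lag per unit normalized length.
    """
    values = series.areas
    n_slices, n_phases = values.shape
    max_phase = np.empty(n_slices)
    for k in range(n_slices):
        row = values[k]
        j = int(np.argmax(row))
        y0, y1, y2 = row[(j - 1) % n_phases], row[j], row[(j + 1) % n_phases]
        denom = y0 - 2 * y1 + y2
        delta = 0.5 * (y0 - y2) / denom if denom < 0 else 0.0
        max_phase[k] = ((j + delta) % n_phases) / n_phases
    unwrapped = np.unwrap(max_phase * 2 * np.pi) / (2 * np.pi)
    s = np.linspace(0.0, 1.0, n_slices)
    slope = float(np.polyfit(s, unwrapped, 1)[0]) if n_slices > 1 else None
    if slope is not None and np.ptp(values, axis=1).max() <= 1e-12:
        slope = None  # static tube: no traveling wave to fit
    return AreaMotionMatrix(
        values=values, layer=layer, max_phase_per_slice=max_phase,
        phase_lag_slope=slope,
    )


# ---------------------------------------------------------------------------
# hexahedral tube mesh
# ---------------------------------------------------------------------------


@dataclass
class TubeMesh:
    """Structured hexahedral mesh of the lumen at one phase.

    Nodes are laid out station-major: node ``q * nodes_per_station +
    local`` belongs to axial station q, so cross-sections, boundary
    faces and the centerline are all index-derivable.  Boundary tags
    partition the boundary: ``inlet_quads`` (first station face),
    ``outlet_quads`` (last), ``wall_quads`` (outer lateral surface).
    ``extension_elements`` marks cells added by the inlet/outlet
    extensions, excluded from post-simulation analyses.
    """

    nodes: np.ndarray              # (N, 3) mm
    hexes: np.ndarray              # (E, 8) VTK ordering
    nodes_per_station: int
    n_stations: int
    station_z: np.ndarray          # axial coordinate per station (mm)
    is_extension_station: np.ndarray  # bool per station
    center_local: int              # local index of the centerline node
    boundary_ring_local: np.ndarray  # local node indices of the wall ring
    ring_theta: np.ndarray         # angle of each wall-ring node
    inlet_quads: np.ndarray
    outlet_quads: np.ndarray
    wall_quads: np.ndarray         # (n_wall, 4) node ids
    wall_elems: np.ndarray         # adjacent hex per wall quad
    wall_theta_idx: np.ndarray     # circumferential index per wall quad
    wall_axial_idx: np.ndarray     # element-layer index per wall quad
    extension_elements: np.ndarray  # bool per hex
    phase_index: int = 0
    includes_extensions: bool = True

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_elements(self) -> int:
        return len(self.hexes)

    @property
    def n_theta(self) -> int:
        return len(self.boundary_ring_local)

    def station_nodes(self, q: int) -> np.ndarray:
        base = q * self.nodes_per_station
        return np.arange(base, base + self.nodes_per_station)

    def centerline_node(self, q: int) -> int:
        return q * self.nodes_per_station + self.center_local

    def analysis_stations(self) -> np.ndarray:
        return np.flatnonzero(~self.is_extension_station)

    def wall_nodes(self) -> np.ndarray:
        """All node ids on the lateral (no-slip) boundary."""
        ring = self.boundary_ring_local
        all_ids = (
            np.arange(self.n_stations)[:, None] * self.nodes_per_station
            + ring[None, :]
        )
        return all_ids.ravel()

    def section_quads(self, q: int) -> np.ndarray:
        """Transverse face quads at station q (for flow-rate sections)."""
        base = q * self.nodes_per_station
        return self._local_quads + base

    # filled by the builder
    _local_quads: np.ndarray = field(default=None, repr=False)


def _disk_template(m: int, n_rad: int) -> tuple[np.ndarray, np.ndarray, np.ndarray, int, np.ndarray]:
    """Unit-disk butterfly template.

    Returns (points (nps, 2) for a unit boundary radius, quads, local
    indices of the boundary ring in angular order, local index of the
    center node, theta of each ring node).  The core square [-1, 1]^2 is
    mapped onto the half-radius disk with the smooth elliptical mapping
    x' = u*sqrt(1 - v^2/2), y' = v*sqrt(1 - u^2/2); ``n_rad`` further
    layers interpolate out to the unit circle.
    """
    if m % 2 != 0:
        raise ValueError("m (n_theta/4) must be even so a center node exists")
    u = np.linspace(-1.0, 1.0, m + 1)
    uu, vv = np.meshgrid(u, u, indexing="ij")
    core_x = uu * np.sqrt(1.0 - vv**2 / 2.0)
    core_y = vv * np.sqrt(1.0 - uu**2 / 2.0)
    core_pts = 0.5 * np.column_stack([core_x.ravel(), core_y.ravel()])
    core_id = np.arange((m + 1) ** 2).reshape(m + 1, m + 1)

    # perimeter of the core grid in counterclockwise order, starting at
    # (u=1, v=0) which maps to angle 0
    per: list[int] = []
    half = m // 2
    for j in range(half, m):          # right edge upward from v=0
        per.append(core_id[m, j])
    for i in range(m, 0, -1):         # top edge leftward
        per.append(core_id[i, m])
    for j in range(m, 0, -1):         # left edge downward
        per.append(core_id[0, j])
    for i in range(0, m):             # bottom edge rightward
        per.append(core_id[i, 0])
    for j in range(0, half):          # right edge from v=-1 up to v=0
        per.append(core_id[m, j])
    per = np.asarray(per)
    n_theta = per.size  # == 4*m
    theta = np.arctan2(core_pts[per, 1], core_pts[per, 0])
    theta = np.mod(theta, 2.0 * np.pi)

    pts = [core_pts]
    ring_ids = [per]
    next_id = (m + 1) ** 2
    for l in range(1, n_rad + 1):
        f = 0.5 + 0.5 * l / n_rad
        ring = f * np.column_stack([np.cos(theta), np.sin(theta)])
        pts.append(ring)
        ring_ids.append(np.arange(next_id, next_id + n_theta))
        next_id += n_theta
    points = np.vstack(pts)

    quads: list[list[int]] = []
    for i in range(m):
        for j in range(m):
            quads.append(
                [core_id[i, j], core_id[i + 1, j], core_id[i + 1, j + 1], core_id[i, j + 1]]
            )
    for l in range(n_rad):
        inner, outer = ring_ids[l], ring_ids[l + 1]
        for i in range(n_theta):
            i2 = (i + 1) % n_theta
            quads.append([inner[i], inner[i2], outer[i2], outer[i]])
    quads = np.asarray(quads)
    # consistent orientation: positive 2-D Jacobian (counterclockwise)
    p = points[quads]
    u, v = p[:, 1] - p[:, 0], p[:, 3] - p[:, 0]
    area2 = u[:, 0] * v[:, 1] - u[:, 1] * v[:, 0]
    quads[area2 < 0] = quads[area2 < 0][:, ::-1]
    center = int(core_id[half, half])
    return points, quads, ring_ids[-1], center, theta


def _contour_radius_at(c: Contour, theta: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Radius of a (star-convex) contour about its centroid at angles
    ``theta``; returns (radii, centroid)."""
    cen = contour_centroid(c)
    rel = c.vertices - cen
    ang = np.mod(np.arctan2(rel[:, 1], rel[:, 0]), 2 * np.pi)
    order = np.argsort(ang)
    return (
        np.interp(theta, ang[order], np.hypot(rel[:, 0], rel[:, 1])[order],
                  period=2 * np.pi),
        cen,
    )


def _smoothstep(t: np.ndarray) -> np.ndarray:
    t = np.clip(t, 0.0, 1.0)
    return t * t * (3.0 - 2.0 * t)


def build_mesh(
    series: CrossSectionSeries,
    phase: int,
    target_axial_layers: int = 20,
    target_circumferential_divisions: int = 16,
    radial_layers: int = 3,
    extension_length_factor: float = 3.0,
    wall_grading: float = 0.7,
) -> TubeMesh:
    """Structured hex mesh of the lumen at one phase, with extensions.

    Contours are resampled to a matching angular parameterization
    (vertex correspondence anchored at the image +x axis), lofted along
    the centerline onto ``target_axial_layers`` element layers, and
    filled with an O-grid of ``radial_layers`` ring layers over a
    square core.  Straight extensions of length
    ``extension_length_factor`` x local diameter are appended at both
    ends, tapering each end contour to its area-preserving circle over
    the first diameter.  ``wall_grading`` < 1 geometrically refines the
    ring layers toward the wall for better near-wall gradients.

    Raises :class:`MeshError` for phases with closed slices or tangled
    lofts (non-positive cell Jacobians).
    """
    n_theta = target_circumferential_divisions
    if n_theta % 8 != 0:
        raise ValueError("circumferential divisions must be a multiple of 8")
    if any(series.contours[k][phase].is_closed_lumen for k in range(series.n_slices)):
        raise MeshError(f"phase {phase} has closed slices; cannot mesh")

    m = n_theta // 4
    tpl_pts, tpl_quads, ring_local, center_local, theta = _disk_template(
        m, radial_layers
    )
    nps = len(tpl_pts)

    # radii/centroids of every body slice at the template angles; radii
    # are rescaled so the sampled n-gon preserves the contour area
    # (otherwise a coarse circumferential discretization systematically
    # undershoots the lumen volume by the inscribed-polygon deficit)
    dtheta = np.diff(np.concatenate([theta, [theta[0] + 2 * np.pi]]))
    radii = np.empty((series.n_slices, n_theta))
    cents = np.empty((series.n_slices, 2))
    for k in range(series.n_slices):
        r, cents[k] = _contour_radius_at(series.contours[k][phase], theta)
        a_poly = 0.5 * np.sum(r * np.roll(r, -1) * np.sin(dtheta))
        a_true = contour_area(series.contours[k][phase])
        radii[k] = r * np.sqrt(a_true / a_poly) if a_poly > 0 else r
    z_body = np.arange(series.n_slices) * series.slice_spacing_mm

    # axial resampling of the body to target_axial_layers element layers
    n_body = target_axial_layers + 1
    zq = np.linspace(z_body[0], z_body[-1], n_body)
    radii_q = np.empty((n_body, n_theta))
    for i in range(n_theta):
        radii_q[:, i] = np.interp(zq, z_body, radii[:, i])
    cents_q = np.column_stack(
        [np.interp(zq, z_body, cents[:, 0]), np.interp(zq, z_body, cents[:, 1])]
    )

    # extensions: taper the end contour to its area-preserving circle
    dz = zq[1] - zq[0]
    stations_r: list[np.ndarray] = []
    stations_c: list[np.ndarray] = []
    stations_z: list[float] = []
    is_ext: list[bool] = []

    def extension(r_end: np.ndarray, c_end: np.ndarray, z0: float, direction: float):
        d_local = 2.0 * float(r_end.mean())
        length = extension_length_factor * d_local
        taper = min(d_local, length)
        # extensions only condition the boundary flow; double axial
        # spacing there keeps cell counts down
        n_ext = max(2, int(round(length / (2.0 * dz))))
        r_circle = np.full(n_theta, np.sqrt(np.mean(r_end**2)))
        out_r, out_c, out_z = [], [], []
        for j in range(1, n_ext + 1):
            dist = length * j / n_ext
            t = _smoothstep(dist / taper)
            out_r.append((1 - t) * r_end + t * r_circle)
            out_c.append(c_end)
            out_z.append(z0 + direction * dist)
        return out_r, out_c, out_z

    in_r, in_c, in_z = extension(radii_q[0], cents_q[0], zq[0], -1.0)
    out_r, out_c, out_z = extension(radii_q[-1], cents_q[-1], zq[-1], +1.0)
    for r, c, z in zip(in_r[::-1], in_c[::-1], in_z[::-1]):
        stations_r.append(r); stations_c.append(c); stations_z.append(z)
        is_ext.append(True)
    for i in range(n_body):
        stations_r.append(radii_q[i]); stations_c.append(cents_q[i])
        stations_z.append(zq[i]); is_ext.append(False)
    for r, c, z in zip(out_r, out_c, out_z):
        stations_r.append(r); stations_c.append(c); stations_z.append(z)
        is_ext.append(True)

    n_stations = len(stations_z)
    is_ext_arr = np.asarray(is_ext)

    # per-node radial scale: template point radius relative to unit disk,
    # then scaled by the local contour radius at the point's angle, with
    # geometric grading of the ring layers toward the wall
    tpl_r = np.hypot(tpl_pts[:, 0], tpl_pts[:, 1])
    tpl_a = np.mod(np.arctan2(tpl_pts[:, 1], tpl_pts[:, 0]), 2 * np.pi)
    if wall_grading != 1.0 and radial_layers > 1:
        # remap ring fractions 0.5..1 with geometric spacing (finer at wall)
        ratios = wall_grading ** np.arange(radial_layers)
        steps = 0.5 * ratios / ratios.sum()
        graded = 0.5 + np.concatenate([[0.0], np.cumsum(steps)])
        uniform = 0.5 + 0.5 * np.arange(radial_layers + 1) / radial_layers
        ring_mask = tpl_r > 0.5 - 1e-9
        tpl_r = tpl_r.copy()
        tpl_r[ring_mask] = np.interp(tpl_r[ring_mask], uniform, graded)

    nodes = np.empty((n_stations * nps, 3))
    for q in range(n_stations):
        r_local = np.interp(tpl_a, theta, stations_r[q], period=2 * np.pi)
        scale = tpl_r * r_local
        nodes[q * nps : (q + 1) * nps, 0] = stations_c[q][0] + scale * np.cos(tpl_a)
        nodes[q * nps : (q + 1) * nps, 1] = stations_c[q][1] + scale * np.sin(tpl_a)
        nodes[q * nps : (q + 1) * nps, 2] = stations_z[q]

    n_quads = len(tpl_quads)
    hexes = np.empty(((n_stations - 1) * n_quads, 8), dtype=int)
    ext_elem = np.empty(len(hexes), dtype=bool)
    for q in range(n_stations - 1):
        lo = tpl_quads + q * nps
        hi = tpl_quads + (q + 1) * nps
        hexes[q * n_quads : (q + 1) * n_quads, :4] = lo
        hexes[q * n_quads : (q + 1) * n_quads, 4:] = hi
        ext_elem[q * n_quads : (q + 1) * n_quads] = is_ext_arr[q] or is_ext_arr[q + 1]

    # boundary faces
    inlet_quads = tpl_quads[:, ::-1]  # outward normal -z
    outlet_quads = tpl_quads + (n_stations - 1) * nps
    ring_elem_offset = m * m  # ring quads follow the core quads
    wall_quads = []
    wall_elems = []
    wall_ti = []
    wall_ai = []
    outer_ring_quads = np.arange(
        ring_elem_offset + (radial_layers - 1) * n_theta,
        ring_elem_offset + radial_layers * n_theta,
    )
    for q in range(n_stations - 1):
        for i in range(n_theta):
            a = ring_local[i] + q * nps
            b = ring_local[(i + 1) % n_theta] + q * nps
            c_ = ring_local[(i + 1) % n_theta] + (q + 1) * nps
            d = ring_local[i] + (q + 1) * nps
            wall_quads.append([a, b, c_, d])
            wall_elems.append(q * n_quads + outer_ring_quads[i])
            wall_ti.append(i)
            wall_ai.append(q)

    mesh = TubeMesh(
        nodes=nodes,
        hexes=hexes,
        nodes_per_station=nps,
        n_stations=n_stations,
        station_z=np.asarray(stations_z),
        is_extension_station=is_ext_arr,
        center_local=center_local,
        boundary_ring_local=ring_local,
        ring_theta=theta,
        inlet_quads=inlet_quads,
        outlet_quads=outlet_quads,
        wall_quads=np.asarray(wall_quads),
        wall_elems=np.asarray(wall_elems),
        wall_theta_idx=np.asarray(wall_ti),
        wall_axial_idx=np.asarray(wall_ai),
        extension_elements=ext_elem,
        phase_index=phase,
    )
    mesh._local_quads = tpl_quads
    jmin = hex_jacobian_min(mesh)
    if jmin <= 0:
        raise MeshError(f"tangled loft: minimum cell Jacobian {jmin:.3e} <= 0")
    return mesh


# trilinear hex shape machinery shared with the flow solver
_XI = np.array(
    [[-1, -1, -1], [1, -1, -1], [1, 1, -1], [-1, 1, -1],
     [-1, -1, 1], [1, -1, 1], [1, 1, 1], [-1, 1, 1]],
    dtype=float,
)
_GP = np.array(
    [[sx / np.sqrt(3.0), sy / np.sqrt(3.0), sz / np.sqrt(3.0)]
     for sz in (-1, 1) for sy in (-1, 1) for sx in (-1, 1)]
)


def hex_shape(local: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Trilinear shape functions N (8,) and gradients dN/dxi (8, 3)."""
    xi, eta, zeta = local
    a = _XI
    N = 0.125 * (1 + a[:, 0] * xi) * (1 + a[:, 1] * eta) * (1 + a[:, 2] * zeta)
    dN = 0.125 * np.column_stack(
        [
            a[:, 0] * (1 + a[:, 1] * eta) * (1 + a[:, 2] * zeta),
            (1 + a[:, 0] * xi) * a[:, 1] * (1 + a[:, 2] * zeta),
            (1 + a[:, 0] * xi) * (1 + a[:, 1] * eta) * a[:, 2],
        ]
    )
    return N, dN


def hex_volumes(mesh: TubeMesh) -> np.ndarray:
    """Per-element volumes by 2x2x2 Gauss quadrature."""
    coords = mesh.nodes[mesh.hexes]  # (E, 8, 3)
    vols = np.zeros(len(coords))
    for gp in _GP:
        _, dN = hex_shape(gp)
        J = np.einsum("ai,eaj->eij", dN, coords)
        vols += np.linalg.det(J)
    return vols


def hex_jacobian_min(mesh: TubeMesh) -> float:
    """Minimum Jacobian determinant over all elements and Gauss points."""
    coords = mesh.nodes[mesh.hexes]
    jmin = np.inf
    for gp in _GP:
        _, dN = hex_shape(gp)
        J = np.einsum("ai,eaj->eij", dN, coords)
        jmin = min(jmin, float(np.linalg.det(J).min()))
    return jmin


def mesh_volume(mesh: TubeMesh, include_extensions: bool = False) -> float:
    """Total mesh volume (mm^3), excluding extensions by default."""
    vols = hex_volumes(mesh)
    if not include_extensions:
        vols = vols[~mesh.extension_elements]
    return float(vols.sum())


def export_vtk(mesh: TubeMesh, path: str, point_data: dict | None = None,
               cell_data: dict | None = None) -> None:
    """Write the mesh (and optional fields) as legacy ASCII VTK."""
    with open(path, "w") as f:
        f.write("# vtk DataFile Version 3.0\noftflow tube mesh\nASCII\n")
        f.write("DATASET UNSTRUCTURED_GRID\n")
        f.write(f"POINTS {mesh.n_nodes} double\n")
        np.savetxt(f, mesh.nodes, fmt="%.9g")
        f.write(f"CELLS {mesh.n_elements} {mesh.n_elements * 9}\n")
        cells = np.column_stack([np.full(mesh.n_elements, 8), mesh.hexes])
        np.savetxt(f, cells, fmt="%d")
        f.write(f"CELL_TYPES {mesh.n_elements}\n")
        np.savetxt(f, np.full(mesh.n_elements, 12), fmt="%d")
        if point_data:
            f.write(f"POINT_DATA {mesh.n_nodes}\n")
            for name, arr in point_data.items():
                arr = np.asarray(arr)
                if arr.ndim == 1:
                    f.write(f"SCALARS {name} double 1\nLOOKUP_TABLE default\n")
                    np.savetxt(f, arr, fmt="%.9g")
                else:
                    f.write(f"VECTORS {name} double\n")
                    np.savetxt(f, arr, fmt="%.9g")
        if cell_data:
            f.write(f"CELL_DATA {mesh.n_elements}\n")
            for name, arr in cell_data.items():
                f.write(f"SCALARS {name} double 1\nLOOKUP_TABLE default\n")
                np.savetxt(f, np.asarray(arr, dtype=float), fmt="%.9g")
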