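"""Hemodynamic post-processing: wall shear stress, oscillatory shear
index, flow rates and volumes, cardiac efficiency, unrolled maps.

Wall shear stress is the tangential projection of the wall traction,

    tau = sigma.n - [(sigma.n).n] n,    sigma = -p I + mu (grad u + grad u^T),

evaluated per wall face from the velocity gradient of the adjacent
cell (one-sided, first interior layer).  The oscillatory shear index

    OSI = 1/2 (1 - |int tau dt| / int |tau| dt)

uses time integrals over the *simulated* portion of the cycle only
(closed, unmeshable phases carry no weight), so OSI is 0 for
consistently unidirectional shear and 0.5 for balanced oscillation.

Flow volumes per beat: V_F = int max(Q, 0) dt, V_B = int max(-Q, 0) dt
(both positive magnitudes), stroke volume SV = V_F - V_B and cardiac
efficiency eta = 1 - V_B / V_F.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .flow import FlowField, FluidProps, CycleSimulation, _flux_through
from .geometry import TubeMesh, hex_shape


@dataclass
class WallSample:
    """Per-wall-face traction state of one flow field.

    Arrays are over the analysis-region wall faces (extensions
    excluded): positions, outward unit normals, full traction vectors
    sigma.n, tangential (WSS) vectors tau, and the (theta, s)
    surface parameterization used by the unrolled maps.
    """

    points: np.ndarray     # (F, 3) face centroids, mm
    normals: np.ndarray    # (F, 3) outward unit normals
    sigma_n: np.ndarray    # (F, 3) Pa
    tau: np.ndarray        # (F, 3) Pa
    areas: np.ndarray      # (F,) mm^2
    theta: np.ndarray      # (F,) circumferential angle, [0, 2*pi)
    s: np.ndarray          # (F,) normalized axial position in [0, 1]

    @property
    def tau_mag(self) -> np.ndarray:
        return np.linalg.norm(self.tau, axis=1)


def wall_shear(field: FlowField, include_extensions: bool = False) -> WallSample:
    """WSS vectors on the lateral wall from near-wall velocity gradients.

    The stress tensor is evaluated at each wall-face centroid using the
    trilinear gradient of the single adjacent cell and projected
    tangentially; tau.n = 0 holds exactly by construction.
    """
    mesh = field.mesh
    mu = field.props.viscosity_pa_s
    keep = np.ones(len(mesh.wall_quads), dtype=bool)
    if not include_extensions:
        keep = ~mesh.extension_elements[mesh.wall_elems]
    quads = mesh.wall_quads[keep]
    elems = mesh.wall_elems[keep]
    theta_idx = mesh.wall_theta_idx[keep]
    axial_idx = mesh.wall_axial_idx[keep]

    pts = mesh.nodes[quads]
    centroids = pts.mean(axis=1)
    v1 = pts[:, 1] - pts[:, 0]
    v2 = pts[:, 3] - pts[:, 0]
    nvec = np.cross(v1, v2)
    areas = np.linalg.norm(
        np.cross(pts[:, 2] - pts[:, 0], pts[:, 3] - pts[:, 1]), axis=1
    ) * 0.5
    normals = nvec / np.linalg.norm(nvec, axis=1, keepdims=True)
    # orient outward: away from the adjacent element centroid
    elem_cent = mesh.nodes[mesh.hexes[elems]].mean(axis=1)
    flip = np.einsum("fi,fi->f", normals, centroids - elem_cent) < 0
    normals[flip] *= -1.0

    sigma_n = np.empty_like(centroids)
    hex_nodes = mesh.hexes[elems]
    coords = mesh.nodes[hex_nodes]
    vels = field.velocity[hex_nodes]
    pres = field.pressure[hex_nodes]
    # group faces by their reference-cell face center (identical for the
    # whole structured wall, so this is one batched evaluation)
    locals_ = np.array(
        [_face_local_center(mesh.hexes[elems[f]], quads[f])
         for f in range(len(quads))]
    )
    for loc in np.unique(locals_, axis=0):
        sel = np.flatnonzero((locals_ == loc).all(axis=1))
        N, dN = hex_shape(loc)
        J = np.einsum("ai,faj->fij", dN, coords[sel])
        dNx = np.einsum("ai,fji->faj", dN, np.linalg.inv(J))
        grad_u = np.einsum("fac,faj->fcj", vels[sel], dNx)
        p = pres[sel] @ N
        sig = mu * (grad_u + np.transpose(grad_u, (0, 2, 1)))
        sig -= p[:, None, None] * np.eye(3)[None]
        sigma_n[sel] = np.einsum("fij,fj->fi", sig, normals[sel])
    tau = sigma_n - np.einsum("fi,fi->f", sigma_n, normals)[:, None] * normals

    # (theta, s) parameterization from the structured wall grid
    n_theta = mesh.n_theta
    th = mesh.ring_theta
    theta = (th[theta_idx] + th[(theta_idx + 1) % n_theta]) / 2.0
    wrap = np.abs(th[theta_idx] - th[(theta_idx + 1) % n_theta]) > np.pi
    theta[wrap] = np.mod(theta[wrap] + np.pi, 2 * np.pi)
    z_mid = 0.5 * (mesh.station_z[axial_idx] + mesh.station_z[axial_idx + 1])
    body = ~mesh.is_extension_station
    z0, z1 = mesh.station_z[body][0], mesh.station_z[body][-1]
    s = np.clip((z_mid - z0) / (z1 - z0), 0.0, 1.0)
    return WallSample(
        points=centroids, normals=normals, sigma_n=sigma_n, tau=tau,
        areas=areas, theta=theta, s=s,
    )


def _face_local_center(hex_conn: np.ndarray, quad: np.ndarray) -> np.ndarray:
    """Reference-cell coordinates of a face center given its corner ids."""
    from .geometry import _XI

    pos = np.array([int(np.where(hex_conn == q)[0][0]) for q in quad])
    return _XI[pos].mean(axis=0)


@dataclass
class WallShearSeries:
    """WSS vector time series over the simulated phases.

    ``tau`` has shape (n_simulated, F, 3); ``time_weights`` (seconds)
    are the phase durations of the simulated phases, summing to the
    simulated cycle length T.
    """

    tau: np.ndarray
    phases: np.ndarray          # simulated phase indices
    time_weights: np.ndarray    # (n_simulated,) seconds
    theta: np.ndarray
    s: np.ndarray
    areas: np.ndarray
    sigma_n: np.ndarray | None = None

    @property
    def tau_mag(self) -> np.ndarray:
        return np.linalg.norm(self.tau, axis=2)

    @property
    def simulated_cycle_s(self) -> float:
        return float(self.time_weights.sum())


def collect_wall_series(
    sim: CycleSimulation, period_s: float, n_phases: int = 100
) -> WallShearSeries:
    """Wall shear histories over a cycle simulation.

    Meshes of different phases share the structured wall-face grid, so
    face f refers to the same material wall patch at every phase.
    """
    phases = sim.simulated_phases
    samples = [wall_shear(sim.fields[int(p)]) for p in phases]
    tau = np.stack([s.tau for s in samples])
    sigma_n = np.stack([s.sigma_n for s in samples])
    weights = np.full(len(phases), period_s / n_phases)
    ref = samples[0]
    areas = np.mean([s.areas for s in samples], axis=0)
    return WallShearSeries(
        tau=tau, phases=phases, time_weights=weights,
        theta=ref.theta, s=ref.s, areas=areas, sigma_n=sigma_n,
    )


def osi(series: WallShearSeries) -> np.ndarray:
    """Per-point oscillatory shear index in [0, 0.5].

    Weighted time integrals over the simulated phases (weights = phase
    durations); an all-zero shear history yields OSI 0.
    """
    return osi_from_history(series.tau, series.time_weights)


def osi_from_history(tau: np.ndarray, weights: np.ndarray) -> np.ndarray:
    """OSI for an arbitrary (n_times, ..., 3) shear history."""
    tau = np.asarray(tau, dtype=float)
    if tau.shape[0] < 2:
        raise ValueError("OSI needs at least two time samples")
    w = np.asarray(weights, dtype=float).reshape((-1,) + (1,) * (tau.ndim - 2))
    num = np.linalg.norm((w[..., None] * tau).sum(axis=0), axis=-1)
    den = (w * np.linalg.norm(tau, axis=-1)).sum(axis=0)
    out = np.zeros(num.shape)
    ok = den > 0
    # |integral| <= integral of | | analytically; clip float noise
    out[ok] = np.clip(0.5 * (1.0 - num[ok] / den[ok]), 0.0, 0.5)
    return out


def flow_rate(field: FlowField, station: int | None = None) -> float:
    """Volume flow rate (mm^3/s) through a transverse section.

    ``station`` indexes the mesh's axial stations and must lie in the
    analysis region (extensions excluded); default mid-tube.  Sign
    convention: inlet -> outlet positive.
    """
    mesh = field.mesh
    stations = mesh.analysis_stations()
    if station is None:
        station = int(stations[len(stations) // 2])
    if mesh.is_extension_station[station]:
        raise ValueError(f"station {station} lies in an extension")
    quads = mesh.section_quads(station)
    # section quads are oriented like the disk template (+z normal)
    return _flux_through(mesh.nodes, quads, field.velocity)


def cycle_volumes(Q: np.ndarray, times_s: np.ndarray) -> dict:
    """Forward/backward flow volumes, stroke volume and efficiency.

    Trapezoidal integration of the clipped waveforms over the sampled
    (simulated) times: V_F = int max(Q,0) dt, V_B = int max(-Q,0) dt,
    SV = V_F - V_B, eta = 1 - V_B/V_F (NaN-flagged when V_F = 0).
    """
    Q = np.asarray(Q, dtype=float)
    t = np.asarray(times_s, dtype=float)
    vf = float(np.trapezoid(np.clip(Q, 0.0, None), t))
    vb = float(np.trapezoid(np.clip(-Q, 0.0, None), t))
    sv = vf - vb
    if vf > 0:
        eta, flagged = 1.0 - vb / vf, False
    else:
        eta, flagged = float("nan"), True
    return {"V_F": vf, "V_B": vb, "SV": sv, "eta": eta, "eta_undefined": flagged}


@dataclass
class UnrolledMap:
    """2-D endocardial map: axial position vertical (inlet at the
    bottom row), circumferential angle horizontal, cut at theta = pi."""

    values: np.ndarray   # (n_s, n_theta)
    theta_grid: np.ndarray
    s_grid: np.ndarray


def unroll_surface(
    series: WallShearSeries | WallSample,
    values: np.ndarray,
    n_theta: int = 64,
    n_s: int = 64,
) -> UnrolledMap:
    """Resample per-wall-face values onto a regular (s, theta) grid.

    The cylinder is cut along theta = pi ("top") and unrolled; row 0 is
    the inlet.  Bilinear interpolation with periodic handling in theta.
    """
    theta = np.mod(np.asarray(series.theta) + np.pi, 2 * np.pi)  # cut at pi
    s = np.asarray(series.s)
    values = np.asarray(values, dtype=float)
    th_u = np.unique(theta)
    s_u = np.unique(s)
    grid = values.reshape(-1)[_grid_order(theta, s, th_u, s_u)].reshape(
        len(s_u), len(th_u)
    )
    theta_grid = np.linspace(0.0, 2 * np.pi, n_theta, endpoint=False)
    s_grid = np.linspace(s_u[0], s_u[-1], n_s)
    # interpolate rows (periodic in theta), then columns
    tmp = np.empty((len(s_u), n_theta))
    for i in range(len(s_u)):
        tmp[i] = np.interp(theta_grid, th_u, grid[i], period=2 * np.pi)
    out = np.empty((n_s, n_theta))
    for j in range(n_theta):
        out[:, j] = np.interp(s_grid, s_u, tmp[:, j])
    return UnrolledMap(values=out, theta_grid=theta_grid, s_grid=s_grid)


def _grid_order(theta, s, th_u, s_u) -> np.ndarray:
    """Indices reordering flat face arrays into an (s, theta) grid."""
    ti = np.searchsorted(th_u, theta)
    si = np.searchsorted(s_u, s)
    order = np.full((len(s_u), len(th_u)), -1, dtype=int)
    order[si, ti] = np.arange(len(theta))
    if (order < 0).any():
        raise ValueError("wall faces do not form a complete (s, theta) grid")
    return order.ravel()


def surface_mean(series: WallShearSeries | WallSample, values: np.ndarray) -> float:
    """Area-weighted mean of per-face values over the wall."""
    return float(np.average(np.asarray(values), weights=series.areas))


@dataclass
class HemoSummary:
    """Cycle-integrated hemodynamic metrics of one run.

    Means over space are area-weighted; 'mean WSS' is the pooled
    space-and-time mean over simulated phases ('time-then-space'
    averaging is available via ``mean_wss_time_then_space``).
    """

    Q_waveform: dict[int, float]
    V_F: float
    V_B: float
    SV: float
    eta: float
    max_wss: float
    mean_wss: float
    mean_wss_time_then_space: float
    max_osi: float
    mean_osi: float
    max_forward_velocity: float
    max_backflow_velocity: float
    max_flow_rate: float
    coverage: float
    simulated_cycle_s: float

    def as_dict(self) -> dict:
        d = {k: v for k, v in self.__dict__.items() if k != "Q_waveform"}
        return d

    def to_frame(self):
        """One-row table with the standard per-embryo metric names."""
        import pandas as pd

        return pd.DataFrame(
            {
                "Maximum WSS (Pa)": [self.max_wss],
                "Mean WSS (Pa)": [self.mean_wss],
                "Mean oscillatory shear index (OSI)": [self.mean_osi],
                "Maximum OSI": [self.max_osi],
                "Maximum backflow velocity (mm/s)": [self.max_backflow_velocity],
                "Maximum forward velocity (mm/s)": [self.max_forward_velocity],
                "Backflow volume (mm^3/beat)": [self.V_B],
                "Forward volume (mm^3/beat)": [self.V_F],
                "Stroke volume (mm^3/beat)": [self.SV],
                "Cardiac efficiency": [self.eta],
                "Maximum flow rate (mm^3/s)": [self.max_flow_rate],
                "Simulated fraction of cycle": [self.coverage],
            }
        )


def export_flowfield(field: FlowField, path: str) -> None:
    """Write one phase's solution as legacy VTK: velocity and pressure
    per node, |wall traction| per cell (zero away from the wall)."""
    from .geometry import export_vtk

    mesh = field.mesh
    ws = wall_shear(field, include_extensions=True)
    keep = np.ones(len(mesh.wall_quads), dtype=bool)
    traction_cell = np.zeros(mesh.n_elements)
    traction_cell[mesh.wall_elems[keep]] = np.linalg.norm(ws.sigma_n, axis=1)
    export_vtk(
        mesh, path,
        point_data={"velocity_mm_s": field.velocity,
                    "pressure_pa": field.pressure},
        cell_data={"wall_traction_pa": traction_cell,
                   "is_extension": mesh.extension_elements.astype(float)},
    )


def centerline_velocities(sim: CycleSimulation) -> np.ndarray:
    """Axial velocity at every analysis-station centerline node for each
    simulated phase; shape (n_simulated, n_stations)."""
    rows = []
    for p in sim.simulated_phases:
        f = sim.fields[int(p)]
        nodes = [f.mesh.centerline_node(int(q)) for q in f.mesh.analysis_stations()]
        rows.append(f.velocity[nodes, 2])
    return np.asarray(rows)


def summarize(
    sim: CycleSimulation,
    period_s: float,
    n_phases: int = 100,
    station: int | None = None,
) -> HemoSummary:
    """Assemble the standard metric set from a cycle simulation."""
    series = collect_wall_series(sim, period_s, n_phases)
    tau_mag = series.tau_mag  # (n_sim, F)
    osi_vals = osi(series)
    w_t = series.time_weights / series.time_weights.sum()
    mean_pooled = float(
        np.average(
            tau_mag, weights=np.outer(w_t, series.areas)
        )
    )
    time_avg = np.einsum("t,tf->f", w_t, tau_mag)
    mean_tts = float(np.average(time_avg, weights=series.areas))

    phases = sim.simulated_phases
    Q = {int(p): flow_rate(sim.fields[int(p)], station) for p in phases}
    times = phases * period_s / n_phases
    vols = cycle_volumes(np.array([Q[int(p)] for p in phases]), times)

    cvel = centerline_velocities(sim)
    return HemoSummary(
        Q_waveform=Q,
        V_F=vols["V_F"],
        V_B=vols["V_B"],
        SV=vols["SV"],
        eta=vols["eta"],
        max_wss=float(tau_mag.max()),
        mean_wss=mean_pooled,
        mean_wss_time_then_space=mean_tts,
        max_osi=float(osi_vals.max()),
        mean_osi=surface_mean(series, osi_vals),
        max_forward_velocity=float(cvel.max()),
        max_backflow_velocity=float(cvel.min()),
        max_flow_rate=float(max(Q.values())),
        coverage=sim.coverage,
        simulated_cycle_s=series.simulated_cycle_s,
    )
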