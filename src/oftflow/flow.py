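"""Quasi-steady incompressible viscous flow with traction boundary
conditions, and the inverse inlet-traction fit to a measured velocity.

Each cardiac phase is treated as an independent steady problem (valid
at the Reynolds < 5 and Womersley ~ 0.1 regime of the embryonic
outflow tract).  The discretization is a standard equal-order
trilinear (Q1-Q1) hexahedral mixed formulation with
Brezzi-Pitkaranta pressure stabilization:

    find (u, p):  2*mu*(eps(u), eps(v)) - (p, div v) = <t, v>_Gamma
                  (q, div u) + sum_e tau_e (grad p, grad q)_e = 0

with no-slip walls, uniform normal traction -P*n at the inlet (natural
boundary condition) and zero traction at the outlet.  The
stress-divergence (symmetric gradient) form makes the natural boundary
condition the true traction sigma.n.  Taking q = 1 in the stabilized
continuity equation shows global mass conservation is retained
exactly.  Convective inertia is available through Picard iteration but
defaults off (Stokes), in which case the response to the inlet
traction is exactly linear and the secant inverse fit converges in at
most two solves.

Unit system: lengths mm, velocities mm/s, viscosity Pa.s, pressures
and tractions Pa.  With these choices viscous stresses come out in Pa
directly; density (kg/m^3) is converted internally to Pa.s^2/mm^2
(factor 1e-6) for the inertial term.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .geometry import TubeMesh, hex_shape, _GP

#: 2x2 Gauss points on a quad face, and the local face frame used to
#: evaluate surface integrals.
_GP2 = np.array(
    [[sx / np.sqrt(3.0), sy / np.sqrt(3.0)] for sy in (-1, 1) for sx in (-1, 1)]
)


class FlowError(RuntimeError):
    pass


@dataclass(frozen=True)
class FluidProps:
    """Newtonian blood analog: density kg/m^3, viscosity Pa.s."""

    density_kg_m3: float = 1060.0
    viscosity_pa_s: float = 0.003

    def __post_init__(self) -> None:
        if self.density_kg_m3 <= 0 or self.viscosity_pa_s <= 0:
            raise ValueError("density and viscosity must be strictly positive")

    @property
    def rho_internal(self) -> float:
        """Density in Pa.s^2/mm^2 (consistent with mm, mm/s, Pa)."""
        return self.density_kg_m3 * 1e-6


@dataclass
class FlowField:
    """Velocity/pressure solution on one phase's mesh."""

    mesh: TubeMesh
    velocity: np.ndarray        # (n_nodes, 3) mm/s
    pressure: np.ndarray        # (n_nodes,) Pa
    inlet_traction: float       # applied uniform normal traction, Pa
    props: FluidProps
    residuals: dict = field(default_factory=dict)


@dataclass
class InverseFitResult:
    traction_history: list[float]
    velocity_history: list[float]
    converged: bool
    final_relative_error: float
    n_solves: int


def _face_normal_load(nodes: np.ndarray, quads: np.ndarray, traction: float):
    """Nodal force vectors for sigma.n = traction * n_hat on the faces
    (n_hat = outward unit normal implied by quad orientation)."""
    pts = nodes[quads]
    corners = np.array([[-1, -1], [1, -1], [1, 1], [-1, 1]], dtype=float)
    load = np.zeros((len(quads), 4, 3))
    for g in _GP2:
        N = 0.25 * (1 + corners[:, 0] * g[0]) * (1 + corners[:, 1] * g[1])
        dNdxi = 0.25 * corners[:, 0] * (1 + corners[:, 1] * g[1])
        dNdeta = 0.25 * (1 + corners[:, 0] * g[0]) * corners[:, 1]
        t1 = np.einsum("a,fai->fi", dNdxi, pts)
        t2 = np.einsum("a,fai->fi", dNdeta, pts)
        nvec = np.cross(t1, t2)  # area-weighted normal (dA included)
        load += traction * N[None, :, None] * nvec[:, None, :]
    return load


class StokesOperator:
    """Assembled (and factorized) system for one mesh + fluid pairing.

    Kept separate from :func:`solve_steady` so the inverse fit can
    reuse the factorization across traction updates (the matrix does
    not depend on the inlet traction).
    """

    def __init__(self, mesh: TubeMesh, props: FluidProps, stab_alpha: float = 0.05):
        self.mesh = mesh
        self.props = props
        self.stab_alpha = stab_alpha
        self._assemble()

    def _assemble(self) -> None:
        mesh, props = self.mesh, self.props
        mu = props.viscosity_pa_s
        coords = mesh.nodes[mesh.hexes]  # (E, 8, 3)
        E = len(coords)
        n = mesh.n_nodes

        A = np.zeros((E, 8, 8))            # grad-grad
        T = np.zeros((E, 8, 3, 8, 3))      # dN_a/dx_i dN_b/dx_j
        P = np.zeros((E, 8, 8, 3))         # N_a dN_b/dx_i
        vol = np.zeros(E)
        self._dNx_gp = []
        self._detJ_gp = []
        for gp in _GP:
            N, dN = hex_shape(gp)
            J = np.einsum("ai,eaj->eij", dN, coords)
            detJ = np.linalg.det(J)
            invJ = np.linalg.inv(J)
            # J[i, j] = dx_j/dxi_i, so dN/dx = dN/dxi . inv(J)^T
            dNx = np.einsum("ai,eji->eaj", dN, invJ)  # (E, 8, 3)
            w = detJ  # unit gauss weights
            A += w[:, None, None] * np.einsum("eai,ebi->eab", dNx, dNx)
            T += w[:, None, None, None, None] * np.einsum(
                "eai,ebj->eaibj", dNx, dNx
            )
            P += w[:, None, None, None] * np.einsum("a,ebi->eabi", N, dNx)
            vol += w
            self._dNx_gp.append(dNx)
            self._detJ_gp.append(detJ)

        h2 = vol ** (2.0 / 3.0)
        tau = self.stab_alpha * h2 / mu

        # element matrices in dof order [ux(8), uy(8), uz(8), p(8)]
        Ke = np.zeros((E, 32, 32))
        for i in range(3):
            for j in range(3):
                block = mu * T[:, :, j, :, i]
                if i == j:
                    block = block + mu * A
                Ke[:, 8 * i : 8 * i + 8, 8 * j : 8 * j + 8] = block
        for i in range(3):
            # momentum: -(p, d_i v) -> G[a, b] = -int dN_a/dx_i N_b
            Ke[:, 8 * i : 8 * i + 8, 24:32] = -np.transpose(P[:, :, :, i], (0, 2, 1))
            # continuity: (q, d_i u_i) -> D[a, b] = int N_a dN_b/dx_i
            Ke[:, 24:32, 8 * i : 8 * i + 8] = P[:, :, :, i]
        Ke[:, 24:32, 24:32] = tau[:, None, None] * A

        edof = np.concatenate(
            [mesh.hexes + k * n for k in range(4)], axis=1
        )  # (E, 32)
        rows = np.repeat(edof, 32, axis=1).ravel()
        cols = np.tile(edof, (1, 32)).ravel()
        K = sp.coo_matrix(
            (Ke.ravel(), (rows, cols)), shape=(4 * n, 4 * n)
        ).tocsr()

        # no-slip walls: Dirichlet u = 0 on all lateral-boundary nodes
        wall = np.unique(mesh.wall_nodes())
        bc = np.concatenate([wall + k * n for k in range(3)])
        free = np.ones(4 * n, dtype=bool)
        free[bc] = False
        keep = sp.diags(free.astype(float))
        K = keep @ K @ keep + sp.diags((~free).astype(float))
        self.K = K.tocsc()
        self.bc_dofs = bc
        self.free = free
        self._lu = None
        self._n = n

        # inlet load template at unit traction (scales linearly)
        self._unit_load = np.zeros(4 * n)
        load = _face_normal_load(mesh.nodes, mesh.inlet_quads, -1.0)
        for a in range(4):
            for i in range(3):
                np.add.at(
                    self._unit_load,
                    mesh.inlet_quads[:, a] + i * n,
                    load[:, a, i],
                )
        self._unit_load[bc] = 0.0

    @property
    def lu(self):
        if self._lu is None:
            # structurally symmetric system: MMD on A^T + A gives much
            # less fill than the default column ordering here
            self._lu = spla.splu(self.K, permc_spec="MMD_AT_PLUS_A")
        return self._lu

    def solve(self, inlet_traction: float) -> tuple[np.ndarray, np.ndarray]:
        """Stokes solve at the given inlet traction (Pa)."""
        rhs = inlet_traction * self._unit_load
        x = self.lu.solve(rhs)
        n = self._n
        vel = x[: 3 * n].reshape(3, n).T
        pres = x[3 * n :]
        return vel, pres

    def convective_matrix(self, velocity: np.ndarray) -> sp.csr_matrix:
        """Picard convection matrix rho * (u_prev . grad u, v)."""
        mesh = self.mesh
        rho = self.props.rho_internal
        n = mesh.n_nodes
        hexes = mesh.hexes
        ue = velocity[hexes]  # (E, 8, 3)
        E = len(hexes)
        Ce = np.zeros((E, 8, 8))
        for gp, dNx, detJ in zip(_GP, self._dNx_gp, self._detJ_gp):
            N, _ = hex_shape(gp)
            ug = np.einsum("a,eai->ei", N, ue)  # velocity at gauss point
            adv = np.einsum("ei,ebi->eb", ug, dNx)  # (u.grad) N_b
            Ce += rho * detJ[:, None, None] * np.einsum("a,eb->eab", N, adv)
        edof = hexes
        blocks = []
        for k in range(3):
            rows = np.repeat(edof + k * n, 8, axis=1).ravel()
            cols = np.tile(edof + k * n, (1, 8)).ravel()
            blocks.append((rows, cols))
        rows = np.concatenate([b[0] for b in blocks])
        cols = np.concatenate([b[1] for b in blocks])
        data = np.concatenate([Ce.ravel()] * 3)
        C = sp.coo_matrix((data, (rows, cols)), shape=(4 * n, 4 * n)).tocsr()
        keep = sp.diags(self.free.astype(float))
        return keep @ C @ keep


def _flux_through(nodes, quads, velocity) -> float:
    """Volumetric flux of the FE velocity through a quad face set,
    positive along the quads' outward normals (mm^3/s)."""
    pts = nodes[quads]
    v = velocity[quads]  # (F, 4, 3)
    corners = np.array([[-1, -1], [1, -1], [1, 1], [-1, 1]], dtype=float)
    flux = 0.0
    for g in _GP2:
        N = 0.25 * (1 + corners[:, 0] * g[0]) * (1 + corners[:, 1] * g[1])
        dNdxi = 0.25 * corners[:, 0] * (1 + corners[:, 1] * g[1])
        dNdeta = 0.25 * (1 + corners[:, 0] * g[0]) * corners[:, 1]
        t1 = np.einsum("a,fai->fi", dNdxi, pts)
        t2 = np.einsum("a,fai->fi", dNdeta, pts)
        nvec = np.cross(t1, t2)
        vg = np.einsum("a,fai->fi", N, v)
        flux += float(np.einsum("fi,fi->", vg, nvec))
    return flux


def solve_steady(
    mesh: TubeMesh,
    props: FluidProps,
    inlet_traction: float,
    include_inertia: bool = False,
    operator: StokesOperator | None = None,
    picard_tol: float = 1e-6,
    max_picard: int = 25,
) -> FlowField:
    """Steady incompressible solve on one phase's mesh.

    Boundary conditions: no-slip on the lateral wall, uniform normal
    traction ``inlet_traction`` (Pa) at the inlet, zero traction at the
    outlet.  A positive inlet traction drives flow inlet -> outlet.
    With ``include_inertia`` the convective term is handled by Picard
    iteration; the default is the Stokes limit appropriate at Re < 5.
    """
    if not np.isfinite(inlet_traction):
        raise ValueError("inlet traction must be finite")
    op = operator or StokesOperator(mesh, props)
    vel, pres = op.solve(inlet_traction)
    picard_iters = 0
    if include_inertia and inlet_traction != 0.0:
        n = mesh.n_nodes
        rhs = inlet_traction * op._unit_load
        for picard_iters in range(1, max_picard + 1):
            C = op.convective_matrix(vel)
            x = spla.splu((op.K + C).tocsc(),
                          permc_spec="MMD_AT_PLUS_A").solve(rhs)
            new_vel = x[: 3 * n].reshape(3, n).T
            pres = x[3 * n :]
            scale = np.abs(new_vel).max()
            change = np.abs(new_vel - vel).max() / (scale if scale > 0 else 1.0)
            vel = new_vel
            if change < picard_tol:
                break
        else:
            raise FlowError("Picard iteration for inertia did not converge")

    q_in = -_flux_through(mesh.nodes, mesh.inlet_quads, vel)  # inflow > 0
    q_out = _flux_through(mesh.nodes, mesh.outlet_quads, vel)
    scale = max(abs(q_in), abs(q_out), 1e-300)
    residuals = {
        "inlet_flux_mm3_s": q_in,
        "outlet_flux_mm3_s": q_out,
        "mass_imbalance_rel": abs(q_in - q_out) / scale,
        "picard_iterations": picard_iters,
    }
    return FlowField(
        mesh=mesh, velocity=vel, pressure=pres,
        inlet_traction=inlet_traction, props=props, residuals=residuals,
    )


def sample_velocity(field: FlowField, point: np.ndarray) -> np.ndarray:
    """Velocity (mm/s) at an arbitrary point by trilinear interpolation.

    Locates the containing hex by Newton inversion of the trilinear
    map, starting from elements adjacent to the nearest node; falls
    back to the nearest node's value if inversion fails.
    """
    mesh = field.mesh
    point = np.asarray(point, dtype=float)
    nearest = int(np.argmin(np.linalg.norm(mesh.nodes - point, axis=1)))
    cand = np.flatnonzero((mesh.hexes == nearest).any(axis=1))
    for e in cand:
        coords = mesh.nodes[mesh.hexes[e]]
        local = np.zeros(3)
        for _ in range(30):
            N, dN = hex_shape(local)
            r = N @ coords - point
            if np.linalg.norm(r) < 1e-12:
                break
            J = dN.T @ coords
            local = local - np.linalg.solve(J.T, r)
        if np.all(np.abs(local) <= 1.0 + 1e-8):
            N, _ = hex_shape(np.clip(local, -1, 1))
            return N @ field.velocity[mesh.hexes[e]]
    return field.velocity[nearest].copy()


def monitor_velocity(field: FlowField, monitor: int | np.ndarray | None = None) -> float:
    """Axial (z) velocity at the monitor location.

    ``monitor`` may be a node id, a 3-D point, or None for the default
    monitor: the lumen-center node of the mid analysis station.
    """
    mesh = field.mesh
    if monitor is None:
        stations = mesh.analysis_stations()
        monitor = mesh.centerline_node(int(stations[len(stations) // 2]))
    if np.isscalar(monitor) or np.ndim(monitor) == 0:
        return float(field.velocity[int(monitor), 2])
    return float(sample_velocity(field, np.asarray(monitor))[2])


def fit_inlet_traction(
    mesh: TubeMesh,
    props: FluidProps,
    target_velocity: float,
    tolerance: float = 0.01,
    warm_start: float = 1.0,
    monitor: int | np.ndarray | None = None,
    include_inertia: bool = False,
    max_iterations: int = 20,
    operator: StokesOperator | None = None,
) -> tuple[FlowField, InverseFitResult]:
    """Secant iteration on the inlet traction until the computed monitor
    velocity matches ``target_velocity`` (mm/s) within ``tolerance``
    relative error.

    The zero-traction solution is identically zero, so (0, 0) serves as
    the free first secant point; in the Stokes limit the response is
    exactly linear and convergence takes at most two solves from any
    nonzero warm start.  A zero target returns the zero field without
    solving.  Non-convergence is flagged, with the last field still
    returned.
    """
    op = operator or StokesOperator(mesh, props)
    if target_velocity == 0.0 or abs(target_velocity) < 1e-300:
        zero = FlowField(
            mesh=mesh,
            velocity=np.zeros((mesh.n_nodes, 3)),
            pressure=np.zeros(mesh.n_nodes),
            inlet_traction=0.0,
            props=props,
            residuals={"inlet_flux_mm3_s": 0.0, "outlet_flux_mm3_s": 0.0,
                       "mass_imbalance_rel": 0.0, "picard_iterations": 0},
        )
        return zero, InverseFitResult([0.0], [0.0], True, 0.0, 0)

    if warm_start == 0.0:
        warm_start = 1.0
    tractions = [float(warm_start)]
    velocities: list[float] = []
    field_out = None
    converged = False
    rel = np.inf
    for it in range(max_iterations):
        field_out = solve_steady(
            mesh, props, tractions[-1], include_inertia=include_inertia,
            operator=op,
        )
        v = monitor_velocity(field_out, monitor)
        velocities.append(v)
        rel = abs(v - target_velocity) / abs(target_velocity)
        if rel < tolerance:
            converged = True
            break
        if len(tractions) == 1:
            # secant through the exact (0, 0) point
            if v == 0.0:
                raise FlowError("monitor velocity is zero at nonzero traction")
            new_t = tractions[-1] * target_velocity / v
        else:
            dv = velocities[-1] - velocities[-2]
            if dv == 0.0:
                raise FlowError("secant stalled: no velocity change")
            new_t = tractions[-1] - (velocities[-1] - target_velocity) * (
                tractions[-1] - tractions[-2]
            ) / dv
        tractions.append(float(new_t))
    result = InverseFitResult(
        traction_history=tractions[: len(velocities)],
        velocity_history=velocities,
        converged=converged,
        final_relative_error=float(rel),
        n_solves=len(velocities),
    )
    return field_out, result


@dataclass
class CycleSimulation:
    """Per-phase flow solutions over the simulated portion of the cycle."""

    fields: dict[int, FlowField]
    fits: dict[int, InverseFitResult]
    skipped: dict[int, str]
    coverage: float
    warnings: list[str]

    @property
    def simulated_phases(self) -> np.ndarray:
        return np.array(sorted(self.fields), dtype=int)


def simulate_cycle(
    meshes: dict[int, TubeMesh],
    targets: dict[int, float],
    props: FluidProps,
    n_phases: int = 100,
    tolerance: float = 0.01,
    monitor: int | np.ndarray | None = None,
    include_inertia: bool = False,
    min_coverage: float = 0.6,
) -> CycleSimulation:
    """Quasi-steady cycle: one inverse-fitted solve per meshable phase.

    ``meshes`` maps phase index -> mesh (phases that could not be
    meshed, e.g. closed configurations, are simply absent and recorded
    as skipped); ``targets`` maps phase index -> measured axial monitor
    velocity (mm/s).  Each phase warm-starts from the previous phase's
    fitted traction.  A coverage fraction below ``min_coverage`` is
    reported as a warning, not an error.
    """
    fields: dict[int, FlowField] = {}
    fits: dict[int, InverseFitResult] = {}
    skipped: dict[int, str] = {}
    warnings: list[str] = []
    warm = 1.0
    for phase in range(n_phases):
        if phase not in meshes:
            skipped[phase] = "unmeshable (closed or failed)"
            continue
        if phase not in targets:
            skipped[phase] = "no Doppler target"
            continue
        try:
            f, r = fit_inlet_traction(
                meshes[phase], props, targets[phase], tolerance=tolerance,
                warm_start=warm, monitor=monitor, include_inertia=include_inertia,
            )
        except FlowError as exc:
            skipped[phase] = f"solver failure: {exc}"
            continue
        fields[phase] = f
        fits[phase] = r
        if f.inlet_traction != 0.0:
            warm = f.inlet_traction
        if not r.converged:
            warnings.append(f"phase {phase}: inverse fit not converged")
    coverage = len(fields) / n_phases
    if coverage < min_coverage:
        warnings.append(
            f"only {coverage:.0%} of the cycle simulated (< {min_coverage:.0%})"
        )
    return CycleSimulation(
        fields=fields, fits=fits, skipped=skipped, coverage=coverage,
        warnings=warnings,
    )


def reynolds_womersley(
    props: FluidProps, radius_mm: float, mean_velocity_mm_s: float, period_s: float
) -> tuple[float, float]:
    """Diagnostic Reynolds and Womersley numbers for the quasi-steady
    assumption, with the lumen radius as the characteristic length, the
    cross-section mean velocity as the characteristic speed, and the
    beat frequency f = 1/T (not omega) in the Womersley number:
    Re = rho*v*r/mu, Wo = r*sqrt(rho/(T*mu))."""
    rho = props.rho_internal
    mu = props.viscosity_pa_s
    re = rho * abs(mean_velocity_mm_s) * radius_mm / mu
    wo = radius_mm * np.sqrt(rho / (period_s * mu))
    return float(re), float(wo)
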