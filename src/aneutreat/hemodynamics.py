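"""Steady incompressible Newtonian flow in a (treated or untreated) lumen.

Blood is modelled as a Newtonian fluid (density 1000 kg/m^3, dynamic
viscosity 0.004 Pa.s by default) in a rigid-walled lumen with no-slip walls,
a radially symmetric (parabolic) inlet velocity profile scaled to a target
volumetric flow, and equal fixed gauge pressure at every outlet.

Discretization: finite volumes on a uniform staggered Cartesian (MAC) grid.
The lumen's signed distance field classifies cells as fluid/solid; inlet and
outlet cap planes turn the cells just beyond them into velocity-Dirichlet and
pressure-Dirichlet ghost zones.  Momentum uses first-order upwind convection
and central diffusion with ghost-cell wall-distance-corrected viscous links
(so the no-slip wall sits at its true sub-grid position rather than at the
voxel boundary).  A SIMPLE-type pressure-correction outer loop is used: the
correction operator is the constant-coefficient discrete Laplacian,
factorized once per mesh — any symmetric positive correction operator leaves
the converged solution unchanged, it only preconditions the continuity
constraint — so each outer iteration performs an exact discrete projection.

A deployed braided device enters either as a homogenized porous screen
(Darcy drag in the cells swept by the braid, permeability from a
Kozeny-Carman fibre-bed law driven by the braid porosity and wire calibre)
or as resolved no-slip strut cells (the high-cost option, physical only when
the grid resolves the wire calibre).

Geometry is in mm; the solver works in SI internally.  Mesh "density" is
fluid cells per mm^3, matching the elements-per-mm^3 convention used for
unstructured vascular meshes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla
from scipy.spatial import cKDTree

__all__ = [
    "FluidModel",
    "SolverConfig",
    "VoxelMesh",
    "FlowField",
    "SolverError",
    "mesh_domain",
    "solve_steady",
    "apply_device_screen",
    "screen_drag_coefficient",
    "mesh_independence_study",
    "write_field_vtk",
]

ML_PER_MIN = 6.0e7  # m^3/s -> ml/min

# cell classification
SOLID, FLUID, INLET_GHOST, OUTLET_GHOST, STRUT = 0, 1, 2, 3, 4
# face classification
F_INACTIVE, F_UNKNOWN, F_INLET, F_WALL = 0, 1, 2, 3


class SolverError(RuntimeError):
    def __init__(self, msg, history=None):
        super().__init__(msg)
        self.history = history or []


@dataclass
class FluidModel:
    """Newtonian fluid properties (SI)."""

    density: float = 1000.0            # kg/m^3
    dynamic_viscosity: float = 0.004   # Pa.s

    def __post_init__(self):
        if self.density <= 0 or self.dynamic_viscosity <= 0:
            raise ValueError("fluid properties must be strictly positive")


@dataclass
class SolverConfig:
    """Boundary conditions and iteration controls.

    ``inlet_flow`` is the prescribed volumetric inflow in ml/min.  The
    documented physiological reference is a mean internal-carotid flow of
    230 ml/min; for synthetic MCA-only domains the value is set directly
    (the parent-vessel flows used by the case pipeline are below this).
    Convergence follows the usual residual bookkeeping: converged when the
    residual has dropped by ``rel_residual_tol`` relative to its initial
    value or below ``abs_residual_tol`` absolutely.
    """

    inlet_flow: float = 230.0            # ml/min
    outlet_gauge_pressure: float = 0.0   # Pa, all outlets equal
    rel_residual_tol: float = 1e-5
    abs_residual_tol: float = 1e-8
    max_iterations: int = 800
    mesh_density_target: float = 4000.0  # elements/mm^3 (reference profile)
    device_coupling: str = "screen"      # "screen" | "resolved"
    alpha_u: float = 0.7                 # momentum under-relaxation
    alpha_p: float = 0.5                 # pressure under-relaxation
    inner_tol: float = 0.02              # momentum inner-solve relative tol
    verbose: bool = False

    def __post_init__(self):
        if not (0 < self.rel_residual_tol < 1 and 0 < self.abs_residual_tol < 1):
            raise ValueError("residual tolerances must lie in (0,1)")
        if self.inlet_flow <= 0:
            raise ValueError("inlet_flow must be positive")
        if self.device_coupling not in ("screen", "resolved"):
            raise ValueError("device_coupling must be 'screen' or 'resolved'")


@dataclass
class VoxelMesh:
    """Uniform Cartesian voxelization of the lumen with labelled boundaries."""

    origin: np.ndarray          # mm, position of cell (0,0,0) centre
    h: float                    # mm, cell edge
    cell_type: np.ndarray       # (nx,ny,nz) int8
    outlet_id: np.ndarray       # (nx,ny,nz) int8, -1 where not outlet ghost
    geom: object
    frame: object = None
    strut_cells: np.ndarray | None = None   # fluid cells swept by the device
    strut_length: np.ndarray | None = None  # wire length per cell, mm
    screen: dict | None = None              # set by apply_device_screen
    n_outlets: int = 0

    @property
    def shape(self):
        return self.cell_type.shape

    @property
    def n_fluid(self):
        return int((self.cell_type == FLUID).sum())

    @property
    def density(self):
        """Fluid cells per mm^3."""
        return self.n_fluid / (self.n_fluid * self.h**3) * 1.0 if False else 1.0 / self.h**3

    def cell_center_grid(self):
        nx, ny, nz = self.shape
        xs = self.origin[0] + self.h * np.arange(nx)
        ys = self.origin[1] + self.h * np.arange(ny)
        zs = self.origin[2] + self.h * np.arange(nz)
        return xs, ys, zs

    def boundary_face_counts(self):
        """Counts of labelled boundary faces {wall, inlet, outlet, strut}."""
        ct = self.cell_type
        counts = dict(wall=0, inlet=0, outlet=0, strut=0)
        for a in range(3):
            W, E = _face_cells(ct, a)
            fluidW, fluidE = W == FLUID, E == FLUID
            counts["inlet"] += int(((W == INLET_GHOST) & fluidE).sum()
                                   + (fluidW & (E == INLET_GHOST)).sum())
            counts["outlet"] += int(((W == OUTLET_GHOST) & fluidE).sum()
                                    + (fluidW & (E == OUTLET_GHOST)).sum())
            counts["wall"] += int(((W == SOLID) & fluidE).sum()
                                  + (fluidW & (E == SOLID)).sum())
            counts["strut"] += int(((W == STRUT) & fluidE).sum()
                                   + (fluidW & (E == STRUT)).sum())
        return counts


def _face_cells(ct, axis):
    """Cell types west/east of every face along ``axis`` (SOLID padding)."""
    pad = [(0, 0)] * 3
    pad[axis] = (1, 1)
    ctp = np.pad(ct, pad, constant_values=SOLID)
    n = ct.shape[axis] + 1
    W = ctp[tuple(slice(0, n) if a == axis else slice(1, -1) if False else slice(None)
                  for a in range(3))]
    # simpler explicit slicing
    sl_w = [slice(None)] * 3
    sl_e = [slice(None)] * 3
    sl_w[axis] = slice(0, n)
    sl_e[axis] = slice(1, n + 1)
    return ctp[tuple(sl_w)], ctp[tuple(sl_e)]


def mesh_domain(geom, frame=None, density=300.0, ghost_layers=3,
                resolved=False) -> VoxelMesh:
    """Voxelize the lumen at the requested density (fluid cells per mm^3).

    Cells beyond the inlet cap plane become the velocity-Dirichlet ghost
    zone; cells beyond each outlet cap plane become that outlet's
    pressure-Dirichlet ghost zone.  With a device ``frame``, cells swept by
    the braid are labelled (and turned into no-slip strut cells when
    ``resolved``).
    """
    if density <= 0:
        raise SolverError("density must be positive")
    if not getattr(geom, "caps", None) or "inlet" not in geom.caps:
        raise SolverError("geometry must carry labelled inlet/outlet caps")
    h = float(density ** (-1.0 / 3.0))
    min_r = min(c.radius for c in geom.caps.values())
    if h > 0.7 * min_r:
        raise SolverError(
            f"density {density}/mm^3 (h={h:.2f} mm) cannot resolve the "
            f"smallest vessel radius {min_r:.2f} mm"
        )

    if getattr(geom, "surface", None) is not None:
        lo, hi = np.array(geom.surface.bounds, float)
    else:
        lo, hi = np.array(geom.bounds, float)
    mid = 0.5 * (lo + hi)
    sym = np.abs(lo + hi) < 0.05 * h  # mirror plane through the origin
    margin = (ghost_layers + 2) * h
    lo, hi = lo - margin, hi + margin
    # irrational offset: keep cap planes off the face grid
    lo = lo - 0.2360679774997897 * h
    shape = [0, 0, 0]
    for a in range(3):
        if sym[a]:
            # centre the grid on the mirror plane (even cell count) so
            # symmetric domains stay symmetric after voxelization
            m = int(np.ceil(max(mid[a] - lo[a], hi[a] - mid[a]) / h))
            lo[a] = mid[a] - m * h
            shape[a] = 2 * m
        else:
            shape[a] = int(np.ceil((hi[a] - lo[a]) / h)) + 1
    shape = tuple(shape)
    xs, ys, zs = (lo[a] + h * (np.arange(shape[a]) + 0.5) for a in range(3))
    X, Y, Z = np.meshgrid(xs, ys, zs, indexing="ij")
    P = np.stack([X.ravel(), Y.ravel(), Z.ravel()], axis=-1)

    d_cut = geom.sdf(P, with_caps=True).reshape(shape)
    d_open = geom.sdf(P, with_caps=False).reshape(shape)
    ct = np.full(shape, SOLID, np.int8)
    ct[d_cut < 0] = FLUID
    outlet_id = np.full(shape, -1, np.int8)

    ghost = (d_open < 0) & (ct != FLUID)
    caps = [c for c in geom.caps.values()]
    n_out = 0
    for cap in caps:
        dist = ((P - cap.origin) @ cap.normal).reshape(shape)
        zone = ghost & (dist > -1e-9) & (dist <= ghost_layers * h)
        if cap.name == "inlet":
            ct[zone] = INLET_GHOST
        else:
            ct[zone] = OUTLET_GHOST
            outlet_id[zone] = n_out
            n_out += 1

    # drop fluid pockets with no face-connected path to an inlet or outlet:
    # they would make the pressure problem singular (isolated Neumann blocks)
    from scipy import ndimage

    lab, _ = ndimage.label(ct == FLUID)
    touched = set()
    ghosts = (ct == INLET_GHOST) | (ct == OUTLET_GHOST)
    for a in range(3):
        for step in (+1, -1):
            nb = _shift(lab.astype(float), a, step)
            touched |= set(np.unique(nb[ghosts & (nb > 0)]).astype(int))
    pocket = (lab > 0) & ~np.isin(lab, sorted(touched))
    ct[pocket] = SOLID

    mesh = VoxelMesh(
        origin=lo + 0.5 * h, h=h, cell_type=ct, outlet_id=outlet_id,
        geom=geom, frame=frame, n_outlets=n_out,
    )
    if frame is not None:
        mesh.strut_cells, mesh.strut_length = _strut_cell_mask(mesh, frame)
        if resolved:
            ct[mesh.strut_cells & (ct == FLUID)] = STRUT
    return mesh


def _strut_cell_mask(mesh, frame, width=None):
    """Fluid cells within the braid layer, plus wire length per cell (mm)."""
    h = mesh.h
    if width is None:
        width = max(0.75 * h, 2.0 * frame.strut_radius)
    pts, wts = [], []
    seg = frame.nodes[frame.struts]
    L = np.linalg.norm(seg[:, 1] - seg[:, 0], axis=1)
    for s, l in zip(seg, L):
        n = max(2, int(np.ceil(l / (h / 3))) + 1)
        t = np.linspace(0, 1, n)[:, None]
        pts.append(s[0] * (1 - t) + s[1] * t)
        wts.append(np.full(n, l / n))
    pts = np.vstack(pts)
    wts = np.concatenate(wts)
    # wire length accumulated per cell
    idx = np.floor((pts - mesh.origin + 0.5 * h) / h).astype(int)
    shape = np.array(mesh.shape)
    ok = np.all((idx >= 0) & (idx < shape), axis=1)
    length_grid = np.zeros(mesh.shape)
    np.add.at(length_grid, tuple(idx[ok].T), wts[ok])
    tree = cKDTree(pts)
    xs, ys, zs = mesh.cell_center_grid()
    X, Y, Z = np.meshgrid(xs, ys, zs, indexing="ij")
    centers = np.stack([X.ravel(), Y.ravel(), Z.ravel()], axis=-1)
    d, _ = tree.query(centers, distance_upper_bound=width)
    mask = (d <= width).reshape(mesh.shape)
    mask &= mesh.cell_type == FLUID
    return mask, length_grid


# --------------------------------------------------------------------------
# porous-screen device coupling
# --------------------------------------------------------------------------

def screen_drag_coefficient(porosity, strut_radius_mm, viscosity,
                            cell_h_mm, kc_constant=180.0):
    """Volumetric Darcy drag C_v (kg m^-3 s^-1) for a braid screen layer.

    Permeability from a Kozeny-Carman fibre-bed law,
    K = phi^3 d_w^2 / (C (1-phi)^2) with d_w the wire diameter; the
    pressure jump of the physical screen (thickness ~ two wire diameters)
    is spread over one grid cell, scaling the drag by t/h.
    """
    if not 0 < porosity <= 1:
        raise ValueError("porosity must lie in (0, 1]")
    if porosity == 1.0:
        return 0.0
    d_w = 2.0 * strut_radius_mm * 1e-3
    t = 2.0 * d_w  # braid layer thickness: two crossing wires
    K = porosity**3 * d_w**2 / (kc_constant * (1.0 - porosity) ** 2)
    return viscosity / K * (t / (cell_h_mm * 1e-3))


def apply_device_screen(mesh: VoxelMesh, frame, porosity=None,
                        viscosity=0.004, layers=1) -> VoxelMesh:
    """Attach a homogenized porous-screen momentum sink to the mesh.

    With a scalar ``porosity`` every swept cell receives the same Darcy
    drag; drag decreases monotonically with porosity, porosity 1 leaves the
    flow untouched and porosity 0 seals the screen (cells become solid).
    With ``porosity=None`` the local porosity of each cell is computed from
    the wire length the deployed braid actually deposits there (projected
    coverage 2 r_w L / h^2), so a compacted braid resists flow where its
    wires crowd together.  ``layers`` stacks the resistance of a multi-layer
    braid built as separate uniform layers (drags in series add); it is
    ignored in per-cell mode, which already counts every wire.
    """
    if porosity is not None and not 0 <= porosity <= 1:
        raise SolverError("porosity must lie in [0, 1]")
    if mesh.strut_cells is None or mesh.frame is not frame:
        mesh.frame = frame
        mesh.strut_cells, mesh.strut_length = _strut_cell_mask(mesh, frame)
    if porosity == 0.0:
        mesh.cell_type[mesh.strut_cells & (mesh.cell_type == FLUID)] = STRUT
        mesh.screen = dict(porosity=0.0, coeff=np.inf)
        return mesh
    coeff_grid = np.zeros(mesh.shape)
    cells = mesh.strut_cells
    if porosity is not None:
        coeff = layers * screen_drag_coefficient(
            porosity, frame.strut_radius, viscosity, mesh.h)
        coeff_grid[cells] = coeff
        mesh.screen = dict(porosity=float(porosity), coeff=float(coeff),
                           coeff_grid=coeff_grid)
        return mesh
    w = 2.0 * frame.strut_radius
    cover = np.clip(mesh.strut_length * w / mesh.h**2, 0.0, 0.97)
    phi = 1.0 - cover
    with np.errstate(divide="ignore"):
        c = np.where(
            cover > 0,
            _darcy_coeff(phi, frame.strut_radius, viscosity, mesh.h), 0.0)
    coeff_grid[cells] = c[cells]
    mesh.screen = dict(porosity=None, coeff=float(c[cells].mean() if cells.any() else 0.0),
                       coeff_grid=coeff_grid)
    return mesh


def _darcy_coeff(porosity, strut_radius_mm, viscosity, cell_h_mm,
                 kc_constant=180.0):
    d_w = 2.0 * strut_radius_mm * 1e-3
    t = 2.0 * d_w
    K = porosity**3 * d_w**2 / (kc_constant * np.maximum(1.0 - porosity, 1e-9) ** 2)
    return viscosity / K * (t / (cell_h_mm * 1e-3))


# --------------------------------------------------------------------------
# flow field container
# --------------------------------------------------------------------------

@dataclass
class FlowField:
    """Converged (or flagged) steady velocity/pressure on a voxel mesh."""

    mesh: VoxelMesh
    faces: list                  # [u, v, w] face-grid arrays, m/s
    pressure: np.ndarray         # cell grid, Pa (0 outside fluid)
    residual_history: list
    converged: bool
    inlet_flux: float            # ml/min (positive into the domain)
    outlet_fluxes: list          # ml/min per outlet (positive out)
    fluid: FluidModel
    config: SolverConfig

    def mass_balance_error(self):
        """|sum(Q_out) - Q_in| / Q_in."""
        return abs(sum(self.outlet_fluxes) - self.inlet_flux) / self.inlet_flux

    def _face_origin(self, axis):
        o = np.array(self.mesh.origin, float) - 0.5 * self.mesh.h
        o = o.copy()
        for a in range(3):
            if a != axis:
                o[a] += 0.5 * self.mesh.h
        return o

    def velocity_at(self, points_mm):
        """Trilinear velocity (m/s) at points given in mm."""
        pts = np.atleast_2d(np.asarray(points_mm, float))
        out = np.zeros_like(pts)
        for a in range(3):
            out[:, a] = _trilinear(self.faces[a], self._face_origin(a),
                                   self.mesh.h, pts)
        return out

    def pressure_at(self, points_mm):
        pts = np.atleast_2d(np.asarray(points_mm, float))
        return _trilinear(self.pressure, np.array(self.mesh.origin), self.mesh.h, pts)

    def divergence(self):
        """Discrete divergence (m^3/s) per fluid cell."""
        h = self.mesh.h * 1e-3
        A = h * h
        u, v, w = self.faces
        div = (u[1:, :, :] - u[:-1, :, :] + v[:, 1:, :] - v[:, :-1, :]
               + w[:, :, 1:] - w[:, :, :-1]) * A
        return np.where(self.mesh.cell_type == FLUID, div, 0.0)


def _trilinear(grid, origin_mm, h_mm, pts_mm):
    t = (pts_mm - origin_mm) / h_mm
    n = np.array(grid.shape)
    i0 = np.clip(np.floor(t).astype(int), 0, n - 2)
    f = np.clip(t - i0, 0.0, 1.0)
    out = np.zeros(len(pts_mm))
    for dx in (0, 1):
        for dy in (0, 1):
            for dz in (0, 1):
                wgt = ((f[:, 0] if dx else 1 - f[:, 0])
                       * (f[:, 1] if dy else 1 - f[:, 1])
                       * (f[:, 2] if dz else 1 - f[:, 2]))
                out += wgt * grid[i0[:, 0] + dx, i0[:, 1] + dy, i0[:, 2] + dz]
    return out


# --------------------------------------------------------------------------
# steady solver
# --------------------------------------------------------------------------

def _shift(arr, axis, step, fill=0.0):
    """Array whose element at i reads arr[i+step] along axis (fill beyond)."""
    out = np.full_like(arr, fill)
    n = arr.shape[axis]
    src = [slice(None)] * 3
    dst = [slice(None)] * 3
    if step > 0:
        src[axis] = slice(step, n)
        dst[axis] = slice(0, n - step)
    else:
        src[axis] = slice(0, n + step)
        dst[axis] = slice(-step, n)
    out[tuple(dst)] = arr[tuple(src)]
    return out


def _pad_axis(arr, axis, front, back):
    pad = [(0, 0)] * 3
    pad[axis] = (front, back)
    return np.pad(arr, pad)


class _Axis:
    """Static per-axis face bookkeeping for the staggered grid."""

    def __init__(self, mesh, axis, inlet_values):
        self.a = axis
        ct = mesh.cell_type
        W, E = _face_cells(ct, axis)
        self.W, self.E = W, E
        fluid = FLUID
        wfl, efl = W == fluid, E == fluid
        unknown = (wfl & efl) | (wfl & (E == OUTLET_GHOST)) | ((W == OUTLET_GHOST) & efl)
        inlet = (wfl & (E == INLET_GHOST)) | ((W == INLET_GHOST) & efl)
        wallish = (wfl | efl) & ~(unknown | inlet)
        self.status = np.full(W.shape, F_INACTIVE, np.int8)
        self.status[unknown] = F_UNKNOWN
        self.status[inlet] = F_INLET
        self.status[wallish] = F_WALL
        self.unk = np.flatnonzero(self.status.ravel() == F_UNKNOWN)
        self.eqid = np.full(self.status.size, -1, np.int64)
        self.eqid[self.unk] = np.arange(len(self.unk))
        self.eqid = self.eqid.reshape(self.status.shape)
        self.values = np.zeros(self.status.shape)
        self.values[self.status == F_INLET] = inlet_values[axis][self.status == F_INLET]


def _inlet_profile(mesh, config):
    """Parabolic inlet velocity on each face grid (m/s), scaled to the flow."""
    cap = mesh.geom.caps["inlet"]
    n_in = -np.asarray(cap.normal, float)  # into the domain
    R = cap.radius
    Q = config.inlet_flow / ML_PER_MIN  # m^3/s
    U_mean = Q / (np.pi * (R * 1e-3) ** 2)
    vals = []
    h = mesh.h
    for a in range(3):
        shp = list(mesh.shape)
        shp[a] += 1
        o = np.array(mesh.origin) - 0.5 * h * np.eye(3)[a]
        xs = [o[k] + h * np.arange(shp[k]) for k in range(3)]
        X, Y, Z = np.meshgrid(*xs, indexing="ij")
        P = np.stack([X, Y, Z], axis=-1)
        rel = P - cap.origin
        axial = rel @ n_in
        radial = rel - axial[..., None] * n_in
        r2 = np.einsum("...k,...k->...", radial, radial)
        prof = 2.0 * U_mean * np.maximum(0.0, 1.0 - r2 / R**2)
        vals.append(prof * n_in[a])
    # rescale so the discrete inlet flux matches Q exactly
    A = (h * 1e-3) ** 2
    flux = 0.0
    for a in range(3):
        W, E = _face_cells(mesh.cell_type, a)
        inlet = ((W == FLUID) & (E == INLET_GHOST)) | ((W == INLET_GHOST) & (E == FLUID))
        sgn = np.where(W == INLET_GHOST, 1.0, -1.0)
        flux += float((vals[a][inlet] * sgn[inlet]).sum()) * A
    if flux <= 0:
        raise SolverError("no inlet faces found; check cap labels and density")
    scale = Q / flux
    return [v * scale for v in vals]


def _wall_delta(mesh, axes):
    """Sub-grid wall distance (units of h) for viscous links at wall faces."""
    geom = mesh.geom
    h = mesh.h
    deltas = []
    for a in range(3):
        shp = list(mesh.shape)
        shp[a] += 1
        o = np.array(mesh.origin) - 0.5 * h * np.eye(3)[a]
        xs = [o[k] + h * np.arange(shp[k]) for k in range(3)]
        X, Y, Z = np.meshgrid(*xs, indexing="ij")
        P = np.stack([X.ravel(), Y.ravel(), Z.ravel()], axis=-1)
        phi = geom.sdf(P, with_caps=False).reshape(shp)
        deltas.append(phi)
    return deltas


def solve_steady(mesh: VoxelMesh, fluid: FluidModel | None = None,
                 config: SolverConfig | None = None) -> FlowField:
    """SIMPLE-type steady solve; returns a :class:`FlowField`.

    Raises :class:`SolverError` (with residual history) on divergence; a run
    that exhausts ``max_iterations`` without meeting the residual rule
    returns with ``converged=False``.
    """
    fluid = fluid or FluidModel()
    config = config or SolverConfig()
    rho, mu = fluid.density, fluid.dynamic_viscosity
    h = mesh.h * 1e-3
    A = h * h
    ct = mesh.cell_type

    inlet_vals = _inlet_profile(mesh, config)
    axes = [_Axis(mesh, a, inlet_vals) for a in range(3)]
    phis = _wall_delta(mesh, axes)
    # face drag from the screen's per-cell coefficient grid (kg m^-3 s^-1)
    drag_faces = [None, None, None]
    if mesh.screen and mesh.screen.get("coeff_grid") is not None:
        Cg = mesh.screen["coeff_grid"]
        for ax in axes:
            cw = _face_adjacent_value(Cg, ax.a, side=0).ravel()[ax.unk]
            ce = _face_adjacent_value(Cg, ax.a, side=1).ravel()[ax.unk]
            drag_faces[ax.a] = 0.5 * (cw + ce)

    # cell numbering and static index structure for the consistent
    # (per-face d) pressure-correction matrix
    fluid_mask = ct == FLUID
    pid = np.full(ct.size, -1, np.int64)
    pid[np.flatnonzero(fluid_mask.ravel())] = np.arange(fluid_mask.sum())
    pid = pid.reshape(ct.shape)
    pstruct = []
    for ax in axes:
        a = ax.a
        idxW = _face_adjacent_pid(pid, a, side=0).ravel()[ax.unk]
        idxE = _face_adjacent_pid(pid, a, side=1).ravel()[ax.unk]
        pstruct.append((idxW, idxE))

    # working fields
    U = [ax.values.copy() for ax in axes]
    p = np.zeros(ct.shape)

    prebuilt = [_prebuild_axis(mesh, ax, phis, mu, A, h) for ax in axes]

    res_hist = []
    res0 = None
    converged = False
    Q_si = config.inlet_flow / ML_PER_MIN
    u_ref = max(Q_si / (np.pi * (mesh.geom.caps["inlet"].radius * 1e-3) ** 2), 1e-9)
    mom_scale = rho * Q_si * u_ref

    n_p = int(fluid_mask.sum())
    q_prev = None
    for it in range(config.max_iterations):
        res_m = 0.0
        d_faces = []
        for ax, pre in zip(axes, prebuilt):
            Amat, b, diag_eff, d_face = _assemble_momentum(
                mesh, ax, pre, U, p, rho, mu, A, h, config,
                drag_faces[ax.a])
            ucur = U[ax.a].ravel()[ax.unk]
            r = b - Amat @ ucur
            res_m += float(np.abs(r).sum())
            Mpre = spla.LinearOperator(Amat.shape, lambda x, d=diag_eff: x / d)
            # correction form: tolerance is relative to the true residual
            delta, info = spla.bicgstab(Amat, r, rtol=config.inner_tol,
                                        atol=0.0, maxiter=200, M=Mpre)
            if not np.all(np.isfinite(delta)):
                raise SolverError(f"momentum solve diverged (axis {ax.a})",
                                  res_hist)
            flat = U[ax.a].ravel()
            flat[ax.unk] = ucur + delta
            U[ax.a] = flat.reshape(U[ax.a].shape)
            d_faces.append(d_face)

        # continuity: consistent per-face correction operator, solved by CG
        # preconditioned with the constant-coefficient factorization
        div = (np.diff(U[0], axis=0) + np.diff(U[1], axis=1)
               + np.diff(U[2], axis=2)) * A  # m^3/s per cell
        m_imb = rho * div
        res_c = float(np.abs(m_imb[fluid_mask]).sum())
        rowsP, colsP, dataP = [], [], []
        diagP = np.zeros(n_p)
        for ax, (idxW, idxE), d_face in zip(axes, pstruct, d_faces):
            coef = rho * A * d_face
            both = (idxW >= 0) & (idxE >= 0)
            rowsP += [idxW[both], idxE[both]]
            colsP += [idxE[both], idxW[both]]
            dataP += [-coef[both], -coef[both]]
            np.add.at(diagP, idxW[idxW >= 0], coef[idxW >= 0])
            np.add.at(diagP, idxE[idxE >= 0], coef[idxE >= 0])
        rowsP.append(np.arange(n_p))
        colsP.append(np.arange(n_p))
        dataP.append(diagP)
        Ap = sp.csr_matrix(
            (np.concatenate(dataP), (np.concatenate(rowsP), np.concatenate(colsP))),
            shape=(n_p, n_p))
        Mp = spla.LinearOperator(
            (n_p, n_p), lambda x, d=diagP: x / d, dtype=np.float64)
        q, infop = spla.cg(Ap, -m_imb[fluid_mask], x0=q_prev, rtol=1e-4,
                           atol=0.0, maxiter=600, M=Mp)
        q_prev = q
        if not np.all(np.isfinite(q)):
            raise SolverError("pressure correction diverged", res_hist)
        pprime = np.zeros(ct.shape)
        pprime[fluid_mask] = q
        for ax, d_face in zip(axes, d_faces):
            a = ax.a
            pW = _face_adjacent_value(pprime, a, side=0).ravel()[ax.unk]
            pE = _face_adjacent_value(pprime, a, side=1).ravel()[ax.unk]
            flat = U[a].ravel()
            flat[ax.unk] += d_face * (pW - pE)
            U[a] = flat.reshape(U[a].shape)
        p[fluid_mask] += config.alpha_p * pprime[fluid_mask]

        res = res_m / mom_scale + res_c / (rho * Q_si)
        res_hist.append(res)
        if not np.isfinite(res):
            raise SolverError("solver diverged (non-finite residual)", res_hist)
        if res0 is None:
            res0 = max(res, 1e-30)
        if config.verbose and it % 20 == 0:
            print(f"  iter {it:4d} residual {res:.3e}")
        if res < config.abs_residual_tol or res / res0 < config.rel_residual_tol:
            converged = True
            break
        if it > 50 and res / res0 > 1e4:
            raise SolverError("solver diverged (residual growth)", res_hist)

    # boundary fluxes
    inlet_flux = 0.0
    outlet_fluxes = np.zeros(max(mesh.n_outlets, 1))
    for ax in axes:
        a = ax.a
        sgnW = 1.0  # ghost on W: positive u flows into domain / out of it
        inletW = (ax.W == INLET_GHOST) & (ax.E == FLUID)
        inletE = (ax.W == FLUID) & (ax.E == INLET_GHOST)
        inlet_flux += float(U[a][inletW].sum() - U[a][inletE].sum()) * A
        outW = (ax.W == OUTLET_GHOST) & (ax.E == FLUID)
        outE = (ax.W == FLUID) & (ax.E == OUTLET_GHOST)
        oidW = _face_adjacent_value(mesh.outlet_id.astype(float), a, side=0)
        oidE = _face_adjacent_value(mesh.outlet_id.astype(float), a, side=1)
        for m, sgn, oid in ((outW, -1.0, oidW), (outE, 1.0, oidE)):
            ids = oid[m].astype(int)
            np.add.at(outlet_fluxes, ids, sgn * U[a][m] * A)

    return FlowField(
        mesh=mesh,
        faces=U,
        pressure=p,
        residual_history=res_hist,
        converged=converged,
        inlet_flux=inlet_flux * ML_PER_MIN,
        outlet_fluxes=list(outlet_fluxes * ML_PER_MIN),
        fluid=fluid,
        config=config,
    )


def _face_adjacent_pid(pid, axis, side):
    """pid of the cell west (side=0) or east (side=1) of each face."""
    padded = _pad_axis(pid + 1, axis, 1, 1) - 1  # -1 fill
    n = pid.shape[axis] + 1
    sl = [slice(None)] * 3
    sl[axis] = slice(0, n) if side == 0 else slice(1, n + 1)
    return padded[tuple(sl)]


def _face_adjacent_value(arr, axis, side, fill=0.0):
    padded = _pad_axis(arr, axis, 1, 1)
    if fill != 0.0:
        pass
    n = arr.shape[axis] + 1
    sl = [slice(None)] * 3
    sl[axis] = slice(0, n) if side == 0 else slice(1, n + 1)
    return padded[tuple(sl)]


def _prebuild_axis(mesh, ax, phis, mu, A, h):
    """Static structure for one momentum matrix: neighbour ids, diffusion."""
    a = ax.a
    unk = ax.unk
    shape = ax.status.shape
    coords = np.array(np.unravel_index(unk, shape)).T
    n_unk = len(unk)
    phi = phis[a]

    nb = []
    for d in range(3):
        for step in (+1, -1):
            eq_nb = _shift(ax.eqid, d, step, fill=-1).ravel()[unk]
            st_nb = _shift(ax.status, d, step, fill=F_INACTIVE).ravel()[unk]
            val_nb_idx = _shift_index(shape, coords, d, step)
            D = np.full(n_unk, mu * A / h)
            if d != a:
                # tangential links: a WALL or INACTIVE neighbour means the
                # no-slip wall sits between this face node and the neighbour
                # position; place it at its sub-grid SDF crossing.  If the
                # SDF is open there (ghost-zone rim), drop the link instead.
                phiF = phi.ravel()[unk]
                phiN = _shift(phi, d, step, fill=1.0).ravel()[unk]
                wallish = (st_nb == F_WALL) | (st_nb == F_INACTIVE)
                delta = np.ones(n_unk)
                cross = wallish & (phiF < 0) & (phiN >= 0)
                delta[cross] = np.clip(
                    -phiF[cross] / np.maximum(phiN[cross] - phiF[cross], 1e-12),
                    0.15, 1.0)
                delta[wallish & (phiF >= 0)] = 0.5
                D = D / delta
                D[wallish & (phiF < 0) & (phiN < 0)] = 0.0
            else:
                D[st_nb == F_INACTIVE] = 0.0
            nb.append(dict(dir=d, step=step, eq=eq_nb, status=st_nb,
                           D=D, val_idx=val_nb_idx))
    return dict(nb=nb, coords=coords, n=n_unk)


def _shift_index(shape, coords, axis, step):
    c = coords.copy()
    c[:, axis] = np.clip(c[:, axis] + step, 0, shape[axis] - 1)
    return np.ravel_multi_index((c[:, 0], c[:, 1], c[:, 2]), shape)


def _mass_fluxes(mesh, ax, U, rho, A):
    """Outward CV mass fluxes (kg/s) at every face of the u_a control volume."""
    a = ax.a
    Ua = U[a]
    fluxes = {}
    fluxes[(a, +1)] = 0.5 * rho * A * (Ua + _shift(Ua, a, +1))
    fluxes[(a, -1)] = -0.5 * rho * A * (Ua + _shift(Ua, a, -1))
    for t in range(3):
        if t == a:
            continue
        Ut = U[t]
        sl_p = [slice(None)] * 3
        sl_m = [slice(None)] * 3
        sl_p[t] = slice(1, None)
        sl_m[t] = slice(0, -1)
        Vp = Ut[tuple(sl_p)]   # cell-shaped, at t+1/2 side +
        Vm = Ut[tuple(sl_m)]
        Mp = 0.5 * rho * A * (_pad_axis(Vp, a, 1, 0) + _pad_axis(Vp, a, 0, 1))
        Mm = 0.5 * rho * A * (_pad_axis(Vm, a, 1, 0) + _pad_axis(Vm, a, 0, 1))
        fluxes[(t, +1)] = Mp
        fluxes[(t, -1)] = -Mm
    return fluxes


def _assemble_momentum(mesh, ax, pre, U, p, rho, mu, A, h, config, drag):
    a = ax.a
    unk = ax.unk
    n_unk = pre["n"]
    fluxes = _mass_fluxes(mesh, ax, U, rho, A)

    diag = np.zeros(n_unk)
    rhs = np.zeros(n_unk)
    rows, cols, data = [], [], []
    for link in pre["nb"]:
        d, step = link["dir"], link["step"]
        m_out = fluxes[(d, step)].ravel()[unk]
        a_nb = link["D"] + np.maximum(-m_out, 0.0)
        diag += link["D"] + np.maximum(m_out, 0.0)
        st = link["status"]
        is_unk = st == F_UNKNOWN
        rows.append(np.flatnonzero(is_unk))
        cols.append(link["eq"][is_unk])
        data.append(-a_nb[is_unk])
        is_dir = st == F_INLET
        if is_dir.any():
            uvals = ax.values.ravel()[link["val_idx"][is_dir]]
            rhs[is_dir] += a_nb[is_dir] * uvals

    # pressure force; ghost outlet cells carry the gauge pressure
    pW = _face_adjacent_value(p, a, side=0).ravel()[unk]
    pE = _face_adjacent_value(p, a, side=1).ravel()[unk]
    rhs += (pW - pE) * A

    if drag is not None:
        diag += drag * h**3

    diag_eff = diag / config.alpha_u
    ucur = U[a].ravel()[unk]
    rhs += (diag_eff - diag) * ucur
    rows.append(np.arange(n_unk))
    cols.append(np.arange(n_unk))
    data.append(diag_eff)
    Amat = sp.csr_matrix(
        (np.concatenate(data), (np.concatenate(rows), np.concatenate(cols))),
        shape=(n_unk, n_unk),
    )
    d_face = A / diag_eff
    return Amat, rhs, diag_eff, d_face


# --------------------------------------------------------------------------
# mesh-independence machinery
# --------------------------------------------------------------------------

def mesh_independence_study(geom, densities, frame=None, fluid=None,
                            config=None, plane=None, wall_region=None,
                            criterion=0.01):
    """Refinement sweep reporting Q_in and WSS_max per density.

    ``densities`` must be an increasing list of at least three values.
    Returns a pandas DataFrame with successive relative changes and an
    ``independent`` flag at the first density where both monitored
    quantities change by less than ``criterion``.
    """
    import pandas as pd

    from .metrics import SamplingPlane, integrate_influx, wall_shear_stress

    densities = list(densities)
    if len(densities) < 3:
        raise SolverError("mesh independence needs at least 3 densities")
    if any(b <= a for a, b in zip(densities, densities[1:])):
        raise SolverError("densities must be strictly increasing")

    if plane is None:
        from .geometry import measure_aneurysm

        m = measure_aneurysm(geom)
        plane = SamplingPlane.from_measures(m)

    rows = []
    prev = None
    for d in densities:
        mesh = mesh_domain(geom, frame=frame, density=d)
        if frame is not None and mesh.screen is None and config \
                and config.device_coupling == "screen":
            raise SolverError("attach the screen via apply_device_screen")
        fieldv = solve_steady(mesh, fluid, config)
        q = integrate_influx(fieldv, plane)
        if wall_region is not None:
            _, wmax = wall_shear_stress(fieldv, wall_region)
        else:
            wmax = np.nan
        row = dict(density=d, Q_in=q, WSS_max=wmax)
        if prev is not None:
            row["dQ_rel"] = abs(q - prev["Q_in"]) / max(abs(prev["Q_in"]), 1e-30)
            row["dWSS_rel"] = (abs(wmax - prev["WSS_max"])
                               / max(abs(prev["WSS_max"]), 1e-30)
                               if np.isfinite(wmax) else np.nan)
        else:
            row["dQ_rel"] = np.nan
            row["dWSS_rel"] = np.nan
        rows.append(row)
        prev = row
    df = pd.DataFrame(rows)
    ok = (df["dQ_rel"] < criterion) & (
        df["dWSS_rel"].isna() | (df["dWSS_rel"] < criterion)
    )
    df["independent"] = ok.fillna(False)
    return df


def write_field_vtk(field: FlowField, path):
    """Write velocity/pressure as legacy-ASCII VTK structured points.

    Point data lives on the cell-centre lattice; velocity is the
    face-averaged vector, pressure the cell value, and ``fluid`` a 0/1 mask.
    """
    mesh = field.mesh
    nx, ny, nz = mesh.shape
    u, v, w = field.faces
    uc = 0.5 * (u[1:, :, :] + u[:-1, :, :])
    vc = 0.5 * (v[:, 1:, :] + v[:, :-1, :])
    wc = 0.5 * (w[:, :, 1:] + w[:, :, :-1])
    with open(path, "w") as f:
        f.write("# vtk DataFile Version 3.0\naneutreat flow field\nASCII\n")
        f.write("DATASET STRUCTURED_POINTS\n")
        f.write(f"DIMENSIONS {nx} {ny} {nz}\n")
        o = mesh.origin
        f.write(f"ORIGIN {o[0]} {o[1]} {o[2]}\n")
        f.write(f"SPACING {mesh.h} {mesh.h} {mesh.h}\n")
        f.write(f"POINT_DATA {nx * ny * nz}\n")
        f.write("VECTORS velocity double\n")
        # VTK structured points vary x fastest
        for k in range(nz):
            for j in range(ny):
                for i in range(nx):
                    f.write(f"{uc[i, j, k]:.6e} {vc[i, j, k]:.6e} {wc[i, j, k]:.6e}\n")
        f.write("SCALARS pressure double\nLOOKUP_TABLE default\n")
        for k in range(nz):
            for j in range(ny):
                for i in range(nx):
                    f.write(f"{field.pressure[i, j, k]:.6e}\n")
        f.write("SCALARS fluid int\nLOOKUP_TABLE default\n")
        for k in range(nz):
            for j in range(ny):
                for i in range(nx):
                    f.write(f"{int(mesh.cell_type[i, j, k] == FLUID)}\n")
    return path
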