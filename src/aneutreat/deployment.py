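"""Fast virtual deployment of device wireframes inside a rigid lumen.

The pipeline mirrors the clinical sequence: the wireframe is *crimped* to the
microcatheter radius and aligned with a delivery path (braid kinematics
elongate the device as its diameter shrinks, conserving wire length); it is
then *released* progressively from the distal to the proximal end with
respect to the aneurysm sac; released nodes relax toward the stress-free
shape by damped gradient descent on an elastic energy (stretch springs along
struts, second-neighbour bending springs along each wire, plus a weak
shape-memory term toward the best-fit rigid placement of the reference
shape, which is what gives braided nitinol its shape recovery), while a
frictionless contact projection keeps every node inside the vessel wall.
The wall is rigid throughout.

Lengths in mm.  The scheme is quasi-static and deterministic; spring
constants are dimensionless model parameters, not material moduli.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq

from .devices import Wireframe

__all__ = [
    "DeliveryPath",
    "DeploymentState",
    "RelaxParams",
    "DeploymentError",
    "crimp",
    "release",
    "deployed_frame",
    "auto_path",
    "fit_crimp_radius",
    "crimped_length",
]


class DeploymentError(RuntimeError):
    """Deployment failed (infeasible crimp or non-converged relaxation)."""

    def __init__(self, msg, state=None):
        super().__init__(msg)
        self.state = state


@dataclass
class DeliveryPath:
    """Polyline the crimped device is threaded along.

    role: "centerline" for intraluminal stents (vessel centreline) or
    "neck_to_dome" for intrasaccular devices (track through the neck into
    the sac).
    """

    points: np.ndarray
    role: str = "centerline"

    def __post_init__(self):
        self.points = np.asarray(self.points, float)
        if self.points.ndim != 2 or len(self.points) < 2:
            raise ValueError("path needs at least 2 points")

    @property
    def arc_length(self):
        return float(np.linalg.norm(np.diff(self.points, axis=0), axis=1).sum())

    def resample(self, spacing=0.25):
        seg = np.linalg.norm(np.diff(self.points, axis=0), axis=1)
        s = np.concatenate([[0.0], np.cumsum(seg)])
        n = max(2, int(np.ceil(s[-1] / spacing)) + 1)
        si = np.linspace(0.0, s[-1], n)
        pts = np.stack([np.interp(si, s, self.points[:, k]) for k in range(3)], axis=1)
        return si, pts

    def frames(self, spacing=0.25):
        """Parallel-transported orthonormal frames along the path."""
        s, pts = self.resample(spacing)
        t = np.gradient(pts, s, axis=0)
        t /= np.linalg.norm(t, axis=1, keepdims=True)
        n1 = np.zeros_like(t)
        seed = np.eye(3)[np.argmin(np.abs(t[0]))]
        n1[0] = seed - (seed @ t[0]) * t[0]
        n1[0] /= np.linalg.norm(n1[0])
        for i in range(1, len(t)):
            v = np.cross(t[i - 1], t[i])
            c = float(np.clip(t[i - 1] @ t[i], -1.0, 1.0))
            if np.linalg.norm(v) < 1e-12:
                n1[i] = n1[i - 1]
            else:
                k = v / np.linalg.norm(v)
                ang = np.arccos(c)
                n = n1[i - 1]
                n1[i] = (n * np.cos(ang) + np.cross(k, n) * np.sin(ang)
                         + k * (k @ n) * (1 - np.cos(ang)))
            n1[i] -= (n1[i] @ t[i]) * t[i]
            n1[i] /= np.linalg.norm(n1[i])
        n2 = np.cross(t, n1)
        return s, pts, t, n1, n2


@dataclass
class DeploymentState:
    """Evolving node positions during virtual stenting."""

    positions: np.ndarray
    release_fraction: float = 0.0
    iteration: int = 0
    max_step: float = np.inf        # mm, largest node move last iteration
    contact_set: np.ndarray = field(default_factory=lambda: np.zeros(0, int))
    converged: bool = False
    axial_coord: np.ndarray | None = None   # arc-length position per node
    energy_history: list = field(default_factory=list)

    def copy(self):
        return DeploymentState(
            positions=self.positions.copy(),
            release_fraction=self.release_fraction,
            iteration=self.iteration,
            max_step=self.max_step,
            contact_set=self.contact_set.copy(),
            converged=self.converged,
            axial_coord=None if self.axial_coord is None else self.axial_coord.copy(),
            energy_history=list(self.energy_history),
        )


@dataclass
class RelaxParams:
    """Relaxation controls (dimensionless stiffnesses, mm tolerances)."""

    k_stretch: float = 1.0
    k_bend: float = 0.3
    compression_factor: float = 1.0  # spring stiffness ratio in compression
    shape_beta: float = 0.25        # shape-memory pull toward rigid-fit reference
    step: float = 0.15              # initial pseudo-time step
    iters_per_increment: int = 15
    max_final_iters: int = 5000
    step_tol: float = 1e-3          # mm
    penetration_tol: float = 0.01   # mm
    contact_inset: float = 0.0      # project onto the wall itself
    n_increments: int = 48


# --------------------------------------------------------------------------
# crimping
# --------------------------------------------------------------------------

def _device_axis_coords(frame: Wireframe):
    """(axial, radial, azimuth) of reference nodes in the device frame.

    Builders put the braided-stent axis along +x and the bowl axis along +z;
    the sweep coordinate is x for stents and z for bowls.
    """
    ref = frame.reference_nodes
    if frame.family == "contour":
        s = ref[:, 2]
        r = np.linalg.norm(ref[:, :2], axis=1)
        phi = np.arctan2(ref[:, 1], ref[:, 0])
    else:
        s = ref[:, 0]
        r = np.linalg.norm(ref[:, 1:], axis=1)
        phi = np.arctan2(ref[:, 2], ref[:, 1])
    return s, r, phi


def crimp(frame: Wireframe, radius: float, path: DeliveryPath,
          offset: float = 0.0) -> DeploymentState:
    """Compress the device to the sheath radius and thread it on the path.

    Wire length is conserved: the radial compression factor fixes an axial
    stretch found by a 1-D root solve (braid kinematics), so crimping
    elongates the device.  ``offset`` shifts the device's proximal end along
    the path arc length.
    """
    if radius <= frame.strut_radius:
        raise DeploymentError("crimp radius must exceed the strut radius")
    nominal_r = frame.nominal_diameter / 2.0
    if radius > nominal_r + 1e-9:
        raise DeploymentError("crimp radius exceeds the nominal device radius")

    s, r, phi = _device_axis_coords(frame)
    rho = min(1.0, radius / max(r.max(), 1e-12))
    ref_len = frame.total_wire_length(reference=True)
    s0 = s.min()
    i, j = frame.struts[:, 0], frame.struts[:, 1]

    def total_len(lam):
        ax = s0 + lam * (s - s0)
        x = np.stack([ax, rho * r * np.cos(phi), rho * r * np.sin(phi)], axis=1)
        return np.linalg.norm(x[j] - x[i], axis=1).sum() - ref_len

    if abs(total_len(1.0)) < 1e-9 * ref_len:
        lam = 1.0
    else:
        lam = brentq(total_len, 1.0, 80.0, xtol=1e-10)
    ax = s0 + lam * (s - s0)
    ax -= ax.min()
    crimped_len = ax.max()

    if path.arc_length < crimped_len + offset:
        raise DeploymentError(
            f"path ({path.arc_length:.1f} mm) shorter than crimped device "
            f"({crimped_len:.1f} mm) plus offset {offset:.1f} mm"
        )

    sp, pts, t, n1, n2 = path.frames()
    pos = (
        np.stack([np.interp(ax + offset, sp, pts[:, k]) for k in range(3)], axis=1)
        + (rho * r * np.cos(phi))[:, None]
        * np.stack([np.interp(ax + offset, sp, n1[:, k]) for k in range(3)], axis=1)
        + (rho * r * np.sin(phi))[:, None]
        * np.stack([np.interp(ax + offset, sp, n2[:, k]) for k in range(3)], axis=1)
    )
    return DeploymentState(positions=pos, axial_coord=ax + offset)


# --------------------------------------------------------------------------
# elastic model
# --------------------------------------------------------------------------

def _bending_pairs(frame: Wireframe):
    """Second-neighbour node pairs along each wire (bending surrogate)."""
    pairs = []
    for w, segs in frame.wire_paths().items():
        idx = [segs[0][0]] + [j for _, j in segs]
        idx = np.asarray(idx)
        if len(idx) >= 3:
            pairs.append(np.stack([idx[:-2], idx[2:]], axis=1))
    return np.vstack(pairs) if pairs else np.zeros((0, 2), int)


def _rigid_fit(ref, cur, weights=None):
    """Best-fit rotation+translation of ref onto cur (Kabsch, det=+1)."""
    if weights is None:
        c_ref = ref.mean(axis=0)
        c_cur = cur.mean(axis=0)
        H = (ref - c_ref).T @ (cur - c_cur)
    else:
        w = weights[:, None]
        c_ref = (ref * w).sum(0) / w.sum()
        c_cur = (cur * w).sum(0) / w.sum()
        H = (ref - c_ref).T @ ((cur - c_cur) * w)
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    R = Vt.T @ np.diag([1.0, 1.0, d]) @ U.T
    return R, c_cur - R @ c_ref


class _Elastic:
    def __init__(self, frame: Wireframe, params: RelaxParams):
        self.p = params
        self.ij = frame.struts
        self.L0 = frame.strut_lengths(reference=True)
        self.bk = _bending_pairs(frame)
        x = frame.reference_nodes
        self.B0 = np.linalg.norm(x[self.bk[:, 1]] - x[self.bk[:, 0]], axis=1) \
            if len(self.bk) else np.zeros(0)
        self.ref = frame.reference_nodes
        self.n = len(x)

    def energy_grad(self, pos, released):
        p = self.p
        E = 0.0
        g = np.zeros_like(pos)
        i, j = self.ij[:, 0], self.ij[:, 1]
        d = pos[j] - pos[i]
        L = np.linalg.norm(d, axis=1)
        e = (L - self.L0) / self.L0
        # braids scissor shut far more easily than they stretch: springs may
        # be softer in compression (compression_factor < 1)
        ks = p.k_stretch * np.where(e < 0, p.compression_factor, 1.0)
        E += 0.5 * float((ks * self.L0) @ e**2)
        f = (ks * e / np.maximum(L, 1e-12))[:, None] * d
        np.add.at(g, i, -f)
        np.add.at(g, j, f)
        if len(self.bk):
            bi, bj = self.bk[:, 0], self.bk[:, 1]
            db = pos[bj] - pos[bi]
            Lb = np.linalg.norm(db, axis=1)
            eb = (Lb - self.B0) / self.B0
            kb = p.k_bend * np.where(eb < 0, p.compression_factor, 1.0)
            E += 0.5 * float((kb * self.B0) @ eb**2)
            fb = (kb * eb / np.maximum(Lb, 1e-12))[:, None] * db
            np.add.at(g, bi, -fb)
            np.add.at(g, bj, fb)
        if p.shape_beta > 0 and released.sum() >= 3:
            R, t = _rigid_fit(self.ref[released], pos[released])
            target = self.ref[released] @ R.T + t
            dv = pos[released] - target
            E += 0.5 * p.shape_beta * float((dv**2).sum())
            g[released] += p.shape_beta * dv
        return E, g


def _lumen_sdf(lumen):
    if callable(lumen):
        return lumen
    return lambda pts: lumen.sdf(pts)


def _project_to_wall(sdf, pos, idx, inset=0.0, eps=1e-4):
    """Move penetrating nodes back onto the wall along the SDF gradient."""
    if not len(idx):
        return idx
    for _ in range(3):
        d = sdf(pos[idx])
        out = d > -inset
        if not out.any():
            break
        sub = idx[out]
        grad = np.zeros((len(sub), 3))
        for k in range(3):
            dp = np.zeros(3)
            dp[k] = eps
            grad[:, k] = (sdf(pos[sub] + dp) - sdf(pos[sub] - dp)) / (2 * eps)
        norm = np.linalg.norm(grad, axis=1, keepdims=True)
        grad /= np.maximum(norm, 1e-12)
        pos[sub] -= (d[out] + inset)[:, None] * grad
    return idx


# --------------------------------------------------------------------------
# progressive release
# --------------------------------------------------------------------------

def release(state: DeploymentState, frame: Wireframe, lumen,
            schedule=None, relax_params: RelaxParams | None = None,
            distal="max", trajectory_dir=None) -> DeploymentState:
    """Unsheathe the device progressively and relax to wall-bounded equilibrium.

    ``schedule`` is an increasing sequence of release fractions in (0, 1]
    (default: 48 equal increments); release proceeds from the distal end of
    the delivery path toward the proximal end ("distal" meaning the large
    arc-length end when ``distal='max'``).  ``lumen`` is a geometry with an
    ``sdf`` method or a bare SDF callable (negative inside).
    ``trajectory_dir`` optionally dumps the wireframe after every release
    increment as a legacy-VTK line-set series for visual QA.

    Returns the converged final state; raises :class:`DeploymentError`
    carrying the last state if the relaxation does not converge.
    """
    p = relax_params or RelaxParams()
    if schedule is None:
        schedule = np.linspace(1.0 / p.n_increments, 1.0, p.n_increments)
    schedule = np.asarray(schedule, float)
    if np.any(np.diff(schedule) <= 0) or schedule[-1] > 1.0 + 1e-12:
        raise ValueError("schedule must be strictly increasing, ending <= 1")
    sdf = _lumen_sdf(lumen)
    if state.axial_coord is None:
        raise ValueError("state lacks axial coordinates; crimp first")

    pos = state.positions.copy()
    inside0 = sdf(pos) < 0
    if not inside0.any():
        raise DeploymentError("device is wholly outside the lumen")

    model = _Elastic(frame, p)
    s = state.axial_coord
    smin, smax = s.min(), s.max()
    span = max(smax - smin, 1e-12)

    out = state.copy()
    out.positions = pos
    dt = p.step
    all_idx = np.arange(len(pos))
    n_it = 0
    E_prev = None

    def released_mask(fraction):
        if distal == "max":
            return s >= smax - fraction * span - 1e-12
        return s <= smin + fraction * span + 1e-12

    if trajectory_dir is not None:
        from pathlib import Path
        traj = Path(trajectory_dir)
        traj.mkdir(parents=True, exist_ok=True)

    phases = [(f, p.iters_per_increment) for f in schedule[:-1]]
    phases.append((schedule[-1], p.max_final_iters))
    final_energy = []
    for step_no, (fraction, iters) in enumerate(phases):
        rel = released_mask(fraction)
        out.release_fraction = float(fraction)
        final = fraction == schedule[-1]
        for _ in range(iters):
            E, g = model.energy_grad(pos, rel)
            g[~rel] = 0.0
            prev = pos
            # backtracking: reject trial steps that raise the elastic energy
            for _attempt in range(5):
                trial = prev - dt * g
                pen = np.flatnonzero(rel & (sdf(trial) > -p.contact_inset))
                _project_to_wall(sdf, trial, pen, inset=p.contact_inset)
                E_trial, _ = model.energy_grad(trial, rel)
                if E_trial <= E * (1 + 1e-12) + 1e-15:
                    dt = min(dt * 1.1, p.step)
                    break
                dt = max(dt * 0.5, 1e-4)
            pos = trial
            out.max_step = float(np.abs(pos - prev).max())
            n_it += 1
            if final:
                final_energy.append(E)
                if out.max_step < p.step_tol:
                    break
        if trajectory_dir is not None:
            from .geometry import _write_vtk_polydata
            _write_vtk_polydata(
                traj / f"release_{step_no:03d}.vtk", pos,
                lines=[list(st) for st in frame.struts],
                comment=f"release fraction {fraction:.3f}")
    out.positions = pos
    out.iteration = n_it
    out.contact_set = np.flatnonzero(sdf(pos) > -2 * p.penetration_tol)
    out.energy_history = final_energy

    pen_depth = float(np.maximum(sdf(pos), 0.0).max())
    out.converged = out.max_step < p.step_tol and pen_depth <= p.penetration_tol
    if not out.converged:
        raise DeploymentError(
            f"relaxation did not converge (max_step={out.max_step:.2e} mm, "
            f"penetration={pen_depth:.2e} mm)", state=out,
        )
    del all_idx
    return out


def deployed_frame(state: DeploymentState, frame: Wireframe) -> Wireframe:
    """Wireframe with deployed positions (reference shape retained)."""
    if not state.converged:
        raise DeploymentError("state is not converged", state=state)
    new = Wireframe(
        nodes=state.positions.copy(),
        struts=frame.struts.copy(),
        wire_id=frame.wire_id.copy(),
        reference_nodes=frame.reference_nodes.copy(),
        strut_radius=frame.strut_radius,
        family=frame.family,
        nominal_diameter=frame.nominal_diameter,
        length=frame.length,
        braid_angle=frame.braid_angle,
        meta=dict(frame.meta),
    )
    return new


# --------------------------------------------------------------------------
# automatic delivery paths
# --------------------------------------------------------------------------

def auto_path(geom, device_family, stented_daughter=0, measures=None) -> DeliveryPath:
    """Default delivery path for a generated bifurcation geometry.

    Braided stents follow the vessel centreline from the inlet through the
    stented daughter; intrasaccular devices follow the parent centreline to
    the bifurcation, then turn through the neck toward the dome.  In both
    cases the distal end of the path (large arc length) is the release
    origin, matching a distal-to-proximal unsheathing with respect to the
    sac.
    """
    parent = geom.centerlines["parent"]
    if device_family == "braided_stent":
        daughter = geom.centerlines[f"daughter_{stented_daughter}"]
        pts = np.vstack([parent, daughter[1:]])
        return DeliveryPath(points=pts, role="centerline")
    if device_family == "contour":
        from .geometry import measure_aneurysm
        m = measures or measure_aneurysm(geom)
        apex = parent[-1]
        tip = geom.dome_center + geom.dome_axes[:, 2] * 0.5 * geom.dome_semi_axes[2]
        pts = np.vstack([
            parent[0],
            apex,
            m.neck_origin,
            geom.dome_center,
            tip,
        ])
        return DeliveryPath(points=pts, role="neck_to_dome")
    raise ValueError(f"unknown device family {device_family}")


def crimped_length(frame: Wireframe, radius: float) -> float:
    """Axial extent of the device crimped to ``radius`` (wire length
    conserved; braid kinematics)."""
    s, r, phi = _device_axis_coords(frame)
    rho = min(1.0, radius / max(r.max(), 1e-12))
    ref_len = frame.total_wire_length(reference=True)
    s0 = s.min()
    i, j = frame.struts[:, 0], frame.struts[:, 1]

    def total_len(lam):
        ax = s0 + lam * (s - s0)
        x = np.stack([ax, rho * r * np.cos(phi), rho * r * np.sin(phi)], axis=1)
        return np.linalg.norm(x[j] - x[i], axis=1).sum() - ref_len

    lam = 1.0 if abs(total_len(1.0)) < 1e-9 * ref_len else brentq(
        total_len, 1.0, 80.0, xtol=1e-10)
    return float(lam * (s.max() - s0))


def fit_crimp_radius(frame: Wireframe, path: DeliveryPath, margin=1.0,
                     floor=None) -> float:
    """Tightest crimp radius whose elongated device still fits the path.

    Braid kinematics make the crimped device longer as the radius shrinks;
    on short synthetic vessels the sheath radius is therefore bounded below
    by the available track length.  Returns the smallest radius (>= floor)
    such that crimped length + margin <= path arc length.
    """
    if floor is None:
        floor = 2.5 * frame.strut_radius
    nominal_r = frame.nominal_diameter / 2.0
    avail = path.arc_length - margin
    if crimped_length(frame, nominal_r * 0.999) > avail:
        raise DeploymentError(
            f"path ({path.arc_length:.1f} mm) cannot host the device even "
            "uncrimped")
    lo, hi = floor, nominal_r * 0.999
    if crimped_length(frame, lo) <= avail:
        return lo
    for _ in range(60):
        mid = 0.5 * (lo + hi)
        if crimped_length(frame, mid) > avail:
            lo = mid
        else:
            hi = mid
    return hi
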