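"""Parametric idealized bifurcation-aneurysm lumens.

A middle-cerebral-artery-like bifurcation is modelled as a parent tube that
splits into two daughter tubes in the xy-plane, with an ellipsoidal aneurysm
dome seated over the bifurcation apex along the parent-axis direction.  The
lumen is the union of the smoothly blended vessel envelope and the dome,
cut by flat cap planes at the inlet and the two outlets.  All lengths are in
millimetres; the canonical frame puts the bifurcation point at the origin and
the inlet at negative x.

The construction is analytic (signed distance fields), so generated
geometries carry an exact inside/outside test that the deployment and flow
modules reuse; the triangulated surface is extracted by marching cubes at a
caller-chosen target edge length.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import trimesh
from scipy.optimize import brentq
from scipy.spatial import cKDTree
from skimage import measure as _skmeasure

__all__ = [
    "BifurcationGeometry",
    "AnalyticLumen",
    "straight_tube_geometry",
    "symmetric_y_geometry",
    "AneurysmMeasures",
    "CASE_I_PARAMS",
    "CASE_II_PARAMS",
    "generate_bifurcation_aneurysm",
    "measure_aneurysm",
    "write_geometry",
    "read_geometry",
    "GeometryError",
]


class GeometryError(ValueError):
    """Invalid or infeasible geometric input."""


# --------------------------------------------------------------------------
# signed-distance primitives (points: (N, 3) arrays, mm; negative inside)
# --------------------------------------------------------------------------

def _sdf_capsule(p, a, b, r):
    """Tube with spherical end caps from a to b, radius r."""
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    pa = p - a
    ba = b - a
    h = np.clip(pa @ ba / (ba @ ba), 0.0, 1.0)
    return np.linalg.norm(pa - np.outer(h, ba), axis=-1) - r


def _sdf_ellipsoid(p, center, axes, semi):
    """Approximate SDF of an ellipsoid; the zero level set is exact.

    axes: (3,3) rotation, columns = principal directions; semi: (3,) semi-axes.
    """
    q = (p - center) @ axes  # local coordinates
    k0 = np.linalg.norm(q / semi, axis=-1)
    k1 = np.linalg.norm(q / (np.asarray(semi) ** 2), axis=-1)
    with np.errstate(divide="ignore", invalid="ignore"):
        d = np.where(k1 > 0, k0 * (k0 - 1.0) / k1, -np.min(semi))
    return d


def _smin(d1, d2, k):
    """Polynomial smooth minimum (union) with blend radius k."""
    if k <= 0:
        return np.minimum(d1, d2)
    h = np.clip(0.5 + 0.5 * (d2 - d1) / k, 0.0, 1.0)
    return d2 + (d1 - d2) * h - k * h * (1.0 - h)


# --------------------------------------------------------------------------
# domain types
# --------------------------------------------------------------------------

@dataclass
class Cap:
    """A flat cut plane closing the lumen at an inlet or outlet."""

    name: str
    origin: np.ndarray          # point on the plane, mm
    normal: np.ndarray          # unit, pointing out of the lumen
    radius: float               # nominal lumen radius at the cap, mm
    face_indices: np.ndarray | None = None


@dataclass
class AneurysmMeasures:
    """Clinically relevant aneurysm measurements used for device sizing."""

    d_n: float                  # neck width, mm
    d_a: float                  # maximum aneurysm width, mm
    sdr: float                  # non-stented-daughter / parent diameter ratio
    neck_origin: np.ndarray     # point on the fitted neck plane, mm
    neck_normal: np.ndarray     # unit normal, oriented into the sac
    neck_contour: np.ndarray = field(default=None, repr=False)  # (M,3) mm

    def __post_init__(self):
        tol = 1e-9 * max(1.0, abs(self.d_a))
        if not (self.d_a >= self.d_n - tol and self.d_n > 0):
            raise GeometryError(
                f"require d_a >= d_n > 0, got d_n={self.d_n}, d_a={self.d_a}"
            )
        self.d_n = min(self.d_n, self.d_a)
        if self.sdr <= 0:
            raise GeometryError("sdr must be positive")
        n = np.linalg.norm(self.neck_normal)
        if abs(n - 1.0) > 1e-9:
            raise GeometryError("neck normal must have unit length")


@dataclass
class BifurcationGeometry:
    """Triangulated lumen of a bifurcation aneurysm plus its skeleton.

    ``surface`` is watertight (caps included).  ``anatomy`` retains the
    analytic construction for generated geometries and is ``None`` for
    meshes loaded without a sidecar; the analytic form provides an exact
    signed distance used by deployment contact and the flow solver.
    """

    surface: trimesh.Trimesh
    caps: dict
    centerlines: dict
    parent_diameter: float
    daughter_diameters: tuple
    bifurcation_angles: tuple
    dome_center: np.ndarray
    dome_axes: np.ndarray       # (3,3) columns = principal directions
    dome_semi_axes: np.ndarray  # (3,) mm; [2] is along the dome axis
    anatomy: dict | None = None
    _mesh_sdf: object = field(default=None, repr=False)

    # -- signed distance ---------------------------------------------------
    def vessel_sdf(self, points):
        """SDF of the blended vessel envelope alone (no dome, no caps).

        The envelope is the parent and daughter tubes plus the junction
        bulb — the fattened confluence a wide-neck bifurcation aneurysm
        incorporates; the neck contour lives on the dome/envelope
        intersection."""
        if self.anatomy is None:
            raise GeometryError("vessel envelope requires analytic anatomy")
        return _envelope_sdf_factory(self.anatomy)(points)

    def dome_sdf(self, points):
        return _sdf_ellipsoid(points, self.dome_center, self.dome_axes,
                              self.dome_semi_axes)

    def sdf(self, points, with_caps=True, outlet_extension=0.0):
        """Signed distance to the lumen (negative inside).

        ``outlet_extension > 0`` ignores the outlet cap cuts so the flow
        domain can be extended past the pressure outlets; the inlet cap cut
        always applies.  Falls back to a mesh-based query for loaded
        geometries without analytic anatomy.
        """
        points = np.atleast_2d(np.asarray(points, float))
        if self.anatomy is None:
            return self._mesh_distance(points)
        d = np.minimum(self.vessel_sdf(points), self.dome_sdf(points))
        if not with_caps:
            return d
        for cap in self.caps.values():
            plane = (points - cap.origin) @ cap.normal
            if cap.name != "inlet":
                plane = plane - outlet_extension
            d = np.maximum(d, plane)
        return d

    def _mesh_distance(self, points):
        if self._mesh_sdf is None:
            self._mesh_sdf = _MeshSDF(self.surface)
        return self._mesh_sdf(points)

    # -- invariant helpers -------------------------------------------------
    def is_watertight(self):
        return bool(self.surface.is_watertight)

    def validate(self):
        if not self.is_watertight():
            raise GeometryError("surface is not watertight")
        if self.parent_diameter <= 0 or min(self.daughter_diameters) <= 0:
            raise GeometryError("all diameters must be positive")
        for name, line in self.centerlines.items():
            if name != "parent":
                cap = self.caps["outlet_0" if name.endswith("0") else "outlet_1"]
                end = line[-1]
                if abs((end - cap.origin) @ cap.normal) > 1e-6:
                    raise GeometryError(f"centerline {name} does not end on its cap")
        return True


class _MeshSDF:
    """Signed distance to a closed triangle soup via nearest sampled point
    and angle-weighted pseudo-normals (no external spatial index needed)."""

    def __init__(self, mesh, samples_per_mm2=8.0):
        n = max(2000, int(mesh.area * samples_per_mm2))
        pts, fidx = trimesh.sample.sample_surface(mesh, n, seed=0)
        self._pts = np.vstack([pts, mesh.vertices])
        self._nrm = np.vstack(
            [mesh.face_normals[fidx], mesh.vertex_normals]
        )
        self._tree = cKDTree(self._pts)

    def __call__(self, points):
        d, i = self._tree.query(points, k=1)
        sign = np.sign(np.einsum("ij,ij->i", points - self._pts[i], self._nrm[i]))
        sign[sign == 0] = 1.0
        return d * sign


# --------------------------------------------------------------------------
# generator
# --------------------------------------------------------------------------

#: Synthetic stand-ins for the two study cases (printed neck and dome widths;
#: vessel calibre, branch angles and dome height are package choices of
#: typical MCA anatomy).
CASE_I_PARAMS = dict(
    parent_diameter=2.4,
    daughter_diameters=(2.0, 2.1),
    branch_angles=(52.0, 55.0),
    neck_width=8.58,
    dome_width=9.37,
    dome_height_ratio=0.90,
    parent_length=12.0,
    daughter_length=13.0,
)

CASE_II_PARAMS = dict(
    parent_diameter=2.8,
    daughter_diameters=(2.6, 1.8),
    branch_angles=(55.0, 60.0),
    neck_width=3.11,
    dome_width=5.56,
    dome_height_ratio=0.95,
    parent_length=12.0,
    daughter_length=13.0,
)


def _daughter_dirs(branch_angles):
    a0, a1 = np.radians(branch_angles)
    return (
        np.array([np.cos(a0), np.sin(a0), 0.0]),
        np.array([np.cos(a1), -np.sin(a1), 0.0]),
    )


def _envelope_sdf_factory(anatomy):
    def f(points):
        d = _sdf_capsule(points, anatomy["parent_a"], anatomy["parent_b"],
                         anatomy["parent_r"])
        for s, e, r in anatomy["daughters"]:
            d = _smin(d, _sdf_capsule(points, s, e, r), anatomy["blend"])
        bulb = anatomy.get("bulb")
        if bulb is not None:
            center, radius = bulb
            d = _smin(d, np.linalg.norm(points - center, axis=-1) - radius,
                      anatomy["blend"])
        return d
    return f


def _neck_contour_points(center, axes, semi, envelope_sdf,
                         n_theta=192, n_phi=384):
    """Intersection curve of the ellipsoid surface with the vessel envelope.

    The dome surface is sampled on a (theta, phi) grid, the envelope SDF is
    evaluated there, and the zero level set is extracted in parameter space
    and mapped back to 3D.  Returns an (M, 3) array (empty if no overlap).
    """
    theta = np.linspace(1e-3, np.pi - 1e-3, n_theta)
    phi = np.linspace(0.0, 2 * np.pi, n_phi, endpoint=False)
    T, P = np.meshgrid(theta, phi, indexing="ij")
    local = np.stack(
        [
            semi[0] * np.sin(T) * np.cos(P),
            semi[1] * np.sin(T) * np.sin(P),
            semi[2] * np.cos(T),
        ],
        axis=-1,
    )
    pts = center + local.reshape(-1, 3) @ axes.T
    f = envelope_sdf(pts).reshape(n_theta, n_phi)
    if f.min() >= 0 or f.max() <= 0:
        return np.empty((0, 3))
    # pad phi to close the periodic seam
    fp = np.concatenate([f, f[:, :1]], axis=1)
    contours = _skmeasure.find_contours(fp, 0.0)
    if not contours:
        return np.empty((0, 3))
    dth = theta[1] - theta[0]
    dph = phi[1] - phi[0]
    out = []
    for c in contours:
        th = theta[0] + c[:, 0] * dth
        ph = (c[:, 1] * dph) % (2 * np.pi)
        loc = np.stack(
            [
                semi[0] * np.sin(th) * np.cos(ph),
                semi[1] * np.sin(th) * np.sin(ph),
                semi[2] * np.cos(th),
            ],
            axis=-1,
        )
        out.append(center + loc @ axes.T)
    return np.vstack(out)


def _max_chord(points):
    if len(points) < 2:
        return 0.0
    # points live on a closed curve; pairwise search is fine at this size,
    # thinned for very dense contours
    if len(points) > 1200:
        points = points[:: len(points) // 1200 + 1]
    d2 = np.sum((points[:, None, :] - points[None, :, :]) ** 2, axis=-1)
    return float(np.sqrt(d2.max()))


def generate_bifurcation_aneurysm(
    parent_diameter=3.0,
    daughter_diameters=(2.4, 2.1),
    branch_angles=(52.0, 55.0),
    neck_width=8.58,
    dome_width=9.37,
    dome_height_ratio=0.90,
    edge_length=0.2,
    parent_length=8.0,
    daughter_length=9.0,
    blend_radius=0.8,
    bulb_radius=None,
    dome_tilt=45.0,
    perturb=0.0,
    seed=None,
):
    """Build an idealized wide-neck bifurcation-aneurysm lumen.

    Parameters are in millimetres/degrees.  The vessel envelope is the
    parent and two daughter tubes blended with a junction bulb of
    ``bulb_radius`` (default scales with the neck width) — the fattened
    confluence that wide-neck bifurcation aneurysms incorporate.  The
    ellipsoidal dome sits on the bulb along an axis tilted ``dome_tilt``
    degrees from vertical (+z) toward the parent-flow direction (+x), since
    the sac grows along the impinging jet; ``neck_width`` (d_n) is hit by a
    1-D calibration of the dome centre along that axis, and ``dome_width``
    is d_a, the dome's equatorial diameter.  Construction is deterministic
    unless ``perturb > 0``, which adds a seed-controlled normal-direction
    surface jitter of the given amplitude.

    Raises :class:`GeometryError` for infeasible parameter combinations.
    """
    lengths = dict(
        parent_diameter=parent_diameter,
        daughter_diameters=min(daughter_diameters),
        neck_width=neck_width,
        dome_width=dome_width,
        dome_height_ratio=dome_height_ratio,
        edge_length=edge_length,
        parent_length=parent_length,
        daughter_length=daughter_length,
    )
    for k, v in lengths.items():
        if v <= 0:
            raise GeometryError(f"{k} must be positive, got {v}")
    if neck_width > dome_width:
        raise GeometryError(
            f"neck width {neck_width} exceeds dome equatorial diameter {dome_width}"
        )

    rp = parent_diameter / 2.0
    rd = [d / 2.0 for d in daughter_diameters]
    dirs = _daughter_dirs(branch_angles)
    semi = np.array([dome_width / 2.0, dome_width / 2.0,
                     dome_width / 2.0 * dome_height_ratio])
    if bulb_radius is None:
        bulb_radius = 0.55 * neck_width
    tilt = np.radians(dome_tilt)
    d_hat = np.array([np.sin(tilt), 0.0, np.cos(tilt)])  # dome axis
    u_hat = np.array([np.cos(tilt), 0.0, -np.sin(tilt)])
    axes = np.stack([u_hat, np.array([0.0, 1.0, 0.0]), d_hat], axis=1)
    bulb_center = np.array([0.25 * bulb_radius, 0.0, 0.0])

    anatomy = dict(
        parent_a=np.array([-parent_length - rp, 0.0, 0.0]),
        parent_b=np.array([rp * 0.5, 0.0, 0.0]),
        parent_r=rp,
        daughters=[
            (np.array([0.0, 0.0, 0.0]), dirs[i] * (daughter_length + rd[i]), rd[i])
            for i in range(2)
        ],
        blend=blend_radius,
        bulb=(bulb_center, float(bulb_radius)),
    )
    envelope = _envelope_sdf_factory(anatomy)

    def measured_dn(t):
        pts = _neck_contour_points(bulb_center + t * d_hat, axes, semi, envelope)
        return _max_chord(pts)

    # calibrate dome offset along its axis: moving the dome off the bulb
    # shrinks the neck monotonically
    ts = np.linspace(0.15 * semi[2], bulb_radius + semi[2], 50)
    vals = np.array([measured_dn(t) for t in ts])
    if vals.max() < neck_width:
        raise GeometryError(
            "infeasible parameters: dome does not intersect the vessel "
            f"envelope widely enough (max attainable neck width "
            f"{vals.max():.2f} mm < requested {neck_width} mm); widen the "
            "junction bulb or the dome"
        )
    tc = None
    for i in range(len(ts) - 1):
        if vals[i] >= neck_width >= vals[i + 1]:
            tc = brentq(lambda t: measured_dn(t) - neck_width,
                        ts[i], ts[i + 1], xtol=1e-4)
            break
    if tc is None:
        raise GeometryError(
            "infeasible parameters: requested neck width is never crossed as "
            "the dome moves off the junction bulb"
        )
    center = bulb_center + tc * d_hat

    # cap planes
    inlet_origin = np.array([-parent_length, 0.0, 0.0])
    caps = {
        "inlet": Cap("inlet", inlet_origin, np.array([-1.0, 0.0, 0.0]), rp),
        "outlet_0": Cap("outlet_0", dirs[0] * daughter_length, dirs[0], rd[0]),
        "outlet_1": Cap("outlet_1", dirs[1] * daughter_length, dirs[1], rd[1]),
    }
    # dome must stay clear of every cap plane (exact ellipsoid support)
    for cap in caps.values():
        support = float(np.linalg.norm(semi * (cap.normal @ axes)))
        reach = (center - cap.origin) @ cap.normal + support
        if reach > -0.5:
            raise GeometryError(
                f"infeasible parameters: dome reaches the {cap.name} cap plane; "
                "lengthen the vessels or shrink the dome"
            )

    geom = BifurcationGeometry(
        surface=None,
        caps=caps,
        centerlines={
            "parent": np.array([inlet_origin, [0.0, 0.0, 0.0]]),
            "daughter_0": np.array([[0.0, 0.0, 0.0], caps["outlet_0"].origin]),
            "daughter_1": np.array([[0.0, 0.0, 0.0], caps["outlet_1"].origin]),
        },
        parent_diameter=parent_diameter,
        daughter_diameters=tuple(daughter_diameters),
        bifurcation_angles=tuple(branch_angles),
        dome_center=center,
        dome_axes=axes,
        dome_semi_axes=semi,
        anatomy=anatomy,
    )
    geom.surface = _extract_surface(geom, edge_length, perturb, seed)
    _label_caps(geom, edge_length)
    geom.params = None
    return geom


def _extract_surface(geom, edge_length, perturb=0.0, seed=None):
    pts_min = np.array([-1e9, -1e9, -1e9])
    pts_max = -pts_min
    a = geom.anatomy
    lo = np.minimum(a["parent_a"], a["parent_b"]) - a["parent_r"]
    hi = np.maximum(a["parent_a"], a["parent_b"]) + a["parent_r"]
    for s, e, r in a["daughters"]:
        lo = np.minimum(lo, np.minimum(s, e) - r)
        hi = np.maximum(hi, np.maximum(s, e) + r)
    if a.get("bulb") is not None:
        c, r = a["bulb"]
        lo = np.minimum(lo, c - r)
        hi = np.maximum(hi, c + r)
    lo = np.minimum(lo, geom.dome_center - geom.dome_semi_axes.max())
    hi = np.maximum(hi, geom.dome_center + geom.dome_semi_axes.max())
    h = float(edge_length)
    margin = 3 * h
    # offset the grid by an irrational fraction of h so that cap planes do
    # not coincide with grid nodes (exact SDF zeros break marching cubes)
    lo, hi = lo - margin - h * 0.2360679774997897, hi + margin
    nx, ny, nz = [int(np.ceil((hi[i] - lo[i]) / h)) + 1 for i in range(3)]
    xs = lo[0] + h * np.arange(nx)
    ys = lo[1] + h * np.arange(ny)
    zs = lo[2] + h * np.arange(nz)
    X, Y, Z = np.meshgrid(xs, ys, zs, indexing="ij")
    P = np.stack([X.ravel(), Y.ravel(), Z.ravel()], axis=-1)
    vol = geom.sdf(P, with_caps=True).reshape(nx, ny, nz)
    vol[vol == 0.0] = -1e-12
    verts, faces, _, _ = _skmeasure.marching_cubes(vol, 0.0, spacing=(h, h, h))
    verts = verts + lo
    mesh = trimesh.Trimesh(vertices=verts, faces=faces, process=True)
    if perturb > 0.0:
        rng = np.random.default_rng(seed)
        keep = geom.sdf(mesh.vertices, with_caps=True)  # ~0 on surface
        jitter = rng.normal(scale=perturb, size=len(mesh.vertices))
        # do not jitter cap vertices (planarity invariant)
        on_cap = np.zeros(len(mesh.vertices), bool)
        for cap in geom.caps.values():
            d = np.abs((mesh.vertices - cap.origin) @ cap.normal)
            on_cap |= d < 2 * perturb + 1e-6
        jitter[on_cap] = 0.0
        mesh = trimesh.Trimesh(
            mesh.vertices + jitter[:, None] * mesh.vertex_normals,
            mesh.faces, process=False)
        del keep
    # snap near-cap vertices exactly onto their planes (flat, labelled caps)
    v = mesh.vertices.copy()
    for cap in geom.caps.values():
        d = (v - cap.origin) @ cap.normal
        near = (np.abs(d) < 0.75 * h) & (
            np.linalg.norm((v - cap.origin) - np.outer(d, cap.normal), axis=1)
            < cap.radius + 2 * h
        )
        v[near] -= np.outer(d[near], cap.normal)
    mesh = trimesh.Trimesh(v, mesh.faces, process=False)
    return mesh


def _label_caps(geom, edge_length):
    mesh = geom.surface
    centroids = mesh.triangles_center
    normals = mesh.face_normals
    for cap in geom.caps.values():
        d = np.abs((centroids - cap.origin) @ cap.normal)
        aligned = normals @ cap.normal > 0.9
        radial = np.linalg.norm(
            (centroids - cap.origin)
            - np.outer((centroids - cap.origin) @ cap.normal, cap.normal),
            axis=1,
        )
        cap.face_indices = np.flatnonzero(
            (d < 1e-6) & aligned & (radial < cap.radius + 2 * edge_length)
        )


# --------------------------------------------------------------------------
# measurement
# --------------------------------------------------------------------------

def measure_aneurysm(geom: BifurcationGeometry, envelope_sdf=None,
                     stented_daughter=0) -> AneurysmMeasures:
    """Measure neck width d_n, maximum width d_a, and the neck plane.

    The neck contour is the intersection curve between the dome surface and
    the vessel lumen envelope; d_n is its maximum chord, the neck plane is
    the least-squares plane through it (normal oriented into the sac), and
    d_a is the dome's maximum chord parallel to that plane.  ``envelope_sdf``
    overrides the vessel envelope (used for idealized test constructions).
    """
    if envelope_sdf is None:
        envelope_sdf = geom.vessel_sdf
    contour = _neck_contour_points(
        geom.dome_center, geom.dome_axes, geom.dome_semi_axes, envelope_sdf
    )
    if len(contour) < 8:
        raise GeometryError("no identifiable neck contour (dome does not "
                            "intersect the vessel envelope)")
    d_n = _max_chord(contour)

    centroid = contour.mean(axis=0)
    _, _, vt = np.linalg.svd(contour - centroid, full_matrices=False)
    normal = vt[2]
    if (geom.dome_center - centroid) @ normal < 0:
        normal = -normal

    # d_a: maximum chord of the ellipsoid parallel to the neck plane
    B = np.diag(geom.dome_semi_axes) @ geom.dome_axes.T
    basis = _plane_basis(normal)
    d_a = 2.0 * np.linalg.svd(B @ basis.T, compute_uv=False)[0]

    other = 1 - stented_daughter
    sdr = geom.daughter_diameters[other] / geom.parent_diameter
    return AneurysmMeasures(
        d_n=float(d_n),
        d_a=float(d_a),
        sdr=float(sdr),
        neck_origin=centroid,
        neck_normal=normal / np.linalg.norm(normal),
        neck_contour=contour,
    )


def _plane_basis(normal):
    n = normal / np.linalg.norm(normal)
    a = np.array([1.0, 0.0, 0.0])
    if abs(n @ a) > 0.9:
        a = np.array([0.0, 1.0, 0.0])
    u = np.cross(n, a)
    u /= np.linalg.norm(u)
    v = np.cross(n, u)
    return np.stack([u, v])


# --------------------------------------------------------------------------
# IO: STL via trimesh, legacy-ASCII VTK PolyData in-house, JSON sidecar
# --------------------------------------------------------------------------

def _write_vtk_polydata(path, vertices, faces=None, lines=None, comment="aneutreat surface"):
    with open(path, "w") as f:
        f.write("# vtk DataFile Version 3.0\n")
        f.write(comment + "\n")
        f.write("ASCII\nDATASET POLYDATA\n")
        f.write(f"POINTS {len(vertices)} double\n")
        for p in np.asarray(vertices, float):
            f.write(f"{float(p[0])!r} {float(p[1])!r} {float(p[2])!r}\n")
        if faces is not None and len(faces):
            f.write(f"POLYGONS {len(faces)} {4 * len(faces)}\n")
            for t in faces:
                f.write(f"3 {t[0]} {t[1]} {t[2]}\n")
        if lines is not None and len(lines):
            total = sum(len(l) + 1 for l in lines)
            f.write(f"LINES {len(lines)} {total}\n")
            for l in lines:
                f.write(" ".join([str(len(l))] + [str(i) for i in l]) + "\n")


def _read_vtk_polydata(path):
    toks = []
    with open(path) as f:
        head = [f.readline() for _ in range(4)]
        if "ASCII" not in "".join(head).upper():
            raise GeometryError(f"{path}: only legacy ASCII VTK is supported")
        toks = f.read().split()
    i = 0

    def expect(word):
        nonlocal i
        while i < len(toks) and toks[i].upper() != word:
            i += 1
        if i >= len(toks):
            raise GeometryError(f"{path}: missing {word} section")
        i += 1

    expect("POINTS")
    n = int(toks[i]); i += 2  # skip dtype
    pts = np.array(toks[i:i + 3 * n], float).reshape(n, 3)
    i += 3 * n
    faces = []
    j = i
    while j < len(toks) and toks[j].upper() != "POLYGONS":
        j += 1
    if j < len(toks):
        i = j + 1
        ncells = int(toks[i]); i += 2
        for _ in range(ncells):
            k = int(toks[i])
            if k != 3:
                raise GeometryError(f"{path}: non-triangular polygon")
            faces.append([int(toks[i + 1]), int(toks[i + 2]), int(toks[i + 3])])
            i += k + 1
    return pts, np.array(faces, int)


def write_geometry(geom: BifurcationGeometry, path, format=None):
    """Write the lumen surface (STL or legacy VTK PolyData) + JSON sidecar.

    The sidecar (same stem, ``.json``) stores cap labels, centerlines and
    the analytic construction so :func:`read_geometry` can restore exact
    inside/outside queries.
    """
    path = Path(path)
    fmt = (format or path.suffix.lstrip(".")).lower()
    if fmt in ("stl", "stl_ascii"):
        geom.surface.export(path, file_type="stl_ascii" if fmt == "stl_ascii" else "stl")
    elif fmt in ("vtk", "vtp"):
        _write_vtk_polydata(path, geom.surface.vertices, geom.surface.faces)
    else:
        raise GeometryError(f"unsupported surface format: {fmt}")
    sidecar = path.with_suffix(".json")
    meta = {
        "caps": {
            k: dict(origin=c.origin.tolist(), normal=c.normal.tolist(),
                    radius=c.radius)
            for k, c in geom.caps.items()
        },
        "centerlines": {k: v.tolist() for k, v in geom.centerlines.items()},
        "parent_diameter": geom.parent_diameter,
        "daughter_diameters": list(geom.daughter_diameters),
        "bifurcation_angles": list(geom.bifurcation_angles),
        "dome_center": geom.dome_center.tolist(),
        "dome_axes": geom.dome_axes.tolist(),
        "dome_semi_axes": geom.dome_semi_axes.tolist(),
        "anatomy": None if geom.anatomy is None else dict(
            parent_a=geom.anatomy["parent_a"].tolist(),
            parent_b=geom.anatomy["parent_b"].tolist(),
            parent_r=geom.anatomy["parent_r"],
            daughters=[[s.tolist(), e.tolist(), r]
                       for s, e, r in geom.anatomy["daughters"]],
            blend=geom.anatomy["blend"],
            bulb=(None if geom.anatomy.get("bulb") is None else
                  [geom.anatomy["bulb"][0].tolist(), geom.anatomy["bulb"][1]]),
        ),
    }
    sidecar.write_text(json.dumps(meta, indent=1))
    return path


def read_geometry(path) -> BifurcationGeometry:
    """Load a lumen surface (STL or legacy VTK) and optional JSON sidecar.

    Duplicated vertices are welded on read; the result must be watertight.
    """
    path = Path(path)
    if not path.exists():
        raise GeometryError(f"no such file: {path}")
    if path.stat().st_size == 0:
        raise GeometryError(f"{path}: empty file")
    suffix = path.suffix.lower()
    if suffix == ".stl":
        mesh = trimesh.load(path, file_type="stl", process=True)
    elif suffix in (".vtk", ".vtp"):
        pts, faces = _read_vtk_polydata(path)
        mesh = trimesh.Trimesh(pts, faces, process=True)
    else:
        raise GeometryError(f"unsupported surface format: {suffix}")
    if isinstance(mesh, trimesh.Scene):
        raise GeometryError(f"{path}: expected a single surface")
    mesh.merge_vertices()
    if not mesh.is_watertight:
        edges = mesh.edges_sorted
        unique, counts = np.unique(edges, axis=0, return_counts=True)
        bad = unique[counts != 2]
        where = mesh.vertices[bad[0][0]] if len(bad) else "unknown"
        raise GeometryError(
            f"{path}: surface not watertight after welding "
            f"({len(bad)} boundary/non-manifold edges, first near {where})"
        )

    sidecar = path.with_suffix(".json")
    meta = json.loads(sidecar.read_text()) if sidecar.exists() else None
    if meta is None:
        return BifurcationGeometry(
            surface=mesh, caps={}, centerlines={},
            parent_diameter=float("nan"), daughter_diameters=(float("nan"),) * 2,
            bifurcation_angles=(float("nan"),) * 2,
            dome_center=np.zeros(3), dome_axes=np.eye(3),
            dome_semi_axes=np.ones(3), anatomy=None,
        )
    caps = {
        k: Cap(k, np.array(c["origin"]), np.array(c["normal"]), c["radius"])
        for k, c in meta["caps"].items()
    }
    anatomy = None
    if meta.get("anatomy"):
        a = meta["anatomy"]
        anatomy = dict(
            parent_a=np.array(a["parent_a"]), parent_b=np.array(a["parent_b"]),
            parent_r=a["parent_r"],
            daughters=[(np.array(s), np.array(e), r) for s, e, r in a["daughters"]],
            blend=a["blend"],
            bulb=(None if a.get("bulb") is None else
                  (np.array(a["bulb"][0]), a["bulb"][1])),
        )
    return BifurcationGeometry(
        surface=mesh,
        caps=caps,
        centerlines={k: np.array(v) for k, v in meta["centerlines"].items()},
        parent_diameter=meta["parent_diameter"],
        daughter_diameters=tuple(meta["daughter_diameters"]),
        bifurcation_angles=tuple(meta["bifurcation_angles"]),
        dome_center=np.array(meta["dome_center"]),
        dome_axes=np.array(meta["dome_axes"]),
        dome_semi_axes=np.array(meta["dome_semi_axes"]),
        anatomy=anatomy,
    )


# --------------------------------------------------------------------------
# analytic benchmark lumens (no triangulation needed)
# --------------------------------------------------------------------------

@dataclass
class AnalyticLumen:
    """A lumen defined purely by an analytic SDF plus labelled cap planes.

    Used for solver verification domains (straight tubes, symmetric
    bifurcations) where a closed-form geometry is the point.  Mimics the
    parts of :class:`BifurcationGeometry` the flow solver consumes.
    """

    open_sdf: object            # callable (N,3)->(N,) mm, caps ignored
    caps: dict
    bounds: np.ndarray          # (2,3) mm bounding box of the lumen
    centerlines: dict = field(default_factory=dict)
    surface: object = None

    def sdf(self, points, with_caps=True, outlet_extension=0.0):
        points = np.atleast_2d(np.asarray(points, float))
        d = self.open_sdf(points)
        if not with_caps and outlet_extension == 0.0:
            return d
        for cap in self.caps.values():
            plane = (points - cap.origin) @ cap.normal
            if cap.name != "inlet" and outlet_extension > 0:
                plane = plane - outlet_extension
            elif not with_caps:
                continue
            d = np.maximum(d, plane)
        return d

    def vessel_sdf(self, points):
        return self.open_sdf(np.atleast_2d(np.asarray(points, float)))


def straight_tube_geometry(radius=1.5, length=8.0) -> AnalyticLumen:
    """Axis-aligned circular tube from x=0 to x=length (Poiseuille oracle)."""

    def sdf(p):
        return np.linalg.norm(p[:, 1:], axis=1) - radius

    caps = {
        "inlet": Cap("inlet", np.array([0.0, 0.0, 0.0]),
                     np.array([-1.0, 0.0, 0.0]), radius),
        "outlet_0": Cap("outlet_0", np.array([length, 0.0, 0.0]),
                        np.array([1.0, 0.0, 0.0]), radius),
    }
    bounds = np.array([[0.0, -radius, -radius], [length, radius, radius]])
    cl = {"parent": np.array([[0.0, 0, 0], [length, 0, 0]])}
    return AnalyticLumen(open_sdf=sdf, caps=caps, bounds=bounds, centerlines=cl)


def symmetric_y_geometry(parent_radius=1.5, daughter_radius=1.2, angle=45.0,
                         parent_length=6.0, daughter_length=7.0,
                         blend=0.6) -> AnalyticLumen:
    """Symmetric Y-bifurcation (mirror plane y=0): equal daughters, equal
    angles, equal outlet pressure distances — outlet flows must split 50/50."""

    a = np.radians(angle)
    d0 = np.array([np.cos(a), np.sin(a), 0.0])
    d1 = np.array([np.cos(a), -np.sin(a), 0.0])
    pa = np.array([-parent_length - parent_radius, 0.0, 0.0])
    pb = np.array([parent_radius * 0.5, 0.0, 0.0])

    def sdf(p):
        d = _sdf_capsule(p, pa, pb, parent_radius)
        for u in (d0, d1):
            d = _smin(d, _sdf_capsule(p, np.zeros(3),
                                      u * (daughter_length + daughter_radius),
                                      daughter_radius), blend)
        return d

    caps = {
        "inlet": Cap("inlet", np.array([-parent_length, 0.0, 0.0]),
                     np.array([-1.0, 0.0, 0.0]), parent_radius),
        "outlet_0": Cap("outlet_0", d0 * daughter_length, d0, daughter_radius),
        "outlet_1": Cap("outlet_1", d1 * daughter_length, d1, daughter_radius),
    }
    ext = daughter_length * np.cos(a) + daughter_radius
    side = daughter_length * np.sin(a) + daughter_radius
    bounds = np.array([
        [-parent_length, -side, -max(parent_radius, daughter_radius)],
        [ext, side, max(parent_radius, daughter_radius)],
    ])
    cl = {
        "parent": np.array([caps["inlet"].origin, [0.0, 0, 0]]),
        "daughter_0": np.array([[0.0, 0, 0], caps["outlet_0"].origin]),
        "daughter_1": np.array([[0.0, 0, 0], caps["outlet_1"].origin]),
    }
    return AnalyticLumen(open_sdf=sdf, caps=caps, bounds=bounds, centerlines=cl)
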