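"""Measurement planes, flux integration, wall shear stress, and the
comparison statistics used to rank devices.

Aneurysm inflow Q_in is the *directional influx* through the neck plane:
the integral of max(0, u.n) with the normal oriented into the sac.  The
signed net flux is also available (``direction="net"``) since either reading
of "total flow entering" is defensible.  Daughter-vessel inflow Q_in-DV uses
a plane perpendicular to the daughter axis, one local diameter downstream of
the carina.  WSS is the viscosity times the magnitude of the wall-tangential
velocity gradient, evaluated by a two-point one-sided difference along the
inward wall normal (exact for locally parabolic profiles); WSS_max is the
literal field maximum over the named wall region, with a 99th-percentile
robust variant reported alongside (never substituted for the maximum).

Percentage reductions are reported to 1 decimal place and relative changes
to 2, rounding half away from zero.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dfield
from decimal import ROUND_HALF_UP, Decimal

import numpy as np

__all__ = [
    "SamplingPlane",
    "WallRegion",
    "HemodynamicReport",
    "MetricsError",
    "integrate_influx",
    "wall_shear_stress",
    "surface_wall_region",
    "percent_reduction",
    "relative_change",
    "comparison_report",
]


class MetricsError(ValueError):
    pass


def _round_half_away(x, decimals):
    # snap away binary-representation dust before the decimal rounding
    v = round(float(x), 9)
    q = Decimal(10) ** -decimals
    d = Decimal(repr(v)).quantize(q, rounding=ROUND_HALF_UP) if v >= 0 else \
        -((-Decimal(repr(v))).quantize(q, rounding=ROUND_HALF_UP))
    return float(d)


@dataclass
class SamplingPlane:
    """A bounded measurement plane clipped to the lumen.

    ``normal`` orientation convention: into the sac for neck planes, along
    the flow direction for daughter planes.  ``bound_radius`` limits the
    quadrature extent; ``polygon`` (optional, (M,3) closed contour on the
    plane) clips it further.
    """

    origin: np.ndarray
    normal: np.ndarray
    role: str = "neck"          # "neck" | "daughter" | "cross_section"
    bound_radius: float = 10.0  # mm
    polygon: np.ndarray | None = None

    def __post_init__(self):
        self.origin = np.asarray(self.origin, float)
        self.normal = np.asarray(self.normal, float)
        n = np.linalg.norm(self.normal)
        if n == 0:
            raise MetricsError("plane normal must be non-zero")
        self.normal = self.normal / n
        if self.polygon is not None and len(self.polygon) < 3:
            raise MetricsError("degenerate clipping polygon")

    @classmethod
    def from_measures(cls, measures, pad=1.05):
        """Neck plane from :class:`~aneutreat.geometry.AneurysmMeasures`."""
        poly = measures.neck_contour
        return cls(
            origin=measures.neck_origin,
            normal=measures.neck_normal,
            role="neck",
            bound_radius=measures.d_n / 2.0 * pad,
            polygon=poly,
        )

    @classmethod
    def daughter_plane(cls, geom, daughter=1, offset_diameters=1.0):
        """Plane across a daughter vessel, ``offset_diameters`` local
        diameters downstream of the carina, normal along the flow.

        If the geometry carries a junction bulb, the plane is pushed past
        it so that it cuts the daughter tube proper rather than the
        confluence."""
        line = geom.centerlines[f"daughter_{daughter}"]
        d = geom.daughter_diameters[daughter]
        axis = line[-1] - line[0]
        axis = axis / np.linalg.norm(axis)
        start = offset_diameters * d
        anatomy = getattr(geom, "anatomy", None)
        if anatomy and anatomy.get("bulb") is not None:
            c, r = anatomy["bulb"]
            reach = float((c - line[0]) @ axis) + r + anatomy.get("blend", 0.0)
            start = max(start, reach + 0.5 * d)
        origin = line[0] + axis * start
        return cls(origin=origin, normal=axis, role="daughter",
                   bound_radius=0.75 * d)

    def basis(self):
        n = self.normal
        a = np.eye(3)[np.argmin(np.abs(n))]
        u = np.cross(n, a)
        u /= np.linalg.norm(u)
        return u, np.cross(n, u)


def _in_polygon(pts2, poly2):
    """Even-odd rule point-in-polygon, vectorized."""
    x, y = pts2[:, 0], pts2[:, 1]
    inside = np.zeros(len(pts2), bool)
    n = len(poly2)
    for i in range(n):
        x1, y1 = poly2[i]
        x2, y2 = poly2[(i + 1) % n]
        cond = ((y1 > y) != (y2 > y))
        with np.errstate(divide="ignore", invalid="ignore"):
            xin = (x2 - x1) * (y - y1) / (y2 - y1) + x1
        inside ^= cond & (x < xin)
    return inside


def integrate_influx(field, plane: SamplingPlane, direction="influx",
                     spacing=None):
    """Volume flux through the plane in ml/min.

    ``direction="influx"`` integrates max(0, u.n); ``"net"`` integrates u.n.
    The quadrature covers the plane's bounded disc (and polygon, if any)
    clipped to the lumen interior.
    """
    if direction not in ("influx", "net"):
        raise MetricsError("direction must be 'influx' or 'net'")
    mesh = field.mesh
    if spacing is None:
        spacing = mesh.h / 2.0
    u_ax, v_ax = plane.basis()
    r = plane.bound_radius
    m = int(np.ceil(2 * r / spacing)) + 1
    s = np.linspace(-r, r, m)
    SU, SV = np.meshgrid(s, s, indexing="ij")
    pts = (plane.origin
           + SU.ravel()[:, None] * u_ax
           + SV.ravel()[:, None] * v_ax)
    keep = (SU.ravel()**2 + SV.ravel()**2) <= r**2
    if plane.polygon is not None:
        rel = plane.polygon - plane.origin
        poly2 = np.stack([rel @ u_ax, rel @ v_ax], axis=1)
        # order the contour points by angle (contours arrive as point sets)
        ang = np.arctan2(poly2[:, 1], poly2[:, 0])
        poly2 = poly2[np.argsort(ang)]
        keep &= _in_polygon(np.stack([SU.ravel(), SV.ravel()], axis=1), poly2)
    inside = mesh.geom.sdf(pts, with_caps=False) < 0
    keep &= inside
    if not keep.any():
        raise MetricsError("sampling plane lies outside the flow domain")
    vel = field.velocity_at(pts[keep])           # m/s
    un = vel @ plane.normal
    if direction == "influx":
        un = np.maximum(un, 0.0)
    dA = (2 * r / (m - 1)) ** 2                  # mm^2
    q_si = float(un.sum()) * dA * 1e-6           # m^3/s
    return q_si * 6.0e7                          # ml/min


@dataclass
class WallRegion:
    """Sample points on the wall with inward unit normals."""

    name: str
    points: np.ndarray
    inward_normals: np.ndarray

    def __post_init__(self):
        if len(self.points) == 0:
            raise MetricsError(f"wall region '{self.name}' has no faces")


def surface_wall_region(geom, region="sac", measures=None) -> WallRegion:
    """Wall sample points for a named region of a generated geometry.

    Regions: "sac" (dome wall outside the vessel envelope), "neck" (wall
    within half a neck-radius of the neck plane), "daughter_0"/"daughter_1",
    "parent", "all" (everything except caps).
    """
    mesh = geom.surface
    if mesh is None:
        raise MetricsError("geometry has no triangulated surface")
    cent = mesh.triangles_center
    inward = -mesh.face_normals
    on_cap = np.zeros(len(cent), bool)
    for cap in geom.caps.values():
        if cap.face_indices is not None:
            on_cap[cap.face_indices] = True
    wall = ~on_cap
    if region == "all":
        mask = wall
    elif region == "sac":
        mask = wall & (geom.vessel_sdf(cent) > 0.05)
    elif region == "neck":
        if measures is None:
            from .geometry import measure_aneurysm
            measures = measure_aneurysm(geom)
        d = np.abs((cent - measures.neck_origin) @ measures.neck_normal)
        radial = np.linalg.norm(
            (cent - measures.neck_origin)
            - np.outer((cent - measures.neck_origin) @ measures.neck_normal,
                       measures.neck_normal), axis=1)
        mask = wall & (d < 0.25 * measures.d_n) & (radial < 0.75 * measures.d_n)
    elif region.startswith("daughter"):
        line = geom.centerlines[region]
        a, b = line[0], line[-1]
        ab = b - a
        t = np.clip((cent - a) @ ab / (ab @ ab), 0, 1)
        dist = np.linalg.norm(cent - a - np.outer(t, ab), axis=1)
        rad = geom.daughter_diameters[int(region[-1])] / 2.0
        mask = wall & (dist < rad + 0.5) & (t > 0.15)
    elif region == "parent":
        line = geom.centerlines["parent"]
        a, b = line[0], line[-1]
        ab = b - a
        t = np.clip((cent - a) @ ab / (ab @ ab), 0, 1)
        dist = np.linalg.norm(cent - a - np.outer(t, ab), axis=1)
        mask = wall & (dist < geom.parent_diameter / 2.0 + 0.3) & (t < 0.9)
    else:
        raise MetricsError(f"unknown region '{region}'")
    return WallRegion(region, cent[mask], inward[mask])


@dataclass
class WSSResult:
    values: np.ndarray   # Pa, per sample point
    max: float           # Pa
    p99: float           # Pa, robust variant (reported alongside)
    region: str = ""


def wall_shear_stress(field, region: WallRegion, offset_factor=1.0):
    """WSS field (Pa) on the region and its maximum.

    The wall-tangential velocity gradient is estimated from samples at
    delta and 2*delta along the inward normal (delta = offset_factor * grid
    spacing) with a second-order one-sided difference, which is exact for a
    parabolic near-wall profile.  Returns ``(WSSResult, WSS_max)``.
    """
    mu = field.fluid.dynamic_viscosity
    h = field.mesh.h
    delta = offset_factor * h            # mm
    p1 = region.points + delta * region.inward_normals
    p2 = region.points + 2 * delta * region.inward_normals
    v1 = field.velocity_at(p1)
    v2 = field.velocity_at(p2)
    n = region.inward_normals
    t1 = v1 - (np.einsum("ij,ij->i", v1, n))[:, None] * n
    t2 = v2 - (np.einsum("ij,ij->i", v2, n))[:, None] * n
    dudn = (4.0 * t1 - t2) / (2.0 * delta * 1e-3)   # 1/s, vector
    wss = mu * np.linalg.norm(dudn, axis=1)
    res = WSSResult(values=wss, max=float(wss.max()),
                    p99=float(np.quantile(wss, 0.99)), region=region.name)
    return res, res.max


# --------------------------------------------------------------------------
# comparison statistics
# --------------------------------------------------------------------------

def percent_reduction(q_untreated, q_treated):
    """100*(1 - Q_treated/Q_untreated), one decimal, half away from zero."""
    if q_untreated <= 0:
        raise MetricsError("untreated flow must be positive")
    if q_treated < 0:
        raise MetricsError("flows must be non-negative")
    return _round_half_away(100.0 * (1.0 - q_treated / q_untreated), 1)


def relative_change(q_baseline, q_device):
    """Signed 100*(Q_device - Q_baseline)/Q_baseline, two decimals."""
    if q_baseline <= 0:
        raise MetricsError("baseline flow must be positive")
    return _round_half_away(100.0 * (q_device - q_baseline) / q_baseline, 2)


@dataclass
class HemodynamicReport:
    """Per-arm summary of the quantities the comparison tables use."""

    label: str
    Q_in: float                      # ml/min, neck influx
    Q_in_DV: float | None = None     # ml/min, monitored daughter inflow
    Q_in_net: float | None = None    # ml/min, signed net neck flux
    WSS_max: dict = dfield(default_factory=dict)   # region -> Pa
    WSS_p99: dict = dfield(default_factory=dict)

    def __post_init__(self):
        if self.Q_in < 0:
            raise MetricsError("Q_in is a directional influx and must be >= 0")


def comparison_report(cases):
    """Tabulate inflow reductions and daughter-flow changes across cases.

    ``cases`` is a list of ``(case_id, arms)`` where ``arms`` maps arm names
    to :class:`HemodynamicReport`; the untreated arm must be named ``"ND"``.
    Returns ``(inflow_table, daughter_table, averages)`` where the tables are
    pandas DataFrames and ``averages`` maps each device arm to the arithmetic
    mean of its per-case (rounded) reduction and relative change.
    """
    import pandas as pd

    if not cases:
        raise MetricsError("at least one case required")
    inflow_rows, dv_rows = [], []
    reductions, changes = {}, {}
    for case_id, arms in cases:
        if "ND" not in arms:
            raise MetricsError(f"case {case_id}: missing untreated arm 'ND'")
        nd = arms["ND"]
        inflow_rows.append(dict(case=case_id, arm="ND",
                                description=nd.label or "No devices",
                                Q_in=nd.Q_in, reduction=None))
        if nd.Q_in_DV is not None:
            dv_rows.append(dict(case=case_id, arm="ND", Q_in_DV=nd.Q_in_DV,
                                relative_change=None))
        for arm, rep in arms.items():
            if arm == "ND":
                continue
            red = percent_reduction(nd.Q_in, rep.Q_in)
            inflow_rows.append(dict(case=case_id, arm=arm,
                                    description=rep.label or arm,
                                    Q_in=rep.Q_in, reduction=red))
            reductions.setdefault(arm, []).append(red)
            if rep.Q_in_DV is not None and nd.Q_in_DV is not None:
                rc = relative_change(nd.Q_in_DV, rep.Q_in_DV)
                dv_rows.append(dict(case=case_id, arm=arm, Q_in_DV=rep.Q_in_DV,
                                    relative_change=rc))
                changes.setdefault(arm, []).append(rc)
    averages = {}
    for arm in set(reductions) | set(changes):
        averages[arm] = dict(
            mean_reduction=(_round_half_away(float(np.mean(reductions[arm])), 2)
                            if arm in reductions else None),
            mean_relative_change=(_round_half_away(float(np.mean(changes[arm])), 2)
                                  if arm in changes else None),
        )
    return pd.DataFrame(inflow_rows), pd.DataFrame(dv_rows), averages
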