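"""Device catalogue, sizing rules, and strut-level wireframe builders.

Two device families are modelled:

* ``braided_stent`` — a conventional intraluminal flow-diverter (Silk Vista
  Baby class): two counter-rotating families of helical nitinol wires on a
  cylinder, deployed in the parent/daughter lumen across the aneurysm neck.
* ``contour`` — an intrasaccular flow disruptor (Contour class): a dual-layer
  braid whose stress-free shape is a bowl, the lower half of a sphere with
  its largest diameter (the nominal size) at the equator, seated inside the
  sac at the neck.

Contour sizing follows the manufacturer's product-selection table on the two
aneurysm measurements d_n (neck width) and d_a (maximum width).  Neck-width
containment is the hard criterion; d_a containment is preferred but advisory
only — clinical practice (and the catalogue's own overlapping bands) allows a
d_a a shade outside the band, so violations warn rather than fail.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from importlib import resources

import numpy as np

__all__ = [
    "DeviceSpec",
    "Wireframe",
    "SizingError",
    "load_catalogue",
    "default_catalogue",
    "select_contour",
    "select_braided_stent",
    "build_braided_stent",
    "build_contour",
    "build_device",
    "compute_porosity",
    "calibrate_strut_radius",
    "deployed_porosity",
    "CylinderSurface",
    "HemisphereSurface",
    "FlatPatch",
]

#: Default wire radii, mm.  Braid wire calibre is not part of the printed
#: catalogue; the braided-stent default is calibrated so that the deployed
#: cylinder porosity matches the catalogue's typical deployed porosity (60%),
#: and the intrasaccular default is a typical 25 um nitinol micro-braid wire.
DEFAULT_CONTOUR_STRUT_RADIUS = 0.0125
#: Braid angle of helical wires measured from the device axis, degrees.
DEFAULT_BRAID_ANGLE = 65.0


class SizingError(ValueError):
    """No catalogue entry fits the supplied aneurysm measurements."""


@dataclass(frozen=True)
class DeviceSpec:
    """One catalogue row (product-selection table entry)."""

    product_code: str
    family: str                      # "contour" | "braided_stent"
    microcatheter_id: float | None   # inner diameter, inches
    nominal_diameter: float          # mm
    length: float | None = None      # mm, braided family only
    dn_range: tuple | None = None    # mm, contour family
    da_range: tuple | None = None    # mm, contour family
    wires_per_layer: int = 72
    layers: int = 1
    nominal_porosity: float | None = None       # fraction
    nominal_pore_density: float | None = None   # per-mm, stored as printed

    def __post_init__(self):
        if self.nominal_diameter <= 0:
            raise ValueError("nominal_diameter must be positive")
        for rng in (self.dn_range, self.da_range):
            if rng is not None and not rng[0] <= rng[1]:
                raise ValueError(f"empty range {rng}")
        if self.nominal_porosity is not None and not 0 < self.nominal_porosity < 1:
            raise ValueError("porosity must lie in (0,1)")


@dataclass
class Wireframe:
    """Strut-level geometric realization of a device.

    ``nodes`` are current positions (mm), ``reference_nodes`` the stress-free
    shape; ``struts`` are node-index pairs and ``wire_id`` assigns each strut
    to its physical wire.  Wires are simple paths (open braids) or loops.
    """

    nodes: np.ndarray             # (N,3) mm
    struts: np.ndarray            # (M,2) int
    wire_id: np.ndarray           # (M,) int
    reference_nodes: np.ndarray   # (N,3) mm
    strut_radius: float           # mm
    family: str = ""
    nominal_diameter: float = 0.0
    length: float | None = None
    braid_angle: float | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.nodes = np.asarray(self.nodes, float)
        self.reference_nodes = np.asarray(self.reference_nodes, float)
        self.struts = np.asarray(self.struts, int)
        self.wire_id = np.asarray(self.wire_id, int)
        if self.nodes.shape != self.reference_nodes.shape:
            raise ValueError("nodes and reference_nodes must match in shape")
        if len(self.struts):
            L = self.strut_lengths()
            if L.min() <= 0:
                raise ValueError("zero-length strut")

    def strut_lengths(self, reference=False):
        x = self.reference_nodes if reference else self.nodes
        return np.linalg.norm(x[self.struts[:, 1]] - x[self.struts[:, 0]], axis=1)

    def wire_paths(self):
        """Node-index sequence per wire; validates path/loop simplicity."""
        paths = {}
        for w in np.unique(self.wire_id):
            seg = self.struts[self.wire_id == w]
            idx, counts = np.unique(seg, return_counts=True)
            ends = idx[counts == 1]
            if len(ends) not in (0, 2) or counts.max() > 2:
                raise ValueError(f"wire {w} is not a simple path or loop")
            paths[int(w)] = seg
        return paths

    def total_wire_length(self, reference=False):
        return float(self.strut_lengths(reference).sum())

    def connectivity_hash(self):
        import hashlib
        h = hashlib.sha256()
        h.update(np.ascontiguousarray(self.struts).tobytes())
        h.update(np.ascontiguousarray(self.wire_id).tobytes())
        return h.hexdigest()


# --------------------------------------------------------------------------
# catalogue and sizing
# --------------------------------------------------------------------------

def load_catalogue(path=None):
    """Load the device catalogue (packaged product-selection table)."""
    if path is None:
        text = resources.files("aneutreat").joinpath("catalogue.json").read_text()
    else:
        text = open(path).read()
    raw = json.loads(text)
    specs = []
    for fam in ("contour", "braided_stent"):
        for row in raw.get(fam, []):
            row = dict(row)
            for key in ("dn_range", "da_range"):
                if row.get(key) is not None:
                    row[key] = tuple(row[key])
            specs.append(DeviceSpec(**row))
    return specs


_CAT = None


def default_catalogue():
    global _CAT
    if _CAT is None:
        _CAT = load_catalogue()
    return _CAT


def select_contour(d_n, d_a, catalogue=None) -> DeviceSpec:
    """Select an intrasaccular device from neck and maximum widths (mm).

    The returned spec is the one whose d_n band contains ``d_n``; ties prefer
    d_a containment, then the smallest nominal diameter.  A d_a outside the
    selected band triggers a warning, not an error.
    """
    if d_n <= 0 or d_a <= 0:
        raise SizingError("d_n and d_a must be positive")
    cat = [s for s in (catalogue or default_catalogue()) if s.family == "contour"]
    if not cat:
        raise SizingError("catalogue contains no intrasaccular devices")
    hits = [s for s in cat if s.dn_range[0] <= d_n <= s.dn_range[1]]
    if not hits:
        nearest = sorted(
            cat, key=lambda s: min(abs(d_n - s.dn_range[0]), abs(d_n - s.dn_range[1]))
        )[:2]
        rows = "; ".join(
            f"{s.product_code} (d_n {s.dn_range[0]}-{s.dn_range[1]} mm)" for s in nearest
        )
        raise SizingError(
            f"no catalogue device accepts neck width {d_n} mm; nearest rows: {rows}"
        )
    hits.sort(
        key=lambda s: (not (s.da_range[0] <= d_a <= s.da_range[1]), s.nominal_diameter)
    )
    best = hits[0]
    if not best.da_range[0] <= d_a <= best.da_range[1]:
        warnings.warn(
            f"maximum width {d_a} mm lies outside the advisory band "
            f"{best.da_range} of {best.product_code}; selection driven by d_n",
            stacklevel=2,
        )
    return best


def select_braided_stent(vessel_diameter, catalogue=None) -> DeviceSpec:
    """Pick the smallest braided stent at least as wide as the vessel."""
    cat = [s for s in (catalogue or default_catalogue()) if s.family == "braided_stent"]
    fits = [s for s in cat if s.nominal_diameter >= vessel_diameter]
    if not fits:
        raise SizingError(
            f"no braided stent covers vessel diameter {vessel_diameter} mm"
        )
    return min(fits, key=lambda s: s.nominal_diameter)


# --------------------------------------------------------------------------
# wireframe builders
# --------------------------------------------------------------------------

def build_braided_stent(diameter, length, wires=48, braid_angle=DEFAULT_BRAID_ANGLE,
                        strut_radius=None, nodes_per_turn=16) -> Wireframe:
    """Two counter-rotating helix families on a cylinder (axis = +x).

    ``braid_angle`` is measured from the device axis in degrees.  The
    stress-free state equals the nominal cylinder.  ``strut_radius=None``
    calibrates the wire calibre to the catalogue's 60% deployed porosity.
    """
    if wires < 4 or wires % 2:
        raise ValueError("wires must be even and >= 4")
    if not 0 < braid_angle < 90:
        raise ValueError("braid_angle must lie in (0, 90) degrees")
    R = diameter / 2.0
    alpha = np.radians(braid_angle)
    pitch = np.pi * diameter / np.tan(alpha)
    if pitch > length:
        raise ValueError(
            f"braid pitch {pitch:.2f} mm exceeds device length {length} mm"
        )
    if strut_radius is None:
        strut_radius = calibrate_strut_radius(diameter, length, wires, braid_angle)

    omega = np.tan(alpha) / R          # dphi/dx
    turns = length * omega / (2 * np.pi)
    n_pts = max(2, int(np.ceil(turns * nodes_per_turn)) + 1)
    x = np.linspace(0.0, length, n_pts)
    per_family = wires // 2

    nodes, struts, wire_ids = [], [], []
    wid = 0
    base = 0
    for handed in (+1, -1):
        for k in range(per_family):
            phi0 = 2 * np.pi * k / per_family + (0.0 if handed > 0 else np.pi / per_family)
            phi = phi0 + handed * omega * x
            pts = np.stack([x, R * np.cos(phi), R * np.sin(phi)], axis=1)
            nodes.append(pts)
            idx = base + np.arange(n_pts)
            struts.append(np.stack([idx[:-1], idx[1:]], axis=1))
            wire_ids.append(np.full(n_pts - 1, wid))
            base += n_pts
            wid += 1
    nodes = np.vstack(nodes)
    return Wireframe(
        nodes=nodes,
        struts=np.vstack(struts),
        wire_id=np.concatenate(wire_ids),
        reference_nodes=nodes.copy(),
        strut_radius=float(strut_radius),
        family="braided_stent",
        nominal_diameter=float(diameter),
        length=float(length),
        braid_angle=float(braid_angle),
        meta=dict(wires=wires, nodes_per_turn=nodes_per_turn),
    )


def build_contour(diameter, wires_per_layer=72, layers=2,
                  strut_radius=DEFAULT_CONTOUR_STRUT_RADIUS,
                  spiral_angle=45.0, nodes_per_wire=24, layer_gap=None,
                  allow_any_diameter=False) -> Wireframe:
    """Dual-layer braided bowl: the lower half of a sphere, rim at the equator.

    Wires are counter-rotating loxodromes (constant ``spiral_angle`` to the
    meridians) running from near the bottom pole to the equatorial rim, whose
    diameter is the nominal size.  The bowl axis is +z with the rim in the
    z=0 plane and the pole at z=-radius; a single inert marker node sits at
    the pole (the radiopaque marker has no mechanical role).
    """
    allowed = {5.0, 7.0, 9.0, 11.0, 14.0}
    if float(diameter) not in allowed and not allow_any_diameter:
        raise ValueError(
            f"diameter {diameter} not in catalogue set {sorted(allowed)}; "
            "pass allow_any_diameter=True to override"
        )
    if layer_gap is None:
        layer_gap = 2.5 * strut_radius
    a_outer = diameter / 2.0
    tan_g = np.tan(np.radians(spiral_angle))
    psi = np.linspace(0.2, np.pi / 2, nodes_per_wire)  # colatitude from -z pole
    # loxodrome: dphi/dpsi = tan(gamma)/sin(psi)
    lox = tan_g * np.log(np.tan(psi / 2) / np.tan(psi[0] / 2))

    nodes, struts, wire_ids = [], [], []
    wid = 0
    base = 0
    for layer in range(layers):
        a = a_outer - layer * layer_gap
        if a <= 0:
            raise ValueError("layer gap exceeds bowl radius")
        per_family = wires_per_layer // 2
        for handed in (+1, -1):
            for k in range(per_family):
                phi0 = 2 * np.pi * k / per_family + layer * np.pi / wires_per_layer
                phi = phi0 + handed * lox
                pts = np.stack(
                    [
                        a * np.sin(psi) * np.cos(phi),
                        a * np.sin(psi) * np.sin(phi),
                        -a * np.cos(psi),
                    ],
                    axis=1,
                )
                nodes.append(pts)
                idx = base + np.arange(nodes_per_wire)
                struts.append(np.stack([idx[:-1], idx[1:]], axis=1))
                wire_ids.append(np.full(nodes_per_wire - 1, wid))
                base += nodes_per_wire
                wid += 1
    nodes.append(np.array([[0.0, 0.0, -a_outer]]))  # inert marker node
    nodes = np.vstack(nodes)
    return Wireframe(
        nodes=nodes,
        struts=np.vstack(struts),
        wire_id=np.concatenate(wire_ids),
        reference_nodes=nodes.copy(),
        strut_radius=float(strut_radius),
        family="contour",
        nominal_diameter=float(diameter),
        length=None,
        braid_angle=float(spiral_angle),
        meta=dict(wires=layers * wires_per_layer, layers=layers,
                  layer_gap=layer_gap, nodes_per_wire=nodes_per_wire),
    )


def build_device(spec: DeviceSpec, strut_radius=None) -> Wireframe:
    """Build the wireframe for a catalogue entry."""
    if spec.family == "braided_stent":
        return build_braided_stent(
            spec.nominal_diameter, spec.length, wires=spec.wires_per_layer,
            strut_radius=strut_radius,
        )
    if spec.family == "contour":
        return build_contour(
            spec.nominal_diameter, wires_per_layer=spec.wires_per_layer,
            layers=spec.layers,
            strut_radius=strut_radius or DEFAULT_CONTOUR_STRUT_RADIUS,
        )
    raise ValueError(f"unknown family {spec.family}")


# --------------------------------------------------------------------------
# porosity
# --------------------------------------------------------------------------

@dataclass
class CylinderSurface:
    """Reference cylinder (axis = +x, from x=0) a braid lies on."""

    radius: float
    length: float

    @property
    def area(self):
        return 2 * np.pi * self.radius * self.length

    def distance(self, pts):
        return np.abs(np.linalg.norm(pts[:, 1:], axis=1) - self.radius)


@dataclass
class HemisphereSurface:
    """Lower half-sphere centred at the origin (rim in z=0 plane)."""

    radius: float

    @property
    def area(self):
        return 2 * np.pi * self.radius**2

    def distance(self, pts):
        return np.abs(np.linalg.norm(pts, axis=1) - self.radius)


@dataclass
class FlatPatch:
    """A planar patch of given area in the z=0 plane (for definition tests)."""

    patch_area: float

    @property
    def area(self):
        return self.patch_area

    def distance(self, pts):
        return np.abs(pts[:, 2])


def _count_crossings_on_surface(frame, on_surface):
    """Crossings between wires, counted by phase unwinding.

    For braids built by this module every wire is monotone in its sweep
    coordinate (axial position or colatitude), so two wires cross wherever
    their azimuth difference passes a multiple of 2*pi at equal sweep
    coordinate.  Returns (count, crossing_angle) with the angle between the
    two wire families at a crossing.
    """
    sel = frame.struts[on_surface]
    wids = frame.wire_id[on_surface]
    # reconstruct per-wire polylines
    from collections import defaultdict
    chains = defaultdict(list)
    for (i, j), w in zip(sel, wids):
        chains[w].append((i, j))
    wires = {}
    for w, segs in chains.items():
        idx = [segs[0][0]] + [j for _, j in segs]
        wires[w] = frame.nodes[idx]

    if frame.family == "braided_stent" or frame.length is not None:
        sweep = {w: p[:, 0] for w, p in wires.items()}              # axial x
        phi = {w: np.unwrap(np.arctan2(p[:, 2], p[:, 1])) for w, p in wires.items()}
    else:
        sweep = {w: np.arccos(np.clip(-p[:, 2] / np.linalg.norm(p, axis=1), -1, 1))
                 for w, p in wires.items()}                         # colatitude
        phi = {w: np.unwrap(np.arctan2(p[:, 1], p[:, 0])) for w, p in wires.items()}

    # classify handedness by azimuth slope
    handed = {w: np.sign(phi[w][-1] - phi[w][0]) for w in wires}
    plus = [w for w in wires if handed[w] > 0]
    minus = [w for w in wires if handed[w] <= 0]
    count = 0
    for wp in plus:
        s = sweep[wp]
        for wm in minus:
            # interpolate the minus wire's azimuth onto the plus wire's sweep
            sm = sweep[wm]
            order = np.argsort(sm)
            lo, hi = max(s.min(), sm.min()), min(s.max(), sm.max())
            mask = (s >= lo) & (s <= hi)
            if mask.sum() < 2:
                continue
            pm = np.interp(s[mask], sm[order], phi[wm][order])
            d = (phi[wp][mask] - pm) / (2 * np.pi)
            count += int(np.floor(d.max()) - np.ceil(d.min()) + 1) if d.max() >= d.min() else 0
    return count


def compute_porosity(frame: Wireframe, reference_surface, tol=None):
    """Open-area fraction of the braid projected on its reference surface.

    porosity = 1 - metal_area / surface_area with
    metal_area = sum(strut length * 2 * strut_radius) minus the double-counted
    overlap at wire crossings (w^2 / sin(crossing angle) per crossing).
    Only struts lying on the reference surface participate; for a dual-layer
    device this computes the porosity of the layer on the given surface.
    """
    if tol is None:
        tol = max(4 * frame.strut_radius, 1e-6)
    mid = 0.5 * (frame.nodes[frame.struts[:, 0]] + frame.nodes[frame.struts[:, 1]])
    on = reference_surface.distance(mid) <= tol
    if not on.any():
        raise ValueError("no struts lie on the reference surface")
    w = 2.0 * frame.strut_radius
    lengths = frame.strut_lengths()[on]
    metal = lengths.sum() * w
    if frame.braid_angle is not None and len(np.unique(frame.wire_id[on])) > 1:
        n_cross = _count_crossings_on_surface(frame, on)
        if frame.family == "braided_stent":
            crossing_angle = np.radians(2 * frame.braid_angle)
        else:
            crossing_angle = np.radians(2 * frame.braid_angle)
        s = abs(np.sin(crossing_angle))
        if s > 1e-6:
            metal -= n_cross * w * w / s
    porosity = 1.0 - metal / reference_surface.area
    return float(porosity)


def calibrate_strut_radius(diameter, length, wires=48,
                           braid_angle=DEFAULT_BRAID_ANGLE, target=0.60):
    """Wire radius giving the target deployed-cylinder porosity (bisection)."""
    surf = CylinderSurface(diameter / 2.0, length)

    def porosity_of(r):
        f = build_braided_stent(diameter, length, wires=wires,
                                braid_angle=braid_angle, strut_radius=r)
        return compute_porosity(f, surf)

    lo, hi = 1e-4, 0.2
    for _ in range(60):
        mid = 0.5 * (lo + hi)
        if porosity_of(mid) > target:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def deployed_porosity(frame: Wireframe, reference_porosity: float) -> float:
    """Porosity of a braid after deployment-induced compaction.

    A braid forced into a cavity smaller than its stress-free shape packs
    its wires closer together: the metal (solid) fraction scales with the
    inverse of the covered-area change, estimated from the mean-square node
    spread about the centroid in the deployed versus reference states.
    Returns the compacted porosity, floored at 0.05.
    """
    ref = frame.reference_nodes - frame.reference_nodes.mean(axis=0)
    cur = frame.nodes - frame.nodes.mean(axis=0)
    area_scale = float((cur**2).sum() / max((ref**2).sum(), 1e-30))
    solidity = (1.0 - reference_porosity) / max(area_scale, 1e-6)
    return float(max(0.05, 1.0 - solidity))
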