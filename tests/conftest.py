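"""Shared fixtures: benchmark flows, toy screened pocket, case bundle.

Expensive CFD solves and deployments are session-scoped and shared between
the unit and acceptance layers so the whole suite stays desk-scale.
"""

import numpy as np
import pytest

from aneutreat.geometry import (CASE_I_PARAMS, CASE_II_PARAMS, AnalyticLumen,
                                Cap, generate_bifurcation_aneurysm,
                                measure_aneurysm, straight_tube_geometry,
                                symmetric_y_geometry)
from aneutreat.devices import Wireframe
from aneutreat.hemodynamics import (FluidModel, SolverConfig,
                                    apply_device_screen, mesh_domain,
                                    solve_steady)

TUBE_RADIUS = 1.5     # mm
TUBE_LENGTH = 8.0     # mm
TUBE_FLOW = 6.0       # ml/min (Re ~ 11: fully developed well within the tube)
TUBE_DENSITY = 300.0  # cells/mm^3


@pytest.fixture(scope="session")
def tube_field():
    """Converged Poiseuille benchmark flow."""
    geom = straight_tube_geometry(TUBE_RADIUS, TUBE_LENGTH)
    mesh = mesh_domain(geom, density=TUBE_DENSITY)
    field = solve_steady(mesh, FluidModel(),
                         SolverConfig(inlet_flow=TUBE_FLOW, max_iterations=500))
    assert field.converged
    return field


@pytest.fixture(scope="session")
def symmetric_split_field():
    """Converged flow in a mirror-symmetric Y bifurcation."""
    geom = symmetric_y_geometry()
    mesh = mesh_domain(geom, density=200.0)
    field = solve_steady(mesh, FluidModel(),
                         SolverConfig(inlet_flow=20.0, max_iterations=600))
    assert field.converged
    return field


# --------------------------------------------------------------------------
# screened side-pocket toy: a tube with a spherical pocket whose opening is
# spanned by a woven disc of struts
# --------------------------------------------------------------------------

POCKET_CENTER = np.array([4.0, 0.0, 2.4])
POCKET_RADIUS = 2.0


def _pocket_geometry():
    def sdf(p):
        tube = np.linalg.norm(p[:, 1:], axis=1) - TUBE_RADIUS
        pocket = np.linalg.norm(p - POCKET_CENTER, axis=1) - POCKET_RADIUS
        return np.minimum(tube, pocket)

    caps = {
        "inlet": Cap("inlet", np.array([0.0, 0, 0]), np.array([-1.0, 0, 0]),
                     TUBE_RADIUS),
        "outlet_0": Cap("outlet_0", np.array([TUBE_LENGTH, 0, 0]),
                        np.array([1.0, 0, 0]), TUBE_RADIUS),
    }
    bounds = np.array([
        [0.0, -TUBE_RADIUS, -TUBE_RADIUS],
        [TUBE_LENGTH, TUBE_RADIUS, POCKET_CENTER[2] + POCKET_RADIUS],
    ])
    return AnalyticLumen(open_sdf=sdf, caps=caps, bounds=bounds)


def _woven_disc_frame(z=1.45, spacing=0.15, radius=1.85, strut_radius=0.05):
    """Two families of parallel wires spanning the pocket opening."""
    nodes, struts, wire_id = [], [], []
    wid = 0
    offs = np.arange(-radius, radius + 1e-9, spacing)
    for family in range(2):
        for o in offs:
            half = np.sqrt(max(radius**2 - o**2, 1e-6))
            ts = np.linspace(-half, half, max(3, int(2 * half / spacing) + 1))
            if family == 0:
                pts = np.stack([POCKET_CENTER[0] + ts,
                                np.full_like(ts, o),
                                np.full_like(ts, z)], axis=1)
            else:
                pts = np.stack([np.full_like(ts, POCKET_CENTER[0] + o),
                                ts, np.full_like(ts, z)], axis=1)
            base = sum(len(n) for n in nodes)
            nodes.append(pts)
            idx = base + np.arange(len(pts))
            struts.append(np.stack([idx[:-1], idx[1:]], axis=1))
            wire_id.append(np.full(len(pts) - 1, wid))
            wid += 1
    nodes = np.vstack(nodes)
    return Wireframe(nodes=nodes, struts=np.vstack(struts),
                     wire_id=np.concatenate(wire_id),
                     reference_nodes=nodes.copy(), strut_radius=strut_radius,
                     family="screen_disc", nominal_diameter=2 * radius)


@pytest.fixture(scope="session")
def pocket_sweep():
    """Pocket influx for the untreated flow and a porosity sweep.

    Returns dict with keys: 'geom', 'frame', 'plane', 'Q_inlet',
    'influx' mapping porosity (None = no device, 0.0 = sealed) -> ml/min,
    and 'identity_gap', the largest velocity difference between the
    porosity-1 field and the untreated field.
    """
    from aneutreat.metrics import SamplingPlane, integrate_influx

    geom = _pocket_geometry()
    frame = _woven_disc_frame()
    plane = SamplingPlane(origin=[4.0, 0.0, 1.8], normal=[0, 0, 1.0],
                          role="neck", bound_radius=1.9)
    q_in = 20.0
    cfg = SolverConfig(inlet_flow=q_in, max_iterations=500)
    results = {}
    fields = {}
    for por in (None, 1.0, 0.8, 0.5, 0.2, 0.0):
        mesh = mesh_domain(geom, frame=None if por is None else frame,
                           density=150.0)
        if por is not None:
            apply_device_screen(mesh, frame, por)
        f = solve_steady(mesh, FluidModel(), cfg)
        assert f.converged
        results[por] = integrate_influx(f, plane)
        fields[por] = f
    gap = max(
        float(np.abs(fields[1.0].faces[a] - fields[None].faces[a]).max())
        for a in range(3)
    )
    return dict(geom=geom, frame=frame, plane=plane, Q_inlet=q_in,
                influx=results, identity_gap=gap)


# --------------------------------------------------------------------------
# study-scale case bundle (used by the directional acceptance check)
# --------------------------------------------------------------------------

@pytest.fixture(scope="session")
def case_i_bundle():
    """Untreated/stent/contour arms of the large wide-neck case."""
    from aneutreat.metrics import SamplingPlane, integrate_influx
    from aneutreat.pipeline import _deploy_contour, _deploy_stent, case_i_config

    cfg = case_i_config(solver=dict(max_iterations=1600))
    geom = generate_bifurcation_aneurysm(**cfg.geometry)
    measures = measure_aneurysm(geom)
    neck = SamplingPlane.from_measures(measures)
    dv = SamplingPlane.daughter_plane(geom, daughter=cfg.monitored_daughter)

    out = dict(geom=geom, measures=measures, devices={}, Q_in={}, Q_dv={},
               states={})
    for arm in ("ND", "Stent", "Contour"):
        frame = None
        if arm == "Stent":
            spec, frame, state, por, layers = _deploy_stent(geom, measures, cfg)
            out["devices"][arm] = spec.product_code
            out["states"][arm] = state
        elif arm == "Contour":
            spec, frame, state, por, layers = _deploy_contour(geom, measures, cfg)
            out["devices"][arm] = spec.product_code
            out["states"][arm] = state
        mesh = mesh_domain(geom, frame=frame, density=cfg.density)
        if frame is not None:
            apply_device_screen(mesh, frame, None)
        field = solve_steady(
            mesh, FluidModel(),
            SolverConfig(inlet_flow=cfg.inlet_flow, max_iterations=1600))
        assert field.converged, f"{arm} arm did not converge"
        out["Q_in"][arm] = integrate_influx(field, neck)
        out["Q_dv"][arm] = integrate_influx(field, dv)
    return out


@pytest.fixture(scope="session")
def small_case_geometry():
    """Coarse narrow-neck case geometry for pipeline-level tests."""
    return generate_bifurcation_aneurysm(
        **dict(CASE_II_PARAMS, edge_length=0.45))
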