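"""End-to-end case orchestration: generate -> size -> deploy -> solve -> report.

A *case* is one aneurysm geometry evaluated under up to three arms on the
same mesh settings: untreated (ND), a braided flow-diverter (Stent), and an
intrasaccular flow disruptor (Contour).  The braided stent is auto-sized to
the stented daughter vessel; the intrasaccular device is auto-sized from the
measured neck and maximum widths via the product-selection table.  Deployed
devices couple to the flow as per-cell porous screens whose local porosity
follows the wire density the deployment actually leaves in each grid cell.

Everything is deterministic for a fixed configuration; the ``seed`` only
feeds optional stochastic extras (surface perturbation) and is recorded in
the provenance block.
"""

from __future__ import annotations

import hashlib
import json
import time
import warnings
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from . import __version__
from .deployment import (RelaxParams, auto_path, crimp, crimped_length,
                         deployed_frame, fit_crimp_radius, release)
from .devices import build_device, select_braided_stent, select_contour
from .geometry import (CASE_I_PARAMS, CASE_II_PARAMS, GeometryError,
                       generate_bifurcation_aneurysm, measure_aneurysm,
                       read_geometry, straight_tube_geometry, write_geometry)
from .hemodynamics import (FluidModel, SolverConfig, apply_device_screen,
                           mesh_domain, solve_steady, write_field_vtk)
from .metrics import (HemodynamicReport, SamplingPlane, comparison_report,
                      integrate_influx, surface_wall_region,
                      wall_shear_stress)

__all__ = [
    "CaseConfig",
    "CaseResult",
    "run_case",
    "make_fixtures",
    "case_i_config",
    "case_ii_config",
    "PipelineError",
]


class PipelineError(RuntimeError):
    def __init__(self, stage, original):
        super().__init__(f"stage '{stage}' failed: {original}")
        self.stage = stage
        self.original = original


@dataclass
class CaseConfig:
    """Single configuration driving all arms of one case."""

    geometry: dict | str            # generator kwargs or path to a surface
    arms: tuple = ("ND", "Stent", "Contour")
    inlet_flow: float = 126.4       # ml/min through the parent vessel
    density: float = 60.0           # elements (fluid cells) per mm^3
    device_coupling: str = "screen"
    stented_daughter: int = 0       # branch the braided stent lands in
    monitored_daughter: int = 1     # non-stented daughter of the tables
    contour_crimp_radius: float = 0.3   # mm
    solver: dict = field(default_factory=dict)    # SolverConfig overrides
    relax: dict = field(default_factory=dict)     # RelaxParams overrides
    output_dir: str | None = None
    seed: int = 0

    def __post_init__(self):
        if isinstance(self.geometry, str) and not Path(self.geometry).exists():
            raise PipelineError("config", FileNotFoundError(self.geometry))
        for arm in self.arms:
            if arm not in ("ND", "Stent", "Contour"):
                raise PipelineError("config", ValueError(f"unknown arm {arm}"))

    def digest(self):
        blob = json.dumps(
            {k: (v if not isinstance(v, tuple) else list(v))
             for k, v in asdict(self).items()},
            sort_keys=True, default=str,
        )
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


@dataclass
class CaseResult:
    reports: dict                    # arm -> HemodynamicReport
    inflow_table: object             # pandas DataFrame
    daughter_table: object
    averages: dict
    measures: object                 # AneurysmMeasures
    devices: dict                    # arm -> product code
    convergence: dict                # arm -> dict(iterations, converged, ...)
    provenance: dict
    files: dict = field(default_factory=dict)


def case_i_config(**overrides) -> CaseConfig:
    """Configuration emulating the study's large wide-neck case."""
    geometry = dict(CASE_I_PARAMS, edge_length=0.35)
    cfg = dict(geometry=geometry, inlet_flow=126.4, density=60.0)
    cfg.update(overrides)
    return CaseConfig(**cfg)


def case_ii_config(**overrides) -> CaseConfig:
    """Configuration emulating the study's small narrow-neck case.

    The untreated parent flow is the printed sac inflow divided by the
    printed fraction of parent flow it represents (51.8 / 0.6963)."""
    geometry = dict(CASE_II_PARAMS, edge_length=0.3)
    cfg = dict(geometry=geometry, inlet_flow=51.8 / 0.6963, density=80.0)
    cfg.update(overrides)
    return CaseConfig(**cfg)


def _deploy_stent(geom, measures, config):
    spec = select_braided_stent(
        geom.daughter_diameters[config.stented_daughter])
    frame = build_device(spec)
    path = auto_path(geom, "braided_stent",
                     stented_daughter=config.stented_daughter)
    radius = fit_crimp_radius(frame, path, margin=1.0)
    offset = path.arc_length - crimped_length(frame, radius) - 0.5
    state = crimp(frame, radius, path, offset=max(offset, 0.0))
    params = RelaxParams(shape_beta=0.1, **config.relax)
    final = release(state, frame, geom, relax_params=params)
    dep = deployed_frame(final, frame)
    # per-cell screen: local porosity from the deployed wire density
    return spec, dep, final, None, 1


def _deploy_contour(geom, measures, config):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # advisory d_a band
        spec = select_contour(measures.d_n, measures.d_a)
    frame = build_device(spec)
    path = auto_path(geom, "contour", measures=measures)
    radius = max(config.contour_crimp_radius,
                 fit_crimp_radius(frame, path, margin=0.5))
    # position so the distal tip opens at the dome centre: the device then
    # relaxes back onto the neck rather than into the dome tip
    seg = np.linalg.norm(np.diff(path.points, axis=0), axis=1)
    arc_to_center = float(seg[:-1].sum())
    offset = min(arc_to_center - crimped_length(frame, radius),
                 path.arc_length - crimped_length(frame, radius) - 0.3)
    state = crimp(frame, radius, path, offset=max(offset, 0.0))
    # the oversized intrasaccular braid densifies to fit the sac: wires
    # scissor shut with little resistance
    params = RelaxParams(compression_factor=0.15, **config.relax)
    final = release(state, frame, geom, relax_params=params)
    dep = deployed_frame(final, frame)
    return spec, dep, final, None, spec.layers


def run_case(config: CaseConfig) -> CaseResult:
    """Run all configured arms of one case and tabulate the comparison."""
    t_start = time.time()
    # -- geometry ----------------------------------------------------------
    try:
        if isinstance(config.geometry, str):
            geom = read_geometry(config.geometry)
        else:
            geom = generate_bifurcation_aneurysm(**config.geometry,
                                                 seed=config.seed)
        measures = measure_aneurysm(geom,
                                    stented_daughter=config.stented_daughter)
    except (GeometryError, OSError) as e:
        raise PipelineError("geometry", e) from e

    neck_plane = SamplingPlane.from_measures(measures)
    dv_plane = SamplingPlane.daughter_plane(
        geom, daughter=config.monitored_daughter)
    fluid = FluidModel()
    out = Path(config.output_dir) if config.output_dir else None
    if out:
        out.mkdir(parents=True, exist_ok=True)

    reports, devices, convergence, files = {}, {}, {}, {}
    deployed = {}
    for arm in config.arms:
        # -- deployment ----------------------------------------------------
        frame, porosity, layers = None, None, 1
        try:
            if arm == "Stent":
                spec, frame, state, porosity, layers = _deploy_stent(
                    geom, measures, config)
                devices[arm] = spec.product_code
            elif arm == "Contour":
                spec, frame, state, porosity, layers = _deploy_contour(
                    geom, measures, config)
                devices[arm] = spec.product_code
        except Exception as e:
            raise PipelineError(f"deploy:{arm}", e) from e
        if frame is not None:
            deployed[arm] = frame

        # -- flow ----------------------------------------------------------
        try:
            mesh = mesh_domain(geom, frame=frame, density=config.density,
                               resolved=config.device_coupling == "resolved")
            if frame is not None and config.device_coupling == "screen":
                apply_device_screen(mesh, frame, porosity, layers=layers,
                                    viscosity=fluid.dynamic_viscosity)
            scfg = SolverConfig(inlet_flow=config.inlet_flow,
                                device_coupling=config.device_coupling,
                                **config.solver)
            fieldv = solve_steady(mesh, fluid, scfg)
        except Exception as e:
            raise PipelineError(f"solve:{arm}", e) from e

        # -- metrics -------------------------------------------------------
        try:
            q_in = integrate_influx(fieldv, neck_plane)
            q_net = integrate_influx(fieldv, neck_plane, direction="net")
            q_dv = integrate_influx(fieldv, dv_plane)
            wss_max, wss_p99 = {}, {}
            if geom.surface is not None:
                for region in ("sac", "neck"):
                    reg = surface_wall_region(geom, region, measures=measures)
                    res, _ = wall_shear_stress(fieldv, reg)
                    wss_max[region] = res.max
                    wss_p99[region] = res.p99
            reports[arm] = HemodynamicReport(
                label={"ND": "No devices", "Stent": devices.get(arm, "stent"),
                       "Contour": devices.get(arm, "contour")}[arm],
                Q_in=q_in, Q_in_DV=q_dv, Q_in_net=q_net,
                WSS_max=wss_max, WSS_p99=wss_p99,
            )
        except Exception as e:
            raise PipelineError(f"metrics:{arm}", e) from e
        convergence[arm] = dict(
            iterations=len(fieldv.residual_history),
            converged=bool(fieldv.converged),
            final_residual=float(fieldv.residual_history[-1]),
            mass_balance_error=float(fieldv.mass_balance_error()),
            n_fluid_cells=mesh.n_fluid,
        )
        if out:
            fpath = out / f"field_{arm.lower()}.vtk"
            write_field_vtk(fieldv, fpath)
            files[f"field_{arm}"] = str(fpath)
            if frame is not None:
                wpath = out / f"device_{arm.lower()}.vtk"
                _write_wireframe_vtk(frame, wpath)
                files[f"device_{arm}"] = str(wpath)

    case_rows = [("case", reports)]
    inflow, daughter, averages = comparison_report(case_rows)

    result = CaseResult(
        reports=reports,
        inflow_table=inflow,
        daughter_table=daughter,
        averages=averages,
        measures=measures,
        devices=devices,
        convergence=convergence,
        provenance=dict(
            config_digest=config.digest(),
            version=__version__,
            seed=config.seed,
            runtime_s=round(time.time() - t_start, 1),
            timestamp=time.strftime("%Y-%m-%dT%H:%M:%S"),
        ),
        files=files,
    )
    if out:
        gpath = out / "geometry.stl"
        write_geometry(geom, gpath)
        files["geometry"] = str(gpath)
        inflow.to_csv(out / "inflow_table.csv", index=False)
        daughter.to_csv(out / "daughter_table.csv", index=False)
        (out / "report.json").write_text(json.dumps(dict(
            devices=devices,
            measures=dict(d_n=measures.d_n, d_a=measures.d_a, sdr=measures.sdr),
            arms={k: dict(Q_in=r.Q_in, Q_in_DV=r.Q_in_DV, Q_in_net=r.Q_in_net,
                          WSS_max=r.WSS_max) for k, r in reports.items()},
            averages=averages,
            convergence=convergence,
            provenance=result.provenance,
        ), indent=1))
        files["report"] = str(out / "report.json")
    return result


def _write_wireframe_vtk(frame, path):
    from .geometry import _write_vtk_polydata

    lines = [list(s) for s in frame.struts]
    _write_vtk_polydata(path, frame.nodes, faces=None, lines=lines,
                        comment="aneutreat device wireframe")
    return path


def make_fixtures(seed=0):
    """Small deterministic test objects: geometries, frames, one tube flow.

    Regeneration with the same seed is bit-identical; the bundle is sized so
    a full verification suite stays desk-scale.
    """
    from .devices import build_braided_stent, build_contour

    rng_seed = int(seed)
    tube = straight_tube_geometry(radius=1.5, length=8.0)
    mesh = mesh_domain(tube, density=150.0)
    fieldv = solve_steady(mesh, FluidModel(),
                          SolverConfig(inlet_flow=6.0, max_iterations=400))
    svb = build_braided_stent(2.25, 15.0, wires=16, nodes_per_turn=10,
                              strut_radius=0.02)
    bowl = build_contour(7.0, wires_per_layer=16, layers=1, nodes_per_wire=12)
    geom = generate_bifurcation_aneurysm(
        **dict(CASE_II_PARAMS, edge_length=0.45), seed=rng_seed)
    return dict(
        seed=rng_seed,
        tube_geometry=tube,
        tube_field=fieldv,
        svb_frame=svb,
        bowl_frame=bowl,
        aneurysm_geometry=geom,
    )
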