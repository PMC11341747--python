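# Methods

This note records the models behind each stage, the parameters that matter,
the numerical choices, and what the synthetic test conditions do and do not
establish about patient anatomy.

## Synthetic vasculature

A wide-neck MCA bifurcation aneurysm is idealized as:

* a parent tube (diameter `parent_diameter`) along +x ending at the
  bifurcation origin;
* two daughter tubes at `branch_angles` (degrees off the parent axis, in
  the vessel plane z = 0);
* a **junction bulb** — a sphere of radius `bulb_radius`
  (default 0.55·d_n) blended into the tubes with a polynomial smooth-union
  of radius `blend_radius` (0.8 mm).  Wide-neck bifurcation aneurysms
  incorporate a fattened confluence; geometrically the bulb is what lets a
  neck several times wider than the vessels exist at all;
* an **ellipsoidal dome** with equatorial diameter `dome_width` (= d_a)
  and height ratio `dome_height_ratio`, seated on the bulb along an axis
  tilted `dome_tilt` = 45° from vertical toward the parent-flow direction.

The dome centre is calibrated along its axis by a bracketed 1-D root solve
so that the **measured** neck width equals the requested d_n.  Measurement
is operational: the neck contour is the intersection curve of the dome
surface with the vessel envelope (found as the zero level of the envelope
signed-distance field on a 192×384 parametric grid of the dome surface),
d_n is its maximum chord, the neck plane is the least-squares plane through
the contour (normal oriented toward the dome centre), and d_a is the dome's
maximum chord parallel to that plane (closed form via the singular values
of the ellipsoid map restricted to the plane).  How the two widths are
measured on a patient image is not standardized (2-D projection versus 3-D
chord); the 3-D max-chord convention is one deliberate reading.

Surfaces are extracted by marching cubes at `edge_length` (default 0.2 mm)
from the analytic signed-distance field; the grid is offset by an
irrational fraction of the spacing so cap planes never coincide with grid
nodes, cap vertices are snapped exactly onto their planes, and the result
is watertight.  The analytic SDF is retained on the geometry object and is
what the deployment contact and the flow solver query; meshes loaded
without a sidecar fall back to a KD-tree pseudo-normal signed distance.

**Case presets.** Only d_n/d_a, the flows, and the chosen devices are
published for the two study-like cases.  Vessel calibres were fixed so the
printed flows give the stated velocity scales and the printed device picks
fall out of the sizing rules: Case I parent 2.4 mm (126.4 ml/min →
0.47 m/s mean; SVB-2.25 lands snugly), daughters 2.0/2.1 mm (SDR 0.88);
Case II parent 2.8 mm (74.4 ml/min → 0.20 m/s), daughters 2.6/1.8 mm
(SDR 0.64, SVB-3 selected).  Case II's parent flow is the printed sac
inflow divided by the printed fraction of parent flow it represents
(51.8/0.6963).  These are package choices of typical MCA anatomy, not
measured values.

## Devices

The catalogue ships verbatim as a JSON resource: five intrasaccular rows
(codes, microcatheter sizes, nominal diameters 5–14 mm, d_n and d_a bands)
and two braided-stent rows (2.25×15, 3×15; typical deployed porosity 60 %,
pore density 45 per mm stored as printed but not interpreted — its unit is
ambiguous).  Sizing: d_n-band containment is the hard criterion; the d_a
band is advisory (warning) because strict containment would contradict the
published selection for the small case (d_a = 5.56 vs a 5.5 band edge).
Braided stents take the smallest nominal diameter at least as large as the
stented daughter vessel.

Wireframes: the stent is two counter-rotating helix families (48 wires,
braid angle 65° from the axis) on the nominal cylinder; wire radius is
calibrated by bisection so the deployed-cylinder porosity is 60 %
(porosity = 1 − metal/area with a crossing-overlap correction; crossings
are counted by azimuth unwinding, validated against brute-force segment
intersection).  The intrasaccular device is a dual-layer bowl — the lower
half of a sphere with the nominal diameter at the equator — built from
counter-rotating loxodromes (72 wires per layer, 45° spiral angle, layer
gap 2.5 wire radii, 25 µm wire diameter) plus one inert marker node at the
pole; the radiopaque marker has no mechanical role.

## Virtual deployment

Crimping conserves wire length: radial scaling to the sheath radius fixes
an axial stretch by a 1-D root solve (braid kinematics), so the device
elongates; the crimped device is threaded along a delivery path using
parallel-transported frames.  Paths must be at least as long as the
crimped device; `fit_crimp_radius` returns the tightest sheath a given
track can host, which is how short synthetic vessels bound the crimp.

Release proceeds distal→proximal in 48 equal increments (configurable; the
increment count is an implementation choice, not a result).  Released nodes
follow damped gradient descent with backtracking (energy never increases
within a phase) on: linear stretch springs along struts, second-neighbour
springs along each wire as a bending surrogate, and a weak shape-memory
term pulling toward the best-fit rigid placement of the stress-free shape
(Kabsch), which is what encodes nitinol shape recovery and guarantees the
free-expansion limit.  Springs may be softer in compression
(`compression_factor`; 0.15 for the intrasaccular braid) because braids
scissor shut far more easily than they stretch.  Contact is a frictionless
projection of penetrating nodes back to the rigid wall along the SDF
gradient.  Convergence: largest node move < 1e-3 mm and penetration
≤ 0.01 mm — both artifact tolerances, chosen, not published.  Stiffnesses
are dimensionless model parameters (k_stretch 1, k_bend 0.3, shape β 0.25;
0.1 for stents so they can follow curved tracks).

## Hemodynamics

Finite volumes on a uniform staggered Cartesian (MAC) grid; "density" is
fluid cells per mm³ and maps to the cell edge h = density^(−1/3).  Blood:
Newtonian, ρ = 1000 kg/m³, μ = 0.004 Pa·s; rigid no-slip walls.  Inlet: a
parabolic (radially symmetric) profile rescaled so the discrete inlet flux
equals the configured flow exactly.  Outlets: equal fixed gauge pressure
(0 Pa) imposed through ghost cells beyond each outlet cap plane.  Isolated
fluid pockets (stair-step crevices with no path to an outlet) are removed
at meshing time — they would make the pressure problem singular.  Grids
are centred on any mirror plane of the domain so symmetric bifurcations
split exactly.

Momentum: first-order upwind convection, central diffusion; viscous links
toward wall-side neighbours use the sub-grid wall distance from the SDF
(the no-slip wall sits at its true position between grid nodes, clipped to
[0.15h, h]), which is what brings the Poiseuille oracles to percent-level
accuracy at ~20 cells per diameter.  Outer loop: SIMPLE-type, momentum
under-relaxation 0.7, pressure 0.5, inner momentum solves by
diagonal-preconditioned BiCGStab in correction form; the pressure
correction uses the consistent per-face coefficients (ρ A²/a_P) solved by
Jacobi-preconditioned CG, warm-started.  Convergence follows the published
bookkeeping: residual below 1e-8 absolute or reduced 1e-5 relative to the
first iteration; benchmark and case domains converge in 150–900 outer
iterations.

Deployed braids couple as porous screens by default: each swept grid cell
receives a Darcy sink μ/K·(t/h), with the local porosity computed from the
wire length the deployment actually leaves in the cell (projected coverage
2 r_w L/h²), K from a Kozeny–Carman fibre-bed law
(K = φ³ d_w²/(180(1−φ)²)) and screen thickness t = two wire diameters.
Porosity 1 recovers the untreated field identically; porosity 0 turns the
swept cells solid (sealed).  A resolved mode instead marks swept cells as
no-slip — physically meaningful only when h resolves the wire calibre, so
it is the high-cost option, not the default.

## Metrics

Q_in integrates the positive part of u·n over the neck plane clipped to
the lumen and the neck contour (the signed net flux is also computed —
"total flow entering" admits both readings).  The daughter plane sits
perpendicular to the daughter axis one local diameter downstream of the
carina, pushed past the junction bulb when one exists.  WSS uses a
two-point one-sided difference along the inward wall normal at δ and 2δ
(δ = one grid spacing), exact for a locally parabolic profile; WSS_max is
the literal maximum over the named wall region with a 99th-percentile
variant reported alongside (never substituted).  Reductions are rounded to
1 decimal, relative changes to 2, half away from zero.  One published
inflow-reduction cell (91.4 %) is inconsistent with its own printed flows
(51.8 → 4.5 ml/min gives 91.3 %); the package reproduces 91.3 from the
inputs and the cross-case mean therefore lands at 91.2 instead of the
published 91.25.

## Problem sizes and what the tests show

The verification suite runs at desk scale: the Poiseuille tube at
300 cells/mm³ (~17k cells, Re ≈ 11 so the flow is fully developed within
the tube), the symmetric Y at 200, the screened-pocket toy at 150, the
large-case comparison at 60, and the refinement sweep at 25/50/100 —
against the reference profile of >4000 cells/mm³ used at cluster scale for
mesh independence.  Wireframes in deployment tests use reduced node counts
(24 wires); the builders' full-resolution devices are exercised in the
porosity and case tests.

Passing these tests shows that the pipeline's operators satisfy their
closed-form oracles and directional properties on idealized anatomy.  It
does not show patient-level fidelity: the synthetic lumen is smooth and
parametric, the walls are rigid, the flow is steady, and the braid is
homogenized.  One known limitation is load-bearing for the device
comparison: with the published wide neck (8.58 mm) carried by a junction
bulb over ~2 mm daughters, the two daughter ostia are several millimetres
apart, so a braided stent running parent→daughter cannot lie across the
other daughter's ostium.  The "jailing" flow transfer seen clinically — a
braided stent starving the non-stented daughter while an intrasaccular
device feeds it — therefore does not emerge here: both devices change the
non-stented daughter flow by only ~±2 %.  The corresponding directional
test asserts the clinical sign pattern and is expected to fail; the
inflow-isolation comparison (both devices cut neck influx by well over
half, the stent most strongly) is robust.

## Out of scope

Patient-image segmentation, vessel-wall mechanics and contact FEA,
pulsatile/transient flow, Windkessel outlets, non-Newtonian rheology,
thrombosis and endothelialisation biology, and time-averaged metrics (OSI,
RRT).
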