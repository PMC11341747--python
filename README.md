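# aneutreat

In-silico comparison of endovascular devices for middle-cerebral-artery
(MCA) bifurcation aneurysms: intrasaccular flow disruptors (Contour class)
versus conventional braided flow-diverters (Silk Vista Baby class).

Treating a bifurcation aneurysm with an intraluminal flow-diverter means
jailing one daughter branch under the braid; an intrasaccular device sits
inside the sac at the neck and leaves the branches open.  This package
provides the whole desk-scale pipeline needed to compare the two
strategies on synthetic anatomy:

* **`geometry`** — parametric wide-neck bifurcation-aneurysm lumens
  (parent + two daughters blended with a junction bulb, ellipsoidal dome),
  calibrated to requested neck width `d_n` and maximum width `d_a`;
  neck-contour measurement; STL / legacy-VTK IO with a JSON sidecar.
* **`devices`** — the Contour product-selection table (sizing on `d_n`,
  `d_a`), braided-stent sizing, strut-level wireframe builders for both
  families, and braid porosity (with the stent wire calibre calibrated to
  the typical 60 % deployed porosity).
* **`deployment`** — fast virtual deployment: crimp (wire-length-conserving
  braid kinematics), threading along a delivery path, progressive
  distal-to-proximal release, damped relaxation with frictionless rigid-wall
  contact.
* **`hemodynamics`** — steady incompressible Newtonian flow
  (ρ = 1000 kg/m³, μ = 0.004 Pa·s) on a staggered Cartesian voxel grid:
  parabolic inlet scaled to a target flow, equal fixed-pressure outlets,
  no-slip walls with sub-grid wall positioning, SIMPLE-type pressure
  correction, and deployed braids coupled as per-cell porous screens (or
  resolved no-slip strut cells).
* **`metrics`** — neck-plane influx `Q_in`, daughter-vessel inflow
  `Q_in-DV`, wall shear stress (WSS, with region maxima), percentage
  reductions and relative changes, cross-case comparison tables.
* **`pipeline` / CLI** — one configuration drives the untreated / stent /
  Contour arms of a case on identical mesh settings.

The central quantities follow the standard definitions:
`Q_in = ∫ max(0, u·n) dA` over the neck plane (normal into the sac),
`WSS = μ |∂u_t/∂n|` on the wall, percentage reduction
`100·(1 − Q_treated/Q_untreated)`, and relative change
`100·(Q_device − Q_baseline)/Q_baseline`.

## Worked example

```python
from aneutreat.devices import select_contour
from aneutreat.pipeline import case_i_config, run_case

spec = select_contour(8.58, 9.37)
print(spec.product_code, spec.nominal_diameter)   # CNS014-15 14.0

result = run_case(case_i_config(arms=("ND", "Stent", "Contour")))
print(result.inflow_table.to_string(index=False))
```

prints (large wide-neck case, 126.4 ml/min parent flow, 60 cells/mm³):

```
case     arm description       Q_in  reduction
case      ND  No devices 185.652751        NaN
case   Stent SVB-2.25x15  16.839418       90.9
case Contour   CNS014-15  75.334724       59.4
```

`Q_in` is the directional influx through the neck plane in ml/min (it
exceeds the parent flow untreated because the sac exchanges recirculating
flow with the main stream); `reduction` is the percentage cut relative to
the untreated arm — both devices isolate the sac, the braided stent most
strongly at this anatomy and resolution.

The same run from a shell:

```bash
aneutreat run-case --preset case-i --out results/case_i
aneutreat size-device --dn 3.11 --da 5.56          # CNS21007-15
```

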