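{
  "contour": [
    {
      "product_code": "CNS21005-15",
      "family": "contour",
      "microcatheter_id": 0.021,
      "nominal_diameter": 5.0,
      "dn_range": [2.0, 3.0],
      "da_range": [2.0, 3.5],
      "wires_per_layer": 72,
      "layers": 2,
      "nominal_porosity": null,
      "nominal_pore_density": null
    },
    {
      "product_code": "CNS21007-15",
      "family": "contour",
      "microcatheter_id": 0.021,
      "nominal_diameter": 7.0,
      "dn_range": [3.0, 5.0],
      "da_range": [3.0, 5.5],
      "wires_per_layer": 72,
      "layers": 2,
      "nominal_porosity": null,
      "nominal_pore_density": null
    },
    {
      "product_code": "CNS21009-15",
      "family": "contour",
      "microcatheter_id": 0.021,
      "nominal_diameter": 9.0,
      "dn_range": [4.0, 6.0],
      "da_range": [5.0, 7.5],
      "wires_per_layer": 72,
      "layers": 2,
      "nominal_porosity": null,
      "nominal_pore_density": null
    },
    {
      "product_code": "CNS011-15",
      "family": "contour",
      "microcatheter_id": 0.027,
      "nominal_diameter": 11.0,
      "dn_range": [5.0, 8.0],
      "da_range": [7.0, 8.5],
      "wires_per_layer": 72,
      "layers": 2,
      "nominal_porosity": null,
      "nominal_pore_density": null
    },
    {
      "product_code": "CNS014-15",
      "family": "contour",
      "microcatheter_id": 0.027,
      "nominal_diameter": 14.0,
      "dn_range": [7.0, 10.0],
      "da_range": [8.0, 10.5],
      "wires_per_layer": 72,
      "layers": 2,
      "nominal_porosity": null,
      "nominal_pore_density": null
    }
  ],
  "braided_stent": [
    {
      "product_code": "SVB-2.25x15",
      "family": "braided_stent",
      "microcatheter_id": 0.017,
      "nominal_diameter": 2.25,
      "length": 15.0,
      "wires_per_layer": 48,
      "layers": 1,
      "nominal_porosity": 0.60,
      "nominal_pore_density": 45.0
    },
    {
      "product_code": "SVB-3x15",
      "family": "braided_stent",
      "microcatheter_id": 0.017,
      "nominal_diameter": 3.0,
      "length": 15.0,
      "wires_per_layer": 48,
      "layers": 1,
      "nominal_porosity": 0.60,
      "nominal_pore_density": 45.0
    }
  ]
}
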