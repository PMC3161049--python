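{
  "description": "Per-temperature reference parameters for COS-7 osmotic volumetry. Volumes in um^3, areas in um^2, osmolality in Osm/kg, osmoles in Osm. 'printed' blocks are the published reference values; derived quantities (V_iso, A, N) are recomputed from V_c_iso, V_b and M_iso by the package. The published 22C area (1021) is not the sphere area of the 22C volume (which is ~1077) and is kept only as a printed reference constant.",
  "constants": {
    "R_gas_um3_atm_per_mol_K": 8.21e13,
    "R_cal_per_mol_K": 1.987,
    "kelvin_offset": 273.15,
    "isotonic_osmolality_osm_per_kg": 0.308
  },
  "temperatures_c": {
    "0": {
      "printed": {"V_c_iso": 3853, "V_b": 1116, "V_iso": 2737, "A": 1188, "N": 8.43e-13},
      "lp_hyper_um_per_min_atm": 0.11,
      "lp_hypo_um_per_min_atm": 0.79,
      "equilibrium_cell_volume_hyper_um3": 2199,
      "equilibrium_cell_volume_hypo_um3": 7090
    },
    "10": {
      "printed": {"V_c_iso": 3920, "V_b": 1135, "V_iso": 2785, "A": 1202, "N": 8.58e-13},
      "lp_hyper_um_per_min_atm": 0.21,
      "lp_hypo_um_per_min_atm": 1.73,
      "equilibrium_cell_volume_hyper_um3": 2626,
      "equilibrium_cell_volume_hypo_um3": 6782
    },
    "22": {
      "printed": {"V_c_iso": 3324, "V_b": 963, "V_iso": 2361, "A": 1021, "N": 7.27e-13},
      "lp_hyper_um_per_min_atm": 0.10,
      "lp_hypo_um_per_min_atm": 1.87,
      "equilibrium_cell_volume_hyper_um3": 1762,
      "equilibrium_cell_volume_hypo_um3": 6548
    }
  },
  "test_osmolalities_mosm_per_kg": [157, 242, 308, 602, 986]
}
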