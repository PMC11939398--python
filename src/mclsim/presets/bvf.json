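{
 "initial_state": {
  "q_ecmo": 0.0,
  "v_la": 330.3532597885583,
  "v_lv": 122.6862835087619,
  "v_ra": 136.68992829499254,
  "v_rv": 210.16176358848313,
  "water_aoc": 887.8512555311969,
  "water_pac": 1519.5775010040265,
  "water_pvc": 2055.644690653925,
  "water_svc": 1496.6091218622535
 },
 "params": {
  "aoc": {
   "air_volume_ref": 1200.0,
   "pressure_abs_ref": 760.0,
   "water_volume": 893.0,
   "water_volume_ref": 800.0
  },
  "aortic": {
   "name": "aortic",
   "resistance": 0.05
  },
  "configuration": "BVFS",
  "coupling": {
   "alpha_lr": 0.0,
   "alpha_rl": 0.0,
   "pericardial_enabled": true,
   "pericardial_stiffness": 0.28857517758678475,
   "pericardial_v0": 330.0
  },
  "ecmo": {
   "c0": 2.6e-05,
   "c1": 0.0,
   "c2": -4.0,
   "enabled": false,
   "inertance": 0.05,
   "r_drainage": 2.8,
   "r_return": 2.8,
   "return_site": "retrograde_femoral",
   "speed": 3000.0
  },
  "fs": {
   "e_max_bounds": [
    0.05,
    12.0
   ],
   "enabled": true,
   "gain": 0.3,
   "intercept_lv": -60.016151944426426,
   "intercept_rv": -31.43871915079295,
   "slope_lv": 4.0,
   "slope_rv": 2.0
  },
  "heart_rate": 60.0,
  "left": {
   "e_max": 0.9510484402590702,
   "e_min": 0.31480999446324365,
   "side": "left",
   "v0": 20.0
  },
  "mitral": {
   "name": "mitral",
   "resistance": 0.02
  },
  "pac": {
   "air_volume_ref": 16000.0,
   "pressure_abs_ref": 760.0,
   "water_volume": 1600.0,
   "water_volume_ref": 800.0
  },
  "pulmonary": {
   "name": "pulmonary",
   "resistance": 0.04
  },
  "pvc": {
   "air_volume_ref": 30000.0,
   "pressure_abs_ref": 760.0,
   "water_volume": 1284.0,
   "water_volume_ref": 800.0
  },
  "right": {
   "e_max": 0.23772622578914213,
   "e_min": 0.17478899411333343,
   "side": "right",
   "v0": 20.0
  },
  "svc": {
   "air_volume_ref": 16000.0,
   "pressure_abs_ref": 760.0,
   "water_volume": 995.0,
   "water_volume_ref": 800.0
  },
  "total_fluid_volume": 6759.573804232198,
  "tricuspid": {
   "name": "tricuspid",
   "resistance": 0.02
  },
  "vascular": {
   "c_la": 10.0,
   "c_ra": 4.0,
   "clamp_factor": 1.0,
   "r_lower_body": 2.3522993613459766,
   "r_pulm_venous": 0.015,
   "r_pulmonary": 0.11115607414535716,
   "r_upper_body": 2.3522993613459766,
   "r_venous_return": 0.03,
   "v_la0": 0.0,
   "v_ra0": 0.0
  },
  "waveform": {
   "n1": 1.9,
   "n2": 21.9,
   "systolic_fraction": 0.3,
   "tau1": null,
   "tau2": null
  }
 }
}
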