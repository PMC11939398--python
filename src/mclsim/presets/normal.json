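{
 "initial_state": {
  "q_ecmo": 0.0,
  "v_la": 117.14804497607996,
  "v_lv": 126.98397094148113,
  "v_ra": 20.948705730109076,
  "v_rv": 155.4873155029849,
  "water_aoc": 873.3314265706607,
  "water_pac": 1197.59699600977,
  "water_pvc": 1297.989921175575,
  "water_svc": 967.0119269355877
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
   "intercept_lv": -137.2392092611544,
   "intercept_rv": 8.578548799874863,
   "slope_lv": 18.0,
   "slope_rv": 2.0
  },
  "heart_rate": 60.0,
  "left": {
   "e_max": 2.0904626476364685,
   "e_min": 0.1,
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
   "e_max": 0.3889337443914969,
   "e_min": 0.02532470984331299,
   "side": "right",
   "v0": 20.0
  },
  "svc": {
   "air_volume_ref": 16000.0,
   "pressure_abs_ref": 760.0,
   "water_volume": 995.0,
   "water_volume_ref": 800.0
  },
  "total_fluid_volume": 4756.498307842248,
  "tricuspid": {
   "name": "tricuspid",
   "resistance": 0.02
  },
  "vascular": {
   "c_la": 10.0,
   "c_ra": 4.0,
   "clamp_factor": 1.0,
   "r_lower_body": 1.6182441431092307,
   "r_pulm_venous": 0.015,
   "r_pulmonary": 0.1035,
   "r_upper_body": 1.6182441431092307,
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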