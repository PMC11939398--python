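{
 "initial_state": {
  "q_ecmo": 0.0,
  "v_la": 163.669084091737,
  "v_lv": 107.25677449141803,
  "v_ra": 12.103234217264047,
  "v_rv": 82.91611607158829,
  "water_aoc": 878.4017087933044,
  "water_pac": 1011.0526332225841,
  "water_pvc": 1209.9505174965154,
  "water_svc": 874.6499316156002
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
   "intercept_lv": -418.64518145567564,
   "intercept_rv": 5.333725516803497,
   "slope_lv": 12.0,
   "slope_rv": 12.0
  },
  "heart_rate": 60.0,
  "left": {
   "e_max": 1.5579368025528775,
   "e_min": 0.4681400907948946,
   "side": "left",
   "v0": 20.0
  },
  "mitral": {
   "name": "mitral",
   "resistance": 0.02
  },
  "pac": {
   "air_volume_ref": 4000.0,
   "pressure_abs_ref": 760.0,
   "water_volume": 1028.0,
   "water_volume_ref": 800.0
  },
  "pulmonary": {
   "name": "pulmonary",
   "resistance": 0.04
  },
  "pvc": {
   "air_volume_ref": 8000.0,
   "pressure_abs_ref": 760.0,
   "water_volume": 1210.0,
   "water_volume_ref": 800.0
  },
  "right": {
   "e_max": 2.102893826251617,
   "e_min": 0.03093182831656592,
   "side": "right",
   "v0": 20.0
  },
  "svc": {
   "air_volume_ref": 16000.0,
   "pressure_abs_ref": 760.0,
   "water_volume": 995.0,
   "water_volume_ref": 800.0
  },
  "total_fluid_volume": 4340.000000000012,
  "tricuspid": {
   "name": "tricuspid",
   "resistance": 0.02
  },
  "vascular": {
   "c_la": 4.0,
   "c_ra": 4.0,
   "clamp_factor": 1.0,
   "femoral_position": 0.1,
   "r_lower_body": 2.8438167237515426,
   "r_pulm_venous": 0.015,
   "r_pulmonary": 0.07748727854392648,
   "r_upper_body": 2.8438167237515426,
   "r_venous_return": 0.01,
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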