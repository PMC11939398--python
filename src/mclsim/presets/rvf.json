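{
 "initial_state": {
  "q_ecmo": 0.0,
  "v_la": 131.63581543255071,
  "v_lv": 140.8955703767362,
  "v_ra": 129.7539732594824,
  "v_rv": 198.07568353727515,
  "water_aoc": 882.2591847721621,
  "water_pac": 1406.4018095045715,
  "water_pvc": 1329.6567270901264,
  "water_svc": 1473.0882748756865
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
   "intercept_lv": 20.88036899581649,
   "intercept_rv": -32.51619179198782,
   "slope_lv": 4.0,
   "slope_rv": 2.0
  },
  "heart_rate": 60.0,
  "left": {
   "e_max": 0.93375400212876,
   "e_min": 0.08465616543378886,
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
   "e_max": 0.1665631267859983,
   "e_min": 0.163884039798433,
   "side": "right",
   "v0": 20.0
  },
  "svc": {
   "air_volume_ref": 16000.0,
   "pressure_abs_ref": 760.0,
   "water_volume": 995.0,
   "water_volume_ref": 800.0
  },
  "total_fluid_volume": 5691.767038848591,
  "tricuspid": {
   "name": "tricuspid",
   "resistance": 0.02
  },
  "vascular": {
   "c_la": 10.0,
   "c_ra": 4.0,
   "clamp_factor": 1.0,
   "r_lower_body": 1.519431163268761,
   "r_pulm_venous": 0.015,
   "r_pulmonary": 0.414,
   "r_upper_body": 1.519431163268761,
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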