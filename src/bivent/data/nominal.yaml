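animal:
  lv:
    emax: 0.85
    emin: 0.046
    v0: 13.0
    act_tau1: 0.269
    act_tau2: 0.452
    act_n1: 1.32
    act_n2: 21.9
  rv:
    emax: 0.26
    emin: 0.034
    v0: 10.0
    act_tau1: 0.269
    act_tau2: 0.452
    act_n1: 1.32
    act_n2: 21.9
  circuit:
    r_av: 0.008
    r_sys_art: 0.612
    r_sys_ven: 0.008
    r_tv: 0.002
    r_pv: 0.006
    r_pul_art: 0.0602
    r_pul_ven: 0.009
    r_mv: 0.006
    c_sys_art: 1.3
    c_sys_ven: 107.0
    c_pul_art: 2.7
    c_pul_ven: 14.0
    total_volume: 4439.0
    vu_sys_art: 450.0
    vu_sys_ven: 2150.0
    vu_pul_art: 80.0
    vu_pul_ven: 250.0
    infusion_rate: 1000.0
  pericardium:
    gain: 2.0
    steepness: 0.011
    v_ref: 315.0
  pump:
    max_flow: 3.5
    head_slope: 0.1
    suction_volume: 40.0
    suction_width: 5.0
    enabled: false
  ne:
    eff_lv_emax: 2.65
    eff_rv_emax: 0.55
    eff_hr: 0.185
    eff_svr: 0.064
    eff_pvr: 0.506
    eff_venous_unstressed: -0.155
    d50: 0.089
    dose: 0.0
  shock:
    lv_emax_step: 0.111
    rv_emax_step: 0.013
    rv_emin_step: 0.056
    pvr_step: 0.102
    volume_per_injection: 27.0
    max_injections: 15
    svo2_drop_fraction: 0.5
    svo2_floor: 30.0
    co_ceiling: 2.0
  o2:
    vo2: 232.0
    hb: 10.0
    sao2: 0.98
    k_o2: 1.34
  lv_sensor:
    alpha: 1.25
    parallel_volume: 50.0
    noise_sd: 2.0
    segment_constant: 1.0
  rv_sensor:
    alpha: 1.1
    parallel_volume: 60.0
    noise_sd: 2.0
    segment_constant: 1.0
  heart_rate: 82.0
  variability:
    lv.emax+rv.emax: 0.1
    lv.emax: 0.04
    rv.emax: 0.04
    lv.emin+rv.emin: 0.06
    lv.emin: 0.02
    rv.emin: 0.02
    circuit.r_sys_art: 0.1
    circuit.r_pul_art: 0.08
    circuit.c_sys_art: 0.08
    circuit.total_volume: 0.03
    o2.vo2: 0.06
    heart_rate: 0.05
    pericardium.gain: 0.08
  seed: 0
protocol:
  settle_duration: 22.0
  stage_duration: 12.0
  analysis_beats: 10
  occlusion_ramp: 8.0
  occlusion_multiplier: 25.0
  saline_duration: 9.0
  saline_gain: 1.3
  saline_lead_in: 10.0
  saline_repeats: 6
  map_threshold: 45.0
  dose_grid:
  - 0.0
  - 0.05
  - 0.1
  - 0.15
  - 0.2
  - 0.25
  - 0.3
  escalation_dose: 0.1
  stage3_volume: -250.0
  stage4_volume: 101.0
  include_escalation: true
  calibrate_per_stage: false
  espvr_r2_warn: 0.9
cohort:
  n: 18
  escalation_n: 8
  seed: 1
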