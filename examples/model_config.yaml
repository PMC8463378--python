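# Example model configuration (synthetic placeholder decay curves).
cohort_mix:
  p_lvo: 0.6
  p_nlvo: 0.3
  p_other: 0.1
  p_good_other: 0.9
  p_good_lvo_untreated: 0.1
  p_good_nlvo_untreated: 0.35
treatment_rates:
  evt_rate: 0.9
  ivt_rate: 0.8
  ivt_window: 270.0
curves:
  evt:
    kind: logistic
    p0: 0.65
    p_floor: 0.1
    t_max: 480.0
    shape: 90.0
  ivt_lvo:
    kind: logistic
    p0: 0.3
    p_floor: 0.1
    t_max: 270.0
    shape: 60.0
  ivt_nlvo:
    kind: logistic
    p0: 0.6
    p_floor: 0.35
    t_max: 270.0
    shape: 60.0
workflow:
  onset_to_fmr: 30.0
  on_scene: 30.0
  dtn_psc: 30.0
  ntd_psc: 20.0
  dtn_csc: 30.0
  dtg_csc: 60.0
  dtg_csc_fast: 30.0
  reimage_window: 90.0
  ntl_dd: 10.0
  arr_to_groin_dd: 20.0
  imaging_offset_psc: 0.0
delta_mode: absolute
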