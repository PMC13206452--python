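# Standard-dose interaction design: perpetrator once daily days 1-14
# (7 pre-treatment days), victim 600 mg twice daily days 8-14; PK read out
# over the final 12-h interval.  The control arm runs the identical victim
# schedule alone.
scenarios:
  - id: monotherapy
    victim_regimen: &victim_bid
      route: oral
      dose: 600.0
      interval_h: 12.0
      n_doses: 14
      start_time_h: 168.0
    perpetrator_regimen: null

  - id: ddi_abcb1
    victim_regimen: *victim_bid
    perpetrator_regimen: &rif_standard
      route: oral
      dose: 600.0
      interval_h: 24.0
      n_doses: 14
      start_time_h: 0.0
    mechanism_flags:
      abcb1_induction: true
      abcb1_inhibition: true
      abcg2_inhibition: false
      abcg2_static_fold: false

  - id: ddi_combined
    victim_regimen: *victim_bid
    perpetrator_regimen: *rif_standard
    mechanism_flags: &all_flags
      abcb1_induction: true
      abcb1_inhibition: true
      abcg2_inhibition: true
      abcg2_static_fold: true

  - id: sensitivity_nilles
    victim_regimen: *victim_bid
    perpetrator_regimen: *rif_standard
    mechanism_flags: *all_flags
    parameter_set: nilles

  - id: sensitivity_asaumi
    victim_regimen: *victim_bid
    perpetrator_regimen: *rif_standard
    mechanism_flags: *all_flags
    parameter_set: asaumi
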