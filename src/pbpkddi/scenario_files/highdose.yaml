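# High-dose perpetrator sweep: rifampin 10-40 mg/kg once daily days 1-14,
# victim 600 mg twice daily days 8-14, combined ABCB1 + ABCG2 mechanisms.
scenarios:
  - id: highdose_10
    victim_regimen: &victim_bid
      route: oral
      dose: 600.0
      interval_h: 12.0
      n_doses: 14
      start_time_h: 168.0
    perpetrator_regimen:
      route: oral
      dose: 10.0
      per_kg: true
      interval_h: 24.0
      n_doses: 14
      start_time_h: 0.0
    mechanism_flags: &all_flags
      abcb1_induction: true
      abcb1_inhibition: true
      abcg2_inhibition: true
      abcg2_static_fold: true

  - id: highdose_20
    victim_regimen: *victim_bid
    perpetrator_regimen:
      route: oral
      dose: 20.0
      per_kg: true
      interval_h: 24.0
      n_doses: 14
      start_time_h: 0.0
    mechanism_flags: *all_flags

  - id: highdose_25
    victim_regimen: *victim_bid
    perpetrator_regimen:
      route: oral
      dose: 25.0
      per_kg: true
      interval_h: 24.0
      n_doses: 14
      start_time_h: 0.0
    mechanism_flags: *all_flags

  - id: highdose_30
    victim_regimen: *victim_bid
    perpetrator_regimen:
      route: oral
      dose: 30.0
      per_kg: true
      interval_h: 24.0
      n_doses: 14
      start_time_h: 0.0
    mechanism_flags: *all_flags

  - id: highdose_35
    victim_regimen: *victim_bid
    perpetrator_regimen:
      route: oral
      dose: 35.0
      per_kg: true
      interval_h: 24.0
      n_doses: 14
      start_time_h: 0.0
    mechanism_flags: *all_flags

  - id: highdose_40
    victim_regimen: *victim_bid
    perpetrator_regimen:
      route: oral
      dose: 40.0
      per_kg: true
      interval_h: 24.0
      n_doses: 14
      start_time_h: 0.0
    mechanism_flags: *all_flags
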