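# Default 12-state advanced-PD template.
# hy_stage gives the upper stage of the band (2-3 -> 3); off_stratum splits
# waking OFF time at 50%.  Utilities are severity-ordered defaults that the
# per-therapy calibration rescales; per-cycle state costs default to 0
# because therapy costs are handled by the costing module.
cycle_length: 1.0
states:
  - {id: hy23_low_off,  flag: on_treatment, hy_stage: 3, off_stratum: low_off,  utility: 0.72, cost_per_cycle: 0.0}
  - {id: hy23_high_off, flag: on_treatment, hy_stage: 3, off_stratum: high_off, utility: 0.58, cost_per_cycle: 0.0}
  - {id: hy4_low_off,   flag: on_treatment, hy_stage: 4, off_stratum: low_off,  utility: 0.50, cost_per_cycle: 0.0}
  - {id: hy4_high_off,  flag: on_treatment, hy_stage: 4, off_stratum: high_off, utility: 0.38, cost_per_cycle: 0.0}
  - {id: hy5_low_off,   flag: on_treatment, hy_stage: 5, off_stratum: low_off,  utility: 0.30, cost_per_cycle: 0.0}
  - {id: hy5_high_off,  flag: on_treatment, hy_stage: 5, off_stratum: high_off, utility: 0.18, cost_per_cycle: 0.0}
  - {id: surgery_complication, flag: surgery_complication, utility: 0.40, cost_per_cycle: 0.0}
  - {id: peg_complication,     flag: peg_complication,     utility: 0.40, cost_per_cycle: 0.0}
  - {id: ae_discontinued,      flag: ae_discontinued,      utility: 0.35, cost_per_cycle: 0.0}
  - {id: switched,             flag: switched,             utility: 0.45, cost_per_cycle: 0.0}
  - {id: second_line,          flag: on_treatment,         utility: 0.40, cost_per_cycle: 0.0}
  - {id: dead,                 flag: dead,                 utility: 0.0,  cost_per_cycle: 0.0}
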