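# Built-in strain x dose calibrations (schema v1).
#
# Whole-lane RDH folds are relative to the rnhAB log culture (= 1.0).
# Repair is two-class exponential (fast = bulk NER, slow = TEC-stalled,
# RDH-anchoring lesions) with a short post-UV lag before excision starts.
# All calibration constants live here, not in code.
schema: 1

_defaults: &defaults
  dose: 36.0
  pd_induction_rate: 41.7
  genome_length: 9200000
  fast_half_life: 7.0
  repair_lag: 5.0
  rdh_length_mean: 6000.0
  rdh_length_dispersion: 0.30
  reference_rdh_nt: 23000.0
  baseline_hybrid_length: 300.0
  baseline_long_fraction: 0.0
  noise_cv: 0.05
  batch_noise_cv: 0.25
  pd_channel_background: 1.1e-04
  s96_channel_background: 5.0e-04
  background_nicks_per_genome: 45.0

scenarios:
  WT:
    <<: *defaults
    slow_pd_fraction: 0.02
    slow_half_life: 15.0
    rdh_log_fold: 0.10
    rdh_fold_table: {0: 0.10, 10: 0.10, 30: 0.20, 60: 0.40, 120: 0.15}
    rdh_dispersed_fraction: 0.5
    survival_by_dose: {0.0: 1.0, 2.0: 0.95, 8.0: 0.8, 36.0: 0.5}
    synthesis_rate_no_uv: [[0, 1.0], [180, 1.0]]
    synthesis_rate_uv:
      [[0, 1.0], [5, 0.08], [30, 0.08], [45, 1.05], [180, 1.2]]

  rnhA:
    <<: *defaults
    slow_pd_fraction: 0.06
    slow_half_life: 60.0
    rdh_log_fold: 0.30
    rdh_fold_table: {0: 0.30, 10: 0.30, 30: 1.1, 60: 2.7, 120: 1.0}
    rdh_dispersed_fraction: 0.5
    survival_by_dose: {0.0: 1.0, 8.0: 0.5, 36.0: 0.1}

  rnhB:
    <<: *defaults
    slow_pd_fraction: 0.02
    slow_half_life: 15.0
    rdh_log_fold: 0.12
    rdh_fold_table: {0: 0.12, 10: 0.12, 30: 0.24, 60: 0.48, 120: 0.2}
    rdh_dispersed_fraction: 0.5
    survival_by_dose: {0.0: 1.0, 8.0: 0.75, 36.0: 0.45}

  rnhAB:
    <<: *defaults
    slow_pd_fraction: 0.12
    slow_half_life: 100.0
    rdh_log_fold: 1.0
    rdh_fold_table: {0: 1.0, 10: 1.0, 30: 6.0, 60: 13.0, 120: 13.0, 180: 12.0}
    rdh_dispersed_fraction: 0.15
    survival_by_dose: {0.0: 1.0, 2.0: 0.7, 4.0: 0.5, 8.0: 0.1, 36.0: 0.02}
    synthesis_rate_no_uv: [[0, 0.5], [180, 0.5]]
    synthesis_rate_uv:
      [[0, 1.0], [5, 0.05], [50, 0.05], [90, 0.5], [120, 0.55], [180, 0.55]]

  rnhAB_rpoB35:
    <<: *defaults
    slow_pd_fraction: 0.02
    slow_half_life: 15.0
    rdh_log_fold: 0.6
    rdh_fold_table: {0: 0.6, 10: 0.6, 30: 1.2, 60: 3.0, 120: 0.8}
    rdh_dispersed_fraction: 0.5
    survival_by_dose: {0.0: 1.0, 36.0: 0.4}

  uvrA:
    <<: *defaults
    slow_pd_fraction: 0.02
    fast_half_life: null      # NER-deficient: PDs are never excised
    slow_half_life: null
    rdh_log_fold: 0.10
    rdh_fold_table: {0: 0.10, 10: 0.25, 30: 0.40, 60: 0.45}
    rdh_dispersed_fraction: 1.0
    survival_by_dose: {0.0: 1.0, 2.0: 0.2, 8.0: 0.001}
    synthesis_rate_no_uv: [[0, 1.0], [180, 1.0]]
    synthesis_rate_uv: [[0, 1.0], [5, 0.03], [180, 0.03]]

  # Excision-deficient double-RNase-H mutant used for DRIP at low dose.
  # The PD density anchor here is 1 PD per 10 kb after 8 J/m^2 (rate 115),
  # the value the co-occurrence model uses; the 36 J/m^2 scenarios keep the
  # plasmid-relaxation anchor of ~42/J/m^2.  The two are not reconciled.
  rnhAB_uvrA:
    <<: *defaults
    dose: 8.0
    pd_induction_rate: 115.0
    slow_pd_fraction: 0.12
    fast_half_life: null
    slow_half_life: null
    rdh_length_mean: 1200.0
    rdh_length_dispersion: 0.35
    rdh_log_fold: 0.1
    rdh_fold_table: {0: 0.1, 10: 0.8, 30: 2.2, 60: 4.5}
    rdh_dispersed_fraction: 0.0
    p_capture_specific: 0.70
    p_capture_background: 5.0e-04
    capture_saturation_nt: 1100.0
    rnase_survival: 0.01
    survival_by_dose: {0.0: 1.0, 0.6: 0.05}

  recF:
    <<: *defaults
    slow_pd_fraction: 0.02
    slow_half_life: 15.0
    rdh_log_fold: 0.10
    rdh_fold_table: {0: 0.10, 60: 0.40}
    rdh_dispersed_fraction: 0.5
    survival_by_dose: {0.0: 1.0, 2.0: 0.6, 4.0: 0.3, 8.0: 0.05}

  # Built multiplicatively from recF x rnhAB (no genetic interaction).
  recF_rnhAB:
    <<: *defaults
    slow_pd_fraction: 0.12
    slow_half_life: 100.0
    rdh_log_fold: 1.0
    rdh_fold_table: {0: 1.0, 60: 13.0}
    rdh_dispersed_fraction: 0.35
    survival_by_dose: {0.0: 1.0, 2.0: 0.42, 4.0: 0.15, 8.0: 0.005}
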