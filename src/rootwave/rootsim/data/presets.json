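{
  "_comment": "Scenario presets for osmotic-stress calcium waves in the primary root. Speeds in µm/s, signed: positive = shoot-ward, negative = tip-ward. amplitude_fold = plateau/baseline. n_replicates = replicate count of the underlying experiment. Fields marked in 'placeholder' are free simulator parameters not backed by a measured value.",
  "presets": {
    "control": {
      "treatment_site": "tip",
      "sidedness": "full",
      "init_arclength_um": 0.0,
      "longitudinal_speed_um_s": 1.0,
      "amplitude_fold": 1.0,
      "n_replicates": 3,
      "description": "Control media only: no calcium front, baseline fluorescence throughout."
    },
    "nacl_dz_full": {
      "treatment_site": "differentiation_zone",
      "sidedness": "full",
      "init_arclength_um": 2300.0,
      "longitudinal_speed_um_s": -6.8,
      "amplitude_fold": 1.5,
      "n_replicates": 10,
      "description": "100 mM NaCl at the differentiation zone, both flanks: 1.5-fold rise, tip-ward wave at 6.8 µm/s."
    },
    "peg_dz_full": {
      "treatment_site": "differentiation_zone",
      "sidedness": "full",
      "init_arclength_um": 2300.0,
      "longitudinal_speed_um_s": -11.6,
      "amplitude_fold": 1.5,
      "n_replicates": 5,
      "description": "20% PEG at the differentiation zone, both flanks: 1.5-fold rise, tip-ward wave at 11.6 µm/s."
    },
    "nacl_tip_full": {
      "treatment_site": "tip",
      "sidedness": "full",
      "init_arclength_um": 0.0,
      "longitudinal_speed_um_s": 5.9,
      "amplitude_fold": 2.5,
      "n_replicates": 10,
      "description": "100 mM NaCl at the tip, both flanks: 2.5-fold burst at the columella, shoot-ward wave at 5.9 µm/s."
    },
    "peg_tip_full": {
      "treatment_site": "tip",
      "sidedness": "full",
      "init_arclength_um": 0.0,
      "longitudinal_speed_um_s": 10.5,
      "amplitude_fold": 4.0,
      "n_replicates": 5,
      "description": "20% PEG at the tip, both flanks: 4-fold burst at the columella, shoot-ward wave at 10.5 µm/s."
    },
    "nacl_dz_oneside": {
      "treatment_site": "differentiation_zone",
      "sidedness": "one_sided",
      "init_arclength_um": 2300.0,
      "longitudinal_speed_um_s": -5.2,
      "transverse_speed_um_s": 9.4,
      "treated_flank": -1,
      "crosses_midline": true,
      "amplitude_fold": 1.5,
      "n_replicates": 10,
      "description": "One-sided 100 mM NaCl at the differentiation zone: transverse wave at 9.4 µm/s crossing to the untreated flank, secondary tip-ward wave at 5.2 µm/s."
    },
    "peg_dz_oneside": {
      "treatment_site": "differentiation_zone",
      "sidedness": "one_sided",
      "init_arclength_um": 2300.0,
      "longitudinal_speed_um_s": 11.0,
      "bidirectional": true,
      "transverse_speed_um_s": 14.0,
      "treated_flank": -1,
      "crosses_midline": false,
      "amplitude_fold": 1.5,
      "n_replicates": 5,
      "placeholder": ["transverse_speed_um_s"],
      "description": "One-sided 20% PEG at the differentiation zone: fast transverse response confined to the treated flank, bidirectional longitudinal wave at ±11 µm/s."
    },
    "nacl_tip_oneside": {
      "treatment_site": "tip",
      "sidedness": "one_sided",
      "init_arclength_um": 0.0,
      "longitudinal_speed_um_s": 4.2,
      "transverse_speed_um_s": 9.4,
      "treated_flank": -1,
      "crosses_midline": true,
      "amplitude_fold": 2.5,
      "n_replicates": 5,
      "placeholder": ["transverse_speed_um_s"],
      "description": "One-sided 100 mM NaCl at the tip: 2.5-fold burst on the treated columella flank, shoot-ward wave at 4.2 µm/s."
    },
    "peg_tip_oneside": {
      "treatment_site": "tip",
      "sidedness": "one_sided",
      "init_arclength_um": 0.0,
      "longitudinal_speed_um_s": 14.2,
      "transverse_speed_um_s": 14.0,
      "treated_flank": -1,
      "crosses_midline": true,
      "amplitude_fold": 3.0,
      "n_replicates": 5,
      "placeholder": ["transverse_speed_um_s"],
      "description": "One-sided 20% PEG at the tip: 3-fold burst (0.5-fold above the NaCl counterpart), shoot-ward wave at 14.2 µm/s."
    }
  }
}
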