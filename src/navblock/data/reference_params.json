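{
  "description": "Reference constants for hNav1.5 state-dependent block, taken from published whole-cell patch-clamp measurements of heterologously expressed channels. Concentrations in uM, voltages in mV. kon values and the F1760A affinity scales are simulator calibration choices, not measured quantities (the scale defaults derive from the ratio of published mutant to wild-type tonic-block Kd values).",
  "compounds": {
    "BPA": {
      "Kr_uM": 58.6,
      "Kr_se_uM": 8.0,
      "Ki_uM": 8.2,
      "Ki_se_uM": 2.4,
      "reference_concentration_uM": 30.0,
      "tonic_Kd_uM_at_-120mV": 74.0,
      "tonic_Kd_se_uM_at_-120mV": 7.6,
      "tonic_Kd_uM_at_-90mV": 25.4,
      "tonic_Kd_se_uM_at_-90mV": 1.3,
      "tonic_Kd_uM_F1760A": 104.1,
      "tonic_Kd_se_uM_F1760A": 6.7,
      "ssfi_shift_mV_at_100uM": -15.8,
      "kon_per_uM_ms": 0.001,
      "f1760a_affinity_scale": 1.41,
      "note": "resting/inactivated dissociation constants measured at 30 uM; tonic-block Kd from Hill fits of dose-response data at the indicated holding potentials"
    },
    "mexiletine": {
      "Kr_uM": 606.2,
      "Kr_se_uM": 127.5,
      "Ki_uM": 6.6,
      "Ki_se_uM": 1.9,
      "reference_concentration_uM": 150.0,
      "tonic_Kd_uM_at_-120mV": 595.9,
      "tonic_Kd_se_uM_at_-120mV": 41.8,
      "tonic_Kd_uM_F1760A": 1142.5,
      "tonic_Kd_se_uM_F1760A": 94.0,
      "ssfi_shift_mV_at_150uM": -12.7,
      "kon_per_uM_ms": 0.001,
      "f1760a_affinity_scale": 1.92,
      "note": "class 1B antiarrhythmic used as the local-anesthetic comparator; resting/inactivated constants measured at 150 uM"
    }
  },
  "boltzmann": {
    "WT_inactivation": {"Vhalf_mV": -90.4, "Vhalf_se_mV": 0.8, "k_mV": 5.1, "k_se_mV": 0.1},
    "F1760A_inactivation": {"Vhalf_mV": -79.9, "Vhalf_se_mV": 0.6, "k_mV": 5.8, "k_se_mV": 0.1},
    "WT_activation": {"Vhalf_mV": -32.0, "Vhalf_se_mV": 2.5},
    "WT_inactivation_pre_100uM_BPA": {"Vhalf_mV": -89.3, "Vhalf_se_mV": 1.5, "k_mV": 5.6, "k_se_mV": 0.3},
    "WT_inactivation_post_100uM_BPA": {"Vhalf_mV": -105.1, "Vhalf_se_mV": 2.1, "k_mV": 6.5, "k_se_mV": 0.2},
    "note": "availability (steady-state fast inactivation) and activation midpoints/slopes of drug-free wild-type and F1760A channels, and the paired pre/post availability fits around 100 uM BPA application"
  },
  "kinetics": {
    "decay_tau_ms_at_-10mV": 1.1,
    "decay_tau_se_ms": 0.08,
    "note": "single-exponential decay time constant of the whole-cell current at a -10 mV test pulse, drug-free"
  }
}
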