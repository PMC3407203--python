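{
 "cell_id": "fixture-cell",
 "condition": {
  "compound": "BPA",
  "concentration_uM": 30.0,
  "vehicle_fraction": 0.0
 },
 "drug_onset_sweep": null,
 "format": "navblock-sweepset",
 "format_version": 1,
 "genotype": "WT",
 "n_rows": 15,
 "n_sweep_columns": 2,
 "protocol": {
  "epochs": [
   [
    -120.0,
    5.0
   ],
   [
    "VAR",
    10.0
   ]
  ],
  "holding_mV": -120.0,
  "inter_sweep_interval_s": 1.0,
  "n_sweeps": 2,
  "name": "mini",
  "sampling_rate_kHz": 1.0,
  "sweep_values_mV": [
   -10.0,
   0.0
  ]
 }
}
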