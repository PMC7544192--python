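{
  "intercept": -76.12557823608422,
  "slope": 3.5646293353439606,
  "training_summary": {
    "clean_mean": 20.548405475639555,
    "clean_sd": 0.5684024501828165,
    "contam_mean": 22.987920237076633,
    "contam_sd": 1.3344125217477947,
    "auc": 0.974375
  },
  "n_train": 80,
  "calibration_id": "default_sim_seed20240901"
}
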