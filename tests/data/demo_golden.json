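{
  "comparison_F": 3.104355776102779,
  "comparison_p": 0.05,
  "criticism_removed": 36,
  "deviance_explained_linear": 0.1422899117,
  "deviance_explained_tensor": 0.1487936235,
  "edf_te": 12.5694230108,
  "n": 3954,
  "parametric_tensor": {
    "Intercept": 5.3291960469,
    "length": 0.0074065452,
    "log_frequency": -0.0005565316,
    "position": -0.0088553704
  },
  "preferred_form": "tensor"
}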