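{
  "form": "linear",
  "predictor": "dbh",
  "n_trees": 12,
  "equations": {
    "stem": {
      "beta0": 0.679,
      "beta1": -0.0188,
      "se0": 0.0468,
      "se1": 0.0037,
      "p0": 0.0001,
      "p1": 0.0005,
      "rse": 0.0658,
      "r2": 0.7172
    },
    "branch": {
      "beta0": 0.1437,
      "beta1": 0.0222,
      "se0": 0.0506,
      "se1": 0.004,
      "p0": 0.0176,
      "p1": 0.0003,
      "rse": 0.0711,
      "r2": 0.7525
    },
    "twig": {
      "beta0": 0.1441,
      "beta1": -0.0045,
      "se0": 0.0173,
      "se1": 0.0014,
      "p0": 0.0001,
      "p1": 0.0082,
      "rse": 0.0243,
      "r2": 0.5194
    }
  },
  "correlation": [
    [1.0, -0.834, -0.14],
    [-0.834, 1.0, -0.3407],
    [-0.14, -0.3407, 1.0]
  ],
  "overall_r2": 0.73,
  "dbh_range_cm": [3.9, 19.7],
  "notes": "Final linear SUR fit with dbh as predictor; foliage ratio is the complement of the three modeled ratios. p-values reported as below 0.0001 are stored as 0.0001."
}
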