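{
  "version": "us-general-population-1990/1.0",
  "description": "1990 US general-population subscale means/SDs and orthogonal factor-score coefficients for the norm-based Physical and Mental Component Summary scores (T-score metric: mean 50, SD 10).",
  "means": {
    "PF": 84.52404,
    "RP": 81.19907,
    "BP": 75.49196,
    "GH": 72.21316,
    "VT": 61.05453,
    "SF": 83.59753,
    "RE": 81.29467,
    "MH": 74.84212
  },
  "sds": {
    "PF": 22.89490,
    "RP": 33.79729,
    "BP": 23.55879,
    "GH": 20.16964,
    "VT": 20.86942,
    "SF": 22.37642,
    "RE": 33.02717,
    "MH": 18.01189
  },
  "pcs_coefficients": {
    "PF": 0.42402,
    "RP": 0.35119,
    "BP": 0.31754,
    "GH": 0.24954,
    "VT": 0.02877,
    "SF": -0.00753,
    "RE": -0.19206,
    "MH": -0.22069
  },
  "mcs_coefficients": {
    "PF": -0.22999,
    "RP": -0.12329,
    "BP": -0.09731,
    "GH": -0.01571,
    "VT": 0.23534,
    "SF": 0.26876,
    "RE": 0.43407,
    "MH": 0.48581
  }
}
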