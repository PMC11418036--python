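{
  "version": 1,
  "populations": {
    "europe": {
      "label": "europe",
      "poly_coeffs_by_sex": {
        "M": [3.2, 0.259, -0.543, -0.00763, 7.9e-05],
        "F": [3.08, 0.177, -0.223, -0.00596, 6.86e-05]
      },
      "adult_plateau_mg_dl": {"M": 0.9, "F": 0.7},
      "reference": null
    },
    "us": {
      "label": "us",
      "poly_coeffs_by_sex": null,
      "adult_plateau_mg_dl": {"M": 0.97, "F": 0.73},
      "reference": "europe"
    }
  }
}
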