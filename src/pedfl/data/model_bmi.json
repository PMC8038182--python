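{
  "id": "bmi",
  "description": "Published BMI-based fatty-liver prediction model for obese children and adolescents (logistic scale).",
  "n": 1672,
  "intercept": -0.533,
  "terms": [
    {"variable": "age", "scale": 1, "powers": [1], "coef": [-0.137],
     "ci": [[-0.193, -0.080]], "ci_suspect": [false]},
    {"variable": "bmi", "scale": 1, "powers": [1], "coef": [0.063],
     "ci": [[0.039, 0.086]], "ci_suspect": [false]},
    {"variable": "alt", "scale": 100, "powers": [-2, -1],
     "coef": [0.036, -0.767],
     "ci": [[0.020, 0.052], [-0.943, -0.591]], "ci_suspect": [false, false]},
    {"variable": "homa", "scale": 10, "powers": [1, 2],
     "coef": [3.583, -2.634],
     "ci": [[1.775, 5.392], [-4.395, -0.873]], "ci_suspect": [false, false]},
    {"variable": "tg", "scale": 1, "powers": [1], "coef": [0.004],
     "ci": [[0.001, 0.007]], "ci_suspect": [false]},
    {"variable": "ur", "scale": 1, "powers": [1], "coef": [0.172],
     "ci": [[0.072, 0.272]], "ci_suspect": [false]}
  ],
  "fit": {"c_statistic": 0.81, "c_ci": [0.79, 0.83], "cox_snell_r2": 0.26,
          "nagelkerke_r2": 0.35, "aic": 1746, "bic": 1794}
}
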