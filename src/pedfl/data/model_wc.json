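{
  "id": "wc",
  "description": "Published waist-circumference-based fatty-liver prediction model for obese children and adolescents (logistic scale). Several printed CI bounds appear to have dropped minus signs; they are stored as printed and flagged ci_suspect.",
  "n": 1672,
  "intercept": -0.925,
  "terms": [
    {"variable": "age", "scale": 1, "powers": [1], "coef": [-0.132],
     "ci": [[-0.189, 0.075]], "ci_suspect": [true]},
    {"variable": "alt", "scale": 100, "powers": [-2, -1],
     "coef": [0.034, -0.728],
     "ci": [[0.018, 0.049], [-0.898, 0.557]], "ci_suspect": [false, true]},
    {"variable": "homa", "scale": 10, "powers": [1, 2],
     "coef": [3.848, -2.662],
     "ci": [[2.015, 5.681], [-4.490, 0.834]], "ci_suspect": [false, true]},
    {"variable": "tg", "scale": 1, "powers": [1], "coef": [0.004],
     "ci": [[0.001, 0.007]], "ci_suspect": [false]},
    {"variable": "ur", "scale": 1, "powers": [1], "coef": [0.171],
     "ci": [[0.070, 0.271]], "ci_suspect": [false]},
    {"variable": "wc", "scale": 1, "powers": [1], "coef": [0.022],
     "ci": [[0.012, 0.032]], "ci_suspect": [false]}
  ],
  "fit": {"c_statistic": 0.81, "c_ci": [0.78, 0.83], "cox_snell_r2": 0.25,
          "nagelkerke_r2": 0.34, "aic": 1755, "bic": 1804}
}
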